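"""Multichannel record container and plain-text I/O.

Recordings are stored as a CSV matrix (first column time, remaining
columns channels) plus a YAML sidecar (``<path>.meta.yaml``) carrying the
sampling rate, channel labels, units and a provenance trail. The sidecar
is authoritative for the sampling rate; a time column that disagrees with
it by more than 0.1% is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["MultiChannelRecord", "read_record", "write_record"]


@dataclass
class MultiChannelRecord:
    """An observed multichannel signal x(t).

    Parameters
    ----------
    samples : ndarray of shape (n_channels, n_samples)
        Channel amplitudes (mV-scale convention, unit-agnostic).
    fs : float
        Sampling rate in Hz, strictly positive.
    labels : list of str
        Unique per-channel labels.
    provenance : list of str
        Ordered descriptors of the processing stages already applied.
    """

    samples: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.labels) != self.n_channels:
            raise ValueError(
                f"{len(self.labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"channel labels must be unique, got {self.labels}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, stage: str) -> "MultiChannelRecord":
        """Copy of the record with new samples and one more provenance entry."""
        return MultiChannelRecord(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            labels=list(self.labels),
            provenance=list(self.provenance) + [stage],
            units=self.units,
        )

    def to_array(self) -> np.ndarray:
        """Samples as an (n_samples, n_channels) array (estimator convention)."""
        return self.samples.T.copy()


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def write_record(record: MultiChannelRecord, path: str | Path) -> None:
    """Write a record as CSV (time + channels) with a YAML metadata sidecar.

    Floats are written with 17 significant digits so that a read/write
    round trip is exact and re-writing an unchanged record is
    byte-identical.
    """
    path = Path(path)
    if record.n_samples == 0:
        raise ValueError(f"refusing to write empty record to {path}")
    header = ",".join(["time"] + list(record.labels))
    data = np.column_stack([record.times(), record.samples.T])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in data:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    meta = {
        "fs": float(record.fs),
        "labels": list(record.labels),
        "units": record.units,
        "provenance": list(record.provenance),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_record(path: str | Path) -> MultiChannelRecord:
    """Read a CSV + sidecar pair written by :func:`write_record`.

    The sidecar ``fs`` overrides the time column; if both are present and
    disagree by more than 0.1% an error naming both values is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar} (required: carries fs/labels)"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} does not declare a sampling rate 'fs'")
    fs = float(meta["fs"])

    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows carry the row number
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax())
        raise ValueError(f"ragged or missing values in {path} at data row {bad}")

    cols = list(frame.columns)
    if cols and cols[0].lower() in ("time", "t", "index", "sample"):
        tcol = frame[cols[0]].to_numpy()
        cols = cols[1:]
        if len(tcol) > 1 and cols:
            dt = np.median(np.diff(tcol))
            if dt > 0:
                fs_inferred = 1.0 / dt
                if abs(fs_inferred - fs) / fs > 1e-3:
                    raise ValueError(
                        f"time column implies fs={fs_inferred:g} Hz but sidecar "
                        f"declares fs={fs:g} Hz (mismatch > 0.1%)"
                    )
    samples = frame[cols].to_numpy().T
    labels = meta.get("labels", cols) or cols
    return MultiChannelRecord(
        samples=samples,
        fs=fs,
        labels=[str(c) for c in labels],
        provenance=list(meta.get("provenance", [])),
        units=str(meta.get("units", "mV")),
    )
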