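"""Synthetic sEMG / ECG / interference sources and linear mixing.

Ground-truth generators for testing artifact removal without recorded
data. Surface EMG is emulated as band-limited Gaussian noise (the
standard surrogate: its 20–250 Hz band and noise-like amplitude
statistics are the features downstream stages rely on) with smooth
contraction-burst envelopes; ECG as a quasi-periodic train of Gaussian
P-Q-R-S-T bumps, which is regular and therefore low-complexity — the
property the fuzzy-entropy discriminator exploits. Observed channels
follow the instantaneous linear mixture model x(t) = A s(t) (+ sensor
noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import MultiChannelRecord

__all__ = [
    "SourceSignal",
    "SyntheticGroundTruth",
    "generate_semg",
    "generate_ecg",
    "generate_interference",
    "mix_sources",
    "contaminated_semg",
]

# Per-wave (amplitude [mV], width as fraction of RR, offset as fraction of RR
# relative to the R peak). Morphology is a schematic normal beat, not a
# pathology model.
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 0.030, -0.22),
    "Q": (-0.12, 0.012, -0.055),
    "R": (1.00, 0.015, 0.0),
    "S": (-0.25, 0.012, 0.055),
    "T": (0.35, 0.055, 0.30),
}


@dataclass
class SourceSignal:
    """A single ground-truth source s_j(t)."""

    samples: np.ndarray
    fs: float
    kind: str  # one of {"semg", "ecg", "mains", "wander", "noise"}
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class SyntheticGroundTruth:
    """Sources, the mixing matrix A, and the observed mixture x = A s (+ noise)."""

    sources: list[SourceSignal]
    mixing: np.ndarray
    observed: MultiChannelRecord
    sensor_noise_sd: float = 0.0

    def source_matrix(self) -> np.ndarray:
        """Stacked sources, shape (n_sources, n_samples)."""
        return np.vstack([s.samples for s in self.sources])

    def source_of_kind(self, kind: str) -> SourceSignal:
        for s in self.sources:
            if s.kind == kind:
                return s
        raise KeyError(f"no source of kind {kind!r}")


def _n_samples(duration: float, fs: float) -> int:
    return int(round(duration * fs))


def generate_semg(
    duration: float,
    fs: float = 1000.0,
    passband: tuple[float, float] = (20.0, 150.0),
    bursts: Sequence[tuple[float, float, float]] | None = None,
    resting_level: float = 1.0,
    ramp: float = 0.05,
    seed: int | None = None,
) -> SourceSignal:
    """Band-limited stochastic sEMG surrogate with contraction bursts.

    White Gaussian noise is band-pass filtered (4th-order Butterworth,
    zero-phase) into ``passband``, normalised to unit standard deviation
    and amplitude-modulated by a smooth envelope: ``resting_level``
    between bursts, raised-cosine ramps of length ``ramp`` seconds up to
    each burst's peak amplitude.

    Parameters
    ----------
    bursts : sequence of (start_s, end_s, peak_amplitude)
        Contraction epochs; must lie inside [0, duration] and not overlap.
    """
    low, high = passband
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"invalid passband {passband} for fs={fs}: need 0 < low < high < fs/2"
        )
    n = _n_samples(duration, fs)
    rng = np.random.default_rng(seed)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd > 0:
        x = x / sd

    envelope = np.full(n, float(resting_level))
    bursts = list(bursts or [])
    spans = sorted((b[0], b[1]) for b in bursts)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping bursts: [{a0},{a1}] and [{b0},{b1}]")
    t = np.arange(n) / fs
    for start, end, peak in bursts:
        if not (0 <= start < end <= duration):
            raise ValueError(f"burst ({start},{end}) outside [0, {duration}]")
        r = min(ramp, (end - start) / 2)
        up = (t >= start) & (t < start + r)
        flat = (t >= start + r) & (t < end - r)
        down = (t >= end - r) & (t < end)
        delta = peak - resting_level
        envelope[up] += delta * 0.5 * (1 - np.cos(np.pi * (t[up] - start) / r))
        envelope[flat] += delta
        envelope[down] += delta * 0.5 * (1 - np.cos(np.pi * (end - t[down]) / r))
    x = x * envelope
    return SourceSignal(
        samples=x,
        fs=fs,
        kind="semg",
        params={
            "duration": duration,
            "passband": tuple(passband),
            "bursts": bursts,
            "resting_level": resting_level,
            "seed": seed,
        },
    )


def generate_ecg(
    duration: float,
    fs: float = 1000.0,
    heart_rate: float = 72.0,
    wave_params: dict[str, tuple[float, float, float]] | None = None,
    rr_jitter: float = 0.0,
    seed: int | None = None,
) -> SourceSignal:
    """Quasi-periodic ECG train of Gaussian P,Q,R,S,T bumps.

    Each beat is the sum of five Gaussian bumps at fixed phase offsets
    within the RR interval; ``rr_jitter`` (fraction of RR, SD of a
    Gaussian perturbation) adds beat-to-beat variability. The first R
    peak sits at RR/2.
    """
    if not (20 <= heart_rate <= 220):
        raise ValueError(f"heart_rate {heart_rate} bpm outside [20, 220]")
    if fs <= 200:
        raise ValueError(f"fs must exceed 200 Hz for ECG synthesis, got {fs}")
    waves = dict(wave_params or DEFAULT_WAVES)
    for name, (_amp, width, _off) in waves.items():
        if width <= 0:
            raise ValueError(f"wave {name!r} width must be positive, got {width}")

    n = _n_samples(duration, fs)
    t = np.arange(n) / fs
    rr = 60.0 / heart_rate
    rng = np.random.default_rng(seed)

    # R-peak times: quasi-periodic with optional Gaussian RR jitter.
    r_times = []
    tk = rr / 2
    while tk < duration + rr:
        r_times.append(tk)
        step = rr * (1.0 + rr_jitter * rng.standard_normal()) if rr_jitter > 0 else rr
        tk += max(step, 0.2 * rr)

    x = np.zeros(n)
    for rk in r_times:
        for amp, width, off in waves.values():
            if amp == 0:
                continue
            mu = rk + off * rr
            sig = width * rr
            lo = max(0, int((mu - 5 * sig) * fs))
            hi = min(n, int((mu + 5 * sig) * fs) + 1)
            if lo >= hi:
                continue
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sig) ** 2)
    return SourceSignal(
        samples=x,
        fs=fs,
        kind="ecg",
        params={
            "duration": duration,
            "heart_rate": heart_rate,
            "rr_jitter": rr_jitter,
            "seed": seed,
            "waves": waves,
        },
    )


def generate_interference(
    duration: float,
    fs: float = 1000.0,
    mains_freq: float = 50.0,
    mains_amp: float = 1.0,
    wander_freq: float = 0.3,
    wander_amp: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> list[SourceSignal]:
    """Mains sinusoid, baseline wander and white sensor noise sources."""
    if mains_freq >= fs / 2:
        raise ValueError(f"mains_freq {mains_freq} >= Nyquist {fs / 2}")
    if wander_freq >= fs / 2:
        raise ValueError(f"wander_freq {wander_freq} >= Nyquist {fs / 2}")
    n = _n_samples(duration, fs)
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    mains = SourceSignal(
        mains_amp * np.sin(2 * np.pi * mains_freq * t),
        fs,
        "mains",
        {"freq": mains_freq, "amp": mains_amp},
    )
    wander = SourceSignal(
        wander_amp * np.sin(2 * np.pi * wander_freq * t),
        fs,
        "wander",
        {"freq": wander_freq, "amp": wander_amp},
    )
    noise = SourceSignal(
        noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n),
        fs,
        "noise",
        {"sd": noise_sd, "seed": seed},
    )
    return [mains, wander, noise]


def mix_sources(
    sources: Sequence[SourceSignal],
    mixing: np.ndarray,
    sensor_noise_sd: float = 0.0,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> SyntheticGroundTruth:
    """Linear instantaneous mixture x = A s + sensor noise.

    All sources must share length and sampling rate; ``mixing`` is the
    (n_channels, n_sources) matrix A with n_channels >= n_sources and
    full column rank (a deficient A is kept but flagged with a warning).
    """
    sources = list(sources)
    if not sources:
        raise ValueError("need at least one source")
    fs = sources[0].fs
    n = len(sources[0].samples)
    for s in sources[1:]:
        if s.fs != fs or len(s.samples) != n:
            raise ValueError(
                "all sources must share sampling rate and length: "
                f"got fs={s.fs} vs {fs}, n={len(s.samples)} vs {n}"
            )
    A = np.atleast_2d(np.asarray(mixing, dtype=float))
    if A.shape[1] != len(sources):
        raise ValueError(f"mixing shape {A.shape} incompatible with {len(sources)} sources")
    if A.shape[0] < A.shape[1]:
        raise ValueError(
            f"underdetermined mixture: {A.shape[0]} channels < {A.shape[1]} sources"
        )
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("mixing matrix is rank-deficient; sources are not identifiable")

    S = np.vstack([s.samples for s in sources])
    X = A @ S
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + sensor_noise_sd * rng.standard_normal(X.shape)
    observed = MultiChannelRecord(
        samples=X,
        fs=fs,
        labels=list(labels) if labels else [f"ch{i + 1}" for i in range(A.shape[0])],
        provenance=[f"simulated mixture of {[s.kind for s in sources]}"],
    )
    return SyntheticGroundTruth(
        sources=sources, mixing=A, observed=observed, sensor_noise_sd=sensor_noise_sd
    )


# Contraction epochs as (start, end, peak) fractions of the recording:
# three bursts, peak amplitude 3x the resting level, emulating repeated
# isokinetic contraction tasks with rest in between.
DEFAULT_BURST_FRACTIONS: tuple[tuple[float, float, float], ...] = (
    (0.10, 0.30, 3.0),
    (0.45, 0.65, 3.0),
    (0.80, 0.95, 3.0),
)


def _default_bursts(duration: float, phase: float = 0.0):
    return [
        (
            min((a + phase) * duration, duration),
            min((b + phase) * duration, duration),
            peak,
        )
        for a, b, peak in DEFAULT_BURST_FRACTIONS
    ]


def _fan_out_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# Fixed well-conditioned mixing with the sEMG-dominant source on channel 1,
# mimicking electrodes at graded distances from the heart.
DEFAULT_MIXING = np.array(
    [
        [1.0, 0.9, 0.7],
        [0.6, 1.0, 0.8],
        [0.8, 0.5, 1.0],
    ]
)


def contaminated_semg(
    duration: float = 10.0,
    fs: float = 1000.0,
    contamination_db: float = 0.0,
    noise_sd: float = 0.1,
    sensor_noise_sd: float = 0.0,
    heart_rate: float = 72.0,
    passband: tuple[float, float] = (20.0, 150.0),
    bursts: Sequence[tuple[float, float, float]] | str | None = "default",
    seed: int | None = None,
) -> SyntheticGroundTruth:
    """Standard 3-channel {sEMG, ECG, noise} contamination fixture.

    The sEMG source carries contraction bursts (isokinetic-task protocol;
    ``bursts="default"`` places three epochs at fixed fractions of the
    recording, peak 3x resting). The ECG source is rescaled so the
    sEMG:ECG power ratio equals ``contamination_db`` (0 dB = equal power,
    severe contamination); ``noise_sd`` is the white-noise source SD
    relative to the unit-SD resting sEMG. A pipeline seed fans out
    deterministically to per-source seeds.
    """
    seeds = _fan_out_seeds(seed, 4)
    if bursts == "default":
        bursts = _default_bursts(duration)
    semg = generate_semg(duration, fs, passband=passband, bursts=bursts, seed=seeds[0])
    ecg = generate_ecg(duration, fs, heart_rate=heart_rate, rr_jitter=0.02, seed=seeds[1])
    p_semg = np.mean(semg.samples**2)
    p_ecg = np.mean(ecg.samples**2)
    if p_ecg > 0:
        scale = np.sqrt(p_semg / p_ecg / 10 ** (contamination_db / 10))
        ecg = SourceSignal(ecg.samples * scale, fs, "ecg", ecg.params | {"scale": scale})
    rng = np.random.default_rng(seeds[2])
    noise = SourceSignal(
        noise_sd * rng.standard_normal(len(semg.samples)), fs, "noise",
        {"sd": noise_sd, "seed": seeds[2]},
    )
    return mix_sources(
        [semg, ecg, noise], DEFAULT_MIXING,
        sensor_noise_sd=sensor_noise_sd, seed=seeds[3],
    )


def uncontaminated_semg(
    duration: float = 10.0,
    fs: float = 1000.0,
    noise_sd: float = 0.1,
    passband: tuple[float, float] = (20.0, 150.0),
    seed: int | None = None,
) -> SyntheticGroundTruth:
    """Negative-control fixture: two muscles + sensor noise, no ECG.

    Two independent burst-modulated sEMG sources (staggered contraction
    timings) and a white-noise source mixed by the same matrix as
    :func:`contaminated_semg`. Used to check that the entropy-gap
    classifier typically flags nothing when no ECG is present.
    """
    seeds = _fan_out_seeds(seed, 3)
    s1 = generate_semg(
        duration, fs, passband=passband, bursts=_default_bursts(duration), seed=seeds[0]
    )
    s2 = generate_semg(
        duration, fs, passband=passband,
        bursts=_default_bursts(duration, phase=-0.05), seed=seeds[1],
    )
    rng = np.random.default_rng(seeds[2])
    noise = SourceSignal(
        noise_sd * rng.standard_normal(len(s1.samples)), fs, "noise",
        {"sd": noise_sd, "seed": seeds[2]},
    )
    return mix_sources([s1, s2, noise], DEFAULT_MIXING)
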