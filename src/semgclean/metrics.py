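"""Evaluation indices: CC, RMSE, SNR, relative error and the Amari index.

CC and RMSE follow the usual definitions (Pearson correlation;
root-mean-square difference). SNR and RE are this package's definitions:
SNR = 10 log10(sum ref^2 / sum (ref - est)^2) dB and
RE = ||est - ref||_2 / ||ref||_2; ``reference_kind`` records whether the
reference was simulation ground truth or the pre-cleaning signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MultiChannelRecord

__all__ = [
    "MetricsReport",
    "correlation_coefficient",
    "rmse",
    "snr_db",
    "relative_error",
    "amari_index",
    "evaluate",
]


@dataclass
class MetricsReport:
    cc: float
    rmse: float
    snr_db: float
    re: float
    reference_kind: str = "ground_truth"


def _pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return x, y


def correlation_coefficient(x, y) -> float:
    """Pearson CC = Cov(x, y) / sqrt(Var(x) Var(y))."""
    x, y = _pair(x, y)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    vx, vy = np.var(x), np.var(y)
    if vx == 0 or vy == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / np.sqrt(vx * vy))


def rmse(estimate, reference) -> float:
    """Root-mean-square error sqrt(mean((est - ref)^2))."""
    e, r = _pair(estimate, reference)
    if len(e) < 1:
        raise ValueError("need at least 1 sample")
    return float(np.sqrt(np.mean((e - r) ** 2)))


def snr_db(signal_ref, estimate) -> float:
    """10 log10 of reference power over residual power, in dB.

    A zero residual returns +inf (perfect reconstruction sentinel); a
    zero-power reference is undefined.
    """
    r, e = _pair(signal_ref, estimate)
    p_sig = float(np.sum(r**2))
    if p_sig == 0:
        raise ValueError("SNR undefined for a zero-power reference")
    p_res = float(np.sum((r - e) ** 2))
    if p_res == 0:
        return float("inf")
    return float(10.0 * np.log10(p_sig / p_res))


def relative_error(estimate, reference) -> float:
    """Scale-free residual: ||est - ref||_2 / ||ref||_2."""
    e, r = _pair(estimate, reference)
    nrm = float(np.linalg.norm(r))
    if nrm == 0:
        raise ValueError("relative error undefined for a zero reference")
    return float(np.linalg.norm(e - r) / nrm)


def amari_index(P) -> float:
    """Amari performance index of a candidate permutation matrix.

    For P = W_est . A_true (in whitened space), the index

        (1 / 2n) * [ sum_i (sum_j |p_ij| / max_j |p_ij| - 1)
                   + sum_j (sum_i |p_ij| / max_i |p_ij| - 1) ]

    is 0 iff P is a scaled permutation and at most n - 1 (all-ones
    matrix). Used as the separation-quality oracle in tests.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"Amari index needs a square matrix, got {P.shape}")
    n = P.shape[0]
    A = np.abs(P)
    if np.any(A.max(axis=1) == 0) or np.any(A.max(axis=0) == 0):
        raise ValueError("matrix has an all-zero row or column")
    rows = (A / A.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (A / A.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n))


def evaluate(
    estimate: MultiChannelRecord,
    reference: MultiChannelRecord,
    reference_kind: str = "ground_truth",
) -> pd.DataFrame:
    """Per-channel metric table (cc, rmse, snr_db, re) against a reference."""
    if estimate.samples.shape != reference.samples.shape:
        raise ValueError(
            f"shape mismatch: estimate {estimate.samples.shape} vs "
            f"reference {reference.samples.shape}"
        )
    rows = []
    for i, label in enumerate(estimate.labels):
        e, r = estimate.samples[i], reference.samples[i]
        rows.append(
            {
                "channel": label,
                "cc": correlation_coefficient(e, r),
                "rmse": rmse(e, r),
                "snr_db": snr_db(r, e),
                "re": relative_error(e, r),
                "reference_kind": reference_kind,
            }
        )
    return pd.DataFrame(rows)
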