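import math

import numpy as np
import pytest

from semgclean import MultiChannelRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record(rng):
    """A 3-channel, 2048-sample random record at 1 kHz."""
    return MultiChannelRecord(
        samples=rng.standard_normal((3, 2048)), fs=1000.0, labels=["a", "b", "c"]
    )


def naive_fuzzy_entropy(x, m=2, r_factor=0.2, r=None):
    """Brute-force FuzzyEn oracle: explicit Python double loop.

    Baseline-removed m-windows, Chebyshev distance, membership
    exp(-ln2 (d/r)^2), phi_m as the mean over i of the mean over j != i,
    entropy ln(phi_m) - ln(phi_{m+1}). Deliberately unvectorised.
    """
    x = [float(v) for v in np.asarray(x).ravel()]
    if r is None:
        r = r_factor * float(np.std(np.asarray(x)))
    ln2 = math.log(2.0)

    def phi(mm):
        n = len(x)
        nv = n - mm + 1
        emb = []
        for i in range(nv):
            w = x[i : i + mm]
            mu = sum(w) / mm
            emb.append([v - mu for v in w])
        total = 0.0
        for i in range(nv):
            s = 0.0
            for j in range(nv):
                if j == i:
                    continue
                d = 0.0
                ei, ej = emb[i], emb[j]
                for k in range(mm):
                    dk = abs(ei[k] - ej[k])
                    if dk > d:
                        d = dk
                s += math.exp(-ln2 * (d / r) ** 2)
            total += s / (nv - 1)
        return total / nv

    return math.log(phi(m)) - math.log(phi(m + 1))


def naive_amari(P):
    """Textbook Amari index by explicit loops (oracle)."""
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    total = 0.0
    for i in range(n):
        mx = max(P[i, j] for j in range(n))
        total += sum(P[i, j] / mx for j in range(n)) - 1.0
    for j in range(n):
        mx = max(P[i, j] for i in range(n))
        total += sum(P[i, j] / mx for i in range(n)) - 1.0
    return total / (2.0 * n)


def best_match_abs_corr(sources_est, sources_true):
    """Per-true-source max |corr| against the estimated sources."""
    k = sources_true.shape[0]
    C = np.corrcoef(np.vstack([sources_est, sources_true]))
    cross = np.abs(C[:sources_est.shape[0], sources_est.shape[0]:])
    return cross.max(axis=0), cross
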