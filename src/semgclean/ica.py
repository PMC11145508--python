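"""Centering, PCA whitening and negentropy FastICA with gradient refinement.

The blind source separation model is x(t) = A s(t) with statistically
independent sources s; separation seeks y(t) = W x(t) recovering s up to
permutation and scale. Preprocessing subtracts the channel means and
whitens via the eigendecomposition of the sample covariance
C = U Lambda U^T, giving Z = Lambda^(-1/2) U^T (x - mu) with identity
covariance, after which W is orthogonal.

Each unmixing direction w maximises a negentropy surrogate
J(w) = (E[G(w^T z)] - E[G(v)])^2 with G(u) = log cosh(u) (g = tanh,
g' = 1 - tanh^2), v standard normal. The fixed-point (approximate
Newton) update is

    w <- E[Z g(w^T Z)] - E[g'(w^T Z)] w,   w <- w / ||w||

Random initial directions make the fixed-point iteration sensitive to the
start, so each direction is first refined by a few steepest-ascent steps
w <- w + step * E[Z g(w^T Z)] with a backtracking step size that never
lets the negentropy surrogate decrease. Components are extracted
sequentially (deflation) with Gram-Schmidt re-orthogonalisation against
the rows already found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WhiteningModel",
    "UnmixingModel",
    "IcaConfig",
    "center",
    "pca_whiten",
    "fastica_fixed_point_update",
    "gradient_refine",
    "extract_components",
    "reconstruct_channels",
    "Whitener",
    "NegentropyFastICA",
]

logger = logging.getLogger(__name__)


def _g(u):
    return np.tanh(u)


def _g_prime(u):
    return 1.0 - np.tanh(u) ** 2


def _G(u):
    # log cosh computed stably for large |u|
    au = np.abs(u)
    return au + np.log1p(np.exp(-2.0 * au)) - np.log(2.0)


def _expected_G_gaussian() -> float:
    """E[G(v)], v ~ N(0,1), by Gauss-Hermite quadrature (deterministic)."""
    nodes, weights = np.polynomial.hermite.hermgauss(61)
    return float(np.sum(weights * _G(np.sqrt(2.0) * nodes)) / np.sqrt(np.pi))


E_G_GAUSS = _expected_G_gaussian()


@dataclass
class WhiteningModel:
    """Mean, eigensystem and the whitening / de-whitening maps."""

    mean: np.ndarray
    eigvecs: np.ndarray  # columns are eigenvectors, variance-descending
    eigvals: np.ndarray  # descending, >= 0 (kept dimensions only)
    whiten: np.ndarray  # Lambda^(-1/2) U^T, shape (kept, n_channels)
    dewhiten: np.ndarray  # U Lambda^(1/2), shape (n_channels, kept)
    kept_dims: int


@dataclass
class IcaConfig:
    """FastICA settings. The contrast is fixed: G = log cosh, g = tanh.

    ``grad_step`` names the steepest-ascent step size; by default it is
    found by backtracking line search (start 1, halve, at most 10 times)
    on the negentropy surrogate. ``mode`` selects refinement + fixed
    point (default) or pure gradient ascent.
    """

    n_components: int | None = None
    tol: float = 1e-6
    max_iter: int = 200
    grad_refine_steps: int = 5
    grad_step: float = 1.0
    mode: str = "refine_fixed_point"  # or "gradient_only"
    n_restarts: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.grad_refine_steps < 0:
            raise ValueError("grad_refine_steps must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.mode not in ("refine_fixed_point", "gradient_only"):
            raise ValueError(f"unknown ica mode {self.mode!r}")


@dataclass
class UnmixingModel:
    """Orthogonal unmixing of whitened data and the separated sources."""

    W: np.ndarray  # (n_components, kept_dims), rows unit-norm orthogonal
    sources: np.ndarray  # W @ Z
    mixing_est: np.ndarray  # back to original channel space when whitening given
    n_iter: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)


def center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove per-channel means; returns (centered, mean vector)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    mu = X.mean(axis=1)
    return X - mu[:, None], mu


def pca_whiten(
    Xc: np.ndarray, var_floor: float = 1e-6, mean: np.ndarray | None = None
) -> tuple[np.ndarray, WhiteningModel]:
    """Eigendecomposition whitening of centered data.

    The sample covariance C = Xc Xc^T / m is decomposed as U Lambda U^T;
    dimensions with eigenvalue below ``var_floor`` times the largest are
    dropped (and reported via ``kept_dims``). The returned Z has sample
    covariance equal to the identity.
    """
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    n, m = Xc.shape
    C = Xc @ Xc.T / m
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    if evals[0] <= 0:
        raise ValueError("degenerate input: all eigenvalues are zero (no variance)")
    keep = evals > var_floor * evals[0]
    kept = int(keep.sum())
    if kept < n:
        logger.info("whitening dropped %d near-zero-variance dimension(s)", n - kept)
    evals, evecs = evals[:kept], evecs[:, :kept]
    whiten = (evecs / np.sqrt(evals)).T  # Lambda^(-1/2) U^T
    dewhiten = evecs * np.sqrt(evals)  # U Lambda^(1/2)
    Z = whiten @ Xc
    model = WhiteningModel(
        mean=np.zeros(n) if mean is None else np.asarray(mean, dtype=float),
        eigvecs=evecs,
        eigvals=evals,
        whiten=whiten,
        dewhiten=dewhiten,
        kept_dims=kept,
    )
    return Z, model


def _negentropy_surrogate(w: np.ndarray, Z: np.ndarray) -> float:
    return abs(float(np.mean(_G(w @ Z))) - E_G_GAUSS)


def fastica_fixed_point_update(w: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """One approximate-Newton fixed-point step; returns a unit vector."""
    u = w @ Z
    w_new = Z @ _g(u) / Z.shape[1] - np.mean(_g_prime(u)) * w
    nrm = np.linalg.norm(w_new)
    if nrm < 1e-12:
        raise FloatingPointError(
            "fixed-point update collapsed to the zero vector; reseed the start"
        )
    return w_new / nrm


def gradient_refine(
    w: np.ndarray,
    Z: np.ndarray,
    steps: int = 5,
    step_rule: str = "backtracking",
    initial_step: float = 1.0,
) -> np.ndarray:
    """Steepest-ascent refinement of a starting direction.

    Performs up to ``steps`` iterations of
    w <- normalize(w + step * E[Z g(w^T Z)]), choosing the step by
    backtracking (start ``initial_step``, halve, <= 10 halvings) so the
    negentropy surrogate |E[G(w^T Z)] - E[G(v)]| never decreases; if no
    step improves it, the best w so far is returned early.
    """
    if step_rule not in ("backtracking", "fixed"):
        raise ValueError(f"unknown step rule {step_rule!r}")
    w = np.asarray(w, dtype=float)
    m = Z.shape[1]
    best = _negentropy_surrogate(w, Z)
    for _ in range(steps):
        grad = Z @ _g(w @ Z) / m
        step = initial_step
        accepted = False
        if step_rule == "fixed":
            cand = w + step * grad
            nrm = np.linalg.norm(cand)
            if nrm > 0:
                w = cand / nrm
            continue
        for _half in range(11):
            cand = w + step * grad
            nrm = np.linalg.norm(cand)
            if nrm > 0:
                cand = cand / nrm
                j = _negentropy_surrogate(cand, Z)
                if j >= best:
                    w, best, accepted = cand, j, True
                    break
            step *= 0.5
        if not accepted:
            break
    return w


def _gram_schmidt(w: np.ndarray, rows: list[np.ndarray]) -> np.ndarray:
    for r in rows:
        w = w - (w @ r) * r
    return w


def extract_components(
    Z: np.ndarray,
    cfg: IcaConfig | None = None,
    whitening: WhiteningModel | None = None,
) -> UnmixingModel:
    """Deflationary extraction of independent components from whitened data.

    For each component: seeded random unit start, gradient refinement,
    then fixed-point iterations with Gram-Schmidt re-orthogonalisation
    against previously found rows after every update; convergence when
    |<w_new, w_old>| >= 1 - tol. Non-convergence after ``max_iter`` is
    flagged, not fatal.
    """
    cfg = cfg or IcaConfig()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    dim = Z.shape[0]
    n_comp = cfg.n_components or dim
    if n_comp > dim:
        raise ValueError(f"n_components={n_comp} exceeds whitened dimension {dim}")
    rng = np.random.default_rng(cfg.seed)
    rows: list[np.ndarray] = []
    n_iter: list[int] = []
    converged: list[bool] = []

    def _one_run(rows):
        """One refined start followed by fixed-point iterations."""
        for _attempt in range(5):
            w = rng.standard_normal(dim)
            w = _gram_schmidt(w, rows)
            nrm = np.linalg.norm(w)
            if nrm > 1e-9:
                w = w / nrm
                break
        else:
            raise FloatingPointError("could not draw an independent starting vector")
        if cfg.grad_refine_steps > 0:
            w = gradient_refine(w, Z, steps=cfg.grad_refine_steps,
                                initial_step=cfg.grad_step)
            w = _gram_schmidt(w, rows)
            nrm = np.linalg.norm(w)
            w = w / nrm if nrm > 1e-12 else rng.standard_normal(dim)

        it, ok = 0, False
        for it in range(1, cfg.max_iter + 1):
            if cfg.mode == "gradient_only":
                w_new = gradient_refine(w, Z, steps=1, initial_step=cfg.grad_step)
            else:
                w_new = fastica_fixed_point_update(w, Z)
            w_new = _gram_schmidt(w_new, rows)
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-12:
                w_new = rng.standard_normal(dim)
                w_new = _gram_schmidt(w_new, rows)
                w_new /= np.linalg.norm(w_new)
            else:
                w_new = w_new / nrm
            if abs(w_new @ w) >= 1.0 - cfg.tol:
                return w_new, it, True
            w = w_new
        return w, it, False

    for _p in range(n_comp):
        # Several seeded restarts guard against the shallow fixed points a
        # single random start can fall into (the low-contrast directions of
        # nearly Gaussian subspaces); the converged direction with the
        # highest negentropy surrogate wins.
        best = None
        for _r in range(cfg.n_restarts):
            w, it, ok = _one_run(rows)
            score = (ok, _negentropy_surrogate(w, Z))
            if best is None or score > best[0]:
                best = (score, w, it, ok)
            if dim - len(rows) == 1:
                break  # the last direction is fully determined
        _, w, it, ok = best
        if not ok:
            logger.warning("component %d did not converge in %d iterations",
                           _p + 1, cfg.max_iter)
        rows.append(w)
        n_iter.append(it)
        converged.append(ok)
    W = np.vstack(rows)
    sources = W @ Z
    if whitening is not None:
        mixing_est = whitening.dewhiten @ W.T
    else:
        mixing_est = W.T
    return UnmixingModel(W=W, sources=sources, mixing_est=mixing_est,
                         n_iter=n_iter, converged=converged)


def reconstruct_channels(
    model: UnmixingModel,
    keep_mask: np.ndarray,
    wmodel: WhiteningModel,
) -> np.ndarray:
    """Map sources back to channel space with dropped components zeroed.

    X_hat = dewhiten . W^T . diag(keep) . sources + mean. With an
    all-true mask this inverts the whole separation (up to the variance
    discarded by the whitening floor).
    """
    keep = np.asarray(keep_mask, dtype=bool)
    if keep.shape != (model.W.shape[0],):
        raise ValueError(
            f"keep_mask length {keep.shape} != n_components {model.W.shape[0]}"
        )
    S = model.sources * keep[:, None]
    X = wmodel.dewhiten @ (model.W.T @ S)
    return X + wmodel.mean[:, None]


class Whitener(TransformerMixin, BaseEstimator):
    """Centering + PCA whitening as an sklearn transformer.

    ``fit`` learns the mean and eigensystem from X of shape
    (n_samples, n_channels); ``transform`` returns whitened data of shape
    (n_samples, kept_dims); ``inverse_transform`` maps back.
    """

    def __init__(self, var_floor: float = 1e-6):
        self.var_floor = var_floor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        Xc, mu = center(X.T)
        _, self.model_ = pca_whiten(Xc, var_floor=self.var_floor, mean=mu)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (self.model_.whiten @ (X.T - self.model_.mean[:, None])).T

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        return (self.model_.dewhiten @ Z.T + self.model_.mean[:, None]).T


class NegentropyFastICA(TransformerMixin, BaseEstimator):
    """Negentropy FastICA with gradient-refined starts (sklearn-style).

    fit(X) on arrays of shape (n_samples, n_channels) learns the
    whitening and the orthogonal unmixing; transform(X) returns the
    separated sources (n_samples, n_components); inverse_transform(S)
    maps sources back to channel space.

    Attributes
    ----------
    whitening_ : WhiteningModel
    unmixing_ : UnmixingModel
    components_ : ndarray (n_components, n_channels)
        Full unmixing from original channels (W . whiten).
    mixing_ : ndarray (n_channels, n_components)
        Estimated mixing matrix back to channel space.
    n_iter_ : list of int
    converged_ : list of bool
    """

    def __init__(
        self,
        n_components: int | None = None,
        tol: float = 1e-6,
        max_iter: int = 200,
        grad_refine_steps: int = 5,
        grad_step: float = 1.0,
        mode: str = "refine_fixed_point",
        n_restarts: int = 3,
        var_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.grad_refine_steps = grad_refine_steps
        self.grad_step = grad_step
        self.mode = mode
        self.n_restarts = n_restarts
        self.var_floor = var_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        Xc, mu = center(X.T)
        Z, wmodel = pca_whiten(Xc, var_floor=self.var_floor, mean=mu)
        cfg = IcaConfig(
            n_components=self.n_components,
            tol=self.tol,
            max_iter=self.max_iter,
            grad_refine_steps=self.grad_refine_steps,
            grad_step=self.grad_step,
            mode=self.mode,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )
        umodel = extract_components(Z, cfg, whitening=wmodel)
        self.whitening_ = wmodel
        self.unmixing_ = umodel
        self.components_ = umodel.W @ wmodel.whiten
        self.mixing_ = umodel.mixing_est
        self.mean_ = mu
        self.n_iter_ = umodel.n_iter
        self.converged_ = umodel.converged
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (self.components_ @ (X.T - self.mean_[:, None])).T

    def inverse_transform(self, S, keep_mask=None):
        S = np.asarray(S, dtype=float).T
        if keep_mask is not None:
            S = S * np.asarray(keep_mask, dtype=bool)[:, None]
        X = self.whitening_.dewhiten @ (self.unmixing_.W.T @ S)
        return (X + self.mean_[:, None]).T
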