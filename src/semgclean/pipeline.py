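"""The full ECG-artifact-removal chain and its configuration.

Order of stages: wavelet threshold denoising per channel -> centering and
PCA whitening -> negentropy FastICA (deflation) -> fuzzy entropy per
separated component -> sorted-gap classification of ECG components ->
reconstruction of the channels with the flagged components removed. The
eliminated part (denoised input minus clean output) is returned as the
ECG artifact estimate, so clean + artifact reproduces the denoised input.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import wavelet as wv
from .entropy import classify_components, entropy_window, fuzzy_entropy, \
    ComponentClassification, FuzzyEntropyParams
from .ica import NegentropyFastICA
from .io import MultiChannelRecord

__all__ = ["PipelineConfig", "PipelineReport", "ECGArtifactRemover", "remove_ecg"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for the whole chain; unknown keys are rejected."""

    # wavelet stage
    wavelet: str = "db4"
    levels: int | str = 9
    rule: str = "improved"
    lambda_method: str = "universal"
    improved_variant: str = "adopted"
    # ICA stage
    n_components: int | None = None
    tol: float = 1e-6
    max_iter: int = 200
    grad_refine_steps: int = 5
    ica_mode: str = "refine_fixed_point"
    var_floor: float = 1e-6
    # fuzzy entropy / classification
    fuzzyen_m: int = 2
    fuzzyen_r_factor: float = 0.2
    fuzzyen_window: int = 5000
    boundary_mode: str = "exclusive"
    # global
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineReport:
    """Everything a run decided: entropies, flags, convergence, timings."""

    classification: ComponentClassification
    entropies: np.ndarray
    n_components: int
    kept_dims: int
    converged: list[bool]
    n_iter: list[int]
    config: dict
    timings_s: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classification": self.classification.to_dict(),
            "entropies": [float(v) for v in self.entropies],
            "n_components": self.n_components,
            "kept_dims": self.kept_dims,
            "converged": list(self.converged),
            "n_iter": list(self.n_iter),
            "config": self.config,
            "timings_s": {k: float(v) for k, v in self.timings_s.items()},
            "warnings": list(self.warnings),
        }


class ECGArtifactRemover(TransformerMixin, BaseEstimator):
    """End-to-end ECG artifact remover as an sklearn-style transformer.

    ``fit(X)`` on an (n_samples, n_channels) array runs the full chain
    and stores the separation and classification; ``transform(X)``
    returns the cleaned channels. The unmixing is learned from the data
    passed to ``fit``, so the intended use is ``fit_transform`` on one
    recording. ``fs`` only matters for provenance; the chain itself is
    sample-rate agnostic (thresholds and entropies are data-driven).

    Parameters mirror :class:`PipelineConfig`; see the package docs for
    units and defaults. ``random_state`` seeds the ICA starts.
    """

    def __init__(
        self,
        wavelet: str = "db4",
        levels: int | str = 9,
        rule: str = "improved",
        lambda_method: str = "universal",
        improved_variant: str = "adopted",
        n_components: int | None = None,
        tol: float = 1e-6,
        max_iter: int = 200,
        grad_refine_steps: int = 5,
        ica_mode: str = "refine_fixed_point",
        var_floor: float = 1e-6,
        fuzzyen_m: int = 2,
        fuzzyen_r_factor: float = 0.2,
        fuzzyen_window: int = 5000,
        boundary_mode: str = "exclusive",
        random_state: int | None = None,
    ):
        self.wavelet = wavelet
        self.levels = levels
        self.rule = rule
        self.lambda_method = lambda_method
        self.improved_variant = improved_variant
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.grad_refine_steps = grad_refine_steps
        self.ica_mode = ica_mode
        self.var_floor = var_floor
        self.fuzzyen_m = fuzzyen_m
        self.fuzzyen_r_factor = fuzzyen_r_factor
        self.fuzzyen_window = fuzzyen_window
        self.boundary_mode = boundary_mode
        self.random_state = random_state

    # -- pipeline stages -------------------------------------------------
    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] < 3:
            logger.warning(
                "fewer than 3 channels: the entropy-gap criterion cannot run"
            )
        timings: dict[str, float] = {}
        warns: list[str] = []

        t0 = time.perf_counter()
        rec = MultiChannelRecord(samples=X.T, fs=1.0)
        denoised = wv.denoise(
            rec,
            wavelet_name=self.wavelet,
            levels=self.levels,
            rule=self.rule,
            lambda_method=self.lambda_method,
            improved_variant=self.improved_variant,
        )
        timings["wavelet_denoise"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        ica = NegentropyFastICA(
            n_components=self.n_components,
            tol=self.tol,
            max_iter=self.max_iter,
            grad_refine_steps=self.grad_refine_steps,
            mode=self.ica_mode,
            var_floor=self.var_floor,
            random_state=self.random_state,
        )
        try:
            sources = ica.fit(denoised.samples.T).transform(denoised.samples.T)
        except (ValueError, FloatingPointError) as exc:
            raise RuntimeError(f"pipeline failed at stage 'ica': {exc}") from exc
        timings["fastica"] = time.perf_counter() - t0
        if not any(ica.converged_):
            raise RuntimeError(
                "pipeline failed at stage 'ica': no component converged"
            )

        t0 = time.perf_counter()
        params = FuzzyEntropyParams(m=self.fuzzyen_m, r_factor=self.fuzzyen_r_factor)
        entropies = []
        for j in range(sources.shape[1]):
            s = entropy_window(sources[:, j], self.fuzzyen_window)
            s = s - s.mean()
            sd = s.std()
            if sd > 0:  # unit variance guard; no-op for relative r
                s = s / sd
            entropies.append(fuzzy_entropy(s, params))
        entropies = np.asarray(entropies)
        timings["fuzzy_entropy"] = time.perf_counter() - t0

        classification = classify_components(entropies, self.boundary_mode)
        if classification.n_flagged == 0:
            warns.append("no ECG component flagged; clean output equals denoised input")

        self.denoised_ = denoised
        self.ica_ = ica
        self.sources_ = sources
        self.classification_ = classification
        self.keep_mask_ = ~classification.ecg_flags
        self.report_ = PipelineReport(
            classification=classification,
            entropies=entropies,
            n_components=sources.shape[1],
            kept_dims=ica.whitening_.kept_dims,
            converged=list(ica.converged_),
            n_iter=list(ica.n_iter_),
            config=self.get_params(),
            timings_s=timings,
            warnings=warns,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Cleaned channels: denoise, separate, drop flagged components."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rec = MultiChannelRecord(samples=X.T, fs=1.0)
        denoised = wv.denoise(
            rec,
            wavelet_name=self.wavelet,
            levels=self.levels,
            rule=self.rule,
            lambda_method=self.lambda_method,
            improved_variant=self.improved_variant,
        )
        S = self.ica_.transform(denoised.samples.T)
        return self.ica_.inverse_transform(S, keep_mask=self.keep_mask_)


def remove_ecg(
    record: MultiChannelRecord, config: PipelineConfig | dict | None = None
) -> tuple[MultiChannelRecord, MultiChannelRecord, PipelineReport]:
    """Run the full chain on a record.

    Returns (clean, artifact, report) where artifact is the eliminated
    part: denoised input minus clean, i.e. the ECG artifact estimate.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    est = ECGArtifactRemover(
        wavelet=config.wavelet,
        levels=config.levels,
        rule=config.rule,
        lambda_method=config.lambda_method,
        improved_variant=config.improved_variant,
        n_components=config.n_components,
        tol=config.tol,
        max_iter=config.max_iter,
        grad_refine_steps=config.grad_refine_steps,
        ica_mode=config.ica_mode,
        var_floor=config.var_floor,
        fuzzyen_m=config.fuzzyen_m,
        fuzzyen_r_factor=config.fuzzyen_r_factor,
        fuzzyen_window=config.fuzzyen_window,
        boundary_mode=config.boundary_mode,
        random_state=config.seed,
    )
    X = record.to_array()
    clean = est.fit(X).transform(X)
    denoised = est.denoised_.samples.T
    artifact = denoised - clean
    flags = est.classification_.ecg_flags
    clean_rec = record.with_samples(
        clean.T, f"remove_ecg(flagged={int(flags.sum())} of {len(flags)})"
    )
    artifact_rec = record.with_samples(artifact.T, "ecg_artifact_estimate")
    est.report_.config = config.to_dict()
    return clean_rec, artifact_rec, est.report_
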