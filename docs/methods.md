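# Methods

This note documents the models, the numerical choices and the known
limits of `semgclean`, in the order the pipeline runs.

## Signal model

Observed channels follow the instantaneous linear mixture
x(t) = A s(t) + ε(t), with statistically independent sources s(t)
(muscle activity, cardiac activity, interference) and optional white
sensor noise ε. Separation estimates y(t) = W x(t) recovering the
sources up to permutation and scale — the inherent ambiguity of blind
source separation. ECG removal therefore never needs the true A; it only
needs to *identify* which separated components are cardiac, zero them,
and map back.

## Wavelet denoising

Each channel is decomposed with a two-channel Daubechies filter-bank
cascade (PyWavelets, symmetric extension; non-dyadic lengths are handled
by the extension convention and reconstruction is truncated to the input
length). Defaults: db4, 9 levels — deep enough at 1 kHz sampling that
the coarsest details sit well below the sEMG band. Only detail
coefficients are thresholded; the coarsest approximation is kept, so
slow components are never distorted by shrinkage.

Three shrinkage rules share the dead zone (output 0 for |w| < λ):

- hard: keeps w unchanged outside the dead zone (discontinuous at ±λ);
- soft: sign(w)(|w| − λ) (continuous, but biased by λ everywhere);
- improved (default): w ∓ 2λ/(1 + exp(±w − λ)), an odd, continuous map
  whose bias 2λ/(1+exp(|w|−λ)) equals λ at the threshold and decays
  exponentially, so large (signal) coefficients pass essentially
  unchanged while the dead zone still suppresses noise.

A sign-flipped exponent variant (`improved_variant="as_printed"`) is
kept for comparison; its bias tends to 2λ for large |w| instead of
vanishing, which defeats the point of the rule, so it is not the
default.

Per-level thresholds default to the universal rule
λⱼ = σ̂ √(2 ln Nⱼ), σ̂ = median(|D₁|)/0.6745 — the standard
wavelet-shrinkage noise estimate from the finest detail band, which at
1 kHz covers 250–500 Hz where neither sEMG (below 250 Hz) nor ECG has
appreciable power, so σ̂ tracks the broadband sensor noise. Whether to
use one λ per level or a single global λ is a genuinely open choice; we
use per-level thresholds, and a manual override accepts user values.

`levels="auto"` sweeps depths 1..9, denoises at each, and computes a
surrogate SNR (reconstructed power over removed power, dB). The smallest
depth whose surrogate beats the depth-1 baseline wins; if the depth-1
residual is already numerically zero the answer is 1, and if no depth
beats the baseline the fallback is the maximum depth. This is an
operational criterion: without a clean reference the true SNR is not
computable, and the surrogate is documented as ours.

## Whitening

Centering subtracts per-channel means; whitening uses the
eigendecomposition C = UΛUᵀ of the sample covariance (normalised by the
sample count), Z = Λ^(−1/2)Uᵀx′. Eigenvalues below `var_floor` (default
1e−6) times the largest are dropped and reported — a rank-deficient
recording yields fewer whitened dimensions, and the pipeline needs at
least 3 of them for the classifier (below that, classification is
skipped and nothing is flagged).

## FastICA with gradient-refined starts

The contrast is G(u) = log cosh u with g = tanh, g′ = 1 − tanh²; the
negentropy surrogate J(w) = |E[G(wᵀZ)] − E[G(v)]| uses the Gaussian
baseline E[G(v)] computed once by 61-node Gauss–Hermite quadrature
(deterministic, no sampling noise). Components are extracted
sequentially (deflation) with Gram–Schmidt re-orthogonalisation after
every update; convergence requires |⟨w_new, w_old⟩| ≥ 1 − tol
(tol 1e−6, max 200 iterations; non-convergence flags the component and
continues).

Two design points deserve explanation:

- **Gradient refinement.** Each random start is first improved by up to
  5 steepest-ascent steps w ← w + λ·E[Z g(wᵀZ)] with a backtracking step
  size (start 1, halve, ≤ 10 halvings) accepted only when J does not
  decrease. Pure fixed-point iteration is sensitive to its random start;
  the refinement pulls the start toward a high-negentropy direction
  first. A pure-gradient mode (`ica_mode="gradient_only"`) is available.
- **Restarts.** Each component is extracted from 3 seeded starts and the
  converged direction with the highest J wins. Finite-sample mixtures
  containing nearly Gaussian sources (band-limited sEMG is marginally
  Gaussian) possess shallow spurious fixed points; restarts make falling
  into one across all starts very unlikely. The last remaining direction
  of the whitened space is fully determined, so it is not restarted.

All randomness flows from a single seed; identical seeds give identical
unmixing matrices.

## Fuzzy entropy and the gap classifier

FuzzyEn(m, r) embeds the series in overlapping windows of length m
(each window baseline-removed by its own mean), measures pairwise
Chebyshev distances, grades similarity with the smooth membership
A(d) = exp(−ln2 (d/r)²), and reports ln Φᵐ − ln Φᵐ⁺¹ where Φᵐ is the
mean over windows of the mean similarity to all other windows (the
window count is N − m + 1 for size m). Defaults m = 2, r = 0.2·SD — the
universal convention for fuzzy/sample entropy. With relative r the
measure is scale-invariant; each component is nevertheless centred and
unit-scaled first to guard the absolute-r option. A constant series is
defined to score exactly 0 (all distances vanish, Φᵐ = Φᵐ⁺¹ = 1) with a
logged warning about the degenerate tolerance.

The pair sum is O(N²); long components are scored on a deterministic
centred window of at most `fuzzyen_window` samples (default 5000). A
compiled (numba) kernel exploits the symmetry of the membership matrix;
a pure-numpy path computes the same quantity when numba is absent.

Classification sorts component entropies ascending, Φ₁ ≤ … ≤ Φₙ, and
takes the minimum k in 2..n−1 with Φₖ₊₁ − Φₖ < Φₖ − Φₖ₋₁ (strict): the
dominant jump in entropy sits just below position k. Two boundary
readings exist for which components to eliminate, and the criterion's
plain wording ("the first k") would remove the component *above* the
jump too, contradicting the rationale that only the regular, low-entropy
components are cardiac. Default `boundary_mode="exclusive"` flags the
k − 1 components below the jump; `"literal"` flags the first k. Neither
reading is claimed to be canonical; the report records which was used.
Equal gaps never satisfy the strict inequality, so an arithmetic
progression of entropies flags nothing — the designed negative-control
behaviour. Fewer than 3 components skip classification entirely.

## Metrics

CC is the Pearson correlation; RMSE the root-mean-square difference.
SNR = 10·log₁₀(Σ ref² / Σ (ref − est)²) dB and
RE = ‖est − ref‖₂/‖ref‖₂ are this package's definitions (the names are
conventional but no single formula is); every report records
`reference_kind` because RE/SNR against ground truth exist only in
simulation — real recordings have no clean reference. The Amari index
(1/(2n) normalisation: 0 for a scaled permutation, n − 1 worst case)
serves as the separation-quality oracle in tests.

## Synthetic data: what it emulates, and what it does not

- **sEMG**: white Gaussian noise band-passed to 20–150 Hz (4th-order
  zero-phase Butterworth) at fs = 1000 Hz, unit resting SD, modulated by
  raised-cosine contraction-burst envelopes. The end-to-end fixtures use
  three bursts (peak 3× resting) per recording, emulating repeated
  isokinetic contraction tasks. The bursts matter beyond realism:
  burst-free band-limited Gaussian noise is marginally Gaussian and
  therefore *unidentifiable* by negentropy ICA — the amplitude
  modulation supplies the non-Gaussianity that real contracting muscle
  has.
- **ECG**: five Gaussian bumps (P, Q, R, S, T) at fixed phase offsets
  within each RR interval, heart rate 72 bpm, 2% RR jitter in the
  fixtures. This reproduces the properties the pipeline relies on —
  quasi-periodicity, 0–100 Hz support, low fuzzy entropy — not clinical
  morphology; no pathology is modelled.
- **Interference**: 50 Hz mains sinusoid, slow baseline-wander sinusoid,
  white Gaussian noise.
- **Mixing**: a fixed well-conditioned 3×3 matrix with the sEMG-dominant
  source on channel 1 (electrodes at graded distances from the heart).
  The contamination fixture rescales the ECG source to a chosen
  sEMG:ECG power ratio (default 0 dB, i.e. severe contamination); the
  white-noise source has SD 0.1 of the resting sEMG. The contamination
  ratio of real recordings varies with electrode placement and is a free
  simulation parameter here.

Consequently, passing tests show that the chain separates and removes a
quasi-periodic low-entropy source from an instantaneous linear mixture
under realistic band and amplitude conditions. They do not show
robustness to electrode motion artifacts, non-stationary mixing
(posture change), convolutive propagation, or ECG morphologies far from
a schematic normal beat.

## Problem sizes and numerical choices

Simulation-based checks use 10 s records at 1 kHz (N = 10 000; entropy
window 5000), 50 seeds for the end-to-end recovery experiment and 20
seeds elsewhere; ICA identifiability checks use n = 20 000 samples.
Whitening exactness is asserted to 1e−8, wavelet perfect reconstruction
to 1e−8 relative, orthogonality of unmixing rows to 1e−6, and the
compiled fuzzy-entropy kernel agrees with a brute-force double loop to
1e−12. Ties and degenerate inputs: zero-threshold shrinkage is the
identity; zero-variance channels make whitening fail loudly; constant
series get entropy 0; a rank-deficient mixing matrix in the simulator
warns but is kept (the ground truth remains valid even if separation
cannot succeed).

## Known limitations

- The gap criterion needs ≥ 3 separated components and flags at most
  n − 2 of them (exclusive mode); with exactly 3 channels it can flag
  only one, so recordings with two distinct cardiac components (e.g.
  strong T-wave split across components) need more channels.
- With near-equal component entropies the strict inequality can fire on
  sampling fluctuations; the negative-control rate is a statistical
  guarantee (most seeds flag nothing), not a per-recording one.
- Entropy on a 5000-sample window assumes the component's character is
  stationary across the record; strongly non-stationary recordings
  should lower `fuzzyen_window` placement assumptions accordingly.
- The pipeline assumes an instantaneous, time-invariant mixture; it is
  not designed for convolutive or moving-source scenarios.
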