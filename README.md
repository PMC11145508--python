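# semgclean

Removal of ECG artifacts from surface electromyography (sEMG) recordings.

When sEMG electrodes sit on trunk or upper-limb muscles close to the
heart, the cardiac electrical signal bleeds into every channel. The two
signals overlap in frequency (sEMG roughly 20–250 Hz, ECG 0–100 Hz), so
plain filtering either leaves the artifact in or destroys low-frequency
muscle activity. `semgclean` implements a blind-source-separation
pipeline for this problem, aimed at researchers in biomechanics,
prosthetics control and electrophysiology who need clean sEMG for force
estimation or motion-intention decoding:

1. **Wavelet threshold denoising.** Each channel is decomposed with a
   Daubechies filter bank (default db4, 9 levels); detail coefficients
   are shrunk with an *improved threshold function*

   ```
   f(w) = w − 2λ / (1 + exp(w − λ))    w ≥ λ
        = 0                            |w| < λ
        = w + 2λ / (1 + exp(−w − λ))   w ≤ −λ
   ```

   which is continuous at ±λ like soft thresholding but, unlike it, has a
   bias that vanishes for large |w| (hard- and soft-threshold rules are
   also provided). Per-level thresholds default to the universal rule
   λⱼ = σ̂√(2 ln Nⱼ) with σ̂ = median(|D₁|)/0.6745.

2. **Centering + PCA whitening.** x′ = x − μ, then
   Z = Λ^(−1/2)Uᵀx′ from the eigendecomposition of the sample covariance,
   so cov(Z) = I.

3. **Negentropy FastICA.** Independent components are extracted by
   deflation with the fixed-point update
   w ← E[Z g(wᵀZ)] − E[g′(wᵀZ)] w, g = tanh, after a few steepest-ascent
   refinement steps w ← w + λ·E[Z g(wᵀZ)] that make the iteration robust
   to the random start.

4. **Fuzzy-entropy identification.** Each component is scored with
   FuzzyEn(m, r) = ln Φᵐ − ln Φᵐ⁺¹, where Φᵐ is the mean pairwise
   similarity of baseline-removed m-windows under the membership
   exp(−ln2·(d/r)²) (Chebyshev distance d, tolerance r = 0.2·SD,
   m = 2). ECG is quasi-periodic and scores low; sEMG is noise-like and
   scores high. Sorting entropies ascending as Φ₁ ≤ … ≤ Φₙ, the first k
   (scanning k = 2..n−1) with Φₖ₊₁ − Φₖ < Φₖ − Φₖ₋₁ marks the dominant
   entropy jump; the components below it are flagged as ECG and removed,
   and the channels are rebuilt from the remaining components.

A seeded synthetic-signal generator (band-limited stochastic sEMG with
contraction bursts, Gaussian-bump PQRST ECG trains, mains/wander/white
noise, linear instantaneous mixing) provides ground truth for every
stage, since the method is otherwise only verifiable on recordings.

## Worked example

```python
import numpy as np
from semgclean import contaminated_semg, remove_ecg, evaluate, MultiChannelRecord

# 3 channels of sEMG contaminated with ECG at equal power (0 dB)
gt = contaminated_semg(duration=10.0, contamination_db=0.0, seed=7)
clean, artifact, report = remove_ecg(gt.observed, {"seed": 7})

print("component fuzzy entropies:", np.round(report.entropies, 3))
print("selected k:", report.classification.k,
      "| flagged as ECG:", [int(i) for i in np.flatnonzero(report.classification.ecg_flags)])

truth = MultiChannelRecord(
    gt.mixing[:, [0]] @ gt.source_of_kind("semg").samples[None, :],
    fs=1000.0, labels=gt.observed.labels,
)
print(evaluate(gt.observed, truth).round(3))  # before
print(evaluate(clean, truth).round(3))        # after
```

Output:

```
component fuzzy entropies: [0.062 0.714 1.297]
selected k: 2 | flagged as ECG: [0]

before cleaning (observed vs sEMG ground truth):
channel    cc  rmse  snr_db    re
    ch1 0.775 2.043   0.909 0.901
    ch2 0.552 2.270  -4.443 1.668
    ch3 0.869 1.139   4.047 0.628

after cleaning (clean vs sEMG ground truth):
channel    cc  rmse  snr_db    re
    ch1 0.992 0.915   7.883 0.404
    ch2 0.989 0.987   2.794 0.725
    ch3 0.988 0.559  10.220 0.308
```

The component with entropy 0.062 is the quasi-periodic ECG; the gap
criterion selects k = 2, so exactly that component is eliminated. On
the sEMG-dominant channel the correlation with the true muscle signal
rises from 0.775 to 0.992 and the SNR improves by about 7 dB.

The same chain is available from the shell:

```bash
semgclean simulate --seed 7 --out-dir data/
semgclean remove-ecg --in data/observed.csv --out-dir out/ --seed 7
semgclean evaluate --estimate out/clean.csv --reference data/source_semg.csv
```

Records are CSV matrices (time column + one column per channel) with a
YAML sidecar (`<file>.csv.meta.yaml`) carrying the sampling rate, channel
labels and provenance.

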