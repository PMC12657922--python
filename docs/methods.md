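# Methods

## The encoding model

For every electrode `e`, layer `ℓ` and lag `λ` on an inclusive arithmetic grid
(default −2000 … +2000 ms in 25 ms steps, 161 lags), the response for word `i`
is the mean of the signal samples whose centre times fall in the closed window
`[onset_i + λ − w/2, onset_i + λ + w/2]` with `w = 200` ms. Positive lags are
windows after word onset; lag 0 is onset. Words whose window leaves the
recording are dropped from both design and target *for that lag only*; if more
than 5% of words are missing at a lag the call fails loudly rather than
silently shrinking the sample.

Each layer's embeddings are reduced to `k = 50` principal components per
layer — never on the pooled layers × words array, which would mix information
between layers. Two dialects are exposed:

- `fold_safe` (default): the projection and the centering mean are learned
  from the training rows of each cross-validation fold only and applied to
  the held-out rows. A leakage probe (perturbing the test rows and asserting
  a bit-identical training projection) is part of the test suite.
- `pooled`: the projection is learned once from all words. Kept for parity
  with analyses that report both variants giving the same result.

Regression is ordinary least squares with an intercept; embeddings are
centred by the PCA step, and since the performance metric (Pearson
correlation between pooled out-of-fold predictions and the observed
responses) is location- and scale-invariant, no further standardization is
needed. Rank-deficient designs fall back to the minimum-norm solution with a
warning. Correlation is computed **once** on the pooled out-of-fold
prediction vector, not averaged across folds. Fold assignment defaults to
contiguous blocks of words, which limits temporal leakage between train and
test windows; a seeded random assignment is available.

## The lag-layer statistic and its nulls

Peak lags are per-row argmaxima of the (ROI-averaged) layers × lags matrix,
with ties broken toward the earliest lag — deterministic and conservative for
positive gradients. The statistic is the Pearson correlation between layer
index and peak lag (Spearman is reported alongside). Three null constructions
are implemented:

- **Exact null.** Under independence of `n` bivariate-normal pairs,
  `(r+1)/2 ~ Beta((n−2)/2, (n−2)/2)`; this is the same monotone map that
  sends `r` to a Student-t statistic with `n−2` degrees of freedom. The tail
  is evaluated directly from the Beta survival function.
- **Layer-index permutation.** Peak lags are held fixed while layer indices
  are shuffled `K` times (default 100 000). The p-value uses the add-one rule
  `(1 + #extreme)/(K + 1)`, so it is never zero and its floor is `1/(K+1)`.
  Every resampling operation in the package follows this rule, including the
  degenerate `iterations = 1` case (where p ∈ {1/2, 1}); an exhaustive
  enumeration mode exists for small layer counts and returns the plain
  fraction. Both one- and two-sided alternatives are exposed; the default is
  two-sided.
- **Interpolation control.** A pool of embeddings is built by linearly
  interpolating between the first and last layers at evenly spaced interior
  weights; each pool member is encoded **once** and its peak lag recorded.
  Each iteration then samples `n_pseudo` members without replacement, sorts
  them by weight, assigns them the interior layer indices, and recomputes the
  lag-layer correlation; the p-value is the add-one fraction of iterations
  reaching the observed correlation. Pre-encoding the pool (rather than
  re-encoding per iteration) is what makes 10 000 iterations tractable and is
  statistically identical, since iterations differ only in which precomputed
  peak lags they draw.

Electrode screening phase-randomizes each electrode's signal (amplitudes
preserved, independent uniform phases, DC and Nyquist kept), re-runs the
encoding with a static single-layer embedding, retains each electrode's
max-over-lags value, and takes the max across electrodes per permutation —
a family-wise-style null — followed by Benjamini–Hochberg FDR across
electrodes. That combination is unusual but implemented as specified;
fidelity was preferred over elegance.

The bootstrap for across-electrode means resamples electrodes with
replacement and assesses the observed mean two-tailed against zero. Whether
the reference should be zero or another layer's mean is genuinely open; the
zero-reference reading is implemented and flagged in the docstring.

## Signal conditioning

- **Despiking**: samples beyond `median ± 4×IQR` per electrode ("four
  quartiles" read as four interquartile ranges — the only reading that
  defines a threshold; the factor is a parameter) are replaced by cubic
  interpolation through unflagged neighbours, nearest-value at the edges.
  Electrodes with >50% flagged samples are marked suspect. The operation is
  idempotent on realistic signals.
- **Common average referencing**: per-sample across-electrode mean removed.
- **High-gamma power**: Morlet wavelets (6 cycles, zero-mean complex kernel,
  L2-normalized, built in-package) at 10 log-spaced frequencies in 70–200 Hz;
  frequencies within a 5 Hz guard of 60/120/180 Hz are dropped and power is
  averaged over the rest. Note a physical limitation: 6-cycle wavelets are
  ≈ f/6 Hz wide, so on the default 10-point grid the line exclusion is a
  grid-thinning operation, not a notch — strong suppression of a line tone
  requires a denser grid and narrower (more-cycle) wavelets, which is how the
  test suite exercises the exclusion logic. Equivalence with any particular
  toolbox's wavelet implementation is asserted only at the level of
  band-selectivity properties, not sample values.
- **Smoothing**: unit-sum Hamming window (default 50 ms), reflective edges.

## The synthetic-data generator

The generator emulates a half-hour naturalistic listening session at desk
scale. Defaults: 800 words at a 350 ms mean inter-onset interval (jittered
±20% on a regular grid, keeping onsets strictly increasing and windows
in-bounds), 24 layers, 64 embedding dimensions, 4 electrodes at 512 Hz, and a
planted lag map rising linearly from −100 ms to +400 ms — the span a
high-order language area exhibits across a deep model's layers.

Embedding regimes:

- `chain_nonlinear`: layer 1 i.i.d. standard normal per word; each step
  applies an independent fixed random affine map followed by `tanh` with gain
  2 and re-standardizes per dimension. The gain sets how fast layers
  decorrelate with depth (adjacent-layer linear predictability ≈ 0.8,
  e-folding over a handful of layers); saturating nonlinearity is exactly
  what a linear interpolation between the first and last layers cannot mimic.
- `linear_interp`: interior layers are convex combinations of the (i.i.d.)
  first and last layers with monotonically increasing weights — the regime
  the interpolation control should *not* reject.
- `null`: all layers i.i.d., and the planted drive is omitted entirely, so
  the signal is pure white noise. Used to calibrate the permutation test.

Each electrode's clean signal is the sum over words and layers of a
Hamming-shaped kernel (200 ms) centred at `onset + lag_map(layer)`, scaled by
a fixed random linear readout of that word's layer embedding (amplitudes
standardized across words so every layer contributes equal variance). White
Gaussian noise is added with **SNR defined on the lagged-window scale**: the
ratio of the variance of the windowed means of the clean signal at the
planted lags to the windowed-mean variance of the noise — the scale the
encoding model actually sees. `snr = 0` produces pure noise.

What the generator does *not* emulate: natural-speech timing, autocorrelated
(1/f) neural noise, acoustic confounds, multi-subject hierarchical structure,
or any particular language model's representational geometry. Passing tests
therefore show that the analysis machinery recovers planted structure and is
calibrated under its own null — not that any particular empirical claim about
real recordings is true.

Two generator-side effects are worth knowing when designing experiments:
dense word spacing lets neighbouring words' kernels bleed into the response
window, biasing recovered peak lags by roughly a lag step; and adjacent chain
layers are strongly linearly related, so with very few layers a layer's
encoding can peak at a neighbour's planted lag under noise. Ground-truth
recovery tests therefore use either wide spacing with full-rank PCA (for
exact ±1-step peak recovery) or many layers (for the gradient statistic,
which is robust to both effects).

## Numerical choices

- Window membership is closed-interval with a 1e−9 relative guard against
  floating-point edge jitter; sample `j` has centre time `j/fs`.
- Windowed means use cumulative sums (exact up to float64 accumulation).
- Peak-lag ties go to the earliest lag; `argmax` of NaN-free rows only.
- Permutation extremity comparisons use a 1e−12 tolerance so ties with the
  observed statistic count as extreme (conservative).
- Degenerate inputs (zero-variance peak lags, zero-norm reference rows,
  non-positive row maxima in scaling) are flagged with warnings or NaN
  rather than silently propagated.
- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  datasets are bit-reproducible under a fixed seed.

## Problem sizes

The package's own acceptance checks run at desk scale, chosen so the full
suite completes in minutes on one CPU: gradient recovery at 800 words ×
24 layers × 4 electrodes × 49 lags (20 seeds), null calibration at 100 words
× 12 layers × 21 lags (200 replicates, K = 499), and the interpolation
control with a pool of 120 interpolations, 22 pseudo-layers and 1000
iterations. The analysis itself scales linearly in electrodes × layers ×
lags and is vectorized across electrodes and lags within each
(layer, fold) pair.

## Known limitations

- The spectral stage asserts band selectivity, not toolbox-equivalent sample
  values; the line exclusion thins the wavelet grid rather than notching.
- The interpolation control's pool is deterministic (evenly spaced weights);
  a randomized pool option would add Monte-Carlo error without changing the
  logic.
- The electrode-selection null (max across electrodes) plus per-electrode
  FDR is implemented exactly as specified even though the combination is
  statistically unusual.
- No mixed-effects modelling across electrodes/participants and no Bayes
  factors; ROI labels are arbitrary strings with no spatial logic.
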