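"""Inferential machinery: peak-lag statistics, nulls, controls, electrode selection.

The headline statistic is the *lag-layer correlation*: the Pearson (and
Spearman) correlation between a layer's index and the lag at which that
layer's encoding performance peaks.  Its significance is assessed three ways:

* the exact null distribution of the sample Pearson correlation,
* a layer-index permutation test (peak lags held fixed, indices shuffled),
* an interpolation control that rebuilds pseudo-layers as sorted linear
  interpolations between the first and last layers' embeddings and asks
  whether the observed correlation exceeds what mere interpolation achieves.

Electrode screening uses phase-randomized surrogate signals with a
max-over-lags, max-over-electrodes null and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .encoding import EncodingConfig, average_over_electrodes, encode_layerwise
from .errors import ValidationError
from .types import (
    ElectrodeSelectionResult,
    EncodingTensor,
    LagLayerResult,
    LayeredEmbeddingSet,
    NeuralRecording,
    WordEventTable,
)

__all__ = [
    "peak_lags",
    "lag_layer_correlation",
    "pearson_exact_p",
    "permutation_test_layer_index",
    "lag_layer_analysis",
    "bootstrap_electrode_means",
    "interpolation_control",
    "orthogonalize_layer",
    "phase_randomize",
    "select_electrodes",
    "bh_fdr",
    "levene_peak_lag_spread",
    "paired_ttest_layers",
]

logger = logging.getLogger(__name__)


def peak_lags(matrix: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Lag of each layer's maximum encoding value; ties go to the earliest lag."""
    matrix = np.asarray(matrix, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != lags.size:
        raise ValidationError("expected a layers x lags matrix matching the lag grid")
    if np.all(np.isnan(matrix), axis=1).any():
        raise ValidationError("a layer has no finite encoding values")
    # np.nanargmax returns the first occurrence, i.e. the earliest lag on ties.
    return lags[np.nanargmax(matrix, axis=1)]


def lag_layer_correlation(peak_lag_values: np.ndarray, layer_ids: np.ndarray) -> tuple:
    """(Pearson, Spearman) correlation between layer index and peak lag."""
    x = np.asarray(layer_ids, dtype=float)
    y = np.asarray(peak_lag_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 matched (layer, peak lag) pairs")
    if np.std(y) == 0 or np.std(x) == 0:
        warnings.warn("zero-variance peak lags: lag-layer correlation undefined")
        return np.nan, np.nan
    r_p = float(sps.pearsonr(x, y).statistic)
    r_s = float(sps.spearmanr(x, y).statistic)
    return r_p, r_s


def pearson_exact_p(r: float, n: int, alternative: str = "two-sided") -> float:
    """Tail probability of the sample Pearson correlation under independence.

    Uses the exact null density of ``r`` for ``n`` bivariate-normal pairs:
    ``(r+1)/2`` is Beta((n-2)/2, (n-2)/2) under the null, equivalent to the
    monotone map onto a Student-t statistic with ``n - 2`` degrees of freedom.
    """
    if n < 4:
        raise ValidationError("exact Pearson p requires n >= 4")
    if not -1.0 <= r <= 1.0:
        raise ValidationError("r must lie in [-1, 1]")
    a = (n - 2) / 2.0
    dist = sps.beta(a, a, loc=-1.0, scale=2.0)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * dist.sf(abs(r))))
    if alternative == "greater":
        return float(dist.sf(r))
    if alternative == "less":
        return float(dist.cdf(r))
    raise ValidationError(f"unknown alternative {alternative!r}")


def permutation_test_layer_index(
    peak_lag_values: np.ndarray,
    layer_ids: np.ndarray,
    K: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    exhaustive: bool = False,
) -> float:
    """Permutation p for the lag-layer correlation: shuffle layer indices only.

    Peak lags stay fixed while the layer indices are permuted ``K`` times; the
    p-value uses the add-one rule ``(1 + #extreme) / (K + 1)`` so it is never
    zero.  With ``exhaustive=True`` all permutations are enumerated instead
    (feasible for small layer counts) and the plain fraction is returned.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    x = np.asarray(layer_ids, dtype=float)
    y = np.asarray(peak_lag_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 matched (layer, peak lag) pairs")
    if np.std(y) == 0:
        warnings.warn("zero-variance peak lags: permutation test degenerate")
        return 1.0
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))

    def extreme(r_null: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(r_null) >= abs(r_obs) - 1e-12
        if alternative == "greater":
            return r_null >= r_obs - 1e-12
        if alternative == "less":
            return r_null <= r_obs + 1e-12
        raise ValidationError(f"unknown alternative {alternative!r}")

    if exhaustive:
        perms = np.array(list(_iter_permutations(range(x.size))))
        r_null = (xc[perms] * yc[None, :]).mean(axis=1)
        return float(extreme(r_null).mean())
    rng = np.random.default_rng(seed)
    count = 0
    block = 10_000
    done = 0
    while done < K:
        b = min(block, K - done)
        idx = np.argsort(rng.random((b, x.size)), axis=1)
        r_null = (xc[idx] * yc[None, :]).mean(axis=1)
        count += int(extreme(r_null).sum())
        done += b
    return (1 + count) / (K + 1)


def lag_layer_analysis(
    matrix: np.ndarray,
    lags: np.ndarray,
    layer_ids: np.ndarray,
    K: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> LagLayerResult:
    """Convenience wrapper: peak lags + correlations + exact and permutation p."""
    pl = peak_lags(matrix, lags)
    r_p, r_s = lag_layer_correlation(pl, layer_ids)
    n = len(layer_ids)
    p_exact = pearson_exact_p(r_p, n, alternative) if np.isfinite(r_p) else np.nan
    p_perm = permutation_test_layer_index(pl, layer_ids, K=K, seed=seed,
                                          alternative=alternative)
    return LagLayerResult(
        peak_lags=pl, r_pearson=r_p, r_spearman=r_s,
        p_exact=p_exact, p_permutation=p_perm, n_layers=n,
    )


def bootstrap_electrode_means(
    values: np.ndarray, B: int = 10_000, seed: int | None = None
) -> dict:
    """Bootstrap the across-electrode mean of per-electrode max correlations.

    Electrodes are resampled with replacement ``B`` times; the observed mean
    is assessed two-tailed against the resampled distribution's position
    relative to zero (add-one rule).  Returns the observed mean, the bootstrap
    distribution, and the two-tailed p.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("bootstrap needs >= 2 electrodes")
    if B < 100:
        warnings.warn("fewer than 100 bootstrap samples gives unstable p-values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    boot_means = values[idx].mean(axis=1)
    p_low = (1 + int((boot_means <= 0).sum())) / (B + 1)
    p_high = (1 + int((boot_means >= 0).sum())) / (B + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {
        "observed_mean": float(values.mean()),
        "boot_means": boot_means,
        "p_two_tailed": float(p),
    }


def interpolation_control(
    embeddings: LayeredEmbeddingSet,
    recording: NeuralRecording,
    events: WordEventTable,
    config: EncodingConfig,
    observed_r: float,
    roi: str | None = None,
    n_pseudo: int = 46,
    pool_size: int = 1000,
    iterations: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Pseudo-layer interpolation null for the lag-layer correlation.

    A pool of ``pool_size`` embeddings is built by linear interpolation
    between the first and last layers (evenly spaced interior weights); each
    pool member is encoded once and its ROI-averaged peak lag recorded.  Each
    iteration then samples ``n_pseudo`` pool members without replacement,
    sorts them by interpolation weight, assigns them indices
    ``2 .. n_pseudo+1`` between the true first (1) and last (n_pseudo+2)
    layers, and computes the lag-layer correlation.  The p-value is the
    add-one fraction of iterations whose correlation reaches ``observed_r``.
    """
    if pool_size < n_pseudo:
        raise ValidationError("interpolation pool smaller than n_pseudo")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    first = embeddings.values[:, 0, :]
    last = embeddings.values[:, -1, :]
    weights = np.linspace(0.0, 1.0, pool_size + 2)[1:-1]
    pseudo = (1 - weights)[None, :, None] * first[:, None, :] + weights[
        None, :, None
    ] * last[:, None, :]
    stack = np.concatenate([first[:, None, :], pseudo, last[:, None, :]], axis=1)
    pseudo_set = LayeredEmbeddingSet(values=stack)
    tensor = encode_layerwise(recording, events, pseudo_set, config)
    mat = average_over_electrodes(tensor, roi)
    pl = peak_lags(mat, tensor.lags)
    first_lag, pool_lags, last_lag = pl[0], pl[1:-1], pl[-1]

    rng = np.random.default_rng(seed)
    layer_index = np.arange(1, n_pseudo + 3, dtype=float)
    r_null = np.empty(iterations)
    for it in range(iterations):
        chosen = np.sort(rng.choice(pool_size, size=n_pseudo, replace=False))
        lags_it = np.concatenate([[first_lag], pool_lags[chosen], [last_lag]])
        if np.std(lags_it) == 0:
            r_null[it] = 0.0
        else:
            r_null[it] = np.corrcoef(layer_index, lags_it)[0, 1]
    p = (1 + int((r_null >= observed_r - 1e-12).sum())) / (iterations + 1)
    return {"p": float(p), "null_correlations": r_null, "pool_peak_lags": pl}


def orthogonalize_layer(layer_embs: np.ndarray, reference_embs: np.ndarray) -> np.ndarray:
    """Remove, per word, the projection of a layer's embedding onto a reference.

    For each word ``w``: ``out_w = x_w - (<x_w, m_w> / <m_w, m_w>) m_w``, so
    the output is exactly orthogonal to the reference row by row.  Zero-norm
    reference rows pass the layer row through unchanged with a warning.
    """
    X = np.asarray(layer_embs, dtype=float)
    M = np.asarray(reference_embs, dtype=float)
    if X.shape != M.shape or X.ndim != 2:
        raise ValidationError("layer and reference must be equally shaped words x dims")
    norms = np.einsum("wd,wd->w", M, M)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm reference row(s) passed through")
    coef = np.where(zero, 0.0, np.einsum("wd,wd->w", X, M) / np.where(zero, 1.0, norms))
    return X - coef[:, None] * M


def phase_randomize(signal: np.ndarray, seed=None) -> np.ndarray:
    """Surrogate signal with the same amplitude spectrum but random phases.

    Independent frequency components receive Uniform(0, 2pi) phases with
    conjugate symmetry enforced (real output); the DC and Nyquist components
    are kept as-is, so a constant signal maps to itself.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValidationError("phase randomization needs a 1-D signal of >= 8 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    k = spec.size
    hi = k - 1 if n % 2 == 0 else k  # exclude Nyquist bin when n is even
    phases = rng.uniform(0.0, 2 * np.pi, hi - 1)
    new = spec.copy()
    new[1:hi] = amp[1:hi] * np.exp(1j * phases)
    return np.fft.irfft(new, n=n)


def bh_fdr(p_values: np.ndarray, q: float = 0.01) -> tuple:
    """Benjamini-Hochberg step-up; returns (q_values, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p values must lie in (0, 1]")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def select_electrodes(
    recording: NeuralRecording,
    events: WordEventTable,
    static_embeddings: np.ndarray,
    config: EncodingConfig | None = None,
    n_perm: int = 5000,
    q_threshold: float = 0.01,
    seed: int | None = None,
) -> ElectrodeSelectionResult:
    """Phase-randomization screening of electrodes against static embeddings.

    The observed statistic per electrode is the maximum over lags of the
    cross-validated encoding correlation with a static (single-layer)
    embedding.  The null distribution is built by phase-randomizing every
    electrode's signal, re-running the encoding, taking each electrode's
    max over lags, and then the max across electrodes - one value per
    permutation.  Per-electrode p-values are the add-one percentile of the
    observed statistic in that null; q-values follow Benjamini-Hochberg and
    electrodes with ``q < q_threshold`` are selected.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null distribution")
    config = config or EncodingConfig()
    static_embeddings = np.asarray(static_embeddings, dtype=float)
    if static_embeddings.ndim != 2:
        raise ValidationError("static embeddings must be words x dims")
    emb = LayeredEmbeddingSet(values=static_embeddings[:, None, :])

    def _max_over_lags(rec: NeuralRecording) -> np.ndarray:
        tensor = encode_layerwise(rec, events, emb, config)
        return np.nanmax(tensor.values[:, 0, :], axis=1)

    observed = _max_over_lags(recording)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        surrogate = np.stack(
            [phase_randomize(recording.signal[e], rng) for e in range(recording.n_electrodes)]
        )
        null_max[i] = _max_over_lags(recording.copy_with(surrogate)).max()
    p_values = (1 + (null_max[None, :] >= observed[:, None] - 1e-12).sum(axis=1)) / (
        n_perm + 1
    )
    q_values, selected = bh_fdr(p_values, q=q_threshold)
    return ElectrodeSelectionResult(
        observed=observed,
        null_max=null_max,
        p_values=p_values,
        q_values=q_values,
        selected=selected,
    )


def levene_peak_lag_spread(
    peak_lags_a: np.ndarray, peak_lags_b: np.ndarray, center: str = "mean"
) -> tuple:
    """Levene's test for unequal spread of peak lags between two ROIs.

    Uses the mean-centered variant by default (``center='median'`` gives the
    Brown-Forsythe flavour).  Returns ``(F, p)``.
    """
    a = np.asarray(peak_lags_a, dtype=float)
    b = np.asarray(peak_lags_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("Levene's test needs >= 3 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValidationError("zero within-group deviation in both groups")
    res = sps.levene(a, b, center=center)
    return float(res.statistic), float(res.pvalue)


def paired_ttest_layers(
    peak_lags_a: np.ndarray, peak_lags_b: np.ndarray, q: float = 0.01
) -> dict:
    """Per-layer paired t-test of peak lags between two conditions, FDR-corrected.

    Inputs are layers x electrodes arrays with matched electrodes.  Layers
    with zero-variance differences are flagged (NaN t, p = 1) rather than
    tested.  Returns arrays of t, p, q and rejection flags per layer.
    """
    A = np.atleast_2d(np.asarray(peak_lags_a, dtype=float))
    B = np.atleast_2d(np.asarray(peak_lags_b, dtype=float))
    if A.shape != B.shape:
        raise ValidationError("conditions must have matched layers x electrodes shapes")
    if A.shape[1] < 3:
        raise ValidationError("paired t-test needs >= 3 electrode pairs")
    n_layers = A.shape[0]
    t = np.full(n_layers, np.nan)
    p = np.ones(n_layers)
    degenerate = np.zeros(n_layers, dtype=bool)
    for l in range(n_layers):
        diff = A[l] - B[l]
        if np.allclose(diff, diff[0]):
            if diff[0] == 0:
                t[l], p[l] = 0.0, 1.0
            else:
                degenerate[l] = True
                warnings.warn(
                    f"layer {l}: constant nonzero shift with zero variance; t undefined"
                )
            continue
        res = sps.ttest_rel(A[l], B[l])
        t[l], p[l] = float(res.statistic), float(res.pvalue)
    q_values, reject = bh_fdr(p, q=q)
    reject = reject & ~degenerate
    return {"t": t, "p": p, "q": q_values, "reject": reject, "degenerate": degenerate}
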