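"""Lag-wise cross-validated linear encoding models.

For every combination of electrode, layer and lag a separate ordinary
least-squares regression predicts the mean neural signal inside a short window
centred at ``onset + lag`` from that layer's (PCA-reduced) word embeddings.
Ten-fold cross-validation produces one held-out prediction per word; the
performance metric is the single Pearson correlation between the pooled
out-of-fold predictions and the observed responses.  The result is an
electrodes x layers x lags tensor of correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .embeddings import pca_per_layer
from .errors import ValidationError
from .types import (
    EncodingTensor,
    LayeredEmbeddingSet,
    NeuralRecording,
    WordEventTable,
)

__all__ = [
    "EncodingConfig",
    "build_lag_grid",
    "lagged_response",
    "lagged_response_matrix",
    "fit_encoding_cv",
    "encode_layerwise",
    "average_over_electrodes",
    "scale_rows",
]

logger = logging.getLogger(__name__)


@dataclass
class EncodingConfig:
    """Lag grid, response window and cross-validation settings.

    ``lag_min``/``lag_max``/``lag_step`` define an inclusive arithmetic lag
    grid in ms (positive lags are windows *after* word onset; lag 0 is onset).
    ``window`` is the width of the rolling response window in ms: at each lag
    the model predicts the average signal within +-``window``/2 of the lag.
    """

    lag_min: float = -2000.0
    lag_max: float = 2000.0
    lag_step: float = 25.0
    window: float = 200.0
    n_folds: int = 10
    pca_k: int = 50

    def validate(self) -> None:
        if self.lag_step <= 0:
            raise ValidationError("lag_step must be positive")
        if self.window <= 0:
            raise ValidationError("window must be positive")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.lag_max < self.lag_min:
            raise ValidationError("lag_max must be >= lag_min")
        span = self.lag_max - self.lag_min
        if abs(span / self.lag_step - round(span / self.lag_step)) > 1e-9:
            raise ValidationError("(lag_max - lag_min) must be divisible by lag_step")
        if self.pca_k < 1:
            raise ValidationError("pca_k must be >= 1")

    def to_dict(self) -> dict:
        return {
            "lag_min": self.lag_min,
            "lag_max": self.lag_max,
            "lag_step": self.lag_step,
            "window": self.window,
            "n_folds": self.n_folds,
            "pca_k": self.pca_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingConfig":
        return cls(**d)


def build_lag_grid(config: EncodingConfig) -> np.ndarray:
    """Inclusive arithmetic lag sequence ``lag_min .. lag_max`` in ms."""
    config.validate()
    n = int(round((config.lag_max - config.lag_min) / config.lag_step)) + 1
    return config.lag_min + config.lag_step * np.arange(n)


def lagged_response_matrix(
    recording: NeuralRecording,
    events: WordEventTable,
    lags: np.ndarray,
    window: float,
    max_missing_frac: float = 0.05,
) -> np.ndarray:
    """Windowed-mean responses for every (word, electrode, lag).

    Returns a words x electrodes x lags array: the mean of the samples whose
    centre times fall inside the closed window
    ``[onset + lag - window/2, onset + lag + window/2]``.  Words whose window
    leaves the recording are NaN for that lag; if more than
    ``max_missing_frac`` of words are missing at some (electrode, lag) the
    call fails.
    """
    lags = np.asarray(lags, dtype=float)
    fs = recording.sampling_rate
    dt = 1000.0 / fs
    centers = events.onsets[:, None] + lags[None, :]  # (W, L)
    lo = np.ceil((centers - window / 2) / dt - 1e-9).astype(int)
    hi = np.floor((centers + window / 2) / dt + 1e-9).astype(int)
    n = recording.n_samples
    valid = (lo >= 0) & (hi < n) & (hi >= lo)
    missing_frac = 1.0 - valid.mean(axis=0)  # per lag
    if np.any(missing_frac > max_missing_frac):
        worst = lags[int(np.argmax(missing_frac))]
        raise ValidationError(
            f"more than {max_missing_frac:.0%} of word windows out of bounds at lag {worst} ms"
        )
    csum = np.concatenate(
        [np.zeros((recording.n_electrodes, 1)), np.cumsum(recording.signal, axis=1)],
        axis=1,
    )
    lo_c = np.clip(lo, 0, n - 1)
    hi_c = np.clip(hi, 0, n - 1)
    sums = csum[:, hi_c + 1] - csum[:, lo_c]  # (E, W, L)
    counts = (hi_c - lo_c + 1)[None, :, :]
    out = sums / counts
    out = np.where(valid[None, :, :], out, np.nan)
    return np.moveaxis(out, 0, 1)  # (W, E, L)


def lagged_response(
    recording: NeuralRecording,
    events: WordEventTable,
    electrode: int,
    lag: float,
    window: float,
) -> np.ndarray:
    """One windowed-mean response per word for a single electrode and lag."""
    mat = lagged_response_matrix(
        recording, events, np.array([lag]), window, max_missing_frac=1.0
    )
    resp = mat[:, electrode, 0]
    if np.isnan(resp).mean() > 0.05:
        raise ValidationError("more than 5% of word windows fall outside the recording")
    return resp


def _check_folds(fold_ids: np.ndarray, n_words: int, n_features: int) -> np.ndarray:
    fold_ids = np.asarray(fold_ids, dtype=int)
    if fold_ids.size != n_words:
        raise ValidationError("fold assignment must cover every word exactly once")
    for f in np.unique(fold_ids):
        n_train = int((fold_ids != f).sum())
        if n_train <= n_features + 1:
            raise ValidationError(
                f"training fold for test fold {f} has {n_train} words; "
                f"need more than {n_features + 1}"
            )
    return fold_ids


def fit_encoding_cv(X: np.ndarray, y: np.ndarray, folds: np.ndarray) -> tuple:
    """Cross-validated OLS encoding fit; returns (pooled correlation, predictions).

    For each fold an OLS model with intercept is estimated on the training
    rows and used to predict the held-out rows; after all folds, a single
    Pearson correlation is computed between the full out-of-fold prediction
    vector and ``y``.  Rank-deficient designs fall back to the minimum-norm
    least-squares solution with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValidationError("X must be words x features and y one value per word")
    fold_ids = _check_folds(folds, y.size, X.shape[1])
    A = np.column_stack([np.ones(y.size), X])
    preds = np.empty_like(y)
    for f in np.unique(fold_ids):
        te = fold_ids == f
        tr = ~te
        beta, _, rank, _ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
        if rank < A.shape[1]:
            warnings.warn(
                "rank-deficient design; using the minimum-norm OLS solution",
                stacklevel=2,
            )
        preds[te] = A[te] @ beta
    r = _pearson(preds, y)
    return r, preds


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _pooled_corr_columns(preds: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation between two equally shaped matrices."""
    pc = preds - preds.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    denom = np.sqrt((pc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * yc).sum(axis=0) / denom
    return r


def encode_layerwise(
    recording: NeuralRecording,
    events: WordEventTable,
    embeddings: LayeredEmbeddingSet,
    config: EncodingConfig,
    dialect: str = "fold_safe",
) -> EncodingTensor:
    """Full encoding analysis: a correlation for every (electrode, layer, lag).

    Embeddings are reduced to ``config.pca_k`` components per layer first
    (fold-safe by default: a separate projection is learned from each fold's
    training rows).  Words whose response window leaves the recording at a
    given lag are dropped from both design and target for that lag only.
    """
    config.validate()
    if dialect not in ("fold_safe", "pooled"):
        raise ValidationError(f"unknown PCA dialect {dialect!r}")
    if embeddings.n_words != events.n_words:
        raise ValidationError("embeddings and events disagree on word count")
    lags = build_lag_grid(config)
    fold_ids = events.fold_ids
    if fold_ids is None:
        fold_ids = events.assign_folds(config.n_folds).fold_ids
    k = min(config.pca_k, embeddings.n_dims)
    _check_folds(fold_ids, events.n_words, k)

    Y3 = lagged_response_matrix(recording, events, lags, config.window)  # (W, E, L)
    W, E, L = Y3.shape
    Ymat = Y3.reshape(W, E * L)
    col_valid = ~np.isnan(Ymat)
    full_cols = col_valid.all(axis=0)

    uniq_folds = np.unique(fold_ids)
    values = np.full((E, embeddings.n_layers, L), np.nan)
    preds = np.empty((W, E * L))

    for li in range(embeddings.n_layers):
        layer_set = LayeredEmbeddingSet(
            values=embeddings.values[:, [li], :], layer_ids=[embeddings.layer_ids[li]]
        )
        preds[:] = np.nan
        if dialect == "pooled":
            red_all, _ = pca_per_layer(layer_set, None, k=k)
            Xall = red_all.values[:, 0, :]
        for f in uniq_folds:
            te = fold_ids == f
            tr = ~te
            tr_idx = np.flatnonzero(tr)
            te_idx = np.flatnonzero(te)
            if dialect == "pooled":
                Xtr = Xall[tr_idx]
                Xte = Xall[te_idx]
            else:
                train_set = LayeredEmbeddingSet(values=layer_set.values[tr_idx])
                test_set = LayeredEmbeddingSet(values=layer_set.values[te_idx])
                red_tr, red_te = pca_per_layer(train_set, test_set, k=k, dialect="fold_safe")
                Xtr = red_tr.values[:, 0, :]
                Xte = red_te.values[:, 0, :]
            Atr = np.column_stack([np.ones(Xtr.shape[0]), Xtr])
            Ate = np.column_stack([np.ones(Xte.shape[0]), Xte])
            P = np.linalg.pinv(Atr)
            # Fast path: all words in-bounds for these columns.
            B = P @ Ymat[tr_idx][:, full_cols]
            preds[np.ix_(te_idx, full_cols)] = Ate @ B
            # Slow path: columns with missing words drop those words per lag.
            for c in np.flatnonzero(~full_cols):
                ok_tr = tr_idx[col_valid[tr_idx, c]]
                ok_te = te_idx[col_valid[te_idx, c]]
                if ok_tr.size <= k + 1 or ok_te.size == 0:
                    continue
                A_ok = np.column_stack([np.ones(ok_tr.size), Xtr[col_valid[tr_idx, c]]])
                beta, *_ = np.linalg.lstsq(A_ok, Ymat[ok_tr, c], rcond=None)
                preds[ok_te, c] = np.column_stack(
                    [np.ones(ok_te.size), Xte[col_valid[te_idx, c]]]
                ) @ beta
        # Pooled correlation per column over the words predicted at that column.
        if full_cols.all():
            r = _pooled_corr_columns(preds, Ymat)
        else:
            r = np.empty(E * L)
            for c in range(E * L):
                ok = col_valid[:, c] & ~np.isnan(preds[:, c])
                r[c] = _pearson(preds[ok, c], Ymat[ok, c]) if ok.sum() > 2 else np.nan
        values[:, li, :] = r.reshape(E, L)

    return EncodingTensor(
        values=values,
        lags=lags,
        layer_ids=embeddings.layer_ids,
        electrode_ids=list(recording.electrode_ids),
        roi_labels=list(recording.roi_labels),
    )


def average_over_electrodes(tensor: EncodingTensor, roi: str | None = None) -> np.ndarray:
    """Unweighted mean of the encoding tensor across an ROI's electrodes."""
    if roi is None:
        mask = np.ones(len(tensor.roi_labels), dtype=bool)
    else:
        mask = np.array([lbl == roi for lbl in tensor.roi_labels])
    if not mask.any():
        raise ValidationError(f"no electrodes carry ROI label {roi!r}")
    return tensor.values[mask].mean(axis=0)


def scale_rows(matrix: np.ndarray) -> np.ndarray:
    """Scale each layer's encoding curve to peak at 1.

    Rows whose maximum is not positive cannot be meaningfully scaled; they are
    returned as NaN and a warning names how many were dropped.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("expected a layers x lags matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        row_max = np.nanmax(matrix, axis=1)
    bad = ~(row_max > 0)
    out = matrix / np.where(bad, np.nan, row_max)[:, None]
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} row(s) with non-positive maximum excluded from scaling",
            stacklevel=2,
        )
    return out
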