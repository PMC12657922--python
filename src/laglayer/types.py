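"""Core in-memory containers joining stimulus events, embeddings and neural signal.

The three input containers mirror the three sides of an event-locked encoding
analysis: :class:`WordEventTable` carries the temporal skeleton (one row per
word), :class:`LayeredEmbeddingSet` the model side (words x layers x dims), and
:class:`NeuralRecording` the brain side (electrodes x samples).  The central
intermediate result of the analysis is an :class:`EncodingTensor` of held-out
correlations for every (electrode, layer, lag) combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "WordEventTable",
    "LayeredEmbeddingSet",
    "NeuralRecording",
    "EncodingTensor",
    "LagLayerResult",
    "ElectrodeSelectionResult",
]


@dataclass
class WordEventTable:
    """Per-word stimulus events.

    Parameters
    ----------
    words : sequence of str
        Word identities (tokens as presented).
    onsets : array of float
        Word onset times in milliseconds, strictly increasing.
    ranks : array of int, optional
        Next-word probability rank assigned to each word by a predictive
        language model (1 = the model's top guess).  Required only for
        predictability splits.
    fold_ids : array of int, optional
        Cross-validation fold assignment, values in ``0 .. n_folds-1``.
    """

    words: Sequence[str]
    onsets: np.ndarray
    ranks: np.ndarray | None = None
    fold_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValidationError("onsets must be a 1-D array of milliseconds")
        if len(self.words) != self.onsets.size:
            raise ValidationError("words and onsets must have equal length")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValidationError("onsets must be strictly increasing")
        if self.ranks is not None:
            self.ranks = np.asarray(self.ranks, dtype=int)
            if self.ranks.shape != self.onsets.shape:
                raise ValidationError("ranks must match onsets in length")
            if np.any(self.ranks < 1):
                raise ValidationError("ranks are 1-based and must be >= 1")
        if self.fold_ids is not None:
            self.fold_ids = np.asarray(self.fold_ids, dtype=int)
            if self.fold_ids.shape != self.onsets.shape:
                raise ValidationError("fold_ids must match onsets in length")

    @property
    def n_words(self) -> int:
        return self.onsets.size

    def assign_folds(
        self, n_folds: int = 10, method: str = "contiguous", seed: int | None = None
    ) -> "WordEventTable":
        """Return a copy with words partitioned into ``n_folds`` folds.

        ``contiguous`` (the default) assigns consecutive blocks of words to
        each fold, which limits temporal leakage between train and test words;
        ``random`` shuffles the assignment with the given seed.
        """
        if n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if n_folds > self.n_words:
            raise ValidationError("cannot have more folds than words")
        ids = (np.arange(self.n_words) * n_folds) // self.n_words
        if method == "random":
            rng = np.random.default_rng(seed)
            ids = rng.permutation(ids)
        elif method != "contiguous":
            raise ValidationError(f"unknown fold method: {method!r}")
        return replace(self, fold_ids=ids)

    def subset(self, idx: np.ndarray) -> "WordEventTable":
        """Row subset preserving onset order (``idx`` must be sorted)."""
        idx = np.asarray(idx)
        return WordEventTable(
            words=[self.words[i] for i in idx],
            onsets=self.onsets[idx],
            ranks=None if self.ranks is None else self.ranks[idx],
            fold_ids=None if self.fold_ids is None else self.fold_ids[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"word": list(self.words), "onset": self.onsets})
        if self.ranks is not None:
            df["rank"] = self.ranks
        if self.fold_ids is not None:
            df["fold_id"] = self.fold_ids
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WordEventTable":
        return cls(
            words=df["word"].astype(str).tolist(),
            onsets=df["onset"].to_numpy(dtype=float),
            ranks=df["rank"].to_numpy() if "rank" in df.columns else None,
            fold_ids=df["fold_id"].to_numpy() if "fold_id" in df.columns else None,
        )


@dataclass
class LayeredEmbeddingSet:
    """A words x layers x dims array of per-word, per-layer embeddings."""

    values: np.ndarray
    layer_ids: np.ndarray | None = None
    word_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be words x layers x dims")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("embedding values must be finite")
        if self.layer_ids is None:
            self.layer_ids = np.arange(1, self.values.shape[1] + 1)
        self.layer_ids = np.asarray(self.layer_ids, dtype=int)
        if self.layer_ids.size != self.values.shape[1]:
            raise ValidationError("layer_ids must match the layer axis")
        if self.layer_ids.size > 1 and not np.all(np.diff(self.layer_ids) > 0):
            raise ValidationError("layer_ids must be strictly increasing")
        if self.word_index is None:
            self.word_index = np.arange(self.values.shape[0])
        self.word_index = np.asarray(self.word_index, dtype=int)
        if self.word_index.size != self.values.shape[0]:
            raise ValidationError("word_index must match the word axis")

    @property
    def n_words(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[1]

    @property
    def n_dims(self) -> int:
        return self.values.shape[2]

    def layer(self, layer_id: int) -> np.ndarray:
        """Words x dims slice for one layer id."""
        pos = np.flatnonzero(self.layer_ids == layer_id)
        if pos.size == 0:
            raise ValidationError(f"unknown layer id {layer_id}")
        return self.values[:, pos[0], :]


@dataclass
class NeuralRecording:
    """Continuous multi-electrode signal with sampling rate and ROI labels."""

    signal: np.ndarray
    sampling_rate: float
    electrode_ids: Sequence[str] | None = None
    roi_labels: Sequence[str] | None = None
    suspect: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be electrodes x samples")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        n = self.signal.shape[0]
        if self.electrode_ids is None:
            self.electrode_ids = [f"E{i:03d}" for i in range(n)]
        if self.roi_labels is None:
            self.roi_labels = ["NA"] * n
        if len(self.electrode_ids) != n or len(self.roi_labels) != n:
            raise ValidationError("electrode_ids / roi_labels must match electrode count")

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def copy_with(self, signal: np.ndarray) -> "NeuralRecording":
        return NeuralRecording(
            signal=signal,
            sampling_rate=self.sampling_rate,
            electrode_ids=list(self.electrode_ids),
            roi_labels=list(self.roi_labels),
            suspect=list(self.suspect),
        )


@dataclass
class EncodingTensor:
    """Electrodes x layers x lags array of held-out encoding correlations."""

    values: np.ndarray
    lags: np.ndarray
    layer_ids: np.ndarray
    electrode_ids: Sequence[str]
    roi_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lags = np.asarray(self.lags, dtype=float)
        self.layer_ids = np.asarray(self.layer_ids, dtype=int)
        if self.values.ndim != 3:
            raise ValidationError("values must be electrodes x layers x lags")
        e, l, g = self.values.shape
        if self.lags.size != g or self.layer_ids.size != l:
            raise ValidationError("coordinate arrays must match tensor shape")
        if len(self.electrode_ids) != e or len(self.roi_labels) != e:
            raise ValidationError("electrode labels must match tensor shape")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")


@dataclass
class LagLayerResult:
    """Headline output: per-layer peak lags and lag-layer correlation stats."""

    peak_lags: np.ndarray
    r_pearson: float
    r_spearman: float
    p_exact: float
    p_permutation: float
    n_layers: int

    def to_dict(self) -> dict:
        return {
            "peak_lags": np.asarray(self.peak_lags, dtype=float).tolist(),
            "r_pearson": float(self.r_pearson),
            "r_spearman": float(self.r_spearman),
            "p_exact": float(self.p_exact),
            "p_permutation": float(self.p_permutation),
            "n_layers": int(self.n_layers),
        }


@dataclass
class ElectrodeSelectionResult:
    """Output of the phase-randomization electrode screening."""

    observed: np.ndarray  # per-electrode max-over-lags encoding correlation
    null_max: np.ndarray  # permutation distribution of max-over-electrodes
    p_values: np.ndarray
    q_values: np.ndarray
    selected: np.ndarray

    def to_frame(self, electrode_ids: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "observed": self.observed,
                "p": self.p_values,
                "q": self.q_values,
                "selected": self.selected,
            }
        )
        if electrode_ids is not None:
            df.insert(0, "electrode", list(electrode_ids))
        return df
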