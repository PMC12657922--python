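"""Layered embeddings: causal alignment, per-layer PCA, splits, symbolic builders.

A layered language model is consumed here only through its precomputed hidden
states (words x layers x dims); the alignment rule that makes embeddings
causal - each word receives the state produced at the *previous* position, so
a word never contributes to its own embedding - is implemented in
:func:`extract_causal_embeddings`.

Dimensionality reduction is always per layer, never on the pooled
layers-x-words array, so no information leaks between layers.  Two dialects
are offered: ``fold_safe`` learns the projection from the training rows only
(the default), ``pooled`` learns it from train and test together.

The symbolic builders construct fixed-length psycholinguistic feature vectors
at four classical levels of description: phonology (binary phoneme features),
morphology (ordered one-hot morphemes), syntax (POS/TAG one-hots for a token,
its head and its outermost descendants) and lexical semantics (dense token
vectors averaged across a word's tokens).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ValidationError
from .types import LayeredEmbeddingSet, WordEventTable

__all__ = [
    "extract_causal_embeddings",
    "pca_per_layer",
    "split_by_predictability",
    "SymbolicAnnotation",
    "build_phoneme_embedding",
    "build_morpheme_embedding",
    "build_syntactic_embedding",
    "build_semantic_embedding",
    "UPOS_TAGS",
    "PTB_TAGS",
]

logger = logging.getLogger(__name__)

# Universal part-of-speech inventory (17 coarse categories).
UPOS_TAGS = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
)

# Penn Treebank fine-grained tag inventory (36 word-level tags).
PTB_TAGS = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNS", "NNP", "NNPS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
    "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP",
    "VBZ", "WDT", "WP", "WP$", "WRB",
)


def extract_causal_embeddings(
    hidden_states: np.ndarray, offset: int = 1
) -> LayeredEmbeddingSet:
    """Align hidden states causally: word ``i`` gets the state from position ``i-offset``.

    With the default ``offset=1`` the embedding assigned to a word is the
    model's output for the *previous* word, so the word itself never enters
    its own representation; the first ``offset`` words are dropped because
    they have no prior context.  ``offset=0`` is the identity alignment.
    """
    hidden_states = np.asarray(hidden_states, dtype=float)
    if hidden_states.ndim != 3:
        raise ValidationError("hidden_states must be words x layers x dims")
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    n_words = hidden_states.shape[0]
    if n_words - offset < 1 or (offset > 0 and n_words < 2):
        raise ValidationError("need at least offset+1 words (>= 2 for causal alignment)")
    if offset == 0:
        values = hidden_states
        word_index = np.arange(n_words)
    else:
        values = hidden_states[: n_words - offset]
        word_index = np.arange(offset, n_words)
    return LayeredEmbeddingSet(values=values, word_index=word_index)


def pca_per_layer(
    train: LayeredEmbeddingSet,
    test: LayeredEmbeddingSet | None = None,
    k: int = 50,
    dialect: str = "fold_safe",
) -> tuple:
    """Reduce each layer independently to ``k`` principal components.

    ``fold_safe`` fits the projection (and the centering mean) on the training
    rows only and applies it to both sets; ``pooled`` fits on the union of
    train and test rows.  Layers are never mixed: layer ``l`` of the output
    depends only on layer ``l`` of the input.
    """
    if dialect not in ("fold_safe", "pooled"):
        raise ValidationError(f"unknown PCA dialect {dialect!r}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > train.n_dims:
        raise ValidationError(f"k={k} exceeds embedding dimension {train.n_dims}")
    n_fit = train.n_words if dialect == "fold_safe" or test is None else (
        train.n_words + test.n_words
    )
    if k > n_fit:
        raise ValidationError(f"k={k} exceeds the number of fitting rows {n_fit}")
    if test is not None and test.n_layers != train.n_layers:
        raise ValidationError("train and test must have the same layers")

    out_train = np.empty((train.n_words, train.n_layers, k))
    out_test = None if test is None else np.empty((test.n_words, test.n_layers, k))
    for li in range(train.n_layers):
        xtr = train.values[:, li, :]
        if dialect == "pooled" and test is not None:
            fit_rows = np.vstack([xtr, test.values[:, li, :]])
        else:
            fit_rows = xtr
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(fit_rows)
        out_train[:, li, :] = pca.transform(xtr)
        if test is not None:
            out_test[:, li, :] = pca.transform(test.values[:, li, :])
    train_red = LayeredEmbeddingSet(
        values=out_train, layer_ids=train.layer_ids, word_index=train.word_index
    )
    if test is None:
        return train_red, None
    test_red = LayeredEmbeddingSet(
        values=out_test, layer_ids=test.layer_ids, word_index=test.word_index
    )
    return train_red, test_red


def split_by_predictability(
    events: WordEventTable, top_predicted_k: int = 1, not_predicted_k: int = 5
) -> tuple:
    """Indices of predicted (rank <= top k) and not-predicted (rank > k') words.

    Words whose rank falls strictly between the two thresholds belong to
    neither subset, which keeps the two analyses comparable in stringency.
    """
    if events.ranks is None:
        raise ValidationError("events carry no predictability ranks")
    if top_predicted_k < 1 or not_predicted_k < top_predicted_k:
        raise ValidationError("need 1 <= top_predicted_k <= not_predicted_k")
    predicted = np.flatnonzero(events.ranks <= top_predicted_k)
    not_predicted = np.flatnonzero(events.ranks > not_predicted_k)
    return predicted, not_predicted


@dataclass
class SymbolicAnnotation:
    """Pluggable psycholinguistic annotations for a word list.

    ``syntax`` maps each word to a list of tokens, each token being four
    ``(POS, TAG)`` pairs for the token itself, its head, and its leftmost and
    rightmost descendants.  ``token_vectors`` maps each word to an
    ``n_tokens x 96`` array of dense vectors.
    """

    phonemes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    phoneme_features: pd.DataFrame | None = None  # index: phoneme, 33 binary cols
    morphemes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    morpheme_inventory: Sequence[str] = field(default_factory=list)
    syntax: Mapping[str, Sequence] = field(default_factory=dict)
    token_vectors: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phoneme_features is not None:
            for word, phs in self.phonemes.items():
                for ph in phs:
                    if ph not in self.phoneme_features.index:
                        raise ValidationError(
                            f"phoneme {ph!r} (word {word!r}) missing from the feature table"
                        )
        inv = set(self.morpheme_inventory)
        for word, ms in self.morphemes.items():
            for m in ms:
                if m not in inv:
                    raise ValidationError(
                        f"morpheme {m!r} (word {word!r}) missing from the inventory"
                    )


def _phoneme_slots(n: int, max_phonemes: int, pad_mode: str) -> np.ndarray:
    if pad_mode == "tail":
        return np.arange(n)
    if pad_mode != "centered":
        raise ValidationError(f"unknown pad_mode {pad_mode!r}")
    if n == 1:
        return np.array([max_phonemes // 2])
    # First phoneme at the first slot, last at the last, middle at the middle.
    return np.round(np.linspace(0, max_phonemes - 1, n)).astype(int)


def build_phoneme_embedding(
    annotation: SymbolicAnnotation,
    word: str,
    max_phonemes: int = 17,
    pad_mode: str = "centered",
) -> np.ndarray:
    """Concatenate a word's binary phoneme-feature vectors into a fixed slot grid.

    Output length is ``max_phonemes * n_features`` (561 with the default 17
    slots and 33 features).  ``tail`` packs phonemes into the leading slots;
    ``centered`` spreads them so the middle phoneme sits at the middle slot
    and the first and last phonemes at the end slots.  Unused slots are zero.
    """
    if annotation.phoneme_features is None:
        raise ValidationError("annotation has no phoneme feature table")
    if word not in annotation.phonemes:
        raise ValidationError(f"no phoneme annotation for word {word!r}")
    phs = list(annotation.phonemes[word])
    if len(phs) == 0 or len(phs) > max_phonemes:
        raise ValidationError(
            f"word {word!r} has {len(phs)} phonemes; expected 1..{max_phonemes}"
        )
    feats = annotation.phoneme_features
    for ph in phs:
        if ph not in feats.index:
            raise ValidationError(f"unknown phoneme {ph!r}")
    n_feat = feats.shape[1]
    out = np.zeros(max_phonemes * n_feat)
    slots = _phoneme_slots(len(phs), max_phonemes, pad_mode)
    for slot, ph in zip(slots, phs):
        out[slot * n_feat : (slot + 1) * n_feat] = feats.loc[ph].to_numpy(dtype=float)
    return out


def build_morpheme_embedding(
    annotation: SymbolicAnnotation, word: str, max_morphemes: int = 6
) -> np.ndarray:
    """Ordered concatenation of one-hot morpheme encodings, zero-padded at the tail.

    Output length is ``|inventory| * max_morphemes`` (6252 for an inventory of
    1042 morphemes and at most 6 morphemes per word).
    """
    if word not in annotation.morphemes:
        raise ValidationError(f"no morpheme annotation for word {word!r}")
    inv = list(annotation.morpheme_inventory)
    if not inv:
        raise ValidationError("empty morpheme inventory")
    index = {m: i for i, m in enumerate(inv)}
    ms = list(annotation.morphemes[word])
    if len(ms) == 0 or len(ms) > max_morphemes:
        raise ValidationError(
            f"word {word!r} has {len(ms)} morphemes; expected 1..{max_morphemes}"
        )
    out = np.zeros(len(inv) * max_morphemes)
    for j, m in enumerate(ms):
        if m not in index:
            raise ValidationError(f"unknown morpheme {m!r}")
        out[j * len(inv) + index[m]] = 1.0
    return out


def _onehot(label: str, inventory: Sequence[str], kind: str) -> np.ndarray:
    try:
        i = inventory.index(label)
    except ValueError:
        raise ValidationError(f"unknown {kind} label {label!r}") from None
    v = np.zeros(len(inventory))
    v[i] = 1.0
    return v


def build_syntactic_embedding(annotation: SymbolicAnnotation, word: str) -> np.ndarray:
    """212-dim syntactic vector: 4 roles x (17 POS one-hot || 36 TAG one-hot).

    The four roles are the token itself, its parse head, and its leftmost and
    rightmost descendants.  Multi-token words are averaged elementwise.
    """
    if word not in annotation.syntax:
        raise ValidationError(f"no syntactic annotation for word {word!r}")
    tokens = annotation.syntax[word]
    if len(tokens) == 0:
        raise ValidationError(f"word {word!r} has no tokens")
    vecs = []
    for tok in tokens:
        if len(tok) != 4:
            raise ValidationError("each token needs 4 (POS, TAG) role pairs")
        parts = []
        for pos, tag in tok:
            parts.append(_onehot(pos, list(UPOS_TAGS), "POS"))
            parts.append(_onehot(tag, list(PTB_TAGS), "TAG"))
        vecs.append(np.concatenate(parts))
    return np.mean(vecs, axis=0)


def build_semantic_embedding(annotation: SymbolicAnnotation, word: str) -> np.ndarray:
    """Elementwise mean of a word's dense token vectors (96-dim by convention)."""
    if word not in annotation.token_vectors:
        raise ValidationError(f"no token vectors for word {word!r}")
    vecs = np.asarray(annotation.token_vectors[word], dtype=float)
    if vecs.ndim == 1:
        vecs = vecs[None, :]
    if vecs.shape[0] == 0:
        raise ValidationError(f"word {word!r} has no token vectors")
    return vecs.mean(axis=0)
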