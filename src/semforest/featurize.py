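"""Turning care episodes into feature vectors.

Under every utilization strategy an episode's representation at one
context window size is a *count-weighted bag of embeddings*: for each data
type, the vectors of the episode's events are multiplied by their
occurrence counts and summed, and the four per-type blocks are
concatenated in the canonical order (word, diagnosis, drug, measurement),
giving a dense vector of length V x T. Representations at different
window sizes are concatenated in ascending window order where a strategy
calls for it.

Occurrences of the target diagnosis code are removed from the visible
diagnosis stream before featurization, so the feature vector never
depends on the label-defining code. Events absent from a space's
vocabulary contribute the zero vector.

The count-based baseline (``bag_of_events``) represents an episode as raw
occurrence counts over the pooled vocabulary of all four streams.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from math import isqrt
from typing import NamedTuple, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import (
    CANONICAL_DATA_TYPES,
    CareEpisode,
    DataType,
    LabeledDataset,
)
from .embedding import SemanticSpaceEnsemble

__all__ = [
    "Strategy", "TransformedDataset", "CountDataset", "FeatureBudget",
    "embed_episode", "transform_dataset", "concat_windows",
    "feature_budget", "bag_of_events",
]


class Strategy(str, Enum):
    """Semantic space ensemble utilization strategies.

    FDR
        Fused Diverse Representations: all window representations are
        concatenated; each tree gets a bootstrap replicate and a random
        sqrt(N) feature subset of the fused matrix.
    RDR_FS
        Randomized Diverse Representations with Feature Subsampling: each
        tree draws one window size at random and a sqrt(N) feature subset
        of that window's representation.
    RDR_ALL
        Randomized Diverse Representations without Feature Subsampling:
        each tree draws one window size at random and uses that
        representation's entire feature set.
    """

    FDR = "fdr"
    RDR_FS = "rdr-fs"
    RDR_ALL = "rdr-all"


class FeatureBudget(NamedTuple):
    ensemble_features: int
    tree_features: int


@dataclass
class TransformedDataset:
    """Dense episode-by-feature matrix plus column-block bookkeeping.

    ``block_index`` lists ``(window, data_type, start, stop)`` for every
    column block, ordered by ascending window then canonical data-type
    order; the ranges partition the columns.
    """

    matrix: np.ndarray
    block_index: list[tuple[int, DataType, int, int]]
    labels: np.ndarray
    windows: tuple[int, ...]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def block(self, window: int, data_type: DataType) -> np.ndarray:
        for w, t, start, stop in self.block_index:
            if w == window and t == data_type:
                return self.matrix[:, start:stop]
        raise KeyError((window, data_type))


@dataclass
class CountDataset:
    """Sparse bag-of-events count matrix (one column per observed token)."""

    matrix: sp.csr_matrix
    columns: list[tuple[DataType, str]]
    labels: np.ndarray


def _visible_counts(
    episode: CareEpisode, data_type: DataType, target_code: Optional[str]
) -> Counter:
    toks = episode.tokens(data_type)
    if data_type is DataType.DIAGNOSIS and target_code is not None:
        toks = [t for t in toks if t != target_code]
    return Counter(toks)


def embed_episode(
    episode: CareEpisode,
    ensemble: SemanticSpaceEnsemble,
    window: int,
    target_code: Optional[str] = None,
) -> np.ndarray:
    """Count-weighted bag-of-embeddings vector of length V x T."""
    if window not in ensemble.windows:
        raise KeyError(f"window {window} not in ensemble windows {ensemble.windows}")
    blocks = []
    for dtype in ensemble.data_types:
        space = ensemble.space(dtype, window)
        vec = np.zeros(ensemble.dim)
        for tok, cnt in _visible_counts(episode, dtype, target_code).items():
            v = space.vectors.get(tok)
            if v is not None:
                vec += cnt * v
        blocks.append(vec)
    return np.concatenate(blocks)


def transform_dataset(
    dataset: LabeledDataset,
    ensemble: SemanticSpaceEnsemble,
    window: int,
) -> TransformedDataset:
    """Represent every episode at one window size (n x V*T matrix)."""
    if window not in ensemble.windows:
        raise KeyError(f"window {window} not in ensemble windows {ensemble.windows}")
    n = len(dataset)
    dim = ensemble.dim
    block_index = []
    blocks = []
    for bi, dtype in enumerate(ensemble.data_types):
        space = ensemble.space(dtype, window)
        index, emb = space.matrix_view()
        rows, cols, vals = [], [], []
        for i, ep in enumerate(dataset.episodes):
            for tok, cnt in _visible_counts(ep, dtype, dataset.target_code).items():
                j = index.get(tok)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(cnt)
        counts = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n, len(index)), dtype=np.float64
        )
        blocks.append(counts @ emb if len(index) else np.zeros((n, dim)))
        block_index.append((window, dtype, bi * dim, (bi + 1) * dim))
    matrix = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return TransformedDataset(
        matrix=matrix, block_index=block_index,
        labels=dataset.labels.copy(), windows=(window,),
    )


def concat_windows(
    dataset: LabeledDataset,
    ensemble: SemanticSpaceEnsemble,
    windows: Sequence[int],
) -> TransformedDataset:
    """Horizontally concatenate per-window representations (FDR input).

    Windows are concatenated in ascending order; the result has
    V x T x len(windows) columns.
    """
    windows = sorted(windows)
    if not windows:
        raise ValueError("windows must be non-empty")
    parts = [transform_dataset(dataset, ensemble, w) for w in windows]
    block_index = []
    offset = 0
    for part in parts:
        for w, t, start, stop in part.block_index:
            block_index.append((w, t, start + offset, stop + offset))
        offset += part.n_features
    return TransformedDataset(
        matrix=np.hstack([p.matrix for p in parts]),
        block_index=block_index,
        labels=dataset.labels.copy(),
        windows=tuple(windows),
    )


def feature_budget(strategy: Strategy, V: int, T: int, P: int) -> FeatureBudget:
    """Feature counts available to the ensemble and to each tree.

    Every strategy exposes V*T*P features to the ensemble as a whole.
    Per tree: FDR samples floor(sqrt(V*T*P)); RDR-FS samples
    floor(sqrt(V*T)); RDR-ALL uses all V*T features of its sampled
    representation.
    """
    if min(V, T, P) < 1:
        raise ValueError("V, T and P must be positive")
    strategy = Strategy(strategy)
    ensemble_features = V * T * P
    if strategy is Strategy.FDR:
        tree_features = isqrt(V * T * P)
    elif strategy is Strategy.RDR_FS:
        tree_features = isqrt(V * T)
    else:
        tree_features = V * T
    return FeatureBudget(ensemble_features, tree_features)


def bag_of_events(
    dataset: LabeledDataset, target_code: Optional[str] = None
) -> CountDataset:
    """Shallow count-based representation: one column per observed token.

    The target diagnosis code (``dataset.target_code`` unless overridden)
    is removed from the diagnosis stream first, so no column depends on it.
    """
    if target_code is None:
        target_code = dataset.target_code
    vocab: dict[tuple[DataType, str], int] = {}
    rows, cols, vals = [], [], []
    for i, ep in enumerate(dataset.episodes):
        for dtype in CANONICAL_DATA_TYPES:
            for tok, cnt in _visible_counts(ep, dtype, target_code).items():
                key = (dtype, tok)
                j = vocab.setdefault(key, len(vocab))
                rows.append(i)
                cols.append(j)
                vals.append(cnt)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(dataset), len(vocab)), dtype=np.int64
    )
    return CountDataset(
        matrix=matrix, columns=list(vocab), labels=dataset.labels.copy()
    )
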