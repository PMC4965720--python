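"""Semantic spaces: skip-gram embeddings of clinical event sequences.

One semantic space maps the event tokens of a single data type, observed
in time-ordered sequences, to dense vectors; a grid of spaces over
(data type, context window size) forms a *semantic space ensemble*. The
trainer implements the skip-gram architecture with negative sampling:
given item-context pairs drawn from symmetric windows, it maximises the
probability of observed contexts under a logistic model, by mini-batch
stochastic gradient descent on the input and output embedding matrices.
The learned input-layer vectors are the semantic vectors.

Training is deterministic for a fixed seed (single-threaded by design),
and the context window is fixed (never randomly shrunk), so a token pair
co-occurring only at distance ``d`` receives training signal iff
``window >= d``.

Spaces persist in the word2vec text format: a ``count dim`` header line
followed by one ``token v1 ... vV`` line per vocabulary entry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import expit

from .corpus import (
    CANONICAL_DATA_TYPES,
    CareEpisode,
    DataType,
    SequenceSet,
    extract_sequences,
)

__all__ = [
    "SkipGramConfig", "SemanticSpace", "SemanticSpaceEnsemble",
    "train_semantic_space", "build_space_grid", "build_target_grids",
    "save_space", "load_space",
]


@dataclass(frozen=True)
class SkipGramConfig:
    """Hyperparameters for skip-gram training.

    ``window`` is the one-sided symmetric context size: a window of 2
    means two items on each side of the focus item ("2+2").
    """

    dim: int = 200
    window: int = 5
    min_count: int = 1
    epochs: int = 20
    negatives: int = 5
    learning_rate: float = 0.05
    seed: int = 0
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.min_count < 1 or self.epochs < 1:
            raise ValueError("dim, window, min_count and epochs must all be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class SemanticSpace:
    """A learned map from tokens of one data type to dense vectors."""

    data_type: DataType
    window: int
    dim: int
    vectors: dict[str, np.ndarray]

    # Lazy cache for the (vocab-index, matrix) view used by featurization.
    _index: Optional[dict[str, int]] = field(default=None, repr=False)
    _matrix: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"vector for {tok!r} has shape {vec.shape}, expected ({self.dim},)"
                )
            if not np.isfinite(vec).all():
                raise ValueError(f"vector for {tok!r} has non-finite entries")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def vocabulary(self) -> list[str]:
        return list(self.vectors)

    def matrix_view(self) -> tuple[dict[str, int], np.ndarray]:
        """Token index and stacked vector matrix (rows in vocab order)."""
        if self._matrix is None:
            self._index = {t: i for i, t in enumerate(self.vectors)}
            if self.vectors:
                self._matrix = np.vstack([self.vectors[t] for t in self.vectors])
            else:
                self._matrix = np.zeros((0, self.dim))
        return self._index, self._matrix

    def similarity(self, a: str, b: str) -> float:
        """Cosine similarity between two vocabulary tokens."""
        u, v = self.vectors[a], self.vectors[b]
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


@dataclass
class SemanticSpaceEnsemble:
    """The complete grid of semantic spaces: data types x window sizes.

    All member spaces share one vector dimensionality; the grid must be
    complete.
    """

    spaces: dict[tuple[DataType, int], SemanticSpace]
    data_types: tuple[DataType, ...]
    windows: tuple[int, ...]
    dim: int

    def __post_init__(self) -> None:
        self.data_types = tuple(DataType(t) for t in self.data_types)
        self.windows = tuple(sorted(self.windows))
        expected = {(t, w) for t in self.data_types for w in self.windows}
        if set(self.spaces) != expected:
            missing = expected - set(self.spaces)
            extra = set(self.spaces) - expected
            raise ValueError(
                f"incomplete space grid: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        for key, sp in self.spaces.items():
            if sp.dim != self.dim:
                raise ValueError(
                    f"space {key} has dim {sp.dim}, ensemble dim is {self.dim}"
                )

    def __len__(self) -> int:
        return len(self.spaces)

    def space(self, data_type: DataType, window: int) -> SemanticSpace:
        return self.spaces[(DataType(data_type), window)]

    @property
    def n_data_types(self) -> int:
        return len(self.data_types)

    def restrict(self, windows: Sequence[int]) -> "SemanticSpaceEnsemble":
        """Sub-ensemble containing only the given window sizes."""
        windows = tuple(sorted(windows))
        if not set(windows) <= set(self.windows):
            raise KeyError(f"windows {windows} not all present in {self.windows}")
        return SemanticSpaceEnsemble(
            spaces={k: v for k, v in self.spaces.items() if k[1] in windows},
            data_types=self.data_types,
            windows=windows,
            dim=self.dim,
        )

    def with_spaces(
        self, replacements: dict[tuple[DataType, int], SemanticSpace]
    ) -> "SemanticSpaceEnsemble":
        spaces = dict(self.spaces)
        spaces.update(replacements)
        return SemanticSpaceEnsemble(
            spaces=spaces, data_types=self.data_types,
            windows=self.windows, dim=self.dim,
        )


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling
# ---------------------------------------------------------------------------

#: Cap on the norm of one row's accumulated per-batch gradient.
_MAX_ROW_GRAD_NORM = 2.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _build_pairs(
    encoded: list[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within the symmetric window."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for seq in encoded:
        n = len(seq)
        for off in range(1, min(window, n - 1) + 1):
            a, b = seq[:-off], seq[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    return np.concatenate(centers), np.concatenate(contexts)


def _negative_table(counts: np.ndarray, size: int = 1 << 17) -> np.ndarray:
    """Sampling table for negatives, proportional to unigram^0.75."""
    p = counts.astype(np.float64) ** 0.75
    p /= p.sum()
    reps = np.maximum(1, np.round(p * size).astype(np.int64))
    return np.repeat(np.arange(len(counts)), reps)


def train_semantic_space(
    sequences: SequenceSet, config: SkipGramConfig
) -> SemanticSpace:
    """Train one semantic space from a set of token sequences.

    The vocabulary is every token with frequency >= ``min_count``
    (lower-frequency tokens are removed from the sequences before windows
    are formed, so remaining tokens become adjacent). Raises
    ``ValueError`` if the vocabulary ends up empty.
    """
    if not sequences.sequences:
        raise ValueError("cannot train a semantic space from zero sequences")
    counts = Counter(t for seq in sequences.sequences for t in seq)
    # Deterministic vocab order: frequency desc, then token.
    vocab = sorted(
        (t for t, c in counts.items() if c >= config.min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab:
        raise ValueError(
            f"empty vocabulary: no token reaches min_count={config.min_count}"
        )
    index = {t: i for i, t in enumerate(vocab)}
    encoded = []
    for seq in sequences.sequences:
        ids = np.array([index[t] for t in seq if t in index], dtype=np.int64)
        if len(ids) >= 2:
            encoded.append(ids)

    rng = np.random.default_rng(config.seed)
    n_vocab, dim = len(vocab), config.dim
    w_in = (rng.random((n_vocab, dim), dtype=np.float64) - 0.5) / dim
    w_out = np.zeros((n_vocab, dim))

    centers, contexts = _build_pairs(encoded, config.window)
    if len(centers):
        table = _negative_table(
            np.array([counts[t] for t in vocab], dtype=np.int64)
        )
        n_pairs = len(centers)
        bs = config.batch_size
        n_batches = int(np.ceil(n_pairs / bs))
        total_steps = config.epochs * n_batches
        step = 0
        k = config.negatives
        for _ in range(config.epochs):
            perm = rng.permutation(n_pairs)
            for start in range(0, n_pairs, bs):
                lr = config.learning_rate * max(1.0 - step / total_steps, 1e-2)
                step += 1
                batch = perm[start:start + bs]
                c, o = centers[batch], contexts[batch]
                neg = table[rng.integers(0, len(table), size=(len(batch), k))]
                vi = w_in[c]                                    # B x d
                uo = w_out[o]                                   # B x d
                un = w_out[neg]                                 # B x k x d
                g_pos = _sigmoid(np.einsum("bd,bd->b", vi, uo)) - 1.0
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", vi, un))
                grad_vi = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
                # Accumulate per-row gradients, then cap each row's step:
                # frequent tokens hit many times in one batch would
                # otherwise take compound steps and diverge.
                g_in = np.zeros_like(w_in)
                np.add.at(g_in, c, grad_vi)
                g_out = np.zeros_like(w_out)
                np.add.at(g_out, o, g_pos[:, None] * vi)
                np.add.at(
                    g_out, neg.ravel(),
                    (g_neg[..., None] * vi[:, None, :]).reshape(-1, dim),
                )
                for g in (g_in, g_out):
                    norms = np.linalg.norm(g, axis=1, keepdims=True)
                    scale = np.where(
                        norms > _MAX_ROW_GRAD_NORM,
                        _MAX_ROW_GRAD_NORM / np.maximum(norms, 1e-12),
                        1.0,
                    )
                    g *= scale
                w_in -= lr * g_in
                w_out -= lr * g_out

    vectors = {t: w_in[i].copy() for t, i in index.items()}
    return SemanticSpace(
        data_type=sequences.data_type, window=config.window,
        dim=config.dim, vectors=vectors,
    )


def _derived_seed(seed: int, *keys: int) -> int:
    """Stable sub-seed for one grid cell (kept below 2**31)."""
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def build_space_grid(
    episodes: Sequence[CareEpisode],
    windows: Sequence[int],
    config: SkipGramConfig,
    exclude_code: Optional[str] = None,
) -> SemanticSpaceEnsemble:
    """Train the full grid of semantic spaces for a corpus.

    One space is trained per (data type, window size); with 4 data types
    and 10 window sizes this yields 40 spaces. ``exclude_code`` is removed
    from the diagnosis sequences before training, so the target ADE code
    never enters any diagnosis vocabulary.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("windows must be non-empty")
    if len(set(windows)) != len(windows):
        raise ValueError(f"duplicate window sizes in {windows}")
    spaces: dict[tuple[DataType, int], SemanticSpace] = {}
    for ti, dtype in enumerate(CANONICAL_DATA_TYPES):
        seqs = extract_sequences(
            episodes, dtype,
            exclude_code=exclude_code if dtype is DataType.DIAGNOSIS else None,
        )
        for w in windows:
            cfg = replace(
                config, window=w, seed=_derived_seed(config.seed, ti, w)
            )
            spaces[(dtype, w)] = train_semantic_space(seqs, cfg)
    return SemanticSpaceEnsemble(
        spaces=spaces, data_types=CANONICAL_DATA_TYPES,
        windows=tuple(sorted(windows)), dim=config.dim,
    )


def build_target_grids(
    episodes: Sequence[CareEpisode],
    windows: Sequence[int],
    config: SkipGramConfig,
    target_codes: Sequence[str],
) -> dict[str, SemanticSpaceEnsemble]:
    """Per-target-code ensembles sharing the non-diagnosis spaces.

    Word, drug and measurement spaces do not depend on the target code,
    so they are trained once; only the diagnosis spaces are retrained per
    target code with that code excluded.
    """
    base = build_space_grid(episodes, windows, config, exclude_code=None)
    grids: dict[str, SemanticSpaceEnsemble] = {}
    for code in target_codes:
        diag_seqs = extract_sequences(episodes, DataType.DIAGNOSIS, exclude_code=code)
        ti = CANONICAL_DATA_TYPES.index(DataType.DIAGNOSIS)
        replacements = {}
        for w in base.windows:
            cfg = replace(config, window=w, seed=_derived_seed(config.seed, ti, w))
            replacements[(DataType.DIAGNOSIS, w)] = train_semantic_space(diag_seqs, cfg)
        grids[code] = base.with_spaces(replacements)
    return grids


# ---------------------------------------------------------------------------
# Persistence: word2vec text format
# ---------------------------------------------------------------------------

def save_space(space: SemanticSpace, path: str | Path) -> None:
    """Write a space in word2vec text format (`count dim` header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(space.vectors)} {space.dim}\n")
        for tok, vec in space.vectors.items():
            vals = " ".join(f"{x:.8g}" for x in vec)
            fh.write(f"{tok} {vals}\n")


def load_space(
    path: str | Path,
    data_type: DataType = DataType.WORD,
    window: int = 1,
) -> SemanticSpace:
    """Read a word2vec text file; raises ``ValueError`` with the line
    number on header/row arity mismatches."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("line 1: header must be 'count dim'")
        count, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"line {lineno}: expected token + {dim} values, got {len(parts) - 1}"
                )
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != count:
        raise ValueError(
            f"header declares {count} vectors but file contains {len(vectors)}"
        )
    return SemanticSpace(
        data_type=DataType(data_type), window=window, dim=dim, vectors=vectors
    )
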