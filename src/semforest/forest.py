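"""Forests of randomized trees over semantic space ensembles.

The model/results pair follows the fit-then-inspect idiom: build a
:class:`SemanticForest` from a labeled dataset and a semantic space
ensemble, call :meth:`~SemanticForest.fit`, and work with the returned
:class:`SemanticForestResults`.

Every strategy trains each tree on a bootstrap replicate of the
(transformed) training set. Diversity among trees comes from bagging
plus, depending on the strategy, per-tree random subspacing and/or a
per-tree random choice of context window size:

* FDR fuses (concatenates) all window representations and gives each tree
  a random sqrt(N) subset of the fused columns.
* RDR-FS draws one window size per tree (uniformly, with replacement) and
  a sqrt(N) column subset of that representation.
* RDR-ALL draws one window size per tree and uses all of its columns.

Base learners are fully grown Gini impurity trees (minimum leaf size 1).
Subspacing is applied per tree; the classical per-node sampling of random
forest proper is available for comparison via ``subspace_per_node``. The
forest predicts by unweighted majority vote; the score of an episode is
the fraction of trees voting positive.

All randomness derives from one master seed through counter-based
sub-seeds, so tree ``i`` is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isqrt
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from sklearn.tree import DecisionTreeClassifier

from .corpus import CareEpisode, DataType, LabeledDataset
from .embedding import SemanticSpaceEnsemble
from .featurize import Strategy, concat_windows, transform_dataset

__all__ = [
    "TreeRecord", "SemanticForest", "SemanticForestResults",
    "BaggedSubspaceForest", "bootstrap_replicate", "sample_feature_subset",
    "fit_forest", "predict_scores", "predict_labels",
]

#: window tag used by FDR trees, which see the fused representation.
ALL_WINDOWS = "ALL"


def bootstrap_replicate(n: int, seed: int) -> np.ndarray:
    """Sample ``n`` row indices uniformly with replacement from [0, n)."""
    if n < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    return np.random.default_rng(seed).integers(0, n, size=n)


def sample_feature_subset(N: int, seed: int) -> np.ndarray:
    """floor(sqrt(N)) distinct column indices, sorted ascending."""
    if N < 1:
        raise ValueError("N must be >= 1")
    k = isqrt(N)
    idx = np.random.default_rng(seed).choice(N, size=k, replace=False)
    return np.sort(idx)


@dataclass
class TreeRecord:
    """One fitted tree plus the sampling choices that produced it."""

    tree: DecisionTreeClassifier
    window_tag: Union[int, str]
    feature_subset: Optional[np.ndarray]
    bootstrap_seed: int


def _tree_seeds(master_seed: int, i: int) -> tuple[int, int, int, int]:
    """(window, bootstrap, subset, tree) sub-seeds for tree ``i``."""
    state = np.random.SeedSequence([master_seed, i]).generate_state(4)
    return tuple(int(s % (2**31)) for s in state)


class SemanticForest:
    """Forest model over a labeled dataset and a semantic space ensemble.

    Parameters
    ----------
    dataset
        Training episodes with binary ADE labels; both classes must be
        present.
    ensemble
        The grid of semantic spaces (all data types, all window sizes).
    strategy
        One of ``Strategy.FDR``, ``Strategy.RDR_FS``, ``Strategy.RDR_ALL``.
    n_trees
        Forest size (500 by default).
    seed
        Master seed for all bootstrap/window/subspace sampling.
    subspace_per_node
        If true, skip the per-tree feature subset and let each tree
        sample sqrt(N) features at every split node instead (random
        forest proper); off by default.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        ensemble: SemanticSpaceEnsemble,
        strategy: Strategy = Strategy.RDR_ALL,
        n_trees: int = 500,
        seed: int = 0,
        subspace_per_node: bool = False,
    ):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        classes = np.unique(dataset.labels)
        if len(classes) < 2:
            raise ValueError(
                f"training data contains a single class ({classes.tolist()}); "
                "both classes are required"
            )
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.dataset = dataset
        self.ensemble = ensemble
        self.strategy = Strategy(strategy)
        self.n_trees = n_trees
        self.seed = seed
        self.subspace_per_node = subspace_per_node

    # -- representations -------------------------------------------------

    def _training_matrices(self) -> dict[Union[int, str], np.ndarray]:
        """Cached training design matrices keyed by window tag."""
        mats: dict[Union[int, str], np.ndarray] = {}
        if self.strategy is Strategy.FDR:
            mats[ALL_WINDOWS] = concat_windows(
                self.dataset, self.ensemble, self.ensemble.windows
            ).matrix
        else:
            for w in self.ensemble.windows:
                mats[w] = transform_dataset(self.dataset, self.ensemble, w).matrix
        return mats

    def fit(self) -> "SemanticForestResults":
        """Fit ``n_trees`` randomized trees and return the results object."""
        mats = self._training_matrices()
        windows = self.ensemble.windows
        y = self.dataset.labels
        records: list[TreeRecord] = []
        for i in range(self.n_trees):
            win_seed, boot_seed, sub_seed, tree_seed = _tree_seeds(self.seed, i)
            if self.strategy is Strategy.FDR:
                tag: Union[int, str] = ALL_WINDOWS
            else:
                tag = windows[
                    np.random.default_rng(win_seed).integers(len(windows))
                ]
            X = mats[tag]
            rows = bootstrap_replicate(X.shape[0], boot_seed)
            subset: Optional[np.ndarray] = None
            max_features = None
            if self.subspace_per_node:
                if self.strategy is not Strategy.RDR_ALL:
                    max_features = "sqrt"
            elif self.strategy in (Strategy.FDR, Strategy.RDR_FS):
                subset = sample_feature_subset(X.shape[1], sub_seed)
            Xb = X[rows]
            if subset is not None:
                Xb = Xb[:, subset]
            tree = DecisionTreeClassifier(
                criterion="gini", max_features=max_features,
                random_state=tree_seed % (2**31),
            )
            tree.fit(Xb, y[rows])
            records.append(TreeRecord(tree, tag, subset, boot_seed))
        return SemanticForestResults(model=self, trees=records)


@dataclass
class SemanticForestResults:
    """Fitted forest: tree records plus prediction and inspection API."""

    model: SemanticForest
    trees: list[TreeRecord]

    # -- convenience views ------------------------------------------------

    @property
    def strategy(self) -> Strategy:
        return self.model.strategy

    @property
    def ensemble_ref(self) -> SemanticSpaceEnsemble:
        return self.model.ensemble

    @property
    def target_code(self) -> str:
        return self.model.dataset.target_code

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- prediction --------------------------------------------------------

    def _test_matrices(
        self, episodes: Sequence[CareEpisode]
    ) -> dict[Union[int, str], np.ndarray]:
        probe = LabeledDataset(
            episodes=list(episodes),
            labels=np.zeros(len(episodes), dtype=int),
            target_code=self.target_code,
        )
        tags = {rec.window_tag for rec in self.trees}
        mats: dict[Union[int, str], np.ndarray] = {}
        ens = self.ensemble_ref
        for tag in tags:
            if tag == ALL_WINDOWS:
                mats[tag] = concat_windows(probe, ens, ens.windows).matrix
            else:
                mats[tag] = transform_dataset(probe, ens, tag).matrix
        return mats

    def tree_predictions(self, episodes: Sequence[CareEpisode]) -> np.ndarray:
        """Per-tree 0/1 votes, shape (n_trees, n_episodes).

        Each tree sees the episodes transformed under its own window tag
        and restricted to its feature subset, if any.
        """
        mats = self._test_matrices(episodes)
        votes = np.empty((len(self.trees), len(episodes)), dtype=int)
        for t, rec in enumerate(self.trees):
            X = mats[rec.window_tag]
            if rec.feature_subset is not None:
                X = X[:, rec.feature_subset]
            votes[t] = rec.tree.predict(X)
        return votes

    def predict_scores(self, episodes: Sequence[CareEpisode]) -> np.ndarray:
        """Fraction of trees voting positive, per episode (in [0, 1])."""
        return self.tree_predictions(episodes).mean(axis=0)

    def predict_labels(
        self, episodes: Sequence[CareEpisode], threshold: float = 0.5
    ) -> np.ndarray:
        """Majority-vote labels: 1 iff score strictly exceeds the
        threshold (exact ties go to the negative class)."""
        return (self.predict_scores(episodes) > threshold).astype(int)

    predict = predict_labels

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        windows = self.ensemble_ref.windows
        tags = [rec.window_tag for rec in self.trees]
        lines = [
            "Semantic space forest results",
            "=" * 38,
            f"strategy:        {self.strategy.value}",
            f"trees:           {self.n_trees}",
            f"training size:   {len(self.model.dataset)}",
            f"target code:     {self.target_code}",
            f"vector dim (V):  {self.ensemble_ref.dim}",
            f"data types (T):  {self.ensemble_ref.n_data_types}",
            f"windows (P):     {list(windows)}",
        ]
        if self.strategy is not Strategy.FDR:
            counts = {w: tags.count(w) for w in windows}
            lines.append(f"trees per window: {counts}")
        subset_sizes = {
            len(rec.feature_subset)
            for rec in self.trees if rec.feature_subset is not None
        }
        if subset_sizes:
            lines.append(f"features per tree: {sorted(subset_sizes)}")
        return "\n".join(lines)


class BaggedSubspaceForest:
    """Bagging + per-tree sqrt(N) subspacing over an explicit feature
    matrix.

    This is the same learner the strategies use, applied directly to a
    given design matrix; it backs the count-based (bag-of-events)
    baseline.
    """

    def __init__(
        self, n_trees: int = 500, seed: int = 0, subspace: bool = True
    ):
        self.n_trees = n_trees
        self.seed = seed
        self.subspace = subspace
        self._records: list[tuple[DecisionTreeClassifier, Optional[np.ndarray]]] = []

    def fit(self, X, y) -> "BaggedSubspaceForest":
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self._records = []
        for i in range(self.n_trees):
            _, boot_seed, sub_seed, tree_seed = _tree_seeds(self.seed, i)
            rows = bootstrap_replicate(X.shape[0], boot_seed)
            subset = (
                sample_feature_subset(X.shape[1], sub_seed)
                if self.subspace else None
            )
            Xb = X[rows]
            if subset is not None:
                Xb = Xb[:, subset]
            tree = DecisionTreeClassifier(
                criterion="gini", random_state=tree_seed % (2**31)
            )
            tree.fit(Xb, y[rows])
            self._records.append((tree, subset))
        return self

    def predict_scores(self, X) -> np.ndarray:
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=np.float64)
        votes = np.empty((len(self._records), X.shape[0]), dtype=int)
        for t, (tree, subset) in enumerate(self._records):
            Xt = X if subset is None else X[:, subset]
            votes[t] = tree.predict(Xt)
        return votes.mean(axis=0)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_scores(X) > threshold).astype(int)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_forest(
    dataset: LabeledDataset,
    ensemble: SemanticSpaceEnsemble,
    strategy: Strategy = Strategy.RDR_ALL,
    n_trees: int = 500,
    seed: int = 0,
) -> SemanticForestResults:
    """Fit a forest under one utilization strategy (model + fit in one)."""
    return SemanticForest(
        dataset, ensemble, strategy=strategy, n_trees=n_trees, seed=seed
    ).fit()


def predict_scores(
    results: SemanticForestResults, episodes: Sequence[CareEpisode]
) -> np.ndarray:
    return results.predict_scores(episodes)


def predict_labels(
    results: SemanticForestResults,
    episodes: Sequence[CareEpisode],
    threshold: float = 0.5,
) -> np.ndarray:
    return results.predict_labels(episodes, threshold=threshold)
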