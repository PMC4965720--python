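"""Evaluation harness: scoring, ensemble inspection and strategy comparison.

Metrics follow the conventions of the multiple-classifier-comparison
literature: accuracy as a percentage of correctly classified instances;
AUC as the probability that a randomly chosen positive scores above a
randomly chosen negative (ties count one half); ensemble *diversity*
crudely estimated as ensemble accuracy minus average tree accuracy (on
the fraction scale). For averaging ensembles in the regression setting,
the ambiguity decomposition E = A - D relates squared ensemble error (E),
average squared base-model error (A) and the average squared deviation of
base predictions from the ensemble prediction (D).

Strategies are compared across datasets with a Friedman rank test
(chi-square form) followed by pairwise post-hoc z-tests adjusted with the
Bergmann-Hommel exhaustive-set procedure (Holm as fallback for more than
four methods).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .corpus import CareEpisode, LabeledDataset
from .embedding import SemanticSpaceEnsemble, SkipGramConfig, build_target_grids
from .featurize import Strategy, bag_of_events
from .forest import BaggedSubspaceForest, SemanticForest, SemanticForestResults

__all__ = [
    "EvaluationReport", "AmbiguityDecomposition", "ScoreMatrix",
    "accuracy", "auc", "inspect_ensemble", "ambiguity_decomposition",
    "cross_validate", "friedman_test", "posthoc_pairwise",
    "pool_size_experiment", "benchmark_strategies",
]


def accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Percentage of correctly classified instances."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot compute accuracy of zero instances")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return 100.0 * float((y_true == y_pred).mean())


def auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative.

    Computed from midranks (equivalent to averaging over all
    positive-negative pairs with ties counting 1/2).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = stats.rankdata(scores)
    pos_rank_sum = ranks[y_true == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class AmbiguityDecomposition:
    """E = A - D for an averaging ensemble on one target."""

    E: float
    A: float
    D: float


def ambiguity_decomposition(
    base_predictions: Sequence[float], target: float
) -> AmbiguityDecomposition:
    """Decompose the squared error of the average of base predictions.

    The ensemble prediction is the plain mean; E is its squared error, A
    the mean squared error of the base predictions, and D their mean
    squared deviation from the ensemble prediction. The identity
    E = A - D holds exactly.
    """
    preds = np.asarray(base_predictions, dtype=float)
    if preds.size == 0:
        raise ValueError("need at least one base prediction")
    mean = preds.mean()
    E = float((mean - target) ** 2)
    A = float(((preds - target) ** 2).mean())
    D = float(((preds - mean) ** 2).mean())
    return AmbiguityDecomposition(E=E, A=A, D=D)


def inspect_ensemble(
    results: SemanticForestResults,
    episodes: Sequence[CareEpisode],
    y_true: Sequence[int],
) -> tuple[float, float, float]:
    """(ensemble accuracy %, average tree accuracy %, diversity fraction).

    Each tree is scored on the test set under its own representation;
    diversity is (ensemble - average tree accuracy) / 100.
    """
    y_true = np.asarray(y_true)
    votes = results.tree_predictions(episodes)
    ens_pred = (votes.mean(axis=0) > 0.5).astype(int)
    ens_acc = accuracy(y_true, ens_pred)
    tree_accs = 100.0 * (votes == y_true[None, :]).mean(axis=1)
    avg_tree_acc = float(tree_accs.mean())
    return ens_acc, avg_tree_acc, (ens_acc - avg_tree_acc) / 100.0


@dataclass
class EvaluationReport:
    """Per-fold and aggregate scores for one (dataset, strategy) run."""

    strategy: Strategy
    dataset_name: str
    fold_accuracy: np.ndarray
    fold_auc: np.ndarray
    fold_tree_accuracy: np.ndarray
    seed: int = 0

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def average_tree_accuracy(self) -> float:
        return float(np.mean(self.fold_tree_accuracy))

    @property
    def diversity(self) -> float:
        """Ensemble minus average tree accuracy, on the fraction scale."""
        return self.accuracy / 100.0 - self.average_tree_accuracy / 100.0

    def summary(self) -> str:
        return "\n".join([
            f"dataset:              {self.dataset_name}",
            f"strategy:             {self.strategy.value}",
            f"folds:                {len(self.fold_accuracy)}",
            f"accuracy:             {self.accuracy:.2f} %",
            f"AUC:                  {self.auc:.3f}",
            f"avg tree accuracy:    {self.average_tree_accuracy:.2f} %",
            f"diversity:            {self.diversity:.4f}",
        ])


def cross_validate(
    dataset: LabeledDataset,
    ensemble: SemanticSpaceEnsemble,
    strategy: Strategy = Strategy.RDR_ALL,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one strategy.

    The semantic spaces are pretrained on the background corpus (an
    unsupervised, label-free step) and shared across folds; only the
    forests are refit per fold.
    """
    y = dataset.labels
    min_class = int(min((y == 0).sum(), (y == 1).sum()))
    if min_class < folds:
        raise ValueError(
            f"smallest class has {min_class} instances; use at most "
            f"{min_class} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, aucs, tree_accs = [], [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = dataset.subset(tr)
        test = dataset.subset(te)
        res = SemanticForest(
            train, ensemble, strategy=strategy, n_trees=n_trees,
            seed=_subseed(seed, fold),
        ).fit()
        votes = res.tree_predictions(test.episodes)
        scores = votes.mean(axis=0)
        accs.append(accuracy(test.labels, (scores > 0.5).astype(int)))
        aucs.append(auc(test.labels, scores))
        tree_accs.append(
            float((100.0 * (votes == test.labels[None, :]).mean(axis=1)).mean())
        )
    return EvaluationReport(
        strategy=Strategy(strategy), dataset_name=dataset.name,
        fold_accuracy=np.array(accs), fold_auc=np.array(aucs),
        fold_tree_accuracy=np.array(tree_accs), seed=seed,
    )


# ---------------------------------------------------------------------------
# Statistical comparison across datasets
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """n_datasets x k_methods score table for rank-based comparison."""

    scores: np.ndarray
    methods: list[str]
    datasets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if self.scores.shape[1] != len(self.methods):
            raise ValueError("one method name per column is required")
        if not self.datasets:
            self.datasets = [f"D{i}" for i in range(self.scores.shape[0])]
        if len(self.datasets) != self.scores.shape[0]:
            raise ValueError("one dataset name per row is required")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains missing/non-finite entries")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.datasets, columns=self.methods)

    def mean_ranks(self) -> np.ndarray:
        """Average rank per method; rank 1 = best (highest score), ties
        get average ranks."""
        ranks = np.vstack([stats.rankdata(-row) for row in self.scores])
        return ranks.mean(axis=0)


def _as_matrix(scores) -> np.ndarray:
    if isinstance(scores, ScoreMatrix):
        return scores.scores
    return np.asarray(scores, dtype=float)


def friedman_test(scores) -> tuple[float, float]:
    """Friedman rank test (chi-square form) across datasets.

    Returns (chi2_F, p). With n datasets and k methods,
    chi2_F = 12n/(k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2 on k-1 degrees of
    freedom. Rows where all methods score equally contribute nothing.
    """
    X = _as_matrix(scores)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 methods")
    ranks = np.vstack([stats.rankdata(-row) for row in X])
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float(
        ((mean_ranks - (k + 1) / 2.0) ** 2).sum()
    )
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return chi2, p


def _set_partitions(items: list[int]):
    """All partitions of a list into non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def _exhaustive_sets(k: int) -> list[frozenset[tuple[int, int]]]:
    """Distinct non-empty exhaustive sets of pairwise hypotheses.

    A set of pairwise equality hypotheses is exhaustive iff it is exactly
    the within-block pairs of some partition of the methods (those
    hypotheses can hold simultaneously while all others fail).
    """
    sets = set()
    for partition in _set_partitions(list(range(k))):
        pairs = frozenset(
            pair
            for block in partition
            for pair in itertools.combinations(sorted(block), 2)
        )
        if pairs:
            sets.add(pairs)
    return sorted(sets, key=lambda s: (len(s), sorted(s)))


def posthoc_pairwise(
    scores, method: str = "bergmann_hommel"
) -> dict[tuple[str, str], float]:
    """Pairwise post-hoc comparison after a Friedman test.

    For each method pair, z = (Rbar_i - Rbar_j) / sqrt(k(k+1)/(6n)) with
    two-sided normal raw p-values, adjusted by the Bergmann-Hommel
    exhaustive-set procedure (k <= 4) or Holm. Adjusted p-values are
    capped at 1.
    """
    X = _as_matrix(scores)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 methods")
    names = (
        scores.methods if isinstance(scores, ScoreMatrix)
        else [f"M{i}" for i in range(k)]
    )
    ranks = np.vstack([stats.rankdata(-row) for row in X])
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    raw = {}
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw[(i, j)] = 2.0 * float(stats.norm.sf(abs(z)))

    if method == "holm":
        adjusted = _holm(raw)
    elif method == "bergmann_hommel":
        if k > 4:
            raise ValueError(
                "bergmann_hommel is implemented by exhaustive-set "
                "enumeration and supports at most 4 methods; use "
                "method='holm'"
            )
        adjusted = {}
        exhaustive = _exhaustive_sets(k)
        for pair in pairs:
            vals = [
                len(I) * min(raw[h] for h in I)
                for I in exhaustive if pair in I
            ]
            adjusted[pair] = min(1.0, max(vals))
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return {(names[i], names[j]): p for (i, j), p in adjusted.items()}


def _holm(raw: dict[tuple[int, int], float]) -> dict[tuple[int, int], float]:
    m = len(raw)
    order = sorted(raw, key=raw.get)
    adjusted = {}
    running = 0.0
    for rank, key in enumerate(order):
        running = max(running, (m - rank) * raw[key])
        adjusted[key] = min(1.0, running)
    return adjusted


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _subseed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def _stratified_split(
    n: int, labels: np.ndarray, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    tr, te = train_test_split(
        np.arange(n), train_size=train_frac, stratify=labels, random_state=seed
    )
    return tr, te


def pool_size_experiment(
    dataset: LabeledDataset,
    full_ensemble: SemanticSpaceEnsemble,
    sizes: Sequence[int],
    strategy: Strategy = Strategy.RDR_ALL,
    split: float = 0.7,
    seed: int = 0,
    n_trees: int = 50,
) -> pd.DataFrame:
    """Effect of the semantic-space pool size on predictive performance.

    For each requested pool size s, every one of the C(P, s) window
    subsets is evaluated on a randomized stratified ``split``/(1-split)
    train-test split, and the scores are averaged per size. Returns a
    DataFrame indexed by size with columns accuracy, auc and
    n_combinations.
    """
    windows = full_ensemble.windows
    P = len(windows)
    if not all(1 <= s <= P for s in sizes):
        raise ValueError(f"sizes must lie in 1..{P}")
    records = []
    for s in sizes:
        accs, aucs = [], []
        for ci, combo in enumerate(itertools.combinations(windows, s)):
            sub = full_ensemble.restrict(combo)
            split_seed = _subseed(seed, s, ci)
            tr, te = _stratified_split(
                len(dataset), dataset.labels, split, split_seed
            )
            train, test = dataset.subset(tr), dataset.subset(te)
            res = SemanticForest(
                train, sub, strategy=strategy, n_trees=n_trees,
                seed=_subseed(seed, s, ci, 1),
            ).fit()
            scores = res.predict_scores(test.episodes)
            accs.append(accuracy(test.labels, (scores > 0.5).astype(int)))
            aucs.append(auc(test.labels, scores))
        records.append({
            "size": s, "accuracy": float(np.mean(accs)),
            "auc": float(np.mean(aucs)), "n_combinations": len(accs),
        })
    return pd.DataFrame(records).set_index("size")


BASELINE = "bag-of-events"


def benchmark_strategies(
    background: Sequence[CareEpisode],
    datasets: Sequence[LabeledDataset],
    windows: Sequence[int],
    config: SkipGramConfig,
    strategies: Sequence[Strategy] = tuple(Strategy),
    n_trees: int = 50,
    seed: int = 0,
    split: float = 0.7,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Evaluate the strategies (and the count baseline) over datasets.

    Semantic spaces are trained once on the background corpus; diagnosis
    spaces are retrained per dataset with the target code excluded. Each
    (dataset, method) cell is scored on one stratified ``split`` train-test
    split shared by all methods. Returns a tidy DataFrame with columns
    dataset, method, accuracy, auc, tree_accuracy, diversity.
    """
    grids = build_target_grids(
        background, windows, config, [ds.target_code for ds in datasets]
    )
    rows = []
    for di, ds in enumerate(datasets):
        ens = grids[ds.target_code]
        tr, te = _stratified_split(
            len(ds), ds.labels, split, _subseed(seed, di)
        )
        train, test = ds.subset(tr), ds.subset(te)
        y_te = test.labels
        for si, strategy in enumerate(strategies):
            res = SemanticForest(
                train, ens, strategy=strategy, n_trees=n_trees,
                seed=_subseed(seed, di, si),
            ).fit()
            ens_acc, tree_acc, div = inspect_ensemble(res, test.episodes, y_te)
            scores = res.predict_scores(test.episodes)
            rows.append({
                "dataset": ds.name or f"D{di}",
                "method": Strategy(strategy).value,
                "accuracy": ens_acc, "auc": auc(y_te, scores),
                "tree_accuracy": tree_acc, "diversity": div,
            })
        if include_baseline:
            counts = bag_of_events(ds)
            Xc = counts.matrix
            model = BaggedSubspaceForest(
                n_trees=n_trees, seed=_subseed(seed, di, 99)
            ).fit(Xc[tr], ds.labels[tr])
            scores = model.predict_scores(Xc[te])
            pred = (scores > 0.5).astype(int)
            rows.append({
                "dataset": ds.name or f"D{di}",
                "method": BASELINE,
                "accuracy": accuracy(y_te, pred), "auc": auc(y_te, scores),
                "tree_accuracy": np.nan, "diversity": np.nan,
            })
    return pd.DataFrame(rows)
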