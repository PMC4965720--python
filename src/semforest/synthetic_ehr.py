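"""Synthetic heterogeneous EHR corpora with controllable ADE signal.

Real clinical corpora cannot be shipped, so this module generates care
episodes with the structural properties the pipeline needs to be
exercised end to end:

* four event streams per episode (note words grouped into sentences,
  diagnosis codes, drug codes, measurement types), so every generated
  episode passes the four-data-type retention filter;
* a latent-state mixture with *synonym clusters*: each latent clinical
  state has its own categorical distribution over latent meanings per
  data type, and each emission picks a meaning and then a uniformly
  random surface token from that meaning's cluster. Distinct surface
  tokens therefore share distributional profiles — learnable by
  embeddings, invisible to raw counts;
* reserved ADE diagnosis codes whose presence defines the positive
  class. A positive episode carries its ADE code in the diagnosis stream
  and, with strength ``signal_strength``, has its emissions shifted
  toward ADE-linked meanings in all four streams. ADE codes belong to no
  synonym cluster and are never emitted by the background process, so
  label leakage cannot sneak back in through a synonym.

This is a stand-in that emulates the statistical skeleton of EHR data,
not a claim about real clinical statistics; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import CareEpisode, DataType, Event, LabeledDataset, Sentence

__all__ = ["SynthConfig", "generate_corpus", "generate_ade_dataset",
           "make_benchmark", "generative_manifest"]

_TOKEN_PREFIX = {
    DataType.WORD: "w",
    DataType.DIAGNOSIS: "dg",
    DataType.DRUG: "rx",
    DataType.MEASUREMENT: "ms",
}


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters of the synthetic EHR process.

    Desk-scale defaults: 300 patients with 1-3 episodes each,
    vocabularies 400/60/40/30 (word/diagnosis/drug/measurement), synonym
    clusters of 4, five reserved ADE codes, 35 % ADE prevalence and a
    moderate (0.4) emission shift for positive episodes. Event streams
    are deliberately sparse (2-5 events, 2-3 short sentences) so that
    per-episode surface counts are a noisy sample of the underlying
    meaning distribution while pooled synonym embeddings estimate it
    well.
    """

    n_patients: int = 300
    episodes_per_patient: tuple[int, int] = (1, 3)
    n_words: int = 400
    n_diagnoses: int = 60
    n_drugs: int = 40
    n_measurements: int = 30
    n_latent_states: int = 4
    synonym_cluster_size: int = 4
    n_ade_codes: int = 5
    sentences_per_episode: tuple[int, int] = (2, 3)
    sentence_length: tuple[int, int] = (5, 9)
    diagnoses_per_episode: tuple[int, int] = (2, 5)
    drugs_per_episode: tuple[int, int] = (2, 5)
    measurements_per_episode: tuple[int, int] = (2, 5)
    episode_duration_days: tuple[int, int] = (3, 10)
    signal_strength: float = 0.4
    ade_prevalence: float = 0.35
    dataset_size_range: tuple[int, int] = (20, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if not (0.0 < self.ade_prevalence < 1.0):
            raise ValueError("ade_prevalence must lie in (0, 1)")
        if self.synonym_cluster_size < 1:
            raise ValueError("synonym_cluster_size must be >= 1")
        for size in (self.n_words, self.n_diagnoses, self.n_drugs,
                     self.n_measurements):
            if size < self.synonym_cluster_size:
                raise ValueError(
                    "every vocabulary must hold at least one full synonym "
                    f"cluster (size {self.synonym_cluster_size})"
                )
        for lo, hi in (self.episodes_per_patient, self.sentences_per_episode,
                       self.sentence_length, self.diagnoses_per_episode,
                       self.drugs_per_episode, self.measurements_per_episode):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")

    @property
    def ade_codes(self) -> tuple[str, ...]:
        """Reserved target diagnosis tokens (never in a synonym cluster)."""
        return tuple(f"ADE_{i}" for i in range(self.n_ade_codes))

    @property
    def ade_code(self) -> str:
        return self.ade_codes[0]

    def vocab_size(self, dtype: DataType) -> int:
        return {
            DataType.WORD: self.n_words,
            DataType.DIAGNOSIS: self.n_diagnoses,
            DataType.DRUG: self.n_drugs,
            DataType.MEASUREMENT: self.n_measurements,
        }[dtype]


class _GenerativeModel:
    """Clusters and emission distributions, drawn once from the seed."""

    def __init__(self, config: SynthConfig):
        self.config = config
        rng = np.random.default_rng([config.seed, 7])
        self.clusters: dict[DataType, list[list[str]]] = {}
        self.state_dists: dict[DataType, np.ndarray] = {}
        self.ade_dists: dict[DataType, np.ndarray] = {}
        for dtype in DataType:
            size = config.vocab_size(dtype)
            tokens = [f"{_TOKEN_PREFIX[dtype]}{i:04d}" for i in range(size)]
            cs = config.synonym_cluster_size
            clusters = [tokens[i:i + cs] for i in range(0, size - size % cs, cs)]
            clusters.extend([[t] for t in tokens[size - size % cs:]])
            self.clusters[dtype] = clusters
            m = len(clusters)
            # state x meaning emission distributions (peaked Dirichlet)
            self.state_dists[dtype] = rng.dirichlet(
                np.full(m, 0.5), size=config.n_latent_states
            )
            # per ADE code: uniform over a small set of ADE-linked meanings
            n_linked = max(2, m // 8)
            dists = np.zeros((config.n_ade_codes, m))
            for a in range(config.n_ade_codes):
                linked = rng.choice(m, size=n_linked, replace=False)
                dists[a, linked] = 1.0 / n_linked
            self.ade_dists[dtype] = dists

    def emit_tokens(
        self, rng: np.random.Generator, dtype: DataType, n: int,
        state: int, ade_index: Optional[int],
    ) -> list[str]:
        p = self.state_dists[dtype][state]
        if ade_index is not None:
            s = self.config.signal_strength
            p = (1.0 - s) * p + s * self.ade_dists[dtype][ade_index]
        meanings = rng.choice(len(p), size=n, p=p)
        clusters = self.clusters[dtype]
        return [
            clusters[m][rng.integers(len(clusters[m]))] for m in meanings
        ]


def _rand_in(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def generate_corpus(config: SynthConfig) -> list[CareEpisode]:
    """Draw a full synthetic corpus of care episodes.

    Every episode has all four streams non-empty (it passes the retention
    filter by construction) and is fully reproducible under the config
    seed. Positive episodes (probability ``ade_prevalence``) receive one
    of the reserved ADE codes in their diagnosis stream and emission
    distributions shifted toward that code's linked meanings.
    """
    model = _GenerativeModel(config)
    rng = np.random.default_rng([config.seed, 11])
    episodes: list[CareEpisode] = []
    for pi in range(config.n_patients):
        patient_id = f"p{pi:05d}"
        for ei in range(_rand_in(rng, config.episodes_per_patient)):
            state = int(rng.integers(config.n_latent_states))
            ade_index: Optional[int] = None
            if rng.random() < config.ade_prevalence:
                ade_index = int(rng.integers(config.n_ade_codes))
            duration = _rand_in(rng, config.episode_duration_days)

            sentences = []
            for _ in range(_rand_in(rng, config.sentences_per_episode)):
                toks = model.emit_tokens(
                    rng, DataType.WORD, _rand_in(rng, config.sentence_length),
                    state, ade_index,
                )
                sentences.append(Sentence(toks))

            def structured(dtype: DataType, bounds: tuple[int, int]) -> list[Event]:
                n = _rand_in(rng, bounds)
                toks = model.emit_tokens(rng, dtype, n, state, ade_index)
                days = np.sort(rng.integers(0, duration + 1, size=n))
                return [Event(dtype, t, int(d)) for t, d in zip(toks, days)]

            diagnoses = structured(DataType.DIAGNOSIS, config.diagnoses_per_episode)
            if ade_index is not None:
                code = config.ade_codes[ade_index]
                day = int(rng.integers(0, duration + 1))
                diagnoses.append(Event(DataType.DIAGNOSIS, code, day))
                diagnoses.sort(key=lambda e: e.day)

            episodes.append(CareEpisode(
                patient_id=patient_id,
                episode_id=f"{patient_id}-e{ei}",
                sentences=sentences,
                diagnosis_events=diagnoses,
                drug_events=structured(DataType.DRUG, config.drugs_per_episode),
                measurement_events=structured(
                    DataType.MEASUREMENT, config.measurements_per_episode
                ),
            ))
    return episodes


def generate_ade_dataset(
    corpus: Sequence[CareEpisode],
    ade_code: str,
    n_pos: int,
    seed: int = 0,
) -> LabeledDataset:
    """Balanced case-control dataset for one target ADE code.

    Positives are sampled from episodes whose diagnosis stream contains
    ``ade_code``; the same number of negatives is sampled uniformly from
    episodes in which the code was never assigned.
    """
    has_code = [
        ade_code in ep.tokens(DataType.DIAGNOSIS) for ep in corpus
    ]
    pos_pool = [i for i, h in enumerate(has_code) if h]
    neg_pool = [i for i, h in enumerate(has_code) if not h]
    if len(pos_pool) < n_pos or len(neg_pool) < n_pos:
        raise ValueError(
            f"need {n_pos} episodes per class but corpus has "
            f"{len(pos_pool)} with {ade_code!r} and {len(neg_pool)} without"
        )
    rng = np.random.default_rng(seed)
    pos = rng.choice(pos_pool, size=n_pos, replace=False)
    neg = rng.choice(neg_pool, size=n_pos, replace=False)
    order = rng.permutation(2 * n_pos)
    indices = np.concatenate([pos, neg])[order]
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_pos, int)])[order]
    return LabeledDataset(
        episodes=[corpus[i] for i in indices],
        labels=labels,
        target_code=ade_code,
        name=ade_code,
    )


def make_benchmark(
    config: SynthConfig,
    n_datasets: int,
    seed: int = 0,
    corpus: Optional[list[CareEpisode]] = None,
) -> list[LabeledDataset]:
    """Benchmark suite: one balanced dataset per distinct ADE code.

    All datasets are sampled from one shared background corpus (generated
    from ``config`` unless passed in); per-dataset sizes are drawn from
    ``config.dataset_size_range``.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if n_datasets > config.n_ade_codes:
        raise ValueError(
            f"only {config.n_ade_codes} distinct ADE codes are configured"
        )
    if corpus is None:
        corpus = generate_corpus(config)
    rng = np.random.default_rng([seed, 13])
    datasets = []
    for di in range(n_datasets):
        n_pos = _rand_in(rng, config.dataset_size_range)
        datasets.append(generate_ade_dataset(
            corpus, config.ade_codes[di], n_pos,
            seed=int(rng.integers(2**31)),
        ))
    return datasets


def generative_manifest(config: SynthConfig) -> dict:
    """Ground-truth generative parameters, for recovery tests and the
    CLI manifest file."""
    model = _GenerativeModel(config)
    return {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "ade_codes": list(config.ade_codes),
        "synonym_clusters": {
            dtype.value: model.clusters[dtype] for dtype in DataType
        },
        "n_meanings": {
            dtype.value: len(model.clusters[dtype]) for dtype in DataType
        },
    }
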