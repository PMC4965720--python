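"""Data model and I/O for heterogeneous care-episode data.

A *care episode* is a contiguous block of one patient's recorded activity,
delimited by at least three whole days without any registered event. Each
episode carries four time-ordered event streams: free-text note words
(grouped into sentences), diagnosis codes, drug codes and measurement
types (values are ignored; only the type of measurement is recorded).

Episodes are persisted as JSON Lines, one episode per line, with keys
``patient_id``, ``episode_id``, ``sentences``, ``diagnoses``, ``drugs``
and ``measurements``; structured streams are arrays of ``{code, day}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "DataType", "Event", "Sentence", "CareEpisode", "LabeledDataset",
    "SequenceSet", "segment_care_episodes", "retain_complete_episodes",
    "extract_sequences", "read_corpus", "write_corpus",
]


class DataType(str, Enum):
    """The four kinds of clinical events an episode can contain."""

    WORD = "word"
    DIAGNOSIS = "diagnosis"
    DRUG = "drug"
    MEASUREMENT = "measurement"


#: Canonical ordering of data types used everywhere feature blocks are
#: concatenated. Fixed for reproducibility.
CANONICAL_DATA_TYPES: tuple[DataType, ...] = (
    DataType.WORD,
    DataType.DIAGNOSIS,
    DataType.DRUG,
    DataType.MEASUREMENT,
)

#: JSONL keys for the three structured streams, in canonical order.
_STREAM_KEYS = {
    DataType.DIAGNOSIS: "diagnoses",
    DataType.DRUG: "drugs",
    DataType.MEASUREMENT: "measurements",
}


@dataclass(frozen=True)
class Event:
    """A single structured clinical event: a code recorded on a calendar day.

    For word events, ``day`` is the day of the containing note.
    """

    data_type: DataType
    code: str
    day: int

    def __post_init__(self) -> None:
        if not self.code or any(c.isspace() for c in self.code):
            raise ValueError(
                f"event code must be non-empty with no whitespace, got {self.code!r}"
            )
        if self.day < 0:
            raise ValueError(f"event day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class Sentence:
    """An ordered list of word tokens from one clinical-note sentence."""

    tokens: tuple[str, ...]

    def __init__(self, tokens: Iterable[str]):
        object.__setattr__(self, "tokens", tuple(tokens))
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")


@dataclass
class CareEpisode:
    """One unit of classification: four time-ordered event streams.

    Structured event lists must be sorted non-decreasingly by day; the
    order of same-day events is preserved as given (the source data has no
    sub-day timestamps).
    """

    patient_id: str
    episode_id: str
    sentences: list[Sentence] = field(default_factory=list)
    diagnosis_events: list[Event] = field(default_factory=list)
    drug_events: list[Event] = field(default_factory=list)
    measurement_events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        for events in (self.diagnosis_events, self.drug_events,
                       self.measurement_events):
            days = [e.day for e in events]
            if any(b < a for a, b in zip(days, days[1:])):
                raise ValueError(
                    f"episode {self.episode_id}: events not sorted by day"
                )

    def stream(self, data_type: DataType) -> list[Event]:
        if data_type is DataType.DIAGNOSIS:
            return self.diagnosis_events
        if data_type is DataType.DRUG:
            return self.drug_events
        if data_type is DataType.MEASUREMENT:
            return self.measurement_events
        raise ValueError("word events are accessed through .sentences")

    def tokens(self, data_type: DataType) -> list[str]:
        """All tokens of one data type, in stream order.

        Words come sentence by sentence; structured codes come in day
        order.
        """
        if data_type is DataType.WORD:
            return [t for s in self.sentences for t in s.tokens]
        return [e.code for e in self.stream(data_type)]

    @property
    def has_all_types(self) -> bool:
        return bool(self.sentences and self.diagnosis_events
                    and self.drug_events and self.measurement_events)


@dataclass
class LabeledDataset:
    """A set of care episodes with binary ADE labels.

    ``target_code`` is the diagnosis token whose presence defines the
    positive class; downstream featurization removes it from the visible
    diagnosis stream so the label cannot leak into the features.
    """

    episodes: list[CareEpisode]
    labels: np.ndarray
    target_code: str
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.episodes) != len(self.labels):
            raise ValueError(
                f"{len(self.episodes)} episodes but {len(self.labels)} labels"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.episodes)

    @property
    def is_balanced(self) -> bool:
        return int(self.labels.sum()) * 2 == len(self.labels)

    def subset(self, indices: Sequence[int], name: str = "") -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            episodes=[self.episodes[i] for i in idx],
            labels=self.labels[idx],
            target_code=self.target_code,
            name=name or self.name,
        )


@dataclass
class SequenceSet:
    """Token sequences of one data type, ready for representation learning."""

    data_type: DataType
    sequences: list[list[str]]

    def __len__(self) -> int:
        return len(self.sequences)


def segment_care_episodes(
    events: Sequence[Event], min_gap_days: int = 3
) -> list[list[Event]]:
    """Split one patient's time-ordered events into care episodes.

    A new episode starts whenever at least ``min_gap_days`` whole calendar
    days pass with no registered activity, i.e. when
    ``day(next) - day(prev) >= min_gap_days + 1``.

    Returns the list of episode event-groups, preserving order; an empty
    input yields an empty list.
    """
    if not events:
        return []
    days = [e.day for e in events]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("events must be sorted by day")
    groups: list[list[Event]] = [[events[0]]]
    for prev, ev in zip(events, events[1:]):
        if ev.day - prev.day >= min_gap_days + 1:
            groups.append([ev])
        else:
            groups[-1].append(ev)
    return groups


def retain_complete_episodes(episodes: Iterable[CareEpisode]) -> list[CareEpisode]:
    """Keep only episodes containing at least one event of each of the
    four data types, preserving order."""
    return [e for e in episodes if e.has_all_types]


def extract_sequences(
    episodes: Iterable[CareEpisode],
    data_type: DataType,
    exclude_code: Optional[str] = None,
) -> SequenceSet:
    """Extract token sequences of one data type for embedding training.

    Structured types yield one day-ordered sequence per episode; words
    yield one sequence per sentence. If ``exclude_code`` is given (allowed
    only for diagnoses), every occurrence of that token is deleted from
    the sequences, so its neighbours become adjacent.
    """
    data_type = DataType(data_type)
    if exclude_code is not None and data_type is not DataType.DIAGNOSIS:
        raise ValueError(
            "exclude_code applies only to the diagnosis stream, "
            f"not {data_type.value}"
        )
    sequences: list[list[str]] = []
    for ep in episodes:
        if data_type is DataType.WORD:
            sequences.extend(list(s.tokens) for s in ep.sentences)
        else:
            toks = ep.tokens(data_type)
            if exclude_code is not None:
                toks = [t for t in toks if t != exclude_code]
            if toks:
                sequences.append(toks)
    return SequenceSet(data_type=data_type, sequences=sequences)


def _episode_to_record(ep: CareEpisode) -> dict:
    rec: dict = {
        "patient_id": ep.patient_id,
        "episode_id": ep.episode_id,
        "sentences": [list(s.tokens) for s in ep.sentences],
    }
    for dtype, key in _STREAM_KEYS.items():
        rec[key] = [{"code": e.code, "day": e.day} for e in ep.stream(dtype)]
    return rec


def _record_to_episode(rec: dict, lineno: int) -> CareEpisode:
    for key in ("patient_id", "episode_id", "sentences", *_STREAM_KEYS.values()):
        if key not in rec:
            raise ValueError(f"line {lineno}: missing field {key!r}")
    streams = {}
    for dtype, key in _STREAM_KEYS.items():
        try:
            streams[dtype] = [
                Event(dtype, item["code"], int(item["day"])) for item in rec[key]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"line {lineno}: malformed {key!r} entry: {exc}") from exc
    try:
        sentences = [Sentence(toks) for toks in rec["sentences"]]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed sentence: {exc}") from exc
    return CareEpisode(
        patient_id=str(rec["patient_id"]),
        episode_id=str(rec["episode_id"]),
        sentences=sentences,
        diagnosis_events=streams[DataType.DIAGNOSIS],
        drug_events=streams[DataType.DRUG],
        measurement_events=streams[DataType.MEASUREMENT],
    )


def read_corpus(path: str | Path) -> list[CareEpisode]:
    """Read a JSONL corpus; raises ``ValueError`` naming the offending
    line for malformed records."""
    episodes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: invalid JSON: {exc}") from exc
            episodes.append(_record_to_episode(rec, lineno))
    return episodes


def write_corpus(episodes: Iterable[CareEpisode], path: str | Path) -> None:
    """Write episodes as JSON Lines; ``read_corpus`` round-trips exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for ep in episodes:
            fh.write(json.dumps(_episode_to_record(ep), ensure_ascii=False))
            fh.write("\n")
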