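"""Hard assignment of drugs to topics and topic-occupancy ranking.

Each drug is assigned to the most probable topic of its θ row (ties broken
by the smallest topic index, so the indicator matrix is deterministic), and
topics are ranked by how many drugs they attracted.  Topics with at least
``min_drugs`` drugs (default 10) are retained for enrichment analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TopicAssignment",
    "TopicSizeTable",
    "assign_drugs",
    "topic_sizes",
    "filter_topics",
]


@dataclass
class TopicAssignment:
    drug_ids: list[str]
    assigned_topic: np.ndarray  # int64 (n_drugs,)
    n_topics: int

    @property
    def indicator(self) -> np.ndarray:
        """Drug x topic 0/1 matrix; each row has exactly one 1."""
        ind = np.zeros((len(self.drug_ids), self.n_topics), dtype=np.int8)
        ind[np.arange(len(self.drug_ids)), self.assigned_topic] = 1
        return ind

    def drugs_in_topic(self, topic: int) -> list[str]:
        return [d for d, t in zip(self.drug_ids, self.assigned_topic) if t == topic]


@dataclass
class TopicSizeTable:
    counts: np.ndarray  # int64 (n_topics,) in topic order
    order: np.ndarray  # topic indices, descending count, ties by index

    @property
    def n_drugs(self) -> int:
        return int(self.counts.sum())

    def rank_of(self, topic: int) -> int:
        """1-based rank of a topic in the descending-size ordering."""
        return int(np.where(self.order == topic)[0][0]) + 1


def assign_drugs(
    theta: np.ndarray,
    drug_ids: Sequence[str] | None = None,
    tol: float = 1e-6,
) -> TopicAssignment:
    """Assign each drug to the argmax topic of its θ row.

    Rows must sum to 1 within ``tol``; ties take the smallest topic index.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("theta must be 2-D (drugs x topics)")
    ids = list(drug_ids) if drug_ids is not None else [f"drug{i}" for i in range(theta.shape[0])]
    if len(ids) != theta.shape[0]:
        raise ValueError("drug_ids length mismatch")
    sums = theta.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > tol)[0]
    if bad.size:
        raise ValueError(
            f"theta row for drug {ids[bad[0]]!r} sums to {sums[bad[0]]:.6g}, not 1"
        )
    # np.argmax already returns the first (smallest) index on ties
    return TopicAssignment(
        drug_ids=ids,
        assigned_topic=theta.argmax(axis=1).astype(np.int64),
        n_topics=theta.shape[1],
    )


def topic_sizes(assignment: TopicAssignment, n_topics: int | None = None) -> TopicSizeTable:
    """Per-topic drug counts (zero-occupancy topics included), ranked
    descending with ties broken by topic index."""
    T = assignment.n_topics if n_topics is None else n_topics
    if assignment.assigned_topic.size and assignment.assigned_topic.max() >= T:
        raise ValueError("assigned topic index exceeds n_topics")
    counts = np.bincount(assignment.assigned_topic, minlength=T).astype(np.int64)
    order = np.lexsort((np.arange(T), -counts))
    return TopicSizeTable(counts=counts, order=order)


def filter_topics(sizes: TopicSizeTable, min_drugs: int = 10) -> set[int]:
    """Topics with at least ``min_drugs`` assigned drugs (inclusive bound)."""
    return {int(t) for t in np.where(sizes.counts >= min_drugs)[0]}


def write_assignment(assignment: TopicAssignment, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tassigned_topic\n")
        for d, t in zip(assignment.drug_ids, assignment.assigned_topic):
            fh.write(f"{d}\t{int(t)}\n")


def write_sizes(sizes: TopicSizeTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("topic\tn_drugs\trank\n")
        for rank, topic in enumerate(sizes.order, 1):
            fh.write(f"{int(topic)}\t{int(sizes.counts[topic])}\t{rank}\n")
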