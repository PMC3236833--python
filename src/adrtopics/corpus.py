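"""Token-level corpus over a shared ADR-term vocabulary.

Each document is one drug's ADR profile expanded to a token sequence; the
vocabulary is the ordered list of term_ids.  This is the input container for
the LDA sampler.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ingest import AdrProfile

__all__ = ["Corpus", "corpus_from_profiles", "read_corpus", "write_corpus"]


@dataclass
class Corpus:
    vocabulary: list[str]
    docs: list[np.ndarray]
    doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_ids:
            self.doc_ids = [f"doc{i}" for i in range(len(self.docs))]
        if len(self.doc_ids) != len(self.docs):
            raise ValueError("doc_ids and docs length mismatch")
        V = len(self.vocabulary)
        self.docs = [np.asarray(d, dtype=np.int32) for d in self.docs]
        for did, d in zip(self.doc_ids, self.docs):
            if d.size and (d.min() < 0 or d.max() >= V):
                raise ValueError(f"document {did}: token index out of range for V={V}")

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return int(sum(d.size for d in self.docs))

    def doc_lengths(self) -> np.ndarray:
        return np.array([d.size for d in self.docs], dtype=np.int64)

    def doc_term_matrix(self) -> np.ndarray:
        """Dense document x vocabulary count matrix."""
        X = np.zeros((self.n_docs, self.n_words), dtype=np.int64)
        for i, d in enumerate(self.docs):
            np.add.at(X[i], d, 1)
        return X


def corpus_from_profiles(
    profiles: Iterable[AdrProfile], vocabulary: Sequence[str] | None = None
) -> Corpus:
    """Expand ADR profiles into token sequences over a shared vocabulary.

    Counts are expanded to repeated tokens in profile order.  If
    ``vocabulary`` is not given, it is the sorted union of all term_ids.
    """
    profiles = list(profiles)
    if vocabulary is None:
        vocab = sorted({t for p in profiles for t in p.term_counts})
    else:
        vocab = list(vocabulary)
    index = {t: i for i, t in enumerate(vocab)}
    docs, doc_ids = [], []
    for p in profiles:
        toks: list[int] = []
        for term_id, count in p.term_counts.items():
            if term_id not in index:
                raise ValueError(f"term {term_id!r} not in vocabulary")
            toks.extend([index[term_id]] * count)
        docs.append(np.asarray(toks, dtype=np.int32))
        doc_ids.append(p.drug_id)
    return Corpus(vocabulary=vocab, docs=docs, doc_ids=doc_ids)


def read_corpus(path: str | os.PathLike, vocabulary: Sequence[str] | None = None) -> Corpus:
    """Read an AdrProfile TSV (``drug_id term_id count``) as a Corpus,
    expanding counts to tokens in file order."""
    from .ingest import read_profiles

    return corpus_from_profiles(read_profiles(path), vocabulary)


def write_corpus(corpus: Corpus, path: str | os.PathLike) -> None:
    """Write a corpus back to the profile TSV dialect (counts in doc order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for did, d in zip(corpus.doc_ids, corpus.docs):
            seen: dict[int, int] = {}
            for w in d.tolist():
                seen[w] = seen.get(w, 0) + 1
            for w, c in seen.items():
                fh.write(f"{did}\t{corpus.vocabulary[w]}\t{c}\n")
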