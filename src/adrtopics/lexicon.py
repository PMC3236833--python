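"""Controlled vocabulary of adverse-drug-reaction (ADR) terms.

A :class:`TermLexicon` plays the role of a MedDRA lowest-level-term (LLT)
dictionary: a flat list of ``(term_id, term)`` pairs, where a term may span
several words ("hepatic failure").  Matching is done on *normalized* token
sequences (see :func:`adrtopics.ingest.normalize_text`), so "Hepatic-Failure"
and "hepatic failure" are the same term.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .ingest import normalize_text

__all__ = ["TermLexicon", "read_lexicon", "write_lexicon"]


@dataclass
class TermLexicon:
    """An ordered collection of ADR terms with a longest-match token index.

    Parameters
    ----------
    entries
        ``(term_id, term)`` pairs.  ``term_id`` values must be unique, and
        terms must be unique after normalization.
    """

    entries: list[tuple[str, str]]
    _index: dict[str, list[tuple[tuple[str, ...], str]]] = field(
        init=False, repr=False, default_factory=dict
    )
    _max_len: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        ids = [tid for tid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term_id in lexicon")
        seen: set[tuple[str, ...]] = set()
        for tid, term in self.entries:
            toks = tuple(normalize_text(term))
            if not toks:
                raise ValueError(f"term {tid!r} normalizes to nothing: {term!r}")
            if toks in seen:
                raise ValueError(f"term {tid!r} duplicates another term after normalization")
            seen.add(toks)
            self._index.setdefault(toks[0], []).append((toks, tid))
            self._max_len = max(self._max_len, len(toks))
        # longest first so the scanner can take the first hit
        for bucket in self._index.values():
            bucket.sort(key=lambda e: len(e[0]), reverse=True)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    @property
    def term_ids(self) -> list[str]:
        return [tid for tid, _ in self.entries]

    @property
    def max_term_tokens(self) -> int:
        """Length in tokens of the longest term."""
        return self._max_len

    def term_string(self, term_id: str) -> str:
        for tid, term in self.entries:
            if tid == term_id:
                return term
        raise KeyError(term_id)

    def match_at(self, tokens: list[str], pos: int) -> tuple[str, int] | None:
        """Longest lexicon term starting at ``tokens[pos]``.

        Returns ``(term_id, n_tokens_consumed)`` or ``None``.
        """
        bucket = self._index.get(tokens[pos])
        if bucket is None:
            return None
        for toks, tid in bucket:
            n = len(toks)
            if pos + n <= len(tokens) and tuple(tokens[pos : pos + n]) == toks:
                return tid, n
        return None


def read_lexicon(path: str | os.PathLike) -> TermLexicon:
    """Read the two-column ``term_id<TAB>term`` dialect (UTF-8, no header)."""
    entries: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            entries.append((parts[0], parts[1]))
    return TermLexicon(entries)


def write_lexicon(lexicon: TermLexicon | Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, term in lexicon:
            fh.write(f"{tid}\t{term}\n")
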