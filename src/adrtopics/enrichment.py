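"""Topic enrichment analysis for Boxed-Warning status and ATC categories.

For each retained topic a 2×2 contingency table is built — drugs in the
topic vs. the rest of the background, with vs. without the attribute — and
tested with Fisher's exact test.  Two analyses are provided:

* Boxed Warning (BW): the attribute is the drug-level BW flag; the default
  background is the union of drugs assigned to the analyzed topics.
* ATC: each topic is first assigned its *top* first-level ATC category (the
  letter carried by most of its ATC-annotated drugs) and tested for
  enrichment of that letter among ATC-annotated drugs; "purity" is the
  fraction of the topic's annotated drugs carrying the top letter.

Topics with attribute fraction above a highlight threshold (default >70%)
and p below the significance level (default 0.05, no multiple-testing
correction by default) are flagged in the report.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .grouping import TopicAssignment

#: the 14 first-level codes of the ATC classification
ATC_LETTERS = tuple("ABCDGHJLMNPRSV")

__all__ = [
    "ATC_LETTERS",
    "DrugAnnotations",
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_exact_two_sided",
    "fisher_pvalue",
    "attribute_enrichment_pvalue",
    "bw_enrichment",
    "atc_top_category",
    "atc_enrichment",
    "make_report",
    "benjamini_hochberg",
    "read_annotations",
    "write_annotations",
]


@dataclass
class DrugAnnotations:
    """Per-drug BW flag and first-level ATC letters.

    Drugs absent from ``bw`` have unknown BW status and are excluded from the
    BW analysis; ``atc`` maps a drug to a (possibly empty) set of letters.
    """

    bw: dict[str, bool] = field(default_factory=dict)
    atc: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(ATC_LETTERS)
        for drug, letters in self.atc.items():
            letters = frozenset(letters)
            if not letters <= valid:
                raise ValueError(f"drug {drug!r}: invalid ATC letters {sorted(letters - valid)}")
            self.atc[drug] = letters


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 table: a/b = in-topic with/without attribute, c/d = rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_pvalue(t: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2×2 table.

    Two-sided by the minimum-likelihood rule: the p-value sums the
    hypergeometric probabilities of all same-margin tables whose probability
    does not exceed the observed table's (within relative tolerance 1e-7).
    Degenerate tables with an all-zero margin give p = 1.
    """
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        return 1.0
    return float(_scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative=alternative)[1])


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    return fisher_pvalue(t, "two-sided")


def attribute_enrichment_pvalue(
    n_topic: int,
    k_topic: int,
    background_n: int,
    background_k: int,
    alternative: str = "two-sided",
    exclude_topic: bool = True,
) -> float:
    """Enrichment p-value for ``k_topic`` of ``n_topic`` drugs carrying an
    attribute, against a background of ``background_n`` drugs of which
    ``background_k`` carry it.

    ``exclude_topic=True`` removes the topic's drugs from the background
    margins (a disjoint two-group comparison).  ``exclude_topic=False``
    instead places the whole cohort, topic included, as the second row of the
    table — the topic-vs-cohort convention in which each group's attribute
    fraction is compared as if the groups were independent samples.
    """
    if exclude_topic:
        t = ContingencyTable(
            a=k_topic,
            b=n_topic - k_topic,
            c=background_k - k_topic,
            d=(background_n - n_topic) - (background_k - k_topic),
        )
    else:
        t = ContingencyTable(
            a=k_topic, b=n_topic - k_topic, c=background_k, d=background_n - background_k
        )
    return fisher_pvalue(t, alternative)


@dataclass
class EnrichmentResult:
    topic: int
    attribute_label: str
    n_drugs: int
    n_with_attribute: int
    percent: float
    p_value: float
    table: ContingencyTable
    top_terms: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# BW analysis


def bw_enrichment(
    assignment: TopicAssignment,
    ann: DrugAnnotations,
    topics: Iterable[int],
    alternative: str = "two-sided",
    background: str = "retained",
    top_terms_by_topic: Mapping[int, Sequence[str]] | None = None,
) -> list[EnrichmentResult]:
    """Per-topic Boxed-Warning enrichment.

    The background is the union of drugs assigned to the analyzed topics
    (``background='retained'``) or all assigned drugs (``'all'``); drugs
    without a known BW flag are excluded.  For topic t the table is
    a = BW drugs in t, b = non-BW in t, c/d from the remaining background.
    """
    topics = sorted(set(int(t) for t in topics))
    assigned = dict(zip(assignment.drug_ids, assignment.assigned_topic))
    missing = [d for d, t in assigned.items() if t in topics and d not in ann.bw]
    if missing:
        raise ValueError(f"drugs without BW annotation in analyzed topics: {missing[:5]}")
    if background == "retained":
        pool = {d: t for d, t in assigned.items() if t in topics}
    elif background == "all":
        pool = {d: t for d, t in assigned.items() if d in ann.bw}
    else:
        raise ValueError(f"unknown background mode {background!r}")
    if not pool:
        raise ValueError("empty background for BW enrichment")
    n_bg = len(pool)
    k_bg = sum(1 for d in pool if ann.bw[d])
    results = []
    for t in topics:
        in_topic = [d for d, tt in pool.items() if tt == t]
        a = sum(1 for d in in_topic if ann.bw[d])
        b = len(in_topic) - a
        table = ContingencyTable(a=a, b=b, c=k_bg - a, d=(n_bg - len(in_topic)) - (k_bg - a))
        p = fisher_pvalue(table, alternative)
        results.append(
            EnrichmentResult(
                topic=t,
                attribute_label="BW",
                n_drugs=len(in_topic),
                n_with_attribute=a,
                percent=100.0 * a / len(in_topic) if in_topic else float("nan"),
                p_value=p,
                table=table,
                top_terms=list(top_terms_by_topic.get(t, [])) if top_terms_by_topic else [],
            )
        )
    return results


# ---------------------------------------------------------------------------
# ATC analysis


def atc_top_category(
    assignment: TopicAssignment, ann: DrugAnnotations, topic: int
) -> tuple[str | None, int, float]:
    """Top first-level ATC letter of a topic.

    Counts letters over the topic's ATC-annotated drugs (a drug with several
    letters counts toward each); returns ``(letter, n_in_category, purity)``
    with ties broken alphabetically.  A topic without any annotated drug
    returns ``(None, 0, nan)``.
    """
    drugs = assignment.drugs_in_topic(topic)
    if not drugs:
        raise ValueError(f"topic {topic} has no assigned drugs")
    annotated = [d for d in drugs if ann.atc.get(d)]
    if not annotated:
        return None, 0, float("nan")
    counts: dict[str, int] = {}
    for d in annotated:
        for letter in ann.atc[d]:
            counts[letter] = counts.get(letter, 0) + 1
    top = min(counts, key=lambda L: (-counts[L], L))
    return top, counts[top], counts[top] / len(annotated)


def atc_enrichment(
    assignment: TopicAssignment,
    ann: DrugAnnotations,
    topics: Iterable[int],
    alternative: str = "two-sided",
    top_terms_by_topic: Mapping[int, Sequence[str]] | None = None,
) -> list[EnrichmentResult]:
    """Per-topic enrichment of the topic's top ATC category.

    Background = ATC-annotated drugs assigned to the analyzed topics.  For
    topic t with top letter L: a = annotated drugs in t carrying L,
    b = remaining annotated drugs in t, c/d from the annotated background.
    Topics with no annotated drug are skipped with a warning.
    """
    topics = sorted(set(int(t) for t in topics))
    assigned = dict(zip(assignment.drug_ids, assignment.assigned_topic))
    pool = {d: t for d, t in assigned.items() if t in topics and ann.atc.get(d)}
    if not pool:
        warnings.warn("no ATC-annotated drugs in the analyzed topics")
        return []
    n_bg = len(pool)
    results = []
    for t in topics:
        letter, n_in, purity = atc_top_category(assignment, ann, t)
        if letter is None:
            warnings.warn(f"topic {t}: no ATC-annotated drugs; skipped")
            continue
        in_topic = [d for d, tt in pool.items() if tt == t]
        a = n_in
        b = len(in_topic) - a
        k_bg = sum(1 for d in pool if letter in ann.atc[d])
        table = ContingencyTable(a=a, b=b, c=k_bg - a, d=(n_bg - len(in_topic)) - (k_bg - a))
        p = fisher_pvalue(table, alternative)
        results.append(
            EnrichmentResult(
                topic=t,
                attribute_label=letter,
                n_drugs=len(in_topic),
                n_with_attribute=a,
                percent=100.0 * purity,
                p_value=p,
                table=table,
                top_terms=list(top_terms_by_topic.get(t, [])) if top_terms_by_topic else [],
            )
        )
    return results


# ---------------------------------------------------------------------------
# reporting


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; the default report uses raw p)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        q[idx] = prev
    return q


def make_report(
    results: Sequence[EnrichmentResult],
    highlight_purity: float = 0.70,
    alpha_level: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Tabulate enrichment results and flag the highlighted subset.

    A row is highlighted when its attribute percentage strictly exceeds
    ``100*highlight_purity`` and its (raw, or BH-adjusted if ``adjust``)
    p-value is below ``alpha_level``.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "topic": r.topic,
                "attribute": r.attribute_label,
                "n_drugs": r.n_drugs,
                "n_with_attribute": r.n_with_attribute,
                "percent": r.percent,
                "p_value": r.p_value,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "top_terms": "; ".join(r.top_terms),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "topic",
            "attribute",
            "n_drugs",
            "n_with_attribute",
            "percent",
            "p_value",
            "a",
            "b",
            "c",
            "d",
            "top_terms",
        ],
    )
    if df.empty:
        df["highlighted"] = pd.Series(dtype=bool)
        return df
    crit_p = benjamini_hochberg(df["p_value"]) if adjust else df["p_value"].to_numpy()
    df["highlighted"] = (df["percent"] > 100.0 * highlight_purity) & (crit_p < alpha_level)
    return df


def write_report(df: pd.DataFrame, path: str | os.PathLike, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        records = df.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=2, default=float)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# annotation IO: drug_id<TAB>bw<TAB>atc (atc = comma-separated letters)


def read_annotations(path: str | os.PathLike) -> DrugAnnotations:
    bw: dict[str, bool] = {}
    atc: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["drug_id", "bw", "atc"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            drug, bw_s, atc_s = f
            if bw_s not in {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: bw must be 0 or 1")
            bw[drug] = bw_s == "1"
            atc[drug] = frozenset(x for x in atc_s.split(",") if x)
    return DrugAnnotations(bw=bw, atc=atc)


def write_annotations(ann: DrugAnnotations, path: str | os.PathLike) -> None:
    drugs = sorted(set(ann.bw) | set(ann.atc))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tbw\tatc\n")
        for d in drugs:
            bw_s = "1" if ann.bw.get(d, False) else "0"
            atc_s = ",".join(sorted(ann.atc.get(d, frozenset())))
            fh.write(f"{d}\t{bw_s}\t{atc_s}\n")
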