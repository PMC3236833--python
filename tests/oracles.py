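"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths (and scipy's Fisher
implementation): counts are enumerated directly and probabilities computed
with exact integer combinatorics.
"""

from __future__ import annotations

from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of same-margin tables.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability is <= the observed table's (relative tolerance
    1e-7), computing each probability from binomial coefficients.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def fisher_one_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment tail) Fisher p: P[X >= a] under fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(r1 + r2, c1)
    hi = min(c1, r1)
    return sum(comb(r1, x) * comb(r2, c1 - x) / denom for x in range(a, hi + 1))


def longest_match_counts(tokens: list[str], terms: dict[str, tuple[str, ...]]) -> dict[str, int]:
    """Naive longest-match scan: at each position try every term by slicing.

    ``terms`` maps term_id -> normalized token tuple.  Left-to-right,
    non-overlapping, longest term wins; ties cannot occur because token
    tuples are unique.
    """
    counts: dict[str, int] = {}
    pos = 0
    n = len(tokens)
    while pos < n:
        best_id, best_len = None, 0
        for tid, toks in terms.items():
            m = len(toks)
            if m > best_len and tuple(tokens[pos : pos + m]) == toks:
                best_id, best_len = tid, m
        if best_id is None:
            pos += 1
        else:
            counts[best_id] = counts.get(best_id, 0) + 1
            pos += best_len
    return counts
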