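"""Synthetic test bed: ground-truth topic mixtures, rendered label text and
annotated drug metadata with planted enrichment.

This module replaces the non-redistributable inputs of a drug-label topic
analysis (label archives and a licensed ADR dictionary) with generators whose
ground truth is known, so every downstream stage — dictionary extraction,
LDA fitting, drug grouping, enrichment testing — has a known-answer test.

The generative story mirrors the model being fitted: topic-word rows φ and
document-topic rows θ are symmetric-Dirichlet draws, document lengths are
Poisson (truncated at ≥1), and each token is drawn by topic-then-word
sampling.  Rendering writes the tokens back as dictionary term strings
interleaved with distractor words from a pool guaranteed disjoint from the
lexicon, split round-robin across the three label sections, which makes the
render → extract round trip exact.  Annotations plant Boxed-Warning and ATC
enrichment of configurable strength on designated topics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus
from .enrichment import ATC_LETTERS, DrugAnnotations
from .ingest import LabelDocument, SECTION_CODES, normalize_text
from .lexicon import TermLexicon

__all__ = [
    "GroundTruth",
    "PlantedAnnotationScheme",
    "generate_lexicon",
    "generate_ground_truth",
    "generate_corpus",
    "render_labels",
    "generate_annotations",
    "default_drug_ids",
]


def default_drug_ids(n_docs: int) -> list[str]:
    return [f"drug{i:04d}" for i in range(n_docs)]


@dataclass
class GroundTruth:
    """True generative quantities of a synthetic corpus."""

    n_topics: int
    phi_true: np.ndarray  # (K, V) row-stochastic
    theta_true: np.ndarray  # (D, K) row-stochastic
    dominant_topic: np.ndarray  # (D,) argmax of theta rows
    seed: int

    def __post_init__(self) -> None:
        for name, m in (("phi_true", self.phi_true), ("theta_true", self.theta_true)):
            if (m < 0).any():
                raise ValueError(f"{name} has negative entries")
            if m.size and np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} rows do not sum to 1 within 1e-9")
        if not np.array_equal(self.dominant_topic, self.theta_true.argmax(axis=1)):
            raise ValueError("dominant_topic inconsistent with theta_true")

    @property
    def n_docs(self) -> int:
        return self.theta_true.shape[0]

    @property
    def vocab_size(self) -> int:
        return self.phi_true.shape[1]


@dataclass
class PlantedAnnotationScheme:
    """How BW flags and ATC letters are planted on synthetic drugs."""

    bw_topics: frozenset[int] = frozenset()
    bw_rate_in: float = 0.9
    bw_rate_out: float = 0.2
    atc_map: dict[int, str] = field(default_factory=dict)
    atc_purity: float = 0.9
    atc_coverage: float = 0.8

    def __post_init__(self) -> None:
        self.bw_topics = frozenset(self.bw_topics)
        for name in ("bw_rate_in", "bw_rate_out", "atc_purity", "atc_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for t, letter in self.atc_map.items():
            if letter not in ATC_LETTERS:
                raise ValueError(f"atc_map[{t}]={letter!r} is not a first-level ATC code")


# ---------------------------------------------------------------------------
# lexicon

_SYLLABLES = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu ga ge gi go gu "
    "ha he hi ho hu ja jo ka ke ki ko ku la le li lo lu ma me mi mo mu na ne ni "
    "no nu pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu va ve vi "
    "vo vu xa xe xi xo za ze zi zo"
).split()

#: distractor vocabulary used by :func:`render_labels`; any word that happens
#: to appear as a lexicon token is dropped and replaced by a numbered filler
DISTRACTOR_WORDS = (
    "patients treatment should reported clinical studies dosing observed "
    "including common events during therapy risk administration caution "
    "severe cases discontinue monitor advised concomitant placebo trials"
).split()


def _unique_tokens(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        k = int(rng.integers(3, 5))
        tok = "".join(rng.choice(_SYLLABLES, size=k))
        if tok not in taken and tok not in DISTRACTOR_WORDS:
            taken.add(tok)
            out.append(tok)
    return out


def generate_lexicon(
    n_terms: int,
    multiword_fraction: float = 0.3,
    seed: int = 0,
    allow_prefixes: bool = False,
) -> TermLexicon:
    """Generate a miniature ADR-term dictionary.

    Approximately ``multiword_fraction`` of the terms span 2–3 words.  By
    construction every term's first token is unique across the lexicon, so no
    term is a token-prefix of another and longest-match extraction recovers
    rendered text exactly.  With ``allow_prefixes=True`` each 3-word term's
    2-word prefix is also admitted as a term (replacing a single-word one),
    which makes the longest-match rule consequential.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not (0.0 <= multiword_fraction <= 1.0):
        raise ValueError("multiword_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_multi = int(round(n_terms * multiword_fraction))
    n_single = n_terms - n_multi
    taken: set[str] = set()
    heads = _unique_tokens(n_terms, rng, taken)
    tails = _unique_tokens(max(2 * n_multi, 1), rng, taken)
    entries: list[tuple[str, str]] = []
    terms: list[str] = list(heads[:n_single])
    for i in range(n_multi):
        head = heads[n_single + i]
        extra = 1 + int(rng.random() < 0.5)  # 2- or 3-word term
        words = [head] + [tails[int(rng.integers(0, len(tails)))] for _ in range(extra)]
        terms.append(" ".join(words))
    if allow_prefixes:
        for i, term in enumerate(terms):
            words = term.split()
            if len(words) == 3 and n_single > 0:
                # sacrifice a single-word term to admit the 2-word prefix
                victim = next((j for j, t in enumerate(terms) if " " not in t), None)
                if victim is not None:
                    terms[victim] = " ".join(words[:2])
                break
    order = rng.permutation(len(terms))
    for rank, idx in enumerate(order):
        entries.append((f"t{rank:04d}", terms[idx]))
    return TermLexicon(entries)


# ---------------------------------------------------------------------------
# ground truth and corpus


def generate_ground_truth(
    n_topics: int,
    vocab_size: int,
    n_docs: int,
    theta_concentration: float = 0.1,
    phi_concentration: float = 0.05,
    seed: int = 0,
    one_hot_theta: bool = False,
) -> GroundTruth:
    """Draw φ and θ from symmetric Dirichlets.

    ``one_hot_theta`` emulates the θ-concentration → 0 limit: document d's
    θ row is the unit vector of topic ``d mod n_topics`` (balanced
    round-robin), giving exactly equal planted topic sizes.
    """
    if n_topics < 1 or vocab_size < 1 or n_docs < 0:
        raise ValueError("n_topics and vocab_size must be positive, n_docs nonnegative")
    if theta_concentration <= 0 or phi_concentration <= 0:
        raise ValueError("Dirichlet concentrations must be positive")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(vocab_size, phi_concentration), size=n_topics)
    phi = phi / phi.sum(axis=1, keepdims=True)
    if one_hot_theta:
        theta = np.zeros((n_docs, n_topics))
        theta[np.arange(n_docs), np.arange(n_docs) % n_topics] = 1.0
    else:
        theta = rng.dirichlet(np.full(n_topics, theta_concentration), size=n_docs)
        theta = theta / theta.sum(axis=1, keepdims=True)
    return GroundTruth(
        n_topics=n_topics,
        phi_true=phi,
        theta_true=theta,
        dominant_topic=theta.argmax(axis=1),
        seed=seed,
    )


def generate_corpus(
    gt: GroundTruth,
    doc_length_mean: float = 50.0,
    seed: int = 0,
    vocabulary: list[str] | None = None,
) -> tuple[Corpus, list[np.ndarray]]:
    """Sample a token corpus from the ground truth.

    Document lengths are Poisson(``doc_length_mean``) truncated at 1; each
    token draws a topic from the document's θ row and then a word from that
    topic's φ row.  Returns the corpus and the per-token true topic labels.
    """
    if doc_length_mean < 1:
        raise ValueError("doc_length_mean must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = vocabulary if vocabulary is not None else [f"t{i:04d}" for i in range(gt.vocab_size)]
    if len(vocab) != gt.vocab_size:
        raise ValueError("vocabulary length must equal ground-truth vocab_size")
    docs: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    lengths = np.maximum(rng.poisson(doc_length_mean, size=gt.n_docs), 1)
    for d in range(gt.n_docs):
        n = int(lengths[d])
        z = rng.choice(gt.n_topics, size=n, p=gt.theta_true[d])
        w = np.array([rng.choice(gt.vocab_size, p=gt.phi_true[j]) for j in z], dtype=np.int32)
        docs.append(w)
        labels.append(z.astype(np.int32))
    corpus = Corpus(vocabulary=list(vocab), docs=docs, doc_ids=default_drug_ids(gt.n_docs))
    return corpus, labels


# ---------------------------------------------------------------------------
# label rendering


def render_labels(
    corpus: Corpus,
    lexicon: TermLexicon,
    distractor_rate: float = 0.3,
    seed: int = 0,
) -> list[LabelDocument]:
    """Write corpus tokens back out as label text.

    Each token is rendered as its lexicon term string; before each term,
    distractor words are interleaved with probability ``distractor_rate``
    (geometric run lengths).  Successive items (terms and distractors) are
    split round-robin across the BW/WP/AR sections.  The distractor pool is
    checked to be disjoint from the lexicon's token set so extraction
    recovers the corpus counts exactly.
    """
    if not (0.0 <= distractor_rate < 1.0):
        raise ValueError("distractor_rate must be in [0, 1)")
    term_for: dict[str, str] = {tid: term for tid, term in lexicon}
    missing = [t for t in corpus.vocabulary if t not in term_for]
    if missing:
        raise ValueError(f"corpus vocabulary not resolvable in lexicon: {missing[:5]}")
    lex_tokens = {tok for _, term in lexicon for tok in normalize_text(term)}
    pool = [w for w in DISTRACTOR_WORDS if w not in lex_tokens]
    i = 0
    while len(pool) < 5:
        cand = f"filler{i}"
        if cand not in lex_tokens:
            pool.append(cand)
        i += 1
    rng = np.random.default_rng(seed)
    labels: list[LabelDocument] = []
    for did, doc in zip(corpus.doc_ids, corpus.docs):
        items: list[str] = []
        for w in doc.tolist():
            while rng.random() < distractor_rate:
                items.append(pool[int(rng.integers(0, len(pool)))])
            items.append(term_for[corpus.vocabulary[w]])
        sections: dict[str, list[str]] = {code: [] for code in SECTION_CODES}
        for k, item in enumerate(items):
            sections[SECTION_CODES[k % 3]].append(item)
        labels.append(
            LabelDocument(
                drug_id=did,
                sections={code: " ".join(parts) for code, parts in sections.items() if parts},
            )
        )
    return labels


# ---------------------------------------------------------------------------
# annotations


def generate_annotations(
    gt: GroundTruth,
    scheme: PlantedAnnotationScheme,
    seed: int = 0,
    drug_ids: list[str] | None = None,
) -> DrugAnnotations:
    """Draw per-drug BW flags and ATC letters with planted topic structure.

    A drug whose dominant topic is in ``scheme.bw_topics`` carries BW with
    probability ``bw_rate_in``, otherwise ``bw_rate_out``.  With probability
    ``atc_coverage`` the drug gets one ATC letter: its topic's mapped letter
    with probability ``atc_purity`` (a uniformly random *other* letter
    otherwise); drugs of unmapped topics draw uniformly from all 14 letters.
    """
    if not set(scheme.atc_map) <= set(range(gt.n_topics)):
        raise ValueError("atc_map keys must be topic indices of the ground truth")
    ids = drug_ids if drug_ids is not None else default_drug_ids(gt.n_docs)
    if len(ids) != gt.n_docs:
        raise ValueError("drug_ids length mismatch")
    rng = np.random.default_rng(seed)
    bw: dict[str, bool] = {}
    atc: dict[str, frozenset[str]] = {}
    letters = list(ATC_LETTERS)
    for d, did in enumerate(ids):
        dom = int(gt.dominant_topic[d])
        rate = scheme.bw_rate_in if dom in scheme.bw_topics else scheme.bw_rate_out
        bw[did] = bool(rng.random() < rate)
        if rng.random() < scheme.atc_coverage:
            mapped = scheme.atc_map.get(dom)
            if mapped is not None and rng.random() < scheme.atc_purity:
                letter = mapped
            elif mapped is not None:
                others = [L for L in letters if L != mapped]
                letter = others[int(rng.integers(0, len(others)))]
            else:
                letter = letters[int(rng.integers(0, len(letters)))]
            atc[did] = frozenset({letter})
        else:
            atc[did] = frozenset()
    return DrugAnnotations(bw=bw, atc=atc)
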