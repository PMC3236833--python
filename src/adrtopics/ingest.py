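"""Drug-label ingestion: record deduplication, text normalization, and
dictionary-based extraction of ADR term profiles.

A drug label here is a :class:`LabelDocument` with up to three safety
sections — Boxed Warning (BW), Warnings and Precautions (WP) and Adverse
Reactions (AR).  Extraction pools the three sections, normalizes the text and
scans it left to right, counting the longest dictionary term starting at each
position (non-overlapping); everything that is not a dictionary term is
discarded.  The result, an :class:`AdrProfile`, is the bag of standardized
ADR terms that downstream topic modeling consumes.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import TermLexicon

logger = logging.getLogger(__name__)

SECTION_CODES = ("BW", "WP", "AR")

#: dose forms / route accepted by the inclusion criteria
DOSE_FORM_WHITELIST = frozenset({"tablet", "capsule"})
ROUTE_WHITELIST = frozenset({"intravenous"})

PLAIN_HEADERS = {
    "## BOXED WARNING": "BW",
    "## WARNINGS AND PRECAUTIONS": "WP",
    "## ADVERSE REACTIONS": "AR",
}
_HEADER_FOR_CODE = {v: k for k, v in PLAIN_HEADERS.items()}

__all__ = [
    "DrugRecord",
    "LabelDocument",
    "AdrProfile",
    "LabelParseError",
    "deduplicate_labels",
    "normalize_text",
    "extract_adr_profile",
    "parse_label_file",
    "write_label",
    "read_drug_records",
    "write_drug_records",
    "read_profiles",
    "write_profiles",
]


class LabelParseError(ValueError):
    """A label file does not conform to its dialect."""


@dataclass(frozen=True)
class DrugRecord:
    """One row of the drug metadata table used by the inclusion criteria."""

    drug_id: str
    generic_name: str
    effective_date: _dt.date
    n_active_ingredients: int
    is_small_molecule: bool
    is_prescription: bool
    dose_form: str
    route: str


@dataclass
class LabelDocument:
    """Free text of a drug label, keyed by section code (BW/WP/AR)."""

    drug_id: str
    sections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sections) - set(SECTION_CODES)
        if bad:
            raise ValueError(f"unknown section codes {sorted(bad)}")


@dataclass
class AdrProfile:
    """Bag of matched ADR terms for one drug: ``term_id -> count >= 1``."""

    drug_id: str
    term_counts: dict[str, int] = field(default_factory=dict)

    def total_tokens(self) -> int:
        return sum(self.term_counts.values())


def deduplicate_labels(records: Iterable[DrugRecord]) -> list[str]:
    """Reduce a label collection to one drug per label.

    Records are grouped by case-insensitive generic name; within each group
    the record with the latest effective date wins (ties broken by drug_id).
    The surviving record is then kept only if it is a single-active-ingredient,
    small-molecule, prescription drug whose dose form is a tablet/capsule or
    whose route is intravenous.

    Returns the kept ``drug_id`` values in input order of first appearance of
    the group.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    groups: dict[str, DrugRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.generic_name.strip().lower()
        cur = groups.get(key)
        if cur is None:
            groups[key] = rec
            order.append(key)
        elif (rec.effective_date, rec.drug_id) > (cur.effective_date, cur.drug_id):
            groups[key] = rec
    kept: list[str] = []
    for key in order:
        rec = groups[key]
        if rec.n_active_ingredients != 1:
            continue
        if not rec.is_small_molecule:
            continue
        if not rec.is_prescription:
            continue
        if rec.dose_form.lower() not in DOSE_FORM_WHITELIST and rec.route.lower() not in ROUTE_WHITELIST:
            continue
        kept.append(rec.drug_id)
    return kept


_NON_WORD = re.compile(r"[^0-9a-z]+")


def normalize_text(raw: str) -> list[str]:
    """Lowercase, map punctuation (incl. hyphens) to spaces, and tokenize."""
    return _NON_WORD.sub(" ", raw.lower()).split()


def extract_adr_profile(label: LabelDocument, lexicon: "TermLexicon") -> AdrProfile:
    """Filter a label's pooled section text down to dictionary ADR terms.

    The three sections (in BW, WP, AR order) are concatenated and normalized;
    the token stream is scanned left to right and at each position the
    *longest* lexicon term starting there is counted, with the scan resuming
    after the match (non-overlapping).  Unmatched tokens are skipped.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    text = " ".join(label.sections.get(code, "") for code in SECTION_CODES)
    tokens = normalize_text(text)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(tokens):
        hit = lexicon.match_at(tokens, pos)
        if hit is None:
            pos += 1
        else:
            term_id, n = hit
            counts[term_id] = counts.get(term_id, 0) + 1
            pos += n
    return AdrProfile(drug_id=label.drug_id, term_counts=counts)


def parse_label_file(path: str | os.PathLike, dialect: str = "plain") -> LabelDocument:
    """Parse a label file in the ``plain`` or ``xml`` dialect.

    Plain dialect: section headers ``## BOXED WARNING``,
    ``## WARNINGS AND PRECAUTIONS``, ``## ADVERSE REACTIONS`` on their own
    lines; the drug_id is the file stem.  XML dialect:
    ``<label drug_id="..."><section code="BW|WP|AR">text</section></label>``.
    Unknown section codes are ignored with a warning; malformed files raise
    :class:`LabelParseError` naming the file.
    """
    path = os.fspath(path)
    if dialect == "plain":
        return _parse_plain(path)
    if dialect == "xml":
        return _parse_xml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_plain(path: str) -> LabelDocument:
    drug_id = os.path.splitext(os.path.basename(path))[0]
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped in PLAIN_HEADERS:
                current = PLAIN_HEADERS[stripped]
                if current in sections:
                    raise LabelParseError(f"{path}: duplicate section {current}")
                sections[current] = []
            elif stripped.startswith("## "):
                warnings.warn(f"{path}: ignoring unknown section header {stripped!r}")
                current = None
            elif current is not None:
                sections[current].append(stripped)
            elif stripped.strip():
                raise LabelParseError(f"{path}: text before any section header")
    return LabelDocument(
        drug_id=drug_id,
        sections={code: "\n".join(lines).strip() for code, lines in sections.items()},
    )


def _parse_xml(path: str) -> LabelDocument:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise LabelParseError(f"{path}: malformed XML: {exc}") from exc
    if root.tag != "label" or "drug_id" not in root.attrib:
        raise LabelParseError(f"{path}: expected <label drug_id=...> root")
    sections: dict[str, str] = {}
    for child in root:
        if child.tag != "section":
            warnings.warn(f"{path}: ignoring element <{child.tag}>")
            continue
        code = child.get("code")
        if code not in SECTION_CODES:
            warnings.warn(f"{path}: ignoring unknown section code {code!r}")
            continue
        if code in sections:
            raise LabelParseError(f"{path}: duplicate section {code}")
        sections[code] = (child.text or "").strip()
    return LabelDocument(drug_id=root.attrib["drug_id"], sections=sections)


def write_label(label: LabelDocument, path: str | os.PathLike, dialect: str = "plain") -> None:
    """Inverse of :func:`parse_label_file` for round-trip use."""
    path = os.fspath(path)
    if dialect == "plain":
        with open(path, "w", encoding="utf-8") as fh:
            for code in SECTION_CODES:
                if code in label.sections:
                    fh.write(_HEADER_FOR_CODE[code] + "\n")
                    fh.write(label.sections[code] + "\n")
    elif dialect == "xml":
        root = ET.Element("label", drug_id=label.drug_id)
        for code in SECTION_CODES:
            if code in label.sections:
                el = ET.SubElement(root, "section", code=code)
                el.text = label.sections[code]
        ET.ElementTree(root).write(path, encoding="unicode")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# tabular IO

_RECORD_COLUMNS = [
    "drug_id",
    "generic_name",
    "effective_date",
    "n_active_ingredients",
    "is_small_molecule",
    "is_prescription",
    "dose_form",
    "route",
]


def read_drug_records(path: str | os.PathLike) -> list[DrugRecord]:
    """Read the headered drug-record TSV; rows with unparseable dates are
    rejected with a logged warning rather than aborting the run."""
    records: list[DrugRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _RECORD_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_RECORD_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(_RECORD_COLUMNS)} fields")
            try:
                date = _dt.date.fromisoformat(f[2])
            except ValueError:
                logger.warning("%s:%d: unparseable date %r; record %s rejected", path, lineno, f[2], f[0])
                continue
            records.append(
                DrugRecord(
                    drug_id=f[0],
                    generic_name=f[1],
                    effective_date=date,
                    n_active_ingredients=int(f[3]),
                    is_small_molecule=f[4] == "1",
                    is_prescription=f[5] == "1",
                    dose_form=f[6],
                    route=f[7],
                )
            )
    return records


def write_drug_records(records: Iterable[DrugRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RECORD_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.drug_id,
                        r.generic_name,
                        r.effective_date.isoformat(),
                        str(r.n_active_ingredients),
                        "1" if r.is_small_molecule else "0",
                        "1" if r.is_prescription else "0",
                        r.dose_form,
                        r.route,
                    ]
                )
                + "\n"
            )


def write_profiles(profiles: Iterable[AdrProfile], path: str | os.PathLike) -> None:
    """Write profiles as the ``drug_id<TAB>term_id<TAB>count`` dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in profiles:
            for term_id, count in p.term_counts.items():
                fh.write(f"{p.drug_id}\t{term_id}\t{count}\n")


def read_profiles(path: str | os.PathLike) -> list[AdrProfile]:
    by_drug: dict[str, AdrProfile] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            drug_id, term_id, count = f[0], f[1], int(f[2])
            if count < 1:
                raise ValueError(f"{path}:{lineno}: count must be >= 1")
            prof = by_drug.setdefault(drug_id, AdrProfile(drug_id=drug_id))
            prof.term_counts[term_id] = prof.term_counts.get(term_id, 0) + count
    return list(by_drug.values())


def profiles_from_labels(
    labels: Iterable[LabelDocument], lexicon: "TermLexicon"
) -> list[AdrProfile]:
    """Convenience: extract a profile for every label (empty profiles kept)."""
    return [extract_adr_profile(lab, lexicon) for lab in labels]
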