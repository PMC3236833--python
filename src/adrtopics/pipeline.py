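"""End-to-end orchestration: deduplicate → extract → corpus → fit →
assign → filter → enrich → report, with seeded reproducibility and a run
manifest.

A run is described by a :class:`RunConfig` holding either real input paths
(label files, lexicon, drug-record table, annotations) or a synthetic
scenario; all printed-threshold defaults (100 topics, ≥10 drugs per retained
topic, >70% highlight, α = 0.05) live here and are never hard-coded
downstream.  One global seed fans out to per-stage seeds so stages can be
rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version

import numpy as np
import yaml

from . import grouping, lda
from .corpus import corpus_from_profiles, write_corpus
from .enrichment import (
    DrugAnnotations,
    atc_enrichment,
    bw_enrichment,
    make_report,
    read_annotations,
    write_annotations,
    write_report,
)
from .ingest import (
    DrugRecord,
    deduplicate_labels,
    extract_adr_profile,
    parse_label_file,
    read_drug_records,
    write_drug_records,
    write_label,
    write_profiles,
)
from .lexicon import read_lexicon, write_lexicon
from .synthetic import (
    PlantedAnnotationScheme,
    default_drug_ids,
    generate_annotations,
    generate_corpus,
    generate_ground_truth,
    generate_lexicon,
    render_labels,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SyntheticScenario", "InputPaths", "run_pipeline", "validate_inputs", "ValidationError"]


class ValidationError(ValueError):
    """Input files are mutually inconsistent (e.g. dangling drug_id)."""


@dataclass
class SyntheticScenario:
    n_topics: int = 10
    vocab_size: int = 300
    n_docs: int = 300
    doc_length_mean: float = 50.0
    theta_concentration: float = 0.1
    phi_concentration: float = 0.05
    one_hot_theta: bool = False
    multiword_fraction: float = 0.3
    distractor_rate: float = 0.3
    bw_topics: list[int] = field(default_factory=lambda: [0, 1])
    bw_rate_in: float = 0.9
    bw_rate_out: float = 0.2
    atc_map: dict[int, str] = field(default_factory=dict)
    atc_purity: float = 0.9
    atc_coverage: float = 0.8


@dataclass
class InputPaths:
    labels_dir: str
    lexicon: str
    records: str
    annotations: str
    dialect: str = "plain"


@dataclass
class RunConfig:
    output_dir: str = "adrtopics_run"
    seed: int = 0
    synthetic: SyntheticScenario | None = None
    inputs: InputPaths | None = None
    lda: lda.LdaConfig = field(default_factory=lda.LdaConfig)
    min_drugs_per_topic: int = 10
    background: str = "retained"
    alternative: str = "two-sided"
    highlight_purity: float = 0.70
    alpha_level: float = 0.05
    top_k_terms: int = 5

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic scenario or input paths must be set")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if "atc_map" in syn and syn["atc_map"]:
                syn["atc_map"] = {int(k): v for k, v in syn["atc_map"].items()}
            d["synthetic"] = SyntheticScenario(**syn)
        if d.get("inputs") is not None:
            d["inputs"] = InputPaths(**d["inputs"])
        if "lda" in d and isinstance(d["lda"], dict):
            d["lda"] = lda.LdaConfig(**d["lda"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output_dir excluded, so the
        same analysis in two directories hashes identically)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan one global seed out to per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------


def _materialize_synthetic(cfg: RunConfig, outdir: str) -> InputPaths:
    """Generate and write the synthetic inputs, returning their paths."""
    syn = cfg.synthetic
    seeds = _stage_seeds(cfg.seed)
    lexicon = generate_lexicon(syn.vocab_size, syn.multiword_fraction, seed=seeds[0])
    gt = generate_ground_truth(
        syn.n_topics,
        syn.vocab_size,
        syn.n_docs,
        theta_concentration=syn.theta_concentration,
        phi_concentration=syn.phi_concentration,
        seed=seeds[1],
        one_hot_theta=syn.one_hot_theta,
    )
    corpus, _ = generate_corpus(gt, syn.doc_length_mean, seed=seeds[2], vocabulary=lexicon.term_ids)
    labels = render_labels(corpus, lexicon, syn.distractor_rate, seed=seeds[3])
    atc_map = syn.atc_map or {
        t: list("ABCDGHJLMNPRSV")[t % 14] for t in range(syn.n_topics)
    }
    scheme = PlantedAnnotationScheme(
        bw_topics=frozenset(syn.bw_topics),
        bw_rate_in=syn.bw_rate_in,
        bw_rate_out=syn.bw_rate_out,
        atc_map=atc_map,
        atc_purity=syn.atc_purity,
        atc_coverage=syn.atc_coverage,
    )
    ann = generate_annotations(gt, scheme, seed=seeds[4])
    # trivial metadata so the deduplication stage exercises the real path
    import datetime as _dt

    records = [
        DrugRecord(
            drug_id=did,
            generic_name=did,
            effective_date=_dt.date(2010, 1, 1),
            n_active_ingredients=1,
            is_small_molecule=True,
            is_prescription=True,
            dose_form="tablet",
            route="oral",
        )
        for did in default_drug_ids(syn.n_docs)
    ]
    labels_dir = os.path.join(outdir, "labels")
    os.makedirs(labels_dir, exist_ok=True)
    for lab in labels:
        write_label(lab, os.path.join(labels_dir, f"{lab.drug_id}.txt"), "plain")
    paths = InputPaths(
        labels_dir=labels_dir,
        lexicon=os.path.join(outdir, "lexicon.tsv"),
        records=os.path.join(outdir, "records.tsv"),
        annotations=os.path.join(outdir, "annotations.tsv"),
        dialect="plain",
    )
    write_lexicon(lexicon, paths.lexicon)
    write_drug_records(records, paths.records)
    write_annotations(ann, paths.annotations)
    np.savetxt(os.path.join(outdir, "theta_true.tsv"), gt.theta_true, delimiter="\t")
    np.savetxt(os.path.join(outdir, "phi_true.tsv"), gt.phi_true, delimiter="\t")
    return paths


def _label_files(paths: InputPaths) -> list[str]:
    pattern = "*.xml" if paths.dialect == "xml" else "*.txt"
    return sorted(glob.glob(os.path.join(paths.labels_dir, pattern)))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    outdir = cfg.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version("adrtopics"),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t0)

    try:
        if cfg.synthetic is not None:
            stage("simulate")
            paths = _materialize_synthetic(cfg, outdir)
        else:
            paths = cfg.inputs

        stage("deduplicate")
        records = read_drug_records(paths.records)
        kept = deduplicate_labels(records)
        manifest["stages"]["deduplicate"] = {"n_records": len(records), "n_kept": len(kept)}

        stage("extract")
        lexicon = read_lexicon(paths.lexicon)
        kept_set = set(kept)
        profiles = []
        for f in _label_files(paths):
            label = parse_label_file(f, paths.dialect)
            if label.drug_id in kept_set:
                profiles.append(extract_adr_profile(label, lexicon))
        profiles.sort(key=lambda p: kept.index(p.drug_id))
        write_profiles(profiles, os.path.join(outdir, "profiles.tsv"))
        manifest["stages"]["extract"] = {
            "n_profiles": len(profiles),
            "n_tokens": int(sum(p.total_tokens() for p in profiles)),
        }

        stage("fit")
        corpus = corpus_from_profiles(profiles, vocabulary=lexicon.term_ids)
        write_corpus(corpus, os.path.join(outdir, "corpus.tsv"))
        lda_cfg = dataclasses.replace(cfg.lda, seed=_stage_seeds(cfg.seed)[5])
        fit = lda.fit_lda(corpus, lda_cfg)
        lda.write_theta(fit, os.path.join(outdir, "theta.tsv"))
        lda.write_phi(fit, os.path.join(outdir, "phi.tsv"))
        lda.write_top_terms(fit, cfg.top_k_terms, os.path.join(outdir, "top_terms.tsv"))
        lda.write_ll_trace(fit, os.path.join(outdir, "ll_trace.tsv"))
        manifest["stages"]["fit"] = {
            "n_docs": corpus.n_docs,
            "n_tokens": corpus.n_tokens,
            "n_topics": lda_cfg.n_topics,
        }

        stage("assign")
        assignment = grouping.assign_drugs(fit.theta, fit.doc_ids)
        sizes = grouping.topic_sizes(assignment)
        grouping.write_assignment(assignment, os.path.join(outdir, "assignment.tsv"))
        grouping.write_sizes(sizes, os.path.join(outdir, "topic_sizes.tsv"))
        retained = grouping.filter_topics(sizes, cfg.min_drugs_per_topic)
        manifest["stages"]["assign"] = {
            "n_drugs": len(assignment.drug_ids),
            "n_retained_topics": len(retained),
        }

        stage("enrich")
        ann = read_annotations(paths.annotations)
        top_by_topic = {
            j: [tid for tid, _ in lda.top_terms(fit, j, min(cfg.top_k_terms, corpus.n_words))]
            for j in sorted(retained)
        }
        bw_results = bw_enrichment(
            assignment, ann, retained, cfg.alternative, cfg.background, top_by_topic
        )
        atc_results = atc_enrichment(assignment, ann, retained, cfg.alternative, top_by_topic)
        bw_report = make_report(bw_results, cfg.highlight_purity, cfg.alpha_level)
        atc_report = make_report(atc_results, cfg.highlight_purity, cfg.alpha_level)
        write_report(bw_report, os.path.join(outdir, "report_bw.tsv"))
        write_report(atc_report, os.path.join(outdir, "report_atc.tsv"))
        write_report(bw_report, os.path.join(outdir, "report_bw.json"), "json")
        write_report(atc_report, os.path.join(outdir, "report_atc.json"), "json")
        manifest["stages"]["enrich"] = {
            "n_bw_rows": int(len(bw_report)),
            "n_bw_highlighted": int(bw_report["highlighted"].sum()) if len(bw_report) else 0,
            "n_atc_rows": int(len(atc_report)),
            "n_atc_highlighted": int(atc_report["highlighted"].sum()) if len(atc_report) else 0,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {list(manifest['stages'])[-1:] or ['simulate']}: {exc}") from exc

    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return manifest


def validate_inputs(cfg: RunConfig) -> dict:
    """Cross-check the input files; dangling drug_id references are fatal.

    Returns a report with an ``issues`` list (empty when consistent) and the
    count of drugs dropped by each inclusion criterion.
    """
    if cfg.synthetic is not None:
        return {"issues": [], "note": "synthetic scenario; inputs generated internally"}
    paths = cfg.inputs
    issues: list[str] = []
    records = read_drug_records(paths.records)
    record_ids = {r.drug_id for r in records}
    lexicon = read_lexicon(paths.lexicon)
    ann = read_annotations(paths.annotations)
    label_ids = set()
    for f in _label_files(paths):
        label = parse_label_file(f, paths.dialect)
        label_ids.add(label.drug_id)
        if label.drug_id not in record_ids:
            issues.append(f"label {f} references unknown drug_id {label.drug_id!r}")

    # per-criterion drop counts on the latest-per-generic representatives
    groups: dict[str, DrugRecord] = {}
    for rec in records:
        key = rec.generic_name.strip().lower()
        cur = groups.get(key)
        if cur is None or (rec.effective_date, rec.drug_id) > (cur.effective_date, cur.drug_id):
            groups[key] = rec
    drops = {
        "duplicate_label": len(records) - len(groups),
        "multi_ingredient": 0,
        "not_small_molecule": 0,
        "not_prescription": 0,
        "dose_form_route": 0,
    }
    kept = []
    for rec in groups.values():
        if rec.n_active_ingredients != 1:
            drops["multi_ingredient"] += 1
        elif not rec.is_small_molecule:
            drops["not_small_molecule"] += 1
        elif not rec.is_prescription:
            drops["not_prescription"] += 1
        elif rec.dose_form.lower() not in {"tablet", "capsule"} and rec.route.lower() != "intravenous":
            drops["dose_form_route"] += 1
        else:
            kept.append(rec.drug_id)
    for did in kept:
        if did in label_ids and did not in ann.bw:
            issues.append(f"kept drug {did!r} missing from the annotation table")
    report = {"issues": issues, "dropped": drops, "n_labels": len(label_ids), "n_terms": len(lexicon)}
    dangling = [i for i in issues if "unknown drug_id" in i]
    if dangling:
        raise ValidationError("; ".join(dangling))
    return report
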