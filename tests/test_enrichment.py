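"""Fisher exact testing, BW/ATC topic enrichment and report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adrtopics import (
    ContingencyTable,
    DrugAnnotations,
    EnrichmentResult,
    TopicAssignment,
    atc_enrichment,
    atc_top_category,
    bw_enrichment,
    fisher_exact_two_sided,
    fisher_pvalue,
    make_report,
)
from adrtopics.enrichment import benjamini_hochberg, read_annotations, write_annotations
from adrtopics.synthetic import (
    PlantedAnnotationScheme,
    default_drug_ids,
    generate_annotations,
    generate_ground_truth,
)

from oracles import fisher_two_sided_enumeration


def make_assignment(topics: list[int]) -> TopicAssignment:
    return TopicAssignment(
        drug_ids=[f"d{i}" for i in range(len(topics))],
        assigned_topic=np.array(topics, dtype=np.int64),
        n_topics=max(topics) + 1,
    )


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable(5, 5, 50, 50)) == pytest.approx(1.0)

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 3, 4)) == 1.0
        assert fisher_exact_two_sided(ContingencyTable(0, 3, 0, 4)) == 1.0

    def test_negative_cells_fatal(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_symmetric_under_row_and_column_swap(self, cells):
        a, b, c, d = cells
        p1 = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        p2 = fisher_exact_two_sided(ContingencyTable(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), abs=1e-10)


class TestBwEnrichment:
    def test_contingency_cells_partition_background(self):
        topics = [0] * 6 + [1] * 8 + [2] * 11
        ann = DrugAnnotations(bw={f"d{i}": i % 3 == 0 for i in range(25)})
        results = bw_enrichment(make_assignment(topics), ann, {0, 1, 2})
        for r in results:
            assert r.table.a + r.table.b == r.n_drugs
            assert r.table.total == 25

    def test_all_bw_topic_beats_equal_size_mixed_topic(self):
        topics = [0] * 8 + [1] * 8 + [2] * 20
        bw = {}
        for i, t in enumerate(topics):
            bw[f"d{i}"] = t == 0 or (t == 1 and i % 2 == 0) or (t == 2 and i % 4 == 0)
        results = {r.topic: r for r in bw_enrichment(make_assignment(topics), ann_for(bw), {0, 1, 2})}
        assert results[0].p_value < results[1].p_value
        assert results[0].percent == 100.0

    def test_missing_bw_annotation_fatal(self):
        topics = [0] * 10
        ann = DrugAnnotations(bw={"d0": True})
        with pytest.raises(ValueError, match="without BW"):
            bw_enrichment(make_assignment(topics), ann, {0})

    def test_planted_topics_detected_and_null_calibrated(self):
        detected = 0
        null_flags = 0
        n_seeds = 40
        for seed in range(n_seeds):
            gt = generate_ground_truth(10, 10, 300, seed=seed, one_hot_theta=True)
            scheme = PlantedAnnotationScheme(bw_topics={0, 1}, bw_rate_in=0.9, bw_rate_out=0.2)
            ann = generate_annotations(gt, scheme, seed=1000 + seed)
            assignment = TopicAssignment(
                default_drug_ids(300), gt.dominant_topic.astype(np.int64), 10
            )
            results = bw_enrichment(assignment, ann, range(10))
            hits = [r for r in results if r.topic in (0, 1) and r.p_value < 0.05 and r.percent > 70]
            detected += len(hits) == 2
            # a null topic (rate 0.2) may reach significance as *depletion*
            # against the pooled background, but must not be highlighted as
            # BW-dense: the report rule requires >70% BW as well
            null_flags += sum(
                1 for r in results if r.topic > 1 and r.p_value < 0.05 and r.percent > 70
            )
        assert detected >= int(0.9 * n_seeds)
        assert null_flags == 0


def ann_for(bw: dict, atc: dict | None = None) -> DrugAnnotations:
    return DrugAnnotations(bw=bw, atc={k: frozenset(v) for k, v in (atc or {}).items()})


class TestAtc:
    def test_top_category_hand_count(self):
        topics = [0] * 5
        atc = {"d0": {"N"}, "d1": {"N"}, "d2": {"N"}, "d3": {"J"}, "d4": set()}
        letter, n, purity = atc_top_category(make_assignment(topics), ann_for({}, atc), 0)
        assert (letter, n, purity) == ("N", 3, 0.75)

    def test_all_same_letter_purity_one(self):
        topics = [0] * 4
        atc = {f"d{i}": {"L"} for i in range(4)}
        letter, n, purity = atc_top_category(make_assignment(topics), ann_for({}, atc), 0)
        assert letter == "L" and purity == 1.0

    def test_tie_broken_alphabetically(self):
        topics = [0] * 4
        atc = {"d0": {"N"}, "d1": {"N"}, "d2": {"B"}, "d3": {"B"}}
        letter, n, _ = atc_top_category(make_assignment(topics), ann_for({}, atc), 0)
        assert letter == "B" and n == 2

    def test_multi_letter_drug_counts_toward_each(self):
        topics = [0] * 3
        atc = {"d0": {"A", "B"}, "d1": {"A"}, "d2": {"B"}}
        letter, n, purity = atc_top_category(make_assignment(topics), ann_for({}, atc), 0)
        assert letter == "A" and n == 2 and purity == pytest.approx(2 / 3)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        letters = list("ABCDGHJLMNPRSV")
        for _ in range(25):
            n = int(rng.integers(1, 15))
            atc = {
                f"d{i}": set(rng.choice(letters, size=rng.integers(0, 3), replace=False))
                for i in range(n)
            }
            assignment = make_assignment([0] * n)
            annotated = [d for d in atc if atc[d]]
            if not annotated:
                letter, cnt, purity = atc_top_category(assignment, ann_for({}, atc), 0)
                assert letter is None and np.isnan(purity)
                continue
            counts = {}
            for d in annotated:
                for L in atc[d]:
                    counts[L] = counts.get(L, 0) + 1
            best = min(counts, key=lambda L: (-counts[L], L))
            letter, cnt, purity = atc_top_category(assignment, ann_for({}, atc), 0)
            assert letter == best and cnt == counts[best]
            assert purity == pytest.approx(counts[best] / len(annotated))

    def test_topic_without_atc_skipped_with_warning(self):
        topics = [0] * 3
        ann = ann_for({}, {f"d{i}": set() for i in range(3)})
        with pytest.warns(UserWarning):
            assert atc_enrichment(make_assignment(topics), ann, {0}) == []

    def test_planted_letters_recovered(self):
        hits = 0
        n_seeds = 30
        letters = list("ABCDGHJLMNPRSV")
        for seed in range(n_seeds):
            gt = generate_ground_truth(5, 10, 150, seed=seed, one_hot_theta=True)
            scheme = PlantedAnnotationScheme(
                atc_map={t: letters[t] for t in range(5)}, atc_purity=0.9, atc_coverage=0.8
            )
            ann = generate_annotations(gt, scheme, seed=2000 + seed)
            assignment = TopicAssignment(
                default_drug_ids(150), gt.dominant_topic.astype(np.int64), 5
            )
            results = atc_enrichment(assignment, ann, range(5))
            ok = all(
                r.attribute_label == letters[r.topic] and r.p_value < 0.05 for r in results
            )
            hits += ok and len(results) == 5
        assert hits >= int(0.9 * n_seeds)


class TestReport:
    def _result(self, topic, n, k, p):
        return EnrichmentResult(
            topic=topic,
            attribute_label="BW",
            n_drugs=n,
            n_with_attribute=k,
            percent=100.0 * k / n,
            p_value=p,
            table=ContingencyTable(k, n - k, 10, 10),
        )

    def test_reference_percentages_all_highlighted(self):
        rows = [(21, 15), (20, 16), (19, 14), (14, 13), (11, 9)]
        results = [self._result(i, n, k, 0.01) for i, (n, k) in enumerate(rows)]
        report = make_report(results, highlight_purity=0.70, alpha_level=0.05)
        assert report["highlighted"].all()
        assert [round(p) for p in report["percent"]] == [71, 80, 74, 93, 82]

    def test_exactly_seventy_percent_not_highlighted(self):
        report = make_report([self._result(0, 10, 7, 0.001)])
        assert not report["highlighted"].any()

    def test_low_significance_not_highlighted(self):
        report = make_report([self._result(0, 10, 9, 0.2)])
        assert not report["highlighted"].any()

    def test_empty_results_empty_report(self):
        report = make_report([])
        assert len(report) == 0 and "highlighted" in report.columns

    def test_bh_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, size=17)
        ours = benjamini_hochberg(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs)


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        ann = DrugAnnotations(
            bw={"d1": True, "d2": False},
            atc={"d1": frozenset({"N", "J"}), "d2": frozenset()},
        )
        path = tmp_path / "ann.tsv"
        write_annotations(ann, path)
        back = read_annotations(path)
        assert back.bw == ann.bw and back.atc == ann.atc

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            DrugAnnotations(atc={"d": frozenset({"Q"})})
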