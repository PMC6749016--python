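import numpy as np
import pytest

from varconcord.callset import CallSet, Platform, SampleRecord, normalize_variant_key
from varconcord.clinical import (
    Confusion2x2,
    build_confusion,
    chi_square_2x2,
    cooccurrence_summary,
    performance_metrics,
    positivity_map,
    prevalence_by_category,
    sample_positivity,
    stratified_performance,
)
from varconcord.fixtures import TERT_C228T, table3_cohort, table4_cohort
from conftest import make_fusion_call, make_variant_call


def _meta(n_benign, n_malignant, gsc="suspicious"):
    samples = [
        SampleRecord(f"B{i}", "III", gsc, "FA") for i in range(n_benign)
    ] + [
        SampleRecord(f"M{i}", "IV", gsc, "PTC") for i in range(n_malignant)
    ]
    return samples


class TestSamplePositivity:
    def test_two_variants_count_once(self):
        calls = CallSet(
            platform=Platform.WTS_RNASEQ,
            variant_calls=[
                make_variant_call(sample="N1", gene="KRAS", change="Q61R"),
                make_variant_call(sample="N1", gene="EIF1AX", change="A113_splice"),
            ],
        )
        samples = [SampleRecord("N1", "III", "suspicious", "FV-PTC")]
        pos = positivity_map(samples, calls)
        assert pos == {"N1": True}

    def test_no_calls_is_negative(self):
        samples = [SampleRecord("N1", "III", "suspicious", "FA")]
        pos = positivity_map(samples, CallSet(platform=Platform.WTS_RNASEQ))
        assert pos == {"N1": False}

    def test_gsc_benign_suppression_rule(self):
        calls = CallSet(
            platform=Platform.WTS_RNASEQ,
            variant_calls=[make_variant_call(sample="N1", gene="TSHR", change="M453T")],
        )
        meta = {"N1": SampleRecord("N1", "III", "benign", "FA")}
        assert sample_positivity("N1", calls, "all_calls", meta)
        assert not sample_positivity("N1", calls, "suppress_gsc_benign", meta)

    def test_promoter_variant_never_positive_on_rna_platform(self):
        rna = CallSet(
            platform=Platform.WTS_RNASEQ,
            variant_calls=[make_variant_call(sample="N1", gene="TERT", change="C228T")],
        )
        dna = CallSet(
            platform=Platform.DNA_PANEL,
            variant_calls=[make_variant_call(sample="N1", gene="TERT", change="C228T",
                                             platform=Platform.DNA_PANEL)],
        )
        assert not sample_positivity("N1", rna)
        assert sample_positivity("N1", dna)

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            sample_positivity("nope", CallSet(platform=Platform.WTS_RNASEQ),
                              metadata={})


class TestBuildConfusion:
    def test_histology_totals_on_nodule_fixture(self):
        samples, calls = table3_cohort()
        confusion = build_confusion(samples, positivity_map(samples, calls))
        assert confusion.tp + confusion.fn == 45
        assert confusion.fp + confusion.tn == 145

    def test_all_negative_calls(self):
        samples = _meta(3, 2)
        pos = {s.sample_id: False for s in samples}
        c = build_confusion(samples, pos)
        assert (c.tp, c.fp) == (0, 0)
        assert (c.fn, c.tn) == (2, 3)

    def test_matches_brute_force_tally(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 25))
            samples = []
            pos = {}
            exp = dict(tp=0, fp=0, fn=0, tn=0)
            for i in range(n):
                malignant = bool(rng.random() < 0.4)
                positive = bool(rng.random() < 0.5)
                s = SampleRecord(f"X{i}", "III", "suspicious",
                                 "PTC" if malignant else "BFN")
                samples.append(s)
                pos[s.sample_id] = positive
                exp[
                    ("tp" if positive else "fn") if malignant
                    else ("fp" if positive else "tn")
                ] += 1
            c = build_confusion(samples, pos)
            assert (c.tp, c.fp, c.fn, c.tn) == (exp["tp"], exp["fp"], exp["fn"], exp["tn"])

    def test_unknown_histology_excluded(self):
        samples = _meta(2, 2) + [SampleRecord("U1", "III", "suspicious", "unknown")]
        pos = {s.sample_id: True for s in samples}
        assert build_confusion(samples, pos).total == 4


class TestPerformanceMetrics:
    def test_matches_independent_formulas(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + fp + fn + tn == 0:
                continue
            m = performance_metrics(Confusion2x2(tp, fp, fn, tn))
            if tp + fn:
                assert m.sensitivity.point == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity.point == pytest.approx(tn / (tn + fp))
            if tp + fp:
                assert m.ppv.point == pytest.approx(tp / (tp + fp))
            if tn + fn:
                assert m.npv.point == pytest.approx(tn / (tn + fn))
            assert m.prevalence.point == pytest.approx((tp + fn) / (tp + fp + fn + tn))

    def test_perfect_classifier(self):
        m = performance_metrics(Confusion2x2(tp=10, fp=0, fn=0, tn=20))
        for metric in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert metric.point == 1.0

    def test_undefined_metrics_flagged_not_raised(self):
        m = performance_metrics(Confusion2x2(tp=0, fp=0, fn=0, tn=5))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity.point == 1.0

    def test_adding_positive_call_monotone(self, rng):
        for _ in range(25):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 20, size=4))
            base = performance_metrics(Confusion2x2(tp, fp, fn, tn))
            plus_tp = performance_metrics(Confusion2x2(tp + 1, fp, fn - 1, tn))
            plus_fp = performance_metrics(Confusion2x2(tp, fp + 1, fn, tn - 1))
            assert plus_tp.sensitivity.point >= base.sensitivity.point
            assert plus_fp.specificity.point <= base.specificity.point


class TestStratification:
    def test_single_stratum_equals_unstratified(self):
        samples = _meta(5, 5)
        pos = {s.sample_id: s.histology_class == "malignant" for s in samples}
        overall = performance_metrics(build_confusion(samples, pos))
        strat = stratified_performance(samples, pos, "gsc_call")
        assert set(strat) == {"suspicious"}
        assert strat["suspicious"].confusion == overall.confusion

    def test_strata_sum_to_unstratified(self, rng):
        samples, calls = table3_cohort()
        pos = positivity_map(samples, calls)
        overall = build_confusion(samples, pos)
        strat = stratified_performance(samples, pos, "gsc_call")
        summed = np.array([0, 0, 0, 0])
        for m in strat.values():
            c = m.confusion
            summed += np.array([c.tp, c.fp, c.fn, c.tn])
        assert tuple(summed) == (overall.tp, overall.fp, overall.fn, overall.tn)

    def test_filter_then_compute_oracle(self, rng):
        samples = _meta(10, 10, gsc="suspicious") + _meta(0, 0)
        samples += [SampleRecord(f"G{i}", "III", "benign", "FA") for i in range(5)]
        pos = {s.sample_id: bool(rng.random() < 0.5) for s in samples}
        strat = stratified_performance(samples, pos, "gsc_call")
        benign_members = [s for s in samples if s.gsc_call == "benign"]
        oracle = build_confusion(benign_members, pos)
        assert strat["benign"].confusion == oracle


class TestChiSquare:
    def test_reconstructed_positivity_table(self):
        # malignant 22/45 vs benign ~24% alteration-positive
        stat, p = chi_square_2x2([[22, 23], [35, 110]], continuity_correction=True)
        assert p == pytest.approx(0.003, abs=5e-4)

    def test_identical_proportions_give_zero_statistic(self):
        stat, p = chi_square_2x2([[10, 20], [20, 40]], continuity_correction=False)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_yates_correction_never_increases_statistic(self, rng):
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2))
            s_corr, _ = chi_square_2x2(t.tolist(), continuity_correction=True)
            s_raw, _ = chi_square_2x2(t.tolist(), continuity_correction=False)
            assert s_corr <= s_raw + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestCooccurrence:
    def test_promoter_cooccurrence_fixture(self):
        samples, calls = table4_cohort()
        summary = cooccurrence_summary(calls, calls, samples, {TERT_C228T})
        assert summary["n_companion_positive"] == 15
        assert summary["n_with_partner"] == 14
        assert summary["n_without_partner"] == 1
        assert summary["family_counts"]["RAS"] + summary["family_counts"]["BRAF"] == 14

    def test_no_companion_positive_samples(self):
        samples, calls = table3_cohort()
        summary = cooccurrence_summary(calls, calls, samples, {TERT_C228T})
        assert summary["rows"] == []


class TestPrevalenceByCategory:
    def test_fusion_fraction_arithmetic(self):
        n, n_fused = 943, 52
        samples = [SampleRecord(f"P{i}", "III", "suspicious", "unknown") for i in range(n)]
        fusions = [make_fusion_call(sample=f"P{i}") for i in range(n_fused)]
        calls = CallSet(platform=Platform.WTS_RNASEQ, fusion_calls=fusions)
        rows = prevalence_by_category(calls, samples, "bethesda")
        (row,) = rows
        assert row["frac_fusion_positive"] == pytest.approx(n_fused / n)

    def test_fractions_consistent(self, rng):
        samples = _meta(20, 10)
        calls = CallSet(
            platform=Platform.WTS_RNASEQ,
            variant_calls=[
                make_variant_call(sample=s.sample_id)
                for s in samples if rng.random() < 0.4
            ],
        )
        for row in prevalence_by_category(calls, samples, "bethesda"):
            assert row["n_alteration_positive"] <= row["n"]
            assert row["frac_alteration_positive"] == pytest.approx(
                row["n_alteration_positive"] / row["n"]
            )
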