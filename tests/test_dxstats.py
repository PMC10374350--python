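"""Record filtering, diagnostic metrics, paired tests, sample size."""

import numpy as np
import pytest
from scipy import stats

from polypcadx import dxstats
from polypcadx.dxstats import (CompetenceCriterion, ConfusionTable, PolypRecord,
                               binary_confusion, compare_predictive_values,
                               competence_check, filter_lesions, fisher_exact,
                               in_segment, mcnemar, mcnemar_sample_size, metrics,
                               one_vs_rest, patients_from_polyps, subgroup,
                               subtype_accuracy, surveillance_agreement)


def rec(i, histology="adenoma", cadx="adenoma", endo="adenoma", segment="proximal",
        patient=None, cadx_tier="high", endo_conf="high"):
    return PolypRecord(
        polyp_id=f"p{i}", patient_id=patient or f"s{i}", size_mm=3,
        segment=segment, endoscopist_dx=endo, endoscopist_confidence=endo_conf,
        cadx_dx=cadx, cadx_tier=cadx_tier, histology=histology)


def records_from_table(tp, fn, fp, tn, rater="cadx"):
    """Constructed records realizing a binary neoplastic confusion table."""
    out = []
    i = 0
    for n, hist, pred in [(tp, "adenoma", "adenoma"), (fn, "adenoma", "hyperplastic"),
                          (fp, "hyperplastic", "adenoma"), (tn, "hyperplastic", "hyperplastic")]:
        for _ in range(n):
            kw = {"cadx": pred} if rater == "cadx" else {"endo": pred}
            out.append(rec(i, histology=hist, **kw))
            i += 1
    return out


class TestFiltering:
    def test_toy_exclusions_tallied(self):
        rs = [rec(0), rec(1), rec(2, histology="carcinoma"), rec(3, histology="missing")]
        kept, tally = filter_lesions(rs)
        assert len(kept) == 2
        assert tally == {"carcinoma": 1, "missing": 1}

    def test_study_shaped_fixture_counts(self):
        rs = ([rec(i, histology="adenoma") for i in range(300)]
              + [rec(300 + i, histology="ssl") for i in range(41)]
              + [rec(400 + i, histology="hyperplastic") for i in range(82)]
              + [rec(600, histology="tsa"), rec(601, histology="normal"),
                 rec(602, histology="inflammatory")])
        kept, tally = filter_lesions(rs)
        assert len(kept) == 423
        assert sum(tally.values()) == 3

    def test_empty_input(self):
        kept, tally = filter_lesions([])
        assert kept == [] and not tally

    def test_unknown_histology_rejected_with_message(self):
        with pytest.raises(ValueError, match="histology"):
            rec(0, histology="weird")


class TestBinaryConfusion:
    def test_study_counts_reproduced(self):
        t = binary_confusion(records_from_table(305, 36, 51, 31), "cadx")
        assert (t.tp, t.fn, t.fp, t.tn) == (305, 36, 51, 31)

    def test_ssl_called_adenoma_is_true_positive(self):
        t = binary_confusion([rec(0, histology="ssl", cadx="adenoma")], "cadx")
        assert t.tp == 1 and t.fn == 0

    def test_all_correct_toy(self):
        rs = [rec(0), rec(1, histology="hyperplastic", cadx="hyperplastic")]
        t = binary_confusion(rs, "cadx")
        assert t.fn == t.fp == 0 and t.tp == 1 and t.tn == 1

    def test_cadx_failures_excluded(self):
        rs = [rec(0), rec(1, cadx=None, cadx_tier=None)]
        assert binary_confusion(rs, "cadx").n == 1


class TestMetrics:
    def test_perfect_table(self):
        m = metrics(ConfusionTable(10, 0, 0, 10))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            e = getattr(m, name)
            assert e.value == 1.0 and e.ci[1] <= 1.0

    def test_zero_denominator_flagged_absent(self):
        m = metrics(ConfusionTable(5, 0, 0, 0))
        assert m.specificity is None and m.npv is None
        assert m.sensitivity is not None and m.sensitivity.value == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_metric_identities(self, seed):
        rng = np.random.default_rng(seed)
        tp, fn, fp, tn = rng.integers(1, 200, 4)
        m = metrics(ConfusionTable(int(tp), int(fn), int(fp), int(tn)))
        p, n = tp + fn, tn + fp
        # accuracy decomposes over prevalence
        assert m.accuracy.value == pytest.approx(
            (m.sensitivity.value * p + m.specificity.value * n) / (p + n))
        # Bayes identity links PPV to sens/spec/prevalence
        prev = p / (p + n)
        expected_ppv = (m.sensitivity.value * prev) / (
            m.sensitivity.value * prev + (1 - m.specificity.value) * (1 - prev))
        assert m.ppv.value == pytest.approx(expected_ppv)
        expected_npv = (m.specificity.value * (1 - prev)) / (
            m.specificity.value * (1 - prev) + (1 - m.sensitivity.value) * prev)
        assert m.npv.value == pytest.approx(expected_npv)

    def test_wald_interval_matches_published_convention(self):
        # the normal-approximation interval reproduces published sensitivity
        # intervals in this design: 305/341 -> 89.4 (86.2-92.7)
        m = metrics(ConfusionTable(305, 36, 51, 31), ci_method="wald")
        lo, hi = m.sensitivity.ci
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (86.2, 92.7)


class TestSubtypes:
    def test_diagonal_is_perfect(self):
        rs = [rec(0), rec(1, histology="ssl", cadx="ssl"),
              rec(2, histology="hyperplastic", cadx="hyperplastic")]
        assert subtype_accuracy(rs, "cadx").value == 1.0

    def test_ssl_sensitivity_from_study_counts(self):
        # 7 of 41 SSLs recognized -> sensitivity 17.1 %
        rs = ([rec(i, histology="ssl", cadx="ssl") for i in range(7)]
              + [rec(10 + i, histology="ssl", cadx="adenoma") for i in range(34)]
              + [rec(100 + i, histology="adenoma", cadx="adenoma") for i in range(50)])
        m = one_vs_rest(rs, "cadx", "ssl")
        assert m.sensitivity.value == pytest.approx(7 / 41)
        assert round(100 * m.sensitivity.value, 1) == 17.1

    def test_ssl_confusion_with_adenoma_hits_subtype_not_binary(self):
        rs = [rec(i, histology="ssl", cadx="adenoma") for i in range(10)]
        assert one_vs_rest(rs, "cadx", "ssl").sensitivity.value == 0.0
        t = binary_confusion(rs, "cadx")
        assert metrics(t).sensitivity.value == 1.0


class TestSubgroups:
    def test_composable_predicates(self):
        rs = [rec(0, segment="rectosigmoid"), rec(1), rec(2, segment="rectosigmoid",
                                                          cadx_tier="low")]
        sub = subgroup(rs, in_segment("rectosigmoid"))
        assert len(sub) == 2
        sub2 = subgroup(sub, dxstats.high_confidence("cadx"))
        assert [r.polyp_id for r in sub2] == ["p0"]

    def test_empty_subgroup_metrics_absent(self):
        t = binary_confusion([], "cadx")
        m = metrics(t)
        assert m.accuracy is None


class TestMcNemar:
    def test_continuity_corrected_statistic(self):
        r = mcnemar(5, 15)
        assert r.statistic == pytest.approx((10 - 1) ** 2 / 20)  # 4.05
        assert r.p_value == pytest.approx(stats.chi2.sf(4.05, 1))

    def test_symmetric_counts_floor_correction(self):
        r = mcnemar(8, 8)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_no_discordance_p_one(self):
        assert mcnemar(0, 0).p_value == 1.0

    def test_exact_option_matches_binomial(self):
        r = mcnemar(3, 11, method="exact")
        assert r.p_value == pytest.approx(stats.binomtest(3, 14, 0.5).pvalue)

    def test_auto_switches_at_25_discordant(self):
        assert mcnemar(2, 10, method="auto").method == "exact"
        assert mcnemar(20, 15, method="auto").method == "cc"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(-1, 2)


class TestPredictiveValueComparison:
    def paired_records(self):
        # identical raters on 40 polyps across 10 patients
        rs = []
        for i in range(40):
            hist = "adenoma" if i % 3 else "hyperplastic"
            pred = hist if i % 5 else ("hyperplastic" if hist == "adenoma" else "adenoma")
            rs.append(rec(i, histology=hist, cadx=pred, endo=pred,
                          patient=f"pat{i % 10}"))
        return rs

    def test_identical_raters_no_difference(self):
        r = compare_predictive_values(self.paired_records(), n_bootstrap=200, seed=1)
        assert r.ppv_diff == 0.0 and r.npv_diff == 0.0
        assert r.ppv_p == 1.0 and r.npv_p == 1.0

    def test_deterministic_under_seed(self):
        rs = self.paired_records()[:30]
        a = compare_predictive_values(rs, n_bootstrap=200, seed=3)
        b = compare_predictive_values(rs, n_bootstrap=200, seed=3)
        assert a == b

    def test_fisher_toy_table(self):
        assert fisher_exact([[3, 1], [1, 3]]).p_value == pytest.approx(0.4857, abs=1e-4)


class TestSurveillance:
    def patients(self, flip_one=False):
        rs = []
        for p in range(6):
            hist = "adenoma" if p % 2 else "hyperplastic"
            pred = hist
            if flip_one and p == 0:
                pred = "adenoma"   # histology hyperplastic, called adenoma
            rs.append(rec(p, histology=hist, cadx=pred, patient=f"pat{p}"))
        return rs

    def test_full_agreement(self):
        e = surveillance_agreement(self.patients())
        assert e.value == 1.0

    def test_one_flipped_patient(self):
        e = surveillance_agreement(self.patients(flip_one=True))
        assert e.value == pytest.approx(5 / 6)

    def test_single_category_rule_table_always_agrees(self):
        rules = ((lambda f: True, "only"),)
        e = surveillance_agreement(self.patients(flip_one=True), rules=rules)
        assert e.value == 1.0

    def test_uncovered_findings_error(self):
        rules = ((lambda f: f["n_neoplastic"] == 0, "routine"),)
        with pytest.raises(ValueError, match="rule"):
            surveillance_agreement(self.patients(), rules=rules)


class TestCompetence:
    def test_published_style_checks(self):
        crits = [CompetenceCriterion("npv_rectosigmoid_90", "npv", 0.90),
                 CompetenceCriterion("agreement_90", "agreement", 0.90),
                 CompetenceCriterion("trivial", "npv", 0.0)]
        out = competence_check(crits, {"npv": 0.667, "agreement": 0.955})
        assert out == {"npv_rectosigmoid_90": False, "agreement_90": True,
                       "trivial": True}

    def test_absent_metric_errors(self):
        with pytest.raises(KeyError):
            competence_check([CompetenceCriterion("x", "ppv", 0.5)], {"npv": 0.9})


class TestSampleSize:
    def test_design_values(self):
        assert mcnemar_sample_size(0.05, 0.90, 0.20, 0.10) == 206
        assert patients_from_polyps(206, 0.74, 0.05) == 292

    def test_boundary_delta_equals_psi(self):
        assert mcnemar_sample_size(0.05, 0.90, 0.20, 0.20) == 49

    def test_monotone_in_difference(self):
        assert (mcnemar_sample_size(0.05, 0.90, 0.20, 0.20)
                < mcnemar_sample_size(0.05, 0.90, 0.20, 0.10))

    def test_invalid_difference_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_sample_size(0.05, 0.90, 0.20, 0.30)

    def test_patient_conversion_edge_cases(self):
        assert patients_from_polyps(100, 1.0, 0.0) == 100
        assert patients_from_polyps(100, 1.0, 0.05) > 100


def test_clopper_pearson_coverage_at_study_scale():
    """Simulated CI coverage >= 94 % at n = 400, p = 0.8 (exact method)."""
    rng = np.random.default_rng(7)
    n, p, reps = 400, 0.8, 2000
    draws = rng.binomial(n, p, size=reps)
    ks, weights = np.unique(draws, return_counts=True)
    covered = 0
    for k, w in zip(ks, weights):
        e = dxstats.proportion_estimate(int(k), n)  # default: Clopper-Pearson
        covered += w * (e.ci[0] <= p <= e.ci[1])
    assert covered / reps >= 0.94
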