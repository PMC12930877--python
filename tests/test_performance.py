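"""Diagnostic-accuracy statistics: exact CIs, DeLong AUC, subgroup evaluation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from slecrit import (
    ConfusionMatrix,
    clopper_pearson,
    compare_groups,
    confusion,
    delong_auc_variance,
    evaluate,
    metrics,
    roc_auc,
)


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([True] * 10 + [False] * 10, [True] * 10 + [False] * 10)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (10, 0, 10, 0)

    def test_all_negative_classifier(self):
        cm = confusion([False] * 8, [True] * 4 + [False] * 4)
        assert cm.tp == 0 and cm.fp == 0 and cm.fn == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])

    def test_cohort_scale_counts(self):
        pred = [True] * 650 + [False] * 5 + [False] * 626
        ref = [True] * 655 + [False] * 626
        cm = confusion(pred, ref)
        assert (cm.tp, cm.fn) == (650, 5)
        assert cm.n_cases == 655 and cm.n_controls == 626


class TestClopperPearson:
    @pytest.mark.parametrize("x,n,expected", [
        (650, 655, (0.9823, 0.9975)),
        (623, 655, (0.9317, 0.9663)),
    ])
    def test_published_scale_intervals(self, x, n, expected):
        lo, hi = clopper_pearson(x, n, 0.95)
        assert round(lo, 4) == expected[0]
        assert round(hi, 4) == expected[1]

    def test_boundary_cases(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    @given(n=st.integers(1, 2000), frac=st.floats(0.0, 1.0),
           level=st.floats(0.5, 0.999))
    def test_interval_contains_point(self, n, frac, level):
        x = min(n, int(round(frac * n)))
        lo, hi = clopper_pearson(x, n, level)
        assert 0.0 <= lo <= x / n <= hi <= 1.0

    def test_width_shrinks_with_n_at_fixed_proportion(self):
        widths = []
        for n in (20, 80, 320, 1280):
            lo, hi = clopper_pearson(int(0.8 * n), n)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(1, 2, level=1.5)


class TestMetrics:
    def test_perfect_classifier_all_100(self):
        m = metrics(ConfusionMatrix(10, 0, 10, 0))
        for v in m.values():
            assert v.point == 100.0

    def test_sensitivity_from_miss_count(self):
        m = metrics(ConfusionMatrix(tp=650, fn=5, tn=557, fp=69))
        assert round(m["sensitivity"].point, 2) == 99.24
        assert round(m["ppv"].point, 2) == 90.40

    def test_specificity_consistent_with_fp_scan(self):
        # fp = 69 is the unique count on 626 controls printing specificity 88.98
        matches = [fp for fp in range(627)
                   if round(100 * (626 - fp) / 626, 2) == 88.98]
        assert matches == [69]

    def test_undefined_ratio_reported_as_none(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=3))
        assert m["sensitivity"] is None and m["npv"] is not None

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_points_inside_cis(self):
        m = metrics(ConfusionMatrix(tp=50, fn=7, tn=40, fp=9))
        for v in m.values():
            assert v.low <= v.point <= v.high


def _auc_bruteforce(scores, ref):
    cases = scores[ref]
    controls = scores[~ref]
    wins = ties = 0
    for c in cases:
        for d in controls:
            wins += c > d
            ties += c == d
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def _delong_var_bruteforce(scores, ref):
    cases = scores[ref]
    controls = scores[~ref]
    n1, n0 = len(cases), len(controls)
    v10 = np.array([np.mean((c > controls) + 0.5 * (c == controls)) for c in cases])
    v01 = np.array([np.mean((cases > d) + 0.5 * (cases == d)) for d in controls])
    return np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0


class TestRocAuc:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert auc == 1.0 and hi == 1.0

    def test_constant_scores_give_half(self):
        auc, _, _ = roc_auc([5.0] * 10, [True] * 5 + [False] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_matches_bruteforce_pairwise_count(self):
        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(10, 60))
            ref = np.zeros(n, dtype=bool)
            ref[: int(rng.integers(2, n - 1))] = True
            rng.shuffle(ref)
            # integer-ish scores force ties to exercise midrank handling
            scores = np.round(rng.normal(ref * 1.0, 1.0), 1)
            auc, var = delong_auc_variance(scores, ref)
            assert auc == pytest.approx(_auc_bruteforce(scores, ref), abs=1e-12)
            assert var == pytest.approx(_delong_var_bruteforce(scores, ref), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        ref = rng.random(60) < 0.5
        ref[0], ref[1] = True, False
        a1, _, _ = roc_auc(scores, ref)
        a2, _, _ = roc_auc(np.exp(3 * scores) + 7, ref)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_binary_scores_give_mean_of_se_sp(self):
        """A dichotomized rule's AUC collapses to (Se+Sp)/2 — why ROC needs the continuous score."""
        rng = np.random.default_rng(8)
        ref = rng.random(300) < 0.5
        ref[0], ref[1] = True, False
        pred = ref ^ (rng.random(300) < 0.2)
        cm = confusion(pred, ref)
        se = cm.tp / cm.n_cases
        sp = cm.tn / cm.n_controls
        auc, _, _ = roc_auc(pred.astype(float), ref)
        assert auc == pytest.approx((se + sp) / 2, abs=1e-12)


class TestEvaluate:
    def test_overall_equals_unfiltered(self, default_cohort, default_classifications):
        rep = evaluate(default_cohort, default_classifications, subgroups=["overall"])
        for r in rep:
            assert r.cm.n_cases == default_cohort.n_cases
            assert r.cm.n_controls == default_cohort.n_controls
            assert r.auc is not None and 0 <= r.auc[0] <= 1

    def test_early_subgroup_keeps_all_controls(self, default_cohort, default_classifications):
        rep = evaluate(default_cohort, default_classifications, subgroups=["early_disease"])
        for r in rep:
            assert r.cm.n_cases == 99
            assert r.cm.n_controls == 626

    def test_sex_strata_case_denominators_sum(self, default_cohort, default_classifications):
        rep = evaluate(default_cohort, default_classifications,
                       subgroups=["sex:female", "sex:male"])
        by_sys = {}
        for r in rep:
            by_sys.setdefault(r.system, 0)
            by_sys[r.system] += r.cm.n_cases
        assert all(v == default_cohort.n_cases for v in by_sys.values())

    def test_subgroup_identity_tp_fn_tn_fp(self, default_cohort, default_classifications):
        rep = evaluate(default_cohort, default_classifications,
                       subgroups=["overall", "early_disease", "duration:>5"])
        for r in rep:
            assert r.cm.n == r.cm.n_cases + r.cm.n_controls


class TestCompareGroups:
    def test_identical_groups_t_near_zero(self, default_cohort):
        import dataclasses
        recs = []
        for i, r in enumerate(default_cohort.records[:40]):
            recs.append(dataclasses.replace(r, patient_id=f"a{i}", reference_sle=True,
                                            age_at_enrollment=50.0, age_at_onset=40.0,
                                            disease_duration=float(i % 5)))
            recs.append(dataclasses.replace(r, patient_id=f"b{i}", reference_sle=False,
                                            age_at_enrollment=50.0, age_at_onset=40.0,
                                            disease_duration=float(i % 5)))
        from slecrit import Cohort
        c = Cohort(records=recs)
        out = compare_groups(c, "disease_duration")
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_chi2_perfect_split_is_n(self, tiny_cohort):
        import dataclasses
        from slecrit import Cohort, FeatureSet
        recs = []
        for i in range(50):
            recs.append(dataclasses.replace(
                tiny_cohort.records[0], patient_id=f"c{i}",
                features=FeatureSet.from_present(["fever"])))
            recs.append(dataclasses.replace(
                tiny_cohort.records[2], patient_id=f"k{i}",
                features=FeatureSet.from_present([])))
        out = compare_groups(Cohort(records=recs), "feature:fever")
        assert out["statistic"] == pytest.approx(100.0)

    def test_chi2_matches_direct_formula(self, default_cohort):
        out = compare_groups(default_cohort, "feature:proteinuria")
        a = sum(r.features.present("proteinuria") for r in default_cohort.records
                if r.reference_sle)
        b = sum(r.features.present("proteinuria") for r in default_cohort.records
                if not r.reference_sle)
        obs = np.array([[a, default_cohort.n_cases - a],
                        [b, default_cohort.n_controls - b]], dtype=float)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        assert out["statistic"] == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_zero_variance_rejected(self, default_cohort):
        import dataclasses
        from slecrit import Cohort
        recs = [dataclasses.replace(r, patient_id=f"z{i}", reference_sle=i % 2 == 0,
                                    age_at_onset=20.0, age_at_enrollment=25.0,
                                    disease_duration=5.0)
                for i, r in enumerate(default_cohort.records[:20])]
        with pytest.raises(ValueError, match="zero-variance"):
            compare_groups(Cohort(records=recs), "disease_duration")


def test_auc_ci_truncated_to_unit_interval():
    auc, lo, hi = roc_auc([0, 1, 2, 10], [False, False, True, True])
    assert 0.0 <= lo <= auc <= hi <= 1.0
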