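"""ROC/DeLong statistics against brute-force oracles, exact binomial
intervals, the LVEDP threshold sweep, matching and subgroup reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pulsewave.errors import ConfigurationError, InsufficientDataError
from pulsewave.evaluation import (clopper_pearson, delong_test,
                                  propensity_match, roc_auc,
                                  sensitivity_operating_threshold,
                                  standardized_mean_difference,
                                  subgroup_report, threshold_sweep, two_by_two)


def pair_count_auc(scores, labels):
    """Exhaustive pos/neg pair counting with ties worth 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.n_pos == 2 and res.n_neg == 2

    def test_hand_counted_example_with_tie(self):
        """pos {3, 2}, neg {1, 2}: (1+1+1+0.5)/4 = 0.875."""
        res = roc_auc([3, 2, 1, 2], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        scores = np.round(rng.normal(size=n), 1)   # induces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(pair_count_auc(scores, labels))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(2.0 * scores) + 1.0, labels).auc
        assert a == pytest.approx(b)

    def test_curve_monotone(self):
        rng = np.random.default_rng(0)
        res = roc_auc(rng.normal(size=60), rng.integers(0, 2, 60))
        curve = np.array(res.curve)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_ci_coverage_under_null(self):
        """Permuted labels: the 95% DeLong CI covers 0.5 ~95% of the time."""
        rng = np.random.default_rng(1)
        n, covered, reps = 500, 0, 1000
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        for _ in range(reps):
            res = roc_auc(rng.normal(size=n), labels)
            covered += res.ci95[0] <= 0.5 <= res.ci95[1]
        assert 0.93 <= covered / reps <= 0.97


class TestDelongTest:
    def test_identical_scores_p_one(self):
        s = np.random.default_rng(0).normal(size=50)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        assert delong_test(s, s, y) == 1.0

    def test_extreme_alternative(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        perfect = np.r_[np.ones(100), np.zeros(100)] + rng.normal(0, 0.01, 200)
        noise = rng.normal(size=200)
        assert delong_test(perfect, noise, y) < 1e-3

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            delong_test([1, 2], [1, 2, 3], [0, 1, 1])

    def test_type_one_error_rate(self):
        """Independent noise scores: rejection rate at alpha=.05 is ~5%."""
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        rejects = sum(
            delong_test(rng.normal(size=200), rng.normal(size=200), y) < 0.05
            for _ in range(1000))
        assert abs(rejects / 1000 - 0.05) <= 0.02


class TestClopperPearson:
    def test_printed_sensitivity_interval(self):
        """65/79 -> (72%, 90%) at the printed rounding."""
        lo, hi = clopper_pearson(65, 79)
        assert round(lo, 2) == 0.72 and round(hi, 2) == 0.90

    def test_boundary_cases(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_beta_quantile_oracle(self):
        lo, hi = clopper_pearson(5, 10)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 5, 6))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 6, 5))
        assert (lo, hi) == pytest.approx((0.187, 0.813), abs=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            clopper_pearson(1, 0)
        with pytest.raises(ConfigurationError):
            clopper_pearson(11, 10)

    @given(st.integers(1, 200), st.integers(0, 200))
    def test_interval_ordering(self, n, k):
        k = min(k, n)
        lo, hi = clopper_pearson(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestTwoByTwoAndOperatingPoint:
    def test_counts_and_rates(self):
        scores = [0.9, 0.8, 0.3, 0.7, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        t = two_by_two(scores, labels, threshold=0.5)
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 1, 1, 2)
        assert t.sens == pytest.approx(2 / 3)
        assert t.spec == pytest.approx(2 / 3)

    def test_operating_point_hits_target_sensitivity(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        scores = rng.normal(labels.astype(float), 1.0)
        thr = sensitivity_operating_threshold(scores, labels, 0.82)
        assert two_by_two(scores, labels, thr).sens >= 0.82


class TestThresholdSweep:
    def test_primary_cell_consistent_with_roc_auc(self):
        rng = np.random.default_rng(5)
        lv = rng.uniform(0, 38, 300)
        scores = rng.normal(size=300) + 0.05 * lv
        mat = threshold_sweep(scores, lv, [25.0], [12.0])
        sel = (lv >= 25) | (lv <= 12)
        expected = roc_auc(scores[sel], (lv[sel] >= 25).astype(int)).auc
        assert mat.loc[25.0, 12.0] == expected

    def test_monotone_scores_give_unity(self):
        lv = np.linspace(0, 38, 200)
        mat = threshold_sweep(lv.copy(), lv, [25.0, 20.0], [12.0, 15.0, 18.0])
        assert np.all(mat.to_numpy() == 1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        lv = rng.uniform(0, 38, 600)
        scores = rng.normal(size=600)
        mat = threshold_sweep(scores, lv, [25.0], list(range(12, 25, 4)))
        for nd in mat.columns:
            sel = (lv >= 25) | (lv <= nd)
            npos = int((lv[sel] >= 25).sum())
            nneg = int(sel.sum()) - npos
            se = np.sqrt((npos + nneg + 1) / (12 * npos * nneg))
            assert abs(mat.loc[25.0, nd] - 0.5) <= 3 * se

    def test_infeasible_cells_missing(self):
        lv = np.r_[np.full(30, 8.0), np.full(30, 30.0)]
        mat = threshold_sweep(np.arange(60, dtype=float), lv, [25.0], [26.0])
        assert np.isnan(mat.loc[25.0, 26.0])


def _toy_subjects(n_treat, n_ctrl, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_treat):
        rows.append({"subject_id": f"T{i}", "stratum": "elevated",
                     "age": rng.normal(62 + shift, 10),
                     "gender": "female" if rng.random() < 0.6 else "male"})
    for i in range(n_ctrl):
        rows.append({"subject_id": f"C{i}", "stratum": "non_elevated",
                     "age": rng.normal(62, 10),
                     "gender": "female" if rng.random() < 0.6 else "male"})
    return pd.DataFrame(rows).set_index("subject_id")


class TestPropensityMatch:
    def test_study_sized_groups_give_full_pairing(self):
        subj = _toy_subjects(79, 258, seed=7)
        pairs = propensity_match(subj, seed=0)
        assert len(pairs) == 79
        assert pairs["control_id"].is_unique and pairs["treated_id"].is_unique

    def test_identical_distributions_balanced(self):
        subj = _toy_subjects(79, 258, seed=8, shift=0.0)
        pairs = propensity_match(subj, seed=1)
        assert standardized_mean_difference(subj, pairs, "age") < 0.1
        assert standardized_mean_difference(subj, pairs, "gender") < 0.1

    def test_toy_set_matches_greedy_oracle(self):
        """3 treated vs 5 controls with unambiguous nearest neighbours."""
        subj = pd.DataFrame({
            "stratum": ["elevated"] * 3 + ["non_elevated"] * 5,
            "age": [40.0, 60.0, 80.0, 40.5, 59.5, 80.5, 20.0, 99.0],
            "gender": ["female"] * 8,
        }, index=[f"T{i}" for i in range(3)] + [f"C{i}" for i in range(5)])
        pairs = propensity_match(subj, covariates=("age",), seed=3)
        got = dict(zip(pairs["treated_id"], pairs["control_id"]))
        assert got == {"T0": "C0", "T1": "C1", "T2": "C2"}

    def test_empty_group_rejected(self):
        subj = _toy_subjects(0, 10, seed=9)
        with pytest.raises(InsufficientDataError):
            propensity_match(subj)


class TestSubgroupReport:
    def test_single_level_equals_overall(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        subj = pd.DataFrame({"grp": ["all"] * 80},
                            index=[f"S{i}" for i in range(80)])
        rep = subgroup_report(scores, labels, subj, "grp")
        assert rep["levels"]["all"].auc == roc_auc(scores, labels).auc

    def test_contrasting_effects(self):
        """Zero-effect group ~0.5 AUC; strong-effect group > 0.9."""
        rng = np.random.default_rng(11)
        n = 200
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        grp = np.array(["null", "strong"] * (n // 2))
        scores = rng.normal(size=n)
        scores[grp == "strong"] += 5.0 * labels[grp == "strong"]
        subj = pd.DataFrame({"grp": grp}, index=[f"S{i}" for i in range(n)])
        rep = subgroup_report(scores, labels, subj, "grp")
        assert abs(rep["levels"]["null"].auc - 0.5) < 0.15
        assert rep["levels"]["strong"].auc > 0.9
        assert rep["delong_p"] < 0.01

    def test_null_p_values_uniform(self):
        """Between two identical random halves the DeLong p is uniform."""
        rng = np.random.default_rng(12)
        n = 200
        labels = np.tile([1, 0], n // 2)
        grp = np.repeat(["a", "b"], n // 2)
        subj = pd.DataFrame({"grp": grp}, index=[f"S{i}" for i in range(n)])
        ps = []
        for _ in range(500):
            rep = subgroup_report(rng.normal(size=n), labels, subj, "grp")
            ps.append(rep["delong_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_class_level_non_evaluable(self):
        scores = [0.1, 0.9, 0.4, 0.6]
        labels = [1, 1, 0, 1]
        subj = pd.DataFrame({"grp": ["a", "a", "b", "b"]},
                            index=[f"S{i}" for i in range(4)])
        rep = subgroup_report(scores, labels, subj, "grp")
        assert rep["levels"]["a"] is None
        with pytest.raises(ConfigurationError):
            subgroup_report(scores, labels, subj, "nope")
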