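from itertools import combinations

import numpy as np
import pytest

from boxfd.cohort_stats import (SubjectRecord, agreement, compare_cohort,
                                mann_whitney_u, pearson_correlation,
                                pvr_positive, roc_analysis)
from boxfd.errors import (DegenerateInputError, InsufficientDataError,
                          InvalidParameterError)
from boxfd.fractal import FDResult


def exact_mann_whitney_p(a, b):
    """Oracle: enumerate every assignment of the pooled values to group A."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_of(subset):
        group_a = [pooled[i] for i in subset]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in subset]
        u = sum(1.0 if x > y else 0.5 if x == y else 0.0
                for x in group_a for y in group_b)
        return u

    observed = u_of(range(n_a))
    n1n2 = n_a * (len(pooled) - n_a)
    obs_dev = abs(observed - n1n2 / 2.0)
    total = more_extreme = 0
    for subset in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(set(subset)) - n1n2 / 2.0) >= obs_dev - 1e-12:
            more_extreme += 1
    return more_extreme / total


def brute_force_auc(scores, labels):
    """Oracle: concordant-pair fraction with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else 0.5 if p == n else 0.0
    return conc / total


def fdr(value):
    return FDResult(fd=value, slope=-value, intercept=0.0, r_squared=1.0, n_calibers=10)


class TestMannWhitney:
    def test_fully_separated_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_interleaved_not_significant(self):
        _, p = mann_whitney_u([1, 3], [2, 4])
        assert p > 0.3

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            mann_whitney_u([5], [])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6).tolist()
        b = rng.normal(0.8, 1, 5).tolist()
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(exact_mann_whitney_p(a, b), abs=1e-10)

    def test_exact_vs_asymptotic_consistency(self):
        # tie-free n=10+10: the exact permutation p and the corrected normal
        # approximation agree within 0.02 on the same data
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(1234)
        for _ in range(20):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0.5, 1, 10)
            _, p_exact = mann_whitney_u(a, b)  # n = 20, tie-free -> exact route
            p_approx = scipy_mwu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True).pvalue
            assert abs(p_exact - p_approx) < 0.02


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = pearson_correlation([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_three_point_half(self):
        r, _ = pearson_correlation([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            pearson_correlation([1, 2], [1, 2, 3])


class TestRoc:
    def test_worked_example(self):
        res = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 11, 12, 13], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0
        assert res.cutoff == 11  # smallest cutoff attaining max Youden J

    def test_constant_scores(self):
        res = roc_analysis([5, 5, 5, 5], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 40)
        labels = (rng.random(40) < 0.4).astype(int)
        res = roc_analysis(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_youden_maximal_over_cutoffs(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, 30)
        labels = (scores + rng.normal(0, 1, 30) > 0).astype(int)
        res = roc_analysis(scores, labels)
        best = res.sensitivity + res.specificity - 1
        for c in np.unique(scores):
            sens = np.mean(scores[labels == 1] >= c)
            spec = np.mean(scores[labels == 0] < c)
            assert sens + spec - 1 <= best + 1e-12


class TestAgreement:
    def test_identity(self):
        x = [10.0, 12.5, 9.1, 20.0, 15.5]
        res = agreement(x, x)
        assert res.cronbach_alpha == pytest.approx(1.0, abs=1e-12)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_penalized(self):
        rng = np.random.default_rng(2)
        auto = rng.normal(100, 10, 30)
        manual = auto + 8.0
        res = agreement(auto, manual)
        assert res.cronbach_alpha == pytest.approx(1.0, abs=1e-9)
        assert res.icc < 1.0  # absolute agreement penalizes the offset

    def test_independent_noise_icc_near_zero(self):
        rng = np.random.default_rng(3)
        iccs = [agreement(rng.normal(0, 1, 50), rng.normal(0, 1, 50)).icc
                for _ in range(200)]
        assert abs(np.mean(iccs)) < 0.05

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(7)
        auto = rng.normal(400, 50, 25)
        manual = auto + rng.normal(5, 12, 25)
        res = agreement(auto, manual)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(25), 2),
            "raters": np.repeat(["auto", "manual"], 25),
            "ratings": np.r_[auto, manual]})
        icc_tab = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings").set_index("Type")
        expected = icc_tab.loc["ICC(A,1)", "ICC"]
        lo, hi = icc_tab.loc["ICC(A,1)", "CI95"]  # pingouin rounds the CI to 2 dp
        assert res.icc == pytest.approx(expected, abs=1e-9)
        assert res.icc_ci_low == pytest.approx(lo, abs=0.01)
        assert res.icc_ci_high == pytest.approx(hi, abs=0.01)

    def test_matches_pingouin_alpha(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(8)
        auto = rng.normal(400, 50, 25)
        manual = auto + rng.normal(0, 20, 25)
        res = agreement(auto, manual)
        alpha = pg.cronbach_alpha(pd.DataFrame({"a": auto, "m": manual}))[0]
        assert res.cronbach_alpha == pytest.approx(alpha, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            agreement([1, 2, 3], [1, 2])


class TestPvrDichotomy:
    @pytest.mark.parametrize("grade,positive", [
        ("none", False), ("trace", False), ("mild", True),
        ("moderate", True), ("severe", True)])
    def test_grouping(self, grade, positive):
        assert pvr_positive(grade) is positive

    def test_unknown_grade(self):
        with pytest.raises(InvalidParameterError):
            pvr_positive("huge")


def make_records(n_per_group, delta, rng, cells=(("annulus", "diastole"),)):
    records = []
    for i in range(n_per_group):
        rec = SubjectRecord(subject_id=f"n{i}", pvr_grade="none")
        for cell in cells:
            rec.fd_by_plane_phase[cell] = fdr(1.03 + rng.normal(0, 0.01))
        records.append(rec)
    for i in range(n_per_group):
        rec = SubjectRecord(subject_id=f"p{i}", pvr_grade="mild")
        for cell in cells:
            shift = delta if cell == ("annulus", "diastole") else 0.0
            rec.fd_by_plane_phase[cell] = fdr(1.03 + shift + rng.normal(0, 0.01))
        records.append(rec)
    return records


class TestCompareCohort:
    ALL_CELLS = (("annulus", "diastole"), ("annulus", "systole"),
                 ("lvot", "diastole"), ("lvot", "systole"))

    def test_planted_difference_detected_only_in_target(self, rng):
        records = make_records(40, 0.03, rng, cells=self.ALL_CELLS)
        report = compare_cohort(records)
        assert report["cells"]["annulus_diastole"]["p_value"] < 0.01
        for cell in ("annulus_systole", "lvot_diastole", "lvot_systole"):
            assert report["cells"][cell]["p_value"] > 0.05
        assert report["roc"].auc > 0.8

    def test_single_subject_per_group(self, rng):
        records = make_records(1, 0.02, rng)
        with pytest.raises(InsufficientDataError):
            compare_cohort(records)

    def test_missing_measurements_excluded_listwise(self, rng):
        records = make_records(10, 0.03, rng, cells=self.ALL_CELLS)
        del records[0].fd_by_plane_phase[("annulus", "diastole")]
        report = compare_cohort(records)
        cell = report["cells"]["annulus_diastole"]
        assert cell["n_negative"] + cell["n_positive"] == 19
        assert report["cells"]["annulus_systole"]["n_negative"] == 10

    def test_subjects_without_outcome_excluded(self, rng):
        records = make_records(10, 0.03, rng)
        records.append(SubjectRecord(subject_id="x",
                                     fd_by_plane_phase={("annulus", "diastole"): fdr(1.1)}))
        report = compare_cohort(records)
        cell = report["cells"]["annulus_diastole"]
        assert cell["n_negative"] + cell["n_positive"] == 20

    def test_median_iqr_reported(self, rng):
        records = make_records(20, 0.02, rng)
        cell = compare_cohort(records)["cells"]["annulus_diastole"]
        for grp in ("negative", "positive"):
            assert cell[grp]["q1"] <= cell[grp]["median"] <= cell[grp]["q3"]

    def test_holm_adjustment_monotone(self, rng):
        records = make_records(30, 0.02, rng, cells=self.ALL_CELLS)
        report = compare_cohort(records, holm=True)
        for name, cell in report["cells"].items():
            assert cell["p_value_holm"] >= cell["p_value"] - 1e-15

    def test_null_p_uniformity(self):
        # identical groups: p-values approximately uniform over replicates
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(300):
            records = make_records(15, 0.0, rng)
            ps.append(compare_cohort(records)["cells"]["annulus_diastole"]["p_value"])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.01 <= rate <= 0.09

    def test_composite_grouping(self, rng):
        records = []
        for i in range(12):
            rec = SubjectRecord(subject_id=f"s{i}", composite_endpoint=i % 2 == 0)
            rec.fd_by_plane_phase[("annulus", "diastole")] = fdr(1.0 + rng.normal(0, 0.01))
            records.append(rec)
        report = compare_cohort(records, grouping="composite")
        cell = report["cells"]["annulus_diastole"]
        assert cell["n_negative"] == cell["n_positive"] == 6
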