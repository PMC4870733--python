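"""Between-session reliability statistics against independent oracles."""

import math

import numpy as np
import pytest

from slicekin.reliability import (
    SessionPairData,
    bland_altman,
    build_reliability_report,
    cv_between_sessions,
    icc_2_1,
    mean_cv,
    paired_t,
    ratio_loa,
)


def icc_2_1_bruteforce(mat):
    """Independent ICC(2,1) oracle from explicit sums of squares."""
    mat = np.asarray(mat, float)
    n, k = mat.shape
    grand = mat.sum() / (n * k)
    ss_rows = sum(k * (mat[i].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (mat[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_tot = sum((mat[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestCV:
    def test_worked_example(self):
        # 11.5 mm in one session, 10.8 mm in the other -> 4.44 %
        assert round(cv_between_sessions(11.5, 10.8), 2) == 4.44

    def test_identical_pair_is_zero(self):
        assert cv_between_sessions(7.3, 7.3) == 0.0

    def test_hand_computed_pair(self):
        # |5-6|/sqrt(2) / 5.5 * 100 = 12.86
        assert round(cv_between_sessions(5.0, 6.0), 2) == 12.86

    def test_zero_mean_undefined(self):
        assert math.isnan(cv_between_sessions(1.0, -1.0))

    def test_symmetry_and_scale_invariance(self):
        a = cv_between_sessions(4.0, 5.0)
        assert cv_between_sessions(5.0, 4.0) == pytest.approx(a)
        assert cv_between_sessions(40.0, 50.0) == pytest.approx(a)


class TestMeanCV:
    def test_identical_sessions_give_zero(self):
        data = SessionPairData([5, 5, 5], [5.1, 5.2, 5.3], [5.1, 5.2, 5.3])
        cv, skipped = mean_cv(data, 5)
        assert cv == 0.0 and skipped == 0

    def test_single_trial_equals_its_cv(self):
        data = SessionPairData([10], [11.5], [10.8])
        cv, _ = mean_cv(data, 10)
        assert cv == pytest.approx(cv_between_sessions(11.5, 10.8))

    def test_arithmetic_mean_of_trial_cvs(self):
        # construct pairs with CVs exactly {2, 4, 6} percent
        pairs = []
        for target in (2.0, 4.0, 6.0):
            m, d = 10.0, 10.0 * target * math.sqrt(2) / 100.0
            pairs.append((m + d / 2, m - d / 2))
        s1, s2 = zip(*pairs)
        for p in pairs:
            assert cv_between_sessions(*p) == pytest.approx(
                100 * abs(p[0] - p[1]) / math.sqrt(2) / np.mean(p))
        data = SessionPairData([1, 1, 1], list(s1), list(s2))
        cv, _ = mean_cv(data, 1)
        assert cv == pytest.approx(4.0, abs=0.01)

    def test_undefined_trials_skipped_and_counted(self):
        data = SessionPairData([0, 0], [1.0, 5.0], [-1.0, 5.5])
        cv, skipped = mean_cv(data, 0)
        assert skipped == 1
        assert cv == pytest.approx(cv_between_sessions(5.0, 5.5))


class TestICC:
    def test_perfect_agreement(self):
        mat = np.column_stack([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        res = icc_2_1(mat)
        assert res.icc == pytest.approx(1.0)

    def test_systematic_bias_lowers_icc(self):
        base = np.array([1.0, 2, 3, 4, 5])
        no_bias = icc_2_1(np.column_stack([base, base])).icc
        biased = icc_2_1(np.column_stack([base, base + 3.0])).icc
        assert biased < no_bias

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.normal(10, 3, size=(10, 2))
        assert icc_2_1(mat).icc == pytest.approx(icc_2_1_bruteforce(mat),
                                                 abs=1e-10)

    def test_matches_pingouin_value_and_ci(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        trial_effect = rng.normal(10, 3, size=(12, 1))
        mat = trial_effect + rng.normal(0, 1, size=(12, 2))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([0, 1], 12),
            "scores": mat.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]  # two-way random, single
        res = icc_2_1(mat)
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        ci = row["CI95"]  # pingouin rounds the interval to 2 d.p.
        assert res.ci_low == pytest.approx(ci[0], abs=0.006)
        assert res.ci_high == pytest.approx(ci[1], abs=0.006)

    def test_zero_variance_flagged(self):
        res = icc_2_1(np.full((5, 2), 3.0))
        assert res.undefined

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(10, 3, (15, 2)) + rng.normal(0, 1, (15, 1))
        res = icc_2_1(mat)
        assert res.ci_low <= res.icc <= res.ci_high


class TestBlandAltman:
    def test_identical_sessions_degenerate(self):
        x = [1.0, 2.0, 3.0]
        res = bland_altman(SessionPairData([0, 1, 2], x, x))
        assert res.bias == 0.0 and res.loa_low == res.loa_high == 0.0
        assert res.scedasticity == "degenerate"

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(SessionPairData([0, 1, 2], x + 1.0, x))
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(0.0)

    def test_monte_carlo_coverage_and_homoscedasticity(self):
        rng = np.random.default_rng(12)
        n = 100_000
        means = rng.uniform(5, 20, n)
        diffs = rng.normal(0.0, 0.8, n)
        data = SessionPairData(np.zeros(n), means + diffs / 2, means - diffs / 2)
        res = bland_altman(data)
        inside = ((data.differences >= res.loa_low)
                  & (data.differences <= res.loa_high)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)
        assert res.r_squared < 0.01
        assert res.scedasticity == "homo"

    def test_heteroscedastic_detected(self):
        rng = np.random.default_rng(13)
        means = rng.uniform(1, 20, 500)
        diffs = rng.normal(0, 0.05, 500) * means
        data = SessionPairData(np.zeros(500), means + diffs / 2, means - diffs / 2)
        assert bland_altman(data).scedasticity == "hetero"


class TestRatioLOA:
    def test_identical_sessions_zero(self):
        x = [1.0, 2.0, 3.0]
        assert ratio_loa(SessionPairData([0, 1, 2], x, x))["ratio_loa_percent"] == 0.0

    def test_hand_evaluated_formula(self):
        s1, s2 = np.array([10.0, 20.0, 31.0]), np.array([9.0, 19.0, 29.0])
        data = SessionPairData([0, 1, 2], s1, s2)
        out = ratio_loa(data)
        # direct evaluation of the printed formula
        sd_diffs = np.std(s1 - s2, ddof=1)
        avg_means = np.mean((s1 + s2) / 2.0)
        assert out["ratio_loa_percent"] == pytest.approx(
            (sd_diffs / avg_means * 1.96) * 100.0, abs=1e-12)
        assert out["systematic_bias"] == pytest.approx(np.mean(s1 - s2))

    def test_factors_pinned(self):
        # the 1.96 and x100 factors: SDdiffs/AVGmeans = 0.1 -> 19.6 %
        s1 = np.array([10.0, 10.0 + np.sqrt(2), 10.0 - np.sqrt(2)])
        s2 = np.array([10.0, 10.0 - np.sqrt(2), 10.0 + np.sqrt(2)])
        data = SessionPairData([0, 1, 2], s1, s2)
        sd = np.std(s1 - s2, ddof=1)
        expected = sd / 10.0 * 1.96 * 100.0
        assert ratio_loa(data)["ratio_loa_percent"] == pytest.approx(expected)

    def test_scale_invariance(self):
        s1, s2 = np.array([10.0, 20.0, 30.0]), np.array([9.0, 21.0, 29.0])
        a = ratio_loa(SessionPairData([0, 1, 2], s1, s2))
        b = ratio_loa(SessionPairData([0, 1, 2], 10 * s1, 10 * s2))
        assert b["ratio_loa_percent"] == pytest.approx(a["ratio_loa_percent"])


class TestTTest:
    def test_identical_sessions_degenerate(self):
        x = [1.0, 2.0, 3.0]
        t, p = paired_t(SessionPairData([0, 1, 2], x, x))
        assert t == 0.0 and math.isnan(p)

    def test_matches_from_scratch_formula(self):
        s1 = np.array([5.1, 9.8, 15.2, 20.3, 4.9])
        s2 = np.array([5.0, 10.1, 14.8, 19.9, 5.2])
        t, p = paired_t(SessionPairData(np.zeros(5), s1, s2))
        d = s1 - s2
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(t_ref, abs=1e-12)
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_swapping_sessions_flips_sign(self):
        s1 = np.array([5.1, 9.8, 15.2])
        s2 = np.array([5.0, 10.1, 14.8])
        t1, p1 = paired_t(SessionPairData(np.zeros(3), s1, s2))
        t2, p2 = paired_t(SessionPairData(np.zeros(3), s2, s1))
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_independent_mode(self):
        rng = np.random.default_rng(5)
        s1, s2 = rng.normal(10, 1, 20), rng.normal(10, 1, 20)
        t, p = paired_t(SessionPairData(np.zeros(20), s1, s2), mode="independent")
        from scipy import stats
        t_ref, p_ref = stats.ttest_ind(s1, s2)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)


class TestReport:
    def test_zero_noise_report(self):
        levels = np.repeat([0.0, 5.0, 10.0], 3)
        vals = levels + 0.5  # avoid zero-mean CVs at level 0
        report = build_reliability_report(SessionPairData(levels, vals, vals))
        assert report.icc.icc == pytest.approx(1.0)
        assert report.overall_mean_cv == pytest.approx(0.0)
        assert len(report.per_level) == 3

    def test_closed_form_icc_recovery(self):
        from slicekin.phantom import SessionPairSim, simulate_session_pair

        levels = np.repeat([0.0, 5.0, 10.0, 15.0, 20.0], 7)
        sigma = 0.5
        iccs = []
        for seed in range(50):
            sim = SessionPairSim(tuple(levels), rater_sigma=sigma, seed=seed)
            s1, s2 = simulate_session_pair(sim)
            iccs.append(icc_2_1(np.column_stack([s1, s2])).icc)
        s_t2 = levels.var(ddof=1)
        expected = s_t2 / (s_t2 + sigma ** 2)
        assert np.mean(iccs) == pytest.approx(expected, abs=0.01)

    def test_report_serialization(self, tmp_path):
        rng = np.random.default_rng(8)
        levels = np.repeat([5.0, 10.0], 4)
        s1 = levels + rng.normal(0, 0.3, 8)
        s2 = levels + rng.normal(0, 0.3, 8)
        data = SessionPairData(levels, s1, s2)
        report = build_reliability_report(data)
        report.to_csv(tmp_path / "per_level.csv")
        text = report.to_text()
        assert "ICC(2,1)" in text and "Ratio LOA" in text
        import pandas as pd
        df = pd.read_csv(tmp_path / "per_level.csv")
        assert len(df) == 2

    def test_session_csv_round_trip(self, tmp_path):
        data = SessionPairData([0.0, 5.0], [0.1, 5.2], [0.2, 4.9])
        path = tmp_path / "pairs.csv"
        data.to_csv(path)
        back = SessionPairData.from_csv(path)
        assert back.session1 == pytest.approx(data.session1)


def test_bland_altman_plot_writes_png(tmp_path):
    rng = np.random.default_rng(2)
    levels = np.repeat([5.0, 10.0], 5)
    data = SessionPairData(levels, levels + rng.normal(0, 0.3, 10),
                           levels + rng.normal(0, 0.3, 10))
    from slicekin.reliability import bland_altman_plot
    out = tmp_path / "ba.png"
    bland_altman_plot(data, out)
    assert out.stat().st_size > 0
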