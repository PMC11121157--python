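import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scclust.simulate import gen_subtype_survival
from scclust.survival import (
    CoxGroupFit,
    cox_fit_subtypes,
    hr_min,
    km_curve,
    logrank_test,
    plot_km,
    schoenfeld_gst,
    sep_statistic,
)


def gst_fixture():
    """60-sample 3-group fixture; reference values from survival::cox.zph
    (classic Grambsch-Therneau global statistic) frozen below."""
    rng = np.random.default_rng(42)
    n = 60
    labels = np.repeat([1, 2, 3], 20)
    rates = np.array([0.1, 0.2, 0.35])[labels - 1]
    t = np.round(rng.exponential(1 / rates), 4)
    e = (rng.uniform(size=n) > 0.2).astype(int)
    return t, e, labels


class TestKMCurve:
    def test_hand_product_limit(self):
        curve = km_curve([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        np.testing.assert_array_equal(curve.event_times, [1, 3, 4, 6])
        np.testing.assert_allclose(
            curve.survival, [5 / 6, 5 / 8, 5 / 12, 0.0], atol=1e-10
        )
        np.testing.assert_array_equal(curve.at_risk, [6, 4, 3, 1])

    def test_counting_process_identity(self, rng):
        """S(t) recomputed independently as the product of (1 - d_j/n_j)."""
        t = rng.exponential(5, 50)
        e = (rng.uniform(size=50) > 0.3).astype(int)
        curve = km_curve(t, e)
        for i, et in enumerate(curve.event_times):
            prod = 1.0
            for d, n_at, tt in zip(curve.n_events, curve.at_risk, curve.event_times):
                if tt <= et:
                    prod *= 1 - d / n_at
            assert curve.survival[i] == pytest.approx(prod, abs=1e-12)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_greenwood_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(5, 80)
        e = (rng.uniform(size=80) > 0.3).astype(int)
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(curve.survival, index=curve.event_times)
        theirs = kmf.survival_function_["KM_estimate"]
        for et in curve.event_times:
            assert ours[et] == pytest.approx(theirs.loc[et], abs=1e-10)

    def test_all_censored_flat(self):
        curve = km_curve([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0  # survival never drops below 1

    def test_single_event(self):
        curve = km_curve([5.0], [1])
        np.testing.assert_array_equal(curve.event_times, [5.0])
        np.testing.assert_array_equal(curve.survival, [0.0])

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [1, 1, 1, 1, 2, 2, 2, 2]
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_separated_groups_significant_vs_permutation(self):
        t = np.array([1.0, 2, 3, 10, 20, 30])
        e = np.ones(6, dtype=int)
        g = np.array([1, 1, 1, 2, 2, 2])
        chi2, _, p = logrank_test(t, e, g)
        assert p < 0.05
        # exact permutation oracle: all 20 balanced relabelings
        from itertools import combinations

        stats_null = []
        for idx in combinations(range(6), 3):
            gp = np.full(6, 2)
            gp[list(idx)] = 1
            stats_null.append(logrank_test(t, e, gp)[0])
        p_perm = np.mean([s >= chi2 - 1e-12 for s in stats_null])
        assert p_perm <= 0.15  # observed split is among the most extreme

    def test_relabeling_invariance(self, rng):
        t = rng.exponential(5, 30)
        e = np.ones(30, dtype=int)
        g = rng.integers(1, 4, 30)
        chi2_a, _, _ = logrank_test(t, e, g)
        remap = {1: 7, 2: 5, 3: 9}
        chi2_b, _, _ = logrank_test(t, e, np.array([remap[x] for x in g]))
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [1, 1])


class TestCoxFit:
    def test_toy_matches_partial_likelihood_grid(self):
        """6-sample two-group fit vs 1-D brute-force maximization."""
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, dtype=int)
        g = np.array([1, 2, 1, 2, 1, 2])
        x = (g == 2).astype(float)

        def pll(b):  # independent implementation (no ties in the toy)
            order = np.argsort(t)
            ll = 0.0
            for i in order:
                risk = t >= t[i]
                ll += x[i] * b - np.log(np.exp(x[risk] * b).sum())
            return ll

        grid = np.arange(-3, 3, 1e-4)
        vals = np.array([pll(b) for b in grid])
        b_star = grid[np.argmax(vals)]
        fit = cox_fit_subtypes(t, e, g)
        assert fit.beta_ref_[0] == pytest.approx(b_star, abs=1e-4)

    def test_identical_groups_zero_beta(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.ones(8, dtype=int)
        g = np.repeat([1, 2], 4)
        fit = cox_fit_subtypes(t, e, g)
        np.testing.assert_allclose(fit.beta, 0, atol=1e-8)
        np.testing.assert_allclose(fit.hr_matrix, 1, atol=1e-8)

    def test_simulated_hazard_ratio_recovered(self):
        labels = np.repeat([1, 2], 500)
        surv = gen_subtype_survival(
            labels, [0.0, np.log(2)], baseline_rate=0.1, censoring_rate=0.0, seed=1
        )
        fit = cox_fit_subtypes(
            surv["time"].to_numpy(), surv["event"].to_numpy(), labels
        )
        est_hr = np.exp(abs(fit.beta[0] - fit.beta[1]))
        assert 1.7 <= est_hr <= 2.4

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        t = np.ceil(rng.exponential(5, 80))
        e = (rng.uniform(size=80) > 0.3).astype(int)
        g = rng.integers(1, 3, 80)
        fit = cox_fit_subtypes(t, e, g, ties="efron")
        df = pd.DataFrame({"T": t, "E": e, "x": (g == 2).astype(float)})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta_ref_[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert fit.cov_beta[0, 0] == pytest.approx(
            cph.variance_matrix_.iloc[0, 0], abs=1e-6
        )

    def test_breslow_matches_r_survival(self):
        """Frozen reference from survival::coxph(ties='breslow')."""
        rng = np.random.default_rng(7)
        t = np.ceil(rng.exponential(5, 80))
        e = (rng.uniform(size=80) > 0.3).astype(int)
        g = rng.integers(1, 3, 80)
        fit = cox_fit_subtypes(t, e, g, ties="breslow")
        assert fit.beta_ref_[0] == pytest.approx(-0.3566503, abs=1e-6)
        fit_e = cox_fit_subtypes(t, e, g, ties="efron")
        assert fit_e.beta_ref_[0] == pytest.approx(-0.3825890, abs=1e-6)

    def test_size_weighted_centering(self):
        t, e, labels = gst_fixture()
        fit = cox_fit_subtypes(t, e, labels)
        assert float(fit.group_sizes @ fit.beta) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_likelihood_capped(self):
        # group 1 holds all the earliest events: beta diverges, gets capped
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.ones(6, dtype=int)
        g = np.array([1, 1, 1, 2, 2, 2])
        with pytest.warns(UserWarning, match="monotone"):
            fit = cox_fit_subtypes(t, e, g)
        assert fit.capped
        assert np.abs(fit.beta_ref_).max() <= 15 + 1e-9

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit_subtypes([1, 2, 3, 4], [0, 0, 0, 0], [1, 1, 2, 2])


def make_fit(beta_centered, sizes):
    """Minimal CoxGroupFit for exercising the separation statistics."""
    beta = np.asarray(beta_centered, dtype=float)
    sizes = np.asarray(sizes)
    return CoxGroupFit(
        group_labels=list(range(1, len(beta) + 1)),
        group_sizes=sizes,
        beta=beta,
        cov_beta=np.eye(len(beta) - 1),
        loglik=0.0,
        hr_matrix=np.exp(beta[:, None] - beta[None, :]),
        hr_min=np.nan,
        sep_printed=np.nan,
        sep_reciprocal=np.nan,
        logrank_stat=0.0,
        logrank_p=1.0,
        gst_stat=0.0,
        gst_p=1.0,
    )


class TestSeparationStatistics:
    def test_hr_min_pairwise_example(self):
        # log-hazards (0, ln2, ln8): pairwise max-ratios {2, 8, 4} -> min 2
        raw = np.array([0.0, np.log(2), np.log(8)])
        fit = make_fit(raw - raw.mean(), [10, 10, 10])
        assert hr_min(fit) == pytest.approx(2.0, abs=1e-12)

    def test_hr_min_permutation_invariant(self):
        raw = np.array([0.3, -0.5, 0.2])
        a = hr_min(make_fit(raw, [5, 5, 5]))
        b = hr_min(make_fit(raw[::-1], [5, 5, 5]))
        assert a == pytest.approx(b)

    def test_hr_min_identical_hazards(self):
        assert hr_min(make_fit([0.0, 0.0], [5, 5])) == 1.0

    def test_sep_example_both_conventions(self):
        fit = make_fit([0.5, -0.5], [10, 10])
        assert sep_statistic(fit, "printed") == pytest.approx(np.exp(-0.5))
        assert sep_statistic(fit, "reciprocal") == pytest.approx(np.exp(0.5))

    def test_sep_no_separation(self):
        fit = make_fit([0.0, 0.0, 0.0], [3, 4, 5])
        assert sep_statistic(fit, "printed") == 1.0
        assert sep_statistic(fit, "reciprocal") == 1.0

    @given(
        st.lists(st.floats(-2, 2), min_size=2, max_size=5),
    )
    def test_bounds_hold_for_any_fit(self, raw):
        raw = np.asarray(raw)
        sizes = np.full(len(raw), 7)
        beta = raw - raw.mean()
        fit = make_fit(beta, sizes)
        assert hr_min(fit) >= 1.0
        assert sep_statistic(fit, "printed") <= 1.0 + 1e-12
        assert sep_statistic(fit, "reciprocal") >= 1.0 - 1e-12
        # antisymmetry of the ratio matrix in logs
        log_hr = np.log(fit.hr_matrix)
        np.testing.assert_allclose(log_hr, -log_hr.T, atol=1e-10)
        np.testing.assert_allclose(
            fit.hr_matrix * fit.hr_matrix.T, 1.0, atol=1e-10
        )

    def test_three_group_parameter_recovery(self):
        """True log-hazards (0, log2, log4): HRmin estimates near 2."""
        labels = np.repeat([1, 2, 3], 300)
        values = []
        for seed in range(20):
            surv = gen_subtype_survival(
                labels, np.log([1, 2, 4]), 0.1, 0.0, seed=seed
            )
            fit = cox_fit_subtypes(
                surv["time"].to_numpy(), surv["event"].to_numpy(), labels
            )
            values.append(fit.hr_min)
        assert all(1.6 <= v <= 2.5 for v in values)


class TestSchoenfeldGST:
    def test_frozen_r_reference(self):
        """Classic Grambsch-Therneau global statistic vs survival::cox.zph
        residual computation (rank and identity transforms)."""
        t, e, labels = gst_fixture()
        fit = cox_fit_subtypes(t, e, labels)
        stat, df, p = schoenfeld_gst(fit, t, e, labels, "rank")
        assert df == 2
        assert stat == pytest.approx(2.198653, abs=1e-5)
        assert p == pytest.approx(0.333095, abs=1e-5)
        stat_i, _, p_i = schoenfeld_gst(fit, t, e, labels, "identity")
        assert stat_i == pytest.approx(0.400202, abs=1e-5)
        assert p_i == pytest.approx(0.818648, abs=1e-5)

    def test_df_one_for_two_groups(self):
        labels = np.repeat([1, 2], 50)
        surv = gen_subtype_survival(labels, [0.0, 0.5], 0.1, 0.0, seed=0)
        fit = cox_fit_subtypes(
            surv["time"].to_numpy(), surv["event"].to_numpy(), labels
        )
        _, df, _ = schoenfeld_gst(
            fit, surv["time"].to_numpy(), surv["event"].to_numpy(), labels
        )
        assert df == 1

    def test_too_few_events_errors(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 0, 0, 0, 0, 0])
        g = np.array([1, 1, 2, 2, 3, 3])
        fit = make_fit([0.0, 0.0, 0.0], [2, 2, 2])
        fit.beta_ref_ = np.zeros(2)
        fit.info_ = np.eye(2)
        with pytest.raises(ValueError, match="events"):
            schoenfeld_gst(fit, t, e, g)


def test_km_plot_writes_figure(tmp_path):
    labels = np.repeat([1, 2], 40)
    surv = gen_subtype_survival(labels, [0.0, 1.0], 0.1, 0.2, seed=0)
    out = tmp_path / "km.png"
    plot_km(surv["time"], surv["event"], labels, path=out)
    assert out.exists() and out.stat().st_size > 0
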