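import numpy as np
import pandas as pd
import pytest

from adta.survival import (
    SurvivalData,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
)

from oracles import cox_grid_mle, logrank_hand, product_limit


def sd(time, event, **cov):
    covariates = pd.DataFrame(cov) if cov else None
    return SurvivalData(np.asarray(time, float), np.asarray(event, int),
                        covariates)


class TestKaplanMeier:
    def test_hand_computed_toy(self):
        """times {1 event, 2 censored, 3 event}: S(1) = 2/3, S(3) = 0."""
        km = km_estimate(sd([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.survival_at(0.5) == 1.0

    def test_all_censored_is_flat_one(self):
        km = km_estimate(sd([5, 8, 12], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0

    def test_matches_product_limit_oracle(self, rng):
        """Random small cohorts with ties match the textbook product-limit
        formula at every event time."""
        for _ in range(50):
            n = int(rng.integers(3, 25))
            time = rng.integers(1, 10, size=n).astype(float)
            event = rng.integers(0, 2, size=n)
            km = km_estimate(sd(time, event))
            t_or, s_or = product_limit(time, event)
            assert np.array_equal(km.event_times, t_or)
            np.testing.assert_allclose(km.survival, s_or, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(10, size=40).round(3)
        km = km_estimate(sd(time, np.ones(40)))
        for t in [1, 5, 10, 20]:
            assert km.survival_at(t) == pytest.approx((time > t).mean())

    def test_at_risk_counts(self):
        km = km_estimate(sd([10, 50, 120, 130], [1, 0, 1, 0]),
                         report_times=[0, 100])
        assert list(km.at_risk) == [4, 2]


class TestLogRank:
    def test_exchangeable_groups_statistic_zero(self):
        a = sd([1, 2, 3, 4], [1, 0, 1, 0])
        res = logrank_test(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_summed_hypergeometric(self):
        """Group A events at {1, 2}, group B censored at {3, 3}: statistic
        equals the per-event-time (O-E)^2/V hand computation."""
        a_t, a_e = [1, 2], [1, 1]
        b_t, b_e = [3, 3], [0, 0]
        res = logrank_test(sd(a_t, a_e), sd(b_t, b_e))
        expect = logrank_hand(a_t, a_e, b_t, b_e)
        assert res.statistic == pytest.approx(expect, abs=1e-10)

    def test_matches_oracle_on_random_cohorts(self, rng):
        for _ in range(30):
            na, nb = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            ta = rng.integers(1, 15, na).astype(float)
            tb = rng.integers(1, 15, nb).astype(float)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(sd(ta, ea), sd(tb, eb))
            assert res.statistic == pytest.approx(
                logrank_hand(ta, ea, tb, eb), abs=1e-10
            )

    def test_symmetry_and_time_rescaling(self, rng):
        ta, ea = rng.exponential(10, 15), rng.integers(0, 2, 15)
        tb, eb = rng.exponential(14, 12), rng.integers(0, 2, 12)
        r1 = logrank_test(sd(ta, ea), sd(tb, eb))
        r2 = logrank_test(sd(tb, eb), sd(ta, ea))
        r3 = logrank_test(sd(ta * 7.3, ea), sd(tb * 7.3, eb))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.statistic == pytest.approx(r3.statistic, abs=1e-10)

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test(sd([1, 2], [0, 0]), sd([3], [0]))


class TestCox:
    def test_identical_groups_null_effect(self):
        t = [1, 2, 3, 4, 5, 6, 7, 8]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        data = sd(t + t, e + e, z=[0] * 8 + [1] * 8)
        fit = cox_fit(data, ["z"])
        assert fit.hazard_ratio[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.ci_low[0] < 1 < fit.ci_high[0]

    def test_beta_matches_grid_search_oracle(self):
        """n=8 tie-free toy: lifelines beta equals golden-section
        maximization of the explicitly written partial likelihood."""
        time = [2, 3, 5, 7, 11, 13, 17, 19]
        event = [1, 1, 1, 0, 1, 1, 0, 1]
        z = [1, 1, 0, 1, 0, 1, 0, 0]
        fit = cox_fit(sd(time, event, z=z), ["z"])
        beta_star = cox_grid_mle(time, event, z)
        assert fit.coef[0] == pytest.approx(beta_star, abs=1e-4)

    def test_score_test_equals_logrank_on_tie_free_data(self, rng):
        """Classical equivalence: the partial-likelihood score test of the
        group indicator reproduces the log-rank chi-square."""
        for _ in range(20):
            n = int(rng.integers(8, 30))
            time = rng.exponential(10, n)  # continuous -> tie-free a.s.
            event = rng.integers(0, 2, n)
            z = rng.integers(0, 2, n)
            if event.sum() == 0 or z.min() == z.max():
                continue
            sc = cox_score_test(time, event, z)
            lr = logrank_test(
                sd(time[z == 0], event[z == 0]), sd(time[z == 1], event[z == 1])
            )
            assert sc.statistic == pytest.approx(lr.statistic, abs=1e-6)

    def test_direction_against_median_event_times(self, rng):
        """No censoring, no ties: HR > 1 for the group with shorter median
        event time."""
        fast = rng.exponential(2, 30)
        slow = rng.exponential(20, 30) + 1e-3
        time = np.concatenate([fast, slow])
        z = np.r_[np.ones(30), np.zeros(30)]
        fit = cox_fit(sd(time, np.ones(60), z=z), ["z"])
        assert np.median(fast) < np.median(slow)
        assert fit.hazard_ratio[0] > 1

    def test_breslow_close_to_efron_without_ties(self):
        time = [2, 3, 5, 7, 11, 13, 17, 19]
        event = [1, 1, 1, 0, 1, 1, 0, 1]
        z = [1, 1, 0, 1, 0, 1, 0, 0]
        efron = cox_fit(sd(time, event, z=z), ["z"], ties="efron")
        breslow = cox_fit(sd(time, event, z=z), ["z"], ties="breslow")
        assert efron.coef[0] == pytest.approx(breslow.coef[0], abs=1e-4)
        assert efron.se[0] == pytest.approx(breslow.se[0], rel=1e-3)

    def test_complete_case_analysis(self):
        data = sd([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 0],
                  z=[0, 1, 0, 1, 0, 1],
                  depth=[1.0, np.nan, 2.0, 3.0, 1.5, np.nan])
        fit = cox_fit(data, ["z", "depth"])
        assert fit.n_used == 4

    def test_collinear_covariates_rejected(self):
        data = sd([1, 2, 3, 4], [1, 1, 0, 1], a=[1, 2, 3, 4], b=[2, 4, 6, 8])
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(data, ["a", "b"])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit(sd([1, 2], [0, 0], z=[0, 1]), ["z"])


def test_loglog_plot_hook(rng):
    import matplotlib

    matplotlib.use("Agg")
    from adta.survival import loglog_plot

    curves = {
        g: km_estimate(sd(rng.exponential(s, 20), np.ones(20)))
        for g, s in (("a", 5.0), ("b", 15.0))
    }
    ax = loglog_plot(curves)
    assert len(ax.lines) == 2
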