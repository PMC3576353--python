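import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from delaycorrect import (
    ConfigurationError,
    DataError,
    InfiniteWeightError,
    RetroHazardEstimator,
    TruncatedDelaySample,
    UndefinedVarianceError,
    delay_quantiles,
    fit_retro_hazard,
    fit_stratified,
    greenwood_variance,
    truncated_loglik,
    weight_variance,
)
from delaycorrect.synthetic import SimulationConfig, sample_delays, true_conditional_cdf


def _empirical_cdf(delays, grid):
    delays = np.asarray(delays)
    return np.array([(delays <= x).mean() for x in grid])


class TestFit:
    def test_worked_example_hazard_and_cdf(self, three_point_fit):
        np.testing.assert_allclose(three_point_fit.hazard_, [1.0, 0.5, 0.5])
        np.testing.assert_allclose(three_point_fit.cdf_, [0.0, 0.25, 0.5, 1.0])
        np.testing.assert_array_equal(three_point_fit.event_counts_, [1, 1, 1])
        np.testing.assert_array_equal(three_point_fit.risk_counts_, [1, 2, 2])
        assert three_point_fit.identifiable_floor_ == 1

    def test_single_unit_is_point_mass(self):
        est = fit_retro_hazard(TruncatedDelaySample(t=[5], tau=[9]))
        assert est.hazard_[4] == 1.0  # u = 5
        assert np.all(est.hazard_[np.arange(9) != 4] == 0.0)
        np.testing.assert_allclose(est.cdf_[5:], 1.0)
        np.testing.assert_allclose(est.cdf_[:5], 0.0)

    def test_cdf_is_monotone_unit_range_right_boundary(self, rng):
        for _ in range(25):
            n = rng.integers(1, 60)
            tau = rng.integers(1, 50, n)
            t = rng.integers(0, tau + 1)
            est = fit_retro_hazard(TruncatedDelaySample(t, tau))
            assert est.cdf_[-1] == 1.0
            assert np.all(np.diff(est.cdf_) >= -1e-15)
            assert np.all((est.cdf_ >= 0) & (est.cdf_ <= 1))
            assert np.all(est.event_counts_ <= est.risk_counts_)

    @given(
        delays=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=40),
        slack=st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_equal_horizons_reduce_to_empirical_cdf(self, delays, slack):
        """With a common truncation horizon the product telescopes to the ecdf."""
        tau = max(delays) + slack
        if tau == 0:
            tau = 1
        sample = TruncatedDelaySample(delays, np.full(len(delays), tau))
        est = fit_retro_hazard(sample)
        np.testing.assert_allclose(
            est.cdf_, _empirical_cdf(delays, np.arange(tau + 1)), atol=1e-12
        )

    def test_multiplicities_equal_expansion(self, rng):
        t = np.array([0, 3, 3, 7])
        tau = np.array([5, 5, 8, 9])
        n = np.array([2, 1, 3, 1])
        grouped = fit_retro_hazard(TruncatedDelaySample(t, tau, n))
        expanded = fit_retro_hazard(
            TruncatedDelaySample(np.repeat(t, n), np.repeat(tau, n))
        )
        np.testing.assert_allclose(grouped.cdf_, expanded.cdf_)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError, match="empty"):
            fit_retro_hazard(TruncatedDelaySample(t=[], tau=[]))

    def test_bin_width_aggregates_grid(self):
        sample = TruncatedDelaySample(t=[3, 10, 17], tau=[20, 20, 20])
        coarse = fit_retro_hazard(sample, bin_width=7)
        assert coarse.tau_star_ == 2
        # equal horizons: still the ecdf, now on the weekly grid
        np.testing.assert_allclose(coarse.cdf_, [1 / 3, 2 / 3, 1.0])

    def test_sklearn_interface_round_trip(self, three_point_sample):
        est = RetroHazardEstimator(bin_width=1, theta=0.0)
        assert clone(est).get_params() == est.get_params()
        est.set_params(theta=0.1).fit(three_point_sample)
        assert est.theta == 0.1
        X = np.column_stack([three_point_sample.t, three_point_sample.tau])
        alt = RetroHazardEstimator().fit(X)
        np.testing.assert_allclose(alt.cdf_, [0.0, 0.25, 0.5, 1.0])

    def test_consistency_toward_true_conditional_cdf(self):
        """Sup error vs F(t)/F(tau*) decreases along n = 100, 1000, 10000."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(11)
        errors = []
        for n in (100, 1000, 10000):
            tau = rng.integers(60, 1100, size=4 * n)
            t = sample_delays(cfg.delay_family, cfg.delay_params, 4 * n, rng)
            keep = t <= tau
            t, tau = t[keep][:n], tau[keep][:n]
            est = fit_retro_hazard(TruncatedDelaySample(t, tau))
            oracle = true_conditional_cdf(cfg, est.tau_star_)
            grid = np.arange(est.tau_star_ + 1)
            errors.append(np.max(np.abs(est.cdf_[grid] - oracle(grid))))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.05

    def test_kaplan_meier_reverse_time_cross_check(self, rng):
        """The estimator equals lifelines' Kaplan-Meier run in reverse time.

        Right-truncated delays become left-truncated survival data after the
        time reversal s = tau* - u; the product-limit cdf must match the KM
        survival curve with delayed entry.
        """
        lifelines = pytest.importorskip("lifelines")
        tau = rng.integers(5, 60, size=80)
        t = rng.integers(0, tau + 1)
        est = fit_retro_hazard(TruncatedDelaySample(t, tau))
        ts = est.tau_star_
        km = lifelines.KaplanMeierFitter()
        km.fit(durations=ts - t, entry=ts - tau - 0.5, event_observed=np.ones_like(t))
        for tt in range(0, ts):
            np.testing.assert_allclose(
                est.cdf_[tt], km.predict(ts - tt - 1), atol=1e-10
            )


class TestVariances:
    def test_worked_example_exact_fractions(self, three_point_fit):
        assert greenwood_variance(three_point_fit, 2) == pytest.approx(1 / 8)
        assert weight_variance(three_point_fit, 2) == pytest.approx(2.0)

    def test_zero_at_tau_star_and_hazard_free_tail(self, three_point_fit):
        assert greenwood_variance(three_point_fit, 3) == 0.0
        assert weight_variance(three_point_fit, 3) == 0.0
        est = fit_retro_hazard(TruncatedDelaySample(t=[2], tau=[9]))
        assert greenwood_variance(est, 5) == 0.0  # no events in (5, 9]

    def test_exhausted_risk_set_raises_naming_u(self, three_point_fit):
        # u = 1 has R = D = 1: variance at t = 0 is undefined
        with pytest.raises(UndefinedVarianceError, match=r"u=\[1\]"):
            greenwood_variance(three_point_fit, 0)

    def test_weight_variance_infinite_below_floor(self, three_point_fit):
        with pytest.raises(InfiniteWeightError):
            weight_variance(three_point_fit, 0)

    def test_delta_method_identity(self, rng):
        """var(1/F) == var(F) / F^4 wherever both are defined."""
        tau = rng.integers(4, 40, size=60)
        t = rng.integers(0, tau + 1)
        est = fit_retro_hazard(TruncatedDelaySample(t, tau))
        for tt in range(est.identifiable_floor_, est.tau_star_ + 1):
            try:
                g = greenwood_variance(est, tt)
            except UndefinedVarianceError:
                continue
            assert weight_variance(est, tt) == pytest.approx(g / est.cdf_[tt] ** 4)

    def test_outside_grid_rejected(self, three_point_fit):
        with pytest.raises(ConfigurationError):
            greenwood_variance(three_point_fit, 99)


class TestLoglik:
    def test_worked_example_termwise_sum(self, three_point_fit):
        val = truncated_loglik(three_point_fit, three_point_fit.hazard_)
        assert val == pytest.approx(4 * np.log(0.5))

    def test_zero_hazard_with_events_is_minus_inf(self, three_point_fit):
        assert truncated_loglik(three_point_fit, np.zeros(3)) == -np.inf

    def test_mle_maximizes_per_coordinate(self, rng):
        """rho_hat = D/R beats every grid perturbation of any one coordinate."""
        grid = np.linspace(0.0, 1.0, 101)
        for _ in range(20):
            n = rng.integers(1, 6)
            tau = rng.integers(1, 5, n)
            t = rng.integers(0, tau + 1)
            est = fit_retro_hazard(TruncatedDelaySample(t, tau))
            best = truncated_loglik(est, est.hazard_)
            for j in range(est.tau_star_):
                for g in grid:
                    rho = est.hazard_.copy()
                    rho[j] = g
                    assert truncated_loglik(est, rho) <= best + 1e-12

    def test_wrong_grid_length_rejected(self, three_point_fit):
        with pytest.raises(ConfigurationError):
            truncated_loglik(three_point_fit, [0.5])


class TestQuantiles:
    def test_point_mass_zero_width(self):
        est = fit_retro_hazard(TruncatedDelaySample(t=[7, 7, 7], tau=[9, 9, 9]))
        q = delay_quantiles(est, probs=(0.25, 0.5, 0.75), n_boot=50, seed=1)
        assert (q["point"] == 7).all()
        assert (q["ci_low"] == 7).all() and (q["ci_high"] == 7).all()

    def test_equal_horizons_match_empirical_quantiles(self, rng):
        delays = rng.integers(0, 50, 200)
        tau = np.full(200, 60)
        est = fit_retro_hazard(TruncatedDelaySample(delays, tau))
        q = delay_quantiles(est, probs=(0.25, 0.5, 0.75), n_boot=10, seed=0)
        ecdf = _empirical_cdf(delays, np.arange(61))
        expected = [int(np.argmax(ecdf >= p)) for p in (0.25, 0.5, 0.75)]
        assert list(q["point"]) == expected

    def test_probs_below_identifiable_floor_flagged(self):
        # floor at t=5 with F(5) = 0.5: prob 0.25 is not identifiable
        est = fit_retro_hazard(TruncatedDelaySample(t=[5, 6], tau=[6, 6]))
        q = delay_quantiles(est, probs=(0.25, 0.75), n_boot=10, seed=0)
        assert list(q["identifiable"]) == [False, True]

    def test_invalid_probs_rejected(self, three_point_fit):
        with pytest.raises(ConfigurationError):
            delay_quantiles(three_point_fit, probs=(0.0,))

    def test_bootstrap_is_seeded(self, rng):
        delays = rng.integers(0, 40, 100)
        est = fit_retro_hazard(TruncatedDelaySample(delays, np.full(100, 45)))
        q1 = delay_quantiles(est, n_boot=50, seed=42)
        q2 = delay_quantiles(est, n_boot=50, seed=42)
        assert q1.equals(q2)


class TestStratified:
    def test_identical_strata_identical_estimates(self):
        t, tau = [1, 2, 3, 1, 2, 3], [3, 3, 3, 3, 3, 3]
        labels = ["a"] * 3 + ["b"] * 3
        sample = TruncatedDelaySample(t, tau, stratum=np.array(labels, dtype=object))
        with pytest.warns(UserWarning):  # small strata
            fits = fit_stratified(sample)
        np.testing.assert_allclose(fits["a"].cdf_, fits["b"].cdf_)

    def test_single_stratum_equals_pooled(self, three_point_sample):
        sample = TruncatedDelaySample(
            three_point_sample.t, three_point_sample.tau,
            stratum=np.array(["x"] * 3, dtype=object),
        )
        with pytest.warns(UserWarning):
            fits = fit_stratified(sample)
        pooled = fit_retro_hazard(three_point_sample)
        np.testing.assert_allclose(fits["x"].cdf_, pooled.cdf_)

    def test_common_law_strata_converge_together(self):
        """KS distance between stratum cdfs shrinks as n grows (shared law)."""
        cfg = SimulationConfig()
        distances = []
        for n in (200, 5000):
            rng = np.random.default_rng(7)
            tau = rng.integers(100, 1000, 4 * n)
            t = sample_delays(cfg.delay_family, cfg.delay_params, 4 * n, rng)
            keep = t <= tau
            t, tau = t[keep][:n], tau[keep][:n]
            labels = np.where(rng.random(len(t)) < 0.5, "M", "F").astype(object)
            fits = fit_stratified(TruncatedDelaySample(t, tau, stratum=labels))
            upto = min(f.tau_star_ for f in fits.values())
            grid = np.arange(upto + 1)
            distances.append(
                np.max(np.abs(fits["M"].cdf_at(grid) - fits["F"].cdf_at(grid)))
            )
        assert distances[1] < distances[0]

    def test_unlabelled_units_rejected(self, three_point_sample):
        with pytest.raises(ConfigurationError):
            fit_stratified(three_point_sample)
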