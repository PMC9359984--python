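"""Titration fitting: forward model identities, recovery, edge cases."""

import math

import numpy as np
import pytest

from anionbind.exceptions import ConfigurationError, DomainError
from anionbind.speciation import BindingSystem
from anionbind.synthetic import SimulationTruth, simulate_titration
from anionbind.titration import (FitResult, ObservableParams, TitrationModel,
                                 TitrationSeries, aggregate_replicates,
                                 fit_baso4_competition, fit_competition_ka,
                                 fit_titration, ka_from_slow_exchange,
                                 predict_observable)


def make_series(ka, host=5e-8, gmax=5e-4, n=15, noise=0.0, seed=0,
                kind="fluorescence"):
    truth = SimulationTruth(ka=ka, host_total=host,
                            guest_grid=tuple(np.linspace(0, gmax, n)),
                            noise=noise, seed=seed)
    series, _ = simulate_titration(truth, kind)
    return series


class TestPredictObservable:
    def system(self, ka=1e4, host=1e-6):
        return BindingSystem(host, (("G", 0.0),), {"HG": ka})

    def test_baseline_at_zero_guest(self):
        p = ObservableParams(2.0, {"HG": 5.0})
        out = predict_observable(self.system(), p, [0.0])
        assert out[0] == 2.0

    def test_saturation_limit(self):
        p = ObservableParams(2.0, {"HG": 5.0})
        out = predict_observable(self.system(ka=1e12, host=1e-9), p, [1e-2])
        assert out[0] == pytest.approx(5.0, rel=1e-8)

    def test_half_saturation_at_reciprocal_ka(self):
        # host << 1/Ka so free guest ~ total: theta(1/Ka) = 1/2
        ka = 1e3
        p = ObservableParams(1.0, {"HG": 3.0})
        out = predict_observable(self.system(ka=ka, host=1e-9), p, [1.0 / ka])
        assert out[0] == pytest.approx(1.0 + 0.5 * 2.0, rel=1e-5)

    def test_params_model_mismatch(self):
        p = ObservableParams(1.0, {"HG": 3.0, "HG2": 4.0})
        with pytest.raises(ConfigurationError, match="inconsistent"):
            predict_observable(self.system(), p, [0.0])

    def test_monotone_in_guest_total(self):
        p = ObservableParams(1.0, {"HG": 3.0})
        grid = np.linspace(0, 1e-3, 40)
        out = predict_observable(self.system(), p, grid)
        assert np.all(np.diff(out) >= -1e-14)


class TestSlowExchange:
    def test_hand_arithmetic(self):
        ka = ka_from_slow_exchange(1.0, 1.0, 3e-4, 3e-4)
        assert ka == pytest.approx(1.5e-4 / (1.5e-4 * 1.5e-4), rel=1e-12)
        assert ka == pytest.approx(6.67e3, rel=1e-3)

    def test_vanishing_bound_integral(self):
        assert ka_from_slow_exchange(1.0, 0.0, 3e-4, 3e-4) == 0.0

    def test_round_trip_through_generator(self):
        truth = SimulationTruth(ka=7.4e3, host_total=3e-4,
                                guest_grid=(1e-4, 2e-4, 5e-4), noise=0.0)
        points, _ = simulate_titration(truth, "nmr_integrals")
        for g, i_f, i_b in points:
            assert ka_from_slow_exchange(i_f, i_b, 3e-4, g) == \
                pytest.approx(7.4e3, rel=1e-9)

    def test_overconsumed_guest_rejected(self):
        with pytest.raises(DomainError, match="over-consumed"):
            ka_from_slow_exchange(0.01, 1.0, 3e-4, 1e-4)


class TestFitTitration:
    @pytest.mark.parametrize("ka", [10.0, 1e3, 5.4e4, 1e6])
    def test_noiseless_recovery(self, ka):
        gmax = 50.0 / ka  # span ~98% saturation
        series = make_series(ka, gmax=gmax)
        res = fit_titration(series)
        assert res.ka == pytest.approx(ka, rel=1e-3)

    def test_nmr_shift_noiseless_recovery(self):
        series = make_series(2000.0, host=3e-4, gmax=0.02, kind="nmr_shift")
        assert fit_titration(series).ka == pytest.approx(2000.0, rel=1e-3)

    def test_noisy_median_log_error(self):
        """1% noise, n=15, 50 seeds: median |log10(Ka_hat/Ka)| <= 0.05."""
        errs = []
        for seed in range(50):
            series = make_series(5.4e4, noise=0.01, seed=seed)
            errs.append(abs(math.log10(fit_titration(series).ka / 5.4e4)))
        assert np.median(errs) <= 0.05

    def test_flat_data_flagged_unidentifiable(self):
        grid = tuple(np.linspace(0, 5e-4, 10))
        series = TitrationSeries(grid, tuple(np.full(10, 2.0)),
                                 "fluorescence_intensity", 5e-8)
        res = fit_titration(series)
        assert "ka_unidentifiable" in res.flags or "covariance_unavailable" in res.flags

    def test_affine_rescaling_invariance(self):
        series = make_series(1e4, gmax=5e-3, noise=0.01, seed=1)
        res_a = fit_titration(series)
        rescaled = TitrationSeries(
            series.guest_totals,
            tuple(7.5 * np.asarray(series.observables) - 3.0),
            series.observable_kind, series.host_total)
        res_b = fit_titration(rescaled)
        assert res_b.ka == pytest.approx(res_a.ka, rel=1e-9)

    def test_recovery_within_3se_95pct(self):
        """Generate-then-fit covers truth within 3 SE in >= 95% of 100 runs."""
        hits = 0
        for seed in range(100):
            series = make_series(5.4e4, noise=0.01, seed=1000 + seed)
            res = fit_titration(series)
            if abs(res.ka - 5.4e4) <= 3 * res.se_ka:
                hits += 1
        assert hits >= 95

    def test_too_few_points_rejected(self):
        truth = SimulationTruth(ka=1e3, guest_grid=tuple(np.linspace(0, 1e-3, 4)))
        series, _ = simulate_titration(truth, "fluorescence")
        with pytest.raises(ConfigurationError, match="points"):
            fit_titration(series)


class TestFitCompetition:
    def make_comp(self, ka_s=370.0, ka_x=45.0, x_tot=0.2, noise=0.0, seed=0,
                  psi0=0.0):
        truth = SimulationTruth(ka=ka_s, host_total=5e-8,
                                guest_grid=tuple(np.linspace(0, 0.5, 15)),
                                competitor="ClO4", competitor_total=x_tot,
                                competitor_ka=ka_x, surface_potential=psi0,
                                noise=noise, seed=seed)
        series, _ = simulate_titration(truth, "competition")
        return series

    def test_generator_round_trip_within_3se(self):
        series = self.make_comp(noise=0.01, seed=5)
        res = fit_competition_ka(series, ka_s=370.0)
        assert abs(res.ka_x - 45.0) <= 3 * res.standard_errors["ka_x"]

    def test_zero_competitor_flagged(self):
        series = self.make_comp(ka_x=0.0, x_tot=0.0)
        with pytest.warns(UserWarning, match="not in large excess"):
            res = fit_competition_ka(series, ka_s=370.0)
        assert res.ka_x == 0.0
        assert "no_detectable_competition" in res.flags

    def test_competitor_concentration_invariance(self):
        """Doubling the competitor changes Ka_x only through noise."""
        a = fit_competition_ka(self.make_comp(x_tot=0.1), ka_s=370.0).ka_x
        b = fit_competition_ka(self.make_comp(x_tot=0.2), ka_s=370.0).ka_x
        assert a == pytest.approx(b, rel=1e-4)

    def test_series_without_competitor_rejected(self):
        series = make_series(370.0, gmax=0.05)
        with pytest.raises(ConfigurationError, match="fixed_competitor"):
            fit_competition_ka(series, ka_s=370.0)


class TestBaSO4Competition:
    def make_points(self, ka=7.4e9, noise=0.0, seed=0):
        truth = SimulationTruth(ka=ka, host_total=3e-4, sulfate_total=5e-4,
                                ksp=1.08e-10,
                                counterion_grid=tuple(np.logspace(-2, 1, 12)),
                                noise=noise, seed=seed)
        points, _ = simulate_titration(truth, "baso4")
        return points

    def test_noiseless_recovery(self):
        res = fit_baso4_competition(self.make_points(), 3e-4, 5e-4, 1.08e-10)
        assert res.ka == pytest.approx(7.4e9, rel=0.01)

    def test_saturated_data_lower_bound_flag(self):
        points = [(c, 1.0) for c in (1e-4, 2e-4, 5e-4, 1e-3, 2e-3)]
        res = fit_baso4_competition(points, 3e-4, 5e-4, 1.08e-10)
        assert "ka_lower_bound_only" in res.flags

    def test_half_saturation_implies_reciprocal_free_sulfate(self):
        from anionbind.speciation import free_sulfate_with_precipitation
        ka = 7.4e9
        points = self.make_points(ka)
        thetas = np.array([t for _, t in points])
        idx = int(np.argmin(np.abs(thetas - 0.5)))
        ba, theta = points[idx]
        bound = theta * 3e-4
        s_free = free_sulfate_with_precipitation(5e-4 - bound, ba,
                                                 1.08e-10).free_guests["SO4"]
        assert ka == pytest.approx((theta / (1 - theta)) / s_free, rel=1e-6)

    def test_undersaturated_grid_rejected(self):
        points = [(1e-8, 0.9), (2e-8, 0.92), (3e-8, 0.93)]
        with pytest.raises(DomainError, match="never engaged"):
            fit_baso4_competition(points, 3e-4, 5e-4, 1.08e-10)


class TestAggregateReplicates:
    def fr(self, ka):
        return FitResult(model="titration/1:1/fluorescence_intensity",
                         params={"ka": ka}, standard_errors={"ka": 1.0})

    def test_identical_replicates(self):
        agg = aggregate_replicates([self.fr(20.0), self.fr(20.0)])
        assert agg.params["ka"] == 20.0
        assert agg.standard_errors["ka"] == 0.0

    def test_hand_arithmetic(self):
        agg = aggregate_replicates([self.fr(19.0), self.fr(21.0)])
        assert agg.params["ka"] == pytest.approx(20.0)
        assert agg.standard_errors["ka"] == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_mixed_models_rejected(self):
        other = FitResult(model="baso4_competition", params={"ka": 1.0},
                          standard_errors={"ka": 0.1})
        with pytest.raises(ConfigurationError, match="different models"):
            aggregate_replicates([self.fr(1.0), other])

    def test_single_replicate_passthrough(self):
        agg = aggregate_replicates([self.fr(5.0)])
        assert agg.params["ka"] == 5.0
        assert "sd_unavailable" in agg.flags


def test_summary_mentions_flags_and_assumptions():
    res = FitResult(model="m", params={"ka": 2.0}, standard_errors={"ka": 0.5},
                    flags=["ka_unidentifiable"], assumptions={"ksp_M2": 1.08e-10})
    text = res.summary()
    assert "ka_unidentifiable" in text and "ksp_M2" in text
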