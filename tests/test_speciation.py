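"""Speciation solvers against brute-force root-scan oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from anionbind.exceptions import DomainError
from anionbind.speciation import (SpeciationState, apparent_ka_under_competition,
                                  free_sulfate_with_precipitation,
                                  invert_competition, mass_balance_error,
                                  solve_1to1, solve_1to2, solve_competition)


def bisect_1to1_free_guest(h, g, ka):
    """Oracle: bisection on the mass-balance residual in free guest."""
    def residual(gf):
        hf = h / (1.0 + ka * gf)
        return gf + ka * hf * gf - g
    lo, hi = 0.0, g
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSolve1to1:
    def test_zero_affinity(self):
        st_ = solve_1to1(1e-4, 1e-4, 0.0)
        assert st_.complexes["HG"] == 0.0
        assert st_.free_host == 1e-4

    def test_matches_bisection_oracle(self):
        st_ = solve_1to1(1e-4, 1e-4, 1e4)
        gf = bisect_1to1_free_guest(1e-4, 1e-4, 1e4)
        assert st_.complexes["HG"] == pytest.approx(1e-4 - gf, rel=1e-8)
        assert st_.complexes["HG"] == pytest.approx(3.8e-5, rel=0.01)

    def test_excess_guest_limit(self):
        # vesicle sulfate regime: host 50 nM drowned in 0.2 M guest
        st_ = solve_1to1(5e-8, 0.2, 370.0)
        theta = st_.complexes["HG"] / 5e-8
        assert theta == pytest.approx(370 * 0.2 / (1 + 370 * 0.2), rel=1e-6)
        assert st_.free_guests["G"] == pytest.approx(0.2, rel=1e-4)

    def test_negative_input_names_field(self):
        with pytest.raises(DomainError, match="guest_total"):
            solve_1to1(1e-4, -1e-4, 10.0)


class TestSolve1to2:
    def test_k2_zero_reduces_to_1to1(self):
        a = solve_1to2(1e-3, 2e-3, 500.0, 0.0)
        b = solve_1to1(1e-3, 2e-3, 500.0)
        assert a.complexes["HG"] == pytest.approx(b.complexes["HG"], rel=1e-12)
        assert a.complexes["HG2"] == 0.0

    def test_matches_root_scan_oracle(self):
        h, g, k1, k2 = 1e-3, 1e-2, 100.0, 10.0

        def residual(gf):
            hf = h / (1.0 + k1 * gf + k1 * k2 * gf * gf)
            return gf + hf * (k1 * gf + 2 * k1 * k2 * gf * gf) - g

        grid = np.linspace(0, g, 2001)
        sign_change = np.flatnonzero(np.diff(np.sign([residual(x) for x in grid])))[0]
        gf = brentq(residual, grid[sign_change], grid[sign_change + 1], xtol=1e-18)
        st_ = solve_1to2(h, g, k1, k2)
        assert st_.free_guests["G"] == pytest.approx(gf, rel=1e-8)

    def test_zero_guest(self):
        st_ = solve_1to2(1e-3, 0.0, 100.0, 10.0)
        assert st_.free_host == 1e-3
        assert all(v == 0.0 for v in st_.complexes.values())


class TestCompetition:
    def test_absent_competitor_matches_1to1(self):
        a = solve_competition(1e-4, 1e-3, 0.05, 2e3, 0.0)
        b = solve_1to1(1e-4, 1e-3, 2e3)
        assert a.complexes["HS"] == pytest.approx(b.complexes["HG"], rel=1e-12)
        assert a.complexes["HX"] == 0.0

    def test_label_swap_symmetry(self):
        a = solve_competition(1e-4, 1e-3, 2e-3, 5e3, 7e2)
        b = solve_competition(1e-4, 2e-3, 1e-3, 7e2, 5e3)
        assert a.complexes["HS"] == pytest.approx(b.complexes["HX"], rel=1e-12)
        assert a.complexes["HX"] == pytest.approx(b.complexes["HS"], rel=1e-12)

    def test_matches_2d_grid_oracle(self):
        # micelle-regime constants: sulfate 5.4e4, perchlorate 32
        h, s_tot, x_tot, ka_s, ka_x = 5e-8, 1e-3, 0.2, 54000.0, 32.0
        st_ = solve_competition(h, s_tot, x_tot, ka_s, ka_x)

        # oracle: refine (free s, free x) on nested grids of the 2-D balance
        s_lo, s_hi, x_lo, x_hi = 0.0, s_tot, 0.0, x_tot
        for _ in range(40):
            s_grid = np.linspace(s_lo, s_hi, 21)
            x_grid = np.linspace(x_lo, x_hi, 21)
            best, best_err = None, np.inf
            for sf in s_grid:
                for xf in x_grid:
                    hf = h / (1.0 + ka_s * sf + ka_x * xf)
                    r1 = sf + ka_s * hf * sf - s_tot
                    r2 = xf + ka_x * hf * xf - x_tot
                    err = abs(r1) / s_tot + abs(r2) / x_tot
                    if err < best_err:
                        best, best_err = (sf, xf), err
            ds, dx = (s_hi - s_lo) / 10, (x_hi - x_lo) / 10
            s_lo, s_hi = max(best[0] - ds, 0.0), min(best[0] + ds, s_tot)
            x_lo, x_hi = max(best[1] - dx, 0.0), min(best[1] + dx, x_tot)
        assert st_.free_guests["S"] == pytest.approx(best[0], rel=1e-6)
        assert st_.free_guests["X"] == pytest.approx(best[1], rel=1e-6)


class TestApparentKa:
    def test_no_competitor(self):
        assert apparent_ka_under_competition(1e4, 0.0, 0.1) == 1e4

    @given(st.floats(1.0, 1e9), st.floats(0.01, 1e6), st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, ka_s, ka_x, x):
        from hypothesis import assume
        assume(ka_x * x >= 1e-2)  # below this, cancellation dominates
        app = apparent_ka_under_competition(ka_s, ka_x, x)
        assert invert_competition(ka_s, app, x) == pytest.approx(ka_x, rel=1e-12)

    def test_apparent_matches_1to1_fit_of_competition_curves(self):
        # host far below both guests: a plain 1:1 fit of curves produced by
        # the exact competition solver returns the apparent constant
        from anionbind.synthetic import SimulationTruth, simulate_titration
        from anionbind.titration import fit_titration
        ka_s, ka_x, x_tot = 5e3, 40.0, 0.05
        truth = SimulationTruth(ka=ka_s, host_total=1e-8,
                                guest_grid=tuple(np.linspace(0, 5e-3, 15)),
                                competitor="X", competitor_total=x_tot,
                                competitor_ka=ka_x, noise=0.0)
        series, _ = simulate_titration(truth, "competition")
        fitted = fit_titration(series).ka
        expected = apparent_ka_under_competition(ka_s, ka_x, x_tot)
        assert fitted == pytest.approx(expected, rel=0.01)

    def test_raised_apparent_affinity_rejected(self):
        with pytest.raises(DomainError, match="cannot raise apparent affinity"):
            invert_competition(100.0, 150.0, 0.1)


class TestPrecipitation:
    def test_undersaturated(self):
        st_ = free_sulfate_with_precipitation(1e-6, 1e-6, 1.08e-10)
        assert st_.precipitate == 0.0
        assert st_.free_guests["SO4"] == 1e-6

    def test_large_excess_asymptotic(self):
        s, c, ksp = 1e-3, 0.5, 1.08e-10
        st_ = free_sulfate_with_precipitation(s, c, ksp)
        excess = c - s
        assert st_.free_guests["SO4"] == pytest.approx(ksp / excess, rel=1e-3)

    @pytest.mark.parametrize("s,c", [(1e-3, 2e-3), (5e-4, 5e-4), (1e-2, 1.1e-2)])
    def test_ion_product_pinned_at_ksp(self, s, c):
        ksp = 1.08e-10
        st_ = free_sulfate_with_precipitation(s, c, ksp)
        assert st_.precipitate > 0
        product = st_.free_guests["SO4"] * st_.free_guests["Ba"]
        assert product == pytest.approx(ksp, rel=1e-10)

    def test_mass_balance_with_precipitate(self):
        st_ = free_sulfate_with_precipitation(2e-3, 1e-3, 1.08e-10)
        assert mass_balance_error(st_, {"SO4": 2e-3, "Ba": 1e-3}) <= 1e-10


@given(
    h=st.floats(1e-9, 1e-2), g=st.floats(0.0, 1.0), ka=st.floats(0.0, 1e10),
)
@settings(max_examples=100, deadline=None)
def test_mass_conservation_1to1(h, g, ka):
    st_ = solve_1to1(h, g, ka)
    assert mass_balance_error(st_, {"H": h, "G": g}) <= 1e-10


@given(h=st.floats(1e-8, 1e-2), g=st.floats(1e-9, 0.5),
       k1=st.floats(0.0, 1e7), k2=st.floats(0.0, 1e5))
@settings(max_examples=100, deadline=None)
def test_mass_conservation_1to2(h, g, k1, k2):
    st_ = solve_1to2(h, g, k1, k2)
    assert mass_balance_error(st_, {"H": h, "G": g}) <= 1e-10


@given(h=st.floats(1e-9, 1e-3), s=st.floats(1e-8, 0.5), x=st.floats(1e-8, 0.5),
       ka_s=st.floats(0.0, 1e8), ka_x=st.floats(0.0, 1e6))
@settings(max_examples=100, deadline=None)
def test_mass_conservation_competition(h, s, x, ka_s, ka_x):
    st_ = solve_competition(h, s, x, ka_s, ka_x)
    assert mass_balance_error(st_, {"H": h, "S": s, "X": x}) <= 1e-10


def test_bound_fraction_monotone_in_guest_and_ka(rng):
    """theta is non-decreasing in guest_total and in Ka (random instances)."""
    for _ in range(30):
        h = 10.0 ** rng.uniform(-8, -3)
        ka = 10.0 ** rng.uniform(0, 8)
        guests = np.sort(10.0 ** rng.uniform(-7, -1, size=8))
        thetas = [solve_1to1(h, g, ka).bound_host_fraction(h) for g in guests]
        assert np.all(np.diff(thetas) >= -1e-12)
        kas = np.sort(10.0 ** rng.uniform(0, 9, size=8))
        thetas_k = [solve_1to1(h, 1e-3, k).bound_host_fraction(h) for k in kas]
        assert np.all(np.diff(thetas_k) >= -1e-12)


def test_solvers_agree_with_root_scan_on_random_instances(rng):
    """Closed-form/bracketed solutions match an independent bisection oracle
    on 100 random small instances to <= 1e-8 relative."""
    for _ in range(100):
        h = 10.0 ** rng.uniform(-8, -2)
        g = 10.0 ** rng.uniform(-7, -1)
        ka = 10.0 ** rng.uniform(-1, 9)
        st_ = solve_1to1(h, g, ka)
        gf = bisect_1to1_free_guest(h, g, ka)
        assert st_.free_guests["G"] == pytest.approx(gf, rel=1e-8, abs=1e-15)
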