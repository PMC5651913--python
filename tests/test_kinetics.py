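"""Kinetic-network simulation: rate matrices, exact propagation,
photostationary states, cooperative-dimer reversion, absorbance rendering."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from phykin.kinetics import (
    PhotoSystem,
    DimerChain,
    OccupancyTrace,
    rate_matrix,
    simulate,
    photostationary_fraction,
    dimer_reversion_trace,
    absorbance_timecourse,
)
from phykin.spectra import Band, StateSpectrum


TWO_STATE_REVERSION = PhotoSystem(states=("Pr", "Pfr"), k_therm=7.91e-3)


def random_system(rng) -> PhotoSystem:
    return PhotoSystem(
        states=("Pr", "Pfr", "Bleached"),
        sigma_fwd=rng.uniform(0, 0.2),
        sigma_rev=rng.uniform(0, 0.2),
        k_therm=rng.uniform(1e-3, 0.5),
        sigma_bleach=rng.uniform(0, 0.05),
        k_bleach_decay=rng.uniform(1e-3, 0.5),
    )


class TestRateMatrix:
    def test_darkness_has_only_thermal_terms(self):
        sys = PhotoSystem(states=("Pr", "Pfr"), sigma_fwd=0.1, sigma_rev=0.02, k_therm=0.01)
        Q = rate_matrix(sys, 0.0)
        assert Q[1, 0] == 0.0  # no Pr→Pfr photochemistry in the dark
        assert Q[0, 1] == pytest.approx(0.01)

    def test_photoconversion_scales_linearly_with_fluence(self):
        # coefficient chosen so Pr→Pfr is 0.98 min⁻¹ at the calibrated
        # 12 μmol·m⁻²·s⁻¹; doubling fluence doubles the entry
        sys = PhotoSystem(states=("Pr", "Pfr"), sigma_fwd=0.98 / 12.0)
        assert rate_matrix(sys, 12.0)[1, 0] == pytest.approx(0.98)
        assert rate_matrix(sys, 24.0)[1, 0] == pytest.approx(1.96)

    def test_columns_sum_to_zero_for_random_systems(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            Q = rate_matrix(random_system(rng), rng.uniform(0, 100))
            np.testing.assert_allclose(Q.sum(axis=0), 0.0, atol=1e-12)

    def test_negative_fluence_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix(TWO_STATE_REVERSION, -1.0)


class TestSimulate:
    def test_time_zero_returns_init_exactly(self):
        trace = simulate(TWO_STATE_REVERSION, 0.0, (0.3, 0.7), np.array([0.0, 1.0]))
        np.testing.assert_array_equal(trace.occupancies[0], [0.3, 0.7])

    def test_pfr_half_life_matches_closed_form(self):
        """Pure thermal reversion at k = 7.91e-3 min⁻¹: Pfr(t) = exp(−k·t),
        half-depleted at t½ = ln2/k ≈ 87.6 min."""
        k = 7.91e-3
        t_half = np.log(2.0) / k
        assert t_half == pytest.approx(87.6, abs=0.1)
        trace = simulate(
            TWO_STATE_REVERSION, 0.0, (0.0, 1.0), np.array([0.0, t_half, 200.0])
        )
        pfr = trace.state("Pfr")
        np.testing.assert_allclose(pfr[1], 0.5, atol=1e-12)
        np.testing.assert_allclose(pfr, np.exp(-k * trace.times), atol=1e-12)

    def test_matches_adaptive_ode_oracle_on_random_three_state_schemes(self):
        """Exact propagation agrees with an independent stiff-capable
        adaptive ODE integration to 1e-8 on randomized schemes."""
        rng = np.random.default_rng(202)
        times = np.linspace(0.0, 30.0, 7)
        for _ in range(25):
            sys = random_system(rng)
            fluence = rng.uniform(0, 50)
            p0 = rng.dirichlet(np.ones(3))
            trace = simulate(sys, fluence, p0, times)
            Q = rate_matrix(sys, fluence)
            sol = solve_ivp(
                lambda t, p: Q @ p, (0.0, times[-1]), p0,
                t_eval=times, method="LSODA", rtol=1e-11, atol=1e-13,
            )
            np.testing.assert_allclose(trace.occupancies, sol.y.T, atol=1e-8)

    def test_occupancies_conserve_and_stay_in_unit_interval(self):
        rng = np.random.default_rng(7)
        times = np.linspace(0.0, 100.0, 31)
        for _ in range(20):
            trace = simulate(
                random_system(rng), rng.uniform(0, 20), rng.dirichlet(np.ones(3)), times
            )
            np.testing.assert_allclose(trace.occupancies.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(trace.occupancies >= 0.0)
            assert np.all(trace.occupancies <= 1.0 + 1e-12)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            simulate(TWO_STATE_REVERSION, 0.0, (0.0, 1.0), np.array([0.0, 2.0, 1.0]))


class TestPhotostationaryFraction:
    def test_pure_forward_photochemistry_gives_full_conversion(self):
        sys = PhotoSystem(states=("Pr", "Pfr"), sigma_fwd=0.1)
        assert photostationary_fraction(sys, 10.0) == pytest.approx(1.0)

    def test_balanced_rates_give_one_third(self):
        # σf·I = σr·I = k_therm ⇒ Pfr* = 1/3
        sys = PhotoSystem(states=("Pr", "Pfr"), sigma_fwd=0.01, sigma_rev=0.01, k_therm=0.1)
        assert photostationary_fraction(sys, 10.0) == pytest.approx(1.0 / 3.0)

    def test_matches_long_time_simulation(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            sys = PhotoSystem(
                states=("Pr", "Pfr"),
                sigma_fwd=rng.uniform(0.01, 0.2),
                sigma_rev=rng.uniform(0.0, 0.2),
                k_therm=rng.uniform(1e-3, 0.2),
            )
            fluence = rng.uniform(1.0, 30.0)
            Q = rate_matrix(sys, fluence)
            slowest = min(abs(x) for x in np.diag(Q) if x != 0)
            t_long = 50.0 / slowest
            trace = simulate(sys, fluence, (1.0, 0.0), np.array([0.0, t_long]))
            assert photostationary_fraction(sys, fluence) == pytest.approx(
                trace.state("Pfr")[-1], abs=1e-6
            )

    def test_monotone_in_fluence_and_saturates(self):
        """Steady-state Pfr rises with fluence and approaches
        σf/(σf+σr) once photochemistry outruns thermal reversion."""
        sys = PhotoSystem(
            states=("Pr", "Pfr"), sigma_fwd=0.08, sigma_rev=0.02, k_therm=0.01
        )
        fluences = np.logspace(-2, 5, 30)
        fracs = [photostationary_fraction(sys, I) for I in fluences]
        assert np.all(np.diff(fracs) >= -1e-12)
        assert fracs[-1] == pytest.approx(0.08 / 0.10, abs=1e-4)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            photostationary_fraction(PhotoSystem(states=("Pr", "Pfr")), 0.0)


class TestDimerReversion:
    # the 1–908 fragment's biexponential pair (min⁻¹)
    CHAIN = DimerChain(k_fast=0.320, k_slow=0.034)

    def test_starts_at_one_and_amplitudes_sum_to_one(self):
        res = dimer_reversion_trace(self.CHAIN, np.array([0.0, 5.0]))
        assert res.pfr_fraction[0] == pytest.approx(1.0)
        assert res.amp_fast + res.amp_slow == pytest.approx(1.0)

    def test_closed_form_matches_matrix_exponential_oracle(self):
        """Closed-form biexponential agrees with expm propagation of the
        three-species chain to 1e-10 at 100 random times."""
        kf, ks = self.CHAIN.k_fast, self.CHAIN.k_slow
        Q = np.array([[-kf, 0, 0], [kf, -ks, 0], [0, ks, 0]])
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0.0, 120.0, 100))
        res = dimer_reversion_trace(self.CHAIN, times)
        oracle = np.array(
            [(expm(Q * t) @ [1.0, 0.0, 0.0]) for t in times]
        )
        f_oracle = (2.0 * oracle[:, 0] + oracle[:, 1]) / 2.0
        np.testing.assert_allclose(res.pfr_fraction, f_oracle, atol=1e-10)

    def test_degenerate_equal_rates_match_analytic_limit(self):
        k = 0.1
        times = np.linspace(0.0, 60.0, 50)
        res = dimer_reversion_trace(DimerChain(k_fast=k, k_slow=k), times)
        assert res.degenerate
        np.testing.assert_allclose(
            res.pfr_fraction, (1.0 + k * times / 2.0) * np.exp(-k * times), atol=1e-9
        )

    def test_near_degenerate_is_continuous_with_the_limit(self):
        times = np.linspace(0.0, 60.0, 50)
        k = 0.1
        near = dimer_reversion_trace(DimerChain(k_fast=k * (1 + 2e-6), k_slow=k), times)
        exact = (1.0 + k * times / 2.0) * np.exp(-k * times)
        np.testing.assert_allclose(near.pfr_fraction, exact, atol=1e-6)

    def test_amplitude_split_depends_only_on_rate_ratio(self):
        a = dimer_reversion_trace(DimerChain(0.32, 0.034), np.array([0.0]))
        b = dimer_reversion_trace(DimerChain(3.2, 0.34), np.array([0.0]))
        assert a.amp_fast == pytest.approx(b.amp_fast, rel=1e-12)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            DimerChain(k_fast=0.0, k_slow=0.1)


class TestAbsorbanceTimecourse:
    def _basis(self, grid):
        return [
            StateSpectrum("Pr", (Band(664.0, 28.0, 0.4),), grid),
            StateSpectrum("Pfr", (Band(724.0, 28.0, 0.24),), grid),
        ]

    def test_single_state_trace_is_constant_in_time(self):
        grid = np.arange(630.0, 851.0, 10.0)
        trace = OccupancyTrace(
            np.linspace(0, 10, 5), np.column_stack([np.ones(5), np.zeros(5)]), ("Pr", "Pfr")
        )
        ds = absorbance_timecourse(trace, self._basis(grid), [660.0, 720.0])
        np.testing.assert_allclose(
            ds.absorbance, np.tile(ds.absorbance[0], (5, 1)), atol=1e-15
        )

    def test_constant_at_isosbestic_wavelength(self):
        """At the wavelength where Pr and Pfr absorb equally, any Pr/Pfr
        redistribution leaves the absorbance unchanged."""
        from scipy.optimize import brentq

        grid = np.arange(630.0, 851.0, 10.0)
        basis = self._basis(grid)
        f = lambda lam: 0.4 * np.exp(-((lam - 664.0) ** 2) / (2 * 28.0**2)) - 0.24 * np.exp(
            -((lam - 724.0) ** 2) / (2 * 28.0**2)
        )
        iso = brentq(f, 664.0, 724.0, xtol=1e-12)
        pfr = np.linspace(1.0, 0.0, 9)
        trace = OccupancyTrace(
            np.linspace(0, 80, 9), np.column_stack([1 - pfr, pfr]), ("Pr", "Pfr")
        )
        ds = absorbance_timecourse(trace, basis, [iso])
        np.testing.assert_allclose(ds.absorbance[:, 0], ds.absorbance[0, 0], atol=1e-9)

    def test_reversion_loses_far_red_and_gains_red_absorbance(self):
        """During Pfr decay the 720-nm signal falls monotonically while
        the 660-nm signal rises — the classic paired reversion readout."""
        times = np.linspace(0.0, 200.0, 40)
        pfr = np.exp(-7.91e-3 * times)
        trace = OccupancyTrace(times, np.column_stack([1 - pfr, pfr]), ("Pr", "Pfr"))
        grid = np.arange(630.0, 851.0, 10.0)
        ds = absorbance_timecourse(trace, self._basis(grid), [720.0, 660.0])
        assert np.all(np.diff(ds.column(720.0)) < 0)
        assert np.all(np.diff(ds.column(660.0)) > 0)

    def test_missing_state_spectrum_rejected(self):
        trace = OccupancyTrace(np.array([0.0]), np.array([[1.0, 0.0]]), ("Pr", "Pfr"))
        grid = np.arange(630.0, 851.0, 10.0)
        only_pr = [StateSpectrum("Pr", (Band(664.0, 28.0, 0.4),), grid)]
        with pytest.raises(ValueError):
            absorbance_timecourse(trace, only_pr, [660.0])
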