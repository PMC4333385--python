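"""Tests for transient-experiment simulation and the fitting chain."""

import math

import numpy as np
import pytest

from recqcycle import (
    RateConstantSet,
    TransientTrace,
    binding_kobs_series,
    burst_amplitude,
    cycle_flux,
    fit_hill,
    fit_kobs_line,
    fit_single_exponential,
    simulate_md_binding,
    simulate_md_chase,
    simulate_pi_release,
    simulate_quenched_flow,
    steady_state_curve,
)
from recqcycle.transients import FitError, KobsConcSeries, SteadyStateCurve

CONCS = (5.0, 10.0, 20.0, 50.0, 100.0)


class TestBindingChain:
    def test_mdatp_series_recovers_table_parameters(self, md_bound_rates,
                                                    md_free_rates):
        """Fitting noiseless mdATP binding transients at five concentrations
        recovers slope k1 and intercept k_m1 + k2 for both conditions."""
        for rates, slope, intercept in ((md_bound_rates, 8.4, 78.0),
                                        (md_free_rates, 8.0, 118.0)):
            series = binding_kobs_series(rates, "mdATP", CONCS)
            line = fit_kobs_line(series)
            assert line.slope == pytest.approx(slope, rel=0.01)
            assert line.intercept == pytest.approx(intercept, rel=0.01)

    def test_mdadp_kobs_is_two_state_relaxation(self, md_free_rates):
        """mdADP binding k_obs equals k_m4*C + k4 exactly."""
        for conc in (10.0, 40.0):
            trace = simulate_md_binding(md_free_rates, "mdADP", conc)
            fit = fit_single_exponential(trace)
            expected = md_free_rates.k_m4 * conc + md_free_rates.k4
            assert fit.k_obs == pytest.approx(expected, rel=1e-4)

    def test_full_ode_cross_check_dna_free(self, md_free_rates):
        """The full four-state relaxation at 10 uM mdATP (DNA-free) gives
        k_obs ~ 8.0*10 + 118 = 198 per second, confirming the linear
        relation against an independent simulation route."""
        trace = simulate_md_binding(md_free_rates, "mdATP", 10.0, model="full")
        fit = fit_single_exponential(trace)
        assert fit.k_obs == pytest.approx(198.0, rel=0.02)

    def test_slope_recovery_invariant(self, bound_rates, free_rates):
        """For any default set, fitted k_obs is linear in concentration with
        slope within 5% of the generating association rate constant."""
        for rates in (bound_rates, free_rates):
            for nucleotide, k_on in (("mdATP", rates.k1), ("mdADP", rates.k_m4)):
                series = binding_kobs_series(rates, nucleotide, CONCS)
                line = fit_kobs_line(series)
                assert line.slope == pytest.approx(k_on, rel=0.05)

    def test_pseudo_first_order_warning(self, md_bound_rates):
        trace = simulate_md_binding(md_bound_rates, "mdATP", 2.0, enzyme=1.0)
        assert trace.meta.get("pseudo_first_order_warning") is True


class TestChase:
    def test_chase_recovers_k4(self, md_bound_rates):
        """Chasing the enzyme.mdADP complex with 0.5 mM ATP gives a decay at
        the mdADP release rate (k4 = 100 of the md set)."""
        trace = simulate_md_chase(md_bound_rates, 20.0, 1.0, 500.0)
        fit = fit_single_exponential(trace)
        assert fit.k_obs == pytest.approx(md_bound_rates.k4, rel=0.05)

    def test_infinite_chase_exact_exponential(self, md_bound_rates):
        trace = simulate_md_chase(md_bound_rates, 20.0, 1.0, math.inf)
        fit = fit_single_exponential(trace)
        assert fit.k_obs == pytest.approx(md_bound_rates.k4, rel=1e-6)

    def test_moderate_chase_within_ten_percent(self, md_bound_rates):
        """A 10x excess chase still reports k4 within 10% despite residual
        mdADP rebinding."""
        trace = simulate_md_chase(md_bound_rates, 20.0, 1.0, 200.0)
        fit = fit_single_exponential(trace)
        assert fit.k_obs == pytest.approx(md_bound_rates.k4, rel=0.10)

    def test_zero_chase_rejected(self, md_bound_rates):
        with pytest.raises(ValueError):
            simulate_md_chase(md_bound_rates, 20.0, 1.0, 0.0)


class TestQuenchedFlow:
    def test_single_turnover_completion(self, bound_rates):
        """Enzyme excess over ATP eventually cleaves essentially all of it.

        At 2 uM enzyme and 1.5 uM ATP, entry into the cycle is limited by
        binding (k1*[E] ~ 17 per second), so completion takes a few
        combined binding-plus-hydrolysis time constants rather than 5/k2
        alone.
        """
        tau = 1.0 / (bound_rates.k1 * 2.0) + 1.0 / bound_rates.k2
        t = np.linspace(0.0, 1.0, 21)[1:]
        trace = simulate_quenched_flow(bound_rates, 2.0, 1.5, t)
        assert trace.signal[-1] >= 0.99
        assert trace.signal[np.searchsorted(t, 6 * tau)] >= 0.95

    def test_monotone_and_bounded(self, bound_rates, free_rates):
        for rates, enzyme, atp in ((bound_rates, 2.0, 25.0), (free_rates, 4.0, 50.0)):
            t = np.geomspace(2e-3, 30.0, 25)
            trace = simulate_quenched_flow(rates, enzyme, atp, t)
            assert np.all(np.diff(trace.signal) >= -1e-9)
            assert np.all(trace.signal <= 1.0 + 1e-9)

    def test_dna_free_no_burst(self, free_rates):
        """Multiple-turnover DNA-free cleavage shows no burst: the
        back-extrapolated intercept is ~0 and the initial slope matches the
        stationary flux."""
        flux = cycle_flux(free_rates, 50.0)
        t = np.linspace(0.0, 3.0, 40)
        trace = simulate_quenched_flow(free_rates, 4.0, 50.0, t)
        # signal is fraction cleaved; convert slope to uM/s per enzyme
        slope, intercept = np.polyfit(t[1:], trace.signal[1:], 1)
        assert abs(intercept) < 0.01
        assert slope * 50.0 / 4.0 == pytest.approx(flux, rel=0.1)

    def test_matches_molecule_level_stochastic_oracle(self, bound_rates):
        """Multiple-turnover cleavage agrees with an exact molecule-count
        stochastic simulation of the same mixture within 3 SEM."""
        enzyme, atp = 2.0, 25.0
        scale = 40.0  # molecules per uM
        t_obs = np.array([0.02, 0.05, 0.1, 0.2, 0.4])
        n_rep = 30
        fracs = np.zeros((n_rep, len(t_obs)))
        rng = np.random.default_rng(2024)
        k = bound_rates
        for rep in range(n_rep):
            nE = int(enzyme * scale)
            nT = nDPi = nD = 0
            nATP = int(atp * scale)
            nADP = nPi = 0
            t_now = 0.0
            out = []
            idx = 0
            while idx < len(t_obs):
                props = np.array([
                    k.k1 * (nATP / scale) * nE,
                    k.k_m1 * nT,
                    k.k2 * nT,
                    k.k_m2 * nDPi,
                    k.k3 * nDPi,
                    k.k4 * nD,
                    k.k_m4 * (nADP / scale) * nE,
                ])
                total = props.sum()
                if total == 0:
                    break
                dt = rng.exponential(1.0 / total)
                while idx < len(t_obs) and t_now + dt > t_obs[idx]:
                    out.append((nDPi + nPi) / (atp * scale))
                    idx += 1
                t_now += dt
                r = rng.choice(7, p=props / total)
                if r == 0:
                    nE -= 1; nT += 1; nATP -= 1
                elif r == 1:
                    nT -= 1; nE += 1; nATP += 1
                elif r == 2:
                    nT -= 1; nDPi += 1
                elif r == 3:
                    nDPi -= 1; nT += 1
                elif r == 4:
                    nDPi -= 1; nD += 1; nPi += 1
                elif r == 5:
                    nD -= 1; nE += 1; nADP += 1
                else:
                    nE -= 1; nD += 1; nADP -= 1
            while len(out) < len(t_obs):
                out.append((nDPi + nPi) / (atp * scale))
            fracs[rep] = out
        mc_mean = fracs.mean(axis=0)
        mc_sem = fracs.std(axis=0, ddof=1) / math.sqrt(n_rep)
        trace = simulate_quenched_flow(bound_rates, enzyme, atp, t_obs)
        assert np.all(np.abs(trace.signal - mc_mean) <= 3 * mc_sem + 5e-3)

    def test_zero_atp_rejected(self, bound_rates):
        with pytest.raises(ValueError):
            simulate_quenched_flow(bound_rates, 2.0, 0.0, [0.1])


class TestPiRelease:
    def test_steady_slope_matches_kcat(self, bound_rates):
        """The linear-phase slope per enzyme of the captured-Pi curve equals
        the stationary turnover (~30 per second at 200 uM ATP)."""
        t = np.linspace(0.0, 0.6, 61)
        trace = simulate_pi_release(bound_rates, 0.25, 200.0, t)
        mask = t >= 5.0 / (bound_rates.k2 * bound_rates.k3
                           / (bound_rates.k3 + bound_rates.k_m2))
        slope, _ = np.polyfit(t[mask], trace.signal[mask], 1)
        assert slope / 0.25 == pytest.approx(30.0, abs=3.0)

    def test_no_burst_with_defaults(self, bound_rates, free_rates):
        """Rate-limiting hydrolysis leaves no pre-steady-state Pi burst."""
        t = np.linspace(0.0, 0.6, 61)
        amp = burst_amplitude(simulate_pi_release(bound_rates, 0.25, 200.0, t))
        assert abs(amp) < 0.1
        t_free = np.linspace(0.0, 60.0, 61)
        amp_free = burst_amplitude(simulate_pi_release(free_rates, 0.25, 200.0, t_free))
        assert abs(amp_free) < 0.1

    def test_fast_hydrolysis_burst_matches_closed_form(self):
        """When hydrolysis is much faster than ADP release the burst
        amplitude approaches the closed-form (k2/(k2+k4))^2 per enzyme."""
        rates = RateConstantSet(100.0, 1.0, 500.0, 0.0, 1e5, 0.0, 50.0, 1.0)
        t = np.linspace(0.0, 0.5, 201)
        trace = simulate_pi_release(rates, 1.0, 2000.0, t)
        amp = burst_amplitude(trace)
        assert amp == pytest.approx((500.0 / 550.0) ** 2, abs=0.02)

    def test_reporter_saturation_flag(self, bound_rates):
        t = np.linspace(0.0, 1.0, 41)
        trace = simulate_pi_release(bound_rates, 0.25, 200.0, t, reporter_conc=2.0)
        assert trace.meta.get("reporter_saturated") is True


class TestFitPrimitives:
    def test_exponential_exact_recovery(self):
        t = np.linspace(0.01, 1.0, 50)
        y = 3.0 - 2.0 * np.exp(-7.5 * t)
        fit = fit_single_exponential(TransientTrace(t, y))
        assert fit.k_obs == pytest.approx(7.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-6)
        assert fit.offset == pytest.approx(3.0, rel=1e-6)

    def test_exponential_noisy_recovery(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.01, 1.0, 50)
        y = 1.0 - 1.0 * np.exp(-6.0 * t) + rng.normal(0, 0.02, 50)
        fit = fit_single_exponential(TransientTrace(t, y))
        assert fit.k_obs == pytest.approx(6.0, rel=0.05)

    def test_constant_trace_raises(self):
        t = np.linspace(0.01, 1.0, 20)
        with pytest.raises(FitError):
            fit_single_exponential(TransientTrace(t, np.ones(20)))

    def test_kobs_line_exact_interpolation(self):
        series = KobsConcSeries(np.array([5.0, 10.0, 20.0, 5.0, 10.0, 20.0]),
                                np.array([60.0, 110.0, 210.0, 60.0, 110.0, 210.0]))
        line = fit_kobs_line(series)
        assert line.slope == pytest.approx(10.0, rel=1e-9)
        assert line.intercept == pytest.approx(10.0, rel=1e-9)

    def test_kobs_line_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_kobs_line(KobsConcSeries(np.array([1.0, 2.0]), np.array([3.0, 4.0])))


class TestSteadyStateAndHill:
    ATP = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)

    def test_curve_saturates_at_kcat(self, bound_rates):
        curve = steady_state_curve(bound_rates, self.ATP, enzyme=0.25)
        assert curve.rate[-1] == pytest.approx(30.0, abs=3.0)

    def test_zero_atp_zero_rate(self, bound_rates):
        curve = steady_state_curve(bound_rates, (0.0, 100.0), enzyme=0.25)
        assert curve.rate[0] == 0.0

    def test_half_max_near_briggs_haldane_km(self, bound_rates):
        """The half-saturating ATP of the simulated curve matches the
        scheme's own Briggs-Haldane K_M (frozen oracle 7.21 uM)."""
        curve = steady_state_curve(bound_rates, self.ATP, enzyme=0.25)
        hill = fit_hill(curve)
        assert hill.K_atp == pytest.approx(7.21, rel=0.10)

    def test_hill_coefficient_near_one(self, bound_rates, free_rates):
        """The single-site cycle cannot generate cooperativity: n in
        [0.95, 1.05] for scheme-generated curves."""
        for rates in (bound_rates, free_rates):
            curve = steady_state_curve(rates, self.ATP, enzyme=0.25)
            hill = fit_hill(curve)
            assert 0.95 <= hill.n <= 1.05

    def test_hill_on_exact_hyperbola(self):
        atp = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
        v = 30.0 * atp / (16.0 + atp)
        hill = fit_hill(SteadyStateCurve(atp, v))
        assert hill.n == pytest.approx(1.0, abs=0.02)
        assert hill.k_cat == pytest.approx(30.0, rel=0.01)

    def test_kcat_matches_cycle_flux(self, bound_rates):
        curve = steady_state_curve(bound_rates, self.ATP, enzyme=0.25)
        hill = fit_hill(curve)
        assert hill.k_cat == pytest.approx(cycle_flux(bound_rates, 1e6), rel=0.03)


class TestBurstAmplitude:
    def test_line_through_origin_is_zero(self):
        t = np.linspace(0.0, 1.0, 30)
        trace = TransientTrace(t, 4.0 * t, "pi_released", {"enzyme_uM": 1.0})
        assert burst_amplitude(trace) == pytest.approx(0.0, abs=1e-12)

    def test_nonlinear_trace_rejected(self):
        t = np.linspace(0.01, 1.0, 30)
        trace = TransientTrace(t, 1 - np.exp(-3 * t), "pi_released",
                               {"enzyme_uM": 1.0})
        with pytest.raises(FitError):
            burst_amplitude(trace)
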