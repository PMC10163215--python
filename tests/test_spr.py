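"""Kinetics arithmetic, closed-form trajectories and global 1:1 fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from genosensor.spr import (
    InjectionPhase,
    KineticParams,
    KineticsDomainError,
    ScheduleError,
    Sensorgram,
    equilibrium_response,
    fit_1to1,
    ka_equilibrium,
    kd_equilibrium,
    observed_rate,
    simulate_association,
    simulate_dissociation,
    simulate_sensorgram,
)
from conftest import make_schedule


def sig3(x):
    return float(f"{x:.3g}")


class TestEquilibriumConstants:
    def test_kd_printed_5382insC_target(self):
        # printed mutant-probe rate constants for the fully complementary target
        assert sig3(kd_equilibrium(9.72e7, 4.26e-3)) == 4.38e-11

    def test_kd_printed_4035delA_target(self):
        assert sig3(kd_equilibrium(8.17e6, 3.86e-4)) == 4.72e-11

    def test_kd_identity(self):
        assert kd_equilibrium(1.0, 1.0) == 1.0

    def test_ka_printed_values(self):
        assert sig3(ka_equilibrium(4.3827e-11)) == 2.28e10
        assert sig3(ka_equilibrium(4.7246e-11)) == 2.12e10

    def test_ka_fixed_point(self):
        assert ka_equilibrium(1.0) == 1.0

    @pytest.mark.parametrize("ka,kd", [(0, 1), (1, 0), (-1, 1), (1, -1)])
    def test_domain_errors(self, ka, kd):
        with pytest.raises(KineticsDomainError):
            kd_equilibrium(ka, kd)

    def test_ka_domain_error(self):
        with pytest.raises(KineticsDomainError):
            ka_equilibrium(0.0)

    @given(
        ka=st.floats(1e2, 1e9),
        kd=st.floats(1e-6, 1e-1),
        rmax=st.floats(1.0, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_ka_kd_product_is_unity(self, ka, kd, rmax):
        p = KineticParams(ka, kd, rmax)
        assert p.Ka * p.Kd == pytest.approx(1.0, rel=1e-12)


class TestObservedRate:
    def test_hand_arithmetic(self, params):
        assert observed_rate(params, 1e-7) == pytest.approx(0.101)

    def test_zero_concentration_gives_kd(self, params):
        assert observed_rate(params, 0.0) == params.kd

    def test_vanishing_kd_limit(self):
        p = KineticParams(1e6, 1e-15, 100.0)
        assert observed_rate(p, 1e-7) == pytest.approx(0.1, rel=1e-8)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(KineticsDomainError):
            observed_rate(params, -1e-9)


class TestClosedForms:
    def test_association_starts_at_zero(self, params):
        assert simulate_association(params, 1e-7, np.array([5.0]), t0=5.0)[0] == 0.0

    def test_association_plateau(self, params):
        req = equilibrium_response(params, 1e-7)
        far = simulate_association(params, 1e-7, np.array([1e6]))[0]
        assert far == pytest.approx(req, rel=1e-10)

    def test_association_matches_ode_integrator(self, params):
        C = 1e-7
        t = np.linspace(0.0, 300.0, 1000)
        sol = solve_ivp(
            lambda _, r: params.ka * C * (params.rmax - r) - params.kd * r,
            (0.0, 300.0),
            [0.0],
            t_eval=t,
            rtol=1e-11,
            atol=1e-13,
        )
        closed = simulate_association(params, C, t)
        rel = np.abs(sol.y[0][1:] - closed[1:]) / np.abs(closed[1:])
        assert np.max(rel) <= 1e-6

    def test_association_monotone_and_bounded(self, params):
        t = np.linspace(0.0, 300.0, 500)
        r = simulate_association(params, 1e-7, t)
        assert np.all(np.diff(r) > 0)
        assert np.all(r <= equilibrium_response(params, 1e-7) + 1e-12)

    def test_dissociation_continuity(self, params):
        assert simulate_dissociation(params, 42.0, np.array([0.0]))[0] == 42.0

    def test_dissociation_half_life(self):
        p = KineticParams(1e6, 1e-3, 100.0)
        t_half = np.log(2.0) / 1e-3
        r = simulate_dissociation(p, 80.0, np.array([t_half]))
        assert r[0] == pytest.approx(40.0, rel=1e-12)

    def test_dissociation_matches_ode_integrator(self, params):
        t = np.linspace(0.0, 600.0, 1000)
        sol = solve_ivp(
            lambda _, r: -params.kd * r,
            (0.0, 600.0),
            [75.0],
            t_eval=t,
            rtol=1e-11,
            atol=1e-13,
        )
        closed = simulate_dissociation(params, 75.0, t)
        rel = np.abs(sol.y[0] - closed) / np.abs(closed)
        assert np.max(rel) <= 1e-6

    def test_dissociation_monotone_nonnegative(self, params):
        t = np.linspace(0.0, 600.0, 500)
        r = simulate_dissociation(params, 50.0, t)
        assert np.all(np.diff(r) < 0)
        assert np.all(r >= 0)

    def test_domain_errors(self, params):
        with pytest.raises(KineticsDomainError):
            simulate_association(params, 0.0, np.array([1.0]))
        with pytest.raises(KineticsDomainError):
            simulate_dissociation(params, -1.0, np.array([1.0]))


class TestSimulateSensorgram:
    def test_noise_free_equals_piecewise_closed_form(self, params, schedule):
        sg = simulate_sensorgram(schedule, params, noise_sd=0.0, seed=0)
        a = sg.association_block()
        d = sg.dissociation_block()
        expected_a = simulate_association(params, 100e-9, sg.time[a], t0=sg.time[a][0])
        np.testing.assert_allclose(sg.response[a], expected_a, rtol=1e-12, atol=1e-12)
        # dissociation decays from the response at the phase boundary
        boundary = simulate_association(
            params, 100e-9, np.array([sg.time[d][0]]), t0=sg.time[a][0]
        )[0]
        expected_d = simulate_dissociation(params, boundary, sg.time[d], t0=sg.time[d][0])
        np.testing.assert_allclose(sg.response[d], expected_d, rtol=1e-10)

    def test_same_seed_identical(self, params, schedule):
        a = simulate_sensorgram(schedule, params, noise_sd=0.5, seed=7)
        b = simulate_sensorgram(schedule, params, noise_sd=0.5, seed=7)
        np.testing.assert_array_equal(a.response, b.response)

    def test_different_seeds_differ(self, params, schedule):
        a = simulate_sensorgram(schedule, params, noise_sd=0.5, seed=7)
        b = simulate_sensorgram(schedule, params, noise_sd=0.5, seed=8)
        assert not np.array_equal(a.response, b.response)

    def test_noisy_replicates_average_to_clean_trace(self, params, schedule):
        clean = simulate_sensorgram(schedule, params, noise_sd=0.0, seed=0).response
        n_rep, sd = 200, 0.5
        acc = np.zeros_like(clean)
        for s in range(n_rep):
            acc += simulate_sensorgram(schedule, params, noise_sd=sd, seed=s).response
        mean = acc / n_rep
        z = np.abs(mean - clean) / (sd / np.sqrt(n_rep))
        # pointwise 3-sigma holds for ~99.7% of the grid; allow the expected
        # handful of exceedances but nothing gross
        assert np.mean(z <= 3.0) >= 0.99
        assert np.max(z) <= 5.0

    def test_drift_is_linear_addition(self, params, schedule):
        base = simulate_sensorgram(schedule, params, noise_sd=0.0, drift=0.0, seed=0)
        drifted = simulate_sensorgram(schedule, params, noise_sd=0.0, drift=0.01, seed=0)
        np.testing.assert_allclose(
            drifted.response - base.response, 0.01 * base.time, rtol=1e-10, atol=1e-12
        )

    def test_bad_schedule_rejected(self, params):
        with pytest.raises(ScheduleError):
            simulate_sensorgram(
                (InjectionPhase("dissociation", 600.0),), params, seed=0
            )
        with pytest.raises(ScheduleError):
            simulate_sensorgram(
                (
                    InjectionPhase("dissociation", 600.0),
                    InjectionPhase("association", 300.0, analyte_concentration=1e-7),
                ),
                params,
                seed=0,
            )

    def test_phase_invariants(self, params):
        with pytest.raises(ScheduleError):
            InjectionPhase("association", 300.0, analyte_concentration=0.0)
        with pytest.raises(ScheduleError):
            InjectionPhase("dissociation", 600.0, analyte_concentration=1e-7)
        with pytest.raises(ScheduleError):
            InjectionPhase("association", -1.0, analyte_concentration=1e-7)


class TestFit:
    def test_noise_free_recovery(self, params, noise_free_sensorgram, concentration):
        fr = fit_1to1(noise_free_sensorgram, concentration)
        assert fr.converged
        assert fr.estimate.ka == pytest.approx(params.ka, rel=1e-4)
        assert fr.estimate.kd == pytest.approx(params.kd, rel=1e-4)
        assert fr.estimate.rmax == pytest.approx(params.rmax, rel=1e-4)

    def test_noisy_recovery_median_error(self, params, schedule, concentration):
        errs_ka, errs_kd = [], []
        for seed in range(20):
            sg = simulate_sensorgram(schedule, params, noise_sd=0.5, seed=seed)
            fr = fit_1to1(sg, concentration)
            assert fr.converged
            errs_ka.append(abs(fr.estimate.ka - params.ka) / params.ka)
            errs_kd.append(abs(fr.estimate.kd - params.kd) / params.kd)
        assert np.median(errs_ka) <= 0.05
        assert np.median(errs_kd) <= 0.05

    def test_flat_trace_not_converged(self):
        n = 900
        sg = Sensorgram(
            np.arange(n, dtype=float),
            np.zeros(n),
            tuple(["association"] * 300 + ["dissociation"] * 600),
        )
        fr = fit_1to1(sg, 1e-7)
        assert not fr.converged
        assert fr.estimate is None

    def test_stderr_reported(self, params, schedule, concentration):
        sg = simulate_sensorgram(schedule, params, noise_sd=0.5, seed=3)
        fr = fit_1to1(sg, concentration)
        assert fr.converged
        assert set(fr.stderr) == {"ka", "kd", "rmax"}
        assert all(v >= 0 for v in fr.stderr.values())

    def test_bad_concentration(self, noise_free_sensorgram):
        with pytest.raises(KineticsDomainError):
            fit_1to1(noise_free_sensorgram, 0.0)

    def test_too_few_points(self, params):
        sg = Sensorgram(
            np.arange(12, dtype=float),
            np.ones(12),
            tuple(["association"] * 6 + ["dissociation"] * 6),
        )
        with pytest.raises(ValueError):
            fit_1to1(sg, 1e-7)

    def test_recovery_over_loguniform_design(self):
        # >= 90% of fits across the kinetic box recover both rates to 10%;
        # fast kinetics need the finer 10 Hz grid to resolve the rise
        rng = np.random.default_rng(42)
        C = 1e-7
        sched = make_schedule(C)
        n, ok = 20, 0
        for _ in range(n):
            ka = 10 ** rng.uniform(4, 8)
            kd = 10 ** rng.uniform(-5, -2)
            p = KineticParams(ka, kd, 100.0)
            sg = simulate_sensorgram(sched, p, noise_sd=0.5, seed=rng, sampling_hz=10.0)
            fr = fit_1to1(sg, C)
            if (
                fr.converged
                and abs(fr.estimate.ka - ka) / ka <= 0.1
                and abs(fr.estimate.kd - kd) / kd <= 0.1
            ):
                ok += 1
        assert ok >= 0.9 * n
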