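"""Closed-form binding model: rate laws, equilibria, lifetimes, competition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopflow import (
    BindingSystem,
    LifetimeInput,
    Protein,
    RateParameters,
    complex_lifetime,
    compute_Kd,
    double_exponential,
    equilibrium_complex,
    equilibrium_partition,
    kinetic_partition,
    kobs_dilution,
    kobs_linear,
    linearized_relaxation_rate,
    simulate_binding_ode,
    single_exponential,
)

rates_st = st.tuples(st.floats(1.0, 500.0), st.floats(0.01, 50.0))


class TestExponentials:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 0.20),                       # exp(0) = 1
        (1e6 / 100.0, 0.15),               # asymptote = offset
        (math.log(2) / 100.0, 0.175),      # half the amplitude gone at t1/2
    ])
    def test_single_exponential_values(self, t, expected):
        assert single_exponential(t, 0.05, 100.0, 0.15) == pytest.approx(expected, abs=1e-12)

    def test_single_exponential_monotone_toward_offset(self):
        t = np.linspace(0, 0.5, 400)
        y = single_exponential(t, 0.05, 30.0, 0.15)
        assert np.all(np.diff(y) < 0) and y[-1] > 0.15

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            single_exponential(-1e-3, 0.05, 100.0, 0.15)
        with pytest.raises(ValueError):
            double_exponential(-1e-3, 0.05, 10.0, 0.05, 100.0, 0.15)

    def test_double_reduces_to_single_when_second_amplitude_zero(self):
        t = np.linspace(0, 0.2, 101)
        np.testing.assert_allclose(
            double_exponential(t, 0.05, 80.0, 0.0, 9999.0, 0.1),
            single_exponential(t, 0.05, 80.0, 0.1), rtol=0, atol=0)

    def test_double_exponential_point_values(self):
        assert double_exponential(0.0, 0.03, 10, 0.02, 1000, 0.1) == pytest.approx(0.15)
        expected = 0.1 + 0.025 * math.exp(-0.007) + 0.025 * math.exp(-0.7)
        assert double_exponential(7e-4, 0.025, 10, 0.025, 1000, 0.1) == pytest.approx(expected, rel=1e-12)


class TestObservedRateLaws:
    @pytest.mark.parametrize("k_on, k_off, conc, expected", [
        (400.0, 6.2, 0.0, 6.2),
        (400.0, 6.2, 1.0, 406.2),
        (51.5, 7.0, 1.0, 58.5),
    ])
    def test_kobs_linear(self, k_on, k_off, conc, expected):
        assert kobs_linear(RateParameters(k_on, k_off), conc) == pytest.approx(expected)

    @pytest.mark.parametrize("k_off, kd_nM, conc, expected", [
        (6.2, 15.5, 1.0, 406.2),
        (6.2, 15.5, 0.0, 6.2),
        (7.0, 7.0 / 51.5 * 1000, 1.0, 58.5),
    ])
    def test_kobs_dilution(self, k_off, kd_nM, conc, expected):
        assert kobs_dilution(k_off, kd_nM, conc) == pytest.approx(expected)

    def test_kobs_dilution_rejects_zero_Kd(self):
        with pytest.raises(ValueError):
            kobs_dilution(6.2, 0.0, 1.0)

    @given(k_off=st.floats(0.01, 50.0), kd=st.floats(0.1, 1e4), conc=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_dilution_and_linear_forms_are_identical(self, k_off, kd, conc):
        """k_off([P]/K_d + 1) is the k_obs line with slope k_on = k_off/K_d."""
        k_on = k_off / kd * 1000.0  # nM -> uM conversion of K_d
        rate = RateParameters(k_on, k_off)
        assert kobs_dilution(k_off, kd, conc) == pytest.approx(
            kobs_linear(rate, conc), rel=1e-12)


class TestKd:
    @pytest.mark.parametrize("k_on, k_off, expected", [
        (400.0, 6.2, 15.5),
        (81.0, 4.8, 59.259259),
        (1.0, 1.0, 1000.0),
    ])
    def test_values(self, k_on, k_off, expected):
        assert compute_Kd(k_on, k_off) == pytest.approx(expected, rel=1e-6)

    def test_rejects_nonpositive_kon(self):
        with pytest.raises(ValueError):
            compute_Kd(0.0, 5.0)

    @given(k_off=st.floats(1e-3, 100.0), kd_target=st.floats(1e-2, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, k_off, kd_target):
        k_on = k_off / kd_target * 1000.0
        assert compute_Kd(k_on, k_off) == pytest.approx(kd_target, rel=1e-12)

    def test_rate_parameters_Kd_consistent(self):
        r = RateParameters(400.0, 6.2)
        assert r.K_d == pytest.approx(r.k_off / r.k_on * 1000.0, rel=1e-9)
        assert math.isinf(RateParameters(0.0, 5.0).K_d)


class TestLifetime:
    def test_eif4f_lifetime(self):
        tau = complex_lifetime(RateParameters(81.0, 4.8), 0.5, 0.1)
        assert tau * 1000 == pytest.approx(18.73, rel=1e-3)

    def test_irp1_lifetime(self):
        tau = complex_lifetime(RateParameters(400.0, 6.2), 0.05, 1.0)
        assert tau * 1000 == pytest.approx(2.346, rel=1e-3)

    def test_pure_dissociation_limit(self):
        tau = complex_lifetime(RateParameters(0.0, 10.0), 0.3, 0.7)
        assert tau == pytest.approx(0.1)

    def test_lifetime_input_form(self):
        inp = LifetimeInput(RateParameters(81.0, 4.8), 0.5, 0.1)
        assert complex_lifetime(inp) == pytest.approx(1.0 / 53.4)

    @given(st.floats(1.0, 500.0), st.floats(0.01, 50.0),
           st.floats(0.001, 5.0), st.floats(0.001, 5.0))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_in_each_argument(self, k_on, k_off, rna, prot):
        rate = RateParameters(k_on, k_off)
        tau = complex_lifetime(rate, rna, prot)
        assert complex_lifetime(RateParameters(k_on * 1.5, k_off), rna, prot) < tau
        assert complex_lifetime(RateParameters(k_on, k_off + 1.0), rna, prot) < tau
        assert complex_lifetime(rate, rna * 1.5, prot) < tau
        assert complex_lifetime(rate, rna, prot * 1.5) < tau


class TestOde:
    def test_no_rates_no_complex_stays_flat(self):
        rate = RateParameters(0.0, 0.0)
        system = BindingSystem.single(0.05, 1.0, rate)
        traj = simulate_binding_ode(system, np.linspace(0, 1, 50))
        np.testing.assert_allclose(traj.complex_total(), 0.0, atol=1e-15)
        np.testing.assert_allclose(traj.rna_free, 0.05, atol=1e-12)

    def test_equilibrium_matches_mass_balance_quadratic(self, frt_system, frt_irp1_rates):
        k_obs = kobs_linear(frt_irp1_rates, 1.0)
        t = np.linspace(0, 50.0 / k_obs, 100)
        traj = simulate_binding_ode(frt_system, t)
        c, r, p = (traj.complexes["IRP1"][-1], traj.rna_free[-1],
                   traj.protein_free["IRP1"][-1])
        assert c / (r * p) == pytest.approx(1000.0 / frt_irp1_rates.K_d, rel=1e-3)
        c_closed = equilibrium_complex(0.05, 1.0, frt_irp1_rates.K_d)
        assert c == pytest.approx(c_closed, abs=1e-8)

    def test_mass_conservation(self, frt_system):
        t = np.linspace(0, 0.5, 400)
        traj = simulate_binding_ode(frt_system, t)
        rna_tot = traj.rna_free + traj.complex_total()
        prot_tot = traj.protein_free["IRP1"] + traj.complexes["IRP1"]
        assert np.max(np.abs(rna_tot - 0.05)) < 1e-8
        assert np.max(np.abs(prot_tot - 1.0)) < 1e-8

    def test_concentrations_never_negative(self, frt_system):
        traj = simulate_binding_ode(frt_system, np.linspace(0, 1.0, 300))
        for arr in (traj.rna_free, traj.complex_total(), traj.protein_free["IRP1"]):
            assert np.all(arr >= 0)

    @pytest.mark.parametrize("protein_excess, max_rel_err, should_exceed", [
        (400.0, 0.01, False),   # deep pseudo-first-order: linear law holds
        (1.0, 0.01, True),      # equimolar: deviation well beyond 1%
    ])
    def test_pseudo_first_order_limit_of_fitted_rate(self, frt_irp1_rates,
                                                     protein_excess, max_rel_err,
                                                     should_exceed):
        """The single-exp rate of the ODE course approaches k_on[P]+k_off as
        protein excess grows; the deviation scales like R_total/P_total."""
        from stopflow import KineticTrace, fit_single_exponential

        prot = 1.0
        rna = prot / protein_excess
        system = BindingSystem.single(rna, prot, frt_irp1_rates)
        k_lin = kobs_linear(frt_irp1_rates, prot)
        t = np.linspace(1e-4, 10.0 / k_lin, 800)
        traj = simulate_binding_ode(system, t)
        trace = KineticTrace(t, traj.complex_total(), "anisotropy")
        fitted = fit_single_exponential(trace).k_obs
        rel_err = abs(fitted - k_lin) / k_lin
        assert (rel_err > max_rel_err) == should_exceed

    def test_initial_complex_relaxes_at_linearized_rate(self, frt_irp1_rates):
        """After dilution, the ODE decay rate matches k_on([R]f+[P]f)+k_off."""
        c0 = equilibrium_complex(0.1, 2.0, frt_irp1_rates.K_d) / 2
        system = BindingSystem.single(0.05, 1.0, frt_irp1_rates,
                                      initial_complex_uM=c0)
        k_relax = linearized_relaxation_rate(0.05, 1.0, frt_irp1_rates)
        t = np.linspace(0, 10.0 / k_relax, 500)
        traj = simulate_binding_ode(system, t)
        c = traj.complex_total()
        c_eq = equilibrium_complex(0.05, 1.0, frt_irp1_rates.K_d)
        # perturbation is small (2x dilution), so decay is near-exponential
        dev = c - c_eq
        mask = np.abs(dev) > 1e-5 * abs(dev[0])
        slope = np.polyfit(t[mask], np.log(np.abs(dev[mask])), 1)[0]
        assert -slope == pytest.approx(k_relax, rel=0.02)


class TestCompetition:
    def test_symmetric_partition(self):
        part = equilibrium_partition(0.01, 0.1, 0.1, 50.0, 50.0)
        assert part.fraction_bound[0] == pytest.approx(part.fraction_bound[1], rel=1e-9)
        assert sum(part.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_irp1_wins_without_metal(self):
        part = equilibrium_partition(0.01, 0.1, 0.1, 15.5, 59.26)
        assert part.fraction_bound[0] > part.fraction_bound[1]

    def test_eif4f_wins_at_high_mn(self):
        part = equilibrium_partition(0.01, 0.1, 0.1, 184.6, 7.9)
        assert part.fraction_bound[1] > part.fraction_bound[0]

    def test_partition_matches_ode_steady_state(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            rna = rng.uniform(0.001, 0.2)
            p1, p2 = rng.uniform(0.01, 2.0, 2)
            kon1, kon2 = rng.uniform(5, 500, 2)
            koff1, koff2 = rng.uniform(0.5, 30, 2)
            r1, r2 = RateParameters(kon1, koff1), RateParameters(kon2, koff2)
            part = equilibrium_partition(rna, p1, p2, r1.K_d, r2.K_d)
            system = BindingSystem(rna, (Protein("a", p1, r1), Protein("b", p2, r2)))
            slowest = min(koff1, koff2)
            t = np.linspace(0, 30.0 / slowest, 30)
            traj = simulate_binding_ode(system, t)
            assert traj.complexes["a"][-1] == pytest.approx(part.complex_uM[0], abs=1e-6)
            assert traj.complexes["b"][-1] == pytest.approx(part.complex_uM[1], abs=1e-6)

    def test_kinetic_partition_values(self):
        r_irp = RateParameters(400.0, 6.2)
        r_eif = RateParameters(81.0, 4.8)
        f = kinetic_partition(0.1, 0.1, r_irp, r_eif)
        assert f[0] == pytest.approx(400.0 / 481.0, rel=1e-9)
        f50 = kinetic_partition(0.1, 0.1, RateParameters(65.0, 12.0),
                                RateParameters(228.0, 1.8))
        assert f50[1] == pytest.approx(228.0 / 293.0, rel=1e-9)

    def test_kinetic_partition_symmetry_and_errors(self):
        r = RateParameters(100.0, 1.0)
        assert kinetic_partition(0.2, 0.2, r, r) == pytest.approx((0.5, 0.5))
        with pytest.raises(ValueError):
            kinetic_partition(0.0, 0.0, r, r)


class TestValidation:
    def test_rate_parameters_reject_negative_kon(self):
        with pytest.raises(ValueError):
            RateParameters(-1.0, 5.0)

    def test_negative_koff_warns_not_raises(self):
        with pytest.warns(RuntimeWarning):
            RateParameters(100.0, -0.5)

    def test_binding_system_limits(self):
        r = RateParameters(100.0, 1.0)
        with pytest.raises(ValueError):
            BindingSystem(-0.1, (Protein("p", 1.0, r),))
        with pytest.raises(ValueError):
            BindingSystem(0.1, tuple(Protein(f"p{i}", 1.0, r) for i in range(3)))
        with pytest.raises(ValueError):
            BindingSystem(0.05, (Protein("p", 1.0, r, initial_complex_uM=0.2),))
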