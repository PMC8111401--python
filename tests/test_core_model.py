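import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from radpk import (
    DoseEvent,
    RadiationEffect,
    apply_radiation,
    auc_infinity,
    disposition_eigenvalues,
    micro_constants,
    solve,
    terminal_half_life,
)
from radpk.core_model import conc_and_urine

from conftest import random_pk_parameters


def numerical_oracle(p, d, times):
    """Adaptive stiff ODE integration of the compartment system."""
    mc = micro_constants(p)
    f = p.F if d.route == "gavage" else 1.0

    def rhs(_, y):
        dep, pla, per, _uri = y
        c = pla / p.V2
        return [
            -p.ka * dep,
            f * p.ka * dep - p.Cl * c - p.Q * c + p.Q * per / p.V3,
            p.Q * c - p.Q * per / p.V3,
            p.Cl * c,
        ]

    y0 = [d.amount, 0, 0, 0] if d.route == "gavage" else [0, d.amount, 0, 0]
    sol = solve_ivp(
        rhs, (0, max(times)), y0, t_eval=times, method="Radau",
        rtol=1e-11, atol=1e-14 * d.amount,
    )
    return sol.y.T


class TestMicroConstants:
    def test_reference_values(self, control):
        mc = micro_constants(control)
        assert mc.k10 == pytest.approx(1.125, rel=1e-12)
        assert mc.k12 == pytest.approx(1.75, rel=1e-12)
        assert mc.k21 == pytest.approx(0.02729044834307992, rel=1e-12)

    def test_no_exchange(self, control):
        mc = micro_constants(replace(control, Q=0.0))
        assert mc.k12 == 0.0 and mc.k21 == 0.0

    def test_equal_volumes_symmetry(self, control):
        mc = micro_constants(replace(control, V2=0.1, V3=0.1))
        assert mc.k12 == mc.k21

    def test_nonpositive_volume_rejected(self, control):
        with pytest.raises(ValueError):
            replace(control, V2=0.0)


class TestDispositionEigenvalues:
    def test_reference_beta_against_quadratic_roots(self, control):
        mc = micro_constants(control)
        alpha, beta = disposition_eigenvalues(mc)
        # oracle: roots of x^2 - (k10+k12+k21) x + k10 k21
        roots = np.roots([1.0, -(mc.k10 + mc.k12 + mc.k21), mc.k10 * mc.k21])
        assert beta == pytest.approx(min(roots), rel=1e-10)
        assert alpha == pytest.approx(max(roots), rel=1e-10)
        assert beta == pytest.approx(0.010617297593959149, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_vieta_relations(self, seed):
        rng = np.random.default_rng(seed)
        p = random_pk_parameters(rng)
        mc = micro_constants(p)
        alpha, beta = disposition_eigenvalues(mc)
        assert alpha >= beta >= 0
        assert alpha + beta == pytest.approx(mc.k10 + mc.k12 + mc.k21, rel=1e-10)
        assert alpha * beta == pytest.approx(mc.k10 * mc.k21, rel=1e-8, abs=1e-14)

    def test_decoupled_when_no_exchange(self, control):
        mc = micro_constants(replace(control, Q=0.0))
        alpha, beta = disposition_eigenvalues(mc)
        assert alpha == pytest.approx(mc.k10) and beta == 0.0

    def test_no_elimination(self, control):
        mc = micro_constants(replace(control, Cl=0.0))
        _, beta = disposition_eigenvalues(mc)
        assert beta == 0.0


class TestTerminalHalfLife:
    def test_control_is_65_hours(self, control):
        assert terminal_half_life(control) == pytest.approx(65.2847, abs=1e-3)

    def test_irradiated_is_83_hours(self, control, ratios):
        t = terminal_half_life(apply_radiation(control, ratios))
        assert t == pytest.approx(83.5269, abs=1e-3)

    def test_one_compartment_limit(self, control):
        # as V3 -> 0 the peripheral pool vanishes: t1/2 -> ln2 V2 / Cl
        t = terminal_half_life(replace(control, V3=1e-9))
        assert t == pytest.approx(math.log(2) * control.V2 / control.Cl, rel=1e-4)

    def test_non_eliminating_model_reported(self, control):
        with pytest.raises(ValueError, match="no terminal elimination"):
            terminal_half_life(replace(control, Cl=0.0))


class TestApplyRadiation:
    def test_reference_products(self, control, ratios):
        p = apply_radiation(control, ratios)
        assert p.ka == pytest.approx(0.246357, rel=1e-9)
        assert p.Cl == pytest.approx(0.008487, rel=1e-9)
        assert p.Q == pytest.approx(0.008610, rel=1e-9)
        assert p.F == pytest.approx(0.254592, rel=1e-9)
        assert (p.V2, p.V3) == (control.V2, control.V3)

    def test_identity_ratios(self, control):
        assert apply_radiation(control, RadiationEffect(1, 1, 1, 1)) == control

    def test_bioavailability_bound(self, control):
        with pytest.raises(ValueError, match="exceeds 1"):
            apply_radiation(control, RadiationEffect(1, 1, 1, 6.0))


class TestSolve:
    def test_iv_initial_concentration(self, control, iv_60):
        traj = solve(control, iv_60, [0.0])
        assert traj.conc_plasma[0] == pytest.approx(18.4957, abs=1e-3)

    def test_urinary_recovery_asymptote(self, control, gavage_300, iv_60):
        po = solve(control, gavage_300, [2e5])
        assert po.urine[-1] == pytest.approx(control.F * gavage_300.amount, rel=1e-6)
        iv = solve(control, iv_60, [2e5])
        assert iv.urine[-1] == pytest.approx(iv_60.amount, rel=1e-6)

    @pytest.mark.parametrize("route", ["gavage", "iv"])
    @pytest.mark.parametrize("seed", range(5))
    def test_mass_balance_and_monotonicity(self, route, seed):
        rng = np.random.default_rng(seed)
        p = random_pk_parameters(rng)
        d = DoseEvent(amount=1.0, route=route)
        times = np.sort(rng.uniform(0, 100, 25))
        traj = solve(p, d, times)
        if route == "iv":
            total = traj.plasma + traj.peri + traj.urine
            assert np.allclose(total, d.amount, rtol=1e-8)
        else:
            total = traj.plasma + traj.peri + traj.urine + p.F * traj.depot
            assert np.allclose(total, p.F * d.amount, rtol=1e-8)
        assert np.all(np.diff(traj.urine) >= -1e-12)
        assert np.all(np.diff(traj.depot) <= 1e-12)

    def test_dose_linearity(self, control):
        times = [0.5, 2.0, 8.0, 24.0]
        t1 = solve(control, DoseEvent(0.5, "gavage"), times)
        t2 = solve(control, DoseEvent(1.5, "gavage"), times)
        for field in ("depot", "plasma", "peri", "urine"):
            assert np.allclose(getattr(t2, field), 3.0 * getattr(t1, field), rtol=1e-10)

    @pytest.mark.parametrize("route", ["gavage", "iv"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_integration(self, route, seed):
        rng = np.random.default_rng(100 + seed)
        p = random_pk_parameters(rng)
        d = DoseEvent(amount=float(rng.uniform(0.1, 2.0)), route=route)
        times = [0.5, 2.0, 8.0, 24.0]
        traj = solve(p, d, times)
        ref = numerical_oracle(p, d, times)
        ours = np.column_stack([traj.depot, traj.plasma, traj.peri, traj.urine])
        assert np.allclose(ours, ref, rtol=1e-8, atol=1e-8 * d.amount)

    def test_terminal_slope_equals_beta(self, control, gavage_300):
        times = np.linspace(200.0, 400.0, 40)
        traj = solve(control, gavage_300, times)
        slope = np.polyfit(times, np.log(traj.conc_plasma), 1)[0]
        _, beta = disposition_eigenvalues(micro_constants(control))
        assert slope == pytest.approx(-beta, rel=0.01)

    def test_input_validation(self, control, gavage_300):
        with pytest.raises(ValueError, match="non-decreasing"):
            solve(control, gavage_300, [2.0, 1.0])
        with pytest.raises(ValueError):
            solve(control, DoseEvent(1.0, "gavage", time=5.0), [1.0])

    @pytest.mark.parametrize("route", ["gavage", "iv"])
    @pytest.mark.parametrize("seed", range(5))
    def test_fast_path_matches_exact_solver(self, route, seed):
        rng = np.random.default_rng(200 + seed)
        p = random_pk_parameters(rng)
        d = DoseEvent(amount=1.0, route=route)
        times = np.sort(rng.uniform(0.01, 60, 12))
        traj = solve(p, d, times)
        mc = micro_constants(p)
        conc, urine = conc_and_urine(
            p.ka, p.F if route == "gavage" else 1.0,
            mc.k10, mc.k12, mc.k21, p.V2, d.amount, route == "iv", times,
        )
        assert np.allclose(conc, traj.conc_plasma, rtol=1e-8, atol=1e-12)
        assert np.allclose(urine, traj.urine, rtol=1e-8, atol=1e-12)


class TestAucInfinity:
    def test_control_gavage_closed_form(self, control, gavage_300):
        # F * dose / Cl with the reference values
        assert auc_infinity(control, gavage_300) == pytest.approx(15.78298, abs=1e-4)

    def test_iv_independent_of_bioavailability(self, control, iv_60):
        low_f = replace(control, F=0.05)
        assert auc_infinity(control, iv_60) == auc_infinity(low_f, iv_60)

    def test_matches_quadrature_of_solution(self, control, gavage_300):
        # dense near the absorption peak, coarser along the slow terminal tail
        times = np.concatenate(
            [np.linspace(0.0, 48.0, 961), np.linspace(48.5, 3000.0, 900)]
        )
        traj = solve(control, gavage_300, times)
        auc_num = np.trapezoid(traj.conc_plasma, times)
        assert auc_num == pytest.approx(auc_infinity(control, gavage_300), rel=1e-3)

    def test_divergent_without_elimination(self, control, gavage_300):
        assert auc_infinity(replace(control, Cl=0.0), gavage_300) == math.inf
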