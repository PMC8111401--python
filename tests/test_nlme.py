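import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize

import radpk
from radpk import (
    DoseEvent,
    ErrorModel,
    FitConfig,
    FitError,
    RandomEffects,
    dose_to_umol,
    individual_parameters,
    lrt,
    marginal_loglik,
    r_squared,
    solve,
)
from radpk.data_etl import DesignCell, StudyDesign
from radpk.nlme import FitResult, fit


class TestIndividualParameters:
    def test_zero_eta_is_identity(self, control):
        assert individual_parameters(control, (0.0, 0.0)) == control

    def test_log_scale_action(self, control):
        p = individual_parameters(control, (math.log(2), 0.0))
        assert p.V2 == pytest.approx(2 * control.V2)
        assert p.V3 == control.V3

    def test_median_of_lognormal_draws_is_typical_value(self, control):
        rng = np.random.default_rng(0)
        v2s = [
            individual_parameters(control, (e, 0.0)).V2
            for e in rng.normal(0, 0.3, 4001)
        ]
        assert np.median(v2s) == pytest.approx(control.V2, rel=0.03)


def gaussian_residual_loglik(theta, error, records):
    """Independent oracle: plain Gaussian log-likelihood of the residuals,
    with predictions from the exact matrix-exponential solver."""
    ll = 0.0
    for r in records:
        d = DoseEvent(dose_to_umol(r.dose_ug), r.route)
        traj = solve(theta, d, [r.time_h])
        pred = traj.conc_plasma[0] if r.compartment == "plasma" else traj.urine[0]
        sig = error.sigma_plasma if r.compartment == "plasma" else error.sigma_urine
        ll += -0.5 * ((r.value - pred) / sig) ** 2 - math.log(sig) - 0.5 * math.log(2 * math.pi)
    return ll


def agh_marginal_loglik(theta, error, eta_sd, records, nq=40):
    """Independent oracle: adaptive Gauss-Hermite quadrature of the marginal
    likelihood, mode and curvature found with Nelder-Mead and plain finite
    differences, model values from the exact solver."""
    xg, wg = hermgauss(nq)
    total = 0.0
    for aid in sorted({r.animal_id for r in records}):
        rows = [r for r in records if r.animal_id == aid]
        d = DoseEvent(dose_to_umol(rows[0].dose_ug), rows[0].route)
        ts = sorted({r.time_h for r in rows})

        def logjoint(eta):
            p_i = individual_parameters(theta, eta)
            traj = solve(p_i, d, ts)
            ll = 0.0
            for r in rows:
                k = ts.index(r.time_h)
                pred = traj.conc_plasma[k] if r.compartment == "plasma" else traj.urine[k]
                sig = error.sigma_plasma if r.compartment == "plasma" else error.sigma_urine
                ll += -0.5 * ((r.value - pred) / sig) ** 2 - math.log(sig)
                ll -= 0.5 * math.log(2 * math.pi)
            for e, om in zip(eta, (eta_sd.omega_V2, eta_sd.omega_V3)):
                ll += -0.5 * (e / om) ** 2 - math.log(om) - 0.5 * math.log(2 * math.pi)
            return ll

        res = minimize(
            lambda e: -logjoint(e), np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 4000},
        )
        mode = res.x
        h = 1e-5
        f0 = logjoint(mode)
        hess = np.zeros((2, 2))
        for i in range(2):
            e = np.zeros(2); e[i] = h
            hess[i, i] = -(logjoint(mode + e) + logjoint(mode - e) - 2 * f0) / h**2
        e0, e1 = np.array([h, 0.0]), np.array([0.0, h])
        hess[0, 1] = hess[1, 0] = -(
            logjoint(mode + e0 + e1) + logjoint(mode - e0 - e1)
            - logjoint(mode + e0 - e1) - logjoint(mode - e0 + e1)
        ) / (4 * h**2)
        chol = np.linalg.cholesky(np.linalg.inv(hess))
        vals = np.empty((nq, nq))
        for i, x1 in enumerate(xg):
            for j, x2 in enumerate(xg):
                eta = mode + math.sqrt(2) * (chol @ np.array([x1, x2]))
                vals[i, j] = logjoint(eta) + x1 * x1 + x2 * x2
        logw = np.log(np.outer(wg, wg))
        m = (vals + logw).max()
        total += (
            math.log(2) + float(np.log(np.diag(chol)).sum())
            + m + math.log(np.exp(vals + logw - m).sum())
        )
    return total


class TestMarginalLoglik:
    def test_degenerate_random_effects_equal_closed_form(self, control, two_animal_toy):
        err = ErrorModel(0.05, 0.005)
        ll = marginal_loglik(control, None, err, RandomEffects(0.0, 0.0), two_animal_toy)
        assert ll == pytest.approx(
            gaussian_residual_loglik(control, err, two_animal_toy), abs=1e-8
        )

    def test_laplace_matches_adaptive_quadrature(self, control, two_animal_toy):
        err = ErrorModel(0.01, 0.001)
        eta_sd = RandomEffects(0.015, 0.015)
        lap = marginal_loglik(control, None, err, eta_sd, two_animal_toy)
        agh = agh_marginal_loglik(control, err, eta_sd, two_animal_toy)
        assert lap == pytest.approx(agh, abs=1e-4)

    @pytest.mark.parametrize("omegas", [(0.0, 0.0), (0.1, 0.1)])
    def test_duplicating_animals_doubles_loglik(self, control, two_animal_toy, omegas):
        err = ErrorModel(0.05, 0.005)
        eta_sd = RandomEffects(*omegas)
        base = marginal_loglik(control, None, err, eta_sd, two_animal_toy)
        dup = two_animal_toy + [
            replace(r, animal_id=r.animal_id + "_copy") for r in two_animal_toy
        ]
        assert marginal_loglik(control, None, err, eta_sd, dup) == pytest.approx(
            2 * base, rel=1e-9
        )

    def test_invariant_to_relabelling_and_reordering(self, control, two_animal_toy):
        err = ErrorModel(0.05, 0.005)
        eta_sd = RandomEffects(0.2, 0.2)
        base = marginal_loglik(control, None, err, eta_sd, two_animal_toy)
        renamed = [
            replace(r, animal_id={"a1": "zz", "a2": "qq"}[r.animal_id])
            for r in reversed(two_animal_toy)
        ]
        assert marginal_loglik(control, None, err, eta_sd, renamed) == pytest.approx(
            base, abs=1e-6
        )


def dense_two_group_design():
    return StudyDesign(
        cells=(
            DesignCell("control", "gavage", 300.0, 4, True, 6),
            DesignCell("control", "iv", 60.0, 3, True, 4),
            DesignCell("irradiated", "gavage", 300.0, 4, True, 6),
            DesignCell("irradiated", "iv", 60.0, 3, True, 4),
        )
    )


class TestFit:
    def test_noiseless_dense_data_recovers_structural_parameters(
        self, control, ratios
    ):
        """With dense noise-free data the optimum must reproduce the
        generating values to well under 1%."""
        cfg = radpk.default_config(
            seed=5,
            design=dense_two_group_design(),
            eta_sd=RandomEffects(1e-12, 1e-12),
            error=ErrorModel(1e-12, 1e-12),
        )
        data = radpk.simulate_study(cfg)
        res = fit(
            data,
            config=FitConfig(
                fix_omega=(0.0, 0.0), fix_sigma=(1e-4, 1e-5), compute_ci=False
            ),
        )
        for name, truth in {
            "ka": control.ka, "F": control.F, "Cl": control.Cl, "Q": control.Q,
            "V2": control.V2, "V3": control.V3,
            "r_ka": ratios.r_ka, "r_Cl": ratios.r_Cl,
            "r_Q": ratios.r_Q, "r_F": ratios.r_F,
        }.items():
            assert res.estimates[name] == pytest.approx(truth, rel=0.01), name

    def test_single_animal_rejected(self, two_animal_toy):
        solo = [r for r in two_animal_toy if r.animal_id == "a1"]
        with pytest.raises(FitError):
            fit(solo)

    def test_inconsistent_animal_metadata_rejected(self, two_animal_toy):
        bad = two_animal_toy + [
            replace(two_animal_toy[0], route="iv", time_h=9.0)
        ]
        with pytest.raises(FitError, match="inconsistent"):
            fit(bad)

    def test_missing_iv_arm_warns(self, control):
        cfg = radpk.default_config(
            seed=6,
            design=StudyDesign(
                cells=(
                    DesignCell("control", "gavage", 300.0, 4, True, 5),
                    DesignCell("irradiated", "gavage", 300.0, 4, True, 5),
                )
            ),
        )
        data = radpk.simulate_study(cfg)
        with pytest.warns(UserWarning, match="no IV arm"):
            fit(
                data,
                config=FitConfig(
                    compute_ci=False, n_restarts=1, maxiter=5, grad_scheme="forward"
                ),
            )


class TestLrt:
    def test_identical_likelihoods(self):
        a = _dummy_fit(loglik=-10.0, n_params=14)
        b = _dummy_fit(loglik=-10.0, n_params=10)
        cmpr = lrt(a, b)
        assert cmpr.lrt_stat == 0.0 and cmpr.p_value == 1.0

    def test_chi_square_tail(self):
        a = _dummy_fit(loglik=-5.0, n_params=12)
        b = _dummy_fit(loglik=-10.0, n_params=10)
        cmpr = lrt(a, b)
        assert cmpr.lrt_stat == pytest.approx(10.0)
        assert cmpr.p_value == pytest.approx(0.006737946999085468, rel=1e-9)

    def test_negative_statistic_flags_failure(self):
        a = _dummy_fit(loglik=-20.0, n_params=14)
        b = _dummy_fit(loglik=-10.0, n_params=10)
        with pytest.raises(ValueError, match="negative LRT statistic"):
            lrt(a, b)


def _dummy_fit(loglik, n_params, predictions=None, error=None):
    return FitResult(
        theta=radpk.CONTROL_PARAMS,
        ratios=None,
        error=error or ErrorModel(1.0, 1.0),
        eta_sd=RandomEffects(0.0, 0.0),
        loglik=loglik,
        estimates={},
        ci={},
        pvalues={},
        predictions=predictions if predictions is not None else pd.DataFrame(),
        converged=True,
        n_params=n_params,
        n_animals=2,
        n_obs=10,
        model="two_compartment",
    )


class TestRSquared:
    def _result(self, obs, pred, compartment="plasma"):
        df = pd.DataFrame(
            {
                "compartment": [compartment] * len(obs),
                "observed": obs,
                "pred_individual": pred,
                "included": [True] * len(obs),
            }
        )
        return _dummy_fit(0.0, 14, predictions=df)

    def test_perfect_predictions(self):
        assert r_squared(self._result([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 1.0

    def test_mean_predictor_scores_zero(self):
        assert r_squared(self._result([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])) == pytest.approx(0.0)

    def test_single_compartment_arithmetic(self):
        assert r_squared(self._result([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_zero_variance_reported(self):
        with pytest.raises(ValueError, match="undefined"):
            r_squared(self._result([2.0, 2.0], [1.0, 2.0]))
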