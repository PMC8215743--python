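"""Extended probit: likelihood oracles, recovery, treatment effects, margins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

import statsmodels.api as sm

from icumort.binary import ModelSpec, fit_binary
from icumort.endogenous import (
    ErmSpec,
    _ErmData,
    _loglik_obs,
    _staged_start,
    bvn_cdf,
    erm_loglik,
    exogeneity_check,
    fit_erm,
    margins_grid,
    treatment_effects,
)
from icumort.pipeline import prepare_table
from icumort.registry import RegistryConfig, generate_registry

STAGE = ("severity_c", "C(hospital_level)", "C(volume_decile)", "C(dx_category)")
FULL_SPEC = ErmSpec(outcome="died", outcome_terms=("age_c", "severity_c"),
                    treatment="ventilated", treatment_terms=STAGE,
                    endog_cont="log_hlos", cont_terms=STAGE + ("ventilated",))
# compact system for tiny-fixture likelihood oracles (full-rank at 100 rows)
SMALL_STAGE = ("severity_c", "C(hospital_level)")
SMALL_SPEC = ErmSpec(outcome="died", outcome_terms=("age_c", "severity_c"),
                     treatment="ventilated", treatment_terms=SMALL_STAGE,
                     endog_cont="log_hlos", cont_terms=SMALL_STAGE + ("ventilated",))


def _handset_theta(data, rho=0.0):
    """A plausible hand-set parameter vector (no fitting; oracles only)."""
    theta = np.zeros(data.k)
    for i, name in enumerate(data.param_names):
        if name.endswith("Intercept"):
            theta[i] = -1.0 if name.startswith("outcome") else 0.5
        elif "severity_c" in name:
            theta[i] = 0.02
        elif name == "log_sigma_h":
            theta[i] = np.log(0.8)
        elif name.startswith("atanh_rho"):
            theta[i] = np.arctanh(rho)
        elif ":" in name:
            theta[i] = 0.1
    return theta


@pytest.fixture(scope="module")
def exo_fit(exogenous_cohort):
    """Full ERM fitted on the no-correlation cohort."""
    import warnings

    t, _ = exogenous_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_erm(t, FULL_SPEC)
    return t, fit


class TestBvnCdf:
    def test_matches_scipy_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            h, k = rng.normal(0, 2, 2)
            r = rng.uniform(-0.98, 0.98)
            ref = multivariate_normal.cdf([h, k], mean=[0, 0], cov=[[1, r], [r, 1]])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("h,k,r", [
        (0.0, 0.0, 0.5), (0.0, 1.0, -0.7), (2.0, -2.0, 0.9),
        (1.0, 1.0, 0.999), (-5.0, -5.0, 0.95), (5.0, 5.0, -0.5),
    ])
    def test_edge_cases(self, h, k, r):
        ref = multivariate_normal.cdf([h, k], mean=[0, 0], cov=[[1, r], [r, 1]])
        assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-9, rel=1e-6)

    def test_independence_product(self):
        from scipy.special import ndtr

        assert bvn_cdf(0.7, -1.2, 0.0) == pytest.approx(
            ndtr(0.7) * ndtr(-1.2), abs=1e-12)


class TestLoglik:
    def test_factorizes_with_zero_correlations(self, exogenous_cohort):
        """With all ρ = 0 the joint likelihood is exactly the sum of the
        probit (treatment), Normal (log HLOS) and probit (mortality) parts."""
        t, _ = exogenous_cohort
        t100 = t.iloc[:100]
        data = _ErmData(t100, SMALL_SPEC)
        theta = _handset_theta(data)
        p = data.unpack(theta)

        total = erm_loglik(theta, t100, SMALL_SPEC)

        a_v = data.Xv @ p["gamma"]
        s_v = 2 * data.v - 1
        ll_v = stats.norm.logcdf(s_v * a_v).sum()
        e = data.h - data.Xh @ p["delta"]
        ll_h = stats.norm.logpdf(e, scale=p["sigma_h"]).sum()
        a_m = data.outcome_index(p["beta"])
        s_m = 2 * data.m - 1
        ll_m = stats.norm.logcdf(s_m * a_m).sum()
        assert total == pytest.approx(ll_v + ll_h + ll_m, abs=1e-10)

    def test_monte_carlo_oracle_five_observations(self):
        """Per-observation contributions match brute-force Monte-Carlo
        integration of the latent trivariate model within 3 MC SEs."""
        rows = pd.DataFrame({
            "died": [1, 0, 1, 0, 0],
            "ventilated": [1, 0, 0, 1, 0],
            "log_hlos": [2.1, 1.4, 2.9, 0.7, 1.9],
            "age_c": [5.0, -10.0, 0.0, 20.0, -3.0],
            "severity_c": [30.0, -20.0, 80.0, 0.0, 10.0],
            "z_iv": [1.0, -0.5, 0.0, 2.0, -1.0],
        })
        spec = ErmSpec(outcome="died", outcome_terms=("age_c", "severity_c"),
                       treatment="ventilated", treatment_terms=("z_iv",),
                       endog_cont="log_hlos", cont_terms=("z_iv", "ventilated"))
        data = _ErmData(rows, spec)
        # hand-set parameters (unconstrained scale)
        sigma, r_hm, r_vm, r_vh = 0.8, -0.3, -0.25, 0.12
        theta = np.array([
            -1.5, 0.01, 0.03, 0.3, 0.2,    # outcome: const, age, sev, V, logh
            0.1, 0.6,                       # treatment: const, z_iv
            1.8, 0.4, 0.3,                  # hlos: const, z_iv, V
            np.log(sigma), np.arctanh(r_hm), np.arctanh(r_vm), np.arctanh(r_vh),
        ])
        ll = _loglik_obs(theta, data)

        corr = np.array([[1.0, r_vh, r_vm], [r_vh, 1.0, r_hm], [r_vm, r_hm, 1.0]])
        rng = np.random.default_rng(123)
        n_mc = 2_000_000
        for i in range(5):
            e_h = rows.log_hlos[i] - (1.8 + 0.4 * rows.z_iv[i] + 0.3 * rows.ventilated[i])
            z = e_h / sigma
            # conditional distribution of (eps_v, eps_m) given eps_h
            mu = np.array([r_vh * z, r_hm * z])
            cov = np.array([[1 - r_vh**2, r_vm - r_vh * r_hm],
                            [r_vm - r_vh * r_hm, 1 - r_hm**2]])
            draws = rng.multivariate_normal(mu, cov, size=n_mc)
            a_v = 0.1 + 0.6 * rows.z_iv[i]
            a_m = (-1.5 + 0.01 * rows.age_c[i] + 0.03 * rows.severity_c[i]
                   + 0.3 * rows.ventilated[i] + 0.2 * rows.log_hlos[i])
            sv = 2 * rows.ventilated[i] - 1
            sm = 2 * rows.died[i] - 1
            inside = (sv * (a_v + draws[:, 0]) > 0) & (sm * (a_m + draws[:, 1]) > 0)
            p_hat = inside.mean()
            se = np.sqrt(p_hat * (1 - p_hat) / n_mc)
            p_analytic = np.exp(ll[i] - stats.norm.logpdf(e_h, scale=sigma))
            assert abs(p_analytic - p_hat) < 3 * se + 1e-12

    def test_per_observation_locality(self, exogenous_cohort):
        """Flipping one row's outcome changes only that row's contribution."""
        t, _ = exogenous_cohort
        t50 = t.iloc[:50].reset_index(drop=True)
        data = _ErmData(t50, SMALL_SPEC)
        theta = _handset_theta(data, rho=0.15)
        base = _loglik_obs(theta, data)
        flipped = t50.copy()
        flipped.loc[7, "died"] = 1 - flipped.loc[7, "died"]
        ll2 = _loglik_obs(theta, _ErmData(flipped, SMALL_SPEC))
        changed = np.flatnonzero(~np.isclose(base, ll2, atol=1e-12))
        assert changed.tolist() == [7]


class TestSpecValidation:
    def test_missing_instrument_rejected(self):
        spec = ErmSpec(outcome_terms=("severity_c",), treatment="ventilated",
                       treatment_terms=("severity_c",), endog_cont=None,
                       cont_terms=None)
        with pytest.raises(ValueError, match="excluded instrument"):
            spec.validate()

    def test_self_regression_rejected(self):
        spec = ErmSpec(outcome_terms=("severity_c",), treatment=None,
                       treatment_terms=None, endog_cont="log_hlos",
                       cont_terms=("log_hlos", "C(dx_category)"))
        with pytest.raises(ValueError, match="on itself"):
            spec.validate()

    def test_endogenous_variable_not_in_outcome_terms(self):
        spec = ErmSpec(outcome_terms=("severity_c", "ventilated"),
                       treatment="ventilated", treatment_terms=STAGE,
                       endog_cont=None, cont_terms=None)
        with pytest.raises(ValueError, match="ventilated"):
            spec.validate()

    def test_no_active_component_rejected(self):
        with pytest.raises(ValueError):
            ErmSpec(treatment=None, treatment_terms=None,
                    endog_cont=None, cont_terms=None).validate()


class TestFitErm:
    def test_exogeneity_reduction(self, exo_fit, exogenous_cohort):
        """ρ = 0 generator: correlation CIs cover 0 and the outcome
        coefficients match a plain probit within 3 SEs."""
        t, fit = exo_fit
        covered = sum(r.ci_lower <= 0.0 <= r.ci_upper for r in fit.rho.values())
        assert covered >= 2      # at least 2 of 3 CIs cover (95% nominal each)
        probit = fit_binary(t, ModelSpec(
            link="probit",
            covariates=("age_c", "severity_c", "ventilated", "log_hlos")))
        # the joint model's own (sandwich) SEs are the right yardstick: the
        # treatment/HLOS coefficients are far less precise once their error
        # correlations are free parameters
        se_erm = pd.Series(np.sqrt(np.diag(fit.vcov.values)), index=fit.param_names)
        for term in ("age_c", "severity_c", "ventilated", "log_hlos"):
            assert (abs(fit.beta[term] - probit.coefficients[term])
                    < 3 * se_erm[f"outcome:{term}"])

    def test_rho_strictly_inside_unit_interval(self, exo_fit):
        _, fit = exo_fit
        for r in fit.rho.values():
            assert -1.0 < r.estimate < 1.0
            assert -1.0 < r.ci_lower < r.ci_upper < 1.0

    def test_loglik_nests_independent_fits(self, exo_fit, exogenous_cohort):
        """The fitted joint log-likelihood is at least the stacked
        independent-equation value at the ρ = 0 staged start."""
        t, fit = exo_fit
        data = _ErmData(t, FULL_SPEC)
        theta0 = _staged_start(data)
        assert fit.loglik >= erm_loglik(theta0, t, FULL_SPEC) - 1e-6

    def test_aic_bic_definitions(self, exo_fit):
        _, fit = exo_fit
        k = len(fit.theta)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * np.log(fit.n_used))


class TestTreatmentEffects:
    def test_null_effect_ate_near_zero(self):
        """λ_V = 0 and ρ_vm = 0: the estimated ATE is within 2 SEs of 0."""
        cfg = RegistryConfig(n_patients=4000, n_sites=40, seed=31, site_sd=0.0,
                             corr_vm=0.0, corr_vh=0.0)
        cfg.beta_outcome.ventilated = 0.0
        t = prepare_table(generate_registry(cfg)[0])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_erm(t, FULL_SPEC)
            te = treatment_effects(fit, t)
        assert abs(te.ate) < 2 * te.ate_se + 0.01

    def test_counterfactual_oracle(self, exo_fit, exogenous_cohort):
        """ATE tracks the generator's true mean counterfactual difference,
        computed by direct simulation of both arms from TrueParameters."""
        t, fit = exo_fit
        _, truth = exogenous_cohort
        cfg = truth.config
        bo = cfg.beta_outcome
        dh = cfg.delta_hlos

        rng = np.random.default_rng(99)
        n_mc = 2000
        eps = rng.multivariate_normal(
            [0.0, 0.0],
            [[cfg.sigma_h**2, cfg.corr_hm * cfg.sigma_h],
             [cfg.corr_hm * cfg.sigma_h, 1.0]], size=n_mc)
        level = t["hospital_level"].cat.codes.to_numpy()
        decile = t["volume_decile"].cat.codes.to_numpy()
        dx = t["dx_category"].cat.codes.to_numpy()
        base_h = (dh.intercept + dh.severity * (t["severity"] - 55.0)
                  + np.asarray(dh.hospital_level)[level]
                  + np.asarray(dh.volume_decile)[decile]
                  + np.asarray(dh.dx_category)[dx]).to_numpy()
        base_m = (truth.outcome_intercept + bo.age * t["age_c"]
                  + bo.severity * t["severity_c"]).to_numpy()
        diffs = np.zeros(len(t))
        for arm, sign in ((1.0, 1.0), (0.0, -1.0)):
            h_arm = base_h[:, None] + dh.ventilated * arm + eps[:, 0][None, :]
            lat = (base_m[:, None] + bo.ventilated * arm + bo.log_hlos * h_arm
                   + eps[:, 1][None, :])
            diffs += sign * (lat > 0).mean(axis=1)
        true_ate = diffs.mean()
        te = treatment_effects(fit, t)
        assert abs(te.ate - true_ate) < 3 * te.ate_se

    def test_atet_equals_ate_under_random_assignment(self):
        """With treatment independent of covariates and errors, the treated
        are exchangeable with everyone: ATET ≈ ATE."""
        cfg = RegistryConfig(n_patients=5000, n_sites=40, seed=32, site_sd=0.0,
                             corr_vm=0.0, corr_vh=0.0)
        cfg.gamma_treatment.severity = 0.0
        cfg.gamma_treatment.hospital_level = (0.0,) * 4
        cfg.gamma_treatment.volume_decile = (0.0,) * 10
        t = prepare_table(generate_registry(cfg)[0])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_erm(t, ErmSpec(
                outcome="died", outcome_terms=("age_c", "severity_c"),
                treatment="ventilated", treatment_terms=STAGE,
                endog_cont="log_hlos", cont_terms=STAGE + ("ventilated",)))
            te = treatment_effects(fit, t)
        assert abs(te.atet - te.ate) < 0.01

    def test_conditional_option_runs(self, exo_fit, exogenous_cohort):
        t, fit = exo_fit
        te = treatment_effects(fit, t, conditional=True)
        assert te.conditional
        assert np.isfinite(te.atet)


class TestMarginsGrid:
    def test_contrast_equals_scenario_difference(self, exo_fit, exogenous_cohort):
        t, fit = exo_fit
        grid = margins_grid(fit, t, "severity_c", [-20.0, 0.0, 40.0])
        tab = grid.table
        np.testing.assert_allclose(tab["contrast"],
                                   tab["p_treated"] - tab["p_untreated"],
                                   atol=1e-12)

    def test_monotone_in_severity(self, exo_fit, exogenous_cohort):
        """Positive severity coefficient: predicted mortality is nondecreasing
        along the severity grid in both counterfactual scenarios."""
        t, fit = exo_fit
        grid = margins_grid(fit, t, "severity_c", [-40.0, 0.0, 40.0, 80.0]).table
        assert grid["p_treated"].is_monotonic_increasing
        assert grid["p_untreated"].is_monotonic_increasing

    def test_out_of_support_warns(self, exo_fit, exogenous_cohort):
        t, fit = exo_fit
        with pytest.warns(UserWarning, match="outside observed support"):
            margins_grid(fit, t, "severity_c", [1e4])

    def test_non_outcome_covariate_rejected(self, exo_fit, exogenous_cohort):
        t, fit = exo_fit
        with pytest.raises(ValueError):
            margins_grid(fit, t, "hlos", [1.0])

    def test_delta_ci_tracks_bootstrap(self):
        """Delta-method CI half-widths agree with a nonparametric bootstrap
        (treatment-only model so each refit is cheap)."""
        cfg = RegistryConfig(n_patients=1500, n_sites=25, seed=33, site_sd=0.0)
        t = prepare_table(generate_registry(cfg)[0])
        spec = ErmSpec(outcome="died", outcome_terms=("age_c", "severity_c"),
                       treatment="ventilated",
                       treatment_terms=("severity_c", "C(hospital_level)"),
                       endog_cont=None, cont_terms=None)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_erm(t, spec)
            grid = margins_grid(fit, t, "severity_c", [0.0]).table
            rng = np.random.default_rng(34)
            boots = []
            for _ in range(80):
                idx = rng.integers(0, len(t), len(t))
                tb = t.iloc[idx].reset_index(drop=True)
                try:
                    fb = fit_erm(tb, spec)
                except Exception:
                    continue
                boots.append(margins_grid(fb, tb, "severity_c", [0.0])
                             .table["contrast"].iloc[0])
        half_delta = 1.96 * grid["contrast_se"].iloc[0]
        half_boot = 1.96 * np.std(boots, ddof=1)
        assert half_delta == pytest.approx(half_boot, rel=0.35)


class TestExogeneityCheck:
    def test_exogenous_severity_covered(self, exogenous_cohort):
        """Severity is exogenous by construction: its error correlation with
        mortality has a CI covering 0."""
        t, _ = exogenous_cohort
        t2 = t.copy()
        t2["severity_f"] = t2["severity"].astype(float)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = exogeneity_check(
                t2, "severity_f",
                first_stage_terms=("age_c", "C(hospital_level)", "C(dx_category)"),
                outcome_terms=("age_c", "ventilated", "log_hlos"))
        assert res.rho.ci_lower <= 0.0 <= res.rho.ci_upper

    def test_rod_flagged_endogenous(self):
        """ROD is built from the outcome's own linear predictor, so its error
        correlation with mortality is bounded away from 0."""
        t = prepare_table(generate_registry(
            RegistryConfig(n_patients=12_000, n_sites=60, seed=50))[0])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = exogeneity_check(
                t, "log_rod",
                first_stage_terms=("age_c", "severity_c", "C(hospital_level)",
                                   "C(dx_category)", "C(volume_decile)"),
                outcome_terms=("age_c", "severity_c"))
        assert res.rho.p_value < 0.05
        assert not (res.rho.ci_lower <= 0.0 <= res.rho.ci_upper)

    def test_missing_variable_named(self, small_cohort):
        t, _ = small_cohort
        with pytest.raises(ValueError, match="not_a_column"):
            exogeneity_check(t, "not_a_column", first_stage_terms=("age_c",),
                             outcome_terms=("severity_c",))
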