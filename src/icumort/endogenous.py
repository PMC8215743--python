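"""Extended probit: probit outcome with endogenous regressors, by one-step ML.

The model jointly estimates up to three equations,

    treatment:  V = 1{ z_v' γ + ε_v > 0 }              (endogenous binary)
    continuous: h = z_h' δ + ε_h                        (endogenous continuous)
    outcome:    M = 1{ x' β + β_T V + β_H h + ε_m > 0 }

with (ε_v, ε_h, ε_m) trivariate Normal — unit variances for the two probit
errors, SD σ_h for the continuous error — and free correlations
(ρ_vh, ρ_vm, ρ_hm).  Nonzero ρ_vm / ρ_hm are what make V / h endogenous in
the mortality equation; instruments are first-stage terms excluded from x.

The likelihood factors per observation as the Normal density of the
continuous residual e_h times the bivariate-Normal orthant probability of
the two signed latent indices conditioned on ε_h = e_h (conditional means
ρ·e_h/σ_h, conditional correlation from the Schur complement).  The
bivariate Normal CDF is evaluated through Owen's T function
(machine-precision accurate, fully vectorized), which matters because the
likelihood is dominated by tail orthants at extreme severity.

Estimation maximizes the exact likelihood in one step (quasi-Newton over an
unconstrained parameterization: atanh ρ, log σ_h) from a staged start
(separate probit/OLS fits with ρ = 0); inference uses a sandwich
(robust) covariance, with correlations reported through the Fisher-z
transform.  Post-estimation: average treatment effects (ATE/ATET) on the
probability scale, counterfactual margins grids, and an exogeneity check
for a single suspect covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
from scipy.special import log_ndtr, ndtr, owens_t
from statsmodels.tools import numdiff

from .binary import EstimationError

__all__ = [
    "bvn_cdf",
    "ErmSpec",
    "ErmFit",
    "RhoEstimate",
    "TreatmentEffects",
    "MarginsGrid",
    "erm_loglik",
    "fit_erm",
    "treatment_effects",
    "margins_grid",
    "exogeneity_check",
    "ExogeneityResult",
]

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# Bivariate normal CDF (Owen's T identity)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """P(X ≤ h, Y ≤ k) for standard bivariate Normal with correlation rho.

    Uses Owen's (1956) identity Φ₂(h,k,ρ) = (Φ(h)+Φ(k))/2 − T(h,a_h) −
    T(k,a_k) − [hk<0]/2 with scipy's Owen's T; exact zeros of h or k are
    nudged by 1e-12, keeping the absolute error below ~5e-13 everywhere.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    rho = np.clip(rho, -1.0 + 1e-15, 1.0 - 1e-15)
    denom = np.sqrt((1.0 - rho) * (1.0 + rho))
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    beta = np.where(h * k < 0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Specification and prepared data
# ---------------------------------------------------------------------------

@dataclass
class ErmSpec:
    """Equation system specification.

    ``outcome_terms`` are the exogenous outcome covariates (patsy terms); the
    treatment and the continuous endogenous variable are appended to the
    outcome equation automatically and must not be listed there.  Each active
    first stage must contain at least one term absent from the outcome
    equation (an excluded instrument).
    """

    outcome: str = "died"
    outcome_terms: tuple[str, ...] = ("age_c", "severity_c")
    treatment: str | None = "ventilated"
    treatment_terms: tuple[str, ...] | None = None
    endog_cont: str | None = "log_hlos"
    cont_terms: tuple[str, ...] | None = None

    @property
    def has_treatment(self) -> bool:
        return self.treatment is not None

    @property
    def has_cont(self) -> bool:
        return self.endog_cont is not None

    def validate(self) -> None:
        if not (self.has_treatment or self.has_cont):
            raise ValueError("at least one endogenous component must be active")
        out = set(self.outcome_terms)
        for name, terms in (("treatment", self.treatment_terms),
                            ("continuous", self.cont_terms)):
            active = self.treatment if name == "treatment" else self.endog_cont
            if active is None:
                continue
            if terms is None:
                raise ValueError(f"{name} equation is active but has no terms")
            lhs = self.treatment if name == "treatment" else self.endog_cont
            if lhs in terms:
                raise ValueError(f"{name} equation regresses {lhs} on itself")
            extra = {t for t in terms if t != self.treatment}
            if not (extra - out):
                raise ValueError(
                    f"{name} equation needs at least one excluded instrument "
                    "(a term absent from the outcome equation)"
                )
        for endo in (self.treatment, self.endog_cont):
            if endo is not None and endo in out:
                raise ValueError(
                    f"endogenous variable {endo} must not be listed in outcome_terms"
                )


def _dmatrix(terms: tuple[str, ...], table: pd.DataFrame):
    rhs = " + ".join(terms) if terms else "1"
    return patsy.dmatrix(rhs, table, return_type="dataframe")


class _ErmData:
    """Design matrices and parameter layout for one specification."""

    def __init__(self, table: pd.DataFrame, spec: ErmSpec):
        spec.validate()
        self.spec = spec
        self.m = np.asarray(table[spec.outcome], dtype=float)
        if len(np.unique(self.m)) < 2:
            raise EstimationError(f"outcome {spec.outcome} has a single class")

        Xm = _dmatrix(spec.outcome_terms, table)
        self.Xm = np.asarray(Xm)
        self.xm_names = list(Xm.columns)
        self.design_m = Xm.design_info

        extra = []
        if spec.has_treatment:
            if spec.treatment not in table.columns:
                raise ValueError(f"treatment column not in table: {spec.treatment}")
            self.v = np.asarray(table[spec.treatment], dtype=float)
            Xv = _dmatrix(spec.treatment_terms, table)
            self.Xv = np.asarray(Xv)
            self.xv_names = list(Xv.columns)
            self.design_v = Xv.design_info
            extra.append(spec.treatment)
        if spec.has_cont:
            if spec.endog_cont not in table.columns:
                raise ValueError(f"endogenous variable not in table: {spec.endog_cont}")
            self.h = np.asarray(table[spec.endog_cont], dtype=float)
            Xh = _dmatrix(spec.cont_terms, table)
            self.Xh = np.asarray(Xh)
            self.xh_names = list(Xh.columns)
            self.design_h = Xh.design_info
            extra.append(spec.endog_cont)
        self.beta_names = self.xm_names + extra
        self.n = len(self.m)

        # parameter layout
        names = [f"outcome:{c}" for c in self.beta_names]
        self.k_beta = len(self.beta_names)
        if spec.has_treatment:
            names += [f"treatment:{c}" for c in self.xv_names]
            self.k_gamma = len(self.xv_names)
        else:
            self.k_gamma = 0
        if spec.has_cont:
            names += [f"{spec.endog_cont}:{c}" for c in self.xh_names]
            names += ["log_sigma_h", "atanh_rho_hm"]
            self.k_delta = len(self.xh_names)
        else:
            self.k_delta = 0
        if spec.has_treatment:
            names += ["atanh_rho_vm"]
        if spec.has_treatment and spec.has_cont:
            names += ["atanh_rho_vh"]
        self.param_names = names
        self.k = len(names)

    def unpack(self, theta: np.ndarray) -> dict:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(f"expected {self.k} parameters, got {theta.shape}")
        i = 0
        out = {}
        out["beta"] = theta[i:i + self.k_beta]; i += self.k_beta
        if self.spec.has_treatment:
            out["gamma"] = theta[i:i + self.k_gamma]; i += self.k_gamma
        if self.spec.has_cont:
            out["delta"] = theta[i:i + self.k_delta]; i += self.k_delta
            out["sigma_h"] = float(np.exp(theta[i])); i += 1
            out["rho_hm"] = float(np.tanh(theta[i])); i += 1
        if self.spec.has_treatment:
            out["rho_vm"] = float(np.tanh(theta[i])); i += 1
        if self.spec.has_treatment and self.spec.has_cont:
            out["rho_vh"] = float(np.tanh(theta[i])); i += 1
        return out

    def outcome_index(self, beta: np.ndarray, v=None, h=None) -> np.ndarray:
        """x'β plus the endogenous components' structural terms."""
        a = self.Xm @ beta[: len(self.xm_names)]
        j = len(self.xm_names)
        if self.spec.has_treatment:
            a = a + beta[j] * (self.v if v is None else v)
            j += 1
        if self.spec.has_cont:
            a = a + beta[j] * (self.h if h is None else h)
        return a


_TINY = 1e-300


def _loglik_obs(theta: np.ndarray, data: _ErmData) -> np.ndarray:
    """Per-observation log-likelihood contributions (−inf on invalid Σ)."""
    p = data.unpack(theta)
    spec = data.spec
    a_m = data.outcome_index(p["beta"])
    s_m = 2.0 * data.m - 1.0

    if spec.has_cont:
        sigma = p["sigma_h"]
        e = data.h - data.Xh @ p["delta"]
        z = e / sigma
        log_fh = stats.norm.logpdf(z) - np.log(sigma)
        r_hm = p["rho_hm"]
        sd_m = np.sqrt(1.0 - r_hm**2)
        w_m = (a_m + r_hm * z) / sd_m
        if not spec.has_treatment:
            return log_fh + log_ndtr(s_m * w_m)
        r_vh, r_vm = p["rho_vh"], p["rho_vm"]
        sd_v = np.sqrt(1.0 - r_vh**2)
        rho_c = (r_vm - r_vh * r_hm) / (sd_v * sd_m)
        if not (-1.0 < rho_c < 1.0):
            return np.full(data.n, -np.inf)
        a_v = data.Xv @ p["gamma"]
        s_v = 2.0 * data.v - 1.0
        w_v = (a_v + r_vh * z) / sd_v
        P = bvn_cdf(s_v * w_v, s_m * w_m, s_v * s_m * rho_c)
        return log_fh + np.log(np.maximum(P, _TINY))

    # treatment only: recursive bivariate probit with endogenous treatment
    a_v = data.Xv @ p["gamma"]
    s_v = 2.0 * data.v - 1.0
    P = bvn_cdf(s_v * a_v, s_m * a_m, s_v * s_m * p["rho_vm"])
    return np.log(np.maximum(P, _TINY))


def _norm_pdf(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _safe_ratio(num, den, cap: float = 1e8):
    """Score ratio num/den guarded against deep-tail underflow of den."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        r = num / den
    return np.clip(np.nan_to_num(r, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)


def _score_obs(theta: np.ndarray, data: _ErmData) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation log-likelihood and its analytic score matrix (n, k).

    Uses the closed-form partials of the bivariate Normal CDF:
    ∂Φ₂/∂x1 = φ(x1)Φ((x2−ρx1)/√(1−ρ²)), ∂Φ₂/∂ρ = φ₂(x1,x2;ρ).
    """
    p = data.unpack(theta)
    spec = data.spec
    n, k = data.n, data.k
    S = np.zeros((n, k))
    names = data.param_names
    col = {nm: i for i, nm in enumerate(names)}

    a_m = data.outcome_index(p["beta"])
    s_m = 2.0 * data.m - 1.0
    # outcome design including the appended endogenous columns
    Xm_full = [data.Xm]
    if spec.has_treatment:
        Xm_full.append(data.v.reshape(-1, 1))
    if spec.has_cont:
        Xm_full.append(data.h.reshape(-1, 1))
    Xm_full = np.column_stack(Xm_full)
    i_beta = slice(0, data.k_beta)

    if spec.has_cont:
        sigma, r_hm = p["sigma_h"], p["rho_hm"]
        e = data.h - data.Xh @ p["delta"]
        z = e / sigma
        sd_m = np.sqrt(1.0 - r_hm**2)
        A_m = a_m + r_hm * z
        w_m = A_m / sd_m
        i_delta = slice(data.k_beta + data.k_gamma,
                        data.k_beta + data.k_gamma + data.k_delta)
        i_lsig = col["log_sigma_h"]
        i_zhm = col["atanh_rho_hm"]

        if not spec.has_treatment:
            x2 = s_m * w_m
            ll = stats.norm.logpdf(z) - np.log(sigma) + log_ndtr(x2)
            lam = np.exp(stats.norm.logpdf(x2) - log_ndtr(x2))   # inverse Mills
            dl_dwm = lam * s_m
            S[:, i_beta] = (dl_dwm / sd_m)[:, None] * Xm_full
            dl_dz = -z + dl_dwm * r_hm / sd_m
            S[:, i_delta] = (-dl_dz / sigma)[:, None] * data.Xh
            S[:, i_lsig] = -dl_dz * z - 1.0
            dwm_drhm = z / sd_m + A_m * r_hm / sd_m**3
            S[:, i_zhm] = dl_dwm * dwm_drhm * (1.0 - r_hm**2)
            return ll, S

        r_vh, r_vm = p["rho_vh"], p["rho_vm"]
        sd_v = np.sqrt(1.0 - r_vh**2)
        num = r_vm - r_vh * r_hm
        rho_c = num / (sd_v * sd_m)
        if not (-1.0 < rho_c < 1.0):
            return np.full(n, -np.inf), S
        a_v = data.Xv @ p["gamma"]
        s_v = 2.0 * data.v - 1.0
        A_v = a_v + r_vh * z
        w_v = A_v / sd_v
        x1, x2 = s_v * w_v, s_m * w_m
        r = s_v * s_m * rho_c
        P = np.maximum(bvn_cdf(x1, x2, r), _TINY)
        ll = stats.norm.logpdf(z) - np.log(sigma) + np.log(P)

        rt = np.sqrt(1.0 - r**2)
        dP_dx1 = _norm_pdf(x1) * ndtr((x2 - r * x1) / rt)
        dP_dx2 = _norm_pdf(x2) * ndtr((x1 - r * x2) / rt)
        dP_dr = np.exp(-(x1**2 - 2.0 * r * x1 * x2 + x2**2) / (2.0 * rt**2)) \
            / (2.0 * np.pi * rt)
        # deep-tail observations (P at the underflow floor) get clipped ratios
        dl_dwv = _safe_ratio(dP_dx1, P) * s_v
        dl_dwm = _safe_ratio(dP_dx2, P) * s_m
        dl_drc = _safe_ratio(dP_dr, P) * s_v * s_m

        i_gamma = slice(data.k_beta, data.k_beta + data.k_gamma)
        S[:, i_beta] = (dl_dwm / sd_m)[:, None] * Xm_full
        S[:, i_gamma] = (dl_dwv / sd_v)[:, None] * data.Xv
        dl_dz = -z + dl_dwv * r_vh / sd_v + dl_dwm * r_hm / sd_m
        S[:, i_delta] = (-dl_dz / sigma)[:, None] * data.Xh
        S[:, i_lsig] = -dl_dz * z - 1.0

        dwm_drhm = z / sd_m + A_m * r_hm / sd_m**3
        drc_drhm = -r_vh / (sd_v * sd_m) + num * r_hm / (sd_v * sd_m**3)
        S[:, i_zhm] = (dl_dwm * dwm_drhm + dl_drc * drc_drhm) * (1.0 - r_hm**2)

        drc_drvm = 1.0 / (sd_v * sd_m)
        S[:, col["atanh_rho_vm"]] = dl_drc * drc_drvm * (1.0 - r_vm**2)

        dwv_drvh = z / sd_v + A_v * r_vh / sd_v**3
        drc_drvh = -r_hm / (sd_v * sd_m) + num * r_vh / (sd_v**3 * sd_m)
        S[:, col["atanh_rho_vh"]] = (dl_dwv * dwv_drvh + dl_drc * drc_drvh) \
            * (1.0 - r_vh**2)
        return ll, S

    # treatment only: recursive bivariate probit
    r_vm = p["rho_vm"]
    a_v = data.Xv @ p["gamma"]
    s_v = 2.0 * data.v - 1.0
    x1, x2 = s_v * a_v, s_m * a_m
    r = s_v * s_m * r_vm
    P = np.maximum(bvn_cdf(x1, x2, r), _TINY)
    ll = np.log(P)
    rt = np.sqrt(1.0 - r**2)
    dP_dx1 = _norm_pdf(x1) * ndtr((x2 - r * x1) / rt)
    dP_dx2 = _norm_pdf(x2) * ndtr((x1 - r * x2) / rt)
    dP_dr = np.exp(-(x1**2 - 2.0 * r * x1 * x2 + x2**2) / (2.0 * rt**2)) \
        / (2.0 * np.pi * rt)
    S[:, i_beta] = (_safe_ratio(dP_dx2, P) * s_m)[:, None] * Xm_full
    S[:, data.k_beta:data.k_beta + data.k_gamma] = \
        (_safe_ratio(dP_dx1, P) * s_v)[:, None] * data.Xv
    S[:, col["atanh_rho_vm"]] = _safe_ratio(dP_dr, P) * s_v * s_m * (1.0 - r_vm**2)
    return ll, S


def erm_loglik(params, table: pd.DataFrame, spec: ErmSpec) -> float:
    """Total extended-probit log-likelihood at an unconstrained parameter vector."""
    data = _ErmData(table, spec)
    return float(np.sum(_loglik_obs(np.asarray(params, dtype=float), data)))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class RhoEstimate:
    estimate: float
    se: float
    z: float
    p_value: float
    ci_lower: float
    ci_upper: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ErmFit:
    spec: ErmSpec
    theta: np.ndarray
    param_names: list[str]
    beta: pd.Series
    gamma: pd.Series | None
    delta: pd.Series | None
    sigma_h: float | None
    rho: dict[str, RhoEstimate]
    loglik: float
    aic: float
    bic: float
    vcov: pd.DataFrame               # sandwich
    vcov_model: pd.DataFrame
    n_used: int
    converged: bool
    weak_instruments: dict[str, float]
    _data: _ErmData = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "outcome": self.beta.to_dict(),
            "treatment": None if self.gamma is None else self.gamma.to_dict(),
            "continuous": None if self.delta is None else self.delta.to_dict(),
            "sigma_h": self.sigma_h,
            "rho": {k: v.to_dict() for k, v in self.rho.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_used": self.n_used,
            "first_stage_joint_p": self.weak_instruments,
        }


def _staged_start(data: _ErmData) -> np.ndarray:
    import statsmodels.api as sm

    spec = data.spec
    Xfull = data.Xm
    extras = []
    if spec.has_treatment:
        extras.append(data.v)
    if spec.has_cont:
        extras.append(data.h)
    Xo = np.column_stack([Xfull] + [e.reshape(-1, 1) for e in extras]) if extras else Xfull
    beta = np.asarray(sm.Probit(data.m, Xo).fit(disp=0, maxiter=200).params)
    parts = [beta]
    if spec.has_treatment:
        gamma = np.asarray(sm.Probit(data.v, data.Xv).fit(disp=0, maxiter=200).params)
        parts.append(gamma)
    if spec.has_cont:
        ols = sm.OLS(data.h, data.Xh).fit()
        parts.append(np.asarray(ols.params))
        sigma0 = float(np.sqrt(np.mean(ols.resid**2)))
        parts.append(np.array([np.log(max(sigma0, 1e-6)), 0.0]))  # log σ, z_hm
    if spec.has_treatment:
        parts.append(np.array([0.0]))                             # z_vm
    if spec.has_treatment and spec.has_cont:
        parts.append(np.array([0.0]))                             # z_vh
    return np.concatenate(parts)


def _first_stage_tests(data: _ErmData, theta: np.ndarray, vcov: np.ndarray) -> dict:
    """Joint Wald test of the excluded instruments in each first stage."""
    spec = data.spec
    out_terms = set(spec.outcome_terms)
    tests = {}

    def joint(block_names, prefix, eq_terms, design_names):
        excl_terms = [t for t in eq_terms if t not in out_terms and t != spec.treatment]
        if not excl_terms:
            return None
        # columns of the design generated by the excluded terms
        idx = [i for i, nm in enumerate(design_names)
               if any(t.split("(")[-1].rstrip(")") in nm or t == nm or nm.startswith(t)
                      for t in excl_terms) and nm != "Intercept"]
        rows = [data.param_names.index(f"{prefix}:{design_names[i]}") for i in idx]
        if not rows:
            return None
        b = theta[rows]
        V = vcov[np.ix_(rows, rows)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            return None
        return float(stats.chi2.sf(stat, len(rows)))

    if spec.has_treatment:
        tests["treatment"] = joint(None, "treatment", spec.treatment_terms, data.xv_names)
    if spec.has_cont:
        tests[spec.endog_cont] = joint(None, spec.endog_cont, spec.cont_terms,
                                       data.xh_names)
    return {k: v for k, v in tests.items() if v is not None}


def fit_erm(table: pd.DataFrame, spec: ErmSpec, maxiter: int = 2000) -> ErmFit:
    """One-step ML fit of the extended probit with sandwich inference."""
    data = _ErmData(table, spec)
    theta0 = _staged_start(data)

    def negll_grad(theta):
        ll, S = _score_obs(theta, data)
        if not np.all(np.isfinite(ll)):
            return 1e12, np.zeros_like(theta)
        return -float(ll.sum()), -S.sum(axis=0)

    res = optimize.minimize(negll_grad, theta0, method="L-BFGS-B", jac=True,
                            options={"maxiter": maxiter, "maxfun": 50 * maxiter,
                                     "ftol": 1e-13, "gtol": 1e-6, "maxcor": 40})
    # accept a tight gradient even if the line search stalled
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
    if not (res.success or grad_ok):
        raise EstimationError(
            f"extended probit did not converge: {res.message}; "
            f"nit={res.nit}, |grad|={np.max(np.abs(res.jac)):.3g}"
        )
    theta = res.x
    ll = -float(res.fun)

    # --- covariance: model-based inverse Hessian and sandwich
    H = numdiff.approx_fprime(theta, lambda t: _score_obs(t, data)[1].sum(axis=0),
                              centered=True)
    H = 0.5 * (H + H.T)
    S = _score_obs(theta, data)[1]
    try:
        Hinv = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(-H)
    vc_model = Hinv
    vc_sand = Hinv @ (S.T @ S) @ Hinv
    vc_sand = 0.5 * (vc_sand + vc_sand.T)

    p = data.unpack(theta)
    names = data.param_names
    vcov = pd.DataFrame(vc_sand, index=names, columns=names)
    vcov_model = pd.DataFrame(vc_model, index=names, columns=names)

    rho = {}
    for label, key in (("rho_hm", "atanh_rho_hm"), ("rho_vm", "atanh_rho_vm"),
                       ("rho_vh", "atanh_rho_vh")):
        if key not in names:
            continue
        i = names.index(key)
        z_hat = float(theta[i])
        se_z = float(np.sqrt(max(vc_sand[i, i], 0.0)))
        r = float(np.tanh(z_hat))
        rho[label] = RhoEstimate(
            estimate=r,
            se=(1.0 - r**2) * se_z,
            z=z_hat / se_z if se_z > 0 else np.inf,
            p_value=float(2.0 * stats.norm.sf(abs(z_hat / se_z))) if se_z > 0 else 0.0,
            ci_lower=float(np.tanh(z_hat - _Z975 * se_z)),
            ci_upper=float(np.tanh(z_hat + _Z975 * se_z)),
        )

    weak = _first_stage_tests(data, theta, vc_sand)
    for eq, pval in weak.items():
        if pval is not None and pval > 0.05:
            warnings.warn(
                f"weak instruments in the {eq} first stage (joint test p = {pval:.3f})",
                UserWarning,
            )

    k = data.k
    return ErmFit(
        spec=spec,
        theta=theta,
        param_names=names,
        beta=pd.Series(p["beta"], index=data.beta_names),
        gamma=pd.Series(p["gamma"], index=data.xv_names) if spec.has_treatment else None,
        delta=pd.Series(p["delta"], index=data.xh_names) if spec.has_cont else None,
        sigma_h=p.get("sigma_h"),
        rho=rho,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(data.n),
        vcov=vcov,
        vcov_model=vcov_model,
        n_used=data.n,
        converged=True,
        weak_instruments=weak,
        _data=data,
    )


# ---------------------------------------------------------------------------
# Potential outcomes: ATE / ATET and margins
# ---------------------------------------------------------------------------

def _pom_designs(data: _ErmData, table: pd.DataFrame,
                 v_values=(0.0, 1.0)) -> tuple[np.ndarray, dict]:
    """Precompute the design matrices the potential-outcome means need."""
    Xm = np.asarray(patsy.dmatrix(data.design_m, table, return_type="dataframe"))
    Xh = {}
    if data.spec.has_cont:
        for v in v_values:
            tab = table.copy()
            if data.spec.has_treatment:
                tab[data.spec.treatment] = float(v)
            Xh[v] = np.asarray(patsy.dmatrix(data.design_h, tab,
                                             return_type="dataframe"))
    return Xm, Xh


def _pom(theta: np.ndarray, data: _ErmData, v_fix: float, Xm: np.ndarray,
         Xh: dict, conditional_on: np.ndarray | None = None) -> np.ndarray:
    """Per-patient potential-outcome mortality probability with V fixed.

    The endogenous continuous variable is evaluated at its structural
    prediction under the fixed treatment; the latent errors (ε_h, ε_m) are
    integrated out jointly, giving Φ(a_m/s) with s² = β_H²σ² + 2β_Hρ_hmσ + 1.
    With ``conditional_on`` (an a_v vector), the expectation additionally
    conditions on the treated region ε_v > −a_v.
    """
    spec = data.spec
    p = data.unpack(theta)
    beta = p["beta"]
    j = len(data.xm_names)
    a = Xm @ beta[:j]
    b_t = beta[j] if spec.has_treatment else 0.0
    if spec.has_treatment:
        a = a + b_t * v_fix
        j += 1
    if spec.has_cont:
        b_h = beta[j]
        h_struct = Xh[v_fix] @ p["delta"]
        a = a + b_h * h_struct
        sigma, r_hm = p["sigma_h"], p["rho_hm"]
        s2 = b_h**2 * sigma**2 + 2.0 * b_h * r_hm * sigma + 1.0
        s = np.sqrt(max(s2, 1e-12))
    else:
        s = 1.0
    q = a / s
    if conditional_on is None:
        return ndtr(q)
    # conditioning on ε_v > −a_v: corr(combined error/s, ε_v)
    r_vm = p.get("rho_vm", 0.0)
    r_vh = p.get("rho_vh", 0.0)
    if spec.has_cont:
        rho_q = (beta[len(data.xm_names) + 1] * r_vh * p["sigma_h"] + r_vm) / s
    else:
        rho_q = r_vm
    a_v = conditional_on
    num = bvn_cdf(q, a_v, rho_q)
    den = np.maximum(ndtr(a_v), 1e-300)
    return num / den


@dataclass
class TreatmentEffects:
    ate: float
    ate_se: float
    ate_ci: tuple[float, float]
    atet: float
    atet_se: float
    atet_ci: tuple[float, float]
    pom0: float
    pom1: float
    conditional: bool

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ate_ci"] = list(self.ate_ci)
        d["atet_ci"] = list(self.atet_ci)
        return d


def treatment_effects(fit: ErmFit, table: pd.DataFrame,
                      conditional: bool = False) -> TreatmentEffects:
    """ATE and ATET on the probability scale with delta-method CIs.

    ATE averages pom1 − pom0 over all patients; ATET over the treated.  With
    ``conditional=True`` the treated patients' potential outcomes condition
    on their own selection region ε_v > −z_v'γ (truncated-error version);
    the default integrates the errors unconditionally.
    """
    spec = fit.spec
    if not spec.has_treatment:
        raise ValueError("treatment equation is not active in this fit")
    data = _ErmData(table, spec)
    treated = data.v == 1.0
    if not treated.any():
        raise ValueError("no treated patients: ATET undefined")
    Xm, Xh = _pom_designs(data, table)

    def effects(theta):
        cond = None
        if conditional:
            p = data.unpack(theta)
            cond = data.Xv @ p["gamma"]
        d = (_pom(theta, data, 1.0, Xm, Xh, cond)
             - _pom(theta, data, 0.0, Xm, Xh, cond))
        return np.array([float(d.mean()), float(d[treated].mean())])

    est = effects(fit.theta)
    G = numdiff.approx_fprime(fit.theta, effects)
    V = G @ fit.vcov.values @ G.T
    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    pom1 = float(_pom(fit.theta, data, 1.0, Xm, Xh).mean())
    pom0 = float(_pom(fit.theta, data, 0.0, Xm, Xh).mean())
    return TreatmentEffects(
        ate=float(est[0]), ate_se=float(se[0]),
        ate_ci=(float(est[0] - _Z975 * se[0]), float(est[0] + _Z975 * se[0])),
        atet=float(est[1]), atet_se=float(se[1]),
        atet_ci=(float(est[1] - _Z975 * se[1]), float(est[1] + _Z975 * se[1])),
        pom0=pom0, pom1=pom1, conditional=conditional,
    )


@dataclass
class MarginsGrid:
    grid_var: str
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {"grid_var": self.grid_var,
                "rows": self.table.to_dict(orient="records")}


def margins_grid(fit: ErmFit, table: pd.DataFrame, grid_var: str,
                 grid_values) -> MarginsGrid:
    """Counterfactual predicted-mortality grid: all-treated vs all-untreated.

    For each grid value every patient's ``grid_var`` is set to it and the
    average potential-outcome probability is computed with treatment fixed at
    1 and at 0; the contrast row is treated − untreated.  Delta-method CIs
    use the sandwich covariance, so they account for the full parameter
    uncertainty.  Grid values outside the observed support raise a warning,
    not an error.
    """
    in_terms = any(grid_var in t for t in fit.spec.outcome_terms)
    if not in_terms:
        raise ValueError(f"{grid_var} is not an outcome-equation covariate")
    lo, hi = float(table[grid_var].min()), float(table[grid_var].max())
    rows = []
    for val in grid_values:
        if not (lo <= val <= hi):
            warnings.warn(f"grid value {val} outside observed support [{lo}, {hi}]",
                          UserWarning)
        tab = table.copy()
        tab[grid_var] = float(val)
        data = _ErmData(tab, fit.spec)
        Xm, Xh = _pom_designs(data, tab)

        def stat(theta):
            p1 = float(_pom(theta, data, 1.0, Xm, Xh).mean())
            p0 = float(_pom(theta, data, 0.0, Xm, Xh).mean())
            return np.array([p1, p0, p1 - p0])

        est = stat(fit.theta)
        G = numdiff.approx_fprime(fit.theta, stat)
        se = np.sqrt(np.maximum(np.diag(G @ fit.vcov.values @ G.T), 0.0))
        rows.append(
            {
                "grid_value": float(val),
                "p_treated": est[0], "p_treated_se": se[0],
                "p_treated_lo": est[0] - _Z975 * se[0],
                "p_treated_hi": est[0] + _Z975 * se[0],
                "p_untreated": est[1], "p_untreated_se": se[1],
                "p_untreated_lo": est[1] - _Z975 * se[1],
                "p_untreated_hi": est[1] + _Z975 * se[1],
                "contrast": est[2], "contrast_se": se[2],
                "contrast_lo": est[2] - _Z975 * se[2],
                "contrast_hi": est[2] + _Z975 * se[2],
                "significant": bool(est[2] - _Z975 * se[2] > 0
                                    or est[2] + _Z975 * se[2] < 0),
            }
        )
    return MarginsGrid(grid_var=grid_var, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Exogeneity check for a single suspect covariate
# ---------------------------------------------------------------------------

@dataclass
class ExogeneityResult:
    variable: str
    rho: RhoEstimate
    fit: ErmFit


def exogeneity_check(table: pd.DataFrame, variable: str,
                     first_stage_terms: tuple[str, ...],
                     outcome_terms: tuple[str, ...],
                     outcome: str = "died") -> ExogeneityResult:
    """Test a continuous covariate for endogeneity.

    Fits the extended probit with ``variable`` as the single endogenous
    continuous regressor (no treatment equation) and returns its error
    correlation with the outcome plus the Wald test on the Fisher-z scale.
    """
    if variable not in table.columns:
        raise ValueError(f"variable not in table: {variable}")
    spec = ErmSpec(outcome=outcome, outcome_terms=tuple(outcome_terms),
                   treatment=None, treatment_terms=None,
                   endog_cont=variable, cont_terms=tuple(first_stage_terms))
    fit = fit_erm(table, spec)
    return ExogeneityResult(variable=variable, rho=fit.rho["rho_hm"], fit=fit)
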