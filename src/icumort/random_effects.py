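"""Random-intercept logit and probit by adaptive Gauss–Hermite quadrature.

Patients are nested in ICU sites; the model is

    P(y_ij = 1 | u_j) = F(x_ij' β + u_j),   u_j ~ Normal(0, τ₀²),

with F the logistic or standard-Normal CDF.  The marginal likelihood
integrates the random intercept out site by site.  Quadrature is adaptive:
for every likelihood evaluation the integrand's mode û_j and curvature are
located by (vectorized) Newton steps and the Gauss–Hermite nodes are
re-centred and re-scaled around them, so a modest node count (12 by default)
integrates accurately even for large sites.  Optimization is over (β, log τ)
to keep the variance nonnegative; a profile check at τ = 0 handles the
boundary.

Also provided: the latent-scale intraclass correlation ICC = τ₀²/(τ₀² + c)
and the McKelvey–Zavoina dichotomous R² = σ_F²/(σ_F² + τ₀² + σ_R²), with the
link constant c = σ_R² = π²/3 (logit) or 1 (probit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.special import expit, log_ndtr, ndtr
from scipy.stats import norm

from .binary import LINK_RESIDUAL_VARIANCE, EstimationError, ModelSpec, fit_binary

__all__ = ["REFit", "fit_re", "icc", "r2_dichot"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class REFit:
    link: str
    coefficients: pd.Series
    tau2: float
    loglik: float
    aic: float
    bic: float
    posterior_modes: pd.Series
    quadrature_points: int
    boundary: bool
    n_used: int
    converged: bool
    dropped_levels: tuple[str, ...] = ()
    row_index: object = None             # rows of the input table actually used
    design_info: object = field(default=None, repr=False)
    site_col: str = "site_id"
    outcome: str = "died"

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.tau2))

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "coefficients": self.coefficients.to_dict(),
            "tau2": self.tau2,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "quadrature_points": self.quadrature_points,
            "boundary": self.boundary,
            "n_used": self.n_used,
            "dropped_levels": list(self.dropped_levels),
        }

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = patsy.dmatrix(self.design_info, table, return_type="dataframe")
        return np.asarray(X.values @ self.coefficients.values)

    def predict_marginal(self, table: pd.DataFrame, n_quad: int = 24) -> np.ndarray:
        """Population-averaged P(y=1): integrates the random intercept out."""
        lp = self.linear_predictor(table)
        if self.tau2 <= 0:
            return _cdf(self.link, lp)
        x, w = hermegauss(n_quad)
        tau = self.tau
        p = np.zeros_like(lp)
        for xi, wi in zip(x, w):
            p += wi * _cdf(self.link, lp + tau * xi)
        return p / np.sqrt(2.0 * np.pi)


def _cdf(link: str, eta: np.ndarray) -> np.ndarray:
    return expit(eta) if link == "logit" else ndtr(eta)


def _log_bernoulli(link: str, eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Numerically stable per-observation log-likelihood at linear predictor eta."""
    s = 2.0 * y - 1.0
    if link == "logit":
        return -np.logaddexp(0.0, -s * eta)
    return log_ndtr(s * eta)


def _score_info(link: str, eta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """d/deta and -d²/deta² of the per-observation log-likelihood."""
    if link == "logit":
        p = expit(eta)
        return y - p, p * (1.0 - p)
    s = 2.0 * y - 1.0
    # probit: score = s·λ(s·eta), info = λ(λ + s·eta) with λ the inverse Mills ratio
    z = s * eta
    lam = np.exp(norm.logpdf(z) - log_ndtr(z))
    return s * lam, lam * (lam + z)


def _marginal_loglik(beta: np.ndarray, log_tau: float, y: np.ndarray, X: np.ndarray,
                     site: np.ndarray, n_sites: int, link: str, n_quad: int,
                     return_modes: bool = False):
    """AGHQ marginal log-likelihood; optionally returns the per-site modes."""
    tau = float(np.exp(log_tau))
    eta0 = X @ beta
    if tau < 1e-8:
        ll = float(_log_bernoulli(link, eta0, y).sum())
        return (ll, np.zeros(n_sites)) if return_modes else ll

    # --- inner Newton for the per-site modes of log ∫-integrand
    u = np.zeros(n_sites)
    for _ in range(50):
        g, h = _score_info(link, eta0 + u[site], y)
        grad = np.bincount(site, weights=g, minlength=n_sites) - u / tau**2
        hess = np.bincount(site, weights=h, minlength=n_sites) + 1.0 / tau**2
        step = grad / hess
        step = np.clip(step, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    g, h = _score_info(link, eta0 + u[site], y)
    curv = np.bincount(site, weights=h, minlength=n_sites) + 1.0 / tau**2
    sigma = 1.0 / np.sqrt(curv)

    nodes, weights = hermegauss(n_quad)  # probabilists' nodes: weights sum to sqrt(2π)
    # log L_j = log σ_j + logsumexp_k [log w_k + x_k²/2 + ℓ_j(û+σx_k) + log φ_τ(û+σx_k)]
    terms = np.empty((n_quad, n_sites))
    for k, (xk, wk) in enumerate(zip(nodes, weights)):
        uk = u + sigma * xk
        lj = np.bincount(site, weights=_log_bernoulli(link, eta0 + uk[site], y),
                         minlength=n_sites)
        log_prior = -0.5 * (uk / tau) ** 2 - np.log(tau) - _LOG_SQRT_2PI
        terms[k] = np.log(wk) + 0.5 * xk**2 + lj + log_prior
    m = terms.max(axis=0)
    log_Lj = np.log(sigma) + m + np.log(np.exp(terms - m).sum(axis=0))
    ll = float(log_Lj.sum())
    return (ll, u) if return_modes else ll


def fit_re(table: pd.DataFrame, link: str = "logit",
           covariates: tuple[str, ...] = ("age_c", "severity_c"),
           outcome: str = "died", site_col: str = "site_id",
           n_quad: int = 12, tau_fixed: float | None = None,
           maxiter: int = 1000) -> REFit:
    """Fit a random-intercept logit/probit by maximum marginal likelihood.

    ``tau_fixed=0`` collapses the model to the single-level fit (used for the
    boundary profile check).  A boundary fit (τ̂ essentially 0) is reported
    with ``boundary=True``, not raised.
    """
    if link not in ("logit", "probit"):
        raise ValueError(f"unknown link: {link}")
    from .binary import drop_perfect_categories

    table, dropped_levels = drop_perfect_categories(table, outcome, covariates)
    codes, sites = pd.factorize(table[site_col], sort=True)
    n_sites = len(sites)
    if n_sites < 2:
        raise EstimationError("need at least 2 sites for a random-intercept model")
    y = np.asarray(table[outcome], dtype=float)
    if len(np.unique(y)) < 2:
        raise EstimationError(f"outcome {outcome} has a single class")

    rhs = " + ".join(covariates) if covariates else "1"
    ymat, X = patsy.dmatrices(f"{outcome} ~ {rhs}", table, return_type="dataframe")
    site = np.asarray(codes)
    n, p = X.shape
    # column scaling: wide-ranging covariates (e.g. interactions) otherwise
    # condition the quasi-Newton search very poorly
    col_sd = np.asarray(X).std(axis=0)
    col_sd = np.where(col_sd > 0, col_sd, 1.0)
    Xv = np.asarray(X) / col_sd

    # staged start: single-level fit for β, moment-style guess for τ
    start_fit = fit_binary(table, ModelSpec(link=link, outcome=outcome,
                                            covariates=tuple(covariates)))
    beta0 = np.asarray(start_fit.coefficients.reindex(X.columns, fill_value=0.0).values)
    beta0 = beta0 * col_sd                # move the start to the scaled basis

    if tau_fixed is not None and tau_fixed <= 0:
        ll, modes = _marginal_loglik(beta0, -np.inf, y, Xv, site, n_sites, link,
                                     n_quad, return_modes=True)

        def negll0(b):
            return -_marginal_loglik(b, -np.inf, y, Xv, site, n_sites, link, n_quad)

        res = optimize.minimize(negll0, beta0, method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-8})
        beta_hat, ll = res.x, -float(res.fun)
        k = p
        return REFit(link=link, coefficients=pd.Series(beta_hat / col_sd, index=X.columns),
                     tau2=0.0, loglik=ll, aic=-2 * ll + 2 * k,
                     bic=-2 * ll + k * np.log(n),
                     posterior_modes=pd.Series(np.zeros(n_sites), index=[str(s) for s in sites]),
                     quadrature_points=n_quad, boundary=True, n_used=n,
                     converged=bool(res.success), dropped_levels=dropped_levels,
                     row_index=table.index, design_info=X.design_info,
                     site_col=site_col, outcome=outcome)

    theta0 = np.concatenate([beta0, [np.log(0.3 if tau_fixed is None else tau_fixed)]])

    def negll(theta):
        return -_marginal_loglik(theta[:p], theta[p], y, Xv, site, n_sites, link, n_quad)

    res = optimize.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 50 * maxiter,
                                     "ftol": 1e-12, "gtol": 1e-7})
    # near the tau boundary the profile is flat in log tau; accept a gradient
    # that is negligible relative to the log-likelihood scale
    if not (res.success or np.abs(res.jac).max() < 1e-5 * max(abs(res.fun), 1.0)):
        raise EstimationError(f"random-effects {link} fit did not converge: {res.message}")
    beta_hat, log_tau_hat = res.x[:p], float(res.x[p])
    ll, modes = _marginal_loglik(beta_hat, log_tau_hat, y, Xv, site, n_sites, link,
                                 n_quad, return_modes=True)
    tau_hat = float(np.exp(log_tau_hat))

    boundary = tau_hat < 1e-3
    if boundary:
        # profile check at τ = 0: if the single-level likelihood is at least as
        # good, report the boundary solution τ² = 0.
        ll0 = float(_log_bernoulli(link, Xv @ beta_hat, y).sum())
        if ll0 >= ll - 1e-6:
            tau_hat, ll, modes = 0.0, ll0, np.zeros(n_sites)

    k = p + 1
    return REFit(
        link=link,
        coefficients=pd.Series(beta_hat / col_sd, index=X.columns),
        tau2=tau_hat**2,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n),
        posterior_modes=pd.Series(modes, index=[str(s) for s in sites]),
        quadrature_points=n_quad,
        boundary=boundary,
        n_used=n,
        converged=True,
        dropped_levels=dropped_levels,
        row_index=table.index,
        design_info=X.design_info,
        site_col=site_col,
        outcome=outcome,
    )


def icc(tau2: float, link: str) -> float:
    """Latent-scale intraclass correlation τ₀²/(τ₀² + c).

    Whether ``tau2`` comes from the null (unconditional ICC) or the full
    model (conditional ICC) is the caller's choice; the denominator constant
    c is π²/3 for the logit and 1 for the probit either way.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    c = LINK_RESIDUAL_VARIANCE[link]
    return float(tau2 / (tau2 + c))


def r2_dichot(fit: REFit, table: pd.DataFrame) -> float:
    """McKelvey–Zavoina R² = σ_F²/(σ_F² + τ₀² + σ_R²).

    σ_F² is the sample variance of the fixed-part linear predictor on
    ``table``; σ_R² is the link residual variance.
    """
    lp = fit.linear_predictor(table)
    sf2 = float(np.var(lp, ddof=1))
    c = LINK_RESIDUAL_VARIANCE[fit.link]
    return sf2 / (sf2 + fit.tau2 + c)
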