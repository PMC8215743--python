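"""Single-level binary outcome models: logit, probit and the LPM.

Fitting is delegated to statsmodels (ML via Newton for logit/probit, OLS for
the linear probability model), wrapped in a uniform :class:`FitResult`.  On
top of the fits this module implements:

* provider fixed effects as site dummies, dropping perfectly predicted sites
  for the ML links;
* the Haggstrom linear-discriminant transform mapping LPM coefficients to
  logistic-discriminant coefficients via K = N/RSS, which yields predicted
  probabilities inside (0, 1) from an OLS fit;
* unit-interval restriction of raw LPM predictions;
* full X-Y standardization of coefficients, β*_k = β_k · sd(x_k) / sd(y*),
  where var(y*) = var(x'β̂) + c with c = π²/3 (logit), 1 (probit) or RSS/N
  (linear) — the latent-outcome standardization that makes coefficients
  comparable across links;
* slope regressions between standardized coefficient vectors of two models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.special import expit, logit as logit_fn
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "LINK_RESIDUAL_VARIANCE",
    "ModelSpec",
    "FitResult",
    "EstimationError",
    "SeparationError",
    "fit_binary",
    "lpm_to_logit",
    "restrict_unit_interval",
    "UnitIntervalRestriction",
    "standardize_xy",
    "compare_standardized",
    "SlopeComparison",
]

#: Latent residual variance by link, used for X-Y standardization, the ICC
#: and the dichotomous R²: π²/3 ≈ 3.29 for the logit, 1 for the probit.
LINK_RESIDUAL_VARIANCE = {"logit": np.pi ** 2 / 3.0, "probit": 1.0}


class EstimationError(RuntimeError):
    """The model could not be estimated (degenerate outcome, non-convergence)."""


class SeparationError(EstimationError):
    """Complete or quasi-complete separation detected."""


@dataclass
class ModelSpec:
    """Specification of a single-level binary model.

    ``covariates`` are formula terms (patsy syntax, so ``C(dx_category)`` and
    interactions like ``age_c:severity_c`` are valid).
    """

    link: str = "logit"              # 'logit' | 'probit' | 'linear'
    outcome: str = "died"
    covariates: tuple[str, ...] = ("age_c", "severity_c")
    site_fixed_effects: bool = False
    robust_se: bool = False
    site_col: str = "site_id"

    def formula(self) -> str:
        rhs = " + ".join(self.covariates) if self.covariates else "1"
        if self.site_fixed_effects:
            rhs += f" + C({self.site_col})"
        return f"{self.outcome} ~ {rhs}"

    def validate(self, table: pd.DataFrame) -> None:
        if self.link not in ("logit", "probit", "linear"):
            raise ValueError(f"unknown link: {self.link}")
        if self.outcome not in table.columns:
            raise ValueError(f"outcome column not in table: {self.outcome}")
        y = table[self.outcome]
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError(f"outcome {self.outcome} must be binary 0/1")


@dataclass
class FitResult:
    """Uniform container for a fitted binary model."""

    link: str
    coefficients: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n_used: int
    aic: float
    bic: float
    fitted: np.ndarray
    dropped_sites: tuple[str, ...] = ()
    dropped_levels: tuple[str, ...] = ()   # perfectly predicted factor cells
    spec: ModelSpec | None = None
    transformed: bool = False            # True for Haggstrom-transformed fits
    row_index: pd.Index | None = None    # rows of the input table actually used
    design_info: object = field(default=None, repr=False)
    _sm_result: object = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        return len(self.coefficients)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.coefficients.index)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = patsy.dmatrix(self.design_info, table, return_type="dataframe")
        X = X[list(self.coefficients.index)]     # aliased columns were dropped
        return np.asarray(X.values @ self.coefficients.values)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted probabilities (linear link: raw linear predictions)."""
        lp = self.linear_predictor(table)
        if self.link == "logit":
            return expit(lp)
        if self.link == "probit":
            from scipy.special import ndtr

            return ndtr(lp)
        return lp

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "coefficients": self.coefficients.to_dict(),
            "se": self.se().to_dict(),
            "loglik": self.loglik,
            "n_used": self.n_used,
            "aic": self.aic,
            "bic": self.bic,
            "dropped_sites": list(self.dropped_sites),
            "dropped_levels": list(self.dropped_levels),
            "transformed": self.transformed,
        }


def _drop_aliased_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Reduce the design to full column rank via pivoted QR (keeps order)."""
    from scipy.linalg import qr

    Xv = np.asarray(X)
    if Xv.shape[1] <= 1:
        return X
    _, R, piv = qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xv.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == Xv.shape[1]:
        return X
    keep = sorted(piv[:rank])
    return X.iloc[:, keep]


def _drop_perfect_sites(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Remove sites whose outcomes are all 0 or all 1 (FE logit/probit only)."""
    grp = table.groupby(spec.site_col, observed=True)[spec.outcome].agg(["mean", "size"])
    bad = grp.index[(grp["mean"] == 0.0) | (grp["mean"] == 1.0)].tolist()
    if not bad:
        return table, ()
    kept = table[~table[spec.site_col].isin(bad)].copy()
    if isinstance(kept[spec.site_col].dtype, pd.CategoricalDtype):
        kept[spec.site_col] = kept[spec.site_col].cat.remove_unused_categories()
    return kept, tuple(str(b) for b in bad)


def drop_perfect_categories(table: pd.DataFrame, outcome: str,
                            covariates) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop factor levels that perfectly predict the outcome (ML links only).

    A categorical cell whose outcomes are all 0 or all 1 sends its dummy
    coefficient to ±inf (quasi-complete separation); the conventional ML
    behaviour is to remove those observations and the aliased dummy.  Applies
    to ``C(column)`` terms; returns the reduced table and the dropped
    ``column=level`` labels.  Iterates because a drop can expose another
    degenerate cell.
    """
    import re as _re

    cols = []
    for term in covariates:
        m = _re.fullmatch(r"C\((\w+)\)", str(term))
        if m:
            cols.append(m.group(1))
    dropped: list[str] = []
    data = table
    for _ in range(5):
        changed = False
        for col in cols:
            grp = data.groupby(col, observed=True)[outcome].mean()
            bad = grp.index[(grp == 0.0) | (grp == 1.0)].tolist()
            if not bad:
                continue
            changed = True
            dropped += [f"{col}={b}" for b in bad]
            data = data[~data[col].isin(bad)].copy()
            if isinstance(data[col].dtype, pd.CategoricalDtype):
                data[col] = data[col].cat.remove_unused_categories()
        if not changed:
            break
    return data, tuple(dropped)


def fit_binary(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a logit, probit or linear probability model by ML/OLS.

    Raises :class:`EstimationError` if the outcome has a single class or the
    optimizer fails, and :class:`SeparationError` when complete separation is
    detected (diverging standardized coefficients rather than a silent huge
    estimate).
    """
    spec.validate(table)
    dropped: tuple[str, ...] = ()
    dropped_levels: tuple[str, ...] = ()
    data = table
    if spec.link in ("logit", "probit"):
        if spec.site_fixed_effects:
            data, dropped = _drop_perfect_sites(data, spec)
        data, dropped_levels = drop_perfect_categories(data, spec.outcome,
                                                       spec.covariates)

    y_all = np.asarray(data[spec.outcome])
    if len(np.unique(y_all)) < 2:
        raise EstimationError(f"outcome {spec.outcome} has a single class")

    y, X = patsy.dmatrices(spec.formula(), data, return_type="dataframe")
    design_info = X.design_info
    X = _drop_aliased_columns(X)
    yv = np.asarray(y).ravel()
    Xv = np.asarray(X)
    n = len(yv)

    if spec.link == "linear":
        model = sm.OLS(yv, Xv)
        res = model.fit(cov_type="HC1" if spec.robust_se else "nonrobust")
        loglik = float(res.llf)
        fitted = np.asarray(res.fittedvalues)
    else:
        cls = sm.Logit if spec.link == "logit" else sm.Probit
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = cls(yv, Xv).fit(disp=0, maxiter=200, tol=1e-10, method="newton")
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"complete separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular design matrix: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            # Newton may report non-convergence while the score is numerically
            # zero (a sparse factor cell drifting toward ±inf); accept those.
            score = np.asarray(res.mle_retvals.get("score", [np.inf]))
            if np.max(np.abs(score)) > 1e-5:
                raise EstimationError(
                    f"{spec.link} fit did not converge in 200 iterations "
                    f"(max |score| = {np.max(np.abs(score)):.3g}, "
                    f"iterations = {res.mle_retvals.get('iterations')})"
                )
        # separation screen: diverging coefficient on the standardized scale
        sds = Xv.std(axis=0, ddof=1)
        scale = np.where(sds > 0, sds, 1.0)
        if np.any(np.abs(res.params * scale) > 20.0):
            worst = X.columns[int(np.argmax(np.abs(res.params * scale)))]
            raise SeparationError(
                f"diverging standardized coefficient for term {worst!r} "
                "suggests (quasi-)complete separation"
            )
        if spec.robust_se:
            res = cls(yv, Xv).fit(disp=0, maxiter=200, tol=1e-10, method="newton",
                                  cov_type="HC1")
        loglik = float(res.llf)
        fitted = np.asarray(res.predict(Xv))

    k = Xv.shape[1]
    coefs = pd.Series(np.asarray(res.params), index=X.columns)
    vcov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    return FitResult(
        link=spec.link,
        coefficients=coefs,
        vcov=vcov,
        loglik=loglik,
        n_used=n,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * np.log(n),
        fitted=fitted,
        dropped_sites=dropped,
        dropped_levels=dropped_levels,
        spec=spec,
        row_index=data.index,
        design_info=design_info,
        _sm_result=res,
    )


# ---------------------------------------------------------------------------
# Haggstrom LPM -> logistic-discriminant transform
# ---------------------------------------------------------------------------

def lpm_to_logit(ols_fit: FitResult, table: pd.DataFrame) -> FitResult:
    """Map an OLS (LPM) fit to logistic-discriminant coefficients.

    Slopes are multiplied by K = N/RSS.  The intercept follows the full
    linear-discriminant mapping: with p̄ the outcome mean and Δ the
    between-class difference in mean OLS fitted values (the plug-in for
    (μ₁−μ₀)'w),

        intercept* = logit(p̄) + K·(b₀ − p̄) − K·(1/2 − p̄)·Δ.

    The last term vanishes for balanced classes; at low prevalence it is the
    dominant correction (the two-group Gaussian discriminant intercept is
    log(π₁/π₀) − (μ₁+μ₀)'w/2, and x̄ sits at the prior-weighted — not the
    mid — point between the class means).  The returned fit carries
    logistic-link fitted probabilities strictly inside (0, 1).
    """
    if ols_fit.link != "linear":
        raise ValueError("lpm_to_logit requires a linear-link fit")
    if "Intercept" not in ols_fit.coefficients.index:
        raise ValueError("lpm_to_logit requires an intercept in the OLS fit")

    X = patsy.dmatrix(ols_fit.design_info, table, return_type="dataframe")
    X = X[list(ols_fit.coefficients.index)]
    y = np.asarray(table[ols_fit.spec.outcome], dtype=float)
    resid = y - np.asarray(X.values @ ols_fit.coefficients.values)
    rss = float(resid @ resid)
    n = len(y)
    if rss <= 0:
        raise EstimationError("perfect linear fit (RSS = 0): Haggstrom transform degenerate")
    K = n / rss
    pbar = float(y.mean())
    fitted_ols = np.asarray(X.values @ ols_fit.coefficients.values)
    delta = float(fitted_ols[y == 1].mean() - fitted_ols[y == 0].mean())

    beta = ols_fit.coefficients * K
    beta["Intercept"] = (logit_fn(pbar)
                         + K * (ols_fit.coefficients["Intercept"] - pbar)
                         - K * (0.5 - pbar) * delta)
    fitted = expit(np.asarray(X.values @ beta.values))
    loglik = float(np.sum(y * np.log(fitted) + (1 - y) * np.log1p(-fitted)))
    k = len(beta)
    return FitResult(
        link="logit",
        coefficients=beta,
        vcov=ols_fit.vcov * K ** 2,     # first-order propagation of the slope scaling
        loglik=loglik,
        n_used=n,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * np.log(n),
        fitted=fitted,
        dropped_sites=ols_fit.dropped_sites,
        spec=ols_fit.spec,
        transformed=True,
        row_index=ols_fit.row_index,
        design_info=ols_fit.design_info,
    )


@dataclass
class UnitIntervalRestriction:
    kept_mask: np.ndarray
    n_below0: int
    n_above1: int
    frac_below0: float
    frac_above1: float
    fitted_kept: np.ndarray
    empty: bool


def restrict_unit_interval(fit: FitResult) -> UnitIntervalRestriction:
    """Drop LPM predictions outside [0, 1], reporting counts and fractions."""
    if fit.link != "linear":
        raise ValueError("restrict_unit_interval applies to linear-link fits")
    p = np.asarray(fit.fitted)
    below = p < 0.0
    above = p > 1.0
    keep = ~(below | above)
    n = len(p)
    return UnitIntervalRestriction(
        kept_mask=keep,
        n_below0=int(below.sum()),
        n_above1=int(above.sum()),
        frac_below0=float(below.mean()),
        frac_above1=float(above.mean()),
        fitted_kept=p[keep],
        empty=not keep.any(),
    )


# ---------------------------------------------------------------------------
# Full X-Y standardization and cross-model slope comparison
# ---------------------------------------------------------------------------

def standardize_xy(fit: FitResult, table: pd.DataFrame) -> pd.Series:
    """Fully standardized coefficients β*_k = β_k · sd(x_k) / sd(y*).

    var(y*) is the latent-outcome variance var(x'β̂) + c with c the link
    residual variance (π²/3 logit, 1 probit, RSS/N linear).  The intercept is
    excluded.  Raises on zero-variance covariates, naming the column.
    """
    X = patsy.dmatrix(fit.design_info, table, return_type="dataframe")
    X = X[list(fit.coefficients.index)]
    lp = np.asarray(X.values @ fit.coefficients.values)
    if fit.link == "linear":
        y = np.asarray(table[fit.spec.outcome], dtype=float)
        c = float(np.mean((y - lp) ** 2))
    else:
        c = LINK_RESIDUAL_VARIANCE[fit.link]
    sd_ystar = np.sqrt(np.var(lp, ddof=1) + c)

    out = {}
    for name in fit.coefficients.index:
        if name == "Intercept":
            continue
        sx = float(np.std(np.asarray(X[name]), ddof=1))
        if sx == 0.0:
            raise ValueError(f"zero-variance covariate: {name}")
        out[name] = float(fit.coefficients[name]) * sx / sd_ystar
    return pd.Series(out)


@dataclass
class SlopeComparison:
    slope: float
    se: float
    p_value: float
    ci_lower: float
    ci_upper: float
    intercept: float | None
    n: int


def compare_standardized(beta_a: pd.Series, beta_b: pd.Series,
                         include_intercept: bool = True) -> SlopeComparison:
    """Regress standardized coefficients of model b on those of model a.

    Mirrors a table of cross-model slopes with 95% CIs; vectors are aligned
    on their shared index.
    """
    a, b = beta_a.align(beta_b, join="inner")
    if len(a) != len(beta_a) or len(b) != len(beta_b):
        if len(beta_a) != len(beta_b):
            raise ValueError(
                f"coefficient vectors differ in length ({len(beta_a)} vs {len(beta_b)}) "
                "and do not align"
            )
    if len(a) < 3:
        raise ValueError("need at least 3 aligned coefficients")
    av, bv = np.asarray(a, float), np.asarray(b, float)
    X = sm.add_constant(av) if include_intercept else av.reshape(-1, 1)
    res = sm.OLS(bv, X).fit()
    i = 1 if include_intercept else 0
    ci = res.conf_int(alpha=0.05)
    return SlopeComparison(
        slope=float(res.params[i]),
        se=float(res.bse[i]),
        p_value=float(res.pvalues[i]),
        ci_lower=float(ci[i][0]),
        ci_upper=float(ci[i][1]),
        intercept=float(res.params[0]) if include_intercept else None,
        n=len(a),
    )
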