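"""Model-assessment machinery for binary risk models.

Discrimination (ROC AUC), the Hosmer–Lemeshow grouped goodness-of-fit test,
the polynomial-logistic calibration belt with likelihood-ratio degree
selection, binned residual analysis, weak-calibration indices
(calibration-in-the-large, calibration slope, E:O ratio), repeated k-fold
shrinkage/overfitting estimates, and a development/validation split report.

Conventions fixed here (and checked by constructed examples in the tests):

* CITL is the intercept of a logistic recalibration of y with logit(p) as a
  fixed offset, so predictions shifted by +0.5 on the logit scale give
  CITL ≈ −0.5.
* Calibration slope is the coefficient of logit(p) in logit(y) ~ logit(p);
  predictions with halved logits give slope ≈ 2.
* Shrinkage % = 100·(1 − calibration slope); out-of-sample shrinkage uses
  held-out predictions pooled across folds; overfitting % is out-of-sample
  minus in-sample shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit as logit_fn
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .binary import FitResult, ModelSpec, fit_binary

__all__ = [
    "roc_auc",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
    "hl_reference_quantile",
    "calibration_belt",
    "CalibrationBelt",
    "binned_residuals",
    "BinnedResiduals",
    "weak_calibration",
    "WeakCalibration",
    "cv_shrinkage",
    "ShrinkageResult",
    "dev_val_report",
    "CalibrationReport",
    "calibration_report",
]


def _check_yp(y, p, open_interval: bool = False):
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if open_interval and (np.any(p <= 0.0) or np.any(p >= 1.0)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    return y, p


def roc_auc(y, p) -> float:
    """Probability a random event outranks a random non-event (ties 1/2)."""
    y, p = _check_yp(y, p)
    return float(roc_auc_score(y, p))


# ---------------------------------------------------------------------------
# Hosmer–Lemeshow
# ---------------------------------------------------------------------------

@dataclass
class HosmerLemeshowResult:
    statistic: float
    p_value: float
    df: int
    n_groups: int
    merged: bool
    table: pd.DataFrame


def hl_reference_quantile(alpha: float = 0.10, df: int = 10) -> float:
    """Upper-alpha χ² quantile used as a large-N significance yardstick."""
    return float(stats.chi2.isf(alpha, df))


def hosmer_lemeshow(y, p, groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer–Lemeshow grouped χ² test on deciles of fitted risk.

    Groups are formed by quantile cut with ties kept in the lower group;
    groups emptied by heavy ties are merged (flagged).  The statistic uses
    the finite-population denominator E_g(1 − E_g/n_g) and is referred to a
    χ² distribution with (effective groups − 2) degrees of freedom.
    """
    y, p = _check_yp(y, p)
    n = len(y)
    if n < groups:
        raise ValueError("need at least as many observations as groups")
    edges = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1])
    edges = np.unique(edges)
    merged = len(edges) < groups - 1
    # ties to the lower group: index counts edges strictly below p
    g = np.searchsorted(edges, p, side="left")
    rows = []
    for gi in range(len(edges) + 1):
        m = g == gi
        ng = int(m.sum())
        if ng == 0:
            merged = True
            continue
        O = float(y[m].sum())
        E = float(p[m].sum())
        rows.append((gi, ng, O, E, float(p[m].mean())))
    tab = pd.DataFrame(rows, columns=["group", "n", "observed", "expected", "mean_p"])
    denom = tab["expected"] * (1.0 - tab["expected"] / tab["n"])
    denom = np.where(denom <= 0, np.nan, denom)
    stat = float(np.nansum((tab["observed"] - tab["expected"]) ** 2 / denom))
    df = max(len(tab) - 2, 1)
    return HosmerLemeshowResult(
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df)),
        df=df,
        n_groups=len(tab),
        merged=merged,
        table=tab,
    )


# ---------------------------------------------------------------------------
# Calibration belt
# ---------------------------------------------------------------------------

@dataclass
class CalibrationBelt:
    degree: int
    p_value: float
    belt: pd.DataFrame         # grid of p, point estimate and 95% bounds
    loglik: float
    loglik_identity: float


def _fit_poly_logit(y: np.ndarray, L: np.ndarray, degree: int):
    X = np.column_stack([L**d for d in range(degree + 1)])
    res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="lbfgs")
    return res


def calibration_belt(y, p, max_degree: int = 4, alpha: float = 0.05,
                     grid: np.ndarray | None = None) -> CalibrationBelt:
    """Polynomial-logistic recalibration with forward LR degree selection.

    logit(y) is regressed on polynomials of logit(p), starting at degree 2;
    the next degree is added while its likelihood-ratio test has p ≤ alpha
    (up to ``max_degree``).  The deviation p-value tests the selected model
    against the identity line (slope 1, intercept 0).  The belt is the
    pointwise 95% delta-method band of the recalibration curve on a
    probability grid.
    """
    y, p = _check_yp(y, p, open_interval=True)
    if np.ptp(p) == 0:
        raise ValueError("degenerate constant predictions")
    if len(y) < 100:
        raise ValueError("calibration belt needs at least 100 observations")
    L = logit_fn(p)

    degree = 2
    res = _fit_poly_logit(y, L, degree)
    while degree < max_degree:
        cand = _fit_poly_logit(y, L, degree + 1)
        lr = 2.0 * (cand.llf - res.llf)
        p_lr = stats.chi2.sf(max(lr, 0.0), 1)
        if p_lr > alpha:
            break
        degree += 1
        res = cand

    # identity model: offset logit(p), no free parameters
    ll_ident = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    lr_dev = 2.0 * (float(res.llf) - ll_ident)
    p_dev = float(stats.chi2.sf(max(lr_dev, 0.0), degree + 1))

    if grid is None:
        grid = np.quantile(p, np.linspace(0.01, 0.99, 50))
    Lg = logit_fn(np.asarray(grid))
    Xg = np.column_stack([Lg**d for d in range(degree + 1)])
    eta = Xg @ res.params
    var = np.einsum("ij,jk,ik->i", Xg, res.cov_params(), Xg)
    half = 1.959963984540054 * np.sqrt(var)
    belt = pd.DataFrame(
        {
            "p": np.asarray(grid),
            "estimate": expit(eta),
            "lower": expit(eta - half),
            "upper": expit(eta + half),
        }
    )
    return CalibrationBelt(degree=degree, p_value=p_dev, belt=belt,
                           loglik=float(res.llf), loglik_identity=ll_ident)


# ---------------------------------------------------------------------------
# Binned residuals
# ---------------------------------------------------------------------------

@dataclass
class BinnedResiduals:
    table: pd.DataFrame        # mean_fitted, mean_residual, bound, n_in_bin
    coverage: float
    n_bins: int


def binned_residuals(y, p, n_bins: int | None = None) -> BinnedResiduals:
    """Average residual (observed − fitted) in equal-count bins of fitted value.

    The per-bin bound is 2·sqrt(p̄(1−p̄)/n_bin) (≈ ±2 SE); coverage is the
    fraction of bins whose mean residual lies inside its bound.
    """
    y, p = _check_yp(y, p)
    n = len(y)
    if n_bins is None:
        n_bins = int(np.floor(np.sqrt(n)))
    n_bins = max(min(n_bins, n), 1)
    if np.ptp(p) == 0:
        n_bins = 1          # constant fitted value: a single effective bin
    order = np.argsort(p, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        if len(chunk) == 0:
            continue
        pb = float(p[chunk].mean())
        rb = float((y[chunk] - p[chunk]).mean())
        nb = len(chunk)
        bound = 2.0 * np.sqrt(max(pb * (1.0 - pb), 0.0) / nb)
        rows.append((pb, rb, bound, nb))
    tab = pd.DataFrame(rows, columns=["mean_fitted", "mean_residual", "bound", "n_in_bin"])
    inside = np.abs(tab["mean_residual"]) <= tab["bound"]
    return BinnedResiduals(table=tab, coverage=float(inside.mean()), n_bins=len(tab))


# ---------------------------------------------------------------------------
# Weak calibration: CITL, slope, E:O
# ---------------------------------------------------------------------------

@dataclass
class WeakCalibration:
    citl: float
    slope: float
    eo_ratio: float


def weak_calibration(y, p) -> WeakCalibration:
    y, p = _check_yp(y, p, open_interval=True)
    L = logit_fn(p)
    # CITL: intercept-only logistic recalibration with logit(p) as offset
    citl_res = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                      offset=L).fit()
    slope_res = sm.Logit(y, sm.add_constant(L)).fit(disp=0)
    return WeakCalibration(
        citl=float(citl_res.params[0]),
        slope=float(slope_res.params[1]),
        eo_ratio=float(p.sum() / y.sum()),
    )


# ---------------------------------------------------------------------------
# Cross-validated shrinkage / overfitting
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageResult:
    shrink_in: float        # percent
    shrink_out: float       # percent
    overfit_pct: float      # percent
    reps: int
    k: int


def _clip_open(p: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def cv_shrinkage(table: pd.DataFrame, spec: ModelSpec, k: int = 10,
                 reps: int = 10, seed: int = 0) -> ShrinkageResult:
    """Repeated k-fold estimates of calibration shrinkage and overfitting.

    Per repetition the folds are a fresh random partition; the model is
    refitted on each training set.  In-sample shrinkage pools the training
    predictions across folds, out-of-sample shrinkage pools the held-out
    predictions; both are averaged over repetitions.
    """
    if reps < 1 or k < 2:
        raise ValueError("need reps >= 1 and k >= 2")
    rng = np.random.default_rng(seed)
    y_all = np.asarray(table[spec.outcome], dtype=float)
    sin, sout = [], []
    for _ in range(reps):
        for attempt in range(10):
            kf = KFold(n_splits=k, shuffle=True,
                       random_state=int(rng.integers(2**31 - 1)))
            folds = list(kf.split(y_all))
            if all(len(np.unique(y_all[tr])) == 2 for tr, _ in folds):
                break
        else:
            raise ValueError("could not build folds with both outcome classes")
        ys_tr, ps_tr, ys_te, ps_te = [], [], [], []
        for tr, te in folds:
            fit = fit_binary(table.iloc[tr], spec)
            ps_tr.append(_clip_open(fit.predict(table.iloc[tr])))
            ys_tr.append(y_all[tr])
            ps_te.append(_clip_open(fit.predict(table.iloc[te])))
            ys_te.append(y_all[te])
        win = weak_calibration(np.concatenate(ys_tr), np.concatenate(ps_tr))
        wout = weak_calibration(np.concatenate(ys_te), np.concatenate(ps_te))
        sin.append(100.0 * (1.0 - win.slope))
        sout.append(100.0 * (1.0 - wout.slope))
    shrink_in = float(np.mean(sin))
    shrink_out = float(np.mean(sout))
    return ShrinkageResult(shrink_in=shrink_in, shrink_out=shrink_out,
                           overfit_pct=shrink_out - shrink_in, reps=reps, k=k)


# ---------------------------------------------------------------------------
# Development / validation split
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    auc: float
    hl_stat: float
    hl_p: float
    belt_degree: int | None
    belt_p: float | None
    citl: float
    slope: float
    eo_ratio: float
    binned_coverage: float | None = None
    shrink_in: float | None = None
    shrink_out: float | None = None
    overfit_pct: float | None = None
    aic: float | None = None
    bic: float | None = None
    n: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def calibration_report(y, p, fit: FitResult | None = None,
                       with_belt: bool = True) -> CalibrationReport:
    """Assemble the per-model assessment row (discrimination + calibration)."""
    y, p = _check_yp(y, p)
    pc = _clip_open(p)
    hl = hosmer_lemeshow(y, pc)
    wk = weak_calibration(y, pc)
    belt_degree = belt_p = None
    if with_belt and np.ptp(pc) > 0 and len(y) >= 100:
        try:
            belt = calibration_belt(y, pc)
            belt_degree, belt_p = belt.degree, belt.p_value
        except (ValueError, np.linalg.LinAlgError):
            pass
    br = binned_residuals(y, pc)
    return CalibrationReport(
        auc=roc_auc(y, pc),
        hl_stat=hl.statistic,
        hl_p=hl.p_value,
        belt_degree=belt_degree,
        belt_p=belt_p,
        citl=wk.citl,
        slope=wk.slope,
        eo_ratio=wk.eo_ratio,
        binned_coverage=br.coverage,
        aic=fit.aic if fit is not None else None,
        bic=fit.bic if fit is not None else None,
        n=len(y),
    )


def dev_val_report(table: pd.DataFrame, spec: ModelSpec, split: float = 0.5,
                   seed: int = 0) -> dict:
    """Fit on a development half, report weak calibration + AUC on both halves.

    Reshuffles (up to 10 times) if a half lacks both outcome classes, then
    raises.
    """
    y_all = np.asarray(table[spec.outcome], dtype=float)
    n = len(table)
    n_dev = int(round(split * n))
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        perm = rng.permutation(n)
        dev_idx, val_idx = perm[:n_dev], perm[n_dev:]
        if (len(np.unique(y_all[dev_idx])) == 2
                and len(np.unique(y_all[val_idx])) == 2):
            break
    else:
        raise ValueError("could not split with both outcome classes in each half")
    dev, val = table.iloc[dev_idx], table.iloc[val_idx]
    fit = fit_binary(dev, spec)

    def _half(tab):
        yv = np.asarray(tab[spec.outcome], dtype=float)
        pv = _clip_open(fit.predict(tab))
        wk = weak_calibration(yv, pv)
        return {
            "citl": wk.citl,
            "slope": wk.slope,
            "auc": roc_auc(yv, pv),
            "eo_ratio": wk.eo_ratio,
            "n": len(tab),
        }

    return {"development": _half(dev), "validation": _half(val),
            "split": split, "seed": seed}
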