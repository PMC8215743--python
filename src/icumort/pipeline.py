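"""Study orchestration: fit every configured model and assemble the report.

``run_study`` reproduces the full comparison on one cohort (generated or
supplied): the eight base models (vanilla and site-FE logit, probit and
Haggstrom-transformed LPM, plus random-intercept logit/probit), the
unit-interval-restricted LPM, two added-covariate logit variants (log HLOS,
log ROD), the calibration suite for each, fully standardized coefficient
comparisons, and the two extended-probit analyses (log HLOS / log ROD
endogenous with ventilation as endogenous treatment) with error-correlation
tables, ATE/ATET and counterfactual margins over the severity span.

All randomness flows from the single master seed via named substreams; a
model failure is recorded in the report with a failure marker and never
aborts the study.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import binary, calibration, endogenous, random_effects, registry

__all__ = [
    "StudyConfig",
    "run_study",
    "loa_summary",
    "LoaSummary",
    "write_report",
    "validate_report",
]

log = logging.getLogger("icumort")

BASE_TERMS = ("age_c", "severity_c", "age_c:severity_c", "C(dx_category)")
ERM_OUTCOME_TERMS = ("age_c", "severity_c")
ERM_STAGE_TERMS = ("severity_c", "C(dx_category)", "C(hospital_level)", "C(volume_decile)")


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    registry: registry.RegistryConfig = field(default_factory=registry.RegistryConfig)
    input_path: str | None = None          # read a cohort CSV instead of simulating
    base_terms: tuple[str, ...] = BASE_TERMS
    added_covariates: tuple[str, ...] = ("log_hlos", "log_rod")
    erm_outcome_terms: tuple[str, ...] = ERM_OUTCOME_TERMS
    erm_stage_terms: tuple[str, ...] = ERM_STAGE_TERMS
    cv_k: int = 10
    cv_reps: int = 5
    severity_grid: tuple[float, ...] = (15.0, 55.0, 95.0, 135.0, 175.0)
    seed: int = 0
    re_quadrature_points: int = 12

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        reg = raw.pop("registry", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if reg:
            base = dataclasses.asdict(registry.RegistryConfig())
            base.update(reg)
            for key in ("beta_outcome", "gamma_treatment", "delta_hlos"):
                if isinstance(base[key], dict):
                    klass = (registry.OutcomeCoefficients if key == "beta_outcome"
                             else registry.StageCoefficients)
                    sub = {k: tuple(v) if isinstance(v, list) else v
                           for k, v in base[key].items()}
                    base[key] = klass(**sub)
            cfg.registry = registry.RegistryConfig(**base)
        return cfg


def prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived modelling columns (centred and logged variables)."""
    t = table.copy()
    t["age_c"] = t["age"] - registry.AGE_REF
    t["severity_c"] = t["severity"] - registry.SEVERITY_REF
    t["log_hlos"] = np.log(t["hlos"])
    t["log_rod"] = np.log(t["rod"])
    return t


# ---------------------------------------------------------------------------
# Limits of agreement
# ---------------------------------------------------------------------------

@dataclass
class LoaSummary:
    mean_difference: float
    loa_lower: float
    loa_upper: float
    sd_difference: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def loa_summary(p_a, p_b) -> LoaSummary:
    """Bland–Altman style numeric summary of paired probability differences."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("probability vectors must have the same length")
    d = p_a - p_b
    m = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return LoaSummary(mean_difference=m, loa_lower=m - 1.96 * sd,
                      loa_upper=m + 1.96 * sd, sd_difference=sd, n=len(d))


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

def _sub_seed(master: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    h = np.random.SeedSequence([master, abs(hash(name)) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def _model_entry(name, fit, y, p, cal_kwargs=None):
    rep = calibration.calibration_report(y, p, fit=fit)
    entry = {"status": "ok", "fit": fit.to_dict(), "calibration": rep.to_dict()}
    if cal_kwargs:
        entry.update(cal_kwargs)
    return entry


def run_study(config: StudyConfig) -> dict:
    """Run the whole study; returns the (JSON-serializable) report dict."""
    report: dict = {
        "seed": config.seed,
        "config": {
            "n_patients": config.registry.n_patients,
            "n_sites": config.registry.n_sites,
            "base_terms": list(config.base_terms),
            "added_covariates": list(config.added_covariates),
            "cv_k": config.cv_k,
            "cv_reps": config.cv_reps,
            "input_path": config.input_path,
        },
        "models": {},
        "standardized_comparison": {},
        "random_effects": {},
        "endogeneity": {},
        "loa": {},
        "ranking": {},
        "failures": [],
        "warnings": [],
    }

    if config.input_path:
        table = registry.read_registry(config.input_path)
        report["truth"] = None
    else:
        cfg = dataclasses.replace(config.registry, seed=_sub_seed(config.seed, "registry"))
        table, truth = registry.generate_registry(cfg)
        report["truth"] = {
            "treatment_intercept": truth.treatment_intercept,
            "outcome_intercept": truth.outcome_intercept,
            "error_correlation": np.asarray(truth.error_correlation).tolist(),
        }
    t = prepare_table(table)
    y = np.asarray(t["died"], dtype=float)
    report["cohort"] = {
        "n": int(len(t)),
        "n_sites": int(t["site_id"].nunique()),
        "mortality": float(t["died"].mean()),
        "ventilated": float(t["ventilated"].mean()),
    }

    def attempt(name, fn):
        try:
            return fn()
        except Exception as exc:  # per-model failures never abort the study
            log.warning("model %s failed: %s", name, exc)
            report["failures"].append({"model": name, "error": str(exc)})
            report["models"].setdefault(name, {"status": "failed", "error": str(exc)})
            return None

    fits: dict[str, binary.FitResult] = {}
    standardized: dict[str, pd.Series] = {}

    # --- eight base models -------------------------------------------------
    base_specs = {
        "logit1": binary.ModelSpec(link="logit", covariates=config.base_terms),
        "logit2": binary.ModelSpec(link="logit", covariates=config.base_terms,
                                   site_fixed_effects=True),
        "probit1": binary.ModelSpec(link="probit", covariates=config.base_terms),
        "probit2": binary.ModelSpec(link="probit", covariates=config.base_terms,
                                    site_fixed_effects=True),
    }
    for name, spec in base_specs.items():
        def _fit(name=name, spec=spec):
            fit = binary.fit_binary(t, spec)
            yk = (np.asarray(t.loc[fit.row_index, "died"], dtype=float)
                  if fit.row_index is not None else y)
            entry = _model_entry(name, fit, yk, fit.fitted)
            try:
                sh = calibration.cv_shrinkage(
                    t, spec, k=config.cv_k, reps=config.cv_reps,
                    seed=_sub_seed(config.seed, f"cv:{name}"))
                entry["calibration"].update(
                    shrink_in=sh.shrink_in, shrink_out=sh.shrink_out,
                    overfit_pct=sh.overfit_pct)
            except Exception as exc:  # e.g. unseen FE site in a held-out fold
                report["warnings"].append({"model": name,
                                           "warning": f"cv_shrinkage failed: {exc}"})
            report["models"][name] = entry
            fits[name] = fit
            if not spec.site_fixed_effects:
                tk = t.loc[fit.row_index] if fit.row_index is not None else t
                standardized[name] = binary.standardize_xy(fit, tk)
            return fit
        attempt(name, _fit)

    # --- LPM family ---------------------------------------------------------
    def _lpm(name, fe):
        spec = binary.ModelSpec(link="linear", covariates=config.base_terms,
                                site_fixed_effects=fe, robust_se=True)
        ols = binary.fit_binary(t, spec)
        ldm = binary.lpm_to_logit(ols, t)
        entry = _model_entry(name, ldm, y, ldm.fitted)
        report["models"][name] = entry
        fits[name] = ldm
        if not fe:
            fits["lpm_raw"] = ols
            standardized["lpm_all_n"] = binary.standardize_xy(ols, t)
            restr = binary.restrict_unit_interval(ols)
            y0 = y[restr.kept_mask]
            p0 = restr.fitted_kept
            rep0 = calibration.calibration_report(
                y0, np.clip(p0, 1e-10, 1 - 1e-10), fit=None)
            report["models"]["lpm0"] = {
                "status": "ok",
                "n_below0": restr.n_below0,
                "n_above1": restr.n_above1,
                "frac_below0": restr.frac_below0,
                "frac_above1": restr.frac_above1,
                "calibration": rep0.to_dict(),
            }
            # standardized coefficients of the LPM refitted on the restricted rows
            sub = t.loc[restr.kept_mask]
            if sub["died"].nunique() == 2:
                ols0 = binary.fit_binary(
                    sub, binary.ModelSpec(link="linear", covariates=config.base_terms,
                                          robust_se=True))
                standardized["lpm_01"] = binary.standardize_xy(ols0, sub)
        return ldm

    attempt("lpm1", lambda: _lpm("lpm1", False))
    attempt("lpm2", lambda: _lpm("lpm2", True))

    # --- random-effects models ---------------------------------------------
    for name, link in (("logit3", "logit"), ("probit3", "probit")):
        def _re(name=name, link=link):
            fit = random_effects.fit_re(
                t, link=link, covariates=config.base_terms,
                n_quad=config.re_quadrature_points)
            null = random_effects.fit_re(t, link=link, covariates=(),
                                         n_quad=config.re_quadrature_points)
            tk = t.loc[fit.row_index] if fit.row_index is not None else t
            yk = np.asarray(tk["died"], dtype=float)
            p = np.clip(fit.predict_marginal(tk), 1e-10, 1 - 1e-10)
            rep = calibration.calibration_report(yk, p)
            rep.aic, rep.bic = fit.aic, fit.bic
            try:
                dv = calibration.dev_val_report(
                    tk, binary.ModelSpec(link=link, covariates=config.base_terms),
                    seed=_sub_seed(config.seed, f"devval:{name}"))
            except Exception as exc:  # degenerate split cells
                dv = None
                report["warnings"].append({"model": name,
                                           "warning": f"dev_val failed: {exc}"})
            entry = {
                "status": "ok",
                "fit": fit.to_dict(),
                "calibration": rep.to_dict(),
                "icc_unconditional": random_effects.icc(null.tau2, link),
                "icc_conditional": random_effects.icc(fit.tau2, link),
                "r2_dichot": random_effects.r2_dichot(fit, tk),
                "dev_val": dv,
            }
            report["models"][name] = entry
            report["random_effects"][name] = {
                "tau2_null": null.tau2, "tau2_full": fit.tau2,
                "icc_unconditional": entry["icc_unconditional"],
                "icc_conditional": entry["icc_conditional"],
                "r2_dichot": entry["r2_dichot"],
            }
            fits[name] = fit
            return fit
        attempt(name, _re)

    # --- added-covariate logit variants --------------------------------------
    for extra in config.added_covariates:
        name = f"logit1_{extra}"
        def _added(name=name, extra=extra):
            spec = binary.ModelSpec(link="logit",
                                    covariates=tuple(config.base_terms) + (extra,))
            fit = binary.fit_binary(t, spec)
            yk = (np.asarray(t.loc[fit.row_index, "died"], dtype=float)
                  if fit.row_index is not None else y)
            report["models"][name] = _model_entry(name, fit, yk, fit.fitted)
            fits[name] = fit
            return fit
        attempt(name, _added)

    # --- standardized-coefficient comparison (logit as comparator) ----------
    if "logit1" in standardized:
        ref = standardized["logit1"]
        for other in ("probit1", "lpm_all_n", "lpm_01"):
            if other not in standardized:
                continue
            try:
                # models may retain different factor cells; compare shared terms
                a, b = ref.align(standardized[other], join="inner")
                cmp = binary.compare_standardized(a, b)
                report["standardized_comparison"][other] = {
                    "slope": cmp.slope, "se": cmp.se, "p_value": cmp.p_value,
                    "ci_lower": cmp.ci_lower, "ci_upper": cmp.ci_upper, "n": cmp.n,
                }
            except ValueError as exc:
                report["failures"].append({"model": f"standardized:{other}",
                                           "error": str(exc)})

    # --- limits of agreement: logit vs transformed LPM -----------------------
    if "logit1" in fits and "lpm1" in fits:
        fa, fb = fits["logit1"], fits["lpm1"]
        pa = pd.Series(fa.fitted, index=fa.row_index)
        pb = pd.Series(fb.fitted, index=fb.row_index)
        common = pa.index.intersection(pb.index)
        report["loa"]["logit1_vs_lpm1"] = loa_summary(
            pa.loc[common].values, pb.loc[common].values).to_dict()

    # --- extended probit analyses -------------------------------------------
    for endog_var in ("log_hlos", "log_rod"):
        name = f"eprobit_{endog_var}"
        def _erm(name=name, endog_var=endog_var):
            spec = endogenous.ErmSpec(
                outcome="died",
                outcome_terms=config.erm_outcome_terms,
                treatment="ventilated",
                treatment_terms=config.erm_stage_terms,
                endog_cont=endog_var,
                cont_terms=tuple(config.erm_stage_terms) + ("ventilated",),
            )
            fit = endogenous.fit_erm(t, spec)
            te = endogenous.treatment_effects(fit, t)
            grid = endogenous.margins_grid(fit, t, "severity_c",
                                           [v - registry.SEVERITY_REF
                                            for v in config.severity_grid])
            report["endogeneity"][name] = {
                "status": "ok",
                "fit": fit.to_dict(),
                "treatment_effects": te.to_dict(),
                "margins_severity": grid.to_dict(),
            }
            return fit
        try:
            _erm()
        except Exception as exc:
            log.warning("model %s failed: %s", name, exc)
            report["failures"].append({"model": name, "error": str(exc)})
            report["endogeneity"][name] = {"status": "failed", "error": str(exc)}

    # --- information-criteria ranking ----------------------------------------
    for crit in ("aic", "bic"):
        vals = {m: e["fit"][crit] for m, e in report["models"].items()
                if e.get("status") == "ok" and "fit" in e and crit in e["fit"]
                and e["fit"][crit] is not None}
        report["ranking"][crit] = sorted(vals, key=vals.get)

    return report


# ---------------------------------------------------------------------------
# Report serialization and schema validation
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path) -> None:
    """Serialize the report deterministically (sorted keys, plain types)."""
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=1, sort_keys=True,
                  allow_nan=False, default=float)


def _load_schema() -> dict:
    with resources.files("icumort").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None, path: str = "$") -> list[str]:
    """Check a report against the shipped structural schema.

    Supports the subset of JSON Schema the report schema uses (type,
    properties, required, items); returns a list of violations (empty =
    valid).
    """
    if schema is None:
        schema = _load_schema()
    errors: list[str] = []
    types = {"object": dict, "array": list, "string": str, "number": (int, float),
             "integer": int, "boolean": bool, "null": type(None)}
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        if not any(isinstance(report, types[a]) and not
                   (a in ("number", "integer") and isinstance(report, bool))
                   for a in allowed):
            errors.append(f"{path}: expected {typ}, got {type(report).__name__}")
            return errors
    if isinstance(report, dict):
        for req in schema.get("required", []):
            if req not in report:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                errors.extend(validate_report(report[key], sub, f"{path}.{key}"))
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            errors.extend(validate_report(item, schema["items"], f"{path}[{i}]"))
    return errors
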