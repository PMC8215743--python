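"""Synthetic ICU-registry cohorts with known endogeneity structure.

The generator emulates a national adult-ICU registry extract: patients nested
in sites, an APACHE-III-like severity score, 28 collapsed diagnostic
categories, hospital classification and annual-volume deciles at the site
level, mechanical-ventilation status, hospital length of stay (HLOS), an
externally derived risk-of-death probability (ROD) and hospital mortality.

The data-generating process is the structural model the estimators in
:mod:`icumort.endogenous` target:

* a latent-probit treatment equation for ventilation,
* a log-linear equation for HLOS that includes ventilation,
* a latent-probit mortality equation with a site random intercept,

with the three equation errors drawn from a trivariate Normal whose
correlations induce endogeneity of ventilation and log-HLOS in the mortality
equation.  ROD is built from the mortality equation's own linear predictor
plus link-scale noise, so it is endogenous by construction.  Full ground
truth (coefficients, realized site intercepts, error draws' correlations) is
returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HOSPITAL_LEVELS",
    "DX_CATEGORIES",
    "VOLUME_DECILES",
    "REGISTRY_COLUMNS",
    "OutcomeCoefficients",
    "StageCoefficients",
    "RegistryConfig",
    "TrueParameters",
    "ConfigurationError",
    "CalibrationError",
    "RegistryParseError",
    "generate_registry",
    "write_registry",
    "read_registry",
    "write_true_parameters",
    "read_true_parameters",
]

# ---------------------------------------------------------------------------
# Fixed categorical vocabularies
# ---------------------------------------------------------------------------

HOSPITAL_LEVELS = ("metropolitan", "private", "rural_regional", "tertiary")
#: Site-level marginal distribution of hospital classification (registry mix:
#: 17% metropolitan non-tertiary, 32.5% private, 6.5% rural/regional, 44% tertiary).
HOSPITAL_LEVEL_PROBS = (0.17, 0.325, 0.065, 0.44)

DX_CATEGORIES = tuple(f"dx{i:02d}" for i in range(1, 29))
VOLUME_DECILES = tuple(f"vol{i:02d}" for i in range(1, 11))

REGISTRY_COLUMNS = (
    "site_id",
    "hospital_level",
    "volume_decile",
    "age",
    "severity",
    "dx_category",
    "ventilated",
    "hlos",
    "rod",
    "died",
)

# Centring constants for linear predictors (documented reference values close
# to the cohort means: age 61.8y, severity 54.5 points).
AGE_REF = 62.0
SEVERITY_REF = 55.0


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. non-PD correlation matrix)."""


class CalibrationError(RuntimeError):
    """Intercept calibration by bisection failed; carries the equation name."""

    def __init__(self, equation: str, message: str = ""):
        self.equation = equation
        super().__init__(f"intercept calibration failed for the {equation} equation"
                         + (f": {message}" if message else ""))


class RegistryParseError(ValueError):
    """A registry file is malformed; names the offending column."""


def _dx_pattern(scale: float, phase: int) -> np.ndarray:
    """Deterministic, sum-zero effect pattern over the 28 diagnostic codes."""
    k = np.arange(28)
    v = np.sin(2.0 * np.pi * (k + phase) / 28.0) + 0.5 * np.cos(4.0 * np.pi * k / 28.0)
    v = v - v.mean()
    return scale * v


@dataclass
class OutcomeCoefficients:
    """Structural mortality-equation coefficients on the latent probit scale.

    ``ventilated`` is the structural treatment effect (λ_V) and ``log_hlos``
    the structural effect of log length of stay (λ_H); both act on the latent
    index, not the probability scale.
    """

    age: float = 0.012          # per year, centred at AGE_REF
    severity: float = 0.035     # per APACHE-III point, centred at SEVERITY_REF
    ventilated: float = 0.30    # λ_V
    log_hlos: float = 0.20      # λ_H


@dataclass
class StageCoefficients:
    """First-stage coefficients (treatment or log-HLOS equation).

    ``hospital_level``, ``volume_decile`` and ``dx_category`` are instruments:
    they enter the first stages but are excluded from the mortality equation.
    """

    severity: float = 0.02
    hospital_level: tuple[float, ...] = (0.0, 0.25, -0.15, 0.35)
    volume_decile: tuple[float, ...] = tuple(np.round(np.linspace(-0.20, 0.30, 10), 4))
    dx_category: tuple[float, ...] = tuple(np.round(_dx_pattern(0.45, 0), 4))
    ventilated: float = 0.0     # used only in the log-HLOS equation (λ_T)
    intercept: float = 0.0      # log-HLOS baseline; treatment intercept is calibrated


def default_treatment_coefficients() -> StageCoefficients:
    return StageCoefficients(severity=0.020)


def default_hlos_coefficients() -> StageCoefficients:
    return StageCoefficients(
        severity=0.008,
        hospital_level=(0.0, 0.10, -0.05, 0.15),
        volume_decile=tuple(np.round(np.linspace(-0.10, 0.15, 10), 4)),
        dx_category=tuple(np.round(_dx_pattern(0.30, 7), 4)),
        ventilated=0.30,        # λ_T: ventilation lengthens stay on the log scale
        intercept=2.10,         # exp(2.1) ≈ 8.2 baseline days
    )


@dataclass
class RegistryConfig:
    """Generator configuration; defaults are the study conditions.

    Correlation defaults are the estimated error-term correlations
    (ventilation–mortality −0.248, logHLOS–mortality −0.315,
    ventilation–logHLOS 0.119); the marginal targets are the cohort's
    hospital mortality (8.82%) and ventilated fraction (43.7%); 124 sites.
    Between-site heterogeneity is split between observable case-mix
    (site-level severity offsets) and a residual provider effect
    (``site_sd``), with case-mix dominating — the pattern in which a large
    unconditional ICC collapses once severity enters the model.
    """

    n_patients: int = 20_000
    n_sites: int = 124
    site_sd: float = 0.25                # τ: residual provider effect after case-mix
    severity_site_sd: float = 15.0       # case-mix: site-level severity offset SD
    corr_vm: float = -0.248
    corr_hm: float = -0.315
    corr_vh: float = 0.119
    sigma_h: float = 0.8                 # SD of the log-HLOS error
    beta_outcome: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    gamma_treatment: StageCoefficients = field(default_factory=default_treatment_coefficients)
    delta_hlos: StageCoefficients = field(default_factory=default_hlos_coefficients)
    target_mortality: float = 0.0882
    target_ventilated: float = 0.437
    rod_noise_sd: float = 0.5            # link-scale noise in the ROD construction
    seed: int = 0

    # -- validation --------------------------------------------------------
    def correlation_matrix(self) -> np.ndarray:
        """Latent error correlation matrix, order (ventilation, logHLOS, mortality)."""
        return np.array(
            [
                [1.0, self.corr_vh, self.corr_vm],
                [self.corr_vh, 1.0, self.corr_hm],
                [self.corr_vm, self.corr_hm, 1.0],
            ]
        )

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError("n_sites must be >= 2")
        if self.n_patients < self.n_sites:
            raise ConfigurationError("n_patients must be >= n_sites")
        if not (0.0 <= self.site_sd):
            raise ConfigurationError("site_sd must be nonnegative")
        if not (0.0 <= self.severity_site_sd):
            raise ConfigurationError("severity_site_sd must be nonnegative")
        if self.sigma_h <= 0:
            raise ConfigurationError("sigma_h must be positive")
        for name in ("corr_vm", "corr_hm", "corr_vh"):
            v = getattr(self, name)
            if not (-1.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie strictly in (-1, 1)")
        for name in ("target_mortality", "target_ventilated"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie strictly in (0, 1)")
        eigmin = np.linalg.eigvalsh(self.correlation_matrix()).min()
        if eigmin <= 1e-10:
            raise ConfigurationError(
                f"latent error correlation matrix is not positive definite "
                f"(smallest eigenvalue {eigmin:.3g})"
            )


@dataclass
class TrueParameters:
    """Ground truth stored verbatim from the generator."""

    config: RegistryConfig
    treatment_intercept: float
    outcome_intercept: float
    site_intercepts: np.ndarray             # realized u_j, length n_sites
    error_correlation: np.ndarray           # population 3x3 (V, logHLOS, M)
    realized_error_correlation: np.ndarray  # sample correlation of the draws

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "config": cfg,
            "treatment_intercept": self.treatment_intercept,
            "outcome_intercept": self.outcome_intercept,
            "site_intercepts": np.asarray(self.site_intercepts).tolist(),
            "error_correlation": np.asarray(self.error_correlation).tolist(),
            "realized_error_correlation": np.asarray(self.realized_error_correlation).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParameters":
        cfg = dict(d["config"])
        cfg["beta_outcome"] = OutcomeCoefficients(**cfg["beta_outcome"])
        for key in ("gamma_treatment", "delta_hlos"):
            sub = dict(cfg[key])
            for f in ("hospital_level", "volume_decile", "dx_category"):
                sub[f] = tuple(sub[f])
            cfg[key] = StageCoefficients(**sub)
        return cls(
            config=RegistryConfig(**cfg),
            treatment_intercept=d["treatment_intercept"],
            outcome_intercept=d["outcome_intercept"],
            site_intercepts=np.asarray(d["site_intercepts"]),
            error_correlation=np.asarray(d["error_correlation"]),
            realized_error_correlation=np.asarray(d["realized_error_correlation"]),
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _bisect_intercept(index: np.ndarray, target: float, equation: str,
                      tol: float = 1e-4, max_iter: int = 100) -> float:
    """Find c with mean(1{c + index > 0}) ≈ target by bisection.

    The empirical exceedance fraction is a monotone step function of ``c``,
    so bisection brackets the target; convergence within ``max_iter``
    iterations is required, otherwise a :class:`CalibrationError` names the
    equation.
    """
    lo, hi = -30.0, 30.0
    c = 0.0
    for _ in range(max_iter):
        c = 0.5 * (lo + hi)
        frac = float(np.mean(c + index > 0))
        if abs(frac - target) <= tol or (hi - lo) < 1e-12:
            return c
        if frac < target:
            lo = c
        else:
            hi = c
    frac = float(np.mean(c + index > 0))
    # the empirical CDF has steps of size 1/n; accept within half a percent
    if abs(frac - target) <= 5e-3:
        return c
    raise CalibrationError(equation, f"bisection did not converge ({max_iter} iterations)")


def _stage_index(coef: StageCoefficients, severity: np.ndarray,
                 level_idx: np.ndarray, decile_idx: np.ndarray,
                 dx_idx: np.ndarray) -> np.ndarray:
    return (
        coef.intercept
        + coef.severity * (severity - SEVERITY_REF)
        + np.asarray(coef.hospital_level)[level_idx]
        + np.asarray(coef.volume_decile)[decile_idx]
        + np.asarray(coef.dx_category)[dx_idx]
    )


def generate_registry(config: RegistryConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Generate a cohort table plus ground truth.

    Intercepts of the treatment and mortality equations are calibrated by
    bisection on the realized sample so the simulated marginals hit the
    configured targets.  Randomness flows from one master seed through
    independent substreams (sites, covariates, latent errors).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_sites, rng_cov, rng_err = (np.random.default_rng(s) for s in ss.spawn(3))
    n, J = config.n_patients, config.n_sites

    # --- sites: weights drive both patient allocation and the volume decile
    site_w = rng_sites.lognormal(mean=0.0, sigma=0.6, size=J)
    site_level_idx = rng_sites.choice(4, size=J, p=HOSPITAL_LEVEL_PROBS)
    # volume decile from the rank of the site's expected volume
    ranks = stats.rankdata(site_w, method="ordinal") - 1
    site_decile_idx = (ranks * 10 // J).astype(int)
    counts = rng_sites.multinomial(n - J, site_w / site_w.sum()) + 1  # every site >= 1
    site_idx = np.repeat(np.arange(J), counts)
    rng_sites.shuffle(site_idx)
    u_site = rng_sites.normal(0.0, config.site_sd, size=J)
    # site-level case-mix: tertiary-style units admit systematically sicker patients
    sev_site = rng_sites.normal(0.0, config.severity_site_sd, size=J)

    # --- patient covariates
    a, b = (16.0 - 61.8) / 17.5, (100.0 - 61.8) / 17.5
    age = stats.truncnorm.rvs(a, b, loc=61.8, scale=17.5, size=n, random_state=rng_cov)
    shape = (54.5 / 25.6) ** 2
    scale = 25.6 ** 2 / 54.5
    severity = np.clip(np.round(rng_cov.gamma(shape, scale, size=n)
                                + sev_site[site_idx]), 0, 299)
    dx_w = 1.0 / (np.arange(28) + 2.0)
    dx_idx = rng_cov.choice(28, size=n, p=dx_w / dx_w.sum())

    level_idx = site_level_idx[site_idx]
    decile_idx = site_decile_idx[site_idx]

    # --- correlated latent errors (ventilation, logHLOS, mortality)
    corr = config.correlation_matrix()
    d = np.array([1.0, config.sigma_h, 1.0])
    cov = corr * np.outer(d, d)
    eps = rng_err.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    eps_v, eps_h, eps_m = eps[:, 0], eps[:, 1], eps[:, 2]
    rod_noise = rng_err.normal(0.0, config.rod_noise_sd, size=n)

    # --- treatment assignment, calibrated to the ventilated target
    idx_v = _stage_index(config.gamma_treatment, severity, level_idx, decile_idx, dx_idx) + eps_v
    gamma0 = _bisect_intercept(idx_v, config.target_ventilated, "treatment")
    ventilated = (gamma0 + idx_v > 0).astype(np.int64)

    # --- hospital length of stay
    log_hlos = (
        _stage_index(config.delta_hlos, severity, level_idx, decile_idx, dx_idx)
        + config.delta_hlos.ventilated * ventilated
        + eps_h
    )
    hlos = np.exp(log_hlos)

    # --- mortality, calibrated to the mortality target
    bo = config.beta_outcome
    idx_m = (
        bo.age * (age - AGE_REF)
        + bo.severity * (severity - SEVERITY_REF)
        + bo.ventilated * ventilated
        + bo.log_hlos * log_hlos
        + u_site[site_idx]
        + eps_m
    )
    beta0 = _bisect_intercept(idx_m, config.target_mortality, "mortality")
    died = (beta0 + idx_m > 0).astype(np.int64)

    # --- ROD: noisy monotone transform of the true linear predictor
    rod = stats.norm.cdf(beta0 + idx_m - eps_m + rod_noise)
    rod = np.clip(rod, 1e-12, 1.0 - 1e-12)

    table = pd.DataFrame(
        {
            "site_id": pd.Categorical.from_codes(
                site_idx, categories=[f"S{j + 1:03d}" for j in range(J)]
            ),
            "hospital_level": pd.Categorical.from_codes(level_idx, categories=list(HOSPITAL_LEVELS)),
            "volume_decile": pd.Categorical.from_codes(decile_idx, categories=list(VOLUME_DECILES)),
            "age": age,
            "severity": severity.astype(np.int64),
            "dx_category": pd.Categorical.from_codes(dx_idx, categories=list(DX_CATEGORIES)),
            "ventilated": ventilated,
            "hlos": hlos,
            "rod": rod,
            "died": died,
        }
    )

    realized = np.corrcoef(np.column_stack([eps_v, eps_h, eps_m]), rowvar=False)
    truth = TrueParameters(
        config=config,
        treatment_intercept=gamma0,
        outcome_intercept=beta0,
        site_intercepts=u_site,
        error_correlation=corr,
        realized_error_correlation=realized,
    )
    return table, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CATEGORIES = {
    "hospital_level": list(HOSPITAL_LEVELS),
    "volume_decile": list(VOLUME_DECILES),
    "dx_category": list(DX_CATEGORIES),
}


def write_registry(table: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV with the canonical column order."""
    missing = [c for c in REGISTRY_COLUMNS if c not in table.columns]
    if missing:
        raise RegistryParseError(f"table is missing column(s): {', '.join(missing)}")
    table.loc[:, REGISTRY_COLUMNS].to_csv(path, index=False)


def read_registry(path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the canonical columns and dtypes."""
    raw = pd.read_csv(path)
    for col in REGISTRY_COLUMNS:
        if col not in raw.columns:
            raise RegistryParseError(f"registry file is missing column: {col}")
    table = raw.loc[:, list(REGISTRY_COLUMNS)].copy()
    if table[REGISTRY_COLUMNS[0]].isna().any() or table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise RegistryParseError(f"registry file has missing values in: {', '.join(bad)}")
    site_cats = sorted(table["site_id"].astype(str).unique())
    table["site_id"] = pd.Categorical(table["site_id"].astype(str), categories=site_cats)
    for col, cats in _CATEGORIES.items():
        vals = table[col].astype(str)
        unknown = set(vals.unique()) - set(cats)
        if unknown:
            raise RegistryParseError(f"unknown level(s) in column {col}: {sorted(unknown)}")
        table[col] = pd.Categorical(vals, categories=cats)
    for col in ("ventilated", "died", "severity"):
        table[col] = table[col].astype(np.int64)
    for col in ("age", "hlos", "rod"):
        table[col] = table[col].astype(np.float64)
    if (table["hlos"] <= 0).any():
        raise RegistryParseError("registry file has non-positive values in column: hlos")
    if ((table["rod"] <= 0) | (table["rod"] >= 1)).any():
        raise RegistryParseError("registry file has out-of-range values in column: rod")
    return table


def write_true_parameters(truth: TrueParameters, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_true_parameters(path) -> TrueParameters:
    with open(path) as fh:
        return TrueParameters.from_dict(json.load(fh))
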