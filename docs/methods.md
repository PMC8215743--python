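# Methods

This note records the models, the generator's assumptions, the numerical
choices, and the limits of what the test suite demonstrates.

## The structural model and the generator

The synthetic registry is generated from the same recursive system the
extended probit estimates:

```
ventilation:  V  = 1{ γ0 + z_v'γ + ε_v > 0 }
log HLOS:     h  = δ0 + z_h'δ + λ_T V + ε_h
mortality:    M  = 1{ β0 + x'β + λ_V V + λ_H h + u_j + ε_m > 0 }
```

with (ε_v, ε_h, ε_m) trivariate Normal — unit variances for the two probit
errors, SD σ_h for the HLOS error — and correlations (ρ_vh, ρ_vm, ρ_hm).
`u_j ~ N(0, τ²)` is a residual site (provider) intercept in the mortality
equation only. Nonzero ρ_vm and ρ_hm are what make ventilation and log-HLOS
endogenous when they appear as mortality covariates. ROD, the external
risk-of-death probability, is built as Φ(true linear predictor + N(0, 0.5))
on the link scale: a regression of the outcome on (a noisy version of) its
own components, endogenous by construction.

Defaults are the study conditions: correlations (−0.248, −0.315, 0.119),
marginal targets 8.82% mortality and 43.7% ventilated, 124 sites, age
truncated-Normal(61.8, 17.5²) on [16, 100], severity Gamma matched to mean
54.5 / SD 25.6 (rounded, capped at 299), 28 diagnostic categories with
smoothly varying prevalences, site-level hospital classification drawn at
the registry mix (17 / 32.5 / 6.5 / 44%) and volume deciles assigned by the
rank of each site's expected volume. Treatment and mortality intercepts are
calibrated by bisection on the realized sample so the marginal targets are
hit to ±0.5 points or better at the default sizes.

Structural values the source analysis does not pin down are scenario
choices, fixed once: λ_V = 0.3 and λ_H = 0.2 on the latent scale,
λ_T = 0.3 on the log-days scale, σ_h = 0.8, ROD link-noise SD 0.5. The
ventilation→mortality effect in particular has no published structural
value; recovery tests measure the estimator against the scenario, not
against the clinical literature.

Between-site heterogeneity is deliberately split into two parts. Observable
case-mix — site-level severity offsets with SD 15 points — dominates; the
residual provider effect is τ = 0.25. This reproduces the qualitative
pattern reported for the real cohort, where the unconditional ICC (≈ 0.2)
collapses to near zero (≈ 0.02) once patient covariates enter the model:
most apparent between-ICU variation is explained by who the ICUs admit. A
generator that put all heterogeneity into `u_j` would invert that pattern,
because covariates could then explain none of it.

Randomness flows from one master seed through three named substreams
(sites, covariates, latent errors); a fixed seed reproduces the table
bit-for-bit.

### What the generator does not emulate

No missing data, no time-varying severity, no informative site sizes beyond
the volume/decile link, no heavy-tailed or zero-inflated length-of-stay
features beyond log-normality, and patient covariates are independent of
the latent errors by construction. Passing recovery tests therefore shows
the estimators are correct under their assumed model — not that those
assumptions hold in any real registry. Joint normality of the three error
terms is exactly the assumption a real analysis cannot verify.

## Binary models

Logit/probit are fitted by Newton ML and the LPM by OLS (statsmodels),
behind a uniform `FitResult`. Two pragmatic policies:

* **Perfectly predicted cells.** A factor level whose outcomes are all 0 or
  all 1 (an all-survivor site under fixed effects, a small diagnostic
  category with no deaths) sends its dummy to ±∞. Such levels are dropped
  with their rows for the ML links and recorded on the fit
  (`dropped_sites`, `dropped_levels`); the LPM keeps them. Newton stops
  that report "non-convergence" with a numerically zero score are accepted —
  that is the drifting-dummy signature, and the likelihood is converged.
  Genuine separation by a continuous covariate (standardized coefficient
  above 20) raises an explicit error instead of returning a silently huge
  estimate.
* **Aliased columns** are removed by pivoted QR before fitting, so
  cross-validation folds that empty a factor cell still fit.

**Haggstrom transform.** Slopes map as β_j = K·b_j with K = N/RSS — this is
exact two-group Gaussian discriminant algebra and needs no prevalence
adjustment. The intercept does: with p̄ the outcome mean and
Δ = mean(ŷ|y=1) − mean(ŷ|y=0) the plug-in for (μ₁−μ₀)'w,

```
intercept* = logit(p̄) + K(b0 − p̄) − K(1/2 − p̄)Δ .
```

The last term comes from x̄ = π₁μ₁ + π₀μ₀, so ½(μ₁+μ₀) = x̄ + (½−π₁)(μ₁−μ₀);
it vanishes for balanced classes, which is why simplified statements of the
rule omit it, but at 8.8% prevalence it is worth about −1.6 logit units and
without it the transformed probabilities are useless. With it, the
transform matches a directly fitted ML logit to a mean absolute difference
below 0.001 on Gaussian discriminant data at any prevalence tested (0.5,
0.2, 0.088), and logit-vs-transformed-LPM mean differences on default
cohorts are ~0.002 — "exceptionally small", as expected.

**X–Y standardization** uses sample SDs (ddof = 1) of the realized design
columns, the latent variance var(x'β̂) + c, and excludes the intercept;
dummy columns are standardized like any other column (the convention of the
standard post-estimation tools). The cross-model comparison regresses one
standardized vector on the other **with** an intercept by default; the
no-intercept variant is a flag.

A note on the dichotomous R² across links: with
R² = σ_F²/(σ_F² + τ₀² + σ_R²), the logit/probit ordering is governed by the
fitted index-variance ratio against π²/3 ≈ 3.29. On data simulated from a
logistic model the fitted slope ratio is ≈ 1.6 (< √3.29 ≈ 1.81), so the
probit R² is marginally the larger; a logit R² clearly above the probit one
(as on the real cohort, where the implied variance ratio is ≈ 5) is a
property of heavy, skewed real-data indexes, not of logistic data per se.
The test suite asserts the formula and the closeness, not a universal
ordering.

## Random-intercept models

The marginal likelihood integrates the site intercept out with adaptive
Gauss–Hermite quadrature: at every evaluation the per-site integrand modes
are found by vectorized damped Newton (tolerance 1e-10), the curvature sets
the scale, and the probabilists' Hermite nodes are re-centred accordingly.
Twelve nodes are the default; accuracy improves with site size, and on
124-site cohorts with ≥ 300 patients per site doubling the node count moves
the total log-likelihood by < 1e-4 (the adaptivity check). Optimization is
over (β, log τ) by L-BFGS-B with the design columns standardized internally
— without that scaling, interaction columns spanning thousands make the
finite-difference quasi-Newton search unreliable. A τ̂ at the boundary is
profiled against the single-level fit and reported as τ² = 0 with a
boundary flag, never raised.

ICC = τ₀²/(τ₀² + c) with c = π²/3 (logit) or 1 (probit); the caller chooses
whether τ₀² comes from the null model (unconditional) or the full model
(conditional), the denominator constant is the same. The conditional ICC
uses the full-model τ₀² directly. Two estimation facts worth knowing when
interpreting null-variance tests: a *misspecified* single-level model
(omitted covariates whose distribution varies by site, or a logit fit to
probit data under site case-mix differences) produces genuinely positive
τ̂² even when the generator has none; the "τ̂² ≈ 0 under τ = 0" property
holds for the correctly specified model.

## Calibration suite

* **Hosmer–Lemeshow**: quantile groups (default 10) with ties kept low,
  heavy-tie groups merged and flagged; statistic Σ(O−E)²/(E(1−E/n_g));
  reference χ² with g−2 df. The quoted large-N yardstick 15.99 is the
  upper-0.10 χ² quantile at 10 df, reproduced as arithmetic, not adopted as
  the df convention.
* **Calibration belt**: logit(y) on polynomials of logit(p), forward LR
  selection starting at degree 2, α = 0.05, maximum degree 4; deviation
  p-value from the LR test of the selected model against the fixed identity
  (offset) model with degree+1 df; 95% pointwise delta-method band on a
  probability grid.
* **Binned residuals**: equal-count bins (default ⌊√n⌋, a constant
  prediction collapses to one bin), bound 2√(p̄(1−p̄)/n_bin), coverage
  reported.
* **Weak calibration**: CITL is the intercept of a Bernoulli GLM with
  logit(p) as offset (so predictions shifted +0.5 on the logit scale give
  CITL ≈ −0.5); slope is the coefficient in logit(y) ~ logit(p) (halved
  logits give ≈ 2); E:O = Σp/Σy. For an ML logit with intercept evaluated
  on its own training data E:O = 1 identically (score equation).
* **Shrinkage / overfitting**: per repetition a fresh k-fold partition;
  in-sample shrinkage % = 100(1 − slope) on pooled training predictions,
  out-of-sample on pooled held-out predictions, overfitting % their
  difference, averaged over repetitions, fully seeded.

## Extended probit

The likelihood conditions on the continuous residual: each observation
contributes the Normal density of e_h = h − z_h'δ times the bivariate
orthant probability of the two signed probit indices given ε_h = e_h
(conditional means ρ·e_h/σ_h, conditional correlation from the Schur
complement, sign flips s = 2y−1 on both thresholds and correlation).
Reduced systems (treatment-only → recursive bivariate probit;
continuous-only → IV-probit) are the same code path with the relevant
pieces removed. The bivariate Normal CDF uses Owen's T identity
(`scipy.special.owens_t`), accurate to ~1e-13 everywhere including the far
tails that dominate at extreme severity.

Estimation is one-step ML over the unconstrained parameterization
(atanh ρ, log σ_h) by L-BFGS-B with an **analytic** per-observation score
(closed-form Φ₂ partials), started from the stacked independent fits with
ρ = 0. Score ratios at the 1e-300 orthant floor are clipped — relevant only
for pathological line-search points. The sandwich covariance uses the
analytic score outer product and a finite-difference Hessian of the score;
ρ inference is reported through the Fisher-z transform (z-statistic on the
atanh scale, CI mapped back through tanh, so it respects (−1,1) by
construction). A joint Wald test of the excluded instruments in each first
stage triggers a weak-instrument warning at p > 0.05.

Potential outcomes fix the treatment, propagate it through the structural
HLOS prediction, and integrate (ε_h, ε_m) jointly:
pom_v(i) = Φ(a_m(i,v)/s), s² = β_H²σ_h² + 2β_Hρ_hmσ_h + 1. ATE averages
pom1 − pom0 over everyone, ATET over the treated; both CIs are delta-method
with the sandwich covariance (numerical gradient of the scalar effect in
the full parameter vector). The default ATET is this unconditional version;
`conditional=True` additionally conditions the treated on their own
selection region ε_v > −z_v'γ via Φ₂ — documented because the choice is
genuinely open, the unconditional default keeps the delta method simple.
Margins grids do the same with a covariate pinned to grid values, so their
bands account for full parameter uncertainty ("unconditional" in the
margins sense: the sandwich already reflects covariate sampling).

The site random intercept is **not** part of the extended probit (it is a
single-level estimator); on cohorts generated with τ > 0 the recovered
correlations and coefficients attenuate by 1/√(1+τ²) relative to the
configured values, because the outcome-equation error is then ε_m + u with
variance 1 + τ². Recovery tests therefore run the generator with τ = 0;
with the default τ = 0.25 the attenuation is ≈ 3%, well inside sampling
noise at test sizes, which is why the worked example still brackets the
configured values. Requesting both log-HLOS and log-ROD simultaneously
endogenous is accepted but not guaranteed to converge (the corresponding
real-data attempt did not either); the iteration guard raises with a trace.

## Problem sizes in the tests

Test and acceptance simulations are sized for a single CPU: cohorts of
2,000–37,200 patients, 10 replicates for extended-probit recovery
(n = 6,000), 6 replicates for τ² recovery (n = 12,400, 124 sites), 150–200
replicates for the null-distribution checks of the calibration machinery,
and the logit/probit multiplier at n = 100,000 × 4 in the suite and at the
full n = 200,000 × 10 in `scripts/acceptance.py`. Statistical assertions
use size-appropriate Monte-Carlo error bands (3 MC SEs, or coverage counts
with the binomial slack the replicate count implies).

## Known limitations

* The extended-probit Hessian is finite-difference; for very large systems
  an analytic Hessian would be faster and slightly more accurate.
* The calibration belt's band is a pointwise delta-method band, not the
  simultaneous band of the original belt construction; degree selection and
  the deviation test follow the LR recipe exactly.
* ATET conditioning, the H-L df convention and the shrinkage definitions
  follow the documented choices above; alternatives are computable but not
  defaults.
* `fit_re` supports a single level of nesting (random intercepts only); no
  random slopes, crossed effects, or correlated-random-effects (Mundlak)
  formulations.
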