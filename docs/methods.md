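# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the synthetic test data can show. Units: exposures are
carried internally in µg/kg BW/day and converted to mg/kg BW/day at the
risk-characterisation boundary, so the margin-of-exposure ratio is
dimensionally consistent with benchmark doses in mg/kg BW/day.

## Exposure model

Person-day exposure is the sum over consumed foods of amount (g) / body
weight (kg) × food concentration (µg/g) × nanofraction F. Food
concentrations come from "basic" powder products: each basic product's
measured total-silica values (mg/g) are summarised by their **arithmetic
mean**, multiplied by the food's composition fraction and by 1000 (mg/g →
µg/g). The mean (rather than a median or a mixture) is chosen because
concentration uncertainty is propagated by bootstrapping the measured rows
within each basic product, and the bootstrap-of-mean logic matches the
mean summary.

The nanofraction F — the fraction of total silica in nano-form after
ingestion — is a single uncertain scalar, not a variability source: chronic
exposure averages day-to-day variation out. Its uncertainty distribution is
logistic-normal, logit(F) ~ N(µ, σ²), fitted to a median of 0.5 and a 95th
percentile of 0.8 (µ = 0, σ = 0.8428). This leaves about 2 % probability
above 0.85 and, by symmetry, 2 % below 0.15.

### Usual-intake (two-part) model

Two recall days per person overstate long-term between-person variation,
so person-day exposures are converted to usual intakes with the two-part
logistic-normal-normal shrinkage model:

* frequency: logit P(positive day | person) = α + u₁,
* amount: ln(exposure | positive) = β + u₂ + ε, ε ~ N(0, σ_ε²),
* (u₁, u₂) bivariate normal with standard deviations σ₁, σ₂ and
  correlation ρ.

The usual intake of an individual is expit(α + u₁) · exp(β + u₂ + σ_ε²/2).
Person effects are integrated by fixed-order Gauss–Hermite quadrature
(21 nodes per dimension). With only two days the frequency–amount
correlation is weakly identified, so the default fixes ρ = 0 ("LNN0"); the
two parts then separate into a logistic random-intercept likelihood
(1-D quadrature over aggregated (positives, days) patterns) and a
compound-symmetric Gaussian likelihood in closed form.
`estimate_correlation=True` fits the joint model by 2-D quadrature. The
amount transform is the natural log (no Box–Cox family) and there are no
covariates; this is a deliberate simplification relative to full
survey-software implementations and is documented as a variant, not a
replication.

Numerical choices:

* the amount intercept β is profiled out in closed form (the GLS weighted
  mean of person means given the two variance components), which removes
  one optimisation dimension and makes the fit exactly equivariant under
  rescaling of the exposures up to optimizer determinism (~1e-8);
* the frequency part is optimised by Nelder–Mead over (α, σ₁); the amount
  dispersions by L-BFGS-B with a Nelder–Mead polish when L-BFGS-B stalls
  near machine precision;
* standard errors come from the numerically differentiated Hessian
  (statsmodels `approx_hess1`); parameters fixed at a boundary report NaN;
* degenerate data are handled explicitly: all person-days positive fixes
  the frequency at 1 (one-way random-effects decomposition remains);
  a single positive day or identical positive amounts set both amount
  variances to zero; no positive exposure at all is an error.

Two prediction modes exist: `simulated-population` draws fresh (u₁, u₂)
individuals — the mode used in the risk engine, so extreme percentiles
(p0.1) are estimable beyond the surveyed n — and `shrunken-persons`
returns empirical-Bayes posterior-mean usual intakes per surveyed person
for diagnostics.

### Dose metrics

The particle-number metric assumes monodisperse spheres at the median
diameter (default 100 nm) with amorphous-silica density 2.2 g/cm³:
particles per mg = 1/(ρ·(π/6)·d³·1000) with d in cm, ≈ 8.68×10¹¹/mg at the
defaults. Both the exposure and the hazard side use the same spec, so the
conversion cancels in the margin of exposure; the engine exploits this by
computing IMoE on the mass scale and converting only the reported
exposure/hazard distributions, which makes the two metrics identical by
construction. Diameter and density stay configurable because the spherical
monodisperse reconstruction is an assumption.

## Hazard model

The response is the number of positive liver-fibrosis slides out of 10 per
rat, Binomial(10, p(dose)). Seven families are fitted by maximum
likelihood with slopes constrained non-negative:

| family | p(d) | free parameters |
|---|---|---|
| logistic | expit(a + b·d) | 2 |
| probit | Φ(a + b·d) | 2 |
| log-logistic | p₀ + (1−p₀)·expit(a + b·ln d) | 3 |
| log-probit | p₀ + (1−p₀)·Φ(a + b·ln d) | 3 |
| weibull | p₀ + (1−p₀)·(1 − exp(−eᵃ·d^b)) | 3 |
| gamma | p₀ + (1−p₀)·P(shape, rate·d) | 3 |
| two-stage | p₀ + (1−p₀)·(1 − exp(−(q₁d + q₂d²))) | 3 |

The default likelihood is plain binomial; a beta-binomial switch adds one
intraclass-correlation parameter for litter-like overdispersion. The
benchmark dose is the **ED50**: the dose at which the response is midway
between background and one ((p₀+1)/2 for background families, 0.5
otherwise — the "additional risk 50 %" convention). Closed forms exist for
all families (the gamma via the inverse regularised incomplete gamma) and
are cross-checked against a generic bracketing root-finder in the tests.
The AIC (2k − 2 logL, with the binomial combinatorial constant included in
logL) selects the nominal model; ties go to fewer parameters, then a fixed
family order. Goodness of fit is the likelihood-ratio statistic against
the saturated (one probability per dose group) model on (groups − k)
degrees of freedom; with zero df the fit is flagged saturated instead.

Boundary handling: all-zero or all-maximal responses, or identical group
fractions at every dose, are flagged at fit time; their ED50 is undefined
and such parametric-bootstrap refits are dropped and counted (a warning
fires when a family loses more than 20 %).

BMD uncertainty pools parametric-bootstrap ED50s: for each family, 100
datasets are simulated from its fitted probabilities at the original
design, refitted within the family, and the ED50s pooled across families
(nominally 700 values). Outer-loop draws resample uniformly with
replacement from the pooled set.

### Extrapolation factors

* **EF_chronic** (subchronic → chronic): nominal 1.475; uncertainty
  lognormal with arithmetic mean 1.80 and sd 1.52. The implied lognormal
  median (1.375) differs from the printed nominal 1.475; both constants
  are kept as given, the nominal for uncertainty-off runs and the
  moment-matched lognormal for draws.
* **EF_inter** (rat → average human): allometric caloric-demand scaling
  (bw_human/bw_rat)^0.25 = (70/0.25)^0.25 ≈ 4.09, rounded to the nominal 4;
  uncertainty lognormal with GM 4 and GSD exp(ln(10/4)/z_0.99) ≈ 1.48.
* **IEF_intra** (individual sensitivity): lognormal variability with GM 1
  and GSD exp(σ₀); uncertainty about σ via σ² = σ₀²·ν/χ²_ν. Requiring the
  central 95 % uncertainty interval of the 95th-percentile sensitivity
  ratio exp(z₀.₉₅·σ) to be [2, 10] pins the chi-square quantile ratio
  χ²₀.₉₇₅,ν/χ²₀.₀₂₅,ν = (ln10/ln2)², a 1-D root giving ν ≈ 6.25, after
  which σ₀ follows in closed form: GSD₀ = exp(σ₀) ≈ 1.91. The chi-square
  is applied to σ² (not σ); this choice reproduces the 1.91 constant.

## Two-dimensional Monte Carlo

Outer (uncertainty) iterations draw: a person-level bootstrap of the
survey, a within-basic-product bootstrap of the concentrations, a
nanofraction, a pooled-BMD value, EF_chronic, EF_inter and the intraspecies
GSD — each from its own named RNG sub-stream keyed by (master seed,
iteration, stage), so toggling one source never perturbs another's draws.
Sources toggled off sit at their nominals (F = 0.5, BMD = AIC-best ED50,
1.475, 4, GSD 1.91). Inner (variability) iterations draw a simulated
population of usual exposures and of individual benchmark doses
(IBMD = BMD/(EF_chronic·EF_inter·IEF), IEF lognormal at the drawn GSD) and
pair them independently: IMoE = IBMD/IEXP.

Because the nanofraction multiplies every exposure, the usual-intake model
is fitted once per (survey, concentration) resample at F = 1 and the
simulated intakes are scaled by the drawn F afterwards — exact under the
log-linear amount model, and the basis for caching the fit when neither
bootstrap is active. Iterations whose usual-intake fit fails are skipped
and logged; more than 5 % skipped aborts the run.

Recorded per iteration: the percentiles (0.1, 1, 5, 50, 95, 99, 99.9) of
the IMoE sample — quantiles throughout use linear interpolation of order
statistics (position p·(n−1)+1) — the fraction at risk (IMoE < 1), and the
drawn components. The nominal run (all sources off) supplies the box of
each IMoE bar; whiskers are the 5 % quantile (across outer iterations) of
the lower percentile and the 95 % quantile of the upper percentile.
Exceedance curves use strict inequality, so an all-positive usual-intake
distribution starts at 1.

Defaults are 500 outer iterations (the study's bootstrap count) and an
inner sample of 10⁵ (the inner size is not fixed by the study design; 10⁵
makes the p0.1/p99.9 estimates usable while keeping one iteration cheap).

## Factorial sensitivity analysis

All 2⁷ = 128 on/off patterns of the seven sources are run with matched
sub-streams and the same master seed; each cell is summarised by the
variance across uncertainty repetitions of **log10** of the target
percentile (the IMoE spans orders of magnitude; the study does not state
the scale, so the log choice is a documented deviation risk). A linear
model variance ≈ β₀ + Σβⱼ·onⱼ is fitted by least squares; contributions
are the clipped-to-zero coefficients normalised to 100 % over the eight
bars (Monte Carlo intercept + seven sources), with raw coefficients kept
alongside. The default 50 repetitions per cell keeps a full analysis
tractable; the full 500 × 128 design is supported.

## Synthetic data

The consumption survey and the rat study are not public, so seeded
generators stand in:

* **Survey**: per person one body weight (normal, mean 70 kg, sd 12 kg,
  truncated positive) and, per food, a Bernoulli consumption indicator per
  person-day (default probability 0.3) with lognormal amounts
  (default ln 50 g intercept, between-person sd 0.5, within-person sd
  0.75). Per-food person effects share a common person component
  (correlation 0.5) so aggregation over foods leaves a genuine two-part
  structure for the usual-intake fit. Defaults are field-plausible choices
  for occasionally consumed powder-based foods, not calibrated claims —
  the real survey's per-product amount distributions are unpublished.
* **Dose-response**: Binomial(10, p(dose)) counts per rat from any of the
  seven families as simulation truth, with an optional beta-binomial
  intraclass correlation. The default design mirrors the original study's
  shape (control + treatment groups, 10 slides per rat).
* **Concentration table**: lognormal (median, GSD) measured values grouped
  1–5 per basic product. The packaged fixture carries the 25 real measured
  products (13 basic products) with their total-silica values and
  composition links; "<0.1 mg/g" nano-range entries are stored as
  left-censored bounds and are not used by the pipeline (the nanofraction
  model replaces them).

Because the generators define their own truth, passing tests demonstrate
*statistical correctness of the machinery* (parameter recovery, interval
coverage, test size, invariances) — they do not reproduce the original
study's population numbers, which depend on the non-public data.

## Known limitations

* Concentration uncertainty rests on 1–5 measurements per basic product;
  the within-product bootstrap understates it.
* The LNN implementation is a log-scale, covariate-free variant of the
  survey-software original; no survey weights or demographics.
* No BMDL/profile-likelihood limits, no litter-random-effect dose-response
  models, no surface-area dose metric, no acute (person-day) risk
  characterisation.
* The additive variance decomposition reports main effects only;
  interactions show up as unexplained variance.
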