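# Methods

## Scope and model

`vancoppk` implements a population-pharmacokinetic analysis of vancomycin in
very-low-birth-weight (VLBW, < 1,500 g) neonates: a covariate-parameterised
one-compartment model, a synthetic-cohort and sparse-sampling data generator,
approximate-maximum-likelihood mixed-effects estimation with likelihood-ratio
covariate selection, simulation-based model evaluation (VPC, NPDE), and a
Monte Carlo dosing engine that produces probability-of-target-attainment
(PTA) tables and dose recommendations stratified by postmenstrual age (PMA)
and serum creatinine (Scr).

The structural model is one-compartment with zero-order (infusion) input and
first-order elimination.  Typical parameters:

    V  = v_ref * (WT / 0.93)
    Cl = cl_ref * (WT / 0.93)^0.75 * (0.6 / Scr)^scr_exp * F(PMA)
    F(PMA) = PMA^hill / (PMA^hill + TMA50^hill)

with fixed allometric exponents (0.75 on Cl, 1 on V), reference weight
0.93 kg and reference creatinine 0.6 mg/dl (Jaffe scale; enzymatic-assay
measurements are first rescaled by `jaffe = 0.122 + enzymatic/1.05`).
Between-subject variability is lognormal, `p_i = p * exp(eta_i)` with
`eta ~ N(0, omega^2)` independently on Cl and V (no covariance; none is
supported by the sparse design).  Residual error is proportional by default,
`y = f (1 + b*eps)`; constant and combined forms are available.

Reference parameter values (the package defaults): `cl_ref = 0.09 L/h`
(mature limit), `v_ref = 0.81 L`, `hill = 4.42`, `TMA50 = 26.3 wk`,
`scr_exp = 0.48`, `omega_cl = 0.28`, `omega_v = 0.24`, `b = 0.3`.  Note that
`cl_ref` is the asymptotic (fully mature) clearance at the reference
covariates; at PMA 30 wk the maturation fraction is about 0.64, so the
typical clearance actually seen in this population is ~0.058 L/h.

## Exposure metrics: initiation phase vs steady state

Two exposure definitions are implemented and both are exact closed forms for
linear elimination:

* **Steady state** (`steady_state_metrics`): `AUC0-24 = (24/tau) * dose / Cl`
  (the time-averaged identity, which is what AUC-based dosing targets mean
  and the only interval-independent definition for q18h regimens); trough is
  the accumulated concentration at the end of a dosing interval; "peak" is
  the concentration 1 h after the end of the infusion (the monitoring
  convention, not Cmax).
* **Initiation phase** (`initiation_exposure_metrics`, the dosing engine's
  default): the exposure of a course started at time 0 — AUC over hours
  24-48 of therapy by the mass-balance identity
  `AUC(w0,w1) = infused_mass/Cl + (C(w0)-C(w1))/ke`, trough 30 min before
  the first dose at or after 24 h (the first routine monitoring trough),
  peak 1 h after that dose's infusion.

The initiation metric is the default for dose selection because the question
the PTA tables answer is *which empiric starting dose to give before any
measured level is available*, and AUC-guided monitoring is evaluated over
the first 24-48 h of therapy.  At typical VLBW half-lives (7-12 h)
concentrations are still accumulating on day 2, so initiation exposure runs
15-25% below steady state; a steady-state reading of the same targets would
overstate both attainment and toxicity of an initial regimen.  Published
neonatal PTA tables of this kind are consistent with the initiation-phase
definition and are mathematically inconsistent with the steady-state one
(steady-state AUC = dose/Cl forces an AUC coefficient of variation of at
least `sqrt(exp(omega_cl^2)-1)` ~ 28.6%, above what such tables report).
Infusion duration defaults to 1.0 h (common neonatal practice; never stated
by dosing references) and is configurable per regimen.

## Synthetic cohort

Covariates are drawn from a Gaussian copula over (weight, PMA, Scr, birth
weight) with truncated-normal marginals:

| covariate     | mean  | SD   | range       | units |
|---------------|-------|------|-------------|-------|
| weight        | 1.0   | 0.29 | 0.46 - 2.2  | kg    |
| PMA           | 30.0  | 3.2  | 22 - 42     | wk    |
| Scr (Jaffe)   | 0.64  | 0.22 | 0.2 - 1.2   | mg/dl |
| birth weight  | 0.966 | 0.27 | 0.46 - 1.5  | kg    |

The stated means/SDs are *realised* (post-truncation) moments: the
underlying normal parameters are moment-matched numerically, so the sampled
marginals reproduce the table above rather than drifting under truncation.
Latent correlations default to corr(weight, PMA) = 0.7 (weight tracks
maturation), corr(PMA, Scr) = -0.2, corr(weight, Scr) = 0, and birth weight
is tied to current weight (0.9) and PMA (0.6); all configurable, since only
marginals are identifiable from published demographics.  Postnatal age is
uniform on 1-30 days, gestational age is derived as `PMA - PNA/7`, sex is
categorical (46/33/21% male/female/missing) and the extremely-low-birth-
weight flag is `birth weight < 1.0 kg` (~57% of the cohort).  About one
third of subjects are flagged as measured with an enzymatic creatinine
assay; their stored raw values pass through the Jaffe calibration exactly
once (a guard flag makes double conversion an error).

Dosing follows tertiary neonatal references (NeoFax-style PMA/PNA bands by
default; Lexicomp age- and kidney-function-directed tables available), with
the printed 10-15 mg/kg ranges resolved to a 15 mg/kg point dose.  Sampling
emulates routine monitoring: every subject contributes one steady-state
trough drawn 30 min before a dose, 32% a second trough one interval later,
and 10% a peak 1 h after an infusion (yielding ~1.4 observations/subject;
162 subjects with the second-trough fraction alone give ~214 observations).
Steady state for scheduling is declared after the later of 72 h of dosing or
five *typical* (covariate-predicted) half-lives.  Using typical rather than
individual half-lives is deliberate: a schedule that depends on the
subject's realised random effects is informative about eta, mis-specifies
any likelihood that conditions on sampling times, and in simulation visibly
biases volume-of-distribution recovery.  The clinician's schedule only ever
uses what a clinician knows.

What the generator does **not** emulate: real assay-specific biases and
censoring (an optional LLOQ flag exists but is off by default, as trough
concentrations rarely reach the 0.5-4 ug/ml assay floors), longitudinal
within-course changes in weight or creatinine (covariates are frozen at
baseline), trough-guided dose adjustments (each subject keeps one regimen),
and the skewness/clustering of real covariate joints (only marginals and a
parametric copula are available).  Passing recovery and calibration tests
therefore shows the estimator and diagnostics are correct *under this
design*, not that any real dataset is this well behaved; the residual
~5% overshoot of the dosing-table reproduction is consistent with the
synthetic covariate joint being wider within subgroups than the study's
empirical one.

## Estimation

The marginal likelihood integrates the two random effects per subject; it is
approximated by a Laplace expansion around the conditional mode, which for
1-2 observations per subject agrees with exact Gauss-Hermite integration to
~0.1 objective-function points per subject (validated in development against
adaptive quadrature).  The objective reported is OFV = -2 log marginal
likelihood.

* Inner problem: damped Newton on `(eta_cl, eta_v)` vectorised across all
  subjects, finite-difference 2x2 Hessians (step 2e-4), positive-definite
  repair by eigenvalue-floor ridge, per-subject backtracking, warm-started
  between outer iterations.
* Outer problem: Nelder-Mead on log-transformed positive parameters
  (`scr_exp` untransformed), relative convergence ~1e-3 on the OFV,
  physiologic box bounds enforced by clipping plus a quadratic penalty
  (defaults: `cl_ref` 0.005-0.6 L/h, `v_ref` 0.1-4 L, `hill` 0.5-12, `TMA50`
  20-38 wk — the PMA support of the cohort — `scr_exp` -0.5-2, omegas
  0.01-1.2, `b` 0.02-1).  The bounds matter: the unconstrained likelihood of
  sparse trough-heavy data has genuine spurious modes at extreme maturation
  shapes.
* Staging: when the maturation shape parameters are free, a first stage pins
  `hill`/`TMA50` at their initial values and settles the remaining
  parameters, then everything is released (sequential model building).
* Empirical Bayes estimates are the conditional modes at the final
  parameters; with no observations the prior mode (eta = 0) is returned.
* Covariate selection: stepwise likelihood-ratio testing at p < 0.05
  (chi-square on the OFV difference; forward inclusion by largest drop, then
  backward elimination).  The creatinine power term costs 1 df, the
  maturation function 2 df.
* Uncertainty: RSE% = 100*se/|estimate|, by subject-resampling bootstrap
  (refits warm-started at the point estimate) or by inverting a
  finite-difference Hessian of the OFV ("fisher"); for log-parameterised
  quantities the SE of the log is reported as the coefficient of variation.

Known limitation (left visible in the acceptance suite): with the default
sparse design the mature-limit clearance and the maturation shape lie on a
likelihood ridge — PMA 22-42 wk never observes mature clearance.  Across 20
replicate synthetic studies the median recovery error of `v_ref` is ~5%,
`TMA50` and the creatinine exponent keep the right location and sign, but
`cl_ref` has a median error of ~22% (roughly half the replicates drift along
the ridge toward a flatter maturation curve with a higher asymptote), and
bootstrap RSEs of `cl_ref` (~38%) and `hill` (~57%) exceed the 30% adequacy
bound; `v_ref`, `TMA50` and `scr_exp` meet it.  Exact Gauss-Hermite
evaluation of the marginal likelihood at the ridge optima confirms they are
genuinely preferred over the generating parameters, so this is the sampling
behaviour of exact maximum likelihood under this design, not an optimizer or
approximation artifact: the mature-limit parameterisation is simply not
identifiable to that precision from trough-dominated data in this PMA range.

## Diagnostics

* **VPC**: `n_sim` replicate datasets (default 1,000) are simulated under
  the observed design; observations are binned by nominal monitoring
  occasion (trough/peak x dosing interval) because the design is sparse and
  dose-interval-aligned — raw clock-time bins would mix intervals.  Bins
  with fewer than 5 observations are merged into a neighbour with a
  warning.  Per bin, the observed 10th/50th/90th percentiles are compared
  with the 90% interval of the same percentile across replicates.
* **NPDE**: per subject, observed and simulated vectors are decorrelated
  with the Cholesky factor of the simulation covariance (ridge-regularised
  with a warning if singular); empirical ranks, with ties broken by seeded
  uniform jitter via `pde = (r + U(t+1))/(K+1)`, are mapped through the
  normal quantile function.  Under a correct model the values are N(0, 1);
  the summary reports mean, SD and a Shapiro-Wilk p-value (the small-sample
  default; no specific test is canonical).
* **Residuals**: PWRES uses the typical prediction and a simulation-based
  marginal SD; IWRES uses the empirical Bayes prediction and the
  residual-error SD, with zero-prediction rows flagged as undefined.

## Dosing simulation

The covariate table is tiled (default 40x, matching the replicate-the-
dataset approach: 40 x 236 = 9,440 virtual subjects), fresh random effects
are drawn per virtual subject and shared across the regimen grid (10-20
mg/kg in 2.5 steps at q6/8/12/18/24 h), and exposure is computed in closed
form.  Subgroups partition the cohort at PMA 29 wk and creatinine bands
[min, 0.6), [0.6, 0.9], (0.9, 1.2] — the band edges at 0.9 are ambiguous in
the source tables and configurable; creatinine is capped at 1.2 mg/dl, the
model's stated range.  MIC is fixed at 1 ug/ml so AUC/MIC is identified
with AUC.  The PTA table reports per subgroup x regimen the mean/SD of AUC
and trough and the percentages with AUC 400-600, 400-800, AUC > 800,
trough > 15, trough > 20 and the union AUC > 800 or trough > 20.

Recommendation policy: a regimen is admissible if the band probability
(400-600 for the narrow policy, floor 60%; 400-800 for the wide policy,
floor 80%) strictly exceeds the floor and the toxicity union stays strictly
below 10%.  Ties break by highest band probability, then lowest
P(trough > 15), then lowest total daily dose — the selection narrative of
the source tables implies but never formalises this rule.  An empty
admissible set yields an explicit "no regimen qualifies" record carrying the
best achieved probability.

## Problem sizes and numerical choices

Simulation sizes are chosen so Monte Carlo error is negligible relative to
the tolerances being checked: the dosing-table checks use a 170,000-subject
cohort (>= 10,000 per subgroup; subgroup means then have standard errors
~1 ug*h/ml of AUC), the acceptance script uses 80,000 (~11,000 in the
target subgroup), parameter recovery uses 20 replicate 162-subject studies
with a 40-resample bootstrap, diagnostic calibration uses 50 NPDE replicates
(500 simulations each) and 10 pooled VPC runs (400 each), and the type-I
error experiment uses 200 replicates of 40 subjects with the variability
parameters of no interest held at their generating values.  All randomness
flows from explicit integer seeds; reruns are byte-identical.  Tie-breaks,
ridges and degenerate inputs follow the rules above; concentrations are
floored at 1e-12 inside likelihoods to keep proportional-error SDs positive.
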