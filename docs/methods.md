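# Methods

This note documents the models implemented in `pkrrf`, the choices made
where the design was genuinely open, and what the synthetic data used in
the tests do and do not establish about real dialysis populations.

## Kinetic model

Beta-2-microglobulin (B2M) is modelled with a two-compartment,
variable-volume system: a plasma/perfusing pool P and a non-plasma pool
NP whose volumes remain in a fixed ratio. Writing Θ = 1 during a
dialysis session and Θ = 0 between sessions,

    d(V_P C_P)/dt  = φ_P G − (K_R + K_ER + Θ K_D) C_P − K_C (C_P − C_NP)
    d(V_NP C_NP)/dt = φ_NP G + K_C (C_P − C_NP)
    dV_P/dt  = φ_P  (−Θ Q_UF + (1 − Θ) α)
    dV_NP/dt = φ_NP (−Θ Q_UF + (1 − Θ) α)

with generation G (mg/min) split across pools by fractional volume,
residual renal clearance K_R (the quantity of clinical interest, "RRF"),
extrarenal clearance K_ER, dialyzer clearance K_D (total of diffusive,
adsorptive and convective removal), intercompartmental clearance K_C,
ultrafiltration rate Q_UF and interdialytic fluid-intake rate α. All
volumes are in liters, time in minutes, concentrations in mg/L;
clearances are accepted in mL/min and converted to L/min when the
parameter objects are constructed, so the ODE right-hand side never
mixes units.

Numerical choices:

* The indicator Θ is never part of the right-hand side. Time is
  segmented at every session boundary and each segment is integrated
  separately with LSODA (`scipy.integrate.odeint`, rtol 1e−8,
  atol 1e−10, both configurable), restarting the solver at each switch
  with a continuous state. This keeps the stiffness-switching heuristics
  honest and makes the session start/end states exact output points.
* α defaults to a per-gap value chosen so the fluid gained over each
  interdialytic gap equals the next session's ultrafiltration volume,
  making every week weight-neutral and the volume trajectory
  week-periodic. An explicit `intake_rate` overrides this.
* Patients start at the no-dialysis steady state
  C_P = G/(K_R + K_ER), C_NP = C_P + φ_NP G/K_C and are then simulated
  for 13 weeks of thrice-weekly treatment, long enough for the weekly
  cycle to become essentially periodic; pre/postdialysis concentrations
  are read off one session of the final week. The extraction session is
  configurable (`first` or `mid` session of the week) with `first` as
  the default.
* Closed-form anchors used by the tests: the no-dialysis steady state
  above, and the single-pool variable-volume session solution
  C(t) = C(0)·(V(t)/V(0))^((K_D−Q_UF)/Q_UF), which the two-pool model
  reproduces as K_C → ∞.

## Population generator

The cohort generator samples per-patient kinetic parameters from
truncated lognormal/normal distributions and prescriptions from
discrete per-modality menus (durations, dialyzer B2M clearances,
uniform ultrafiltration volumes) patterned on the large HD and
on-line-HDF trials. The exact population distributions behind the
original meta-analytic parameterization are not published at full
precision, so the defaults here are approximations chosen on
physiologic grounds — e.g. generation around 0.16 mg/min, distribution
volume around 21% of body weight, plasma fraction around one third,
extrarenal clearance around 3 mL/min — calibrated only in the sense
that the anuric predialysis B2M distribution falls in the plausible
20–45 mg/L band (simulated anuric median ≈ 35 mg/L, IQR ≈ 28–45).
Residual renal clearance is assigned as a mixture of a point mass at
zero (anuric fraction, default 0.25 for development cohorts) and a
uniform 0–10 mL/min component. The HD/HDF split defaults to 50/50 for
development cohorts.

The external-validation fixture emulates the structure of a published
real-world validation cohort: 391 patients by default, roughly
two-thirds HDF, 36% anuric, 70% with urea clearance below 2 mL/min,
postdialysis B2M available in roughly 300/391. True RRF is mapped to
"measured" urea clearance through the linear link (slope 0.751,
intercept 0.007, Gaussian noise SD 0.35 mL/min, anuric patients fixed
at zero), and auxiliary biomarkers (cystatin C, urea, creatinine) are
generated as linear-in-RRF trends with independent noise at typical
dialysis-population levels. The fixture therefore *plants* residual RRF
signal in cystatin C by construction; tests that show multibiomarker
calibration beating linear recalibration demonstrate that the machinery
can exploit such signal, not that real cystatin C carries this much
independent information. More generally, passing tests on these
synthetic cohorts show internal consistency of the pipeline under its
own generating assumptions — they cannot establish real-world
discrimination or calibration, which require external patient data.

## Dialytic clearance estimation

Two estimators of the dialyzer B2M clearance from session observables:

* the classical single-pool variable-volume closed form
  K = Q_UF·[1 + ln(pre/post)/ln(V_pre/V_post)] with
  V_post = 0.2·weight (the conventional extracellular-volume
  assumption, configurable) and V_pre = V_post + UF volume; generation,
  non-dialytic clearance and the second pool are neglected, which biases
  the estimate in realistic patients;
* a Matérn-3/2 Gaussian-process emulator of the simulator, regressing
  true dialyzer clearance on (log pre-B2M, log post-B2M, weight,
  duration, UF volume), standardized; amplitude, ARD length scales and
  a white-noise term are refined by marginal-likelihood optimization
  from unit starting values with a few restarts (the restarts matter —
  a single start can collapse into a pure-noise optimum). Above 1,500
  training rows a reproducible subset-of-data approximation keeps the
  cubic-cost fit tractable.

On held-out simulated patients the emulator's median bias is an order
of magnitude smaller than the closed form's and its error IQR is
consistently smaller.

## PK-RRF estimating equations

Four equations are fitted on simulated cohorts under a seeded 2/3–1/3
train/test split: {basic, clearance-based} × {logistic, continuous}.
The basic feature set is predialysis B2M only; the clearance-based set
adds postdialysis B2M, weight, duration and UF volume, fed directly to
a multi-input smoother rather than through a precomputed clearance.
B2M enters all smoothers on the log scale (concentrations are
right-skewed).

The logistic outcome is preserved residual function,
RRF ≥ 2/0.751 ≈ 2.66 mL/min — the image on the RRF scale of the
2 mL/min urea-clearance guideline cutoff. The continuous outcome is RRF
in mL/min, clipped at zero, convertible to the urea-clearance scale by
the 0.751 slope.

Smoothers: the one-dimensional basic equation uses a penalized
B-spline additive model (`statsmodels` GLMGam; basis dimension capped
at one tenth of the sample, penalty chosen by the package's
penalization-weight selection, with a fixed fallback). Outside the
training covariate span the spline is evaluated at the span boundary
(flat extrapolation). The multi-covariate clearance-based equation uses
a Matérn-3/2 Gaussian process (classifier with Laplace approximation
for the logistic outcome, regressor for the continuous one) on
standardized covariates with marginal-likelihood-tuned hyperparameters
and the same subset-of-data cap (1,200 rows).

## Clearance-to-RRF link

Replicate measured GFR readings (iothalamate, inulin, DTPA) are treated
as unbiased noisy measurements of a latent per-patient RRF_i, while
urea and creatinine clearances load on it linearly:

    mGFR_ij = RRF_i + e_ij
    UrCl_i  = a_U + β_U RRF_i + U_i
    CrCl_i  = a_C + β_C RRF_i + C_i

with independent Gaussian errors and a Gaussian population prior
RRF_i ~ N(μ, τ²). Because everything is linear-Gaussian the latent
RRF_i integrate out in closed form (per-patient Woodbury identity on
sufficient statistics), giving a fast marginal likelihood. Two fitting
paths are provided and agree within 1 SE on well-identified synthetic
data:

* marginal maximum likelihood (L-BFGS-B on the 9 hyperparameters with
  log-parameterized SDs bounded in [e−20, e10] to tame degenerate
  noise-free data; Hessian-based SEs, delta-method intervals for SDs);
* a Bayesian path using an affine-invariant ensemble sampler (emcee,
  32 walkers, 1,500 steps, 500 burn-in) with weakly informative priors
  — Normal(0, 10²) on intercepts/slopes and μ, half-Normal(0, 10²) on
  the SDs.

Missing measurement blocks simply drop out of the per-patient
likelihood; no imputation. Latent RRF_i posteriors are reported in
closed form at the hyperparameter estimates. Identifiability requires
at least some patients with measured GFR (the latent scale is otherwise
free) and at least two measurement types overall.

The package-wide RRF ↔ urea-clearance conversion uses the proportional
simplification UrCl = 0.751·RRF (intercept dropped as negligible);
any fitted link object can override it.

## Evaluation metrics

AUC is the rank-sum (Mann–Whitney) statistic with midrank ties.
Calibration-in-the-large and calibration slope come from regressing
observations on predictions — OLS for continuous outcomes, logistic
regression on the prediction's logit for binary ones. The probability
metrics are the Brier score, the Spiegelhalter z test
(z = Σ(y−p)(1−2p) / sqrt(Σ(1−2p)²p(1−p)), terms with p(1−p)=0 dropped
with a warning), Somers' D = 2·AUC − 1, and an unreliability index
defined here as the likelihood-ratio test of (intercept, slope) = (0, 1)
in the logistic recalibration regression (2 df). Continuous errors are
prediction − observation; quantiles use linear interpolation so the IQR
is platform-stable; agreement proportions are reported within 0.5, 1
and 2 mL/min.

## Decision-curve analysis (opt-out framing)

The rule's threshold R on the predicted risk of the low-clearance state
encodes the cost-benefit valuation R = C/(C+B). A patient opts out of
thrice-weekly dialysis when their predicted risk is strictly below R
(ties stay on standard care; the inequality direction is a convention
fixed here). With TNR the fraction of truly-preserved patients who opt
out and FNR the fraction of truly-low-clearance patients who wrongly
opt out,

    SNB = TNR − prevalence/(1 − prevalence) · (B/C) · FNR.

The standard of care scores TNR = FNR = SNB = 0 and a perfect rule
scores 1. Curves are computed on a default grid of 99 thresholds
(0.01–0.99, spanning benefit:cost from 99:1 to 1:99); loess smoothing
(span 0.3) is available for display only and never replaces the raw
points. Prevalence-sensitivity analyses reuse the class-conditional TNR
and FNR and recompute SNB under assumed prevalences
(default {0.1, 0.3, 0.5, 0.7, 0.9}).

## Recalibration

The simulation-derived equation is always frozen; only a calibration
layer is refit to external data. The intercept update shifts the linear
predictor (logit scale for logistic equations); linear recalibration
refits intercept and slope on it, leaving discrimination unchanged by
construction. "Internal-external" leave-one-out cross-validation refits
*the layer only* for each held-out patient — the base equation never
sees the validation outcomes — and is implemented as an explicit
n-refit loop (tests verify it against brute force).

Multibiomarker calibration augments the layer with cystatin C, urea,
creatinine and/or sex: the covariance is a dot-product
(Bayesian-linear) kernel — carrying the intercept/slope terms — plus an
amplitude-scaled Matérn-3/2 surface over the standardized (prediction,
biomarkers) space. Hyperparameters are fixed rather than optimized so
that, at the few hundred rows of a typical validation table, the
flexible surface cannot overwhelm the base prediction; with zero
amplitude the model reduces exactly to linear recalibration.

## Problem sizes

The test suite exercises the pipeline at deliberately modest scales
chosen to probe each claim with adequate power: shared 240-patient and
120-row fixtures for unit tests, a regenerated 3,000-patient cohort for
the comparative claims (emulator vs closed form, clearance-based vs
basic discrimination), 20 replicate fits at n=100 for the
interval-coverage check of the hierarchical link, and 50 seeded
parameter sets for the steady-state oracle. The acceptance script runs
the full pipeline at n=2,000 (development cohort) and n=391
(validation fixture). Comparative conclusions at the original
10,000-patient scale follow the same code path via
`PopulationConfig(cohort_size=10_000)`.

## Known limitations

* The population distributions are stand-ins; absolute AUCs and error
  magnitudes on simulated cohorts depend on them and should not be read
  as estimates for any real population.
* The generator draws prescription parameters independently of patient
  size, so implausible combinations (large patients on short, low-dose
  sessions) occur; they widen the error distribution of the continuous
  equations.
* Longitudinal RRF decline, urea/creatinine intradialytic kinetics,
  access recirculation and dialyzer mass-transfer modelling are out of
  scope.
* The Bayesian path samples the marginalized likelihood; per-draw
  latent RRF posteriors are conditional on hyperparameter point values
  rather than fully propagated.
* An externally published comparator equation is supported only as a
  user-supplied plug-in predictor (any callable mapping records to
  scores can be passed to the evaluation and DCA functions); its
  coefficients are not redistributed here.
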