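# Methods

This note records the model, the numerical machinery, the synthetic
data-generating process, and the design decisions taken where the
underlying study left choices open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Structural model

**Vitamin D₃ side.** Five compartments: GI tract, arterial blood,
venous blood, liver, and a lumped rest-of-body pool of non-eliminating
organs. Oral doses enter the GI tract as instantaneous amount
increments and are absorbed into the liver with first-order rate
constant `ka` (default 0.25 h⁻¹). Distribution is blood-flow-limited
with tissue-to-venous partition coefficients (liver Kp_l = 1,
rest-of-body Kp_rb = 0.5 for vitamin D). The liver eliminates vitamin D
at `CL_H · C_liver / Kp_l` (CL_H default 20 L/h); a fraction
F_m = 0.33 of that molar flux reappears as newly formed hepatic
25(OH)D. A constant zero-order endogenous input (cutaneous synthesis +
dietary intake) enters venous blood.

**25(OH)D side.** The same blood/liver scaffold; the non-eliminating
organs are either lumped (rest-of-body, Kp25_rb) or split into fat mass
and lean mass (Kp25_fm = 4.66, Kp25_lm = 4; the final model variant).
Elimination is from venous blood with the sigmoidal rate constant
`CL(C) = CLmax·C^γ/(C50^γ + C^γ)` applied to the venous amount, so the
flux saturates at high concentrations — the mechanistic source of the
sub-proportional dose–exposure relationship. Defaults C50 = 30 nmol/L
and γ = 1 follow the adult-model lineage; neither is identifiable from
single-dose paediatric data, and both are configuration entries users
should treat as assumptions, not estimates.

**Physiology.** Compartment volumes are proportional to body weight
with apparent density 1 kg/L: arterial blood 2 %, venous blood 6 %,
liver 2.57 % (so a 30 kg child has 0.6, 1.80 and 0.77 L). The fractions
were reverse-engineered from the 30 kg worked example; they live in
`ModelConfig`, not in code. Cardiac output is anchored at 273 L/h for
30 kg (the mean of 4.8 and 4.3 L/min reference values for boys and
girls aged 7–9) and scales linearly with weight; the liver receives a
configurable fraction of it (default 0.255, the adult reference-man
split — the paediatric organ-level table was not available, so this is
a documented assumption). The fat-mass fraction follows a cubic in the
BMI-for-age Z-score, `(28.61 + 7.82z − 0.91z² + 0.03z³)/100`, floored
at 0.05 and capped at 0.49 above z = 6.19. The cubic reaches 0.4927 at
the boundary, so the cap is continuous only to ~0.003 — we keep the
published form rather than smoothing it. Weight over the 3-year study
is constant, population-linear (3.08/3.23 kg/year for boys/girls) or
per-child interpolated between recorded baseline and 3-year weights,
depending on model variant; extrapolation beyond 3 years continues the
same line. The maximal clearance scales as (WT/30 kg)^0.75.

**Units.** Amounts nmol, concentrations nmol/L, time hours, doses µg at
the interface (molar mass 384.64 g/mol ⇒ 250 µg = 650 nmol).

## Endogenous-input calibration

At the flow-limited steady state of the no-dose system the entire
25(OH)D production flux equals its elimination flux, which gives a
closed form for the endogenous input required to hold a child at an
observed baseline concentration c₀:

    endog = CL(c₀) · c₀ · V_ven / F_m        [nmol/h]

together with explicit steady-state values for every compartment. The
package uses this closed form (no root finding is needed) and a test
verifies that a calibrated child simulated for three years stays within
0.5 % of baseline. Calibration uses the baseline physiology; when
weight grows afterwards while the endogenous input stays constant, the
baseline level erodes over the study (growth dilution) — this is a
property of the model, not an artefact.

## QSS reduction and integrators

The arterial and rest-of-body vitamin D amounts equilibrate with venous
blood within minutes, far below the weekly dosing/annual observation
timescales. In reduced mode these two states are replaced by their
quasi-steady-state algebraic relations and the three pools are
integrated as one mass-conserving lumped state, re-split at output.
Full and reduced systems agree on 25(OH)D to ~10⁻⁶ relative on a
3-year weekly regimen (tested to <1 %).

Two integration backends exist:

- **reference** — SciPy LSODA, segment-by-segment between dose events,
  rtol 1e−8 / atol 1e−10, full or reduced mode; the accuracy yardstick.
- **fast** — a numba-compiled TR-BDF2 scheme (one-step, L-stable,
  γ = 2−√2) for the reduced system, used inside SAEM and
  population-simulation loops where the model is solved 10⁴–10⁵ times.
  Steps follow a geometric plan restarted at every dose event (1.5 h
  after a dose, growing ×2.5 to a 60 h cap), with a chord Newton on a
  segment-frozen finite-difference Jacobian and a hand-rolled LU
  factorisation. Step-halving retries on Newton failure. Amounts are
  clipped at zero after each step (a stiff decay can undershoot by a
  fraction of a nmol on a large step). Agreement with the reference
  backend is ~4×10⁻⁴ max relative on 3-year weekly regimens (tested at
  5×10⁻³), at ~3 ms per 3-year trajectory.

## Population layer and variant registry

Individual parameters: `CLmax_i(t) = exp(θ + η_i)·(WT_i(t)/30)^0.75`
with η ~ N(0, ω²) (lognormal IIV); partition coefficients are lognormal
fixed effects; the ZBMI covariate model for the lumped rest-of-body
coefficient is `Kp25rb = exp(T + ZBMI·β + η)`. Residual error is
combined: `y = f·(1+ε_p) + ε_a`. The IIV coefficient of variation is
reported as √(e^ω − 1)·100 % (the variance 0.332 corresponds to 62.7 %,
matching the published 62.8 % to rounding; the published footnote's
formula is missing the square root typographically).

Eleven nested variants span: reference vs baseline-fixed vs
population-linear vs per-child-interpolated weight; weight scaling of
volumes and/or clearance; the ZBMI covariate; the fat/lean split; and
an estimated C50. The exact pairwise differences among the intermediate
weight-covariate models were not documented; the registry's assumed
mapping is: 1 base (reference 30 kg physiology, no covariates);
2 volumes ∝ WT; 3 CLmax ∝ WT^0.75; 4 both (2–4 at baseline weight);
5 = 4 with population-linear growth; 6 = 5 + ZBMI on Kp25rb; 7 = 4 with
interpolated weight; 8 = 7 + ZBMI; 9 = 7 with the fat/lean split
(Kp25lm fixed); 10 = 9 with Kp25lm estimated (the final model);
11 = 4 + estimated C50. Baseline (not time-varying) ZBMI enters the
covariate model, matching when it was measured.

## SAEM estimation

The E-step runs a random-walk Metropolis kernel on each child's random
effects (1–2 proposals per child per iteration; proposal scales adapt
toward 40 % acceptance during burn-in). The M-step updates:

- fixed effects carrying random effects and their variances through
  stochastically smoothed sufficient statistics of φ = θ + η (η is
  re-centred when θ moves so φ is invariant);
- fixed effects without random effects by a damped Gauss-Newton step
  with forward-difference prediction sensitivities (step capped at 0.25
  log units);
- residual components (σ_add, σ_prop) by an inner 2-parameter
  maximisation over the current conditional residuals, smoothed.

Step sizes are 1 during burn-in and decay as 1/k afterwards. During
burn-in all variance components carry a simulated-annealing floor
(≥ 0.95 of their previous value) to prevent the early collapse that
otherwise freezes the η chains. Defaults are 300 burn-in + 200
accumulation iterations and 2 chains; the recovery tests use 120 + 80
with 1 chain, which is sufficient at 77 children × 3 informative visits.
Runs are bit-reproducible under a fixed seed.

The marginal log-likelihood for AIC/BIC and standard errors is computed
by adaptive Gauss-Hermite quadrature (9 nodes, centred at the empirical
Bayes mode with a finite-difference Hessian) for one random effect, and
by a Laplace approximation for two; with all variances zero it reduces
to the exact Gaussian likelihood (tested to 1e−6). Standard errors come
from a central finite-difference Fisher information in the fixed
effects. BIC uses the number of observations. The baseline observation
anchors the calibration and is excluded from the residual likelihood;
below-quantification observations are excluded with a logged count.

## Diagnostics

- **CWRES** — FOCE linearisation around the empirical Bayes mode
  (central differences in η); the observation vector is whitened with
  `G Ω G' + R`. Under the true model CWRES are ≈ N(0,1); a clearance
  misspecification surfaces primarily as a location bias because the
  CLmax random effect absorbs the per-child level (tested: 2× CLmax
  gives mean CWRES ≈ +0.55).
- **NPDE** — simulation-based: each child's observation vector is
  decorrelated with the simulated mean/covariance (Cholesky), ranked
  among its nsim simulated replicates, boundary-corrected by 1/(2·nsim)
  and mapped through Φ⁻¹.
- **VPC** — nsim (default 1000) full-observation-process replicates,
  binned strictly by nominal visit time; observed percentiles overlaid
  on the simulated 5th/50th/95th with 90 % prediction intervals.

Monte-Carlo loops exploit that, in the final model, a trajectory
depends on randomness through a single smooth scalar (the CLmax η):
per-child predictions are precomputed on a 15-node η grid spanning
±4.5 prior SD and interpolated cubically (tested against direct solves
at 2×10⁻³ relative). Multi-η variants fall back to direct simulation.

## Virtual populations and dose simulation

Printed percentile tables are turned into samples by percentile-uniform
sampling: a draw lands in the stratum between neighbouring percentiles
with its nominal probability mass and is uniform within it; explicit
bounds close the tails (10 and 90 nmol/L for baseline 25(OH)D).
Six-year-olds sample weight-for-age directly (the weight-for-age
Z-score proxies the BMI Z-score); eleven-year-olds sample BMI and
height independently and set weight = BMI·height². The shipped tables
are synthetic, WHO-like fixtures (lognormal/normal shapes at
plausible paediatric medians and spreads; filenames say `synthetic`) —
the engine only requires strictly monotone tables, and official values
can be substituted as CSVs.

Prediction bands: an outer loop of virtual studies draws fixed-effect
uncertainty lognormally using the fitted standard errors; an inner loop
draws the CLmax η and additive residual error (the proportional
component is not sampled, so trajectories start exactly at the observed
baseline). Percentiles are computed within each study; their median and
95 % prediction interval across studies form the band. Threshold
attainment is read off the band's lowest percentile trajectory
(equivalent in distribution to counting children). The full design is
30 studies × 2500 samples; tests and examples run scaled-down versions
(4–5 studies, 150–300 samples) whose bands are visually and
decision-equivalent for the assertions made.

## Synthetic trial generator

Defaults emulate the supplementation-trial design the analysis assumes:
77 children; age ~ N(8.9, 1.3²) truncated to [6, 11] years;
ZBMI ~ N(0, 1); baseline 25(OH)D ~ N(64.7, 14.9²) truncated above
15 nmol/L with a −2.644 nmol/L-per-Z coupling to ZBMI (the residual SD
is shrunk so the marginal SD stays 14.9); sex-specific age-linear
baseline weights (28/27.5 kg at age 9, 15 % lognormal spread) growing
3.08/3.23 kg/year to a noisy 3-year weight; weekly 250 µg doses for
3 years; visits at 0/1/2/3 years. The baseline visit is the calibration
anchor and carries no residual error; later visits get combined
additive + proportional noise at the published magnitudes.

Adherence: each child takes a scheduled week's dose with probability
drawn from Beta(8, 2) (mean 0.8; the real per-child distribution is
unpublished — this is labelled synthetic). Dosing continues through
school holidays, matching the trial's parent-supervised administration;
a term/holiday/lockdown gap calendar is available and tested for
studying interrupted regimens, because always-missed holiday gaps
roughly halve the mean 3-year response. Under the defaults the
generator yields mean Δ25(OH)D ≈ 22 nmol/L with a per-child 90 % range
of about [−14, +73] nmol/L — the same order and spread as the trial it
emulates — with ~77 % of children rising (high-clearance children plus
growth dilution and assay noise account for the rest).

What the generator does **not** emulate: seasonal baseline variation
(the ~11.5 nmol/L sinusoid is a diagnostics fixture, not part of the
cohort draw), assay-specific error structure, dropout, and any
covariance between adherence and covariates. Passing recovery tests
therefore demonstrate internal consistency of estimation under the
model's own assumptions, not robustness to these real-data features.

## Problem sizes and runtimes

Chosen so the full suite runs comfortably on one CPU: parameter
recovery at 77 children × 3 seeds with 120 + 80 SAEM iterations
(~3–4 min per seed); diagnostic calibration on 20 replicate 77-child
datasets at nsim = 1000 via the η-grid (~1.5 min total);
virtual-population ordering at 150 children × 4 studies per age group.
The acceptance script itself is deterministic desk arithmetic and runs
in milliseconds.

## Known limitations

- C50 and γ of the clearance sigmoid, CL_H, ka and the vitamin D
  partition coefficients are inherited defaults, not estimable from
  single-dose annual data; conclusions sensitive to them (notably
  absolute attainment times) should be read as conditional.
- The model targets multi-month timescales; within-day and within-week
  kinetics are structurally present but not validated.
- Constant endogenous input plus growing body weight implies baseline
  erosion over years; real children's synthesis presumably scales with
  body size and season.
- 25(OH)D₂, 1,25(OH)₂D formation, enterohepatic recirculation and
  renal impairment are out of scope.
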