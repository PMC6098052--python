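# Methods

This note documents the models, estimators and numerical choices behind
`cmlkinetics`, and what the synthetic validation does and does not show.

## The measurement scale

Tumor load is the BCR-ABL/ABL transcript ratio in percent on the
international scale (IS); all modelling happens on `LRATIO =
log10(ratio %)`.  Values below the assay's quantification limit (QL) are
left-censored: files store the QL itself with a flag, and only the flag
enters the likelihood.  The package does not convert raw PCR exports or
lab-specific conversion factors; inputs are assumed IS-normalised.

## Bi-exponential response model

The decline under TKI therapy is modelled as

    LRATIO(t) = log10( A e^(-alpha t) + B e^(-beta t) ),    t in months,

with `A > B >= 0` (percent-scale intercepts), `alpha > 0` per month and
`beta` free in sign.  On the log scale this is a smoothed two-segment line:
the first slope reflects the depletion of cycling leukemic cells, the
second the slow elimination of quiescent leukemic stem cells.  A config
switch (`biexp.exp_base`) reproduces the base-10 reading
`log10(A·10^(-alpha t) + B·10^(-beta t))` instead; slopes then rescale by
`ln 10`.

### Individual fits

Per-patient estimation maximises a censored-Gaussian (Tobit) likelihood on
the LRATIO scale: uncensored points contribute normal densities, censored
points contribute `Phi((log10 QL - mu)/sigma)`, each weighted by the
measurement weight.  "Least squares with censored values" is not a
well-defined estimator; the Tobit likelihood is the standard resolution and
collapses exactly to weighted least squares when nothing is censored — in
that case the implementation dispatches to a Levenberg-Marquardt
least-squares solver with an analytic Jacobian, so the equivalence holds to
optimizer precision.  Constraints are enforced by the reparameterisation
`A = B + e^u`, `B = e^v`, `alpha = e^w`; `B` may approach 0 (one-phase
boundary, where a tiny floor keeps `A > B` strict).  The likelihood is
multimodal under censoring, so fits use a deterministic two-phase
log-linear heuristic start plus seeded jittered restarts (default 10; bulk
simulation studies in the test-suite use 1-3 starts, which the heuristic
start makes sufficient on well-behaved synthetic series — an optimizer-cost
choice, not a change of estimator).  `sigma2` is reported as the ML
estimate (`RSS/n` in the uncensored case).

The supplementary robustness reanalysis is available as a weighting mode:
measurements above 10 % (configurable) are down-weighted by 1/2 (`halve`)
or dropped (`omit`), reflecting reference-gene saturation at high tumor
load.

### Confidence bands

Point-wise bands for the mean curve come from a parametric bootstrap at the
patient's own design: simulate residuals on the fitted curve, re-censor at
the QL, refit, and take percentile envelopes per grid point.  Two
calibration details matter at n ≈ 15 points and 4 curve parameters:

* the ML variance is biased low, so replicate noise uses the df-corrected
  SD `sigma_hat * sqrt(n / (n - 4))`;
* `sigma_hat` itself is uncertain (≈ 11 effective degrees of freedom), so
  each replicate draws its noise SD from the scaled inverse-chi-square
  distribution of the variance estimate.  Without this the bands undercover
  by several percent, concentrated in "deceptively smooth" noise
  realisations.

Replicate refits start from the point estimate; censored replicates are
refitted with sigma held at the replicate's generating value (profiling the
curve parameters only), which is both faster and consistent with the
sigma-mixture above.  Coverage of the nominal 95 % band, measured pointwise
over synthetic patients at the trial design, sits near 94 %; exact
pointwise calibration is not attainable by a plug-in band at this n, and
residual misses concentrate in datasets whose realised noise mimics a
shifted curve.

### Halving time

`ln 2 / alpha`, converted months to days (30.44 d/month): the first-phase
approximation `A >> B`.  It is a monotone transform of `alpha` and carries
the same information.

## Synthetic cohorts

The generator emulates a five-year, two-arm first-line trial design:
sampling at month 0, quarterly to month 24, then semi-annually to month 60
(15 points).  Arm-level fixed effects default to published two-arm
estimates (`A = 37.375`, `B = 0.196` shared; `alpha` 0.674 vs 1.168 /month,
`beta` 0.039 vs 0.048 /month).  Between-patient variability is lognormal
for `A`, `alpha`, `B` (SDs 0.4, 0.3, 0.6 on the log scale) and additive
normal for `beta` (SD 0.015) — the published source gives no
between-patient variances, so these are package choices set once to produce
visually realistic heterogeneity.  Residual noise is Gaussian on the LRATIO
scale (SD 0.25) and the synthetic QL defaults to 0.0032 % (MR4.5-scale
deep-response assay).  Draws violating `A > B` are rejected and redrawn.

What this does **not** emulate: assay batch effects, visit-time jitter,
non-compliance and dose interruptions, resistance-driven regrowth, or
informative dropout (dropout is an optional independent per-visit hazard,
default 0).  Passing recovery and calibration tests on these cohorts shows
the estimators work under the stated noise model, not that real trial data
satisfy that model.

## Mechanistic model

CML is represented as clonal competition between normal and leukemic stem
cells that alternate between quiescence (A) and cycle (Omega), following
the affinity-based single-cell framework for hematopoietic stem-cell
organisation.  Each cell carries an affinity `a` in `[a_min, a_max]`
(0.002-1.0): in A it grows by a factor 1.4 per hour, in Omega it shrinks by
the same factor; a cycling cell whose affinity falls below `a_min`
differentiates out of the pool.  Because gain and loss use the same factor,
affinity lives on a 19-bin geometric grid and the update is a one-bin
shift.  Transition intensities per hour are

    omega(a) = f_omega(N_Omega) * (a_min / a)     A -> Omega
    alpha(a) = f_alpha(N_A)     * (a / a_max)     Omega -> A

with decreasing sigmoids `f` of the compartment totals for normal cells
(`f_alpha` from 3.0 to 0.01 around `N_A ≈ n_stem`, Hill 4; `f_omega` held
effectively constant at 0.4 in the default parameterisation — the
homeostatic feedback through `f_alpha` is sufficient).  Cycling cells
divide at rate `1/cycle_hours` (49 h normal, 24 h leukemic).  The leukemic
advantage is an unregulated activation amplitude (`f_omega_leuk = 2`,
insensitive to crowding) plus the faster cycle; an untreated leukemic clone
expands slowly and steadily while suppressing normal hematopoiesis through
the shared `f_alpha` feedback.

TKI therapy acts only on leukemic cells, after a gradual naive->affected
conversion at rate `r_trans` per hour (treatment onset).  Affected cells in
cycle are killed with probability `r_deg` per hour (cytotoxic effect on
proliferating cells; a config flag extends the kill to quiescent cells for
sensitivity analysis), their activation is rescaled by `f_omega_cml <= 1`
and their deactivation by `f_alpha_cml >= 1` (TKI-enhanced quiescence).
Quiescent cells are killed only while cycling, so strong quiescence
protects the residual clone — the mechanism behind flat second slopes with
persisting stem-cell burden.

The peripheral readout aggregates differentiation flux into a mature
compartment with fixed amplification (2^10) and exponential lifespan (10
days), shared by both clones; the measured ratio is
`n1 / (n1 + 2 n2) * 100 %` on mature counts.  Mature counts are *reported*
as the running average since the previous sample time: when few leukemic
stem cells remain, output arrives as isolated differentiation events and
the instantaneous compartment is a spike train; the window average is a
variance-reduced estimator of the same mean and mirrors how the trajectory
summaries are consumed.

### Numerics and scale

The default pool is 5,000 stem cells at 1-hour steps over 60 months
(1e5 cells behind the same interface).  Normal cells are propagated
mean-field (float expectations) — their counts are large and near
equilibrium, so their demographic noise is irrelevant to the readout —
while leukemic cells are integer counts updated with per-bin binomial draws
in a numba kernel; the grouped update is distribution-identical to per-cell
Bernoulli simulation (binomial = sum of Bernoullis), which the test suite
verifies against a per-cell reference on one-step event statistics.  Event
tallies (activation, deactivation, division, kill, differentiation,
conversion) balance the leukemic ledger exactly at every step.  All
density dependence is per-capita (`N / n_stem`), so halving the pool size
leaves the mean readout unchanged to Monte-Carlo error.

The initial state mixes two cached mean-field burn-ins — a normal-only
steady state and a leukemic-only quasi-stationary shape (renormalised each
step) — at the proportion that makes the mature readout equal
`10^lratio_init` percent exactly at t = 0; leukemic bin counts are then a
single multinomial draw and all leukemic cells start TKI-naive.  Burn-in is
12,000 steps, well past equilibration.

## Parameter screen and look-up table

Five parameters are screened: initial burden `lratio_init`, kill rate
`r_deg`, onset rate `r_trans`, and the activation/deactivation multipliers.
The full grid assigns 10/16/13/10/13 values (270,400 configurations); a 3^5
coarse grid serves desk-scale runs.  Ranges are configuration, not code:
`r_deg` 0.03-0.3 /h log-spaced (below ≈ 0.03 the kill no longer outpaces
the clonal growth per activation cycle and the clone relapses),
`f_omega_cml` 0.05-1, `f_alpha_cml` 1-2 (beyond ≈ 2 the escape probability
through the cycling cascade is so small that the clone becomes invisible in
blood), `r_trans` 5e-4 - 0.05 /h, `lratio_init` 0.8-2 (diagnosis-level
burden; the coarse grid starts at 1.2 where the leukemic pool is large
enough for a stable readout at the desk-scale pool size).

Each configuration is simulated `replicates` times (default 3) with seeds
derived from `(root seed, config index, replicate)` — reproducible under
any chunking or parallelism — and the replicate-mean ratio is summarised by
an uncensored bi-exponential fit restricted to the quantifiable part of the
series (samples with mean ratio above a 1e-5 % floor; at least 8 required).
Entries violating `alpha > beta > 0` stay in the table flagged invalid and
are excluded from matching, mirroring the clinical model filter.  The table
persists as a directory (JSON metadata including a base-parameter digest,
plus a flat CSV; stem-cell series semicolon-joined) and refuses to load
against different base parameters.

## Matching, prediction and cross-validation

A configuration is *suitable* for a patient at horizon tau if its fitted
curve lies inside the patient's point-wise band at every monthly grid point
up to tau (both curves are smooth, so monthly containment bounds the error
well below band width); suitable sets are ranked by RMS curve distance to
the patient's own fit.  Envelopes of the suitable curves give the
peripheral-blood interval at five years and the members' stem-cell series
give the residual-LSC interval, with log10 widths `delta_bcr_abl` and
`delta_lsc` (`delta_lsc` flagged undefined when the minimum is an extinct
clone).  Widening a band can only add members (superset guarantee); with a
fixed band, extending tau can only remove them.

Cross-validation compares suitable sets from truncated data (tau = 24, 36,
48 months) against the full five-year set.  The "confidence interval at
five years determined by a data set" is operationalised as the
peripheral-blood envelope of that data set's suitable configurations at
t = 60; classification is per configuration over the union of the two sets
(the whole-table universe is available by flag): inside both envelopes TP,
neither TN, reduced-only FP, full-only FN.  Patients with an empty suitable
set are reported unmatched, never silently dropped.  Per-patient and pooled
rates are reported; on mechanistically generated cohorts the pooled FP+FN
rate declines as the monitoring period grows.

## Arm comparison

The population analysis is deliberately a two-stage procedure: per-patient
censored-ML fits, then a Wald z test on arm means of the per-patient
estimates — `alpha` on the log scale (positivity-constrained, right-skewed),
`beta` raw — with standard errors from the empirical between-patient
variance.  This replaces a full nonlinear mixed-effects analysis: it is
dependency-light, its calibration is testable by simulation (type-I error
≈ 5 % at n = 60/arm; power ≈ 1 at the published alpha contrast), and it
treats estimation error as part of the between-patient spread, which is
conservative.  It does not estimate random-effect covariances, and
published mixed-effects estimates serve only as simulation inputs, never as
validation targets.

## Problem sizes in the shipped validation

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each qualitative claim is stable:
coarse 3^5 screen with 3 replicates at n_stem = 5,000; 200 synthetic
patients for recovery; 500 patients at 300 bootstrap replicates for band
coverage; 20 mechanistic patients for the cross-validation; 400/200
repetitions for type-I error and power.  The full-scale settings (270,400
configurations, n_boot = 1000, n_stem = 1e5) run behind the same interfaces
via configuration.

## Known limitations

* No resistance mutations, disease acceleration, immune effects,
  treatment interruptions or cessation modelling; treatment effects are
  constant in time.
* Deep responses ("too good" responders) are only partially identifiable:
  once the ratio falls below the QL — or, in the simulator, below the
  single-event granularity of the mature compartment — the second slope is
  informed only by censoring terms, and mechanistic configurations
  differing mainly in deep-response behaviour become indistinguishable.
  This is a property of the measurement process, and the width of the
  residual-LSC interval quantifies it.
* Pointwise plug-in bands undercover mildly for unlucky noise
  realisations; the sigma-mixture bootstrap recovers most but not all of
  the nominal level.
* The mechanistic base parameterisation is a stylised reduction (binned
  affinity, exponential cycle, mean-field normal clone); conclusions drawn
  from it in this package are sign- and ordering-level, and the tests
  assert exactly that level.
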