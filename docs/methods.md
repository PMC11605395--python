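# Methods

This note documents the model, the numerical machinery, the synthetic-data
generator and the design choices made where the design was genuinely open.
Units throughout: time in hours (1 week = 168 h, 1 year = 8766 h), amounts
in mg at the interface and µg internally, volumes in L, so amount/volume is
µg/L ≡ ng/mL with no conversion factors.

## Structural model

States: fast IM depot, slow IM depot, central (V3), peripheral (V4), all in
µg.  Disposition micro-constants are k10 = CL/V3, k12 = Q/V3, k21 = Q/V4;
the macro rates λ1 > λ2 are the roots of s² − (k10+k12+k21)s + k10·k21, and
λ2 is refined as k10·k21/λ1 to avoid cancellation when k21 ≪ k10.

* An oral dose delivers amount·F_oral at a constant rate into the central
  compartment over D_oral (fixed at 4 h).  There is no oral depot state.
* An IM dose deposits amount·F_im,fast into the fast depot and the
  remainder into the slow depot (IM bioavailability is 1 by definition);
  each depot drains first-order (ka_fast, ka_slow) into the central
  compartment.

The system is linear, so regimens are evaluated by closed-form
superposition: a bi-exponential step response for zero-order input and the
standard tri-exponential unit-input solution for each depot.  The kernel
(`superpose_profile`) is broadcast over a dose axis and accepts per-dose
parameters, which is how occasion-varying clearance enters (below).  A
piecewise numerical integration of the same ODE system (LSODA,
rtol 1e-10, atol 1e-8 µg, segmented at every input discontinuity, with a
cumulative-elimination bookkeeping state) serves as an independent oracle;
the two routes agree to better than 0.1% relative (measured ~1e-10) across
random parameter/regimen draws, and the ODE satisfies mass conservation to
~1e-14.

Evaluating the closed form exactly at an injection time yields the
concentration *before* that dose (the depot contributes nothing at Δt = 0);
the whole package uses this pre-dose convention for troughs.

Derived quantities: oral biphasic half-lives ln2/λ1 and ln2/λ2 (16.9 h and
240.4 h at the packaged estimates); the apparent IM terminal half-life
ln2/ka_slow (18.0 weeks) — valid because ka_slow < ka_fast < λ2 < k10
(flip-flop), which is asserted for the packaged set and warned about
otherwise; time to steady state as 5 terminal half-lives (1.7 years).  The
5-half-life convention (≈97% of steady state) reproduces the reported point
value and, propagated through the log-normal ka_slow distribution
(82.7% CV), its 90% interval of 5.5–59.0 weeks.

## Hierarchical layer

Individual parameters:

    CL_i(occ)   = CL · exp(η_CL + κ_occ)       κ_occ fresh per injection, occ = 1..6
    F_oral_i    = F_oral · exp(η_Foral)         not truncated at 1
    ka_slow_i   = ka_slow · exp(η_kaslow)
    F_imfast_i  = expit( logit(θ*) + η_Ffast ), θ* = θ·(1 + θ_female·female)

Ω is diagonal (no covariances are part of the model).  F_oral is
deliberately untruncated: individual values above 1 are read as oral
exposure exceeding the IM-relative reference.  ω values are stored as SDs;
the published CV% representations convert via CV = √(exp(ω²) − 1), and the
logit-scale SD of F_im,fast converts through the delta-method
CV ≈ (1 − θ)·ω (good to ~10% relative for ω ≲ 0.3, verified by Monte
Carlo).  Residual error: additive σ_add = 18 ng/mL for oral records,
proportional σ_prop = 0.18 for IM records.

**IOV convention (dose-wise superposition).**  With clearance varying by
injection occasion the system is only piecewise time-invariant and exact
superposition no longer holds.  The package applies each dose's occasion
clearance to that dose's entire contribution.  This keeps the profile a
single superposition sum (fast, vectorisable, identical in the generator,
the simulator and the estimator, so self-consistency experiments are
exact), at the cost of not representing the change in elimination of
*previously* absorbed drug when a new occasion starts — a second-order
effect at the 13% CV magnitude of the IOV term.  Oral doses belong to
occasion 0 and carry no IOV.

The covariate layer defaults to OFF everywhere: the sex effect on
F_im,fast (θ_female = −0.456, i.e. a 45.6% lower fast-pathway fraction in
females) ships as an optional `CovariateModel` because it was judged
clinically irrelevant for the validated model; simulation utilities accept
it explicitly.

## Estimation

The OFV is −2·Σ_i log ∫ p(y_i|η_i) p(η_i) dη_i with the integral
approximated by Laplace's method.

* **Inner problem.**  The per-subject mode η̂ is found by a damped (GN +
  Levenberg) Newton iteration run simultaneously for all subjects via
  numpy broadcasting.  The Jacobian of predictions w.r.t. η uses forward
  differences (h = 1e-5·(1+|η|)).  The curvature weight is the exact
  second derivative of the per-observation −log density with respect to
  the prediction — for the proportional-error model this includes the
  variance-derivative terms, without which the iteration degrades to a
  slow linear rate; second derivatives of the prediction itself are
  dropped (Gauss-Newton spirit).  Steps are capped at 3 per component and
  η at ±30 to keep trial points inside the numerically valid region;
  iteration stops when the gradient falls below 1e-6·(1+|g|) or the
  objective stops moving (the attainable floor under finite-difference
  Jacobians).
* **Laplace determinant.**  By default the mode curvature entering
  log det H is the same Gauss-Newton matrix (the first-order-conditional
  convention, positive definite by construction); an exact
  central-finite-difference Hessian is available (`curvature="exact"`).
  On one-subject/one-η toy problems the OFV agrees with adaptive
  quadrature of the marginal likelihood to ≲0.05 units (contract: 0.5).
  Random-effect dimensions a subject has no data for (e.g. unused
  occasions) integrate out exactly and contribute zero.
* **Outer problem.**  L-BFGS-B on transformed scales — log for positive
  parameters and variance components, logit for F_im,fast, identity with
  bounds for covariate coefficients — with finite-difference gradients
  (eps 1e-5) and restarts from the optimum until the OFV stops improving
  (a restart clears the quasi-Newton memory and recovers from premature
  line-search termination on a noisy gradient).  Standard errors come
  from the central-FD Hessian of the OFV at the optimum (relative step
  1e-2, large enough that OFV differences dominate inner-solver noise),
  mapped to the natural scale by the delta method; RSE% = 100·SE/estimate.
* OFV values are internally consistent (nested-model monotonicity is
  tested) but are an implementation-specific quantity, not comparable
  with other estimation software.  D_oral is fixed, never estimated.

Stepwise covariate search: univariate forward scan at α = 0.05
(ΔOFV < −3.84 per added parameter), then backward deletion from the full
model at α = 0.01 (removal must cost > 6.63).  Candidate forms: sex as a
multiplicative change inside the F_im,fast logit; continuous covariates as
θ·(1 + β·(x − median)); an allometric form is available for body size.
Candidate fits warm-start at the base optimum.  Empirical-Bayes
η-shrinkage is 100·(1 − SD(η̂)/ω).  The bootstrap resamples subjects with
replacement, stratified by sex (preserving the female count), refits each
replicate and reports medians with 2.5/97.5 percentile intervals;
non-converged replicates are dropped and counted.

## Monte-Carlo simulation

`simulate_population` draws n virtual subjects (default 5000; Monte-Carlo
SE of a median near 50 ng/mL is then ≲1%) on a shared regimen with fresh
κ per injection, evaluating true (noise-free) individual concentrations —
prediction bands therefore reflect BSV + IOV, not assay error.  The grid
is half-weekly plus every dose instant, so troughs are read exactly at
injection times.  Threshold summaries report exceedance fractions for
50/32/24/12 ng/mL (the optimal-response target, the registrational-trial
first quartile, and 2× / 1× the protein-adjusted IC90).  The sex contrast
simulates an all-male and an all-female cohort with common random numbers
and compares median troughs per week.

Week numbering is anchored at the start of the oral lead-in: the loading
injection falls at week 4, so "week 8" is 4 weeks after the loading dose.

At the packaged estimates these simulations give: oral steady-state median
trough ≈80 ng/mL with ~83% above 50 ng/mL; IM week-8 troughs ~49% above
50 ng/mL, ~4% below 24 and ~15% below 32 ng/mL; an ~18% median drop at
week 16 followed by a rise through week 48.  The simulated sex contrast is
≈−16% at week 8 and ≈+8.6% at week 48; the late-week contrast has a
structural plateau of about +10% — as t→∞ it tends to the ratio of
sex-weighted pathway contributions (0.850·S+0.150·F)/(0.724·S+0.276·F) —
so larger late-week contrasts are not reachable under this parameter set.

The population median does not generally coincide with the typical
individual's profile: troughs are a joint nonlinear (in ka_slow,
non-monotone) function of several log-normal effects, and under the full
variability the median sits up to ~9% from the typical curve at late
accumulation times.  The exact median-mapping property holds, and is
tested, for a single monotone BSV dimension.

## Synthetic cohorts

`CohortSpec` defaults encode the study design: 238 subjects, 20% female,
28 rich-sampled subjects, LLOQ 5 ng/mL, oral 25 mg daily for a 4-week
lead-in, 900 mg IM at weeks 4 and 8 and every 8 weeks thereafter (a
600 mg-monthly template covers the compassionate-use schedule), follow-up
log-normal with median 26 weeks truncated to 4–96.  Demographics are
independent truncated log-normals matched to the reported medians and
ranges (age 46 [20–79] y, weight 78 [50–126] kg, BMI 25.4 [18.2–43.3]
kg/m²).  Sparse subjects contribute one oral trough (immediately before
the loading injection) plus a trough before every later injection — a
median of 4 samples each; rich subjects add samples 1, 2 and 4 weeks after
the second injection.  Nominal times are jittered by ±10% of the elapsed
interval, pre-injection samples only earlier so they remain troughs.
Observations get route-specific residual noise; values below the LLOQ are
flagged and excluded from fitting (censored-likelihood handling is out of
scope).  Tables round-trip bit-identically through the NONMEM-convention
CSV reader/writer, and generation is deterministic under a seed.

What the generator does **not** emulate: non-adherence and dosing-history
errors, assay batch effects, correlated demographics (weight–BMI
coherence), ethnicity or renal-function strata, gastric-bypass
malabsorption, and real-world irregular visit patterns beyond the simple
jitter.  Passing tests therefore demonstrate self-consistency of the
machinery under the declared design, not robustness to those real-data
features.

## Validation toolkit

*pcVPC*: records are binned by time since last dose (strictly positive;
a sample at an injection instant belongs to the preceding interval),
equal-count bins (default 8) per route; every observed and simulated value
is scaled by bin-median-PRED/record-PRED with PRED the typical (η = 0)
prediction; 200 (default) replicates of the observed design give 90% CIs
of the 5/50/95th percentiles.  Simulated values below the LLOQ are dropped
to mirror the BLQ exclusion on the observed side — without this the low
percentiles are systematically miscalibrated.  Under the true model the
observed statistics fall inside the CIs in ≈90% of cells (measured 88% on
average across 10 seeds at n = 100 subjects).

*Cross-validation*: repeated random subject-level 80/20 splits (default 5);
population predictions on held-out subjects are scored by
MPE% = 100·mean(log y − log ŷ) and RMSE% = 100·√mean((log y − log ŷ)²);
the MPE confidence interval is computed across splits (t-based).  Each
split's MPE carries Monte-Carlo noise of order ω/√n_test (~10% at 10
held-out subjects), so unbiasedness is asserted as "the across-split CI
covers zero", not as a tight point bound.

## Self-consistency experiment sizes

Chosen to make the checks sharp while keeping a single-core run practical:

* parameter recovery: 20 cohorts × 24 subjects with an information-rich
  design (20 rich-sampled, 48-week median follow-up), estimating CL,
  F_im,fast, ka_slow and their ωs from off-truth initials.  Median
  relative bias is within ±5% for all three (ka_slow the least precise).
  Under the sparse clinical design the approximate likelihood shows a
  ridge between CL, F_im,fast and ka_slow and recovery degrades — an
  expected property of conditional-mode approximations with ~4
  observations per subject and an 82.7% CV effect, which is why the
  recovery experiment uses the enriched design.
* stepwise search: a 60-subject cohort with the sex effect injected
  (retains sex, rejects age/weight/BMI) and a 40-subject null cohort
  (returns an empty covariate model).
* pcVPC calibration: 10 seeds × 100 subjects, 150 replicates.
* cross-validation: 50 subjects, 5 splits.

## Known limitations

* The estimator is a deterministic Laplace/FOCE-type approximation; no
  stochastic-EM or importance-sampling refinement, no Ω covariance blocks,
  no censored (M3) likelihood.
* Dose-wise IOV superposition approximates the piecewise-constant-CL
  dynamics (exact only within each dose's contribution).
* η-shrinkage on F_im,fast under the synthetic sparse design (~70%) is
  higher than is typical for real cohorts of this layout, because the
  synthetic troughs carry less absorption-phase information than real
  opportunistic sampling; diagnostics that depend on EB effects should be
  read accordingly.
* Simulated sex contrasts are capped near +10% at late weeks by the
  pathway-mixture structure (see above).
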