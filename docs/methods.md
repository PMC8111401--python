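# Methods

## The model

`radpk` analyses single-dose lisinopril kinetics in rats with a linear
two-compartment disposition model plus two external compartments: a gut
depot for oral (gavage) dosing and a cumulative urine compartment. With
amounts Y in µmol and the plasma concentration C₂ = Y₂/V₂ (µmol/L):

    dY_depot/dt  = -ka · Y_depot
    dY_plasma/dt = +F · ka · Y_depot − Cl · C₂ − Q · C₂ + Q · Y_peri / V₃
    dY_peri/dt   = +Q · C₂ − Q · Y_peri / V₃
    dY_urine/dt  = +Cl · C₂

Parameters: absorption rate ka (1/h), bioavailability F ∈ (0, 1], renal
clearance Cl (L/h), inter-compartmental clearance Q (L/h), central volume
V₂ (L), peripheral volume V₃ (L). Working units are fixed internally —
hours, litres, µmol, µmol/L — and all conversions (µg dose → µmol via the
405.5 g/mol molar mass, extraction-efficiency division) happen at the data
boundary.

Two modelling conventions matter and are deliberate:

* **F scales the depot-to-plasma transfer**, not the depot initial
  condition. The two forms give identical plasma curves but different
  depot contents; the gavage mass-balance invariant
  Y₂ + Y₃ + Y_urine + F·Y_depot = F·dose holds only under the transfer
  form, and the tests enforce it.
* **IV bolus dosing bypasses the depot and F entirely** (the full dose is
  placed in plasma). The peripheral compartment is the lumped internal
  tissue pool; no organ-level sub-compartments are modelled, and tissue
  assay values are not fitted observations.

Because the system is linear and time-invariant, `solve()` evaluates the
matrix exponential exactly — there is no step-size control to tune. A
vectorised closed-form bi-/tri-exponential fast path (`po_profiles`,
`iv_profiles`) serves the likelihood and the simulator; it nudges the
absorption rate by one part in 10⁶ when it collides with a disposition
eigenvalue, and the exact solver covers confluent cases. Agreement between
the two paths, and against adaptive stiff ODE integration, is enforced to
1e-8 relative error in the test suite.

Secondary quantities follow from the disposition eigenvalues: the terminal
half-life is ln 2 / β where β is the slow root of
x² − (k10+k12+k21)x + k10·k21 (micro-constants k10 = Cl/V₂, k12 = Q/V₂,
k21 = Q/V₃), and AUC(0, ∞) = F·dose/Cl (dose/Cl for IV), because all
absorbed drug ultimately exits through urine.

## Mixed-effects estimation

Irradiated animals share the control-group typical parameters scaled by
four multiplicative group ratios (on ka, Cl, Q, F). Animal-level
variability is a log-normal multiplicative random effect on V₂ and V₃
(eta ~ N(0, ω²) on the log scale); residual error is additive Gaussian
with separate SDs for plasma concentrations and the single 24-h cumulative
urine amount. Only plasma and urine enter the likelihood. Pre-dose (t = 0)
plasma draws carry prediction zero and are excluded from the likelihood;
zero-dose (vehicle) animals are retained and inform only the residual SD.

The marginal likelihood integrates the per-animal random effects out with
the **Laplace approximation** at each animal's conditional mode. The mode
search is a damped Newton (Levenberg–Marquardt) ascent with
finite-difference curvature (step 1e-4 on the eta scale), batched across
all animals *and* across all outer parameter sets being evaluated — the
outer finite-difference gradient therefore costs one vectorised pass
rather than 2k separate likelihood evaluations. An animal is frozen once
its predicted quadratic gain falls below the floating-point resolution of
its density (residual mode gradients ≤ 1e-5 leave a Laplace error around
1e-9, far below anything that matters). The Laplace value is validated
against an adaptive Gauss–Hermite quadrature oracle on small, near-Gaussian
toys (ω = 0.015), where the approximation itself is accurate to ~1e-4;
at larger ω the Laplace-vs-quadrature gap grows like ω² (≈1e-3 at ω = 0.1),
which is a property of the approximation, not of this implementation.

Optimisation maximises the marginal likelihood over transformed parameters
(log for rates, clearances, volumes, ω, σ; logit for F; log for the group
ratios) with L-BFGS-B in two stages: a pooled fit without random effects
pins down the structural parameters from rough NCA-style starting values
(Cl from IV dose/AUC, V₂ from IV back-extrapolation, ka from reciprocal
time-to-peak, F from the urinary-recovery contrast between routes, with
fixed fallbacks), then the full mixed model starts there with
residual-based σ inits. Up to `n_restarts` attempts (default 3: one from
the data-driven start, the rest jittered under a fixed seed) are run and
the best likelihood wins — sparse designs occasionally present local
optima in which F and its radiation ratio trade off. Objective tolerance
is 1e-11 (scaled); gradients are central differences by default, with a
forward-difference option for well-conditioned repeated-fit experiments.

Wald 95% intervals and per-ratio p-values (log-ratio against 0) come from
the central finite-difference Hessian at the optimum (step 2e-3, chosen
well above the ~1e-9 relative noise floor left by the inner mode search),
inverted after eigenvalue flooring. Parameters stuck at a transform bound
or with non-positive curvature — typically variance components a small
design cannot inform — are excluded from the covariance, since keeping
them makes the information matrix singular and leaks spurious variance
into every other parameter's SE.

Model comparison uses the likelihood-ratio test of the nested
one-compartment model (Q, V₃, their ratio and ω_V3 removed; four degrees
of freedom) against the two-compartment model.

The goodness-of-fit R² pools plasma and urine records after standardising
each compartment by its fitted residual SD, then computes
1 − SS_res/SS_tot on observed vs individual-predicted (conditional-mode)
values.

## Non-compartmental analysis

Gavage plasma concentrations are corrected for extraction efficiency,
dose-normalised to 300 µg, and averaged arithmetically per scheduled
sampling time; AUC(0–tlast) is the linear trapezoid over those means, with
tlast = 24 h by default. Because nearly every animal contributes a single
plasma sample, the design is treated as a batch (serial-sampling) design:
the bootstrap resamples animals with replacement independently within each
time-point batch. Intervals are bootstrap-t: each replicate's AUC is
studentised by its own plug-in SE (Σ w_t² s_t²/n_t with trapezoid weights
w_t), and the replicate t-quantiles calibrate the interval around the
point estimate. Batches with one animal cannot be studentised; they
contribute their mean but no variance, with a warning. The radiation AUC
ratio is computed on the log scale with a delta-method SE and a
bootstrap-t p-value against log-ratio = 0. The generator and seed are
recorded in the output.

## The synthetic-study generator

No raw animal data are deposited, so every pipeline stage is tested
against simulated studies that reproduce the original design exactly: 219
rats in 20 cells of radiation group × route × dose (gavage 300/600 µg,
IV 60 µg, plus a 4-animal vehicle arm), each animal drawing 0–4 plasma
sampling times without replacement from the route's scheduled menu
(13 gavage times between 0 and 48 h; 5 min, 1.5 h and 24 h for IV) and,
where the design says so, one cumulative 24-h urine collection.

Per animal the generator draws the volume random effects, applies the
radiation ratios for irradiated cells, evaluates the exact model, adds
additive Gaussian noise per compartment, and multiplies by the extraction
efficiency so that raw values mimic incomplete recovery (the ETL
correction divides it back out; with zero noise the round trip is exact).
Negative noisy values are retained, consistent with the additive-Gaussian
likelihood.

The published analysis reports no residual or random-effect magnitudes, so
the defaults are explicitly synthetic choices, fixed once: σ_plasma = 5%
of the model peak concentration of the control 300 µg gavage profile
(≈ 0.067 µmol/L), σ_urine = 5% of the model 24-h urine amount of the same
scenario (≈ 0.0036 µmol), and ω_V2 = ω_V3 = 0.3, which yields roughly
1.5–3-fold spread between animals, comparable to the variability the
original study describes qualitatively. Extraction efficiencies default
to 0.9 for both matrices. Simulated studies therefore validate the
*estimator* under the stated stochastic model; they do not probe model
misspecification (nonlinear ACE binding, non-Gaussian error,
time-varying clearance), so passing recovery tests says nothing about
those failure modes in real data.

`reduced_design()` is a 38-animal compact design for repeated-fit
operating-characteristic experiments (e.g. the 200-replicate type-I error
check): it keeps the full factorial structure (both groups, both routes,
both gavage dose levels, urine collections) but uses denser per-animal
sampling so each replicate's likelihood stays well conditioned. The
full-design problem sizes are used wherever a single-study quantity is
reported (parameter recovery over 5 seeds at 219 animals, the LRT at 219
animals).

## Numerical choices and degenerate inputs

* Eigenvalue degeneracy: the closed form floors the eigenvalue gap at
  1e-12·(trace) and nudges ka off collisions; `solve()` (matrix
  exponential) is exact in all cases including α = β.
* β = 0 (no elimination): the terminal half-life reports a
  non-eliminating model; AUC(0, ∞) is returned as infinite.
* Urine-integral terms use `expm1` so (1 − e^(−λt))/λ is stable as λ → 0.
* ω = 0 collapses the marginal likelihood to the plain Gaussian residual
  likelihood (no integral), used both as an option (`fix_omega=(0,0)`)
  and as the first fitting stage.
* A dataset with one animal, fewer usable observations than parameters,
  or inconsistent per-animal metadata raises; missing IV or urine arms
  warn about weak identifiability of F and ka.

## Known limitations

* Laplace (not SAEM/adaptive quadrature) is the only estimator; its bias
  grows with ω and with the sparsity of per-animal data.
* Wald inference is first-order; on very small designs the per-ratio test
  size is only approximately nominal (the 38-animal null experiment sits
  within binomial bounds of 5%, but individual ratios range ~2–6%).
* Single-dose only; no between-occasion variability, no covariates other
  than the radiation group, no below-quantification-limit handling (the
  source analysis describes none).
* The bootstrap-t variant (animal-within-batch resampling, B, studentised
  quantiles) is one defensible reading of a tersely described procedure;
  headline data-dependent values from the original animals (AUC ratio
  1.42, R² = 90.1%) are not reproducible without the raw data and are not
  targets of the test suite.
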