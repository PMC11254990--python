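# Methods

## Structural model

Unbound docetaxel concentrations follow a linear three-compartment model
with first-order elimination from the central compartment, shared by both
routes of administration. IV doses are zero-order infusions into the
central compartment; oral doses deposit `F × amount` into an absorption
depot at `dose time + t_lag` and transfer first-order (`k_a`) to the
central compartment. All clearances and volumes are on the unbound scale;
total concentrations follow from constant, route-specific binding,
`C_total = C_u / fu`, with `fu_iv < fu_po` because the IV formulation's
polysorbate 80 provides additional binding. Unit convention: doses in mg,
volumes in L, clearances in L/h, times in h, concentrations in ng/mL
(`C = amount × 1000 / V`).

Because the system is linear with piecewise-constant input, profiles are
computed **exactly**: within each segment between input breakpoints the
state is propagated through the eigendecomposition of the 4×4 rate matrix
(depot, central, two peripheral), with a matrix-exponential fallback when
the eigenvector matrix is ill-conditioned (condition number above 1e10,
e.g. exactly coincident rate constants). The 3-minute output grid is a
reporting grid only — accuracy does not depend on it. Round-off negatives
smaller than 1e-12 of the profile maximum are clamped to zero. The solver
is verified against independent stiff-ODE integration (LSODA,
rtol 1e-11) to 1e-6 relative accuracy, and against the one-compartment
closed form when both inter-compartmental clearances are zero.

Not modelled, by design: nonlinear elimination, enterohepatic
recirculation, transit-compartment absorption, time-varying bioavailability
or binding, and the inhibitor's own kinetics (encequidar acts only through
the value of `F`).

## Default parameters

Typical values anchor on the reported final-model quantities: unbound
clearance 8570 L/h, oral bioavailability 25% (8% without the inhibitor),
fraction unbound 0.67% (IV) / 1.02% (oral), total-scale V_ss 425 L and
total clearance ≈ 57.3 L/h. The quantities those reports do not pin down
are package defaults, chosen once for realism:

| parameter | default (total scale) | rationale |
|---|---|---|
| V1/V2/V3 | 20 / 35 / 370 L (sum 425 L) | small central volume, dominant deep compartment, as in published docetaxel three-compartment models |
| Q2 / Q3 | 35 / 12 L/h | disposition phases of ≈ 7 min / 1.1 h / 26 h — docetaxel's characteristic well-separated tri-phasic decline; near-equal peripheral time constants would make the two compartments practically indistinguishable |
| k_a, t_lag | 0.85 1/h, 0.5 h | oral t_max of ~2 h after the lag |
| ω (cl_u, v1_u, k_a, F) | 0.35, 0.30, 0.50, 0.30 | moderate BSV on disposition, larger on absorption, typical of oral oncology PK |
| σ_prop (total, unbound) | 20%, 25% | assay plus model misspecification scale |
| σ_add (total, unbound) | 0.5, 0.02 ng/mL | a fraction of each assay's LLOQ (2 and 0.084 ng/mL) |
| ρ (L2) | 0.5 | both observables derive from the same plasma sample |

Unbound volumes/clearances are the total-scale values divided by `fu_iv`.
Ω is diagonal by default (no BSV correlations are reported); an optional
correlation map is accepted. No between-occasion variability, carryover,
period or sequence effects are simulated. Every default can be overridden
from a YAML/JSON config (`theta` / `omega` / `sigma` sections).

These defaults are *synthetic stand-ins* for the study's fitted variance
structure, which is not published in the main text. Simulation outputs
that depend on the BSV magnitudes (PTA values, the GO classification)
therefore characterise the package's default population, not the study
population; the structural conversions (clearance, V_ss) and all framework
mechanics are parameter-exact.

## Synthetic trial generator

The generator emulates the phase-I design: 9 patients, two occasions — a
130 mg IV infusion over 1 h sampled 24 times (0 to 73 h) and one oral dose
(75/150/300 mg/m² cycled across subjects, BSA fixed at 1.7 m²) sampled 23
times (0 to 96 h). Total docetaxel is observed at every sample; unbound on
fixed 7 (IV) and 8 (oral) sample subsets spanning infusion/absorption,
peak and elimination — the study chose its subsets by optimal design, which
is out of scope here, so the subsets are a documented, overridable choice.
At n = 9 this yields exactly 135 unbound and 423 total observation rows.
Pre-dose (t = 0) samples are recorded and fall to BLQ handling.

What it does **not** emulate: per-patient BSA distributions, the study's
actual dose allocations, assay batch effects, dropout, or between-occasion
variability. Passing tests on these data therefore demonstrate correctness
of the machinery and internal consistency of the model, not fidelity to
any real patient series.

BLQ handling: observations strictly below the observable's LLOQ (including
negatives produced by the additive error) are flagged; values at the LLOQ
are quantifiable by definition. The M6 convention then replaces the first
observation of each maximal consecutive BLQ run with LLOQ/2 (retained in
the likelihood) and discards the rest of the run, applied to leading and
trailing runs alike; the procedure is idempotent.

## Estimation

The joint likelihood multiplies residual densities over all retained
observations: combined error `var = σ_add² + (σ_prop · f)²` per observable,
and a bivariate normal with correlation ρ for the standardized residual
pair from one blood sample (univariate for lone observations; M6-imputed
rows enter as ordinary observations). Subject random effects are
integrated out by a Laplace approximation at the per-subject
empirical-Bayes mode, which is exact in the limit ω → 0 and is verified
against brute-force quadrature on a one-random-effect toy to within 0.1
OFV units. FOCE-style linearisation is not implemented; OFV parity with
other estimators is not claimed, only differences of OFVs between nested
models fit to the same data (ΔOFV > χ²₀.₉₅(df), i.e. 3.84 for 1 df).

Numerical choices: optimisation runs on log-transformed parameters (logit
for fractions, atanh for ρ) with L-BFGS-B (ftol 1e-10, gtol 1e-6,
finite-difference step 1e-5); the inner mode search uses BFGS with
gradient tolerance 1e-5 — tighter thresholds are below the truncation
error of finite-difference gradients at typical OFV magnitudes. Inner
searches warm-start from the previous outer iteration. Standard errors
come from the inverse central-difference Hessian of OFV/2 at the optimum,
delta-method-transformed to the natural scale (RSE% = 100·SE/estimate);
a non-positive-definite Hessian reports SEs as unavailable without
failing the fit. Parameters whose initial value is zero are implicitly
fixed (no log transform exists); model reduction (fewer compartments, no
lag, no L2) is expressed by fixing the corresponding parameters.

The parameter-recovery check fits 50 synthetic subjects on a *rich*
variant of the trial design (unbound assayed at every sample — the 7/8
subsets reflect the study's assay budget, not an informative-design
choice), with the variance parameters fixed at their generating values so
the check isolates the structural typical values; all eleven are recovered
within 15% (most within 4%).

## Exposure metrics and the decision framework

AUCOEC at effective concentration EC is the trapezoidal area of
`C_u − EC` over the region where the profile exceeds EC. The default
`strict_points` mode drops sampled points below EC and integrates each
maximal retained run — the literal point-removal procedure, adequate on
the 3-minute grid (≤ 1% from the dense-grid value); `interpolated` mode
additionally inserts the exact EC crossings and is grid-robust. AUCOEC is
computed on the unbound profile; `AUCOEC(0) = AUC`. Simulation horizon
24 h in 3-minute steps. Multi-dose AUCOEC is `n × single dose` under the
complete-washout assumption (24 h dosing interval, unbound docetaxel
essentially undetectable by 12 h).

The PTA grid simulates one shared cohort (common random numbers) of
`n_patients` (default 1000) and reuses it for every cell, matching the
paired own-control design and guaranteeing PTA monotonicity in EC, dose
and number of doses per fixed seed. Oral dose levels scale a per-patient
unit-dose profile (the system is linear in dose); the no-inhibitor
comparator rescales the same profile to F = 8% at 600 mg. The IV dose is
fixed at 130 mg for all virtual patients. The AUCOEC-Target applies a 20%
non-inferiority margin per patient; ties count as successes; the 80% PTA
threshold is strict (`>`). GO requires some regimen to pass at every EC in
the 0.1–1.0 ng/mL grid; otherwise the highest passing EC per regimen is
reported with a CONDITIONAL_GO, or NO_GO if nothing passes anywhere.

## Known limitations

* Variance-structure defaults are synthetic (see above); decision outputs
  shift with the BSV configuration.
* The Laplace OFV differs from FOCE-I implementations by O(1) amounts;
  only within-package model comparisons are meaningful.
* Strict-mode AUCOEC is grid-dependent by construction; use interpolated
  mode for coarse grids.
* Toxicity/tolerability of multi-dose regimens is outside the model; the
  framework addresses exposure feasibility only.
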