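# odoxpk

Population pharmacokinetics of **unbound and total docetaxel** after IV
docetaxel and oral docetaxel + encequidar (oDox + E), with a
simulation-based dose-feasibility framework.

Docetaxel is given IV because its oral bioavailability is below 10%.
Encequidar, an intestine-restricted P-glycoprotein inhibitor, raises oral
bioavailability to roughly 25%, which makes an oral regimen conceivable —
but only if it can match the unbound exposure of the standard-of-care
130 mg IV infusion. Because the IV formulation contains polysorbate 80,
which binds docetaxel, the fraction unbound is route-specific
(fu ≈ 0.67% IV, ≈ 1.02% oral) and the comparison must be made on the
**unbound** scale. This package is aimed at pharmacometricians who want to
run that comparison end to end: structural PK model, population
variability, synthetic phase-I data, mixed-effects estimation, and the
virtual-trial decision analysis.

## Model

Unbound docetaxel follows a three-compartment disposition model with linear
elimination, parameterised on the unbound scale (CL_u ≈ 8570 L/h):

* IV doses enter the central compartment as a zero-order infusion;
* oral doses enter a depot after a lag t_lag and transfer first-order (k_a)
  with constant bioavailability F ≈ 0.25;
* total concentration is C_u / fu with a constant, route-specific fu, so the
  total-scale clearance is CL = CL_u · fu ≈ 57 L/h and
  V_ss = (V1_u + V2_u + V3_u) · fu ≈ 425 L.

The population layer adds log-normal between-subject variability
(p_i = θ_p · e^{η_p}, η ~ N(0, ω²)) and a combined additive + proportional
residual error in which the (total, unbound) residuals from one blood
sample may be correlated (correlation ρ). Estimation maximises the Laplace
marginal likelihood (exact when all ω = 0); nested models are compared by
the ΔOFV > 3.84 chi-squared rule.

The decision framework simulates 1000 virtual patients who each receive
both the IV reference and every candidate oral regimen (each patient is
their own control). For an effective concentration EC, the exposure metric
is **AUCOEC** — the area of the unbound profile above EC, after subtracting
EC. Each patient's IV AUCOEC minus a 20% non-inferiority margin sets their
**AUCOEC-Target**; an oral regimen succeeds in that patient if its AUCOEC
(× number of doses, 24 h washout) meets the target, and **PTA** is the
percentage of successes. A regimen grid (400–600 mg × 1–3 doses ×
EC 0.1–1.0 ng/mL) is classified **GO** (some regimen passes the 80% PTA
threshold at every EC), **CONDITIONAL_GO** (passes only below some EC
boundary) or **NO_GO** (never passes).

## Worked example

```python
import numpy as np
from odoxpk import (Regimen, SimConfig, classify_decision, compute_aucoec,
                    default_population_model, default_structural_params,
                    predict_unbound, run_pta_grid, total_cl_from_unbound)

theta = default_structural_params()
print(f"total clearance: {total_cl_from_unbound(theta.cl_u, theta.fu_iv):.1f} L/h")

t = np.arange(0, 24.0001, 0.05)            # 3-minute reporting grid
c_iv = predict_unbound(theta, Regimen.single_iv(130, duration=1.0), t)
c_po = predict_unbound(theta, Regimen.single_oral(600), t)
iv_aucoec = compute_aucoec(t, c_iv, ec=0.1).value
po_aucoec = compute_aucoec(t, c_po, ec=0.1).value
print(f"IV 130 mg  AUCOEC(0.1): {iv_aucoec:.2f} ng*h/mL -> target {0.8*iv_aucoec:.2f}")
print(f"oral 600 mg AUCOEC(0.1): {po_aucoec:.2f} ng*h/mL")

pop = default_population_model()
grid = run_pta_grid(pop, SimConfig(n_patients=1000, seed=1))
print(f"PTA, single 600 mg at EC 0.1: {grid.pta(600, 1, 0.1):.1f}%")
print(f"PTA, 600 mg x 3 at EC 1.0:   {grid.pta(600, 3, 1.0):.1f}%")
report = classify_decision(grid, SimConfig(n_patients=1000, seed=1))
print(f"decision: {report.classification}")
```

prints

```
total clearance: 57.4 L/h
IV 130 mg  AUCOEC(0.1): 12.04 ng*h/mL -> target 9.63
oral 600 mg AUCOEC(0.1): 13.91 ng*h/mL
PTA, single 600 mg at EC 0.1: 86.4%
PTA, 600 mg x 3 at EC 1.0:   97.9%
decision: GO
```

Reading this: for the typical subject a single 600 mg oral dose already
clears the margin-reduced IV target at EC 0.1 ng/mL (13.91 ≥ 9.63), but
across a variable population the single dose attains the target in only
86.4% of patients at the most favourable EC; a triple 600 mg regimen covers
all ECs up to 1.0 ng/mL, so with these default population parameters the
framework returns GO. The decision is sensitive to the between-subject
variability configuration — see `docs/methods.md`.

The same pipeline is scriptable from the shell:

```bash
odoxpk simulate-trial --seed 1 --out trial.csv          # synthetic phase-I data
odoxpk fit --dataset trial.csv --out fit.json \
    --free theta.cl_u --free theta.v1_u --free omega.cl_u   # population fit
odoxpk simulate-pta --seed 1 --out grid.csv             # 1000-patient PTA grid
odoxpk decide --grid grid.csv --out decision.json       # GO / NO-GO
odoxpk report --grid grid.csv --decision decision.json  # summary tables
```

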