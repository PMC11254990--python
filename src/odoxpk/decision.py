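"""Dose-feasibility simulation: AUCOEC targets, PTA and GO/NO-GO.

Each virtual patient acts as their own control: the patient's individual
parameters generate both the standard-of-care IV profile (130 mg over 1 h)
and every candidate oral docetaxel + encequidar regimen.  For each effective
concentration (EC) the IV AUCOEC minus a 20% non-inferiority margin sets the
AUCOEC-Target; an oral regimen whose AUCOEC meets or exceeds the target in
that patient is a success, and the probability of target attainment (PTA) is
the percentage of successes across the cohort.  A comparator arm simulates
600 mg oral docetaxel without the P-gp inhibitor (bioavailability 8%).

Classification: NO_GO if no regimen exceeds the PTA threshold anywhere;
GO if some regimen exceeds it at every EC; otherwise CONDITIONAL_GO with the
highest covered EC reported per regimen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exposure import AUCOECMode, compute_aucoec, multidose_aucoec
from .pk_core import Regimen, predict_unbound
from .population import PopulationModel, sample_individuals

__all__ = [
    "SimConfig",
    "PTAGrid",
    "DecisionReport",
    "aucoec_target",
    "success_indicator",
    "pta",
    "run_pta_grid",
    "classify_decision",
]


def _default_ec_grid() -> tuple[float, ...]:
    # 0.1 to 1.0 ng/mL in 0.1 increments (10 values)
    return tuple(np.round(np.arange(1, 11) * 0.1, 1))


@dataclass(frozen=True)
class SimConfig:
    iv_dose: float = 130.0          # mg (75 mg/m² × 1.7 m²)
    iv_infusion_duration: float = 1.0
    oral_doses: tuple[float, ...] = (400.0, 450.0, 500.0, 550.0, 600.0)
    ec_grid: tuple[float, ...] = field(default_factory=_default_ec_grid)
    n_doses_list: tuple[int, ...] = (1, 2, 3)
    n_patients: int = 1000
    margin: float = 0.20
    pta_threshold: float = 80.0     # percent, strict >
    comparator_f: float = 0.08      # oral docetaxel without encequidar
    comparator_dose: float = 600.0
    horizon: float = 24.0           # h
    step: float = 0.05              # h (3-minute reporting grid)
    aucoec_mode: AUCOECMode = AUCOECMode.STRICT_POINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.margin < 1.0:
            raise ValueError("margin must be in [0, 1)")
        if not 0.0 < self.pta_threshold <= 100.0:
            raise ValueError("pta_threshold must be in (0, 100]")
        ec = np.asarray(self.ec_grid)
        if len(ec) == 0 or np.any(ec <= 0) or np.any(np.diff(ec) <= 0):
            raise ValueError("ec_grid must be positive and ascending")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.oral_doses or not self.n_doses_list:
            raise ValueError("dose grid must be non-empty")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.step))
        return np.linspace(0.0, n * self.step, n + 1)


@dataclass
class PTAGrid:
    """PTA per (dose, n_doses, EC) cell, plus the no-inhibitor comparator."""

    df: pd.DataFrame  # columns: arm, dose_mg, n_doses, ec_ng_ml, pta_pct, n_sim

    def pta(self, dose: float, n_doses: int, ec: float, arm: str = "odox_e") -> float:
        m = self.df[(self.df.arm == arm) & (self.df.dose_mg == dose)
                    & (self.df.n_doses == n_doses)
                    & np.isclose(self.df.ec_ng_ml, ec)]
        if m.empty:
            raise KeyError((arm, dose, n_doses, ec))
        return float(m.pta_pct.iloc[0])

    def panel(self, n_doses: int, arm: str = "odox_e") -> pd.DataFrame:
        return self.df[(self.df.arm == arm) & (self.df.n_doses == n_doses)]


@dataclass
class DecisionReport:
    classification: str  # GO | CONDITIONAL_GO | NO_GO
    pta_threshold: float
    boundary_ec: dict[str, float | None]  # per "dose x n_doses" regimen
    best_regimen: str | None
    best_boundary_ec: float | None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def aucoec_target(iv_aucoec: float, margin: float = 0.20) -> float:
    """AUCOEC-Target: the patient's IV AUCOEC reduced by the margin."""
    if iv_aucoec < 0:
        raise ValueError("iv_aucoec must be >= 0")
    if not 0.0 <= margin < 1.0:
        raise ValueError("margin must be in [0, 1)")
    return iv_aucoec * (1.0 - margin)


def success_indicator(psi_oral: float, target: float) -> int:
    """1 if the oral AUCOEC meets or exceeds the target, else 0 (ties succeed)."""
    if psi_oral < 0 or target < 0:
        raise ValueError("inputs must be >= 0")
    return int(psi_oral >= target)


def pta(successes: Sequence[int]) -> float:
    """Probability of target attainment: 100 × mean of the 0/1 indicators."""
    s = np.asarray(successes, dtype=float)
    if s.size == 0:
        raise ValueError("empty success list")
    return float(100.0 * s.mean())


def run_pta_grid(pop: PopulationModel, config: SimConfig) -> PTAGrid:
    """Simulate the cohort once and fill the full PTA grid.

    One shared virtual cohort (common random numbers) is used for every
    cell, matching the paired own-control design; oral dose levels scale a
    per-patient unit-dose profile because the system is linear in dose.
    """
    t = config.time_grid
    individuals = sample_individuals(pop, config.n_patients, config.seed)
    ecs = list(config.ec_grid)
    doses = list(config.oral_doses)
    mode = config.aucoec_mode

    n_pat, n_ec, n_dose = len(individuals), len(ecs), len(doses)
    targets = np.empty((n_pat, n_ec))
    oral_single = np.empty((n_pat, n_dose, n_ec))
    comp_single = np.empty((n_pat, n_ec))

    iv_reg = Regimen.single_iv(config.iv_dose, config.iv_infusion_duration)
    unit_oral = Regimen.single_oral(1.0)
    for i, p in enumerate(individuals):
        c_iv = predict_unbound(p, iv_reg, t)
        c_unit = predict_unbound(p, unit_oral, t)  # per mg at the patient's F
        for k, ec in enumerate(ecs):
            iv_val = compute_aucoec(t, c_iv, ec, mode).value
            targets[i, k] = aucoec_target(iv_val, config.margin)
            for j, dose in enumerate(doses):
                oral_single[i, j, k] = compute_aucoec(t, dose * c_unit, ec, mode).value
            c_comp = config.comparator_dose * (config.comparator_f / p.f_oral) * c_unit
            comp_single[i, k] = compute_aucoec(t, c_comp, ec, mode).value

    rows = []
    for n_doses in config.n_doses_list:
        for j, dose in enumerate(doses):
            for k, ec in enumerate(ecs):
                vals = np.array([multidose_aucoec(v, n_doses)
                                 for v in oral_single[:, j, k]])
                succ = (vals >= targets[:, k]).astype(int)
                rows.append(dict(arm="odox_e", dose_mg=dose, n_doses=n_doses,
                                 ec_ng_ml=ec, pta_pct=pta(succ), n_sim=n_pat))
        for k, ec in enumerate(ecs):
            vals = np.array([multidose_aucoec(v, n_doses) for v in comp_single[:, k]])
            succ = (vals >= targets[:, k]).astype(int)
            rows.append(dict(arm="oral_alone", dose_mg=config.comparator_dose,
                             n_doses=n_doses, ec_ng_ml=ec,
                             pta_pct=pta(succ), n_sim=n_pat))
    return PTAGrid(pd.DataFrame(rows))


def classify_decision(grid: PTAGrid, config: SimConfig) -> DecisionReport:
    """Apply the two-part GO / NO-GO framework to a completed grid."""
    thr = config.pta_threshold
    ecs = list(config.ec_grid)
    main = grid.df[(grid.df.arm == "odox_e") & (grid.df.dose_mg <= 600.0)]
    expected = len(config.oral_doses) * len(config.n_doses_list) * len(ecs)
    if len(main) < expected:
        raise ValueError("grid is incomplete for the configured regimens")

    boundary: dict[str, float | None] = {}
    any_pass = False
    full_cover = False
    for (dose, nd), cell in main.groupby(["dose_mg", "n_doses"]):
        key = f"{dose:g} mg x {nd}"
        passing = cell[cell.pta_pct > thr].ec_ng_ml
        if passing.empty:
            boundary[key] = None
        else:
            any_pass = True
            boundary[key] = float(passing.max())
            if len(passing) == len(ecs):
                full_cover = True

    if not any_pass:
        classification = "NO_GO"
    elif full_cover:
        classification = "GO"
    else:
        classification = "CONDITIONAL_GO"
    covered = {k: v for k, v in boundary.items() if v is not None}
    best = max(covered, key=lambda k: covered[k]) if covered else None
    return DecisionReport(
        classification=classification,
        pta_threshold=thr,
        boundary_ec=boundary,
        best_regimen=best,
        best_boundary_ec=covered.get(best) if best else None,
    )
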