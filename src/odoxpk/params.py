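"""Default parameter values and YAML/JSON config I/O.

The typical values anchor on the quantities reported for the final docetaxel
model: unbound clearance 8570 L/h, oral bioavailability 25% (with
encequidar), fraction unbound 0.67% (IV formulation) and 1.02% (oral), and a
total-scale steady-state volume of 425 L.  The split of that volume across
compartments, the inter-compartmental clearances, the absorption constants
and all variability magnitudes are package defaults chosen to be realistic
for docetaxel (proportions consistent with published three-compartment
models, moderate log-normal BSV, assay-scale residual terms); see
docs/methods.md for the rationale.  Any value can be overridden from a YAML
or JSON config with sections ``theta``, ``omega``, ``sigma``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .pk_core import StructuralParams
from .population import OBSERVABLES, PopulationModel

__all__ = [
    "default_structural_params",
    "default_population_model",
    "population_model_from_dict",
    "population_model_to_dict",
    "load_population_model",
    "save_population_model",
]

# Total-scale Vss of 425 L split 20 / 35 / 370 L across central and the two
# peripheral compartments, with inter-compartmental clearances giving the
# well-separated tri-phasic disposition characteristic of docetaxel
# (distribution half-lives of minutes and ~1 h, terminal phase > 10 h);
# everything is then moved to the unbound scale via fu_iv.
_FU_IV = 0.0067
_FU_PO = 0.0102

_THETA = dict(
    cl_u=8570.0,
    v1_u=round(20.0 / _FU_IV, 1),   # ~2985 L unbound (20 L total scale)
    v2_u=round(35.0 / _FU_IV, 1),   # ~5224 L (35 L), shallow compartment
    v3_u=round(370.0 / _FU_IV, 1),  # ~55224 L (370 L), deep compartment
    q2_u=round(35.0 / _FU_IV, 1),   # ~5224 L/h (35 L/h total scale)
    q3_u=round(12.0 / _FU_IV, 1),   # ~1791 L/h (12 L/h)
    ka=0.85,
    tlag=0.5,
    f_oral=0.25,
    fu_iv=_FU_IV,
    fu_po=_FU_PO,
)

_OMEGA = dict(cl_u=0.35, v1_u=0.30, ka=0.50, f_oral=0.30)

_SIGMA = dict(
    sigma_add={"total": 0.5, "unbound": 0.02},
    sigma_prop={"total": 0.20, "unbound": 0.25},
    rho_l2=0.5,
)


def default_structural_params() -> StructuralParams:
    return StructuralParams(**_THETA)


def default_population_model() -> PopulationModel:
    return PopulationModel(
        theta=default_structural_params(),
        omega_sd=dict(_OMEGA),
        sigma_add=dict(_SIGMA["sigma_add"]),
        sigma_prop=dict(_SIGMA["sigma_prop"]),
        rho_l2=_SIGMA["rho_l2"],
    )


def population_model_from_dict(cfg: Mapping[str, Any]) -> PopulationModel:
    """Build a PopulationModel from a config mapping.

    Recognised sections: ``theta`` (StructuralParams fields), ``omega``
    (per-parameter log-scale SDs), ``sigma`` (``add``/``prop`` per
    observable plus ``rho_l2``).  Missing entries fall back to package
    defaults.
    """
    theta = dict(_THETA)
    theta.update(cfg.get("theta", {}))
    omega = dict(cfg.get("omega", _OMEGA))
    sigma = cfg.get("sigma", {})
    add = dict(_SIGMA["sigma_add"])
    prop = dict(_SIGMA["sigma_prop"])
    add.update(sigma.get("add", {}))
    prop.update(sigma.get("prop", {}))
    unknown = set(theta) - set(StructuralParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown theta fields: {sorted(unknown)}")
    for obs_map in (add, prop):
        bad = set(obs_map) - set(OBSERVABLES)
        if bad:
            raise ValueError(f"unknown observables in sigma: {sorted(bad)}")
    return PopulationModel(
        theta=StructuralParams(**theta),
        omega_sd=omega,
        sigma_add=add,
        sigma_prop=prop,
        rho_l2=float(sigma.get("rho_l2", _SIGMA["rho_l2"])),
    )


def population_model_to_dict(pop: PopulationModel) -> dict[str, Any]:
    return {
        "theta": {k: getattr(pop.theta, k) for k in StructuralParams.__dataclass_fields__},
        "omega": dict(pop.omega_sd),
        "sigma": {
            "add": dict(pop.sigma_add),
            "prop": dict(pop.sigma_prop),
            "rho_l2": pop.rho_l2,
        },
    }


def load_population_model(path: str | Path) -> PopulationModel:
    """Read a population model from a YAML (or JSON) config file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} does not contain a mapping")
    return population_model_from_dict(cfg)


def save_population_model(pop: PopulationModel, path: str | Path) -> None:
    path = Path(path)
    cfg = population_model_to_dict(pop)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
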