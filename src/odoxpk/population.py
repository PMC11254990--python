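"""Population layer: between-subject variability and residual error.

Between-subject variability (BSV) is log-normal: each individual parameter
is theta * exp(eta) with eta ~ N(0, omega^2), independent across parameters
by default (an optional full covariance can be supplied).  Residual error is
combined additive + proportional per observable (total, unbound), and the
two residuals arising from the same blood sample may be correlated
(the "L2" structure): the standardized pair is bivariate normal with
correlation rho_l2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pk_core import StructuralParams

__all__ = ["PopulationModel", "sample_individuals", "apply_residual_error"]

OBSERVABLES = ("total", "unbound")

#: structural parameter names that may carry BSV
PARAM_NAMES = (
    "cl_u", "v1_u", "v2_u", "v3_u", "q2_u", "q3_u",
    "ka", "tlag", "f_oral", "fu_iv", "fu_po",
)


@dataclass
class PopulationModel:
    """Typical values plus variability terms.

    Parameters
    ----------
    theta : StructuralParams
        Typical (population median) structural parameters.
    omega_sd : mapping
        Log-scale BSV standard deviation per parameter name; parameters not
        listed (or listed with 0) are fixed at their typical value.
    omega_corr : optional mapping
        Pairwise correlations between etas, keyed by frozenset-like tuples;
        default none (diagonal Omega).
    sigma_add : mapping
        Additive residual SD per observable, ng/mL.
    sigma_prop : mapping
        Proportional residual SD per observable (fraction).
    rho_l2 : float
        Within-blood-sample correlation of the standardized (total, unbound)
        residual pair.
    """

    theta: StructuralParams
    omega_sd: Mapping[str, float] = field(default_factory=dict)
    sigma_add: Mapping[str, float] = field(default_factory=lambda: {"total": 0.0, "unbound": 0.0})
    sigma_prop: Mapping[str, float] = field(default_factory=lambda: {"total": 0.0, "unbound": 0.0})
    rho_l2: float = 0.0
    omega_corr: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega_sd = {k: float(v) for k, v in dict(self.omega_sd).items()}
        for k, v in self.omega_sd.items():
            if k not in PARAM_NAMES:
                raise ValueError(f"unknown parameter in omega_sd: {k!r}")
            if v < 0:
                raise ValueError("omega_sd must be >= 0")
        for obs in OBSERVABLES:
            if self.sigma_add.get(obs, 0.0) < 0 or self.sigma_prop.get(obs, 0.0) < 0:
                raise ValueError("sigma terms must be >= 0")
        if not -1.0 < self.rho_l2 < 1.0:
            raise ValueError("rho_l2 must lie strictly inside (-1, 1)")

    @property
    def random_effect_names(self) -> tuple[str, ...]:
        return tuple(k for k in PARAM_NAMES if self.omega_sd.get(k, 0.0) > 0.0)

    def omega_matrix(self) -> np.ndarray:
        names = self.random_effect_names
        sd = np.array([self.omega_sd[k] for k in names])
        corr = np.eye(len(names))
        for (a, b), r in self.omega_corr.items():
            if a in names and b in names:
                i, j = names.index(a), names.index(b)
                corr[i, j] = corr[j, i] = r
        return corr * np.outer(sd, sd)

    def individual_from_etas(self, etas: Mapping[str, float]) -> StructuralParams:
        """Apply log-normal deviations to the typical values."""
        updates = {k: getattr(self.theta, k) * float(np.exp(v)) for k, v in etas.items()}
        # exp(eta) can push a fraction above 1; binding/availability fractions
        # are capped at 1 to stay physical.
        for frac in ("f_oral", "fu_iv", "fu_po"):
            if frac in updates:
                updates[frac] = min(updates[frac], 1.0)
        return self.theta.with_updates(**updates)

    def residual_sd(self, obs: str, pred: float | np.ndarray) -> float | np.ndarray:
        """SD of the combined error model at prediction f: sqrt(add^2 + (prop*f)^2)."""
        add = self.sigma_add.get(obs, 0.0)
        prop = self.sigma_prop.get(obs, 0.0)
        return np.sqrt(add ** 2 + (prop * np.asarray(pred)) ** 2)


def sample_individuals(
    pop: PopulationModel, n: int, seed: int | np.random.Generator
) -> list[StructuralParams]:
    """Draw ``n`` virtual individuals with log-normal BSV.

    Deterministic given the seed; with all omega zero every individual
    equals the typical subject.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = pop.random_effect_names
    if not names:
        return [pop.theta] * n
    cov = pop.omega_matrix()
    etas = rng.multivariate_normal(np.zeros(len(names)), cov, size=n, method="cholesky")
    return [pop.individual_from_etas(dict(zip(names, row))) for row in etas]


def apply_residual_error(
    pred_pairs: Sequence[tuple[float, float | None]],
    pop: PopulationModel,
    seed: int | np.random.Generator,
) -> list[tuple[float, float | None]]:
    """Corrupt (total, unbound) prediction pairs with the residual model.

    Each pair comes from one blood sample; its standardized residuals are
    drawn from a bivariate normal with correlation ``rho_l2``.  A pair whose
    unbound entry is None (no unbound assay on that sample) uses the
    univariate total model.  Negative observed values are possible from the
    additive term and are retained (BLQ handling is downstream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = pop.rho_l2
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    out: list[tuple[float, float | None]] = []
    for f_tot, f_unb in pred_pairs:
        if f_tot < 0 or (f_unb is not None and f_unb < 0):
            raise ValueError("predictions must be >= 0")
        if f_unb is None:
            z = rng.standard_normal()
            y_tot = f_tot + z * pop.residual_sd("total", f_tot)
            out.append((float(y_tot), None))
        else:
            z = chol @ rng.standard_normal(2)
            y_tot = f_tot + z[0] * pop.residual_sd("total", f_tot)
            y_unb = f_unb + z[1] * pop.residual_sd("unbound", f_unb)
            out.append((float(y_tot), float(y_unb)))
    return out
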