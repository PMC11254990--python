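"""Structural pharmacokinetic model for docetaxel.

Three-compartment disposition with linear elimination, parameterised on the
*unbound* concentration scale: clearances and volumes refer to unbound drug,
and total concentrations are recovered by dividing by the route-specific
fraction unbound (constant binding).  Oral doses (docetaxel tablets given
after the P-gp inhibitor encequidar) enter a depot compartment after an
absorption lag and transfer first-order to the central compartment; IV doses
are zero-order infusions into the central compartment.

The system is linear with piecewise-constant input, so concentration-time
profiles are computed exactly by propagating the state through an
eigendecomposition of the rate matrix (matrix-exponential fallback for
defective cases) rather than by time-step integration.

Units: dose amounts in mg, volumes in L, clearances in L/h, times in h,
concentrations in ng/mL (1 mg/L = 1000 ng/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Route",
    "StructuralParams",
    "DoseEvent",
    "Regimen",
    "ConcProfile",
    "predict_unbound",
    "total_from_unbound",
    "total_cl_from_unbound",
    "total_vss",
]

MG_PER_L_TO_NG_PER_ML = 1000.0


class Route(str, Enum):
    IV_INFUSION = "iv_infusion"
    ORAL = "oral"


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters on the unbound scale.

    Parameters
    ----------
    cl_u : float
        Unbound clearance from the central compartment, L/h.
    v1_u, v2_u, v3_u : float
        Unbound central and peripheral volumes, L.
    q2_u, q3_u : float
        Unbound inter-compartmental clearances, L/h.
    ka : float
        First-order absorption rate constant, 1/h.
    tlag : float
        Absorption lag time, h.
    f_oral : float
        Absolute oral bioavailability (fraction), ~0.25 with encequidar.
    fu_iv, fu_po : float
        Fraction unbound by route (the IV formulation binds additionally to
        polysorbate 80, hence a lower fu).
    """

    cl_u: float
    v1_u: float
    v2_u: float = 0.0
    v3_u: float = 0.0
    q2_u: float = 0.0
    q3_u: float = 0.0
    ka: float = 1.0
    tlag: float = 0.0
    f_oral: float = 1.0
    fu_iv: float = 1.0
    fu_po: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_u", "v1_u"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("v2_u", "v3_u", "q2_u", "q3_u", "tlag"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.ka) or self.ka <= 0:
            raise ValueError("ka must be finite and > 0")
        for name in ("f_oral", "fu_iv", "fu_po"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")

    def fu(self, route: Route | str) -> float:
        route = Route(route)
        return self.fu_iv if route is Route.IV_INFUSION else self.fu_po

    def with_updates(self, **kwargs: float) -> "StructuralParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: IV zero-order infusion or oral first-order input."""

    route: Route
    amount: float
    time: float = 0.0
    duration: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        if not np.isfinite(self.amount) or self.amount < 0:
            raise ValueError("amount must be finite and >= 0")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.route is Route.IV_INFUSION:
            if self.duration is None or self.duration <= 0:
                raise ValueError("iv_infusion requires duration > 0")
        elif self.duration is not None:
            raise ValueError("oral doses take no infusion duration")


@dataclass(frozen=True)
class Regimen:
    events: tuple[DoseEvent, ...]

    def __init__(self, events: Sequence[DoseEvent]):
        events = tuple(events)
        if not events:
            raise ValueError("regimen must contain at least one dose event")
        if any(b.time < a.time for a, b in zip(events, events[1:])):
            raise ValueError("dose events must be sorted by time")
        object.__setattr__(self, "events", events)

    @classmethod
    def single_iv(cls, amount: float, duration: float = 1.0, time: float = 0.0) -> "Regimen":
        return cls([DoseEvent(Route.IV_INFUSION, amount, time, duration)])

    @classmethod
    def single_oral(cls, amount: float, time: float = 0.0) -> "Regimen":
        return cls([DoseEvent(Route.ORAL, amount, time)])

    @classmethod
    def repeated_oral(cls, amount: float, n_doses: int, interval: float = 24.0) -> "Regimen":
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        return cls([DoseEvent(Route.ORAL, amount, i * interval) for i in range(n_doses)])

    @property
    def route_context(self) -> Route:
        routes = {e.route for e in self.events}
        return Route.ORAL if routes == {Route.ORAL} else Route.IV_INFUSION


@dataclass
class ConcProfile:
    """Paired unbound/total concentration-time profile on a common grid."""

    times: np.ndarray
    c_unbound: np.ndarray
    c_total: np.ndarray
    route_context: Route

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_unbound = np.asarray(self.c_unbound, dtype=float)
        self.c_total = np.asarray(self.c_total, dtype=float)
        if not (len(self.times) == len(self.c_unbound) == len(self.c_total)):
            raise ValueError("times and concentration arrays must share a length")

    def to_csv(self, path) -> None:
        """Write the profile as CSV with one pair of columns per observable."""
        import pandas as pd

        pd.DataFrame({
            "time_h": self.times,
            "unbound_ng_per_ml": self.c_unbound,
            "total_ng_per_ml": self.c_total,
        }).to_csv(path, index=False)


# --- linear-system machinery -------------------------------------------------

_N_STATES = 4  # depot, central, peripheral-2, peripheral-3


def _rate_matrix(p: StructuralParams) -> np.ndarray:
    """System matrix for amounts (mg) in [depot, central, periph2, periph3]."""
    a = np.zeros((_N_STATES, _N_STATES))
    a[0, 0] = -p.ka
    a[1, 0] = p.ka
    a[1, 1] = -(p.cl_u / p.v1_u)
    if p.v2_u > 0 and p.q2_u > 0:
        a[1, 1] -= p.q2_u / p.v1_u
        a[1, 2] = p.q2_u / p.v2_u
        a[2, 1] = p.q2_u / p.v1_u
        a[2, 2] = -p.q2_u / p.v2_u
    if p.v3_u > 0 and p.q3_u > 0:
        a[1, 1] -= p.q3_u / p.v1_u
        a[1, 3] = p.q3_u / p.v3_u
        a[3, 1] = p.q3_u / p.v1_u
        a[3, 3] = -p.q3_u / p.v3_u
    return a


class _LinearPropagator:
    """Exact propagation of x' = A x + u (u constant per segment).

    Uses the eigendecomposition of A when it is well conditioned, which lets
    a whole vector of output times be evaluated at once; falls back to the
    matrix exponential of the augmented system otherwise.
    """

    def __init__(self, a: np.ndarray):
        self.a = a
        self._eig = None
        try:
            lam, v = np.linalg.eig(a)
            vinv = np.linalg.inv(v)
            if np.linalg.cond(v) < 1e10:
                self._eig = (lam, v, vinv)
        except np.linalg.LinAlgError:
            pass

    @staticmethod
    def _phi(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
        """(exp(lam*t) - 1)/lam, elementwise, with the lam->0 limit t."""
        lt = np.multiply.outer(t, lam)
        small = np.abs(lt) < 1e-8
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(small, t[:, None] * (1.0 + lt / 2.0),
                           (np.exp(lt) - 1.0) / np.where(lam == 0.0, 1.0, lam)[None, :])
        return out

    def evolve(self, x0: np.ndarray, u: np.ndarray, dts: np.ndarray) -> np.ndarray:
        """State at each elapsed time in ``dts`` (shape (m, n_states))."""
        dts = np.asarray(dts, dtype=float)
        if self._eig is not None:
            lam, v, vinv = self._eig
            z0 = vinv @ x0.astype(complex)
            w = vinv @ u.astype(complex)
            elt = np.exp(np.multiply.outer(dts, lam))
            z = elt * z0[None, :] + self._phi(lam, dts) * w[None, :]
            return np.real(z @ v.T)
        # augmented-matrix fallback: d/dt [x; 1] = [[A, u], [0, 0]] [x; 1]
        aug = np.zeros((_N_STATES + 1, _N_STATES + 1))
        aug[:_N_STATES, :_N_STATES] = self.a
        aug[:_N_STATES, -1] = u
        y0 = np.append(x0, 1.0)
        out = np.empty((len(dts), _N_STATES))
        for i, dt in enumerate(dts):
            out[i] = (expm(aug * dt) @ y0)[:_N_STATES]
        return out


def _input_schedule(p: StructuralParams, regimen: Regimen):
    """Break the timeline into (start, input-vector, bolus-vector) pieces.

    Returns sorted breakpoint times, constant input rate (mg/h per state)
    active from each breakpoint, and instantaneous bolus amounts applied at
    each breakpoint.
    """
    starts: dict[float, dict[str, np.ndarray]] = {}

    def _at(t: float) -> dict[str, np.ndarray]:
        return starts.setdefault(
            float(t), {"rate": np.zeros(_N_STATES), "bolus": np.zeros(_N_STATES)}
        )

    _at(0.0)
    for ev in regimen.events:
        if ev.route is Route.IV_INFUSION:
            rate = ev.amount / ev.duration
            _at(ev.time)["rate"][1] += rate
            _at(ev.time + ev.duration)["rate"][1] -= rate
        else:
            _at(ev.time + p.tlag)["bolus"][0] += ev.amount * p.f_oral
    times = np.array(sorted(starts))
    rates = np.cumsum([starts[t]["rate"] for t in times], axis=0)
    boluses = np.array([starts[t]["bolus"] for t in times])
    return times, rates, boluses


def predict_unbound(
    params: StructuralParams, regimen: Regimen, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Unbound concentration (ng/mL) at each requested time.

    Superposes all dose events exactly: the state is propagated analytically
    through each piecewise-constant-input segment and read out on the
    requested grid.  Times before the first event return zero.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if len(t) and np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if len(t) and t[0] < 0:
        raise ValueError("times must be non-negative")

    prop = _LinearPropagator(_rate_matrix(params))
    seg_starts, seg_rates, seg_boluses = _input_schedule(params, regimen)
    seg_ends = np.append(seg_starts[1:], np.inf)

    conc = np.zeros_like(t)
    x = np.zeros(_N_STATES)
    for start, end, rate, bolus in zip(seg_starts, seg_ends, seg_rates, seg_boluses):
        x = x + bolus
        mask = (t >= start) & (t < end)
        if mask.any():
            states = prop.evolve(x, rate, t[mask] - start)
            conc[mask] = states[:, 1]
        if np.isfinite(end):
            x = prop.evolve(x, rate, np.array([end - start]))[0]
    # amounts are mathematically non-negative; clear eigen-solver round-off
    tiny = 1e-12 * max(1.0, float(np.abs(conc).max(initial=0.0)))
    conc[(conc < 0) & (conc > -tiny)] = 0.0
    return conc * MG_PER_L_TO_NG_PER_ML / params.v1_u


def total_from_unbound(c_unbound: Sequence[float] | np.ndarray, fu: float) -> np.ndarray:
    """Total concentration from unbound via constant binding: C_tot = C_u / fu."""
    if not (0.0 < fu <= 1.0):
        raise ValueError("fu must be in (0, 1]")
    return np.asarray(c_unbound, dtype=float) / fu


def total_cl_from_unbound(cl_u: float, fu: float) -> float:
    """Total clearance CL = CLu * fu (e.g. 8570 L/h * 0.0067 ≈ 57.4 L/h)."""
    if not np.isfinite(cl_u) or cl_u <= 0:
        raise ValueError("cl_u must be finite and > 0")
    if not (0.0 < fu <= 1.0):
        raise ValueError("fu must be in (0, 1]")
    return cl_u * fu


def total_vss(params: StructuralParams, route: Route | str) -> float:
    """Total-scale steady-state volume: (V1u + V2u + V3u) * fu_route."""
    return (params.v1_u + params.v2_u + params.v3_u) * params.fu(route)


def predict_profile(
    params: StructuralParams, regimen: Regimen, times: Sequence[float] | np.ndarray
) -> ConcProfile:
    """Convenience wrapper returning paired unbound and total profiles."""
    route = regimen.route_context
    cu = predict_unbound(params, regimen, times)
    return ConcProfile(
        times=np.asarray(times, dtype=float),
        c_unbound=cu,
        c_total=total_from_unbound(cu, params.fu(route)),
        route_context=route,
    )
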