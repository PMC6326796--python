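"""Deterministic model of inducer-driven reporter expression.

The AND gate's estradiol arm is reduced to a two-variable system: the
hormone--transcription-factor complex equilibrates across the nuclear
boundary by first-order diffusion, and the nuclear complex drives reporter
mRNA production through a Hill function, balanced by first-order
degradation/dilution:

    d es_n / dt = gamma * (es_m - es_n)
    d g    / dt = -delta * g + f(es_n),    f(x) = nu (x/k)^h / (1 + (x/k)^h)

``es_m`` (the medium concentration) is an experimental condition, held
constant over a run.  Concentrations are in nM and time in hours; a linear
scale ``phi`` maps reporter abundance to measured fluorescence (a.u.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GateParameters",
    "GateState",
    "Trajectory",
    "hill_activation",
    "ode_rhs",
    "solve_deterministic",
    "steady_state",
    "predict_dose_response",
]


@dataclass(frozen=True)
class GateParameters:
    """Kinetic constants of the gate, shared by the deterministic and
    stochastic models.

    Parameters
    ----------
    gamma : float
        Nuclear import/export (diffusion) rate of the inducer--TF complex,
        per hour.
    delta : float
        Reporter mRNA degradation/dilution rate, per hour.
    nu : float
        Maximum expression rate, nM per hour.
    k : float
        Half-saturation constant of the activation curve, nM.
    h : float
        Hill coefficient (steepness), dimensionless, >= 0.
    phi : float
        Fluorescence scale: measured a.u. per nM of reporter (deterministic
        context) or per molecule (stochastic context).
    basal : float
        Optional leaky expression rate added to the Hill term, nM per hour.
        The default 0 gives the bare model; measured OFF states sit at
        instrument background instead.
    """

    gamma: float
    delta: float
    nu: float
    k: float
    h: float
    phi: float = 1.0
    basal: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma", "delta", "nu", "k", "phi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.basal < 0:
            raise ValueError("basal must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GateParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class GateState:
    """Instantaneous state: nuclear complex and reporter concentrations (nM)
    at time ``t`` (hours)."""

    es_n: float = 0.0
    g: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.es_n < 0 or self.g < 0 or self.t < 0:
            raise ValueError("es_n, g and t must be non-negative")


@dataclass
class Trajectory:
    """Time course of the deterministic system on a fixed grid."""

    times: np.ndarray
    es_n: np.ndarray
    g: np.ndarray
    params: GateParameters | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.es_n = np.asarray(self.es_n, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if not (len(self.times) == len(self.es_n) == len(self.g)):
            raise ValueError("times, es_n and g must be aligned")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def fluorescence(self) -> np.ndarray:
        phi = self.params.phi if self.params is not None else 1.0
        return phi * self.g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "es_n_nM": self.es_n,
                "g_nM": self.g,
                "fluorescence_au": self.fluorescence,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def hill_activation(es_n, params: GateParameters):
    """Hill activation rate f(es_n) = nu (es_n/k)^h / (1 + (es_n/k)^h).

    Accepts scalars or arrays.  f(0) = 0 for h > 0; the h = 0 case is the
    pointwise limit nu/2 everywhere (the formula is then constant).  Does
    not include the optional basal rate.
    """
    x = np.asarray(es_n, dtype=float)
    if np.any(x < 0):
        raise ValueError("es_n must be non-negative")
    if params.h == 0:
        out = np.full_like(x, params.nu / 2.0)
    else:
        r = np.power(x / params.k, params.h)
        out = params.nu * r / (1.0 + r)
    return out if out.ndim else float(out)


def ode_rhs(state: GateState, es_m: float, params: GateParameters) -> tuple[float, float]:
    """Time derivatives (d es_n/dt, d g/dt) at the given state."""
    if es_m < 0:
        raise ValueError("es_m must be non-negative")
    d_es = params.gamma * (es_m - state.es_n)
    d_g = -params.delta * state.g + hill_activation(state.es_n, params) + params.basal
    return d_es, d_g


def solve_deterministic(
    params: GateParameters,
    es_m: float,
    t_grid: Sequence[float],
    init: GateState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the two-variable system on ``t_grid`` at constant ``es_m``.

    Uses an adaptive, stiffness-switching integrator (LSODA).  The default
    initial condition is the uninduced state (0, 0) at the first grid time:
    cells are pre-grown without inducer and the hormone is added at t = 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if init is None:
        init = GateState(0.0, 0.0, float(t_grid[0]))
    if not math.isclose(t_grid[0], init.t, abs_tol=1e-12):
        raise ValueError("t_grid must start at init.t")
    if es_m < 0:
        raise ValueError("es_m must be non-negative")

    def rhs(t, y):
        es_n, g = y
        es_n = max(es_n, 0.0)
        return (
            params.gamma * (es_m - es_n),
            -params.delta * g + hill_activation(es_n, params) + params.basal,
        )

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [init.es_n, init.g],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    g = np.clip(sol.y[1], 0.0, None)  # guard tiny negative round-off
    return Trajectory(times=sol.t, es_n=np.clip(sol.y[0], 0.0, None), g=g, params=params)


def steady_state(params: GateParameters, es_m: float) -> GateState:
    """Fixed point of the system: es_n* = es_m, g* = (f(es_m) + basal)/delta."""
    if es_m < 0:
        raise ValueError("es_m must be non-negative")
    g = (hill_activation(es_m, params) + params.basal) / params.delta
    return GateState(es_n=float(es_m), g=float(g), t=0.0)


def predict_dose_response(
    params: GateParameters,
    doses: Sequence[float],
    t_end: float,
    init: GateState | None = None,
) -> np.ndarray:
    """Model mean fluorescence phi * g(t_end) for each medium dose.

    With the default zero initial state the prediction is non-decreasing in
    dose.  ``t_end`` much larger than 1/gamma and 1/delta approaches the
    stationary value phi * f(dose)/delta.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    out = np.empty(len(doses))
    for i, d in enumerate(doses):
        traj = solve_deterministic(params, float(d), np.array([0.0, t_end]), init=init)
        out[i] = params.phi * traj.g[-1]
    return out
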