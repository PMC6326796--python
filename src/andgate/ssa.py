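"""Exact stochastic simulation of the gate at yeast-nucleus copy numbers.

The reaction network has four channels acting on integer molecule counts
(ES_n = nuclear inducer--TF complex, G = reporter mRNA):

    influx       ES_m -> ES_n     rate gamma * N_m          (bath, constant)
    efflux       ES_n -> ES_m     rate gamma per molecule
    expression   0    -> G        rate f(es_n) in nM/h, volume-converted
    degradation  G    -> 0        rate delta per molecule

The medium species is an infinite reservoir at fixed concentration; its
count N_m is the concentration converted at the nuclear volume (~3 um^3
for yeast).  The Hill function keeps its deterministic meaning: it is
evaluated on the concentration scale after count -> nM conversion, and the
resulting rate (nM/h) is converted back to events/h via the volume factor.

Trajectories are sampled with the direct-method Gillespie algorithm (exact
waiting times, no tau-leaping), compiled with numba.  Per-cell seeds are
derived from the master seed with ``numpy.random.SeedSequence`` so ensembles
are bit-reproducible and order-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .model import GateParameters

__all__ = [
    "AVOGADRO",
    "StochasticSettings",
    "CountState",
    "CountTrajectory",
    "concentration_to_count",
    "count_to_concentration",
    "propensities",
    "ssa_trajectory",
    "simulate_population",
]

AVOGADRO = 6.02214076e23

# molecules per nM per um^3: 1e-9 mol/L * N_A * 1e-15 L/um^3
_COUNT_PER_NM_UM3 = 1e-9 * AVOGADRO * 1e-15


@dataclass(frozen=True)
class StochasticSettings:
    """Ensemble simulation settings.

    volume is the nuclear volume in cubic micrometres (yeast ~3).
    """

    volume: float = 3.0
    t_end: float = 20.0
    n_cells: int = 1
    seed: int = 0
    record_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class CountState:
    """Integer molecule counts at time t (hours)."""

    es_n_count: int = 0
    g_count: int = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.es_n_count < 0 or self.g_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CountTrajectory:
    times: np.ndarray
    es_n_count: np.ndarray
    g_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "es_n_count": self.es_n_count, "g_count": self.g_count}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def concentration_to_count(conc: float, volume: float) -> float:
    """Expected molecule count of a concentration (nM) in a volume (um^3)."""
    if np.any(np.asarray(conc) < 0) or volume <= 0:
        raise ValueError("conc must be >= 0 and volume > 0")
    return conc * _COUNT_PER_NM_UM3 * volume


def count_to_concentration(count: float, volume: float) -> float:
    """Concentration (nM) of a molecule count in a volume (um^3)."""
    if np.any(np.asarray(count) < 0) or volume <= 0:
        raise ValueError("count must be >= 0 and volume > 0")
    return count / (_COUNT_PER_NM_UM3 * volume)


def propensities(
    state: CountState,
    es_m: float,
    params: GateParameters,
    settings: StochasticSettings,
) -> np.ndarray:
    """Propensity (events/hour) of each channel in the order
    (influx, efflux, expression, degradation)."""
    if es_m < 0:
        raise ValueError("es_m must be non-negative")
    factor = _COUNT_PER_NM_UM3 * settings.volume
    influx = params.gamma * concentration_to_count(es_m, settings.volume)
    efflux = params.gamma * state.es_n_count
    conc = count_to_concentration(state.es_n_count, settings.volume)
    if params.h == 0:
        f = params.nu / 2.0
    elif conc > 0:
        r = (conc / params.k) ** params.h
        f = params.nu * r / (1.0 + r)
    else:
        f = 0.0
    expression = (f + params.basal) * factor
    degradation = params.delta * state.g_count
    return np.array([influx, efflux, expression, degradation])


@njit(cache=False)
def _ssa_record(
    seed, t_end, bath, gamma, delta, nu, k, h, basal, factor, es0, g0, rec_times
):  # pragma: no cover - exercised through wrappers
    np.random.seed(seed)
    t = 0.0
    n_es = es0
    n_g = g0
    influx = gamma * bath
    n_rec = rec_times.size
    es_out = np.empty(n_rec, np.int64)
    g_out = np.empty(n_rec, np.int64)
    i_rec = 0
    while True:
        a1 = influx
        a2 = gamma * n_es
        conc = n_es / factor
        if h == 0.0:
            f = 0.5 * nu
        elif conc > 0.0:
            r = (conc / k) ** h
            f = nu * r / (1.0 + r)
        else:
            f = 0.0
        a3 = (f + basal) * factor
        a4 = delta * n_g
        a0 = a1 + a2 + a3 + a4
        if a0 <= 0.0:
            t_next = t_end + 1.0  # frozen: jump past the horizon
        else:
            t_next = t + np.random.exponential(1.0 / a0)
        while i_rec < n_rec and rec_times[i_rec] < t_next:
            es_out[i_rec] = n_es
            g_out[i_rec] = n_g
            i_rec += 1
        if t_next > t_end:
            break
        t = t_next
        u = np.random.random() * a0
        if u < a1:
            n_es += 1
        elif u < a1 + a2:
            n_es -= 1
        elif u < a1 + a2 + a3:
            n_g += 1
        else:
            n_g -= 1
    return es_out, g_out


@njit(cache=False)
def _ssa_population(
    seeds, t_end, bath, gamma, delta, nu, k, h, basal, factor, es0, g0
):  # pragma: no cover - exercised through wrappers
    n = seeds.size
    es_fin = np.empty(n, np.int64)
    g_fin = np.empty(n, np.int64)
    for c in range(n):
        np.random.seed(seeds[c])
        t = 0.0
        n_es = es0
        n_g = g0
        influx = gamma * bath
        while True:
            a1 = influx
            a2 = gamma * n_es
            conc = n_es / factor
            if h == 0.0:
                f = 0.5 * nu
            elif conc > 0.0:
                r = (conc / k) ** h
                f = nu * r / (1.0 + r)
            else:
                f = 0.0
            a3 = (f + basal) * factor
            a4 = delta * n_g
            a0 = a1 + a2 + a3 + a4
            if a0 <= 0.0:
                break
            t += np.random.exponential(1.0 / a0)
            if t > t_end:
                break
            u = np.random.random() * a0
            if u < a1:
                n_es += 1
            elif u < a1 + a2:
                n_es -= 1
            elif u < a1 + a2 + a3:
                n_g += 1
            else:
                n_g -= 1
        es_fin[c] = n_es
        g_fin[c] = n_g
    return es_fin, g_fin


def cell_seeds(master_seed: int, n_cells: int) -> np.ndarray:
    """Deterministic per-cell seeds: hash of (master_seed, cell_index)."""
    return np.array(
        [
            np.random.SeedSequence((master_seed, i)).generate_state(1, np.uint32)[0]
            for i in range(n_cells)
        ],
        dtype=np.int64,
    )


def ssa_trajectory(
    es_m: float,
    params: GateParameters,
    settings: StochasticSettings,
    seed: int,
    init: CountState | None = None,
) -> CountTrajectory:
    """One exact SSA trajectory recorded on ``settings.record_grid``
    (default: 201 evenly spaced points on [0, t_end]).

    A state with zero total propensity is frozen: time is advanced to t_end
    and the remaining grid points repeat the frozen state.
    """
    if es_m < 0:
        raise ValueError("es_m must be non-negative")
    init = init or CountState()
    grid = settings.record_grid
    if grid is None:
        grid = np.linspace(0.0, settings.t_end, 201)
    grid = np.asarray(grid, dtype=float)
    factor = _COUNT_PER_NM_UM3 * settings.volume
    bath = concentration_to_count(es_m, settings.volume)
    seed32 = int(np.random.SeedSequence((int(seed), 0)).generate_state(1, np.uint32)[0])
    es, g = _ssa_record(
        seed32,
        float(settings.t_end),
        bath,
        params.gamma,
        params.delta,
        params.nu,
        params.k,
        params.h,
        params.basal,
        factor,
        init.es_n_count,
        init.g_count,
        grid,
    )
    return CountTrajectory(times=grid, es_n_count=es, g_count=g)


def simulate_population(
    es_m: float,
    params: GateParameters,
    settings: StochasticSettings,
    init: CountState | None = None,
    noise_log_sd: float = 0.0,
    autofluorescence: float = 0.0,
    return_counts: bool = False,
):
    """Endpoint fluorescence sample over an ensemble of independent cells.

    Each cell runs an exact SSA to ``settings.t_end``; its fluorescence is
    phi * g_count, optionally degraded by multiplicative log-normal
    measurement noise (median 1, ``noise_log_sd`` on the log scale) and an
    additive autofluorescence offset.  Defaults reproduce the bare model.
    With ``return_counts`` the raw (es_n, g) count arrays are returned too.
    """
    if es_m < 0:
        raise ValueError("es_m must be non-negative")
    if noise_log_sd < 0:
        raise ValueError("noise_log_sd must be >= 0")
    init = init or CountState()
    seeds = cell_seeds(settings.seed, settings.n_cells)
    factor = _COUNT_PER_NM_UM3 * settings.volume
    bath = concentration_to_count(es_m, settings.volume)
    es, g = _ssa_population(
        seeds,
        float(settings.t_end),
        bath,
        params.gamma,
        params.delta,
        params.nu,
        params.k,
        params.h,
        params.basal,
        factor,
        init.es_n_count,
        init.g_count,
    )
    fl = params.phi * g.astype(float)
    if noise_log_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((settings.seed, 1)))
        fl = fl * rng.lognormal(0.0, noise_log_sd, size=fl.size)
    fl = fl + autofluorescence
    if return_counts:
        return fl, es, g
    return fl


def sample_to_csv(path, sample: np.ndarray, *, dose: float, t_end: float, seed: int) -> None:
    """Write an ensemble fluorescence sample as single-column CSV with a
    metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# dose_nM: {dose}\n# t_end_h: {t_end}\n# seed: {seed}\n")
        fh.write(f"# n_cells: {len(sample)}\n")
        fh.write("fluorescence_au\n")
        for v in sample:
            fh.write(f"{v}\n")
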