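"""In-silico flow-cytometry experiments for the AND gate.

Generates complete per-cell event tables with the statistical structure the
analysis pipeline assumes, so every stage (gating, summaries, fitting, ROC)
is exercisable without instrument data:

* singlet fluorescence = stochastic-model endpoint (phi * mRNA count) with
  multiplicative log-normal measurement noise, a dose-dependent
  non-responder fraction zeta(dose) plus a dose-independent one, and
  additive log-normal autofluorescence;
* scatter channels: a log-normal singlet cloud, debris at low scatter and
  doublets at ~2x FSC-A with a reduced FSC-H/FSC-A ratio, appended at
  configurable fractions;
* a hidden ``label_truth`` column (singlet/debris/doublet) retained for
  evaluation and ignored by the analysis operations.

All randomness derives from a single master seed; regenerating with the
same config is bit-identical.  Default parameters are illustrative: they
are chosen to reproduce the qualitative regime of the characterised gate
(half-maximum in the low-nM range, saturation by ~20-35 nM, roughly
100-fold induction, bimodal histograms at sub-k doses), not measured
values.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cytometry import EventTable, default_gate_config, apply_gates
from .detrimental import ZetaParameters, zeta, apply_detrimental
from .fit import DoseResponseSeries
from .model import GateParameters, solve_deterministic
from .ssa import StochasticSettings, simulate_population, concentration_to_count

__all__ = [
    "SyntheticConfig",
    "generate_condition",
    "generate_dose_series",
    "generate_timecourse",
]

DEFAULT_DOSES = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 100.0)


def _default_gate() -> GateParameters:
    return GateParameters(gamma=0.3, delta=0.3, nu=12.0, k=5.0, h=2.0, phi=170.0)


def _default_zeta() -> ZetaParameters:
    return ZetaParameters(zeta_max=0.10, k_zeta=40.0, h_zeta=2.0)


@dataclass
class SyntheticConfig:
    """Full generative description of one in-silico experiment."""

    gate: GateParameters = field(default_factory=_default_gate)
    zeta: ZetaParameters = field(default_factory=_default_zeta)
    volume: float = 3.0
    t_end: float = 20.0
    doses: tuple = DEFAULT_DOSES
    n_cells_per_condition: int = 5000
    autofluorescence_log_mean: float = float(np.log(100.0))
    autofluorescence_log_sd: float = 0.35
    noise_log_sd: float = 0.2
    nonresponder_extra: float = 0.02
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nonresponder_extra", "debris_fraction", "doublet_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells_per_condition < 1:
            raise ValueError("n_cells_per_condition must be >= 1")
        if np.any(np.asarray(self.doses) < 0):
            raise ValueError("doses must be non-negative")

    # -- config (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["gate"] = self.gate.to_dict()
        d["zeta"] = asdict(self.zeta)
        d["doses"] = list(self.doses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        try:
            d["gate"] = GateParameters.from_dict(d["gate"]) if "gate" in d else _default_gate()
            if "zeta" in d:
                d["zeta"] = ZetaParameters(**{k: float(v) for k, v in d["zeta"].items()})
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc
        if "doses" in d:
            d["doses"] = tuple(float(x) for x in d["doses"])
        return cls(**d)

    # -- derived quantities -------------------------------------------------------
    @property
    def autofluorescence_mean(self) -> float:
        return float(
            np.exp(self.autofluorescence_log_mean + self.autofluorescence_log_sd**2 / 2)
        )

    def nonresponder_fraction(self, dose: float) -> float:
        return min(zeta(dose, self.zeta) + self.nonresponder_extra, 1.0)

    def expected_mean_fluorescence(self, dose: float) -> float:
        """Model-predicted population mean at ``dose``: deterministic
        reporter level at t_end, scaled to counts and fluorescence, with the
        non-responder fraction and noise/autofluorescence means applied."""
        traj = solve_deterministic(self.gate, float(dose), np.array([0.0, self.t_end]))
        count = concentration_to_count(traj.g[-1], self.volume)
        signal = self.gate.phi * count * np.exp(self.noise_log_sd**2 / 2)
        return float(
            (1.0 - self.nonresponder_fraction(dose)) * signal + self.autofluorescence_mean
        )

    def expected_fold_activation(self, on_dose: float = 100.0) -> float:
        """Configured fold-activation target: predicted ON mean over the
        autofluorescence-only OFF mean."""
        return self.expected_mean_fluorescence(on_dose) / self.autofluorescence_mean


def _dose_entropy(dose: float, t: float) -> tuple[int, int]:
    """Stable integer entropy from the IEEE bits of (dose, time)."""
    return (
        struct.unpack("<Q", struct.pack("<d", float(dose)))[0] & 0x7FFFFFFF,
        struct.unpack("<Q", struct.pack("<d", float(t)))[0] & 0x7FFFFFFF,
    )


# scatter-cloud shapes (log-normal medians / log-sds; H/A ratio gaussians)
_SINGLET_FSC = (np.log(1e5), 0.15)
_SINGLET_SSC = (np.log(5e4), 0.20)
_SINGLET_RATIO = (0.95, 0.03)
_DEBRIS_FSC = (np.log(5e3), 0.5)
_DEBRIS_SSC = (np.log(3e3), 0.5)
_DEBRIS_RATIO = (0.90, 0.10)
_DOUBLET_RATIO = (0.55, 0.03)


def generate_condition(
    dose: float,
    config: SyntheticConfig,
    t_end: float | None = None,
    replicate: int = 0,
) -> EventTable:
    """One flow-cytometry sample at a fixed inducer dose.

    Rows are singlets (``n_cells_per_condition``) plus appended debris and
    doublet contaminants at their configured fractions, shuffled; the
    ``label_truth`` column records the origin of every event.
    """
    t_end = config.t_end if t_end is None else float(t_end)
    n = config.n_cells_per_condition
    de, te = _dose_entropy(dose, t_end)
    cond_seed = int(
        np.random.SeedSequence((config.master_seed, de, te, replicate)).generate_state(
            1, np.uint32
        )[0]
    )
    settings = StochasticSettings(
        volume=config.volume, t_end=max(t_end, 1e-9), n_cells=n, seed=cond_seed
    )
    if t_end <= 0:
        signal = np.zeros(n)
    else:
        signal = simulate_population(
            float(dose), config.gate, settings, noise_log_sd=config.noise_log_sd
        )
    frac = config.nonresponder_fraction(dose)
    signal = apply_detrimental(signal, frac, seed=cond_seed + 1)

    rng = np.random.default_rng(np.random.SeedSequence((cond_seed, 2)))
    af = rng.lognormal(config.autofluorescence_log_mean, config.autofluorescence_log_sd, n)
    fl_singlet = signal + af

    def scatter(n_rows, fsc_spec, ssc_spec, ratio_spec, fsc_scale=1.0):
        fsc = fsc_scale * rng.lognormal(*fsc_spec, n_rows)
        ssc = fsc_scale * rng.lognormal(*ssc_spec, n_rows)
        ratio = rng.normal(*ratio_spec, n_rows)
        return fsc, ssc, ratio * fsc

    fsc_s, ssc_s, fsch_s = scatter(n, _SINGLET_FSC, _SINGLET_SSC, _SINGLET_RATIO)
    parts = [
        pd.DataFrame(
            {
                "fsc_a": fsc_s,
                "ssc_a": ssc_s,
                "fsc_h": fsch_s,
                "fl1": fl_singlet,
                "label_truth": "singlet",
            }
        )
    ]
    n_debris = int(np.floor(config.debris_fraction * n + 0.5))
    if n_debris:
        fsc, ssc, fsch = scatter(n_debris, _DEBRIS_FSC, _DEBRIS_SSC, _DEBRIS_RATIO)
        fl = rng.lognormal(config.autofluorescence_log_mean - 1.0,
                           config.autofluorescence_log_sd, n_debris)
        parts.append(
            pd.DataFrame(
                {"fsc_a": fsc, "ssc_a": ssc, "fsc_h": fsch, "fl1": fl,
                 "label_truth": "debris"}
            )
        )
    n_doublet = int(np.floor(config.doublet_fraction * n + 0.5))
    if n_doublet:
        fsc, ssc, fsch = scatter(
            n_doublet, _SINGLET_FSC, _SINGLET_SSC, _DOUBLET_RATIO, fsc_scale=2.0
        )
        # a doublet carries roughly the summed fluorescence of two cells
        idx = rng.integers(0, n, size=(n_doublet, 2))
        fl = fl_singlet[idx].sum(axis=1)
        parts.append(
            pd.DataFrame(
                {"fsc_a": fsc, "ssc_a": ssc, "fsc_h": fsch, "fl1": fl,
                 "label_truth": "doublet"}
            )
        )
    df = pd.concat(parts, ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    meta = {
        "dose_nM": float(dose),
        "time_h": t_end,
        "medium": "SG+ES" if dose > 0 else "SG",
        "replicate": replicate,
        "seed": cond_seed,
        "instrument": "synthetic flow-cytometry generator",
    }
    return EventTable(df, meta)


def generate_dose_series(
    config: SyntheticConfig,
    gate_config=None,
) -> tuple[dict, DoseResponseSeries]:
    """Per-dose event tables plus the gated dose--response summary.

    The summary is computed through the cytometry module (constant gates,
    then the FL1 population mean), so the fit consumes exactly what the
    analysis pipeline produces.
    """
    if len(config.doses) < 2:
        raise ValueError("need at least 2 doses")
    gate_config = gate_config or default_gate_config()
    tables = {}
    rows = []
    for dose in config.doses:
        table = generate_condition(dose, config)
        tables[dose] = table
        gated, _ = apply_gates(table, gate_config)
        fl = gated.fl1
        rows.append((dose, float(np.mean(fl)), float(np.std(fl, ddof=1)), len(fl)))
    arr = np.array(rows)
    series = DoseResponseSeries(
        dose=arr[:, 0], mean=arr[:, 1], sd=arr[:, 2], n=arr[:, 3].astype(int),
        reporter_label="synthetic",
    )
    return tables, series


def generate_timecourse(
    dose: float,
    config: SyntheticConfig,
    sample_times,
) -> dict:
    """Destructive hourly-style sampling: an independent event table per
    time point, each simulated to its own horizon from the same seed base."""
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(sample_times) <= 0):
        raise ValueError("sample_times must be increasing")
    return {float(t): generate_condition(dose, config, t_end=float(t)) for t in sample_times}


def write_dataset(outdir, config: SyntheticConfig, gate_config=None) -> dict:
    """Generate a dose series, write every table plus the summary and a
    manifest (config hash, seeds, per-file checksums) under ``outdir``."""
    from .cytometry import write_events

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, series = generate_dose_series(config, gate_config)
    files = {}
    for dose, table in tables.items():
        name = f"events_dose_{dose:g}nM.csv"
        write_events(outdir / name, table)
        files[name] = _sha256(outdir / name)
    series.to_csv(outdir / "dose_response.csv")
    files["dose_response.csv"] = _sha256(outdir / "dose_response.csv")
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.master_seed,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
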