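"""Event-level flow-cytometry handling.

Implements the minimal two-gate analysis used for the gate characterisation:
one constant scatter box (FSC-A/SSC-A) to exclude debris and one constant
FSC-H/FSC-A ratio band to exclude doublets, followed by population
summaries (mean fluorescence, fold activation, log-binned histograms) on
the single fluorescence channel (FL1).  Also provides the single-cell trace
utilities used for microfluidic time-lapse data: per-frame background
correction with a per-cell reference frame, and moving-average smoothing.

Event tables are stored as pandas DataFrames with columns ``fsc_a``,
``ssc_a``, ``fsc_h``, ``fl1`` (arbitrary units) plus optional extra columns
(e.g. a ``label_truth`` column in synthetic data, ignored by the analysis
operations).  The CSV dialect is comma-separated with a header row and
``#``-prefixed ``key: value`` metadata lines before it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "EventTable",
    "GateConfig",
    "GateReport",
    "CellTrace",
    "Histogram",
    "read_events",
    "write_events",
    "apply_gates",
    "population_mean",
    "fold_activation",
    "fluorescence_histogram",
    "count_modes",
    "mode_locations",
    "is_bimodal",
    "smooth_trace",
    "trace_background_correct",
    "default_gate_config",
]

CHANNELS = ("fsc_a", "ssc_a", "fsc_h", "fl1")


@dataclass
class EventTable:
    """Per-cell measurement records plus condition metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(
                f"missing channels {missing}; available: {list(self.data.columns)}"
            )
        vals = self.data[list(CHANNELS)].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("channel values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fl1(self) -> np.ndarray:
        return self.data["fl1"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GateConfig:
    """Two constant gates: a scatter box (debris) and an FSC-H/FSC-A ratio
    band (doublets)."""

    scatter_box: tuple = (-np.inf, np.inf, -np.inf, np.inf)  # fsc lo, hi, ssc lo, hi
    singlet_band: tuple = (-np.inf, np.inf)  # fsc_h/fsc_a lo, hi

    def __post_init__(self) -> None:
        f_lo, f_hi, s_lo, s_hi = self.scatter_box
        r_lo, r_hi = self.singlet_band
        if not (f_lo <= f_hi and s_lo <= s_hi and r_lo <= r_hi):
            raise ValueError("gate bounds must be ordered")


def default_gate_config() -> GateConfig:
    """Constant gates matched to the synthetic generator's scatter
    populations (intact singlets around FSC-A 1e5, SSC-A 5e4, H/A ~ 0.95)."""
    return GateConfig(scatter_box=(3e4, 4e5, 1e4, 3e5), singlet_band=(0.85, 1.05))


@dataclass
class GateReport:
    n_input: int
    n_removed_debris: int
    n_removed_doublets: int
    n_kept: int
    warning: str = ""

    def to_text(self) -> str:
        out = [
            f"n_input = {self.n_input}",
            f"n_removed_debris = {self.n_removed_debris}",
            f"n_removed_doublets = {self.n_removed_doublets}",
            f"n_kept = {self.n_kept}",
        ]
        if self.warning:
            out.append(f"warning = {self.warning}")
        return "\n".join(out) + "\n"


@dataclass
class CellTrace:
    """Fluorescence time course of one immobilised cell."""

    times: np.ndarray
    fluorescence: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.times) != len(self.fluorescence):
            raise ValueError("times and fluorescence must be aligned")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def write_events(path, table: EventTable) -> None:
    with open(path, "w") as fh:
        for key, val in table.metadata.items():
            fh.write(f"# {key}: {val}\n")
        table.data.to_csv(fh, index=False)


def _parse_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def read_events(path, format: str = "csv", channel_map: dict | None = None) -> EventTable:
    """Read an event table from CSV (native dialect) or an FCS 3.0 file.

    ``channel_map`` renames source columns/detector names to the canonical
    channels, e.g. ``{"FSC-A": "fsc_a", ...}``.  FCS ingestion requires the
    optional ``fcsparser`` dependency.
    """
    path = Path(path)
    if format == "fcs3":
        try:
            import fcsparser
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "FCS ingestion requires the optional 'fcsparser' package "
                "(pip install andgate[fcs])"
            ) from exc
        meta, df = fcsparser.parse(str(path))
        df = df.rename(columns=channel_map or {})
        df.columns = [str(c).lower() for c in df.columns]
        return EventTable(df, {"source": str(path)})
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    metadata: dict = {}
    lines = path.read_text().splitlines(keepends=True)
    if not lines:
        raise ValueError(f"{path}: empty file")
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            body_start += 1
            stripped = ln.lstrip("#").strip()
            if ":" in stripped:
                key, val = stripped.split(":", 1)
                metadata[key.strip()] = _parse_meta(val.strip())
        else:
            break
    body = "".join(lines[body_start:])
    if not body.strip():
        raise ValueError(f"{path}: no event rows")
    df = pd.read_csv(io.StringIO(body))
    if channel_map:
        df = df.rename(columns=channel_map)
    df.columns = [str(c).lower() for c in df.columns]
    return EventTable(df, metadata)


def apply_gates(events: EventTable, config: GateConfig) -> tuple[EventTable, GateReport]:
    """Keep events inside the scatter box AND the singlet ratio band.

    The debris (scatter box) gate is accounted first; the kept set is the
    intersection, so gate order does not change it.  Gates are constant:
    the same config is meant to be applied to every condition of an
    experiment.
    """
    df = events.data
    fsc, ssc, fsch = (df[c].to_numpy(dtype=float) for c in ("fsc_a", "ssc_a", "fsc_h"))
    f_lo, f_hi, s_lo, s_hi = config.scatter_box
    in_box = (fsc >= f_lo) & (fsc <= f_hi) & (ssc >= s_lo) & (ssc <= s_hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc != 0, fsch / fsc, np.inf)
    r_lo, r_hi = config.singlet_band
    in_band = (ratio >= r_lo) & (ratio <= r_hi)
    kept = in_box & in_band
    n_debris = int(np.sum(~in_box))
    n_doublet = int(np.sum(in_box & ~in_band))
    report = GateReport(
        n_input=len(df),
        n_removed_debris=n_debris,
        n_removed_doublets=n_doublet,
        n_kept=int(kept.sum()),
        warning="no events survived gating" if kept.sum() == 0 else "",
    )
    gated = EventTable(df.loc[kept].reset_index(drop=True), dict(events.metadata))
    return gated, report


def population_mean(events: EventTable) -> float:
    """Arithmetic mean of the FL1 channel (the fold-activation statistic is
    a ratio of these population means)."""
    if len(events) == 0:
        raise ValueError("cannot take the mean of an empty event table")
    return float(np.mean(events.fl1))


def fold_activation(on: EventTable, off: EventTable) -> float:
    """Ratio of ON to OFF population mean fluorescence."""
    off_mean = population_mean(off)
    if off_mean <= 0:
        raise ValueError(
            "OFF population mean is not positive; configure a background "
            "offset so uninduced cells sit at instrument background"
        )
    return population_mean(on) / off_mean


@dataclass
class Histogram:
    """Density-normalised log-binned histogram with an explicit first bin
    for non-positive values (given the same log width as the first positive
    bin so that sum(density * width) == 1)."""

    edges: np.ndarray  # edges of the positive bins, length n_bins + 1
    density: np.ndarray  # length n_bins
    zero_mass: float
    zero_bin_width: float
    n_events: int = 0

    @property
    def mass(self) -> np.ndarray:
        return self.density * np.diff(self.edges)

    def total_mass(self) -> float:
        return float(self.zero_mass + np.sum(self.mass))


def fluorescence_histogram(
    events: EventTable | np.ndarray,
    n_bins: int = 48,
    fl_range: tuple | None = None,
) -> Histogram:
    """Log-spaced FL1 histogram normalised to unit total mass.

    Values <= 0 (possible after background correction) are collected in the
    explicit zero bin.  ``fl_range`` fixes the positive bin range (lo, hi);
    by default it spans the positive data.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    fl = events.fl1 if isinstance(events, EventTable) else np.asarray(events, dtype=float)
    if fl.size == 0:
        raise ValueError("empty sample")
    pos = fl[fl > 0]
    if fl_range is None:
        if pos.size == 0:
            lo, hi = 1.0, 10.0
        else:
            lo, hi = float(np.min(pos)), float(np.max(pos)) * (1 + 1e-9)
            if lo >= hi:
                lo, hi = lo / 2, lo * 2
    else:
        lo, hi = fl_range
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(pos, lo, np.nextafter(hi, lo)), bins=edges)
    n_total = fl.size
    zero_mass = float((fl <= 0).sum()) / n_total
    widths = np.diff(edges)
    density = counts / n_total / widths
    return Histogram(edges=edges, density=density, zero_mass=zero_mass,
                     zero_bin_width=float(widths[0]), n_events=int(n_total))


def mode_locations(
    hist: Histogram, smooth_window: int = 3, min_mass: float = 0.02
) -> np.ndarray:
    """Fluorescence locations of the modes of a histogram.

    The zero bin is prepended to the per-bin mass vector, the vector is
    smoothed with a centred moving average (shrinking at the edges), and
    local maxima whose smoothed bin carries at least ``min_mass`` of the
    distribution are reported.  The zero bin is located at 0; positive bins
    at their geometric centres.
    """
    mass = np.concatenate([[hist.zero_mass], hist.mass])
    if smooth_window > 1:
        w2 = smooth_window // 2
        mass = np.array(
            [mass[max(0, i - w2): i + w2 + 1].mean() for i in range(len(mass))]
        )
    centers = np.concatenate([[0.0], np.sqrt(hist.edges[:-1] * hist.edges[1:])])
    locs = []
    for i in range(len(mass)):
        left = mass[i - 1] if i > 0 else -np.inf
        right = mass[i + 1] if i < len(mass) - 1 else -np.inf
        if mass[i] >= left and mass[i] > right and mass[i] >= min_mass:
            if i > 0 and mass[i] == left:
                continue  # plateau: keep only its first bin
            locs.append(centers[i])
    return np.asarray(locs)


def count_modes(hist: Histogram, smooth_window: int = 3, min_mass: float = 0.02) -> int:
    """Number of modes of a histogram (see :func:`mode_locations`)."""
    return len(mode_locations(hist, smooth_window, min_mass))


def is_bimodal(
    hist: Histogram,
    smooth_window: int = 1,
    z: float = 4.0,
    min_peak_events: int = 10,
) -> bool:
    """Whether a (log-binned) fluorescence histogram has a separated
    OFF-like mode below its main (induced) mode.

    Operational definition: on the smoothed per-bin mass vector (zero bin
    prepended), locate the global maximum; a lower bin is a second mode if
    it rises above the valley separating it from the main peak by at least
    ``z`` combined Poisson standard errors and carries at least
    ``min_peak_events`` events.  The significance requirement keeps
    sampling wiggles on the flank of the main peak from counting as modes.

    Use coarse binning (about 10 bins per decade, e.g. ``n_bins=24`` over
    two and a half decades) and no smoothing: a moving average fills in
    exactly the dip this test looks for.
    """
    mass = np.concatenate([[hist.zero_mass], hist.mass])
    if smooth_window > 1:
        w2 = smooth_window // 2
        mass = np.array(
            [mass[max(0, i - w2): i + w2 + 1].mean() for i in range(len(mass))]
        )
    i_main = int(np.argmax(mass))
    if i_main == 0:
        return False
    n = max(hist.n_events, 1)
    valley = np.minimum.accumulate(mass[i_main::-1])[::-1]  # min(mass[j..i_main])
    for j in range(i_main - 1):
        peak_c = mass[j] * n
        valley_c = valley[j + 1] * n
        if peak_c < min_peak_events:
            continue
        if peak_c - valley_c >= z * np.sqrt(peak_c + valley_c):
            return True
    return False


def smooth_trace(trace: CellTrace, window: int = 3) -> CellTrace:
    """Centred moving average; edge windows shrink so length is preserved."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(trace.times):
        raise ValueError("window longer than trace")
    w2 = window // 2
    x = trace.fluorescence
    out = np.array([x[max(0, i - w2): i + w2 + 1].mean() for i in range(len(x))])
    return CellTrace(trace.times, out, trace.cell_id)


def trace_background_correct(
    trace: CellTrace,
    frame_background: np.ndarray,
    reference_time: float,
) -> CellTrace:
    """Subtract each frame's background, then the cell's own corrected value
    at ``reference_time`` (so the trace is 0 there).

    If the reference time is not on the trace grid the nearest frame is
    used, with a warning.
    """
    bg = np.asarray(frame_background, dtype=float)
    if len(bg) != len(trace.times):
        raise ValueError("frame_background must align with trace times")
    corrected = trace.fluorescence - bg
    hits = np.flatnonzero(np.isclose(trace.times, reference_time))
    if hits.size:
        idx = int(hits[0])
    else:
        idx = int(np.argmin(np.abs(trace.times - reference_time)))
        warnings.warn(
            f"reference_time {reference_time} not on trace grid; using "
            f"nearest frame t={trace.times[idx]}",
            stacklevel=2,
        )
    corrected = corrected - corrected[idx]
    return CellTrace(trace.times, corrected, trace.cell_id)
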