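"""Stationary dose--response fitting.

At stationarity the model mean fluorescence is a four-parameter Hill curve

    F(d) = background + amplitude * (d/k)^h / (1 + (d/k)^h)

where the amplitude is the composite phi * nu / delta (the three factors
enter the stationary mean only through their product, so a single scale is
the identifiable parameterisation) and the background absorbs the
autofluorescence of uninduced cells.  The fit minimises the sum of squared
residuals with a box-constrained quasi-Newton method (L-BFGS-B, analytic
gradient); an optional 1/sd^2 weighting flag is provided but the default is
unweighted, on the linear fluorescence scale.

A confidence band for the model mean comes from a residual bootstrap:
residuals are inflated by sqrt(n/(n-p)) to undo the degrees-of-freedom
shrinkage of least-squares residuals, resampled with replacement, added to
the fitted curve, and the model refitted; pointwise quantiles over the
refits form the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm as norm_dist, t as student_t

__all__ = [
    "DoseResponseSeries",
    "FitResult",
    "hill_mean",
    "fit_dose_response",
    "confidence_band",
    "predicted_saturation_dose",
]


@dataclass
class DoseResponseSeries:
    """Stationary dose--response summary: per dose (nM) the mean
    fluorescence (a.u.), its sample SD and the number of gated cells."""

    dose: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    reporter_label: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.dose) == len(self.mean) == len(self.sd) == len(self.n)):
            raise ValueError("dose, mean, sd, n must be aligned")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if len(np.unique(self.dose)) != len(self.dose):
            raise ValueError("doses must be unique")
        if np.any(self.sd < 0) or np.any(self.n < 1):
            raise ValueError("sd must be >= 0 and n >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_nM": self.dose, "mean_fl": self.mean, "sd_fl": self.sd, "n": self.n}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reporter_label: str = "") -> "DoseResponseSeries":
        df = pd.read_csv(path, comment="#")
        return cls(
            dose=df["dose_nM"].to_numpy(),
            mean=df["mean_fl"].to_numpy(),
            sd=df["sd_fl"].to_numpy(),
            n=df["n"].to_numpy(),
            reporter_label=reporter_label,
        )


@dataclass
class FitResult:
    k_hat: float
    h_hat: float
    amplitude_hat: float
    background_hat: float
    residual_sum_of_squares: float
    converged: bool
    n_iterations: int
    message: str = ""

    def params(self) -> np.ndarray:
        return np.array([self.background_hat, self.amplitude_hat, self.k_hat, self.h_hat])

    def to_report(self) -> str:
        lines = [
            f"k_hat_nM = {self.k_hat:.6g}",
            f"h_hat = {self.h_hat:.6g}",
            f"amplitude_hat_au = {self.amplitude_hat:.6g}",
            f"background_hat_au = {self.background_hat:.6g}",
            f"rss = {self.residual_sum_of_squares:.6g}",
            f"converged = {self.converged}",
            f"n_iterations = {self.n_iterations}",
        ]
        return "\n".join(lines) + "\n"


def hill_mean(dose, background: float, amplitude: float, k: float, h: float):
    """Model mean F(d); F(0) = background for h > 0."""
    d = np.asarray(dose, dtype=float)
    out = np.full(d.shape, float(background))
    pos = d > 0
    r = np.power(d[pos] / k, h)
    out[pos] += amplitude * r / (1.0 + r)
    return out


def _rss_and_grad(theta, d, y, w):
    # internal parameterisation (background, amplitude, ln k, h): the log
    # scale on k makes the optimiser invariant to the dose unit
    b, A, lk, h = theta
    k = np.exp(lk)
    pos = d > 0
    u = np.zeros_like(d)
    r = np.power(d[pos] / k, h)
    u[pos] = r / (1.0 + r)
    resid = b + A * u - y
    rss = float(np.sum(w * resid**2))
    # du/d(ln k) = -h u(1-u);  du/dh = u(1-u) ln(d/k)  (d > 0)
    u1u = u * (1.0 - u)
    dlk = np.zeros_like(d)
    dh = np.zeros_like(d)
    dlk[pos] = -h * u1u[pos]
    with np.errstate(divide="ignore"):
        dh[pos] = u1u[pos] * np.log(d[pos] / k)
    wr = 2.0 * w * resid
    grad = np.array(
        [np.sum(wr), np.sum(wr * u), A * np.sum(wr * dlk), A * np.sum(wr * dh)]
    )
    return rss, grad


def _default_init(data: DoseResponseSeries) -> np.ndarray:
    b0 = float(np.min(data.mean))
    a0 = max(float(np.max(data.mean) - b0), 1e-12)
    half = b0 + a0 / 2.0
    pos = data.dose > 0
    if np.any(pos):
        idx = np.argmin(np.abs(data.mean[pos] - half))
        k0 = float(data.dose[pos][idx])
    else:
        k0 = 1.0
    return np.array([b0, a0, max(k0, 1e-6), 2.0])


def _default_bounds(data: DoseResponseSeries):
    pos = data.dose[data.dose > 0]
    dmin = float(np.min(pos)) if len(pos) else 1e-3
    dmax = float(np.max(data.dose)) if np.max(data.dose) > 0 else 1.0
    top = float(np.max(data.mean))
    return [
        (0.0, max(top, 1e-12)),
        (0.0, 10.0 * max(top, 1e-12)),
        (dmin / 50.0, dmax * 50.0),
        (0.2, 10.0),
    ]


def fit_dose_response(
    data: DoseResponseSeries,
    init: Sequence[float] | None = None,
    bounds: Sequence[tuple] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Least-squares Hill fit of a stationary dose--response series.

    ``init``/``bounds`` are in the order (background, amplitude, k, h).
    Returns ``converged=False`` (with a diagnostic message) for data with
    no usable dose dependence — a flat series, or doses that do not bracket
    the half-maximum so k runs into its box bound.
    """
    if len(data.dose) < 4:
        raise ValueError("need at least 4 distinct doses")
    d, y = data.dose, data.mean
    w = 1.0 / np.maximum(data.sd, 1e-12) ** 2 if weighted else np.ones_like(y)

    span = np.max(y) - np.min(y)
    scale = max(np.max(np.abs(y)), 1e-12)
    if span <= 1e-10 * scale:
        return FitResult(
            np.nan, np.nan, 0.0, float(np.mean(y)), 0.0, False, 0,
            "flat series: no dose dependence to fit",
        )

    theta0 = np.asarray(init, dtype=float) if init is not None else _default_init(data)
    box = list(bounds) if bounds is not None else _default_bounds(data)

    # optimise on a normalised fluorescence scale: conditions the problem
    # and makes the convergence thresholds scale-free
    yscale = max(float(np.max(np.abs(y))), 1e-12)
    y_n = y / yscale
    w_n = w * yscale**2 if weighted else w
    theta0_n = np.array(
        [theta0[0] / yscale, theta0[1] / yscale, np.log(theta0[2]), theta0[3]]
    )
    box_n = [
        (box[0][0] / yscale, box[0][1] / yscale),
        (box[1][0] / yscale, box[1][1] / yscale),
        (np.log(box[2][0]), np.log(box[2][1])),
        box[3],
    ]
    res = minimize(
        _rss_and_grad,
        theta0_n,
        args=(d, y_n, w_n),
        jac=True,
        method="L-BFGS-B",
        bounds=box_n,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    b, A, lk, h = res.x
    k = np.exp(lk)
    rss_n, grad_n = _rss_and_grad(res.x, d, y_n, w_n)
    # projected gradient: at an active box bound only the infeasible
    # direction counts
    proj = grad_n.copy()
    for i, (lo_b, hi_b) in enumerate(box_n):
        if res.x[i] <= lo_b + 1e-12 and proj[i] > 0:
            proj[i] = 0.0
        if res.x[i] >= hi_b - 1e-12 and proj[i] < 0:
            proj[i] = 0.0
    b, A = b * yscale, A * yscale
    rss = float(rss_n * yscale**2)
    # scale-free convergence: tiny projected gradient is good enough even
    # when the line search stalls on round-off ("ABNORMAL" status)
    grad_ok = float(np.max(np.abs(proj))) < 1e-6 * (1.0 + rss_n)
    converged = bool(res.success) or grad_ok
    msg = str(res.message)

    # k pinned against its box means the doses do not bracket the rise
    (klo, khi) = box[2]
    if converged and (k <= klo * 1.0001 or k >= khi * 0.9999):
        converged = False
        msg = "k_hat at its bound: doses do not bracket the half-maximum"
    return FitResult(float(k), float(h), float(A), float(b), rss, converged,
                     int(res.nit), msg)


def confidence_band(
    data: DoseResponseSeries,
    fit: FitResult,
    level: float = 0.90,
    n_boot: int = 1000,
    seed: int = 0,
    dose_grid: np.ndarray | None = None,
):
    """Residual-bootstrap confidence band for the model mean.

    Returns ``(grid, lower, upper, n_failed)``.  Residuals are inflated by
    sqrt(n/(n-p)) before resampling; bootstrap refits that fail to converge
    are dropped and counted (an error is raised if more than 20% fail).
    The band is widened, where necessary, to contain the point fit.
    """
    if not fit.converged:
        raise ValueError("confidence_band requires a converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    d, y = data.dose, data.mean
    yhat = hill_mean(d, fit.background_hat, fit.amplitude_hat, fit.k_hat, fit.h_hat)
    resid = y - yhat
    n, p = len(y), 4
    if n > p:
        resid = resid * np.sqrt(n / (n - p))
    if dose_grid is None:
        pos = d[d > 0]
        lo = np.min(pos) / 2 if len(pos) else 0.1
        dose_grid = np.concatenate([[0.0], np.geomspace(lo, np.max(d), 49)])
    dose_grid = np.asarray(dose_grid, dtype=float)

    rng = np.random.default_rng(seed)
    curves = np.empty((n_boot, len(dose_grid)))
    n_failed = 0
    n_ok = 0
    init = fit.params()
    for _ in range(n_boot):
        y_star = yhat + rng.choice(resid, size=n, replace=True)
        boot = DoseResponseSeries(d, y_star, data.sd, data.n)
        try:
            f = fit_dose_response(boot, init=init)
        except ValueError:
            f = None
        if f is None or not f.converged:
            n_failed += 1
            continue
        curves[n_ok] = hill_mean(
            dose_grid, f.background_hat, f.amplitude_hat, f.k_hat, f.h_hat
        )
        n_ok += 1
    if n_failed > 0.2 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed")
    curves = curves[:n_ok]
    alpha = (1.0 - level) / 2.0
    q_lo = np.quantile(curves, alpha, axis=0)
    q_hi = np.quantile(curves, 1.0 - alpha, axis=0)
    point = hill_mean(dose_grid, fit.background_hat, fit.amplitude_hat, fit.k_hat, fit.h_hat)
    # small-sample fattening: the residual scale carries only n-p degrees
    # of freedom, so stretch the band around the point fit by the ratio of
    # Student-t to normal quantiles (tends to 1 as n grows)
    stretch = student_t.ppf(1.0 - alpha, n - p) / norm_dist.ppf(1.0 - alpha)
    lower = point - (point - q_lo) * stretch
    upper = point + (q_hi - point) * stretch
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return dose_grid, lower, upper, n_failed


def predicted_saturation_dose(fit: FitResult, threshold_fraction: float = 0.95) -> float:
    """Dose at which the fitted mean reaches a given fraction of its
    plateau rise: d = k (q/(1-q))^(1/h)."""
    if not fit.converged:
        raise ValueError("requires a converged fit")
    q = threshold_fraction
    if not 0 < q < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    return float(fit.k_hat * (q / (1.0 - q)) ** (1.0 / fit.h_hat))
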