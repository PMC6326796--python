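"""Switch quality at single-cell resolution: ROC curves.

A fluorescence threshold T classifies cells as ON (> T, strictly) or OFF.
Sweeping T over all pooled observed values traces the receiver-operating
characteristic: true-positive rate (fraction of the induced sample above T)
against false-positive rate (fraction of the uninduced sample above T).  A
dysfunctional switch gives the diagonal (AUC 0.5); perfectly separated
states give a step through (0, 1) (AUC 1).  The trapezoidal AUC equals the
Mann-Whitney probability P(X_on > X_off) + 0.5 P(X_on = X_off).

The curve is stored from high threshold to low: (fpr, tpr) runs from
(0, 0) at threshold +inf to (1, 1) at -inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROCCurve", "roc_curve", "auc", "operating_point", "pairwise_auc"]


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending, +inf first, -inf last
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_on: int
    n_off: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# auc: {self.auc}\n# n_on: {self.n_on}\n# n_off: {self.n_off}\n")
            self.to_frame().to_csv(fh, index=False)


def roc_curve(on_sample, off_sample) -> ROCCurve:
    """ROC curve of ON-state vs OFF-state fluorescence samples.

    Thresholds are the sorted unique pooled values plus +/-inf sentinels;
    classification is strictly-greater.
    """
    on = np.asarray(on_sample, dtype=float)
    off = np.asarray(off_sample, dtype=float)
    if on.size == 0 or off.size == 0:
        raise ValueError("both samples must be non-empty")
    thresholds = np.concatenate(
        [[np.inf], np.unique(np.concatenate([on, off]))[::-1], [-np.inf]]
    )
    on_sorted = np.sort(on)
    off_sorted = np.sort(off)
    # fraction of sample strictly greater than T (integer numerators keep
    # the rates exact, e.g. fpr = 1/3 comparable with a 1/3 budget)
    tpr = (on.size - np.searchsorted(on_sorted, thresholds, side="right")) / on.size
    fpr = (off.size - np.searchsorted(off_sorted, thresholds, side="right")) / off.size
    tpr[0], fpr[0] = 0.0, 0.0  # +inf sentinel
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area,
        n_on=int(on.size), n_off=int(off.size),
    )


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the (fpr, tpr) curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def pairwise_auc(on_sample, off_sample) -> float:
    """Mann-Whitney probability P(X_on > X_off) + 0.5 P(X_on = X_off) by
    exhaustive pairwise comparison (O(n*m); the independent reference for
    the trapezoidal AUC)."""
    on = np.asarray(on_sample, dtype=float)[:, None]
    off = np.asarray(off_sample, dtype=float)[None, :]
    wins = (on > off).sum() + 0.5 * (on == off).sum()
    return float(wins / (on.size * off.size))


def operating_point(curve: ROCCurve, target_fpr: float) -> tuple[float, float, float]:
    """(threshold, achieved_fpr, tpr) of the best operating point within a
    false-positive budget.

    This is how an ROC curve is read off a plot: at the largest usable fpr
    <= target, report the highest true-positive rate the switch achieves.
    Among thresholds with that tpr the one with the smallest fpr (and then
    the highest threshold) is returned.
    """
    if not 0 <= target_fpr <= 1:
        raise ValueError("target_fpr must be in [0, 1]")
    ok = np.flatnonzero(curve.fpr <= target_fpr)
    best_tpr = curve.tpr[ok].max()
    cand = ok[curve.tpr[ok] == best_tpr]
    best_fpr = curve.fpr[cand].min()
    idx = int(cand[curve.fpr[cand] == best_fpr][0])  # highest threshold first
    return float(curve.thresholds[idx]), float(curve.fpr[idx]), float(curve.tpr[idx])
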