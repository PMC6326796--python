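"""Dose-dependent non-responder (detrimental-effect) correction.

High inducer doses impose a metabolic burden (and, for the oxidase dual
reporter, H2O2 stress) that leaves a fraction of cells non-fluorescent.
This is captured phenomenologically by a Hill-shaped fraction zeta(ES): a
randomly chosen subset of that size is set to background in the simulated
sample, leaving the rest of the distribution intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ZetaParameters", "zeta", "apply_detrimental"]


@dataclass(frozen=True)
class ZetaParameters:
    """Parameters of the non-responder fraction zeta(ES) =
    zeta_max (ES/k_zeta)^h_zeta / (1 + (ES/k_zeta)^h_zeta)."""

    zeta_max: float
    k_zeta: float
    h_zeta: float

    def __post_init__(self) -> None:
        if not 0 <= self.zeta_max <= 1:
            raise ValueError("zeta_max must be in [0, 1]")
        if self.k_zeta <= 0:
            raise ValueError("k_zeta must be positive")
        if self.h_zeta < 0:
            raise ValueError("h_zeta must be >= 0")


def zeta(es, zp: ZetaParameters):
    """Non-responding fraction at medium dose ``es`` (nM); monotone
    non-decreasing, bounded by ``zeta_max``."""
    x = np.asarray(es, dtype=float)
    if np.any(x < 0):
        raise ValueError("es must be non-negative")
    if zp.h_zeta == 0:
        out = np.full_like(x, zp.zeta_max / 2.0)
    else:
        r = np.power(x / zp.k_zeta, zp.h_zeta)
        out = zp.zeta_max * r / (1.0 + r)
    return out if out.ndim else float(out)


def apply_detrimental(
    sample: np.ndarray,
    fraction: float,
    seed: int,
    background: float = 0.0,
    binomial: bool = False,
    rescale: str = "none",
) -> np.ndarray:
    """Zero out a random subset of a per-cell fluorescence sample.

    ``round(fraction * n)`` cells chosen uniformly at random (without
    replacement) are set to ``background`` — the measured level of a cell
    expressing nothing; pass 0 for the bare model.  The number zeroed is
    deterministic by default; ``binomial=True`` draws it Binomial(n,
    fraction) instead.  ``rescale="preserve-mean"`` divides the surviving
    values by (1 - fraction) so the sample mean is unchanged in
    expectation; the default leaves survivors untouched (the distribution's
    mass renormalises automatically for samples).

    Output length always equals input length; reproducible under ``seed``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if rescale not in ("none", "preserve-mean"):
        raise ValueError("rescale must be 'none' or 'preserve-mean'")
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    rng = np.random.default_rng(seed)
    if binomial:
        n_zero = int(rng.binomial(n, fraction))
    else:
        # round-half-away-from-zero so fraction=0.5, n odd is stable
        n_zero = int(np.floor(fraction * n + 0.5))
    n_zero = min(n_zero, n)
    out = sample.copy()
    if rescale == "preserve-mean" and fraction < 1:
        out = out / (1.0 - fraction)
    idx = rng.choice(n, size=n_zero, replace=False)
    out[idx] = background
    return out
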