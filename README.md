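# andgate

Modelling and single-cell analysis toolkit for a β-estradiol/galactose
controlled CRISPR-dCas9 AND gate in *Saccharomyces cerevisiae*.

The gate couples two switchable parts: dCas9 expressed from the
galactose-inducible *GAL10* promoter, and the MCP-VP64 activator expressed
under control of the β-estradiol (ES) responsive transcription factor
LexA-ER-AD.  Reporter fluorescence appears only when both inducers are
present, and the ES arm makes the output finely tunable in the low-nM
range.  This package implements the computational side of characterising
such a gate:

* **Deterministic model** (`andgate.model`) — the ES arm reduced to two
  ODEs: first-order diffusion of the hormone–TF complex across the nuclear
  boundary, and Hill-activated reporter expression balanced by first-order
  degradation,

  ```
  d es_n/dt = γ (es_m − es_n)
  d g/dt    = −δ g + f(es_n),     f(x) = ν (x/k)^h / (1 + (x/k)^h)
  ```

  with a linear fluorescence scale Φ (a.u. per unit reporter).
* **Exact stochastic model** (`andgate.ssa`) — the same reaction network at
  yeast-nucleus copy numbers (volume ≈ 3 µm³, where 1 nM ≈ 1.8 molecules),
  sampled with the direct-method Gillespie algorithm.  At low ES doses the
  slow diffusion of a handful of complexes produces the bimodal
  single-cell fluorescence distributions seen by flow cytometry.
* **Non-responder correction** (`andgate.detrimental`) — a Hill-shaped,
  dose-dependent fraction ζ(ES) of cells that never fluoresce (metabolic
  burden / H₂O₂ stress), applied by zeroing randomly chosen cells.
* **Dose–response fitting** (`andgate.fit`) — box-constrained quasi-Newton
  least squares of the stationary Hill curve
  `F(d) = background + amplitude·(d/k)^h/(1+(d/k)^h)` to gated population
  means, with a residual-bootstrap confidence band and a closed-form
  saturation-dose predictor.
* **Flow cytometry** (`andgate.cytometry`) — CSV (and optional FCS 3.0)
  event tables, the minimal two-gate strategy (constant scatter box for
  debris, constant FSC-H/FSC-A band for doublets), population means, fold
  activation, log-binned histograms with bimodality detection, and
  microfluidic trace utilities (background correction, moving average).
* **Switch quality** (`andgate.roc`) — ROC curves over all fluorescence
  thresholds, with the trapezoidal AUC equal to the Mann–Whitney
  probability, and operating-point lookup at a false-positive budget.
* **Synthetic experiments** (`andgate.synth`) — a seeded generator of
  complete in-silico flow datasets (stochastic signal, autofluorescence,
  measurement noise, non-responders, debris and doublets with truth
  labels) so the whole pipeline is testable without instrument data.
* **CLI** (`andgate.cli`) — `andgate synth | fit | simulate | evaluate |
  report`.

## Worked example

```python
import numpy as np
from andgate import (SyntheticConfig, generate_dose_series, fit_dose_response,
                     predicted_saturation_dose, apply_gates, default_gate_config,
                     fold_activation, roc_curve)

cfg = SyntheticConfig(master_seed=1)          # default in-silico experiment
tables, series = generate_dose_series(cfg)    # simulate, gate, summarise
fit = fit_dose_response(series)
print(f"k = {fit.k_hat:.2f} nM, h = {fit.h_hat:.2f}")
print(f"saturation (95%) at {predicted_saturation_dose(fit, 0.95):.1f} nM")

gc = default_gate_config()
on, _ = apply_gates(tables[100.0], gc)
off, _ = apply_gates(tables[0.0], gc)
print(f"fold activation: {fold_activation(on, off):.1f}")
print(f"AUC at 5 nM: {roc_curve(apply_gates(tables[5.0], gc)[0].fl1, off.fl1).auc:.3f}")
```

prints

```
k = 4.92 nM, h = 2.05
saturation (95%) at 20.7 nM
fold activation: 105.4
AUC at 5 nM: 0.990
```

The generating truth is k = 5 nM, h = 2: the full pipeline (stochastic
simulation → gating → population means → fit) recovers the half-saturation
within a few percent.  The fold activation of ~105 is the ratio of gated
mean fluorescence at saturating ES (100 nM) over the uninduced condition,
and the AUC quantifies how cleanly single cells separate into ON and OFF
states at 5 nM.

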