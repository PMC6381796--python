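# unwindkit

Simulation and analysis tools for DNA unwinding by the eukaryotic
replicative helicase CMG at strand-specific protein barriers.

CMG encircles the leading-strand template and excludes the lagging strand
from its central channel (steric exclusion). A protein block on the
excluded strand therefore leaves the helicase alone — unless the block
also clamps and stabilises the surrounding duplex, in which case the
helicase pauses transiently; the same block on the tracking strand arrests
it outright. Quantifying this behaviour takes three kinds of measurement,
and this package implements the analysis for all of them, plus a
ground-truth simulator to validate the pipelines end to end:

* **Ensemble kinetics** (`unwindkit.ensemble_kinetics`) — bulk
  fluorophore/quencher unwinding curves are described by an m-step
  sequential model: completion requires `m` consecutive steps, each with
  observed rate constant `k_obs`, so the unwound fraction is the
  Erlang CDF

  ```
  f_ss(t) = 1 − Σ_{r=1..m} (k_obs·t)^(r−1) / (r−1)! · exp(−k_obs·t)
  ```

  (`m = 2` captures the lag phase of single-turnover curves). The module
  normalises raw curves by jointly fitting amplitude and baseline,
  extracts `k_obs` ± SE, and measures a barrier-induced slow-down as the
  shift in t50 (time to half-maximal unwinding) with a bootstrap CI.

* **Single-molecule trace analysis** (`unwindkit.trace_analysis`) —
  per-molecule fluorescent-RPA intensity trajectories from a TIRF assay
  are calibrated to base pairs unwound, completion is detected from the
  terminal signal drop, pauses (> 30 s below 1 bp/s, near a known barrier
  position) are called by threshold segmentation with interval-level
  validation, fork rates are estimated with pause intervals excised, and
  pause durations get a truncation-corrected exponential fit.

* **Gel densitometry** (`unwindkit.densitometry`) — background-corrected
  band-fraction arithmetic (percent substrate unwound) on band-intensity
  tables, with replicate aggregation.

* **Simulator** (`unwindkit.simulate`) — stochastic per-molecule traces
  and ensemble curves with arrest / pause / transparent barriers, partial
  barrier occupancy, completion signal drop, and additive noise; every
  trace carries a latent truth channel so analysis output can be scored
  exactly.

## Worked example

Simulate 200 molecules unwinding a 2.7-kb substrate carrying a
duplex-stabilising methyltransferase block on the lagging-strand template
800 bp from the loading tail, then run the full single-molecule pipeline:

```python
import numpy as np
import unwindkit as uk
from unwindkit import defaults

params, barrier, config = defaults.mh_lagging(seed=7)
traces = uk.simulate_traces(params, barrier, 200, config)
results, summary = uk.analyze_traces(traces, 2700, barrier_bp=800)

print(f"fraction pausing:          {summary.frac_paused:.1%}")
print(f"mean fork rate:            {summary.mean_rate_bp_s:.1f} +/- {summary.sd_rate_bp_s:.1f} bp/s")
print(f"pause duration (exp fit):  {summary.pause_fit.mean_min:.2f} +/- {summary.pause_fit.se_min:.2f} min")
positions = [p.position_bp for r in results for p in r.pauses if p.near_barrier]
print(f"mean pause position:       {np.mean(positions):.0f} bp (block at 800 bp)")
```

prints

```
fraction pausing:          23.5%
mean fork rate:            7.8 +/- 3.7 bp/s
pause duration (exp fit):  5.13 +/- 0.73 min
mean pause position:       800 bp (block at 800 bp)
```

Of the 200 molecules, 149 unwound without interruption and 47 paused at
the block before finishing. The pausing fraction and pause-duration fit
recover the generator's settings (26% discernible pausing, 4.63-min
exponential mean — the fitted 5.13 min is within one SE of the configured
value for this batch); the mean detected pause position lands on the
block. The same pipeline drives the `unwindkit` command-line tool
(`unwindkit simulate`, `analyze-traces`, `fit-ensemble`, `quantify`).

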