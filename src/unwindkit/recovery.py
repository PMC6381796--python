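"""Parameter-recovery experiments under the package's default conditions.

Each function simulates data with the default study conditions (a 2.7-kb
substrate imaged at 10-s intervals, the 8.2 +/- 4.2 bp/s rate population,
the 800-bp barrier, the 4.63-min exponential pause law, the 26%
discernible-pausing and 80% stalling fractions), runs the corresponding
analysis pipeline from scratch, and returns the recovered quantity.  They
are the package's self-check that analysis recovers what the generator
put in, and the basis of ``scripts/acceptance.py``.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import defaults
from .ensemble_kinetics import estimate_delay, fss_model
from .simulate import EnsembleCurve, HelicaseParams, simulate_traces
from .trace_analysis import analyze_traces, fit_pause_durations

__all__ = [
    "fork_rate_recovery",
    "pause_duration_recovery",
    "pausing_fraction_recovery",
    "delay_shift_recovery",
    "stall_fraction_recovery",
    "pause_position_recovery",
]

#: Delay printed for the lagging-strand duplex-stabilising block in the
#: ensemble assay; injected as a pure time shift in delay_shift_recovery.
ENSEMBLE_DELAY_MIN = 4.09


def _sub_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def fork_rate_recovery(seed: int, n: int = 500) -> dict:
    """Mean unwinding rate (bp/s) recovered from unadducted molecules.

    The observation window covers the slowest admissible molecule
    (0.5 bp/s over 2.7 kb) so the estimate is free of censoring bias.
    """
    params, _, config = defaults.unadducted(seed=_sub_seed(seed, 1), duration_s=5600.0)
    traces = simulate_traces(params, None, n, config)
    _, summary = analyze_traces(traces, config.substrate_length_bp)
    return {"value": float(summary.mean_rate_bp_s), "n": summary.n_completed}


def pause_duration_recovery(seed: int, n: int = 109) -> dict:
    """Mean pause duration (min) from the truncation-corrected fit.

    Draws ``n`` durations from the exponential pause law left-truncated at
    the 30-s detection threshold, mirroring the published event count.
    """
    rng = np.random.default_rng(_sub_seed(seed, 2))
    durations = defaults.MIN_PAUSE_S + rng.exponential(defaults.PAUSE_MEAN_S, size=n)
    fit = fit_pause_durations(durations, min_pause_s=defaults.MIN_PAUSE_S)
    return {"value": float(fit.mean_min), "n": n}


def pausing_fraction_recovery(seed: int, n: int = 420) -> dict:
    """Percent of lagging-strand-block molecules with a discernible pause."""
    params, barrier, config = defaults.mh_lagging(seed=_sub_seed(seed, 3))
    traces = simulate_traces(params, barrier, n, config)
    _, summary = analyze_traces(
        traces, config.substrate_length_bp, barrier_bp=barrier.position_bp
    )
    return {"value": float(100.0 * summary.frac_paused), "n": n}


def delay_shift_recovery(seed: int = 0) -> dict:
    """Ensemble delay (min) recovered from an injected pure time shift."""
    t = np.arange(0.0, 3600.0 + 5.0, 5.0)
    ref = EnsembleCurve(
        times_s=t, signal=fss_model(t / 60.0, 0.2, 2), normalized=True
    )
    shifted = EnsembleCurve(
        times_s=t,
        signal=fss_model(np.maximum(t / 60.0 - ENSEMBLE_DELAY_MIN, 0.0), 0.2, 2),
        normalized=True,
    )
    estimate = estimate_delay(ref, shifted, n_boot=200, seed=_sub_seed(seed, 4))
    return {"value": float(estimate.delay_min), "n": len(t)}


def stall_fraction_recovery(seed: int, n: int = 100) -> dict:
    """Percent of leading-strand-block molecules classified as stalled."""
    params, barrier, config = defaults.mh_leading(seed=_sub_seed(seed, 5))
    traces = simulate_traces(params, barrier, n, config)
    _, summary = analyze_traces(
        traces, config.substrate_length_bp, barrier_bp=barrier.position_bp
    )
    return {"value": float(100.0 * summary.frac_stalled), "n": n}


def pause_position_recovery(seed: int, n: int = 100) -> dict:
    """Mean detected pause position (bp) across pausing molecules.

    Every simulated molecule carries and responds to the block
    (pause probability 1), giving ``n`` pausing traces as the experiment
    requires.
    """
    params, barrier, config = defaults.mh_lagging(seed=_sub_seed(seed, 6))
    params = dataclasses.replace(params, pause_probability=1.0)
    traces = simulate_traces(params, barrier, n, config)
    results, _ = analyze_traces(
        traces, config.substrate_length_bp, barrier_bp=barrier.position_bp
    )
    positions = [
        p.position_bp for r in results for p in r.pauses if p.near_barrier
    ]
    return {"value": float(np.mean(positions)), "n": len(positions)}
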