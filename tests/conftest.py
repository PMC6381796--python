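import numpy as np
import pytest

from unwindkit import defaults, simulate, trace_analysis as ta


@pytest.fixture(scope="session")
def no_barrier_batch():
    """200 unadducted traces observed long enough for every molecule to finish."""
    params, _, config = defaults.unadducted(seed=11, duration_s=5600)
    return simulate.simulate_traces(params, None, 200, config)


@pytest.fixture(scope="session")
def mh_lag_batch():
    """420 traces with the lagging-strand duplex-stabilising block at 800 bp."""
    params, barrier, config = defaults.mh_lagging(seed=12)
    return simulate.simulate_traces(params, barrier, 420, config), barrier


@pytest.fixture(scope="session")
def mh_lag_analysis(mh_lag_batch):
    traces, barrier = mh_lag_batch
    results, summary = ta.analyze_traces(
        traces, defaults.SUBSTRATE_LENGTH_BP, barrier_bp=barrier.position_bp
    )
    return traces, results, summary


def staircase_trajectory(
    rate_bp_s=8.0,
    pause_at_bp=None,
    pause_duration_s=0.0,
    substrate_length_bp=2700,
    frame_interval_s=10.0,
    total_s=None,
):
    """Noise-free piecewise-linear bp trajectory for constructed-input tests."""
    if total_s is None:
        total_s = substrate_length_bp / rate_bp_s + pause_duration_s
    t = np.arange(0.0, total_s + frame_interval_s, frame_interval_s)
    if pause_at_bp is None:
        bp = rate_bp_s * t
    else:
        t_hit = pause_at_bp / rate_bp_s
        t_end = t_hit + pause_duration_s
        bp = np.where(
            t < t_hit, rate_bp_s * t,
            np.where(t < t_end, pause_at_bp, pause_at_bp + rate_bp_s * (t - t_end)),
        )
    bp = np.minimum(bp, substrate_length_bp)
    return ta.Trajectory(times_s=t, bp=bp, substrate_length_bp=substrate_length_bp)
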