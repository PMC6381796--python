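"""Single-molecule pipeline: calibration, completion, pauses, rates, stats."""

import numpy as np
import pytest

from unwindkit import defaults
from unwindkit.simulate import (
    BarrierSpec,
    HelicaseParams,
    SimConfig,
    Trace,
    simulate_trace,
    simulate_traces,
)
from unwindkit.trace_analysis import (
    Trajectory,
    analyze_traces,
    batch_intensity_scale,
    calibrate_trace,
    detect_completion,
    detect_pauses,
    estimate_rate,
    fit_pause_durations,
    pause_duration_histogram,
    summarize_population,
    TraceResult,
)

from conftest import staircase_trajectory

L = defaults.SUBSTRATE_LENGTH_BP


# ------------------------------------------------------------ calibration


def test_calibration_tracks_truth_on_noiseless_trace():
    params = HelicaseParams(rate_mean=8.2, rate_sd=0.0)
    config = SimConfig(noise_sd=0.0, duration_s=400.0)
    trace = simulate_trace(params, None, config)
    traj = calibrate_trace(trace, L)
    truth = trace.truth.unwound_bp[: len(traj.bp)]
    # the completion drop is only localised to one frame, so the
    # self-calibrated scale carries up to half a frame of advance
    # (v * dt / 2 ~ 1.5% of L) of quantisation error
    assert np.max(np.abs(traj.bp[2:-2] - truth[2:-2])) < 0.016 * L


def test_calibration_scale_invariance():
    params, config = HelicaseParams(), SimConfig(seed=5)
    trace = simulate_trace(params, None, config)
    scaled = Trace(
        molecule_id=trace.molecule_id,
        times_s=trace.times_s,
        intensity=trace.intensity * 37.5,
        truth=trace.truth,
    )
    a = calibrate_trace(trace, L)
    b = calibrate_trace(scaled, L)
    np.testing.assert_allclose(a.bp, b.bp, rtol=1e-12)


def test_calibration_rejects_flat_trace():
    rng = np.random.default_rng(0)
    t = np.arange(0.0, 600.0, 10.0)
    trace = Trace(molecule_id=0, times_s=t, intensity=rng.normal(100.0, 1.0, len(t)))
    with pytest.raises(ValueError, match="flat"):
        calibrate_trace(trace, L)


def test_batch_scale_close_to_configured_intensity():
    params, _, config = defaults.unadducted(seed=5, duration_s=5600.0)
    traces = simulate_traces(params, None, 100, config)
    scale = batch_intensity_scale(traces, L)
    assert scale == pytest.approx(config.intensity_per_bp, rel=0.02)


# ------------------------------------------------------------- completion


def test_completion_detected_within_one_frame_of_truth():
    params, _, config = defaults.unadducted(seed=3, duration_s=5600.0)
    hits = 0
    for i in range(40):
        trace = simulate_trace(params, None, config, molecule_id=i)
        truth = trace.truth.completion_time_s
        if truth is None:
            continue
        detected = detect_completion(trace)
        assert detected is not None
        assert abs(detected - truth) <= config.frame_interval_s
        hits += 1
    assert hits >= 35


def test_completion_censored_for_arrested_trace():
    params = HelicaseParams()
    barrier = BarrierSpec(800, "leading", "arrest", occupancy=1.0)
    config = SimConfig(seed=2)
    trace = simulate_trace(params, barrier, config, molecule_id=1)
    assert detect_completion(trace) is None


def test_single_frame_spike_is_not_a_completion():
    t = np.arange(0.0, 1200.0, 10.0)
    intensity = np.minimum(8.0 * t, 2700.0).astype(float)
    spiked = intensity.copy()
    spiked[80] *= 0.6  # one-frame 40% dip on the plateau
    assert detect_completion(Trace(0, t, spiked)) is None


# ----------------------------------------------------------------- pauses


def test_ideal_staircase_has_no_pauses():
    traj = staircase_trajectory(rate_bp_s=8.0)
    assert detect_pauses(traj, barrier_bp=800) == []


def test_constructed_pause_recovered_with_position_and_duration():
    traj = staircase_trajectory(rate_bp_s=8.0, pause_at_bp=800, pause_duration_s=300.0)
    pauses = detect_pauses(traj, barrier_bp=800)
    assert len(pauses) == 1
    p = pauses[0]
    assert p.duration_s == pytest.approx(300.0, abs=10.0)
    assert p.position_bp == pytest.approx(800.0, abs=20.0)
    assert p.near_barrier


def test_sub_threshold_flat_segment_ignored():
    """A 20-s dwell is below the 'more than 30 s' criterion."""
    traj = staircase_trajectory(rate_bp_s=8.0, pause_at_bp=800, pause_duration_s=20.0)
    assert detect_pauses(traj, barrier_bp=800) == []


def test_terminal_plateau_is_not_a_pause():
    t = np.arange(0.0, 2400.0, 10.0)
    bp = np.minimum(8.0 * t, 800.0)  # stalls at 800 and stays
    traj = Trajectory(times_s=t, bp=bp, substrate_length_bp=L)
    assert detect_pauses(traj, barrier_bp=800) == []


def test_detect_pauses_invariant_to_intensity_rescaling():
    params, barrier, config = defaults.mh_lagging(seed=17)
    params_all = HelicaseParams(
        rate_mean=params.rate_mean, rate_sd=params.rate_sd,
        pause_mean_duration=params.pause_mean_duration, pause_probability=1.0,
    )
    trace = simulate_trace(params_all, barrier, config, molecule_id=4)
    scale = 1.0
    base = calibrate_trace(trace, L, intensity_per_bp=scale,
                           completion_time_s=detect_completion(trace))
    scaled_trace = Trace(4, trace.times_s, trace.intensity * 11.0, trace.truth)
    scaled = calibrate_trace(scaled_trace, L, intensity_per_bp=scale * 11.0,
                             completion_time_s=detect_completion(scaled_trace))
    p1 = detect_pauses(base, barrier_bp=800)
    p2 = detect_pauses(scaled, barrier_bp=800)
    assert [(p.start_s, p.end_s) for p in p1] == [(p.start_s, p.end_s) for p in p2]


def test_detect_pauses_requires_long_enough_trajectory():
    traj = staircase_trajectory(rate_bp_s=8.0, total_s=20.0)
    with pytest.raises(ValueError):
        detect_pauses(traj)


def test_pause_recall_and_precision_on_blocked_batch(mh_lag_analysis):
    """Pauses longer than a minute are recovered at >=0.9 recall and >=0.9
    precision against the simulator truth; shorter events sit at the
    noise floor (54 bp/frame ~ one minute of sub-floor drift) and are
    recovered best-effort."""
    traces, results, _ = mh_lag_analysis
    matched_long = n_long = 0
    matched_all = n_all = 0
    tp = fp = 0
    for trace, result in zip(traces, results):
        truth = trace.truth
        has = truth.pause_start_s is not None
        d = truth.pause_duration_s if has else 0.0
        hit = any(
            p.start_s <= truth.pause_end_s and p.end_s >= truth.pause_start_s
            for p in result.pauses
        ) if has else False
        if has and d >= 30.0:
            n_all += 1
            matched_all += hit
        if has and d >= 60.0:
            n_long += 1
            matched_long += hit
        for p in result.pauses:
            if has and p.start_s <= truth.pause_end_s and p.end_s >= truth.pause_start_s:
                tp += 1
            else:
                fp += 1
    assert matched_long / n_long >= 0.9
    assert matched_all / n_all >= 0.75
    assert tp / (tp + fp) >= 0.9


def test_no_barrier_batch_is_nearly_pause_free(no_barrier_batch):
    """Unadducted molecules yield at most ~1% spurious pause calls."""
    results, _ = analyze_traces(no_barrier_batch, L)
    false_pauses = sum(len(r.pauses) for r in results)
    assert false_pauses <= 0.02 * len(no_barrier_batch)


# ------------------------------------------------------------------ rates


def test_estimate_rate_exact_on_line():
    t = np.arange(0.0, 300.0, 10.0)
    traj = Trajectory(times_s=t, bp=8.2 * t)
    assert estimate_rate(traj) == pytest.approx(8.2, abs=1e-12)


def test_estimate_rate_rejects_short_interval():
    t = np.arange(0.0, 300.0, 10.0)
    traj = Trajectory(times_s=t, bp=8.2 * t)
    with pytest.raises(ValueError):
        estimate_rate(traj, (0.0, 25.0))


def test_per_trace_rate_close_to_truth(no_barrier_batch):
    results, _ = analyze_traces(no_barrier_batch, L)
    checked = 0
    for trace, result in zip(no_barrier_batch, results):
        if result.rate_bp_s is None:
            continue
        assert result.rate_bp_s == pytest.approx(trace.truth.rate_bp_s, rel=0.15)
        checked += 1
    assert checked >= 0.9 * len(no_barrier_batch)


def test_end_to_end_mean_rate_within_five_percent(no_barrier_batch):
    _, summary = analyze_traces(no_barrier_batch, L)
    assert summary.mean_rate_bp_s == pytest.approx(8.2, rel=0.05)


# -------------------------------------------------- pause-duration fitting


def test_pause_fit_reduces_to_sample_mean_without_truncation():
    fit = fit_pause_durations([120.0, 240.0, 360.0, 120.0, 240.0, 360.0], min_pause_s=0.0)
    assert fit.mean_min == pytest.approx(4.0, abs=1e-12)


def test_pause_fit_unbiased_on_truncated_exponential():
    """MLE recovers the configured mean from left-truncated draws."""
    for mean_min in (1.0, 4.63, 10.0):
        rng = np.random.default_rng(int(mean_min * 100))
        durations = 30.0 + rng.exponential(mean_min * 60.0, size=500)
        fit = fit_pause_durations(durations, min_pause_s=30.0)
        assert abs(fit.mean_min - mean_min) < 2 * mean_min / np.sqrt(500)


def test_pause_fit_requires_five_events():
    with pytest.raises(ValueError):
        fit_pause_durations([100.0, 200.0, 300.0])


def test_pause_histogram_counts_everything():
    durations = [60.0, 90.0, 200.0, 400.0, 700.0]
    hist = pause_duration_histogram(durations, bin_width_min=1.0)
    assert hist["count"].sum() == len(durations)


# ------------------------------------------------------ population summary


def test_summary_counts_constructed_results():
    results = [
        TraceResult(0, "completed"),
        TraceResult(1, "completed"),
        TraceResult(2, "completed"),
        TraceResult(3, "stalled"),
    ]
    summary = summarize_population(results)
    assert summary.frac_stalled == 0.25
    assert summary.frac_completed == 0.75
    assert summary.n_total == 4


def test_summary_rejects_empty_input():
    with pytest.raises(ValueError):
        summarize_population([])


def test_pausing_fraction_recovered_on_blocked_batch(mh_lag_analysis):
    """Detected discernible-pause fraction lands within 3 binomial SE of 26%."""
    _, _, summary = mh_lag_analysis
    se = np.sqrt(0.26 * 0.74 / summary.n_total)
    assert abs(summary.frac_paused - 0.26) <= 3 * se


def test_stall_fraction_recovered_on_leading_block():
    params, barrier, config = defaults.mh_leading(seed=6)
    traces = simulate_traces(params, barrier, 100, config)
    _, summary = analyze_traces(traces, L, barrier_bp=barrier.position_bp)
    se = np.sqrt(0.8 * 0.2 / 100)
    assert abs(summary.frac_stalled - 0.8) <= 3 * se
    # accounting: every molecule lands in exactly one class
    total = (
        summary.frac_completed + summary.frac_stalled + summary.frac_ambiguous
    )
    assert total == pytest.approx(1.0, abs=1e-12)
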