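"""Simulator: trajectory mechanics, barrier semantics, and statistical laws."""

import numpy as np
import pytest
from scipy import stats

from unwindkit.simulate import (
    BarrierSpec,
    HelicaseParams,
    SimConfig,
    sample_completion_times,
    simulate_ensemble,
    simulate_trace,
    simulate_traces,
)
from unwindkit.ensemble_kinetics import fss_model


def test_fixed_rate_completion_time_matches_arithmetic():
    """A 2700-bp substrate at exactly 8.2 bp/s finishes at 2700/8.2 s."""
    params = HelicaseParams(rate_mean=8.2, rate_sd=0.0)
    config = SimConfig(noise_sd=0.0, duration_s=400.0)
    trace = simulate_trace(params, None, config)
    assert trace.truth.completion_time_s == pytest.approx(2700 / 8.2, abs=1e-9)
    # intensity drops after completion and the truth trajectory saturates at L
    assert trace.truth.unwound_bp.max() == 2700
    post = trace.times_s >= trace.truth.completion_time_s
    assert np.all(trace.intensity[post] == 0.5 * 2700)


def test_transparent_barrier_trace_identical_to_no_barrier():
    """A block that only touches the displaced strand changes nothing."""
    params, config = HelicaseParams(), SimConfig(seed=42)
    barrier = BarrierSpec(800, "lagging", "transparent", occupancy=1.0)
    for mol in range(5):
        a = simulate_trace(params, None, config, molecule_id=mol)
        b = simulate_trace(params, barrier, config, molecule_id=mol)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.truth.unwound_bp, b.truth.unwound_bp)


def test_arrest_barrier_plateaus_without_completion():
    params, config = HelicaseParams(), SimConfig(seed=1)
    barrier = BarrierSpec(800, "leading", "arrest", occupancy=1.0)
    trace = simulate_trace(params, barrier, config, molecule_id=3)
    assert trace.truth.unwound_bp.max() == 800
    assert trace.truth.completion_time_s is None


def test_seed_determinism_bit_identical():
    params, config = HelicaseParams(), SimConfig(seed=7)
    barrier = BarrierSpec(800, "lagging", "pause", occupancy=0.5)
    a = simulate_traces(params, barrier, 10, config)
    b = simulate_traces(params, barrier, 10, config)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.intensity, y.intensity)


def test_truth_trajectory_monotone_until_completion(no_barrier_batch):
    for trace in no_barrier_batch[:50]:
        assert np.all(np.diff(trace.truth.unwound_bp) >= 0)
        assert trace.truth.unwound_bp.max() <= 2700


def test_rate_population_moments_match_configuration():
    """Truncated-normal sampling is moment-matched to the configured mean/SD."""
    params, config = HelicaseParams(), SimConfig(seed=1)
    rates = np.array(
        [simulate_trace(params, None, config, molecule_id=i).truth.rate_bp_s for i in range(4000)]
    )
    assert rates.min() >= 0.5
    assert rates.mean() == pytest.approx(8.2, abs=3 * 4.2 / np.sqrt(4000))
    assert rates.std() == pytest.approx(4.2, rel=0.05)


def test_pause_durations_exponentially_distributed():
    params = HelicaseParams(pause_probability=1.0)
    barrier = BarrierSpec(800, "lagging", "pause", occupancy=1.0)
    config = SimConfig(seed=9, duration_s=6000.0)
    durations = [
        tr.truth.pause_duration_s
        for tr in (simulate_trace(params, barrier, config, molecule_id=i) for i in range(1000))
        if tr.truth.pause_duration_s is not None
    ]
    assert len(durations) == 1000
    ks = stats.kstest(durations, "expon", args=(0, params.pause_mean_duration))
    assert ks.pvalue > 0.01


def test_ensemble_curve_matches_erlang_cdf():
    """Monte-Carlo completion fraction agrees with the closed form at t=1 min."""
    params = HelicaseParams(m_steps=2, k_obs=1.0)
    config = SimConfig(noise_sd=0.0, frame_interval_s=6.0, duration_s=600.0, seed=4)
    curve = simulate_ensemble(params, None, 50_000, config)
    idx = np.searchsorted(curve.times_s, 60.0)
    expected = 1 - 2 * np.exp(-1)
    se = np.sqrt(expected * (1 - expected) / 50_000)
    assert curve.signal[idx] == pytest.approx(expected, abs=3 * se)
    assert curve.signal[0] == 0.0


def test_ensemble_arrest_never_completes():
    params = HelicaseParams()
    barrier = BarrierSpec(800, "leading", "arrest", occupancy=1.0)
    config = SimConfig(noise_sd=0.0, seed=2)
    curve = simulate_ensemble(params, barrier, 500, config)
    assert np.all(curve.signal == 0.0)


def test_completion_times_erlang_dkw():
    """Empirical completion CDF within DKW bounds of the m-step model."""
    n = 10_000
    eps = np.sqrt(np.log(2 / 0.05) / (2 * n))
    for m in (1, 2, 3, 5):
        params = HelicaseParams(m_steps=m, k_obs=0.5)
        rng = np.random.default_rng(100 + m)
        times = sample_completion_times(params, None, n, rng)
        grid = np.linspace(0.0, np.quantile(times, 0.999), 400)
        ecdf = (times[None, :] <= grid[:, None] * 60.0).mean(axis=1)
        model = fss_model(grid, 0.5, m)
        assert np.max(np.abs(ecdf - model)) < eps


def test_gillespie_stepping_agrees_with_continuous_law():
    """Single-bp stepping preserves the mean rate and completion time."""
    params = HelicaseParams(rate_mean=8.2, rate_sd=0.0)
    config = SimConfig(noise_sd=0.0, duration_s=800.0, stepping="gillespie", seed=21)
    completions = []
    for i in range(200):
        trace = simulate_trace(params, None, config, molecule_id=i)
        assert np.all(np.diff(trace.truth.unwound_bp) >= 0)
        if trace.truth.completion_time_s is not None:
            completions.append(trace.truth.completion_time_s)
    # completion time is a sum of 2700 iid exponential(1/8.2 s) steps
    expected = 2700 / 8.2
    se = (np.sqrt(2700) / 8.2) / np.sqrt(len(completions))
    assert len(completions) >= 195
    assert np.mean(completions) == pytest.approx(expected, abs=4 * se)


def test_gillespie_pause_and_arrest_semantics():
    params = HelicaseParams(rate_mean=8.2, rate_sd=0.0, pause_probability=1.0)
    config = SimConfig(noise_sd=0.0, duration_s=2400.0, stepping="gillespie", seed=22)
    paused = simulate_trace(
        params, BarrierSpec(800, "lagging", "pause", occupancy=1.0), config
    )
    assert paused.truth.pause_duration_s is not None
    arrested = simulate_trace(
        params, BarrierSpec(800, "leading", "arrest", occupancy=1.0), config
    )
    assert arrested.truth.unwound_bp.max() == 800
    assert arrested.truth.completion_time_s is None


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(position_bp=800, strand="leading", mechanism="pause"),
        dict(position_bp=800, strand="lagging", mechanism="arrest"),
        dict(position_bp=800, strand="leading", mechanism="transparent"),
        dict(position_bp=-5, strand="leading", mechanism="arrest"),
        dict(position_bp=800, strand="lagging", mechanism="pause", occupancy=1.5),
    ],
)
def test_barrier_spec_rejects_invalid_combinations(kwargs):
    with pytest.raises(ValueError):
        BarrierSpec(**kwargs)


def test_config_and_params_validation():
    with pytest.raises(ValueError):
        SimConfig(duration_s=5.0, frame_interval_s=10.0)
    with pytest.raises(ValueError):
        SimConfig(drop_factor=1.0)
    with pytest.raises(ValueError):
        HelicaseParams(rate_mean=-1.0)
    with pytest.raises(ValueError):
        HelicaseParams(m_steps=0)
    with pytest.raises(ValueError):
        simulate_trace(
            HelicaseParams(),
            BarrierSpec(3000, "lagging", "pause"),
            SimConfig(),
        )
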