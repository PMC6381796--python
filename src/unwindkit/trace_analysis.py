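"""Single-molecule unwinding trace analysis.

Pipeline for per-molecule fluorescence trajectories from a
surface-tethered unwinding assay (ssDNA-binding-protein intensity versus
time): intensity-to-bp calibration, completion detection from the terminal
signal drop, pause calling near a known barrier position, unwinding-rate
estimation, truncation-corrected exponential pause-duration statistics,
and population summaries.

Conventions
-----------
* A *pause* is a transient interval in which the local unwinding rate
  stays below ``rate_floor_bp_s`` (default 1 bp/s, well below the bulk of
  the 8.2 +/- 4.2 bp/s rate distribution) for at least ``min_pause_s``
  (default 30 s) and is followed by resumed advance of at least 100 bp;
  the terminal plateau of a stalled or completed trace is never a pause.
* A *stall* is a censored completion whose terminal plateau sits within
  the barrier window: the helicase halted permanently at the block.
* Pause-duration statistics correct for the detection threshold: observed
  durations are left-truncated at ``min_pause_s``, and by memorylessness
  of the exponential the maximum-likelihood mean is the sample mean minus
  the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .simulate import BarrierSpec, Trace

__all__ = [
    "Trajectory",
    "Pause",
    "TraceResult",
    "PopulationSummary",
    "PauseDurationFit",
    "calibrate_trace",
    "batch_intensity_scale",
    "detect_completion",
    "detect_pauses",
    "estimate_rate",
    "fit_pause_durations",
    "pause_duration_histogram",
    "analyze_trace",
    "analyze_traces",
    "summarize_population",
]

MIN_PAUSE_S = 30.0
RATE_FLOOR_BP_S = 1.0
BARRIER_WINDOW_BP = 150
MIN_POST_ADVANCE_BP = 100.0
_MEDIAN_WINDOW = 3
_DROP_FRAC = 0.3
_PERSISTENCE_FRAMES = 3
_TERMINAL_WINDOW_FRAMES = 30


@dataclass(frozen=True)
class Trajectory:
    """Calibrated unwinding trajectory: base pairs unwound versus time."""

    times_s: np.ndarray
    bp: np.ndarray
    molecule_id: int | str = 0
    substrate_length_bp: int | None = None

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))


@dataclass(frozen=True)
class Pause:
    """One called pause event."""

    start_s: float
    end_s: float
    position_bp: float
    near_barrier: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class TraceResult:
    """Per-molecule analysis outcome."""

    molecule_id: int | str
    classification: str  # completed | paused_then_completed | stalled | ambiguous
    pauses: tuple[Pause, ...] = ()
    rate_bp_s: float | None = None
    rate_pre_bp_s: float | None = None
    rate_post_bp_s: float | None = None
    completion_time_s: float | None = None


class PauseDurationFit(NamedTuple):
    mean_min: float
    se_min: float


@dataclass(frozen=True)
class PopulationSummary:
    """Aggregate statistics over a batch of analysed molecules."""

    n_total: int
    n_completed: int
    n_paused: int
    n_stalled: int
    n_ambiguous: int
    frac_completed: float
    frac_paused: float
    frac_stalled: float
    frac_ambiguous: float
    mean_rate_bp_s: float | None
    sd_rate_bp_s: float | None
    pause_fit: PauseDurationFit | None
    n_pauses: int
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# calibration and completion


def _filtered_intensity(trace: Trace) -> np.ndarray:
    return median_filter(np.asarray(trace.intensity, dtype=float), size=_MEDIAN_WINDOW, mode="nearest")


def _noise_estimate(intensity: np.ndarray) -> float:
    d = np.diff(intensity)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def detect_completion(
    trace: Trace,
    drop_frac: float = _DROP_FRAC,
    persistence_frames: int = _PERSISTENCE_FRAMES,
) -> float | None:
    """Time of the completion signal drop, or ``None`` if censored.

    Completion of unwinding releases the strand not coupled to the surface
    and its bound fluorescent protein, so the intensity falls abruptly.
    The drop is called at the earliest frame after the pre-drop plateau at
    which the (median-filtered) intensity has fallen by at least
    ``drop_frac`` of the plateau and stays there for ``persistence_frames``
    consecutive frames; a single-frame downward spike is not a completion.
    """
    smoothed = _filtered_intensity(trace)
    n = len(smoothed)
    if n < persistence_frames + 2:
        return None
    i_peak = int(np.argmax(smoothed))
    peak = smoothed[i_peak]
    near_peak = smoothed >= 0.9 * peak
    plateau = float(np.median(smoothed[near_peak])) if near_peak.any() else float(peak)
    thresh = (1.0 - drop_frac) * plateau
    below = smoothed <= thresh
    for i in range(i_peak, n - persistence_frames + 1):
        if below[i : i + persistence_frames].all():
            return float(trace.times_s[i])
    return None


def _full_scale_from_rise(
    times: np.ndarray, smoothed: np.ndarray, t_drop: float, n_fit: int = 8
) -> float | None:
    """Full-substrate intensity, extrapolating the rise to the drop time.

    The completion drop fires the moment unwinding finishes, so the last
    pre-drop frames are still rising and their median underestimates the
    full-scale level.  A short line through only the final pre-drop frames
    (which sit after any mid-trace pause) evaluated at the
    half-frame-centred drop time is unbiased for an advancing molecule.
    """
    pre = np.nonzero(times < t_drop)[0]
    if len(pre) < 6:
        return None
    # the final pre-drop frame is excluded: its median-filter window
    # already mixes in the dropped frame and sits biased low
    pre = pre[:-1]
    sel = pre[-min(n_fit, len(pre)) :]
    tw, yw = times[sel], smoothed[sel]
    tc = tw - tw.mean()
    slope = float(np.dot(tc, yw - yw.mean()) / np.dot(tc, tc))
    dt = float(np.median(np.diff(times)))
    value = float(yw.mean()) + slope * (t_drop - 0.5 * dt - float(tw.mean()))
    return value if value > 0 else None


def calibrate_trace(
    trace: Trace,
    substrate_length_bp: int,
    intensity_per_bp: float | None = None,
    completion_time_s: float | None = None,
) -> Trajectory:
    """Map an intensity trace onto base pairs unwound.

    A 3-frame median filter is applied first.  If ``intensity_per_bp`` is
    given (preferred: a batch-level scale from :func:`batch_intensity_scale`)
    it is used directly; otherwise the trace self-calibrates by mapping its
    own full-unwinding intensity (rise extrapolated to the completion
    drop, or the upper plateau for traces without a drop) to
    ``substrate_length_bp`` — correct only for molecules that unwind the
    full substrate.  The calibrated trajectory is clipped to [0, L] and
    truncated at ``completion_time_s`` (the post-drop frames carry no
    positional information).

    The mapping is invariant to uniform rescaling of the input intensity.
    """
    if len(trace.times_s) < 20:
        raise ValueError("trace too short to calibrate (need >= 20 frames)")
    times = np.asarray(trace.times_s, dtype=float)
    smoothed = _filtered_intensity(trace)
    if np.ptp(smoothed) == 0 or np.ptp(smoothed) <= 6.0 * _noise_estimate(np.asarray(trace.intensity, float)):
        raise ValueError("flat trace: no discernible unwinding signal")
    if intensity_per_bp is None:
        if completion_time_s is None:
            completion_time_s = detect_completion(trace)
        full_scale = None
        if completion_time_s is not None:
            full_scale = _full_scale_from_rise(times, smoothed, completion_time_s)
        if full_scale is None:
            pre = smoothed if completion_time_s is None else smoothed[times < completion_time_s]
            if len(pre) == 0:
                pre = smoothed
            peak = float(np.max(pre))
            full_scale = float(np.median(pre[pre >= 0.9 * peak]))
        intensity_per_bp = full_scale / float(substrate_length_bp)
    if intensity_per_bp <= 0:
        raise ValueError("intensity_per_bp must be positive")
    keep = np.ones(len(smoothed), dtype=bool)
    if completion_time_s is not None:
        keep = times < completion_time_s
    bp = np.clip(smoothed[keep] / intensity_per_bp, 0.0, float(substrate_length_bp))
    return Trajectory(
        times_s=times[keep],
        bp=bp,
        molecule_id=trace.molecule_id,
        substrate_length_bp=substrate_length_bp,
    )


def batch_intensity_scale(
    traces: Sequence[Trace],
    substrate_length_bp: int,
    drop_frac: float = _DROP_FRAC,
) -> float:
    """Intensity units per base pair, estimated from a batch of traces.

    Molecules whose completion drop is detected expose the full-substrate
    intensity (their rise extrapolated to the drop time); the batch scale
    is the median of those estimates over L and applies to every molecule
    imaged under the same conditions, including stalled ones that never
    reach full length.  Falls back to the median of per-trace maxima if
    no molecule completed.
    """
    full_scales = []
    maxima = []
    for trace in traces:
        times = np.asarray(trace.times_s, dtype=float)
        smoothed = _filtered_intensity(trace)
        maxima.append(float(np.max(smoothed)))
        t_c = detect_completion(trace, drop_frac=drop_frac)
        if t_c is None:
            continue
        estimate = _full_scale_from_rise(times, smoothed, t_c)
        if estimate is not None:
            full_scales.append(estimate)
    if full_scales:
        return float(np.median(full_scales)) / float(substrate_length_bp)
    warnings.warn(
        "no completed molecules in batch; calibrating from per-trace maxima",
        stacklevel=2,
    )
    return float(np.median(maxima)) / float(substrate_length_bp)


# --------------------------------------------------------------------------
# pause calling


def _central_rates(t: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Per-frame local unwinding rate (bp/s), 3-frame central difference."""
    rates = np.full(len(t), np.nan)
    if len(t) >= 3:
        rates[1:-1] = (bp[2:] - bp[:-2]) / (t[2:] - t[:-2])
    return rates


def _positional_noise_sd(bp: np.ndarray) -> float:
    """Robust per-frame positional noise from second differences.

    Second differencing annihilates any locally linear advance, so the
    residual scatter reflects measurement noise alone; for iid noise the
    second difference has variance 6 sigma^2.
    """
    d2 = np.diff(bp, n=2)
    if len(d2) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / np.sqrt(6.0)


def _theil_sen_slope(t: np.ndarray, bp: np.ndarray, a: int, b: int) -> float:
    """Median pairwise slope (bp/s) over frames [a, b]."""
    tw = t[a : b + 1]
    bw = bp[a : b + 1]
    dt = tw[None, :] - tw[:, None]
    db = bw[None, :] - bw[:, None]
    upper = np.triu_indices(len(tw), k=1)
    return float(np.median(db[upper] / dt[upper]))


def _interval_slope(t: np.ndarray, bp: np.ndarray, a: int, b: int) -> tuple[float, float]:
    """Least-squares slope and its standard error over frames [a, b]."""
    tw = t[a : b + 1]
    bw = bp[a : b + 1]
    tc = tw - tw.mean()
    denom = float(np.dot(tc, tc))
    slope = float(np.dot(tc, bw - bw.mean()) / denom)
    resid = bw - bw.mean() - slope * tc
    dof = max(len(tw) - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / denom))
    return slope, se


def detect_pauses(
    traj: Trajectory,
    min_pause_s: float = MIN_PAUSE_S,
    rate_floor_bp_s: float = RATE_FLOOR_BP_S,
    barrier_bp: int | None = None,
    barrier_window_bp: int = BARRIER_WINDOW_BP,
    min_post_advance_bp: float = MIN_POST_ADVANCE_BP,
) -> list[Pause]:
    """Call pauses: intervals where the trajectory dwells at one position.

    Threshold segmentation in three stages, designed so that sensitivity
    comes from a narrow rate window while specificity comes from interval-
    level validation (a single noisy frame can seed a candidate but can
    never survive validation):

    1. *Seed*: frames whose 3-frame central-difference rate falls below
       ``rate_floor_bp_s``.
    2. *Refine*: around each seed run the pause level ``p`` (median bp of
       the seeds) is expanded frame-by-frame while the trajectory stays
       within a noise-scaled band of ``p`` (single-frame excursions are
       tolerated); overlapping refined intervals merge.  The reported
       span counts the frames within a half-step band, so a clean flat
       segment of duration d is reported as d.
    3. *Validate*: the refined interval is a pause only if (a) its
       least-squares slope plus one standard error stays below the floor
       (rejects molecules merely translocating slowly, whose dwell in any
       band scales with 1/v but whose slope is resolvably above the
       floor), (b) its duration reaches ``min_pause_s``, (c) the molecule
       advances by at least ``min_post_advance_bp`` afterwards (the
       terminal plateau of a stalled or completed trace is never a
       pause), and (d) the trajectory segments flanking the candidate are
       offset in time: a genuine pause delays everything downstream by
       its duration, whereas a transient noise excursion leaves the
       upstream and downstream advance lines collinear.  The offset
       between the flanking lines, converted to seconds at the molecule's
       own speed, must agree with the dwell span (at least half of it and
       at least half of ``min_pause_s``).

    ``position_bp`` is the median calibrated position during the pause;
    ``near_barrier`` marks pauses within ``barrier_window_bp`` of
    ``barrier_bp``.
    """
    t = np.asarray(traj.times_s, dtype=float)
    bp = np.asarray(traj.bp, dtype=float)
    n = len(t)
    dt = traj.frame_interval_s
    if min_pause_s < 2 * dt:
        raise ValueError("min_pause_s must span at least two frames")
    if n < 3 or (t[-1] - t[0]) < min_pause_s:
        raise ValueError("trajectory shorter than min_pause_s")

    rates = _central_rates(t, bp)
    valid = ~np.isnan(rates)
    below = np.zeros(n, dtype=bool)
    below[valid] = rates[valid] < rate_floor_bp_s
    if not below.any():
        return []

    sigma = _positional_noise_sd(bp)
    moving = rates[valid] >= rate_floor_bp_s
    v_ref = float(np.median(rates[valid][moving])) if moving.any() else rate_floor_bp_s
    step = max(v_ref * dt, 1e-9)
    band = max(3.0 * sigma, 0.5 * step)  # refinement reach
    edge = max(2.0 * sigma, 0.5 * step)  # span membership (half a step)

    # seed runs of consecutive below-floor frames
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1

    # refine each seed run around its pause level
    intervals: list[tuple[int, int, float]] = []
    for i, j in runs:
        level = float(np.median(bp[i : j + 1]))
        a = i
        while a - 1 >= 0:
            if abs(bp[a - 1] - level) <= band:
                a -= 1
            elif a - 2 >= 0 and abs(bp[a - 2] - level) <= band:
                a -= 2  # tolerate a single-frame excursion
            else:
                break
        b = j
        while b + 1 < n:
            if abs(bp[b + 1] - level) <= band:
                b += 1
            elif b + 2 < n and abs(bp[b + 2] - level) <= band:
                b += 2
            else:
                break
        intervals.append((a, b, level))

    # merge overlapping or nearly touching refined intervals with no
    # advance between them (one pause, many seeds / split by an excursion)
    intervals.sort()
    merged: list[list[float]] = []
    for a, b, level in intervals:
        if merged and (
            a <= merged[-1][1]
            or (a - merged[-1][1] <= 3 and abs(bp[a] - bp[int(merged[-1][1])]) <= band)
        ):
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b, level])

    flank_frames = max(int(round(120.0 / dt)), 4)
    pauses: list[Pause] = []
    for a, b, _ in merged:
        a, b = int(a), int(b)
        level = float(np.median(bp[a : b + 1]))
        inside = np.abs(bp[a : b + 1] - level) <= edge
        if inside.sum() < 2:
            continue
        idx = np.nonzero(inside)[0] + a
        a_in, b_in = int(idx[0]), int(idx[-1])
        # the true boundaries lie between the last out-of-band and first
        # in-band frame; the midpoint convention adds half a frame per side
        duration = float(t[b_in] - t[a_in]) + dt
        if not duration > min_pause_s:
            continue
        if b_in >= n - 2:
            continue  # terminal plateau
        if float(np.max(bp[b_in:]) - level) < min_post_advance_bp:
            continue
        # robust dwell slope over the interior: entry/exit frames are
        # still partly moving and would bias the slope upward.  The
        # threshold carries a one-floor margin because the pairwise-median
        # slope of a genuinely flat dwell fluctuates by a sizeable
        # fraction of the floor at this noise level; candidates that pass
        # here still face the flank-offset test, which is the decisive
        # arbiter for slow translocation.
        if b_in - a_in >= 5:
            slope = _theil_sen_slope(t, bp, a_in + 1, b_in - 1)
            if slope >= 2.0 * rate_floor_bp_s:
                continue
        if not _offset_consistent(
            t, bp, a_in, b_in, flank_frames, rate_floor_bp_s, min_pause_s,
            duration - dt,  # conservative dwell span for the expected delay
        ):
            continue
        pos = float(np.clip(level, 0.0, traj.substrate_length_bp or np.inf))
        near = barrier_bp is not None and abs(pos - float(barrier_bp)) <= float(barrier_window_bp)
        pauses.append(
            Pause(
                start_s=float(t[a_in]) - 0.5 * dt,
                end_s=float(t[b_in]) + 0.5 * dt,
                position_bp=pos,
                near_barrier=near,
            )
        )
    return pauses


def _offset_consistent(
    t: np.ndarray,
    bp: np.ndarray,
    a_in: int,
    b_in: int,
    flank_frames: int,
    rate_floor_bp_s: float,
    min_pause_s: float,
    duration: float,
) -> bool:
    """Check that the flanks of a candidate pause are time-offset.

    Lines are fitted to the trajectory just before and just after the
    candidate; the vertical offset between them at the candidate midpoint,
    divided by the molecule's own advance rate, estimates how long the
    molecule was delayed.  A real pause delays the downstream trajectory
    by its duration; a noise excursion leaves the lines collinear.  The
    offset must exceed the delay expected of a pause half as long as the
    dwell span by a margin set by the lines' extrapolation error.  A
    candidate whose flank cannot be fitted (fewer than 4 frames of
    trajectory on either side) is rejected: it cannot be told apart from
    an acquisition-boundary artefact.
    """
    n = len(t)
    pre_lo, pre_hi = max(a_in - flank_frames, 0), a_in - 1
    post_lo, post_hi = b_in + 1, min(b_in + flank_frames, n - 1)
    if pre_hi - pre_lo < 3 or post_hi - post_lo < 3:
        return False

    def line(lo: int, hi: int, at: float) -> tuple[float, float]:
        slope, _ = _interval_slope(t, bp, lo, hi)
        tw = t[lo : hi + 1]
        bw = bp[lo : hi + 1]
        tc = tw - tw.mean()
        pred = float(bw.mean() + slope * (at - tw.mean()))
        resid = bw - bw.mean() - slope * tc
        s2 = float(np.sum(resid**2)) / max(len(tw) - 2, 1)
        var = s2 * (1.0 / len(tw) + (at - tw.mean()) ** 2 / float(np.dot(tc, tc)))
        return pred, var, slope

    t_mid = 0.5 * (t[a_in] + t[b_in])
    pre_at_mid, pre_var, slope_pre = line(pre_lo, pre_hi, t_mid)
    post_at_mid, post_var, slope_post = line(post_lo, post_hi, t_mid)
    offset_bp = pre_at_mid - post_at_mid
    sigma = np.sqrt(pre_var + post_var)
    v_hat = max(0.5 * (slope_pre + slope_post), 1.5 * rate_floor_bp_s)
    # short candidates never see the dwell-slope test, so they must clear
    # a stricter significance margin here
    z = 2.0 if b_in - a_in < 5 else 1.64
    required = v_hat * max(0.5 * min_pause_s, 0.5 * duration) + z * sigma
    return offset_bp >= required


# --------------------------------------------------------------------------
# rates and pause-duration statistics


def estimate_rate(traj: Trajectory, interval: tuple[float, float] | None = None) -> float:
    """Least-squares unwinding rate (bp/s) over a time interval.

    The caller is responsible for excising pauses; the interval must
    contain at least 5 frames.
    """
    t = np.asarray(traj.times_s, dtype=float)
    bp = np.asarray(traj.bp, dtype=float)
    if interval is not None:
        mask = (t >= interval[0]) & (t <= interval[1])
        t, bp = t[mask], bp[mask]
    if len(t) < 5:
        raise ValueError("interval too short: need at least 5 frames")
    tc = t - t.mean()
    return float(np.dot(tc, bp - bp.mean()) / np.dot(tc, tc))


def fit_pause_durations(
    durations_s: Iterable[float],
    min_pause_s: float = MIN_PAUSE_S,
) -> PauseDurationFit:
    """Single-exponential mean pause duration, corrected for truncation.

    Detected pauses are left-truncated at the ``min_pause_s`` threshold.
    For an exponential law the excess over the threshold is again
    exponential (memorylessness), so the maximum-likelihood mean is the
    sample mean minus the threshold; its standard error is mean/sqrt(n).
    Returns (mean, SE) in minutes.
    """
    d = np.asarray(list(durations_s), dtype=float)
    if len(d) < 5:
        raise ValueError("need at least 5 pause durations to fit")
    if np.any(d < min_pause_s - 1e-9):
        raise ValueError("durations below the detection threshold are not fittable")
    mean_s = float(np.mean(d)) - min_pause_s
    se_s = mean_s / np.sqrt(len(d))
    return PauseDurationFit(mean_min=mean_s / 60.0, se_min=se_s / 60.0)


def pause_duration_histogram(
    durations_s: Iterable[float],
    bin_width_min: float = 1.0,
) -> pd.DataFrame:
    """Histogram of pause durations (minutes), ready for plotting/export."""
    d = np.asarray(list(durations_s), dtype=float) / 60.0
    edges = np.arange(0.0, d.max() + bin_width_min, bin_width_min)
    counts, edges = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_left_min": edges[:-1], "bin_right_min": edges[1:], "count": counts}
    )


# --------------------------------------------------------------------------
# per-trace classification and population summaries


def _pause_excised_rate(
    traj: Trajectory, pauses: Sequence[Pause], excise_pauses: bool = True
) -> float | None:
    """Advance rate over the moving part of a trajectory.

    A pause time-shifts the downstream trajectory, so a single line
    through the surviving frames would under-estimate the speed; instead
    each inter-pause segment is fitted separately and the slopes are
    combined weighted by segment span.  With ``excise_pauses`` off the
    single-line fit (rate averaged through the pause) is returned.
    """
    L = traj.substrate_length_bp
    t, bp = traj.times_s, traj.bp
    mask = np.ones(len(t), dtype=bool)
    if L is not None:
        mask &= (bp >= 0.02 * L) & (bp <= 0.98 * L)
    dt = traj.frame_interval_s

    def slope_of(sel: np.ndarray) -> float | None:
        if sel.sum() < 5:
            return None
        tc = t[sel] - t[sel].mean()
        return float(np.dot(tc, bp[sel] - bp[sel].mean()) / np.dot(tc, tc))

    if not excise_pauses or not pauses:
        return slope_of(mask)

    bounds = [t[0] - dt]
    for p in sorted(pauses, key=lambda p: p.start_s):
        bounds.extend([p.start_s - dt, p.end_s + dt])
    bounds.append(t[-1] + dt)
    slopes, weights = [], []
    for lo, hi in zip(bounds[::2], bounds[1::2]):
        sel = mask & (t >= lo) & (t <= hi)
        s = slope_of(sel)
        if s is not None:
            slopes.append(s)
            weights.append(float(t[sel][-1] - t[sel][0]))
    if not slopes:
        return None
    return float(np.average(slopes, weights=weights))


def analyze_trace(
    trace: Trace,
    substrate_length_bp: int,
    barrier_bp: int | None = None,
    intensity_per_bp: float | None = None,
    min_pause_s: float = MIN_PAUSE_S,
    rate_floor_bp_s: float = RATE_FLOOR_BP_S,
    barrier_window_bp: int = BARRIER_WINDOW_BP,
    excise_pauses: bool = True,
) -> TraceResult:
    """Classify one molecule and extract its pauses and rates.

    Classification: a detected completion gives ``completed`` (or
    ``paused_then_completed`` if pauses were called); a censored completion
    whose terminal plateau (local rate below the floor over the last
    frames) sits within the barrier window gives ``stalled``; anything
    else — still advancing at the end of acquisition, or a plateau away
    from the barrier — is ``ambiguous``.

    ``excise_pauses`` controls whether ``rate_bp_s`` excludes the pause
    interval (default, so post-block rates compare cleanly with
    unadducted molecules) or averages straight through it.
    """
    completion = detect_completion(trace)
    try:
        traj = calibrate_trace(
            trace, substrate_length_bp,
            intensity_per_bp=intensity_per_bp,
            completion_time_s=completion,
        )
    except ValueError:
        return TraceResult(molecule_id=trace.molecule_id, classification="ambiguous")
    try:
        pauses = detect_pauses(
            traj,
            min_pause_s=min_pause_s,
            rate_floor_bp_s=rate_floor_bp_s,
            barrier_bp=barrier_bp,
            barrier_window_bp=barrier_window_bp,
        )
    except ValueError:
        pauses = []

    rate = _pause_excised_rate(traj, pauses, excise_pauses=excise_pauses)
    rate_pre = rate_post = None
    if pauses:
        first, last = pauses[0], pauses[-1]
        dt = traj.frame_interval_s
        try:
            rate_pre = estimate_rate(traj, (traj.times_s[0], first.start_s - dt))
        except ValueError:
            pass
        try:
            rate_post = estimate_rate(traj, (last.end_s + dt, traj.times_s[-1]))
        except ValueError:
            pass
    else:
        rate_pre = rate_post = rate

    if completion is not None:
        cls = "paused_then_completed" if pauses else "completed"
        return TraceResult(
            molecule_id=trace.molecule_id,
            classification=cls,
            pauses=tuple(pauses),
            rate_bp_s=rate,
            rate_pre_bp_s=rate_pre,
            rate_post_bp_s=rate_post,
            completion_time_s=completion,
        )

    # censored: stalled only if the trace ends in a plateau at the barrier
    cls = "ambiguous"
    k = min(_TERMINAL_WINDOW_FRAMES, len(traj.times_s))
    if k >= 5 and barrier_bp is not None:
        try:
            terminal_rate = estimate_rate(traj, (traj.times_s[-k], traj.times_s[-1]))
            terminal_pos = float(np.median(traj.bp[-k:]))
            if terminal_rate < rate_floor_bp_s and abs(terminal_pos - barrier_bp) <= barrier_window_bp:
                cls = "stalled"
        except ValueError:
            pass
    return TraceResult(
        molecule_id=trace.molecule_id,
        classification=cls,
        pauses=tuple(pauses),
        rate_bp_s=rate,
        rate_pre_bp_s=rate_pre,
        rate_post_bp_s=rate_post,
        completion_time_s=None,
    )


def analyze_traces(
    traces: Sequence[Trace],
    substrate_length_bp: int,
    barrier_bp: int | None = None,
    min_pause_s: float = MIN_PAUSE_S,
    rate_floor_bp_s: float = RATE_FLOOR_BP_S,
    barrier_window_bp: int = BARRIER_WINDOW_BP,
    excise_pauses: bool = True,
) -> tuple[list[TraceResult], PopulationSummary]:
    """Run the full pipeline on a batch sharing one imaging condition.

    The intensity scale is calibrated once per batch from the molecules
    that completed (their pre-drop plateau equals the full substrate), so
    stalled molecules are placed correctly on the bp axis.
    """
    if len(traces) == 0:
        raise ValueError("empty trace batch")
    scale = batch_intensity_scale(traces, substrate_length_bp)
    results = [
        analyze_trace(
            tr, substrate_length_bp,
            barrier_bp=barrier_bp,
            intensity_per_bp=scale,
            min_pause_s=min_pause_s,
            rate_floor_bp_s=rate_floor_bp_s,
            barrier_window_bp=barrier_window_bp,
            excise_pauses=excise_pauses,
        )
        for tr in traces
    ]
    summary = summarize_population(results, min_pause_s=min_pause_s)
    return results, summary


def summarize_population(
    results: Sequence[TraceResult],
    barrier: BarrierSpec | None = None,
    min_pause_s: float = MIN_PAUSE_S,
) -> PopulationSummary:
    """Aggregate per-molecule results into population statistics.

    ``frac_paused`` counts molecules with at least one near-barrier pause
    (any pause if no barrier position was supplied to the per-trace
    analysis); ambiguous molecules are counted and reported, never
    dropped.  The mean +/- SD rate is over fully unwound molecules
    (pause intervals excised).  Pause durations are pooled into a
    truncation-corrected exponential fit when at least 5 are available.
    """
    if len(results) == 0:
        raise ValueError("empty result list")
    n = len(results)
    completed = [r for r in results if r.classification in ("completed", "paused_then_completed")]
    stalled = [r for r in results if r.classification == "stalled"]
    ambiguous = [r for r in results if r.classification == "ambiguous"]

    # if any pause in the batch was annotated against a barrier position,
    # "paused" means a near-barrier pause; otherwise any pause counts
    any_near = any(p.near_barrier for r in results for p in r.pauses)
    paused = [
        r for r in results
        if (any(p.near_barrier for p in r.pauses) if any_near else bool(r.pauses))
    ]

    rates = np.array([r.rate_bp_s for r in completed if r.rate_bp_s is not None])
    durations = [p.duration_s for r in results for p in r.pauses]
    pause_fit = None
    if len(durations) >= 5:
        pause_fit = fit_pause_durations(durations, min_pause_s=min_pause_s)

    return PopulationSummary(
        n_total=n,
        n_completed=len(completed),
        n_paused=len(paused),
        n_stalled=len(stalled),
        n_ambiguous=len(ambiguous),
        frac_completed=len(completed) / n,
        frac_paused=len(paused) / n,
        frac_stalled=len(stalled) / n,
        frac_ambiguous=len(ambiguous) / n,
        mean_rate_bp_s=float(np.mean(rates)) if len(rates) else None,
        sd_rate_bp_s=float(np.std(rates, ddof=1)) if len(rates) > 1 else None,
        pause_fit=pause_fit,
        n_pauses=len(durations),
        metadata={"barrier": barrier},
    )
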