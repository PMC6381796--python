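"""Stochastic simulation of helicase-mediated DNA unwinding.

Generates per-molecule unwinding trajectories and ensemble fluorescence
curves with the statistical structure assumed by the analysis modules:

* per-molecule unwinding rates drawn from a truncated-normal population
  distribution (moment-matched so the realised mean/SD equal the configured
  values);
* strand-specific protein barriers that either arrest the helicase
  permanently (leading-strand block), insert an exponentially distributed
  pause (lagging-strand duplex-stabilising block), or have no effect
  (transparent lagging-strand block);
* a fluorescence read-out proportional to unwound base pairs (ssDNA-binding
  protein accumulation) with additive Gaussian noise and a multiplicative
  signal drop when unwinding completes and the untethered strand is
  released;
* ensemble completion times following an Erlang(m, k_obs) law, i.e. the sum
  of m sequential exponential steps.

Every simulated object carries a ground-truth channel so analysis output
can be scored against the latent trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BarrierSpec",
    "HelicaseParams",
    "SimConfig",
    "TraceTruth",
    "Trace",
    "EnsembleCurve",
    "simulate_trace",
    "simulate_traces",
    "simulate_ensemble",
    "sample_completion_times",
]

#: Minimum physically sensible per-molecule rate; the population rate
#: distribution is truncated below this floor (bp/s).
RATE_FLOOR_BP_S = 0.5

_LEADING = "leading"
_LAGGING = "lagging"
_MECHANISMS = ("arrest", "transparent", "pause")


@dataclass(frozen=True)
class BarrierSpec:
    """A site-specific protein block on one strand of the substrate.

    Parameters
    ----------
    position_bp:
        Distance of the block from the 3' ssDNA loading tail, in base
        pairs.
    strand:
        ``"leading"`` (the strand the helicase tracks on) or ``"lagging"``
        (the displaced strand).
    mechanism:
        ``"arrest"`` — permanent halt at the block (leading strand only);
        ``"pause"`` — transient, exponentially distributed pause (lagging
        strand, duplex-stabilising block); ``"transparent"`` — no effect
        on translocation (lagging strand).
    occupancy:
        Fraction of substrate molecules that actually carry the block
        (crosslinking is never 100% efficient).
    """

    position_bp: int
    strand: str
    mechanism: str
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.position_bp <= 0:
            raise ValueError("barrier position must be positive")
        if self.strand not in (_LEADING, _LAGGING):
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "arrest" and self.strand != _LEADING:
            raise ValueError("arrest blocks act on the leading (tracking) strand")
        if self.mechanism in ("pause", "transparent") and self.strand != _LAGGING:
            raise ValueError(f"{self.mechanism} blocks act on the lagging strand")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class HelicaseParams:
    """Kinetic parameters of the helicase population.

    ``rate_mean``/``rate_sd`` are the mean and SD (bp/s) of the
    *realised* per-molecule rate distribution (truncated normal, floor
    ``RATE_FLOOR_BP_S``).  ``pause_mean_duration`` (s) is the mean of the
    exponential pause-length distribution at a duplex-stabilising block and
    ``pause_probability`` the chance that a block-bearing molecule pauses
    discernibly.  ``m_steps`` and ``k_obs`` (1/min) parameterise the
    ensemble completion-time model: completion is the sum of ``m_steps``
    sequential exponential steps with observed rate constant ``k_obs``
    (an Erlang law).
    """

    rate_mean: float = 8.2
    rate_sd: float = 4.2
    pause_mean_duration: float = 4.63 * 60.0
    pause_probability: float = 0.26
    m_steps: int = 2
    k_obs: float = 0.2

    def __post_init__(self) -> None:
        if self.rate_mean <= 0:
            raise ValueError("rate_mean must be positive")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be non-negative")
        if self.pause_mean_duration < 0:
            raise ValueError("pause_mean_duration must be non-negative")
        if not 0.0 <= self.pause_probability <= 1.0:
            raise ValueError("pause_probability must lie in [0, 1]")
        if self.m_steps < 1:
            raise ValueError("m_steps must be a positive integer")
        if self.k_obs <= 0:
            raise ValueError("k_obs must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Observation geometry and read-out model for a simulated experiment.

    ``noise_sd`` is the per-frame additive Gaussian noise expressed as a
    fraction of the full-scale signal (the intensity of a fully unwound
    substrate for traces; the plateau of an ensemble curve).
    ``drop_factor`` is the fraction of intensity retained after completion,
    when the released strand takes its share of bound fluorescent protein
    with it.  ``stepping`` selects how the helicase advances between
    frames: ``"continuous"`` (default; single-bp stochasticity is far
    below the frame noise at 10-s framing) or ``"gillespie"``
    (exponential per-bp waiting times, for property tests of the
    continuous approximation).
    """

    substrate_length_bp: int = 2700
    frame_interval_s: float = 10.0
    duration_s: float = 2400.0
    noise_sd: float = 0.02
    drop_factor: float = 0.5
    intensity_per_bp: float = 1.0
    stepping: str = "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stepping not in ("continuous", "gillespie"):
            raise ValueError("stepping must be 'continuous' or 'gillespie'")
        if self.substrate_length_bp <= 0:
            raise ValueError("substrate_length_bp must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.duration_s < self.frame_interval_s:
            raise ValueError("duration_s must cover at least one frame")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.drop_factor < 1.0:
            raise ValueError("drop_factor must lie in (0, 1)")
        if self.intensity_per_bp <= 0:
            raise ValueError("intensity_per_bp must be positive")

    @property
    def frame_times(self) -> np.ndarray:
        n = int(math.floor(self.duration_s / self.frame_interval_s)) + 1
        return np.arange(n) * self.frame_interval_s


@dataclass(frozen=True)
class TraceTruth:
    """Latent ground truth of one simulated trace."""

    rate_bp_s: float
    barrier_present: bool
    unwound_bp: np.ndarray
    pause_start_s: float | None = None
    pause_end_s: float | None = None
    completion_time_s: float | None = None

    @property
    def pause_duration_s(self) -> float | None:
        if self.pause_start_s is None or self.pause_end_s is None:
            return None
        return self.pause_end_s - self.pause_start_s


@dataclass(frozen=True)
class Trace:
    """One molecule's intensity time series (and, if simulated, its truth)."""

    molecule_id: int | str
    times_s: np.ndarray
    intensity: np.ndarray
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1 or len(t) != len(self.intensity):
            raise ValueError("times and intensity must be 1-D and equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class EnsembleCurve:
    """Bulk unwinding signal versus time.

    ``signal`` is either raw (arbitrary units) or normalized to the model
    scale where 0 is the pre-unwinding baseline and 1 the plateau.
    """

    times_s: np.ndarray
    signal: np.ndarray
    normalized: bool = False
    n_molecules: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1 or len(t) != len(self.signal):
            raise ValueError("times and signal must be 1-D and equal length")

    @property
    def times_min(self) -> np.ndarray:
        return np.asarray(self.times_s, dtype=float) / 60.0


# --------------------------------------------------------------------------
# rate distribution


@lru_cache(maxsize=32)
def _truncnorm_parent(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose truncation at ``floor`` has the target moments.

    The population rate distribution is specified by its realised mean and
    SD; because the distribution is truncated below at the rate floor, the
    parent normal parameters must be solved for rather than used directly.
    """
    if sd == 0:
        return max(mean, floor), 0.0
    # if the floor is far in the lower tail, truncation is negligible
    if (floor - mean) / sd < -8.0:
        return mean, sd

    def moments(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a = (floor - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.root(moments, x0=np.array([mean, math.log(sd)]), method="hybr")
    if not sol.success:  # pragma: no cover - hybr converges for sane inputs
        raise RuntimeError(f"rate-distribution moment matching failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _draw_rate(params: HelicaseParams, rng: np.random.Generator) -> float:
    mu, sigma = _truncnorm_parent(params.rate_mean, params.rate_sd, RATE_FLOOR_BP_S)
    if sigma == 0:
        return mu
    a = (RATE_FLOOR_BP_S - mu) / sigma
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng))


# --------------------------------------------------------------------------
# single-molecule trajectories


def _molecule_rngs(seed: int, molecule_id: int) -> tuple[np.random.Generator, ...]:
    # Independent streams per purpose so that a mechanistically inert
    # barrier (transparent, or occupancy draws) cannot perturb the rate or
    # noise streams: transparent-barrier traces are bit-identical to
    # no-barrier traces under the same seed.
    ss = np.random.SeedSequence([seed, molecule_id])
    return tuple(np.random.default_rng(c) for c in ss.spawn(3))


def _latent_trajectory(
    v: float,
    length_bp: float,
    barrier: BarrierSpec | None,
    present: bool,
    pausing: bool,
    pause_duration_s: float,
    times: np.ndarray,
):
    """Piecewise-linear unwound-bp trajectory evaluated at frame times."""
    pause_start = pause_end = completion = None
    if barrier is not None and present and barrier.mechanism == "arrest":
        bp = np.minimum(v * times, float(barrier.position_bp))
    elif barrier is not None and present and barrier.mechanism == "pause" and pausing:
        t_hit = barrier.position_bp / v
        pause_start = t_hit
        pause_end = t_hit + pause_duration_s
        shifted = np.where(
            times < t_hit, v * times,
            np.where(times < pause_end, float(barrier.position_bp),
                     barrier.position_bp + v * (times - pause_end)),
        )
        bp = np.minimum(shifted, length_bp)
        completion = (length_bp - barrier.position_bp) / v + pause_end
    else:
        bp = np.minimum(v * times, length_bp)
        completion = length_bp / v
    if completion is not None and completion > times[-1]:
        completion = None  # censored: not observed within the acquisition
    return bp, pause_start, pause_end, completion


def _gillespie_trajectory(
    v: float,
    length_bp: float,
    barrier: BarrierSpec | None,
    present: bool,
    pausing: bool,
    pause_duration_s: float,
    times: np.ndarray,
    rng: np.random.Generator,
):
    """Single-bp stochastic stepping: exponential waiting time per bp."""
    arrivals = np.cumsum(rng.exponential(1.0 / v, size=int(length_bp)))
    pause_start = pause_end = None
    cap = int(length_bp)
    if barrier is not None and present and barrier.mechanism == "arrest":
        cap = int(barrier.position_bp)
    elif barrier is not None and present and barrier.mechanism == "pause" and pausing:
        pos = int(barrier.position_bp)
        pause_start = float(arrivals[pos - 1])
        pause_end = pause_start + pause_duration_s
        arrivals[pos:] += pause_duration_s
    bp = np.minimum(np.searchsorted(arrivals, times, side="right"), cap).astype(float)
    completion = float(arrivals[-1]) if cap == int(length_bp) else None
    if completion is not None and completion > times[-1]:
        completion = None
    return bp, pause_start, pause_end, completion


def simulate_trace(
    params: HelicaseParams,
    barrier: BarrierSpec | None,
    config: SimConfig,
    molecule_id: int = 0,
) -> Trace:
    """Simulate one molecule's unwinding trace.

    The per-molecule rate ``v`` is drawn from the truncated-normal
    population distribution and the helicase advances deterministically at
    ``v`` between frames.  A barrier carried by the molecule
    (Bernoulli(occupancy)) acts according to its mechanism when unwinding
    reaches its position.  Intensity is ``intensity_per_bp * unwound_bp``
    plus per-frame Gaussian noise; after completion the deterministic part
    is multiplied by ``drop_factor``.
    """
    if barrier is not None and barrier.position_bp >= config.substrate_length_bp:
        raise ValueError("barrier position must lie inside the substrate")
    rate_rng, barrier_rng, noise_rng = _molecule_rngs(config.seed, molecule_id)
    v = _draw_rate(params, rate_rng)

    present = pausing = False
    pause_duration = 0.0
    if barrier is not None:
        present = bool(barrier_rng.random() < barrier.occupancy)
        if barrier.mechanism == "pause":
            # drawn unconditionally to keep the stream layout fixed
            pausing = bool(barrier_rng.random() < params.pause_probability)
            pause_duration = float(barrier_rng.exponential(params.pause_mean_duration))
        if barrier.mechanism == "transparent":
            present = False  # mechanistically inert

    times = config.frame_times
    L = float(config.substrate_length_bp)
    if config.stepping == "gillespie":
        bp, pause_start, pause_end, completion = _gillespie_trajectory(
            v, L, barrier, present, pausing, pause_duration, times, rate_rng
        )
    else:
        bp, pause_start, pause_end, completion = _latent_trajectory(
            v, L, barrier, present, pausing, pause_duration, times
        )

    signal = config.intensity_per_bp * bp
    if completion is not None:
        signal = np.where(times >= completion, config.intensity_per_bp * L * config.drop_factor, signal)
    full_scale = config.intensity_per_bp * L
    noise = noise_rng.normal(0.0, config.noise_sd * full_scale, size=len(times))
    intensity = signal + noise

    truth = TraceTruth(
        rate_bp_s=v,
        barrier_present=present,
        unwound_bp=bp,
        pause_start_s=pause_start,
        pause_end_s=pause_end,
        completion_time_s=completion,
    )
    return Trace(molecule_id=molecule_id, times_s=times, intensity=intensity, truth=truth)


def simulate_traces(
    params: HelicaseParams,
    barrier: BarrierSpec | None,
    n: int,
    config: SimConfig,
) -> list[Trace]:
    """Simulate a batch of ``n`` independent molecules (ids 0..n-1)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return [simulate_trace(params, barrier, config, molecule_id=i) for i in range(n)]


# --------------------------------------------------------------------------
# ensemble curves


def sample_completion_times(
    params: HelicaseParams,
    barrier: BarrierSpec | None,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` molecule completion times (seconds; inf = never completes).

    Each completion time is the sum of ``m_steps`` exponential waiting
    times with rate ``k_obs`` (Erlang model), plus an exponential pause for
    block-bearing, pausing molecules; molecules carrying an arrest block
    never complete.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    k_per_s = params.k_obs / 60.0
    t = rng.gamma(shape=params.m_steps, scale=1.0 / k_per_s, size=n)
    if barrier is not None and barrier.mechanism != "transparent":
        present = rng.random(n) < barrier.occupancy
        if barrier.mechanism == "arrest":
            t = np.where(present, np.inf, t)
        else:  # pause
            pausing = present & (rng.random(n) < params.pause_probability)
            pauses = rng.exponential(params.pause_mean_duration, size=n)
            t = t + np.where(pausing, pauses, 0.0)
    return t


def simulate_ensemble(
    params: HelicaseParams,
    barrier: BarrierSpec | None,
    n: int,
    config: SimConfig,
) -> EnsembleCurve:
    """Simulate a bulk unwinding curve from ``n`` molecules.

    The signal at each frame is the fraction of molecules whose completion
    time has elapsed, plus per-frame Gaussian noise of SD
    ``config.noise_sd`` (fractions of the unit plateau).  With no barrier
    and no noise the expected curve is the Erlang(m_steps, k_obs) CDF.
    """
    ss = np.random.SeedSequence([config.seed, 1_000_003])
    draw_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    completions = sample_completion_times(params, barrier, n, draw_rng)
    times = config.frame_times
    signal = (completions[None, :] <= times[:, None]).mean(axis=1)
    if config.noise_sd > 0:
        signal = signal + noise_rng.normal(0.0, config.noise_sd, size=len(times))
    return EnsembleCurve(
        times_s=times,
        signal=signal,
        normalized=config.noise_sd == 0,
        n_molecules=n,
        metadata={"seed": config.seed, "m_steps": params.m_steps, "k_obs": params.k_obs},
    )
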