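"""Default experimental conditions for the three standard substrates.

The single-molecule assay uses a 2.7-kb linear duplex with a 3' ssDNA
loading tail, imaged at 10-s frame intervals for ~40 min.  The helicase
population unwinds at 8.2 +/- 4.2 bp/s.  The lagging-strand
methyltransferase block (MH-lag, a duplex-stabilising crosslink ~800 bp
from the loading tail) produces a discernible pause (mean 4.63 min) in
26% of molecules; the same block on the leading strand (MH-lead) arrests
the helicase permanently, observed on 80% of molecules.  How the 26%
splits between crosslinking occupancy and pause penetrance is not
resolved experimentally; here occupancy defaults to 1 and the pause
probability carries the full 26%, and the two can be varied
independently.
"""

from __future__ import annotations

import numpy as np

from .simulate import BarrierSpec, HelicaseParams, SimConfig

__all__ = [
    "RATE_MEAN_BP_S",
    "RATE_SD_BP_S",
    "PAUSE_MEAN_S",
    "PAUSE_FRACTION",
    "LEAD_BLOCK_OCCUPANCY",
    "BARRIER_POSITION_BP",
    "SUBSTRATE_LENGTH_BP",
    "MIN_PAUSE_S",
    "FRAME_INTERVAL_S",
    "DURATION_S",
    "unadducted",
    "mh_lagging",
    "mh_leading",
]

RATE_MEAN_BP_S = 8.2
RATE_SD_BP_S = 4.2
PAUSE_MEAN_S = 4.63 * 60.0
#: Observed fraction of molecules with a discernible (> 30 s) pause.
DISCERNIBLE_PAUSE_FRACTION = 0.26
#: Latent per-molecule pausing probability: the observed fraction counts
#: only pauses longer than the 30-s detection threshold, so the latent
#: probability is the observed one divided by P(duration > threshold)
#: under the exponential pause-length law.
PAUSE_FRACTION = DISCERNIBLE_PAUSE_FRACTION / float(np.exp(-30.0 / PAUSE_MEAN_S))
LEAD_BLOCK_OCCUPANCY = 0.8
BARRIER_POSITION_BP = 800
SUBSTRATE_LENGTH_BP = 2700
MIN_PAUSE_S = 30.0
FRAME_INTERVAL_S = 10.0
DURATION_S = 2400.0


def _params() -> HelicaseParams:
    return HelicaseParams(
        rate_mean=RATE_MEAN_BP_S,
        rate_sd=RATE_SD_BP_S,
        pause_mean_duration=PAUSE_MEAN_S,
        pause_probability=PAUSE_FRACTION,
    )


def _config(seed: int, duration_s: float) -> SimConfig:
    return SimConfig(
        substrate_length_bp=SUBSTRATE_LENGTH_BP,
        frame_interval_s=FRAME_INTERVAL_S,
        duration_s=duration_s,
        seed=seed,
    )


def unadducted(seed: int = 0, duration_s: float = DURATION_S):
    """No-barrier substrate: (params, None, config)."""
    return _params(), None, _config(seed, duration_s)


def mh_lagging(seed: int = 0, duration_s: float = DURATION_S):
    """Lagging-strand duplex-stabilising block at 800 bp: (params, barrier, config)."""
    barrier = BarrierSpec(
        position_bp=BARRIER_POSITION_BP,
        strand="lagging",
        mechanism="pause",
        occupancy=1.0,
    )
    return _params(), barrier, _config(seed, duration_s)


def mh_leading(seed: int = 0, duration_s: float = DURATION_S):
    """Leading-strand arrest block at 800 bp, 80% occupancy: (params, barrier, config)."""
    barrier = BarrierSpec(
        position_bp=BARRIER_POSITION_BP,
        strand="leading",
        mechanism="arrest",
        occupancy=LEAD_BLOCK_OCCUPANCY,
    )
    return _params(), barrier, _config(seed, duration_s)
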