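"""Band-intensity arithmetic for gel-based unwinding assays.

Operates on band-intensity tables (lane id, band label, intensity,
optional background) exported from gel-quantification software; image
linearisation and ROI extraction are upstream of this module.  The central
quantity is the background-corrected fraction of signal in a set of bands,
e.g. percent of substrate unwound = unwound-strand band over (unwound +
intact fork) bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["Lane", "band_fraction", "percent_unwound_series", "aggregate_replicates", "lanes_from_frame"]


@dataclass(frozen=True)
class Lane:
    """One gel lane: labelled band intensities plus background.

    ``background`` is either a scalar applied to every band or a
    per-band mapping (local background).
    """

    lane_id: str
    bands: Mapping[str, float]
    background: float | Mapping[str, float] = 0.0
    condition: str | float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in self.bands.items():
            if value < 0:
                raise ValueError(f"band {label!r} has negative intensity")

    def corrected(self, label: str) -> float:
        if label not in self.bands:
            raise KeyError(f"band {label!r} missing from lane {self.lane_id!r}")
        bg = self.background[label] if isinstance(self.background, Mapping) else self.background
        value = self.bands[label] - bg
        if value < 0:
            warnings.warn(
                f"background exceeds band {label!r} in lane {self.lane_id!r}; clipping to 0",
                stacklevel=2,
            )
            value = 0.0
        return value


def band_fraction(
    lane: Lane,
    numerator: Sequence[str],
    denominator: Sequence[str],
) -> float:
    """Percent of background-corrected signal in the numerator bands.

    ``100 * sum(numerator - bg) / sum(denominator - bg)``; scale-invariant
    under uniform rescaling of intensities and background.
    """
    num = sum(lane.corrected(label) for label in numerator)
    den = sum(lane.corrected(label) for label in denominator)
    if den <= 0:
        raise ValueError(f"denominator bands sum to zero in lane {lane.lane_id!r}")
    return 100.0 * num / den


def percent_unwound_series(
    lanes: Sequence[Lane],
    numerator: Sequence[str],
    denominator: Sequence[str],
    replicate: str | int | None = None,
) -> pd.DataFrame:
    """Apply :func:`band_fraction` across lanes of one gel.

    All lanes must share the band scheme.  Returns a tidy table
    (lane_id, condition, percent, replicate) ready for mean +/- SD
    aggregation across replicate gels.
    """
    if len(lanes) == 0:
        raise ValueError("no lanes supplied")
    schemes = {frozenset(lane.bands) for lane in lanes}
    needed = set(numerator) | set(denominator)
    for scheme in schemes:
        if not needed <= scheme:
            raise ValueError("inconsistent band scheme across lanes")
    rows = [
        {
            "lane_id": lane.lane_id,
            "condition": lane.condition,
            "percent": band_fraction(lane, numerator, denominator),
            "replicate": replicate,
        }
        for lane in lanes
    ]
    return pd.DataFrame(rows)


def aggregate_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SD of percent unwound per condition across replicate gels.

    Input tables are outputs of :func:`percent_unwound_series` (one per
    replicate); conditions must match across replicates.
    """
    if len(tables) == 0:
        raise ValueError("no replicate tables supplied")
    pooled = pd.concat(tables, ignore_index=True)
    out = (
        pooled.groupby("condition", dropna=False, sort=False)["percent"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def lanes_from_frame(frame: pd.DataFrame) -> list[Lane]:
    """Build lanes from a long-format table.

    Expected columns: ``lane_id``, ``band_label``, ``intensity``; optional
    ``background`` (per band) and ``condition``.
    """
    required = {"lane_id", "band_label", "intensity"}
    if not required <= set(frame.columns):
        raise ValueError(f"lane table needs columns {sorted(required)}")
    lanes = []
    for lane_id, group in frame.groupby("lane_id", sort=False):
        bands = dict(zip(group["band_label"], group["intensity"]))
        background: float | dict = 0.0
        if "background" in group:
            background = dict(zip(group["band_label"], group["background"]))
        condition = None
        if "condition" in group:
            condition = group["condition"].iloc[0]
        lanes.append(Lane(lane_id=str(lane_id), bands=bands, background=background, condition=condition))
    return lanes
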