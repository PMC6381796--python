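"""Reading and writing the package's plain-text interchange formats.

Trace batches travel as long-format CSV (molecule_id, time_s, intensity)
with an optional truth sidecar TSV; ensemble curves as two-column CSV
(time_s, signal); configurations as YAML or JSON files covering the
simulation parameter types.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .simulate import BarrierSpec, HelicaseParams, SimConfig, EnsembleCurve, Trace

__all__ = [
    "traces_to_frame",
    "frame_to_traces",
    "write_traces",
    "read_traces",
    "truth_to_frame",
    "write_curve",
    "read_curve",
    "load_config",
]


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    parts = [
        pd.DataFrame(
            {"molecule_id": tr.molecule_id, "time_s": tr.times_s, "intensity": tr.intensity}
        )
        for tr in traces
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame) -> list[Trace]:
    required = {"molecule_id", "time_s", "intensity"}
    if not required <= set(frame.columns):
        raise ValueError(f"trace table needs columns {sorted(required)}")
    traces = []
    for mol_id, group in frame.groupby("molecule_id", sort=False):
        g = group.sort_values("time_s")
        traces.append(
            Trace(
                molecule_id=mol_id,
                times_s=g["time_s"].to_numpy(dtype=float),
                intensity=g["intensity"].to_numpy(dtype=float),
            )
        )
    return traces


def truth_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        if tr.truth is None:
            continue
        rows.append(
            {
                "molecule_id": tr.molecule_id,
                "rate_bp_s": tr.truth.rate_bp_s,
                "barrier_present": tr.truth.barrier_present,
                "pause_start_s": tr.truth.pause_start_s,
                "pause_end_s": tr.truth.pause_end_s,
                "completion_time_s": tr.truth.completion_time_s,
            }
        )
    return pd.DataFrame(rows)


def write_traces(
    traces: Sequence[Trace],
    path: str | Path,
    truth_path: str | Path | None = None,
    seed: int | None = None,
) -> None:
    frame = traces_to_frame(traces)
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)
    if truth_path is not None:
        truth_to_frame(traces).to_csv(truth_path, sep="\t", index=False)


def read_traces(path: str | Path) -> list[Trace]:
    return frame_to_traces(pd.read_csv(path, comment="#"))


def write_curve(curve: EnsembleCurve, path: str | Path, seed: int | None = None) -> None:
    frame = pd.DataFrame({"time_s": curve.times_s, "signal": curve.signal})
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)


def read_curve(path: str | Path, normalized: bool = False) -> EnsembleCurve:
    frame = pd.read_csv(path, comment="#")
    if not {"time_s", "signal"} <= set(frame.columns):
        raise ValueError("curve table needs columns ['time_s', 'signal']")
    return EnsembleCurve(
        times_s=frame["time_s"].to_numpy(dtype=float),
        signal=frame["signal"].to_numpy(dtype=float),
        normalized=normalized,
    )


def load_config(path: str | Path) -> tuple[HelicaseParams, BarrierSpec | None, SimConfig]:
    """Load (params, barrier, config) from a YAML or JSON file.

    Top-level keys ``helicase``, ``barrier`` (optional) and ``sim`` map to
    the field names of the corresponding parameter types.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    params = HelicaseParams(**data.get("helicase", {}))
    barrier = BarrierSpec(**data["barrier"]) if data.get("barrier") else None
    config = SimConfig(**data.get("sim", {}))
    return params, barrier, config
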