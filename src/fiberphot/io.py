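"""File I/O: long-format trace CSVs, TIFF stacks, JSON summaries."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import RawRecording

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_json",
]


def write_traces_csv(recording: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    recording.to_frame().to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path, rate_hz: float | None = None) -> RawRecording:
    df = pd.read_csv(path)
    required = {"time_s", "region", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    traces = {}
    for (region, channel), g in df.groupby(["region", "channel"], sort=True):
        traces[(region, channel)] = g.sort_values("time_s")["value"].to_numpy(float)
    if rate_hz is None:
        t = np.sort(df["time_s"].unique())
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return RawRecording(traces=traces, rate_hz=rate_hz)


def write_tiff_stack(frames: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, frames)
    return path


def read_tiff_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))
    return path
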