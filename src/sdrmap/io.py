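"""Plain-text interchange formats.

Signals travel as wide CSV (a ``time_ms`` column plus one column per
channel, named by the grid's channel-label codec); annotations as a
single CSV holding beats and events; geometry as JSON.  Truth sidecars
accompany synthetic datasets so detectors can be scored, but the
analysis path never reads them.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .grid import MappingGrid, format_label
from .simulate import RhythmRecord

__all__ = [
    "write_signals_csv", "read_signals_csv",
    "write_annotations_csv", "read_annotations_csv",
    "write_blocks_csv", "read_blocks_csv",
    "write_fiducials_csv",
]

FLOAT_FORMAT = "%.6f"


def _label_for(grid: MappingGrid, key: tuple[int, int]) -> str:
    nid, depth = key
    n = grid.needle(nid)
    return format_label(n.wall, n.level, n.column, depth)


def write_signals_csv(path, signals: Mapping[tuple[int, int], np.ndarray],
                      grid: MappingGrid, fs_hz: float) -> None:
    """Write a wide signal CSV: time_ms plus one column per channel."""
    if not signals:
        raise ParameterError("no signals to write")
    lengths = {len(v) for v in signals.values()}
    if len(lengths) != 1:
        raise ParameterError("all channels must share one beat-window length")
    n = lengths.pop()
    data = {"time_ms": np.arange(n) / fs_hz * 1000.0}
    for key in sorted(signals):
        data[_label_for(grid, key)] = np.asarray(signals[key], dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_signals_csv(path, grid: MappingGrid,
                     ) -> tuple[dict[tuple[int, int], np.ndarray], float]:
    """Read a wide signal CSV back into per-channel arrays; the sampling
    rate is recovered from the time column."""
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParameterError("signal file holds fewer than 2 samples")
    fs_hz = 1000.0 / float(np.median(np.diff(t)))
    out = {}
    for col in df.columns:
        if col == "time_ms":
            continue
        addr = grid.address_from_label(col)
        out[addr.key] = df[col].to_numpy(dtype=float)
    return out, fs_hz


def write_annotations_csv(path, rhythm: RhythmRecord) -> None:
    """Beats and events in one stream: columns time_ms, beat_class,
    morphology_index, event_type, block_id."""
    beats = rhythm.beats.copy()
    beats["event_type"] = "beat"
    events = rhythm.events.copy()
    events["beat_class"] = ""
    events["morphology_index"] = np.nan
    cols = ["time_ms", "beat_class", "morphology_index", "event_type",
            "block_id"]
    frames = [f[cols] for f in (beats, events) if len(f)]
    pd.concat(frames, ignore_index=True).sort_values(
        "time_ms", kind="stable").to_csv(path, index=False,
                                         float_format=FLOAT_FORMAT)


def read_annotations_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an annotation CSV back into (beats, events) frames."""
    df = pd.read_csv(path, keep_default_na=False,
                     na_values={"morphology_index": [""]})
    beats = df[df["event_type"] == "beat"][
        ["time_ms", "beat_class", "morphology_index", "block_id"]
    ].reset_index(drop=True)
    events = df[df["event_type"] != "beat"][
        ["time_ms", "event_type", "block_id"]].reset_index(drop=True)
    return beats, events


def write_blocks_csv(path, blocks: pd.DataFrame) -> None:
    blocks.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_blocks_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fiducials_csv(path, rows) -> None:
    """Fiducial table: channel_label, beat_id, at_ms, rt_ms, rtc_ms, qc."""
    pd.DataFrame(rows, columns=["channel_label", "beat_id", "at_ms", "rt_ms",
                                "rtc_ms", "qc"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
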