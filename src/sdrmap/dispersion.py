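"""Spatial dispersion of repolarization (SDR) statistics and polar maps.

SDR is quantified as the average of max-min repolarization-time
differences over spatial *units* in four orientations:

==========  ==========================================================
TRANSMURAL  the (up to) four electrodes of one needle
VERTICAL    the electrodes of two needles adjacent along the
            base-apex axis
HORIZONTAL  the electrodes of two circumferentially adjacent needles
CUBIC       the 16 electrodes of a 2x2 needle square
==========  ==========================================================

Units with too few accepted electrodes after quality control are
dropped, never imputed (minimum 2 electrodes per needle; a pair unit
needs >=4, a cubic unit >=8).  All computations use uncorrected RT at
the fixed paced cycle length of the analysis timepoint; polar maps can
additionally show rate-corrected RT (RTc), which at a fixed RR is a
constant shift and therefore leaves every dispersion value unchanged.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .egm import correct_rt
from .errors import AnalysisError, ParameterError
from .grid import MappingGrid, N_DEPTHS, Wall

__all__ = [
    "SDROrientation",
    "RTField",
    "OrientationResult",
    "SDRSummary",
    "WallSummary",
    "sdr_orientation",
    "sdr_summary",
    "interventricular_drt",
    "wall_summaries",
    "PolarMap",
    "polar_map_export",
    "plot_polar_map",
]


class SDROrientation(enum.Enum):
    TRANSMURAL = "transmural"
    VERTICAL = "vertical"
    HORIZONTAL = "horizontal"
    CUBIC = "cubic"


#: minimum accepted electrodes per needle for that needle to contribute
MIN_PER_NEEDLE = 2
#: minimum accepted electrodes for a unit to be kept, per orientation
MIN_PER_UNIT = {
    SDROrientation.TRANSMURAL: 2,
    SDROrientation.VERTICAL: 4,
    SDROrientation.HORIZONTAL: 4,
    SDROrientation.CUBIC: 8,
}


@dataclass(frozen=True)
class RTField:
    """Per-electrode AT/RT values for one analysis timepoint.

    Values are keyed by (needle_id, depth_index) and are present only
    for electrodes accepted by quality control.
    """

    grid: MappingGrid
    rt_ms: Mapping[tuple[int, int], float]
    at_ms: Optional[Mapping[tuple[int, int], float]] = None
    rr_ms: Optional[float] = None
    timepoint: Optional[str] = None

    @property
    def rtc_ms(self) -> dict[tuple[int, int], float]:
        """Rate-corrected RT per electrode (needs ``rr_ms``)."""
        if self.rr_ms is None:
            raise AnalysisError("rr_ms required for rate correction")
        return {k: float(correct_rt(v, self.rr_ms)) for k, v in self.rt_ms.items()}

    def needle_values(self, needle_id: int) -> list[float]:
        return [self.rt_ms[(needle_id, d)] for d in range(N_DEPTHS)
                if (needle_id, d) in self.rt_ms]

    def wall_values(self, wall: Wall, which: str = "rt") -> np.ndarray:
        src = self.rt_ms if which == "rt" else (self.at_ms or {})
        vals = [v for (nid, d), v in src.items()
                if self.grid.needle(nid).wall is wall]
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_truth(cls, truth, accepted: Optional[Iterable[tuple[int, int]]] = None,
                   timepoint: Optional[str] = None) -> "RTField":
        """Build a field from a generator truth field, optionally keeping
        only the accepted channel keys."""
        rt = truth.by_key("rt")
        at = truth.by_key("at")
        if accepted is not None:
            keep = set(accepted)
            rt = {k: v for k, v in rt.items() if k in keep}
            at = {k: v for k, v in at.items() if k in keep}
        return cls(grid=truth.grid, rt_ms=rt, at_ms=at, rr_ms=truth.rr_ms,
                   timepoint=timepoint)


@dataclass(frozen=True)
class OrientationResult:
    orientation: SDROrientation
    mean_ms: Optional[float]
    n_units: int
    unit_values: tuple[float, ...]
    unit_ids: tuple[tuple[int, ...], ...]

    @property
    def is_empty(self) -> bool:
        return self.n_units == 0


@dataclass(frozen=True)
class SDRSummary:
    """All four orientation means plus interventricular and wall metrics."""

    transmural: OrientationResult
    vertical: OrientationResult
    horizontal: OrientationResult
    cubic: OrientationResult
    drt_ms: Optional[float] = None
    walls: Optional[dict] = None


def _dedupe_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, ...]]:
    seen = set()
    out = []
    for a, b in pairs:
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            out.append(tuple(sorted((a, b))))
    return out


def _units_for(grid: MappingGrid, orientation: SDROrientation) -> list[tuple[int, ...]]:
    if orientation is SDROrientation.TRANSMURAL:
        return [(n.needle_id,) for n in grid.needles]
    if orientation is SDROrientation.VERTICAL:
        return _dedupe_pairs(grid.vertical_pairs)
    if orientation is SDROrientation.HORIZONTAL:
        return _dedupe_pairs(grid.horizontal_pairs)
    if orientation is SDROrientation.CUBIC:
        return [tuple(sorted(sq)) for sq in grid.squares]
    raise ParameterError(f"unknown orientation {orientation}")


def sdr_orientation(field: RTField, orientation: SDROrientation) -> OrientationResult:
    """Mean max-min RT difference over the units of one orientation.

    A needle contributes to a unit only when at least
    :data:`MIN_PER_NEEDLE` of its electrodes were accepted; a unit is
    kept only when every member needle contributes and the total
    electrode count reaches the orientation minimum.  With no eligible
    unit an explicit empty result is returned (``mean_ms`` is None, not
    zero).
    """
    values = []
    ids = []
    min_total = MIN_PER_UNIT[orientation]
    for unit in _units_for(field.grid, orientation):
        per_needle = [field.needle_values(nid) for nid in unit]
        if any(len(v) < MIN_PER_NEEDLE for v in per_needle):
            continue
        pool = [x for v in per_needle for x in v]
        if len(pool) < min_total:
            continue
        values.append(max(pool) - min(pool))
        ids.append(unit)
    if not values:
        return OrientationResult(orientation, None, 0, (), ())
    return OrientationResult(orientation, float(np.mean(values)), len(values),
                             tuple(values), tuple(ids))


def interventricular_drt(field: RTField) -> float:
    """dRT = mean(LV RT) - mean(RV RT) over accepted electrodes.

    The septum belongs to neither ventricular mean."""
    lv = field.wall_values(Wall.LV)
    rv = field.wall_values(Wall.RV)
    empty = [w for w, v in (("LV", lv), ("RV", rv)) if v.size == 0]
    if empty:
        raise AnalysisError(
            f"no accepted electrodes in {' and '.join(empty)}; "
            "interventricular dRT undefined")
    return float(lv.mean() - rv.mean())


@dataclass(frozen=True)
class WallSummary:
    wall: Wall
    at_mean_ms: Optional[float]
    at_sd_ms: Optional[float]
    rt_mean_ms: float
    rt_sd_ms: float
    n: int
    single_electrode: bool = False  # n == 1: SD reported as 0


def _mean_sd(vals: np.ndarray) -> tuple[float, float, bool]:
    if vals.size == 1:
        return float(vals[0]), 0.0, True
    return float(vals.mean()), float(vals.std(ddof=1)), False


def wall_summaries(field: RTField) -> dict[Wall, WallSummary]:
    """Per-wall AT/RT means +- SD over accepted electrodes.

    The septum is summarized separately and never pooled into the RV or
    LV means.  Walls without accepted electrodes are absent from the
    result (callers must treat a missing ventricle explicitly)."""
    out: dict[Wall, WallSummary] = {}
    for wall in Wall:
        rt = field.wall_values(wall, "rt")
        if rt.size == 0:
            continue
        rt_m, rt_sd, single = _mean_sd(rt)
        at = field.wall_values(wall, "at")
        if at.size:
            at_m, at_sd, _ = _mean_sd(at)
        else:
            at_m = at_sd = None
        out[wall] = WallSummary(wall=wall, at_mean_ms=at_m, at_sd_ms=at_sd,
                                rt_mean_ms=rt_m, rt_sd_ms=rt_sd,
                                n=int(rt.size), single_electrode=single)
    return out


def sdr_summary(field: RTField) -> SDRSummary:
    """Convenience bundle: all four orientations plus dRT and wall stats."""
    res = {o: sdr_orientation(field, o) for o in SDROrientation}
    try:
        drt = interventricular_drt(field)
    except AnalysisError:
        drt = None
    return SDRSummary(transmural=res[SDROrientation.TRANSMURAL],
                      vertical=res[SDROrientation.VERTICAL],
                      horizontal=res[SDROrientation.HORIZONTAL],
                      cubic=res[SDROrientation.CUBIC],
                      drt_ms=drt, walls=wall_summaries(field))


# ---------------------------------------------------------------------------
# polar (bullseye) maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarMap:
    """Bullseye layout: one panel per wall, rings = levels (base outward
    to apex inward), sectors = columns.  ``cells`` maps (level, column)
    to the needle-mean value; ``deltas`` lists adjacent-cell absolute
    differences for gradient annotation."""

    timepoint: Optional[str]
    corrected: bool
    panels: dict  # wall code -> {"levels": [...], "ncols": int,
    #               "cells": {(level, col): value},
    #               "deltas": [((l1,c1),(l2,c2), dv), ...]}

    def to_json(self) -> str:
        ser = {}
        for wall, p in self.panels.items():
            ser[wall] = {
                "levels": p["levels"], "ncols": p["ncols"],
                "cells": [{"level": l, "column": c, "value": v}
                          for (l, c), v in sorted(p["cells"].items())],
                "deltas": [{"from": list(a), "to": list(b), "delta": d}
                           for a, b, d in p["deltas"]],
            }
        return json.dumps({"timepoint": self.timepoint,
                           "corrected": self.corrected,
                           "panels": ser}, indent=1)


def polar_map_export(field: RTField, use_corrected: bool = False) -> PolarMap:
    """Reduce a field to needle-mean cell values and neighbor gradients.

    Cell value = mean RT (or RTc) of the needle's accepted electrodes;
    needles with no accepted electrode get a NaN cell.  Delta
    annotations cover vertical and horizontal grid adjacency.
    """
    values = field.rtc_ms if use_corrected else dict(field.rt_ms)
    per_needle: dict[int, float] = {}
    for n in field.grid.needles:
        vals = [values[(n.needle_id, d)] for d in range(N_DEPTHS)
                if (n.needle_id, d) in values]
        per_needle[n.needle_id] = float(np.mean(vals)) if vals else math.nan
    panels: dict = {}
    for n in field.grid.needles:
        p = panels.setdefault(n.wall.code, {"levels": [], "ncols": 0,
                                            "cells": {}, "deltas": []})
        if n.level not in p["levels"]:
            p["levels"].append(n.level)
        p["ncols"] = max(p["ncols"], n.column + 1)
        p["cells"][(n.level, n.column)] = per_needle[n.needle_id]
    for p in panels.values():
        p["levels"].sort()
    for pairs in (field.grid.vertical_pairs, field.grid.horizontal_pairs):
        seen = set()
        for a, b in pairs:
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            na, nb = field.grid.needle(a), field.grid.needle(b)
            dv = per_needle[a] - per_needle[b]
            panels[na.wall.code]["deltas"].append(
                ((na.level, na.column), (nb.level, nb.column),
                 float(abs(dv)) if not math.isnan(dv) else math.nan))
    return PolarMap(timepoint=field.timepoint, corrected=use_corrected,
                    panels=panels)


def plot_polar_map(pmap: PolarMap, path=None, cmap: str = "turbo",
                   vmin: Optional[float] = None, vmax: Optional[float] = None):
    """Render the bullseye panels with matplotlib; returns the Figure."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import cm
    from matplotlib.colors import Normalize

    walls = sorted(pmap.panels)
    all_vals = [v for p in pmap.panels.values() for v in p["cells"].values()
                if not math.isnan(v)]
    norm = Normalize(vmin if vmin is not None else min(all_vals),
                     vmax if vmax is not None else max(all_vals))
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
    fig, axes = plt.subplots(1, len(walls), figsize=(4 * len(walls), 4.5),
                             subplot_kw={"projection": "polar"})
    if len(walls) == 1:
        axes = [axes]
    for ax, wall in zip(np.atleast_1d(axes), walls):
        p = pmap.panels[wall]
        levels = p["levels"]
        nlev, ncols = len(levels), p["ncols"]
        for i, level in enumerate(levels):  # base outermost
            r0 = 1.0 - (i + 1) / nlev
            for col in range(ncols):
                v = p["cells"].get((level, col), math.nan)
                color = mapper.to_rgba(v) if not math.isnan(v) else "0.85"
                theta0 = 2 * np.pi * col / ncols
                ax.bar(theta0, 1.0 / nlev, width=2 * np.pi / ncols,
                       bottom=r0, align="edge", color=color,
                       edgecolor="white", linewidth=0.5)
        ax.set_title(wall)
        ax.set_xticks([])
        ax.set_yticks([])
    label = "RTc (ms)" if pmap.corrected else "RT (ms)"
    fig.colorbar(mapper, ax=list(np.atleast_1d(axes)), shrink=0.8, label=label)
    if pmap.timepoint:
        fig.suptitle(pmap.timepoint)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
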