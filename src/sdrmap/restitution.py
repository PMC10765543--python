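"""Repolarization restitution: RT as a function of paced cycle length.

Restitution curves are built per ventricle from the wall-mean RT of the
needle electrograms at each pacing block and the block's RR interval.
A straight line is fitted over the observed RR range (four rate points
cannot constrain more structure; an exponential fit is available as an
option).  The clinically relevant readout is the divergence between the
two ventricles: the LV curve is steeper than the RV curve, so the
interventricular RT difference widens at long cycle lengths and shrinks
under high-rate pacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dispersion import RTField
from .errors import AnalysisError, ParameterError
from .grid import Wall

__all__ = ["RestitutionCurve", "DivergenceReport", "build_restitution",
           "fit_restitution_curve"]


@dataclass(frozen=True)
class RestitutionCurve:
    ventricle: Wall
    points: tuple[tuple[float, float], ...]  # (rr_ms, mean_rt_ms), rr-sorted
    slope_ms_per_ms: float
    intercept_ms: float
    model: str = "linear"

    def predict(self, rr_ms) -> np.ndarray:
        return self.intercept_ms + self.slope_ms_per_ms * np.asarray(rr_ms, float)

    @property
    def residual_rms_ms(self) -> float:
        rr = np.array([p[0] for p in self.points])
        rt = np.array([p[1] for p in self.points])
        return float(np.sqrt(np.mean((rt - self.predict(rr)) ** 2)))


@dataclass(frozen=True)
class DivergenceReport:
    """Predicted LV-RV difference at each observed cycle length plus the
    slope difference (beta_LV - beta_RV)."""

    table: pd.DataFrame  # rr_ms, rv_rt_ms, lv_rt_ms, difference_ms
    slope_difference_ms_per_ms: float


def fit_restitution_curve(ventricle: Wall,
                          points: Sequence[tuple[float, float]],
                          model: str = "linear") -> RestitutionCurve:
    pts = sorted((float(rr), float(rt)) for rr, rt in points)
    rr = np.array([p[0] for p in pts])
    rt = np.array([p[1] for p in pts])
    if np.unique(rr).size < 2:
        raise AnalysisError(
            f"{ventricle.code}: need >=2 distinct RR values for a restitution "
            "slope")
    if model == "linear":
        slope, intercept = np.polyfit(rr, rt, 1)
    elif model == "exponential":
        # RT = a - b exp(-rr / tau); report the local slope at mean RR
        def f(x, a, b, tau):
            return a - b * np.exp(-x / tau)
        p0 = (rt.max(), rt.max() - rt.min() + 1.0, rr.mean())
        (a, b, tau), _ = curve_fit(f, rr, rt, p0=p0, maxfev=20000)
        rr0 = rr.mean()
        slope = b / tau * np.exp(-rr0 / tau)
        intercept = (a - b * np.exp(-rr0 / tau)) - slope * rr0
    else:
        raise ParameterError(f"unknown restitution model {model!r}")
    return RestitutionCurve(ventricle=ventricle, points=tuple(pts),
                            slope_ms_per_ms=float(slope),
                            intercept_ms=float(intercept), model=model)


def build_restitution(fields: Sequence[RTField], model: str = "linear",
                      ) -> tuple[RestitutionCurve, RestitutionCurve, DivergenceReport]:
    """Build RV and LV restitution curves from timepoint fields.

    Each field contributes one point per ventricle: (the field's paced
    RR, the wall-mean RT over accepted electrodes).
    """
    pts: dict[Wall, list[tuple[float, float]]] = {Wall.RV: [], Wall.LV: []}
    for f in fields:
        if f.rr_ms is None:
            raise AnalysisError(f"field {f.timepoint!r} has no RR interval")
        for w in (Wall.RV, Wall.LV):
            vals = f.wall_values(w)
            if vals.size == 0:
                raise AnalysisError(
                    f"field {f.timepoint!r}: no accepted electrodes in {w.code}")
            pts[w].append((f.rr_ms, float(vals.mean())))
    rv = fit_restitution_curve(Wall.RV, pts[Wall.RV], model)
    lv = fit_restitution_curve(Wall.LV, pts[Wall.LV], model)
    rr_obs = sorted({p[0] for p in pts[Wall.RV]})
    table = pd.DataFrame({
        "rr_ms": rr_obs,
        "rv_rt_ms": rv.predict(rr_obs),
        "lv_rt_ms": lv.predict(rr_obs),
    })
    table["difference_ms"] = table["lv_rt_ms"] - table["rv_rt_ms"]
    report = DivergenceReport(
        table=table,
        slope_difference_ms_per_ms=lv.slope_ms_per_ms - rv.slope_ms_per_ms)
    return rv, lv, report


def plot_restitution(rv: RestitutionCurve, lv: RestitutionCurve, path=None):
    """RT-restitution figure: observed wall means and fitted lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, color in ((rv, "tab:blue"), (lv, "tab:red")):
        rr = [p[0] for p in curve.points]
        rt = [p[1] for p in curve.points]
        ax.plot(rr, rt, "o", color=color)
        grid = np.linspace(min(rr), max(rr), 50)
        ax.plot(grid, curve.predict(grid), "-", color=color,
                label=f"{curve.ventricle.code} "
                      f"(slope {curve.slope_ms_per_ms:.3f} ms/ms)")
    ax.set_xlabel("RR (ms)")
    ax.set_ylabel("wall-mean RT (ms)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
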