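"""Study-condition presets for the synthetic arms.

Each analysis timepoint of the pacing protocol is emulated by a preset
that fixes the paced cycle length, the per-wall mean activation and
repolarization times, the surface QT, and a target mean cubic
dispersion.  The values are the serial group means of the chronic
AV-block dog experiments this pipeline emulates: a proarrhythmic
dofetilide challenge under RVA pacing at 50/min (timepoints just before
the first ectopic beat, "EB", and just before the first TdP, "TdP"),
followed by 2-min pacing blocks at 100, 80 and 60/min, plus a
retrospective arm paced at 60/min directly after defibrillation.

Dispersion-noise SDs are not stated as such anywhere; they are obtained
by the documented generator inversion (:func:`sdrmap.simulate.
calibrate_noise_sd`) so that the expected cubic dispersion of the truth
field matches the timepoint's target.  Deterministic gradients are set
to a small fixed fraction of the target so that noise dominates and the
inversion always brackets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

from .grid import MappingGrid, Wall, build_default_grid
from .simulate import RTFieldParams, calibrate_noise_sd

__all__ = ["TimepointCondition", "TIMEPOINTS", "TIMEPOINT_ORDER",
           "timepoint_preset", "restitution_slopes"]


@dataclass(frozen=True)
class TimepointCondition:
    """Emulated group means for one analysis timepoint (ms, unless noted)."""

    name: str
    rr_ms: float
    qt_ms: float
    rv_at_ms: float
    lv_at_ms: float
    rv_rt_ms: float
    lv_rt_ms: float
    cubic_target_ms: float


#: serial conditions: RR / QT / wall AT / wall RT / cubic-dispersion target
TIMEPOINTS: dict[str, TimepointCondition] = {tc.name: tc for tc in [
    TimepointCondition("EB", 1200.0, 573.0, 40.0, 63.0, 363.0, 453.0, 103.0),
    TimepointCondition("TdP", 1200.0, 626.0, 41.0, 62.0, 403.0, 480.0, 125.0),
    TimepointCondition("RVA100", 600.0, 453.0, 39.0, 60.0, 330.0, 363.0, 49.0),
    TimepointCondition("RVA80", 750.0, 508.0, 39.0, 60.0, 376.0, 413.0, 62.0),
    TimepointCondition("RVA60", 1000.0, 598.0, 38.0, 60.0, 392.0, 464.0, 107.0),
    TimepointCondition("RVA60_retro", 1000.0, 513.0, 42.0, 59.0, 360.0, 395.0,
                       101.0),
]}

#: protocol order; the retrospective arm sits outside the serial protocol
#: but is orderable after RVA60 for validation purposes
TIMEPOINT_ORDER = ["EB", "TdP", "RVA100", "RVA80", "RVA60", "RVA60_retro"]

#: fraction of the cubic target assigned to the deterministic gradients
GRADIENT_FRACTION_APICOBASAL = 0.05
GRADIENT_FRACTION_TRANSMURAL = 0.03


def restitution_slopes(beta_rv: float = 0.04, beta_lv: float = 0.10,
                       ) -> dict[Wall, float]:
    """Default per-wall restitution slopes (ms RT per ms RR), LV steeper
    than RV; the septum takes the midpoint."""
    return {Wall.RV: beta_rv, Wall.LV: beta_lv,
            Wall.SEPTUM: 0.5 * (beta_rv + beta_lv)}


@lru_cache(maxsize=32)
def _calibrated_params(name: str, wrap: bool) -> tuple[RTFieldParams, float, float]:
    """Preset parameters on the *default* grid, cached because the noise
    inversion re-runs the generator."""
    return _build_preset(TIMEPOINTS[name], build_default_grid(wrap=wrap))


def _build_preset(tc: TimepointCondition, grid: MappingGrid,
                  ) -> tuple[RTFieldParams, float, float]:
    wall_means = {Wall.RV: tc.rv_rt_ms, Wall.LV: tc.lv_rt_ms,
                  Wall.SEPTUM: 0.5 * (tc.rv_rt_ms + tc.lv_rt_ms)}
    at_means = {Wall.RV: tc.rv_at_ms, Wall.LV: tc.lv_at_ms,
                Wall.SEPTUM: 0.5 * (tc.rv_at_ms + tc.lv_at_ms)}
    params = RTFieldParams.from_wall_means(
        wall_means, tc.rr_ms, restitution_slopes(),
        apicobasal_gradient_ms_per_level=GRADIENT_FRACTION_APICOBASAL * tc.cubic_target_ms,
        transmural_gradient_ms_per_depth=GRADIENT_FRACTION_TRANSMURAL * tc.cubic_target_ms,
        at_mean_ms=at_means,
        seed=0,
    )
    noise_sd = calibrate_noise_sd(grid, params, tc.rr_ms, tc.cubic_target_ms)
    return (replace(params, dispersion_noise_sd_ms=noise_sd),
            tc.rr_ms, tc.qt_ms)


def timepoint_preset(name: str, seed: int = 0,
                     grid: Optional[MappingGrid] = None, *, wrap: bool = True,
                     ) -> tuple[RTFieldParams, float, float]:
    """Calibrated field parameters for one timepoint.

    Returns ``(params, rr_ms, qt_ms)``.  ``seed`` replaces the params
    seed so repeated draws are independent but reproducible.  With the
    default grid the calibration is cached; a custom grid triggers a
    fresh inversion.
    """
    alias = {"pre-TdP": "TdP"}
    name = alias.get(name, name)
    if name not in TIMEPOINTS:
        raise KeyError(f"unknown timepoint {name!r}; known: "
                       f"{sorted(TIMEPOINTS)}")
    if grid is None:
        params, rr, qt = _calibrated_params(name, True)
    else:
        params, rr, qt = _build_preset(TIMEPOINTS[name], grid)
    return replace(params, seed=seed), rr, qt
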