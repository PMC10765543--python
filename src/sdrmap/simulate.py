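"""Ground-truthed synthetic inputs for the mapping analysis.

This module stands in for the animal recordings: it produces unipolar
electrograms on the needle lattice, a lead-II-like surface signal, and
annotated rhythm streams under the pacing protocol (continuous RVA pacing
at 50/min during the proarrhythmic challenge, then 100/80/60 per minute
blocks), together with machine-readable ground truth for every quantity a
downstream detector estimates.

The waveform family is deliberately simple -- sums of logistic sigmoids --
because the design requirement is that the analytic fiducials are exactly
known, not that the traces look like any particular animal:

* the QRS is a biphasic R/S complex whose steepest *negative* slope sits
  exactly at the activation time ``at_ms``;
* the T deflection is a wide rising sigmoid whose steepest *positive*
  slope sits exactly at the repolarization time ``rt_ms``;
* channel corruptions (injury current, flat T, broadband noise, cavity
  potential) are applied on top with controllable magnitude.

Repolarization fields follow a linear restitution law per wall,
``RT = alpha_wall + beta_wall * RR``, plus centered apicobasal and
transmural gradients and i.i.d. Gaussian dispersion noise, so wall means
and interventricular differences have closed forms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ParameterError, SpecificationError
from .grid import MappingGrid, N_DEPTHS, Wall

__all__ = [
    "WaveformParams",
    "ChannelQuality",
    "ChannelQualityTruth",
    "DofetilideEffect",
    "RTFieldParams",
    "TruthField",
    "EgmTrace",
    "LeadTrace",
    "EpisodeSpec",
    "PacingBlock",
    "RhythmParams",
    "RhythmRecord",
    "egm_waveform",
    "egm_waveform_derivative",
    "generate_egm",
    "generate_rt_field",
    "generate_beat_series",
    "generate_surface_lead",
    "assign_channel_quality",
    "calibrate_noise_sd",
    "n_samples_for_window",
]


# ---------------------------------------------------------------------------
# electrogram waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of the synthetic unipolar electrogram (mV, ms).

    The QRS is built from three sigmoids: a small R wave rising
    ``r_offset_ms`` before the intrinsic deflection, the main negative
    deflection of amplitude ``r_amp_mv + s_amp_mv`` centred at the
    activation time, and a slower recovery returning the baseline to zero
    before the ST segment.  The T wave is a single wide rising sigmoid
    centred at the repolarization time.
    """

    r_amp_mv: float = 2.0
    s_amp_mv: float = 5.0
    qrs_width_ms: float = 2.0
    r_offset_ms: float = 12.0
    s_recovery_offset_ms: float = 30.0
    s_recovery_width_ms: float = 8.0
    t_amp_mv: float = 2.0
    t_width_ms: float = 15.0
    #: onset/width of the baseline-shift step used for injury current
    injury_onset_offset_ms: float = 15.0
    injury_width_ms: float = 5.0
    #: corruption magnitudes
    flat_t_scale: float = 0.02
    noise_sd_mv: float = 0.6
    cavity_amp_mv: float = 0.4
    cavity_t_amp_mv: float = 0.2


DEFAULT_WAVEFORM = WaveformParams()


def egm_waveform(t_ms: np.ndarray, at_ms: float, rt_ms: float,
                 params: WaveformParams = DEFAULT_WAVEFORM) -> np.ndarray:
    """Clean unipolar electrogram evaluated at times ``t_ms`` (in mV)."""
    p = params
    t = np.asarray(t_ms, dtype=float)
    v = p.r_amp_mv * expit((t - (at_ms - p.r_offset_ms)) / p.qrs_width_ms)
    v -= (p.r_amp_mv + p.s_amp_mv) * expit((t - at_ms) / p.qrs_width_ms)
    v += p.s_amp_mv * expit(
        (t - (at_ms + p.s_recovery_offset_ms)) / p.s_recovery_width_ms)
    v += p.t_amp_mv * expit((t - rt_ms) / p.t_width_ms)
    return v


def egm_waveform_derivative(t_ms: np.ndarray, at_ms: float, rt_ms: float,
                            params: WaveformParams = DEFAULT_WAVEFORM) -> np.ndarray:
    """Closed-form dV/dt (mV/ms) of the clean waveform.

    Uses sigma'(x) = sigma(x) (1 - sigma(x)).  Serves as the independent
    oracle for fiducial placement: the global minimum in the QRS window
    is at ``at_ms`` and the maximum in the T window at ``rt_ms`` up to
    sub-sample perturbation from neighbouring deflections.
    """
    p = params
    t = np.asarray(t_ms, dtype=float)

    def dsig(center, width, amp):
        s = expit((t - center) / width)
        return amp * s * (1.0 - s) / width

    d = dsig(at_ms - p.r_offset_ms, p.qrs_width_ms, p.r_amp_mv)
    d -= dsig(at_ms, p.qrs_width_ms, p.r_amp_mv + p.s_amp_mv)
    d += dsig(at_ms + p.s_recovery_offset_ms, p.s_recovery_width_ms, p.s_amp_mv)
    d += dsig(rt_ms, p.t_width_ms, p.t_amp_mv)
    return d


class ChannelQuality(enum.Enum):
    CLEAN = "CLEAN"
    INJURY = "INJURY"
    FLAT_T = "FLAT_T"
    NOISY = "NOISY"
    CAVITY = "CAVITY"


@dataclass(frozen=True)
class ChannelQualityTruth:
    """Ground-truth quality label for one channel."""

    label: ChannelQuality = ChannelQuality.CLEAN
    #: injury-current amplitude as a fraction of the T-wave amplitude
    injury_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.injury_fraction <= 3.0:
            raise ParameterError(
                f"injury_fraction must be in [0, 3], got {self.injury_fraction}")


@dataclass(frozen=True)
class EgmTrace:
    """A sampled electrogram plus its generation truth."""

    signal: np.ndarray
    fs_hz: float
    truth: dict


def n_samples_for_window(fs_hz: float, window_ms: float) -> int:
    """Sample count of a beat window: floor(fs * window); e.g. 2048 Hz x
    1200 ms -> 2457 samples (the fractional last sample is dropped)."""
    return int(math.floor(fs_hz * window_ms / 1000.0))


def generate_egm(at_ms: float, rt_ms: float,
                 quality: ChannelQualityTruth = ChannelQualityTruth(),
                 fs_hz: float = 2048.0, beat_window_ms: float = 1200.0,
                 params: WaveformParams = DEFAULT_WAVEFORM,
                 rng: Optional[np.random.Generator] = None) -> EgmTrace:
    """Synthesize one beat window of a unipolar electrogram.

    The returned truth dict records the analytic fiducials and the
    quality label so every downstream detector can be scored.
    """
    if not (0.0 < at_ms < rt_ms < beat_window_ms):
        raise ParameterError(
            f"fiducials must satisfy 0 < at ({at_ms}) < rt ({rt_ms}) < "
            f"window ({beat_window_ms})")
    n = n_samples_for_window(fs_hz, beat_window_ms)
    t = np.arange(n) / fs_hz * 1000.0
    p = params
    q = quality.label

    if q is ChannelQuality.CAVITY:
        # low-amplitude monophasic QS with a vestigial T deflection
        v = -p.cavity_amp_mv * expit((t - at_ms) / p.qrs_width_ms)
        v += p.cavity_amp_mv * expit((t - (at_ms + 40.0)) / 10.0)
        v += p.cavity_t_amp_mv * expit((t - rt_ms) / p.t_width_ms)
    else:
        wf = p if q is not ChannelQuality.FLAT_T else replace(
            p, t_amp_mv=p.t_amp_mv * p.flat_t_scale)
        v = egm_waveform(t, at_ms, rt_ms, wf)
        if q is ChannelQuality.INJURY:
            offset = quality.injury_fraction * p.t_amp_mv
            v += offset * expit(
                (t - (at_ms + p.injury_onset_offset_ms)) / p.injury_width_ms)
        elif q is ChannelQuality.NOISY:
            rng = np.random.default_rng() if rng is None else rng
            v = v + rng.normal(0.0, p.noise_sd_mv, size=n)
    truth = {"at_ms": float(at_ms), "rt_ms": float(rt_ms),
             "quality": q.value, "injury_fraction": quality.injury_fraction,
             "n_samples": n}
    return EgmTrace(signal=v, fs_hz=fs_hz, truth=truth)


def assign_channel_quality(grid: MappingGrid,
                           rng: np.random.Generator,
                           rates: Optional[Mapping[ChannelQuality, float]] = None,
                           ) -> dict[tuple[int, int], ChannelQualityTruth]:
    """Randomly label channels, mostly CLEAN with a small corrupted tail.

    Default corruption rates reflect a stabilized preparation in which a
    few percent of channels are unusable: 3% injury current, 2% each of
    flat T, broadband noise, and cavity potentials.
    """
    if rates is None:
        rates = {ChannelQuality.INJURY: 0.03, ChannelQuality.FLAT_T: 0.02,
                 ChannelQuality.NOISY: 0.02, ChannelQuality.CAVITY: 0.02}
    labels = [ChannelQuality.CLEAN] + list(rates)
    probs = np.array([1.0 - sum(rates.values())] + [rates[k] for k in rates])
    if probs[0] < 0:
        raise ParameterError("corruption rates sum to more than 1")
    out: dict[tuple[int, int], ChannelQualityTruth] = {}
    for addr in grid.electrodes():
        lab = labels[rng.choice(len(labels), p=probs)]
        frac = float(rng.uniform(0.9, 1.8)) if lab is ChannelQuality.INJURY else 0.0
        out[addr.key] = ChannelQualityTruth(label=lab, injury_fraction=frac)
    return out


# ---------------------------------------------------------------------------
# repolarization / activation fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DofetilideEffect:
    """I_Kr-block surrogate: uniform RT prolongation plus a multiplicative
    increase of every dispersion component (gradients and noise)."""

    rt_prolongation_ms: float = 0.0
    dispersion_multiplier: float = 1.0

    def __post_init__(self):
        if self.dispersion_multiplier < 0:
            raise ParameterError("dispersion_multiplier must be >= 0")


def _default_at_means() -> dict[Wall, float]:
    return {Wall.RV: 40.0, Wall.LV: 60.0, Wall.SEPTUM: 50.0}


@dataclass(frozen=True)
class RTFieldParams:
    """Parameters of the synthetic AT/RT landscape.

    ``rt_intercept_ms`` and ``restitution_slope_ms_per_ms`` define the
    per-wall linear restitution law RT = alpha + beta * RR.  The
    apicobasal and transmural gradients are *centered* within each wall
    (they average to ~0), so the wall mean RT equals alpha + beta * RR
    (+ dofetilide prolongation) in expectation regardless of gradient
    settings.  Activation times follow a paced-RVA template: the RV is
    activated earliest, the LV base latest.
    """

    rt_intercept_ms: Mapping[Wall, float]
    restitution_slope_ms_per_ms: Mapping[Wall, float]
    apicobasal_gradient_ms_per_level: float = 0.0
    transmural_gradient_ms_per_depth: float = 0.0
    dispersion_noise_sd_ms: float = 0.0
    dofetilide: Optional[DofetilideEffect] = None
    at_mean_ms: Mapping[Wall, float] = field(default_factory=_default_at_means)
    at_apicobasal_ms_per_level: float = 2.0
    at_noise_sd_ms: float = 5.0
    interventricular_divergence: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dispersion_noise_sd_ms < 0 or self.at_noise_sd_ms < 0:
            raise ParameterError("noise SDs must be >= 0")
        if self.interventricular_divergence:
            b = self.restitution_slope_ms_per_ms
            if not b[Wall.LV] > b[Wall.RV]:
                raise ParameterError(
                    "interventricular divergence mode requires beta_LV > beta_RV")

    @classmethod
    def from_wall_means(cls, wall_rt_means_ms: Mapping[Wall, float],
                        rr_ms: float,
                        restitution_slope_ms_per_ms: Optional[Mapping[Wall, float]] = None,
                        **kwargs) -> "RTFieldParams":
        """Anchor the intercepts so wall mean RT equals the given values
        at the given cycle length."""
        slopes = restitution_slope_ms_per_ms or {
            Wall.RV: 0.04, Wall.LV: 0.10, Wall.SEPTUM: 0.07}
        intercepts = {w: wall_rt_means_ms[w] - slopes[w] * rr_ms
                      for w in wall_rt_means_ms}
        return cls(rt_intercept_ms=intercepts,
                   restitution_slope_ms_per_ms=slopes, **kwargs)


@dataclass(frozen=True)
class TruthField:
    """Ground-truth AT/RT per electrode, aligned with ``grid.electrodes()``."""

    grid: MappingGrid
    at_ms: np.ndarray
    rt_ms: np.ndarray
    rr_ms: float

    def by_key(self, which: str = "rt") -> dict[tuple[int, int], float]:
        vals = self.rt_ms if which == "rt" else self.at_ms
        return {a.key: float(v) for a, v in zip(self.grid.electrodes(), vals)}

    def wall_mean(self, wall: Wall, which: str = "rt") -> float:
        vals = self.rt_ms if which == "rt" else self.at_ms
        mask = np.array([a.wall is wall for a in self.grid.electrodes()])
        return float(vals[mask].mean())


def generate_rt_field(grid: MappingGrid, params: RTFieldParams,
                      rr_ms: float) -> TruthField:
    """Draw one AT/RT truth field at cycle length ``rr_ms``.

    Reproducible: the same (grid, params, rr) always yields the same
    field because the RNG is seeded from ``params.seed``.
    """
    if rr_ms <= 0:
        raise ParameterError(f"rr_ms must be positive, got {rr_ms}")
    addrs = grid.electrodes()
    for a in addrs:
        if a.wall not in params.rt_intercept_ms:
            raise ParameterError(f"no RT intercept for wall {a.wall.code}")
    rng = np.random.default_rng(params.seed)
    mult = (params.dofetilide.dispersion_multiplier
            if params.dofetilide is not None else 1.0)
    prolong = (params.dofetilide.rt_prolongation_ms
               if params.dofetilide is not None else 0.0)

    # centre gradients per wall so they do not move wall means
    level_mid = {}
    for w in {a.wall for a in addrs}:
        levels = [a.level for a in addrs if a.wall is w]
        level_mid[w] = sum(levels) / len(levels)
    depth_mid = (N_DEPTHS - 1) / 2.0

    n = len(addrs)
    rt = np.empty(n)
    at = np.empty(n)
    rt_noise = rng.normal(0.0, 1.0, size=n)
    at_noise = rng.normal(0.0, 1.0, size=n)
    for i, a in enumerate(addrs):
        base = (params.rt_intercept_ms[a.wall]
                + params.restitution_slope_ms_per_ms[a.wall] * rr_ms)
        grad = (params.apicobasal_gradient_ms_per_level * (a.level - level_mid[a.wall])
                + params.transmural_gradient_ms_per_depth * (a.depth_index - depth_mid))
        rt[i] = base + mult * grad + prolong \
            + mult * params.dispersion_noise_sd_ms * rt_noise[i]
        # paced-RVA activation template: apex (high level) earliest
        at[i] = (params.at_mean_ms[a.wall]
                 - params.at_apicobasal_ms_per_level * (a.level - level_mid[a.wall])
                 + params.at_noise_sd_ms * at_noise[i])
    # physiological floor: repolarization cannot precede activation; extreme
    # noise tails are clamped to a minimal 120 ms repolarization interval
    rt = np.maximum(rt, at + 120.0)
    return TruthField(grid=grid, at_ms=at, rt_ms=rt, rr_ms=float(rr_ms))


def _brute_cubic_mean(field: TruthField) -> float:
    """Mean max-min RT over the grid's 2x2 needle squares (calibration-side
    helper; the analysis-side implementation lives in ``dispersion``)."""
    by_needle: dict[int, list[float]] = {}
    for a, v in zip(field.grid.electrodes(), field.rt_ms):
        by_needle.setdefault(a.needle_id, []).append(float(v))
    vals = []
    for square in field.grid.squares:
        pool = [x for nid in square for x in by_needle[nid]]
        vals.append(max(pool) - min(pool))
    if not vals:
        raise ParameterError("grid has no squares to calibrate against")
    return float(np.mean(vals))


def calibrate_noise_sd(grid: MappingGrid, params: RTFieldParams, rr_ms: float,
                       target_cubic_ms: float, *, n_fields: int = 24,
                       calibration_seed: int = 987654) -> float:
    """Invert the generator for a requested mean cubic dispersion.

    Solves for the dispersion-noise SD such that the Monte-Carlo expected
    cubic dispersion of the truth field (mean over ``n_fields`` internal
    seeds) equals ``target_cubic_ms``.  Gradients in ``params`` are kept
    fixed; they must not already exceed the target on their own.  The
    root is found by bisection (Brent) on [0, target], which brackets the
    solution because the range of 16 i.i.d. normals grows like ~3.5 sigma.
    """
    if target_cubic_ms <= 0:
        raise ParameterError("target cubic dispersion must be positive")

    def expected_cubic(sd: float) -> float:
        acc = 0.0
        for k in range(n_fields):
            p = replace(params, dispersion_noise_sd_ms=sd,
                        seed=calibration_seed + k)
            acc += _brute_cubic_mean(generate_rt_field(grid, p, rr_ms))
        return acc / n_fields

    lo = expected_cubic(0.0)
    if lo > target_cubic_ms:
        raise ParameterError(
            f"deterministic gradients alone give cubic dispersion {lo:.1f} ms, "
            f"above the target {target_cubic_ms} ms")
    return float(brentq(lambda s: expected_cubic(s) - target_cubic_ms,
                        0.0, target_cubic_ms, xtol=0.01))


# ---------------------------------------------------------------------------
# rhythm streams
# ---------------------------------------------------------------------------

PACED, ECTOPIC = "PACED", "ECTOPIC"
EVENT_DEFIB = "defibrillation"


@dataclass(frozen=True)
class EpisodeSpec:
    """One scripted tachyarrhythmia episode inside a pacing block.

    ``start_s`` is the offset of the first episode beat from the start of
    the block.  Episodes longer than 10 s must script at least one
    defibrillation (sustained TdP is cardioverted, it does not stop by
    itself).
    """

    n_beats: int
    duration_s: float
    n_defibs: int = 0
    start_s: float = 0.0
    polymorphic: bool = True

    def __post_init__(self):
        if self.n_beats < 1 or self.duration_s <= 0 or self.n_defibs < 0:
            raise SpecificationError(f"malformed episode spec {self}")
        if self.duration_s > 10.0 and self.n_defibs == 0:
            raise SpecificationError(
                f"episode of {self.duration_s} s (> 10 s) must be terminated "
                "by at least one defibrillation")


@dataclass(frozen=True)
class PacingBlock:
    block_id: str
    pacing_rate_bpm: float
    duration_s: float
    ectopy_hazard: float = 0.0
    episodes: tuple[EpisodeSpec, ...] = ()

    def __post_init__(self):
        if self.pacing_rate_bpm <= 0 or self.duration_s <= 0:
            raise SpecificationError(
                f"block {self.block_id}: rate and duration must be positive")
        if not 0.0 <= self.ectopy_hazard <= 1.0:
            raise SpecificationError(
                f"block {self.block_id}: ectopy_hazard must be a probability")
        for ep in self.episodes:
            if ep.start_s + ep.duration_s > self.duration_s:
                raise SpecificationError(
                    f"block {self.block_id}: episode ending at "
                    f"{ep.start_s + ep.duration_s} s exceeds the block "
                    f"duration {self.duration_s} s")


@dataclass(frozen=True)
class RhythmParams:
    blocks: tuple[PacingBlock, ...]
    seed: int = 0

    def __post_init__(self):
        if not self.blocks:
            raise SpecificationError("protocol must contain >= 1 pacing block")


@dataclass(frozen=True)
class RhythmRecord:
    """Annotated beat and event streams plus episode ground truth."""

    beats: pd.DataFrame       # time_ms, beat_class, morphology_index, block_id
    events: pd.DataFrame      # time_ms, event_type, block_id
    blocks: pd.DataFrame      # block_id, pacing_rate_bpm, start_ms, end_ms
    truth: dict


def generate_beat_series(params: RhythmParams) -> RhythmRecord:
    """Render the pacing protocol into an annotated beat stream.

    Paced beats are strictly periodic at 60000/rate ms.  Scattered
    ectopic beats are inserted between paced beats (a premature coupling
    at 55% of the cycle) by an independent Bernoulli draw per paced slot,
    so isolated ectopy never forms a consecutive run.  Scripted episodes
    suppress pacing capture inside their window and lay down a run of
    consecutive ectopic beats whose morphology index alternates in sign
    when polymorphic ("twisting" surrogate) and keeps a constant sign
    when monomorphic.  Defibrillation events are placed 0.5 s apart right
    after the episode ends.
    """
    rng = np.random.default_rng(params.seed)
    beat_rows = []
    event_rows = []
    block_rows = []
    truth_eps = []
    t0 = 0.0
    for blk in params.blocks:
        interval = 60000.0 / blk.pacing_rate_bpm
        dur_ms = blk.duration_s * 1000.0
        windows = [(t0 + ep.start_s * 1000.0,
                    t0 + (ep.start_s + ep.duration_s) * 1000.0)
                   for ep in blk.episodes]
        n_paced = int(round(blk.duration_s * blk.pacing_rate_bpm / 60.0))
        for i in range(n_paced):
            t = t0 + i * interval
            if any(lo <= t <= hi for lo, hi in windows):
                continue  # tachyarrhythmia overdrives the paced rhythm
            beat_rows.append((t, PACED, 1.0, blk.block_id))
            if rng.random() < blk.ectopy_hazard:
                te = t + 0.55 * interval
                if te < t0 + dur_ms and not any(lo <= te <= hi for lo, hi in windows):
                    beat_rows.append(
                        (te, ECTOPIC, abs(rng.normal(1.0, 0.2)), blk.block_id))
        for ep, (lo, hi) in zip(blk.episodes, windows):
            times = (np.linspace(lo, hi, ep.n_beats) if ep.n_beats > 1
                     else np.array([lo]))
            for j, te in enumerate(times):
                sign = (-1.0) ** j if ep.polymorphic else 1.0
                beat_rows.append(
                    (float(te), ECTOPIC, sign * abs(rng.normal(1.0, 0.2)),
                     blk.block_id))
            for k in range(ep.n_defibs):
                event_rows.append((float(hi + 500.0 * (k + 1)), EVENT_DEFIB,
                                   blk.block_id))
            truth_eps.append({"block_id": blk.block_id, "start_ms": float(lo),
                              "end_ms": float(hi), "n_beats": ep.n_beats,
                              "n_defibs": ep.n_defibs,
                              "polymorphic": ep.polymorphic})
        block_rows.append((blk.block_id, blk.pacing_rate_bpm, t0, t0 + dur_ms))
        t0 += dur_ms
    beats = pd.DataFrame(
        beat_rows, columns=["time_ms", "beat_class", "morphology_index",
                            "block_id"]).sort_values("time_ms", kind="stable",
                                                     ignore_index=True)
    events = pd.DataFrame(event_rows,
                          columns=["time_ms", "event_type", "block_id"])
    blocks = pd.DataFrame(block_rows, columns=["block_id", "pacing_rate_bpm",
                                               "start_ms", "end_ms"])
    return RhythmRecord(beats=beats, events=events, blocks=blocks,
                        truth={"episodes": truth_eps, "seed": params.seed})


# ---------------------------------------------------------------------------
# surface lead
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadTrace:
    signal: np.ndarray
    fs_hz: float
    truth: dict


def generate_surface_lead(beat_times_ms: Sequence[float], qt_ms: float,
                          fs_hz: float = 1024.0) -> LeadTrace:
    """Render a lead-II-like signal with measurable QRS onset and T end.

    Each beat contributes a piecewise-linear R/S complex with a sharp
    onset exactly at the beat time and a half-sine T wave ending exactly
    ``qt_ms`` later, so the QT interval is known by construction.  The
    signal is noiseless; measurement error is purely algorithmic.
    """
    times = np.asarray(list(beat_times_ms), dtype=float)
    if times.size == 0:
        return LeadTrace(signal=np.zeros(0), fs_hz=fs_hz,
                         truth={"qt_ms": float(qt_ms), "beat_times_ms": []})
    if qt_ms <= 60.0:
        raise ParameterError(f"qt_ms too short: {qt_ms}")
    if times.size > 1 and qt_ms >= float(np.min(np.diff(np.sort(times)))):
        raise ParameterError(
            f"qt_ms ({qt_ms}) must be shorter than the shortest RR interval")
    total_ms = float(times.max()) + qt_ms + 100.0
    n = n_samples_for_window(fs_hz, total_ms)
    t = np.arange(n) / fs_hz * 1000.0
    v = np.zeros(n)
    t_dur = min(200.0, 0.4 * qt_ms)
    for tb in times:
        v += np.interp(t, [tb, tb + 10.0, tb + 25.0, tb + 35.0],
                       [0.0, 1.0, -0.2, 0.0], left=0.0, right=0.0)
        lo, hi = tb + qt_ms - t_dur, tb + qt_ms
        m = (t >= lo) & (t <= hi)
        v[m] += 0.3 * np.sin(np.pi * (t[m] - lo) / t_dur)
    return LeadTrace(signal=v, fs_hz=fs_hz,
                     truth={"qt_ms": float(qt_ms),
                            "beat_times_ms": [float(x) for x in times]})
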