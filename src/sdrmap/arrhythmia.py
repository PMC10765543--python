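"""Surface-ECG intervals, Torsade de Pointes detection and severity scoring.

A TdP episode is a run of at least five consecutive ectopic beats whose
QRS morphology "twists" around the isoelectric line; here twisting is
operationalized as at least one sign change of the per-beat morphology
index inside the run.  Shorter runs and monomorphic runs count as
ectopy only.  Episodes lasting more than 10 s do not self-terminate and
are ended by electrical cardioversion; severity is scored as the beat
count for a self-terminating episode and 50/75/100 points for episodes
requiring 1/2/>=3 defibrillations.  Per pacing block, all ectopic beats
are counted and the most severe episode is scored; during the
proarrhythmic challenge (RVA50) only the last 2 min before the first
TdP are considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .egm import van_de_water
from .errors import ContractError, MeasurementError, ParameterError
from .simulate import ECTOPIC, EVENT_DEFIB

__all__ = [
    "IntervalMeasurement",
    "EpisodeRecord",
    "BlockDefinition",
    "BlockSummary",
    "measure_intervals",
    "measure_lead_intervals",
    "qtc_van_de_water",
    "detect_tdp_episodes",
    "tdp_score",
    "summarize_block",
    "round_half_up",
]

MIN_TDP_RUN = 5
#: self-terminating scores live below the defibrillation codes 50/75/100
MAX_SELF_TERMINATING_SCORE = 49
DEFIB_ATTRIBUTION_WINDOW_MS = 5000.0
RVA50_LOOKBACK_MS = 120000.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (table style)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def qtc_van_de_water(qt_ms: float, rr_ms: float) -> float:
    """Rate-corrected QT for the anesthetized dog: QT - 0.087 (RR - 1000).

    Full precision is returned; tables round with :func:`round_half_up`.
    """
    return van_de_water(qt_ms, rr_ms)


@dataclass(frozen=True)
class IntervalMeasurement:
    rr_ms: float
    qt_ms: float
    qtc_ms: float
    n_beats_averaged: int = 5
    timepoint: Optional[str] = None

    def __post_init__(self):
        if self.n_beats_averaged < 1:
            raise ParameterError("n_beats_averaged must be >= 1")
        if not self.qt_ms < self.rr_ms:
            raise MeasurementError(
                f"QT ({self.qt_ms}) must be shorter than RR ({self.rr_ms})")


def measure_intervals(qt_ms: Sequence[float], rr_ms,
                      n_beats: int = 5,
                      timepoint: Optional[str] = None) -> IntervalMeasurement:
    """Average per-beat RR/QT over ``n_beats`` consecutive beats.

    ``rr_ms`` may be a scalar (fixed pacing) or a per-beat sequence of
    the same length as ``qt_ms``.
    """
    qt = np.asarray(list(qt_ms), dtype=float)
    rr = (np.full(qt.shape, float(rr_ms)) if np.isscalar(rr_ms)
          else np.asarray(list(rr_ms), dtype=float))
    if qt.size < n_beats or rr.size < n_beats:
        raise MeasurementError(
            f"need {n_beats} consecutive beats, got {min(qt.size, rr.size)}")
    qt_bar = float(qt[:n_beats].mean())
    rr_bar = float(rr[:n_beats].mean())
    return IntervalMeasurement(rr_ms=rr_bar, qt_ms=qt_bar,
                               qtc_ms=qtc_van_de_water(qt_bar, rr_bar),
                               n_beats_averaged=n_beats, timepoint=timepoint)


def measure_lead_intervals(signal: np.ndarray, fs_hz: float, n_beats: int = 5,
                           timepoint: Optional[str] = None,
                           amplitude_floor: float = 0.005) -> IntervalMeasurement:
    """Measure RR and QT from a lead-II-like trace.

    QRS complexes are located via R peaks; the onset is the last
    sub-threshold sample before the R upstroke and the T end the last
    supra-threshold sample before the next onset.  Averages the first
    ``n_beats`` complete beats.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise MeasurementError("empty signal")
    peaks, _ = find_peaks(x, height=0.6 * float(x.max()),
                          distance=max(1, int(0.25 * fs_hz)))
    if len(peaks) < n_beats + 1:
        raise MeasurementError(
            f"need {n_beats + 1} QRS complexes to average {n_beats} beats, "
            f"found {len(peaks)}")
    onsets = []
    for pk in peaks:
        i = pk
        while i > 0 and x[i - 1] > amplitude_floor:
            i -= 1
        onsets.append(i)
    rr, qt = [], []
    for k in range(len(peaks) - 1):
        rr.append((onsets[k + 1] - onsets[k]) / fs_hz * 1000.0)
        seg_end = onsets[k + 1] - int(0.05 * fs_hz)
        seg = np.abs(x[peaks[k]:seg_end]) > amplitude_floor
        if not seg.any():
            raise MeasurementError("no T wave found before the next beat")
        t_end = peaks[k] + int(np.nonzero(seg)[0][-1]) + 1
        qt.append((t_end - onsets[k]) / fs_hz * 1000.0)
    return measure_intervals(qt, rr, n_beats=n_beats, timepoint=timepoint)


# ---------------------------------------------------------------------------
# episode detection and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpisodeRecord:
    start_ms: float
    end_ms: float
    n_beats: int
    duration_s: float
    n_defibs: int
    polymorphic: bool

    @property
    def self_terminating(self) -> bool:
        return self.n_defibs == 0

    @property
    def is_tdp(self) -> bool:
        return self.polymorphic and self.n_beats >= MIN_TDP_RUN


def _sign_changes(morph: np.ndarray) -> int:
    s = np.sign(morph[morph != 0])
    return int(np.sum(s[1:] != s[:-1])) if s.size > 1 else 0


def detect_tdp_episodes(beats: pd.DataFrame,
                        events: Optional[pd.DataFrame] = None,
                        min_run: int = MIN_TDP_RUN) -> list[EpisodeRecord]:
    """Scan the beat stream for TdP episodes.

    Maximal runs of consecutive ECTOPIC beats of length >= ``min_run``
    with at least one morphology sign change qualify.  Defibrillation
    events are attributed to the episode they fall inside, or to the
    nearest preceding episode that ended within 5 s; events matching no
    episode raise a warning and stay unattributed.
    """
    df = beats.sort_values("time_ms", kind="stable", ignore_index=True)
    is_ect = (df["beat_class"] == ECTOPIC).to_numpy()
    times = df["time_ms"].to_numpy(dtype=float)
    morph = df["morphology_index"].to_numpy(dtype=float)
    episodes = []
    i = 0
    n = len(df)
    while i < n:
        if not is_ect[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_ect[j + 1]:
            j += 1
        run_len = j - i + 1
        poly = _sign_changes(morph[i:j + 1]) >= 1
        if run_len >= min_run and poly:
            episodes.append({
                "start_ms": float(times[i]), "end_ms": float(times[j]),
                "n_beats": run_len, "n_defibs": 0, "polymorphic": True})
        i = j + 1
    if events is not None and len(events):
        defibs = events[events["event_type"] == EVENT_DEFIB]
        for t in defibs["time_ms"].to_numpy(dtype=float):
            candidates = [ep for ep in episodes
                          if ep["start_ms"] <= t <= ep["end_ms"]
                          or 0.0 < t - ep["end_ms"] <= DEFIB_ATTRIBUTION_WINDOW_MS]
            if not candidates:
                warnings.warn(
                    f"defibrillation at {t:.0f} ms matches no episode; "
                    "left unattributed", stacklevel=2)
                continue
            max(candidates, key=lambda ep: ep["end_ms"])["n_defibs"] += 1
    return [EpisodeRecord(start_ms=ep["start_ms"], end_ms=ep["end_ms"],
                          n_beats=ep["n_beats"],
                          duration_s=(ep["end_ms"] - ep["start_ms"]) / 1000.0,
                          n_defibs=ep["n_defibs"], polymorphic=True)
            for ep in episodes]


def tdp_score(episode: EpisodeRecord) -> int:
    """Severity of one TdP episode.

    Self-terminating: the number of beats (capped at 49 so the score can
    never collide with the defibrillation codes; a cap triggers a
    warning).  Non-self-terminating: 50/75/100 points for 1/2/>=3
    defibrillations.
    """
    if not episode.is_tdp:
        raise ContractError(
            "tdp_score requires a classified TdP (>=5 consecutive "
            "polymorphic ectopic beats)")
    if episode.self_terminating:
        if episode.n_beats > MAX_SELF_TERMINATING_SCORE:
            warnings.warn(
                f"self-terminating episode of {episode.n_beats} beats capped "
                f"at {MAX_SELF_TERMINATING_SCORE} to avoid colliding with "
                "defibrillation codes", stacklevel=2)
            return MAX_SELF_TERMINATING_SCORE
        return episode.n_beats
    return {1: 50, 2: 75}.get(episode.n_defibs, 100)


def _severity_key(ep: EpisodeRecord) -> tuple:
    # any defibrillated episode outranks any self-terminating one; then
    # defib count; then beat count
    return (0 if ep.self_terminating else 1, ep.n_defibs, ep.n_beats)


@dataclass(frozen=True)
class BlockDefinition:
    block_id: str
    pacing_rate_bpm: float
    start_ms: float
    end_ms: float
    #: proarrhythmic-challenge block: the analysis window is anchored to
    #: the last 2 min before the first TdP instead of the block bounds
    anchor_to_first_tdp: bool = False


@dataclass(frozen=True)
class BlockSummary:
    block_id: str
    pacing_rate_bpm: float
    n_ectopic_beats: int
    n_tdp: int
    tdp_score: int
    window_ms: tuple[float, float]

    def __post_init__(self):
        if self.n_tdp == 0 and self.tdp_score != 0:
            raise ContractError("a block without TdP cannot carry a score")


def summarize_block(beats: pd.DataFrame, episodes: Sequence[EpisodeRecord],
                    block: BlockDefinition,
                    include_episode_beats: bool = True) -> BlockSummary:
    """Count ectopy and score the most severe TdP of one pacing block."""
    window = (block.start_ms, block.end_ms)
    block_eps = [ep for ep in episodes
                 if block.start_ms <= ep.start_ms < block.end_ms]
    if block.anchor_to_first_tdp:
        tdps = [ep for ep in block_eps if ep.is_tdp]
        if not tdps:
            raise MeasurementError(
                f"block {block.block_id}: no TdP to anchor the pre-TdP "
                "window to")
        first = min(tdps, key=lambda ep: ep.start_ms)
        window = (max(block.start_ms, first.start_ms - RVA50_LOOKBACK_MS),
                  first.start_ms)
        block_eps = [first]
    lo, hi = window
    in_win = beats[(beats["time_ms"] >= lo) & (beats["time_ms"] < hi)]
    ect = in_win[in_win["beat_class"] == ECTOPIC]
    n_ect = len(ect)
    if not include_episode_beats:
        for ep in block_eps:
            n_ect -= len(ect[(ect["time_ms"] >= ep.start_ms)
                             & (ect["time_ms"] <= ep.end_ms)])
    if block.anchor_to_first_tdp:
        # the anchoring TdP itself is counted even though it starts at the
        # window's right edge
        tdps = block_eps
    else:
        tdps = [ep for ep in block_eps if ep.is_tdp]
    score = tdp_score(max(tdps, key=_severity_key)) if tdps else 0
    return BlockSummary(block_id=block.block_id,
                        pacing_rate_bpm=block.pacing_rate_bpm,
                        n_ectopic_beats=int(n_ect), n_tdp=len(tdps),
                        tdp_score=score, window_ms=(float(lo), float(hi)))
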