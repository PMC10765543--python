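"""End-to-end orchestration: simulate -> detect -> disperse -> score -> report.

A run is fully specified by a :class:`RunConfig` (geometry, timepoint
schedule, seed, QC mode).  Under a fixed seed the run is deterministic:
the same config produces byte-identical summary tables.  The main
artifact is a serial summary table shaped like the experiments' group
table -- rows are electrophysiological parameters (RR, QT, QTc, wall
AT/RT, dRT, the four dispersion orientations) and arrhythmia scores,
columns are the protocol timepoints -- plus polar maps, restitution
curves and a machine-readable manifest.

``synthesize_dataset`` and ``analyze_dataset`` split the same run into a
file-based handshake (wide-CSV signals, annotation CSV, geometry JSON)
so recorded data in the same layout can be analyzed without the
generator; ``run_pipeline`` composes the two halves in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as sdrio
from .arrhythmia import (BlockDefinition, BlockSummary, EpisodeRecord,
                         IntervalMeasurement, detect_tdp_episodes,
                         measure_lead_intervals, summarize_block)
from .dispersion import (RTField, SDRSummary, polar_map_export, plot_polar_map,
                         sdr_summary)
from .egm import (BeatWindows, QCParams, QCResult, SmoothingConfig,
                  channel_qc, detect_fiducials)
from .errors import ComparisonError, ValidationError
from .grid import MappingGrid, Wall, build_default_grid, load_geometry, save_geometry
from .presets import TIMEPOINT_ORDER, TIMEPOINTS, timepoint_preset
from .restitution import build_restitution, plot_restitution
from .simulate import (EpisodeSpec, PacingBlock, RhythmParams,
                       RhythmRecord, assign_channel_quality,
                       generate_beat_series, generate_egm, generate_rt_field,
                       generate_surface_lead)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_arms",
           "validate_config", "default_protocol", "synthesize_dataset",
           "analyze_dataset", "SUMMARY_ROWS", "SUMMARY_SCHEMA_VERSION"]

log = logging.getLogger("sdrmap")

SUMMARY_SCHEMA_VERSION = "1"

SUMMARY_ROWS = [
    "RR (ms)", "QT (ms)", "QTc (ms)",
    "RV-AT (ms)", "LV-AT (ms)", "RV-RT (ms)", "LV-RT (ms)", "dRT (ms)",
    "Transmural dispersion (ms)", "Vertical dispersion (ms)",
    "Horizontal dispersion (ms)", "Cubic dispersion (ms)",
    "TdP occurrence (%)", "n TdP", "TdP score", "n ectopy",
]

DEFAULT_SCHEDULE = ("EB", "TdP", "RVA100", "RVA80", "RVA60")

#: which pacing block feeds the arrhythmia rows of each timepoint column
_BLOCK_FOR_TIMEPOINT = {"TdP": "RVA50", "RVA100": "RVA100",
                        "RVA80": "RVA80", "RVA60": "RVA60",
                        "RVA60_retro": "RVA60"}

LEAD_FS_HZ = 1024.0


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int
    out_dir: Optional[str] = None
    geometry: Optional[str] = None
    wrap: bool = True
    qc_mode: str = "channel"
    fs_hz: float = 2048.0
    timepoints: tuple[str, ...] = DEFAULT_SCHEDULE
    #: False analyses the truth fields directly (no waveform synthesis or
    #: detection); used for fast multi-seed calibration studies
    synthesize_signals: bool = True
    corrected_maps: bool = False
    render_figures: bool = False
    qc_params: QCParams = QCParams()
    smoothing: SmoothingConfig = SmoothingConfig()

    def config_hash(self) -> str:
        d = asdict(self)
        d["out_dir"] = None  # output location does not change the run
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violations (empty when valid)."""
    v = []
    if not isinstance(config.seed, (int, np.integer)):
        v.append("seed must be an integer (mandatory in synthesis mode)")
    if config.qc_mode not in ("channel", "needle"):
        v.append(f"qc_mode must be 'channel' or 'needle', got {config.qc_mode!r}")
    if config.fs_hz <= 0:
        v.append("fs_hz must be positive")
    if not config.timepoints:
        v.append("schedule must contain at least one timepoint")
    for t in config.timepoints:
        if t not in TIMEPOINTS:
            v.append(f"unknown timepoint {t!r}")
    known = [t for t in config.timepoints if t in TIMEPOINTS]
    order = [TIMEPOINT_ORDER.index(t) for t in known]
    if any(b <= a for a, b in zip(order, order[1:])):
        v.append("schedule must respect the protocol order "
                 f"{' -> '.join(TIMEPOINT_ORDER)}; got {list(config.timepoints)}")
    return v


def default_protocol(seed: int) -> RhythmParams:
    """The pacing protocol rendered as synthetic rhythm parameters.

    RVA50 carries the proarrhythmic challenge: dense ectopy and a
    sustained TdP (12 s, one cardioversion) at t = 300 s; pacing then
    steps through RVA100/80/60 for 2 min each.  Ectopy hazards are set
    so the expected per-block counts match the emulated experiments
    (about 87 ectopic beats in the 2 min before TdP, a handful at
    RVA100, ~33 at RVA60); TdP recurrence at RVA80/RVA60 happens with
    probability 0.25 per block, drawn reproducibly from the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11)))
    recur80 = (EpisodeSpec(n_beats=20, duration_s=11.0, n_defibs=1,
                           start_s=70.0),) if rng.random() < 0.25 else ()
    recur60 = (EpisodeSpec(n_beats=25, duration_s=11.0, n_defibs=1,
                           start_s=70.0),) if rng.random() < 0.25 else ()
    blocks = (
        PacingBlock("RVA50", 50.0, 360.0, ectopy_hazard=0.87,
                    episodes=(EpisodeSpec(n_beats=30, duration_s=12.0,
                                          n_defibs=1, start_s=300.0),)),
        PacingBlock("RVA100", 100.0, 120.0, ectopy_hazard=0.02),
        PacingBlock("RVA80", 80.0, 120.0, ectopy_hazard=0.05,
                    episodes=recur80),
        PacingBlock("RVA60", 60.0, 120.0, ectopy_hazard=0.28,
                    episodes=recur60),
    )
    return RhythmParams(blocks=blocks, seed=seed)


def _sub_seed(seed: int, *tags: int) -> int:
    """Derive a reproducible child seed below 2**31."""
    return int(np.random.SeedSequence((seed, *tags)).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------------------
# synthesis half
# ---------------------------------------------------------------------------

@dataclass
class TimepointData:
    """Synthetic inputs for one analysis timepoint."""

    name: str
    rr_ms: float
    qt_ms: float
    signals: Optional[dict]         # (needle_id, depth) -> trace
    lead: np.ndarray                # surface-lead segment
    truth: dict                     # at/rt per channel + quality labels


@dataclass
class SyntheticDataset:
    grid: MappingGrid
    fs_hz: float
    timepoints: dict[str, TimepointData]
    rhythm: RhythmRecord
    seed: int


def synthesize_dataset(config: RunConfig) -> SyntheticDataset:
    """Generate all inputs of a run (signals, lead segments, rhythm)."""
    violations = validate_config(config)
    if violations:
        raise ValidationError(violations)
    custom = config.geometry is not None
    grid = (load_geometry(config.geometry, wrap=config.wrap) if custom
            else build_default_grid(wrap=config.wrap))
    rhythm = generate_beat_series(default_protocol(_sub_seed(config.seed, 0)))
    tps: dict[str, TimepointData] = {}
    for name in config.timepoints:
        params, rr, qt = timepoint_preset(
            name, seed=_sub_seed(config.seed, 1, TIMEPOINT_ORDER.index(name)),
            grid=grid if custom else None, wrap=config.wrap)
        truth_field = generate_rt_field(grid, params, rr)
        rng = np.random.default_rng(np.random.SeedSequence(
            (config.seed, 2, TIMEPOINT_ORDER.index(name))))
        quality = assign_channel_quality(grid, rng)
        at_truth, rt_truth = truth_field.by_key("at"), truth_field.by_key("rt")
        signals = None
        if config.synthesize_signals:
            signals = {key: generate_egm(at_truth[key], rt_truth[key],
                                         quality[key], config.fs_hz,
                                         beat_window_ms=rr, rng=rng).signal
                       for key in at_truth}
        lead = generate_surface_lead([100.0 + i * rr for i in range(6)], qt,
                                     fs_hz=LEAD_FS_HZ).signal
        tps[name] = TimepointData(
            name=name, rr_ms=rr, qt_ms=qt, signals=signals, lead=lead,
            truth={"at_ms": at_truth, "rt_ms": rt_truth,
                   "quality": {k: q.label.value for k, q in quality.items()}})
    return SyntheticDataset(grid=grid, fs_hz=config.fs_hz, timepoints=tps,
                            rhythm=rhythm, seed=config.seed)


def write_dataset(ds: SyntheticDataset, out_dir) -> Path:
    """Write a dataset directory (geometry JSON, wide-CSV signals and lead
    segments, annotation CSV, truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_geometry(ds.grid, out / "geometry.json")
    sdrio.write_annotations_csv(out / "annotations.csv", ds.rhythm)
    sdrio.write_blocks_csv(out / "blocks.csv", ds.rhythm.blocks)
    meta = {"fs_hz": ds.fs_hz, "lead_fs_hz": LEAD_FS_HZ, "seed": ds.seed,
            "timepoints": {}}
    truth_sidecar = {"rhythm": ds.rhythm.truth["episodes"], "channels": {}}
    for name, tp in ds.timepoints.items():
        meta["timepoints"][name] = {"rr_ms": tp.rr_ms, "qt_ms": tp.qt_ms}
        if tp.signals is not None:
            sdrio.write_signals_csv(out / f"signals_{name}.csv", tp.signals,
                                    ds.grid, ds.fs_hz)
        pd.DataFrame({"time_ms": np.arange(len(tp.lead)) / LEAD_FS_HZ * 1000.0,
                      "lead_ii": tp.lead}).to_csv(
            out / f"lead_{name}.csv", index=False, float_format="%.6f")
        truth_sidecar["channels"][name] = {
            "{}:{}".format(*k): {"at_ms": tp.truth["at_ms"][k],
                                 "rt_ms": tp.truth["rt_ms"][k],
                                 "quality": tp.truth["quality"][k]}
            for k in tp.truth["at_ms"]}
    sdrio.write_json(out / "dataset.json", meta)
    sdrio.write_json(out / "truth.json", truth_sidecar)
    return out


def read_dataset(data_dir, *, wrap: bool = True) -> SyntheticDataset:
    """Load a dataset directory back (the truth sidecar is not consumed
    by the analysis; it is re-attached only if present, for scoring)."""
    data = Path(data_dir)
    grid = load_geometry(data / "geometry.json", wrap=wrap)
    meta = sdrio.read_json(data / "dataset.json")
    beats, events = sdrio.read_annotations_csv(data / "annotations.csv")
    blocks = sdrio.read_blocks_csv(data / "blocks.csv")
    rhythm = RhythmRecord(beats=beats, events=events, blocks=blocks, truth={})
    tps = {}
    for name, m in meta["timepoints"].items():
        sig_path = data / f"signals_{name}.csv"
        signals = None
        if sig_path.exists():
            signals, _ = sdrio.read_signals_csv(sig_path, grid)
        lead = pd.read_csv(data / f"lead_{name}.csv")["lead_ii"].to_numpy()
        tps[name] = TimepointData(name=name, rr_ms=m["rr_ms"],
                                  qt_ms=m["qt_ms"], signals=signals,
                                  lead=lead, truth={})
    return SyntheticDataset(grid=grid, fs_hz=meta["fs_hz"], timepoints=tps,
                            rhythm=rhythm, seed=meta.get("seed", -1))


# ---------------------------------------------------------------------------
# analysis half
# ---------------------------------------------------------------------------

@dataclass
class TimepointResult:
    name: str
    rr_ms: float
    field: RTField
    sdr: SDRSummary
    intervals: IntervalMeasurement
    qc: Optional[QCResult] = None


@dataclass
class RunResult:
    config: RunConfig
    grid: MappingGrid
    summary: pd.DataFrame
    timepoints: dict[str, TimepointResult]
    episodes: list[EpisodeRecord]
    block_summaries: dict[str, BlockSummary]
    rhythm: RhythmRecord
    restitution: Optional[tuple] = None
    out_dir: Optional[Path] = None


def _analyze_timepoint(tp: TimepointData, grid: MappingGrid,
                       config: RunConfig,
                       truth: Optional[dict]) -> TimepointResult:
    name, rr = tp.name, tp.rr_ms
    windows = BeatWindows.for_cycle_length(rr)
    qc_result = None
    if tp.signals is not None:
        qc_result = channel_qc(tp.signals, config.fs_hz, windows,
                               config.qc_params, grid=grid,
                               mode=config.qc_mode,
                               smoothing=config.smoothing)
        rt, at = {}, {}
        addr_by_key = {a.key: a for a in grid.electrodes()}
        for key in qc_result.accepted:
            fid = detect_fiducials(tp.signals[key], [windows], config.fs_hz,
                                   smoothing=config.smoothing,
                                   channel=addr_by_key[key])[0]
            rt[key], at[key] = fid.rt_ms, fid.at_ms
        field = RTField(grid=grid, rt_ms=rt, at_ms=at, rr_ms=rr,
                        timepoint=name)
        log.info("%s: %d/%d channels rejected by QC", name,
                 grid.n_electrodes - len(qc_result.accepted),
                 grid.n_electrodes)
    else:
        if truth is None:
            raise ValidationError([f"{name}: no signals and no truth field"])
        accepted = [k for k, q in truth["quality"].items() if q == "CLEAN"]
        field = RTField(
            grid=grid,
            rt_ms={k: truth["rt_ms"][k] for k in accepted},
            at_ms={k: truth["at_ms"][k] for k in accepted},
            rr_ms=rr, timepoint=name)
    sdr = sdr_summary(field)
    for orient in ("transmural", "vertical", "horizontal", "cubic"):
        if getattr(sdr, orient).is_empty:
            log.warning("%s: no eligible %s units", name, orient)
    intervals = measure_lead_intervals(tp.lead, LEAD_FS_HZ, n_beats=5,
                                       timepoint=name)
    return TimepointResult(name=name, rr_ms=rr, field=field, sdr=sdr,
                           intervals=intervals, qc=qc_result)


def _summary_table(results: dict[str, TimepointResult],
                   block_summaries: dict[str, BlockSummary]) -> pd.DataFrame:
    cols = {}
    for name, r in results.items():
        walls = r.sdr.walls or {}
        rv, lv = walls.get(Wall.RV), walls.get(Wall.LV)
        col = {
            "RR (ms)": r.intervals.rr_ms,
            "QT (ms)": r.intervals.qt_ms,
            "QTc (ms)": r.intervals.qtc_ms,
            "RV-AT (ms)": rv.at_mean_ms if rv else np.nan,
            "LV-AT (ms)": lv.at_mean_ms if lv else np.nan,
            "RV-RT (ms)": rv.rt_mean_ms if rv else np.nan,
            "LV-RT (ms)": lv.rt_mean_ms if lv else np.nan,
            "dRT (ms)": r.sdr.drt_ms if r.sdr.drt_ms is not None else np.nan,
            "Transmural dispersion (ms)": r.sdr.transmural.mean_ms,
            "Vertical dispersion (ms)": r.sdr.vertical.mean_ms,
            "Horizontal dispersion (ms)": r.sdr.horizontal.mean_ms,
            "Cubic dispersion (ms)": r.sdr.cubic.mean_ms,
        }
        blk = block_summaries.get(_BLOCK_FOR_TIMEPOINT.get(name, ""))
        if blk is not None:
            col["TdP occurrence (%)"] = 100.0 if blk.n_tdp > 0 else 0.0
            col["n TdP"] = blk.n_tdp
            col["TdP score"] = blk.tdp_score
            col["n ectopy"] = blk.n_ectopic_beats
        else:
            for k in ("TdP occurrence (%)", "n TdP", "TdP score", "n ectopy"):
                col[k] = np.nan
        cols[name] = col
    df = pd.DataFrame(cols, index=SUMMARY_ROWS, columns=list(results))
    df.index.name = "parameter"
    return df


def analyze_dataset(ds: SyntheticDataset, config: RunConfig,
                    truth_by_timepoint: Optional[Mapping[str, dict]] = None,
                    ) -> RunResult:
    """Run the full analysis on a dataset (synthetic or recorded)."""
    episodes = detect_tdp_episodes(ds.rhythm.beats, ds.rhythm.events)
    block_summaries = {}
    for _, row in ds.rhythm.blocks.iterrows():
        bd = BlockDefinition(block_id=row["block_id"],
                             pacing_rate_bpm=row["pacing_rate_bpm"],
                             start_ms=row["start_ms"], end_ms=row["end_ms"],
                             anchor_to_first_tdp=row["block_id"] == "RVA50")
        block_summaries[bd.block_id] = summarize_block(ds.rhythm.beats,
                                                       episodes, bd)
    results = {}
    for name, tp in ds.timepoints.items():
        truth = (truth_by_timepoint or {}).get(name) or tp.truth or None
        results[name] = _analyze_timepoint(tp, ds.grid, config, truth)
    summary = _summary_table(results, block_summaries)

    restit = None
    restit_fields = [r.field for n, r in results.items()
                     if n in ("EB", "RVA100", "RVA80", "RVA60")]
    if len({f.rr_ms for f in restit_fields}) >= 2:
        restit = build_restitution(restit_fields)

    out_dir = Path(config.out_dir) if config.out_dir else None
    result = RunResult(config=config, grid=ds.grid, summary=summary,
                       timepoints=results, episodes=episodes,
                       block_summaries=block_summaries, rhythm=ds.rhythm,
                       restitution=restit, out_dir=out_dir)
    if out_dir is not None:
        _write_artifacts(result)
    return result


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute one full synthetic run; see module docstring."""
    ds = synthesize_dataset(config)
    truth = {name: tp.truth for name, tp in ds.timepoints.items()}
    return analyze_dataset(ds, config, truth_by_timepoint=truth)


def _write_artifacts(result: RunResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    result.summary.to_csv(out / "summary.csv", float_format="%.3f")
    (out / "summary.json").write_text(
        result.summary.to_json(orient="index", indent=1) + "\n")
    unit_rows = []
    for name, r in result.timepoints.items():
        for orient in ("transmural", "vertical", "horizontal", "cubic"):
            res = getattr(r.sdr, orient)
            for uid, val in zip(res.unit_ids, res.unit_values):
                unit_rows.append((name, orient, "+".join(map(str, uid)), val))
    pd.DataFrame(unit_rows, columns=["timepoint", "orientation", "unit",
                                     "max_min_rt_ms"]).to_csv(
        out / "sdr_units.csv", index=False, float_format="%.3f")
    fid_rows = []
    for name, r in result.timepoints.items():
        rtc = r.field.rtc_ms
        for key, rt_val in sorted(r.field.rt_ms.items()):
            nid, depth = key
            n = result.grid.needle(nid)
            fid_rows.append({
                "channel_label": f"W{n.wall.code}L{n.level}C{n.column}D{depth}",
                "beat_id": 0, "at_ms": (r.field.at_ms or {}).get(key),
                "rt_ms": rt_val, "rtc_ms": rtc[key], "qc": "ACCEPT",
                "timepoint": name})
    pd.DataFrame(fid_rows).to_csv(out / "fiducials.csv", index=False,
                                  float_format="%.3f")
    pd.DataFrame([{"block_id": b.block_id,
                   "pacing_rate_bpm": b.pacing_rate_bpm,
                   "n_ectopic_beats": b.n_ectopic_beats,
                   "n_tdp": b.n_tdp, "tdp_score": b.tdp_score,
                   "window_start_ms": b.window_ms[0],
                   "window_end_ms": b.window_ms[1]}
                  for b in result.block_summaries.values()]).to_csv(
        out / "block_summaries.csv", index=False, float_format="%.3f")
    sdrio.write_annotations_csv(out / "annotations.csv", result.rhythm)
    sdrio.write_blocks_csv(out / "blocks.csv", result.rhythm.blocks)
    if result.restitution is not None:
        rv, lv, report = result.restitution
        rows = [{"ventricle": c.ventricle.code, "rr_ms": p[0],
                 "mean_rt_ms": p[1], "slope_ms_per_ms": c.slope_ms_per_ms,
                 "intercept_ms": c.intercept_ms}
                for c in (rv, lv) for p in c.points]
        pd.DataFrame(rows).to_csv(out / "restitution.csv", index=False,
                                  float_format="%.4f")
        if cfg.render_figures:
            plot_restitution(rv, lv, out / "restitution.png")
    for name, r in result.timepoints.items():
        pmap = polar_map_export(r.field, use_corrected=cfg.corrected_maps)
        (out / f"polar_map_{name}.json").write_text(pmap.to_json() + "\n")
        if cfg.render_figures:
            plot_polar_map(pmap, out / f"polar_map_{name}.png")
    manifest = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "geometry_fingerprint": hashlib.sha256(
            result.grid.fingerprint().encode()).hexdigest()[:16],
        "timepoints": list(cfg.timepoints),
        "summary_rows": SUMMARY_ROWS,
    }
    sdrio.write_json(out / "manifest.json", manifest)


# ---------------------------------------------------------------------------
# arm comparison
# ---------------------------------------------------------------------------

def _as_runs(x) -> list[RunResult]:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def compare_arms(runs_a, runs_b,
                 timepoint_a: Optional[str] = None,
                 timepoint_b: Optional[str] = None) -> pd.DataFrame:
    """Descriptive side-by-side comparison of two arms.

    Each arm is one run or a sequence of runs (seeds); the compared
    column defaults to the arm's last scheduled timepoint.  Rows are the
    summary metrics; columns give per-arm mean and SD over runs plus the
    difference of means.  No inferential statistics are computed.
    """
    a, b = _as_runs(runs_a), _as_runs(runs_b)
    fp = {r.grid.fingerprint() for r in a + b}
    if len(fp) != 1:
        raise ComparisonError("runs use different grid geometries")
    schemas = {tuple(r.summary.index) for r in a + b}
    if len(schemas) != 1:
        raise ComparisonError("runs use different summary schemas")
    tp_a = timepoint_a or a[0].config.timepoints[-1]
    tp_b = timepoint_b or b[0].config.timepoints[-1]
    va = pd.concat([r.summary[tp_a] for r in a], axis=1)
    vb = pd.concat([r.summary[tp_b] for r in b], axis=1)
    df = pd.DataFrame({
        f"A:{tp_a} mean": va.mean(axis=1),
        f"A:{tp_a} sd": va.std(axis=1, ddof=1) if len(a) > 1 else 0.0,
        f"B:{tp_b} mean": vb.mean(axis=1),
        f"B:{tp_b} sd": vb.std(axis=1, ddof=1) if len(b) > 1 else 0.0,
    })
    df["difference (A-B)"] = df[f"A:{tp_a} mean"] - df[f"B:{tp_b} mean"]
    df.index.name = "parameter"
    return df
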