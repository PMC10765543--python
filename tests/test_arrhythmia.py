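import numpy as np
import pandas as pd
import pytest

from oracles import brute_episode_scan
from sdrmap.arrhythmia import (BlockDefinition, EpisodeRecord,
                               detect_tdp_episodes, measure_intervals,
                               qtc_van_de_water, round_half_up,
                               summarize_block, tdp_score)
from sdrmap.errors import ContractError, MeasurementError
from sdrmap.simulate import (EpisodeSpec, PacingBlock, RhythmParams,
                             generate_beat_series)


def beats_frame(rows):
    """rows: (time_ms, beat_class, morphology_index)"""
    return pd.DataFrame(rows, columns=["time_ms", "beat_class",
                                       "morphology_index"]).assign(block_id="B")


def run_of(n, start=0.0, step=400.0, alternating=True, pad=True):
    rows = []
    if pad:
        rows.append((start - step, "PACED", 1.0))
    for i in range(n):
        m = (-1.0) ** i if alternating else 1.0
        rows.append((start + i * step, "ECTOPIC", m))
    if pad:
        rows.append((start + n * step, "PACED", 1.0))
    return beats_frame(rows)


class TestIntervals:
    def test_five_beat_average(self):
        m = measure_intervals([451, 452, 453, 454, 455], 600.0)
        assert m.qt_ms == 453.0 and m.rr_ms == 600.0
        assert m.qtc_ms == pytest.approx(487.8)

    def test_too_few_beats_errors(self):
        with pytest.raises(MeasurementError):
            measure_intervals([450, 451, 452, 453], 600.0, n_beats=5)

    @pytest.mark.parametrize("qt, rr, expected", [
        (453.0, 600.0, 488), (508.0, 750.0, 530),
        (626.0, 1200.0, 609), (598.0, 1000.0, 598)])
    def test_qtc_rounds_to_table_values(self, qt, rr, expected):
        assert round_half_up(qtc_van_de_water(qt, rr)) == expected

    def test_qtc_identity_at_rr_1000(self):
        for qt in (300.0, 456.7, 620.0):
            assert qtc_van_de_water(qt, 1000.0) == qt


class TestEpisodeDetection:
    def test_four_beat_run_is_not_an_episode(self):
        assert detect_tdp_episodes(run_of(4)) == []

    def test_five_alternating_beats_self_terminating_episode(self):
        eps = detect_tdp_episodes(run_of(5))
        assert len(eps) == 1
        ep = eps[0]
        assert ep.n_beats == 5 and ep.self_terminating and ep.is_tdp

    def test_monomorphic_run_is_ectopy_only(self):
        assert detect_tdp_episodes(run_of(8, alternating=False)) == []

    def test_long_episode_with_defibrillation(self):
        beats = run_of(30, step=400.0)  # spans 11.6 s
        end = 29 * 400.0
        events = pd.DataFrame([(end + 1000.0, "defibrillation", "B")],
                              columns=["time_ms", "event_type", "block_id"])
        (ep,) = detect_tdp_episodes(beats, events)
        assert ep.n_defibs == 1 and not ep.self_terminating
        assert ep.duration_s == pytest.approx(11.6)

    def test_unmatched_defib_warns(self):
        events = pd.DataFrame([(99000.0, "defibrillation", "B")],
                              columns=["time_ms", "event_type", "block_id"])
        with pytest.warns(UserWarning, match="unattributed"):
            detect_tdp_episodes(run_of(5), events)

    def test_matches_bruteforce_run_scan_on_random_streams(self):
        """100 seeded random beat streams: episode starts/ends/sizes match
        an independent run-length scan."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = []
            t = 0.0
            for _ in range(rng.integers(30, 120)):
                t += float(rng.uniform(300, 900))
                if rng.random() < 0.4:
                    m = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5))
                    rows.append((t, "ECTOPIC", m))
                else:
                    rows.append((t, "PACED", 1.0))
            beats = beats_frame(rows)
            got = [(e.start_ms, e.end_ms, e.n_beats)
                   for e in detect_tdp_episodes(beats)]
            want = brute_episode_scan([tuple(r) for r in rows])
            assert got == want, seed


class TestScoring:
    def mk(self, n_beats, n_defibs, polymorphic=True):
        return EpisodeRecord(start_ms=0.0, end_ms=n_beats * 400.0,
                             n_beats=n_beats, duration_s=n_beats * 0.4,
                             n_defibs=n_defibs, polymorphic=polymorphic)

    def test_self_terminating_scores_beat_count(self):
        assert tdp_score(self.mk(12, 0)) == 12

    @pytest.mark.parametrize("n_defibs, expected",
                             [(1, 50), (2, 75), (3, 100), (5, 100)])
    def test_defibrillated_scores(self, n_defibs, expected):
        assert tdp_score(self.mk(30, n_defibs)) == expected

    def test_non_tdp_rejected(self):
        with pytest.raises(ContractError):
            tdp_score(self.mk(4, 0))
        with pytest.raises(ContractError):
            tdp_score(self.mk(10, 0, polymorphic=False))

    def test_self_terminating_above_49_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            assert tdp_score(self.mk(60, 0)) == 49

    def test_score_range_always_valid(self):
        import itertools
        for n, d in itertools.product((5, 12, 49), (0, 1, 2, 3, 4)):
            s = tdp_score(self.mk(n, d))
            assert s == 0 or 5 <= s <= 49 or s in (50, 75, 100)


class TestBlockSummary:
    def test_most_severe_episode_scored(self):
        eps = [EpisodeRecord(1000.0, 4000.0, 8, 3.0, 0, True),
               EpisodeRecord(10000.0, 22000.0, 30, 12.0, 1, True)]
        beats = beats_frame([(t, "PACED", 1.0) for t in (0.0, 500.0)])
        blk = BlockDefinition("B", 80.0, 0.0, 30000.0)
        s = summarize_block(beats, eps, blk)
        assert s.tdp_score == 50 and s.n_tdp == 2

    def test_block_without_episodes(self):
        beats = beats_frame([(t * 500.0, "ECTOPIC", 1.0) for t in range(4)])
        s = summarize_block(beats, [], BlockDefinition("B", 80.0, 0.0, 5000.0))
        assert s.n_ectopic_beats == 4 and s.n_tdp == 0 and s.tdp_score == 0

    def test_counting_conservation_over_disjoint_blocks(self):
        params = RhythmParams(blocks=(
            PacingBlock("B1", 100.0, 60.0, ectopy_hazard=0.3),
            PacingBlock("B2", 80.0, 60.0, ectopy_hazard=0.5),
            PacingBlock("B3", 60.0, 60.0, ectopy_hazard=0.1)), seed=17)
        rec = generate_beat_series(params)
        eps = detect_tdp_episodes(rec.beats, rec.events)
        total = 0
        for _, row in rec.blocks.iterrows():
            bd = BlockDefinition(row["block_id"], row["pacing_rate_bpm"],
                                 row["start_ms"], row["end_ms"])
            total += summarize_block(rec.beats, eps, bd).n_ectopic_beats
        assert total == int((rec.beats["beat_class"] == "ECTOPIC").sum())

    def test_rva50_window_anchored_to_first_tdp(self):
        """The pre-TdP window spans the 2 min before the first TdP; a
        stream built with 87 ectopic beats in that window reports 87."""
        rows = []
        tdp_start = 180000.0
        # 87 isolated ectopic beats inside [60 s, 180 s)
        for i in range(87):
            t = 60000.0 + i * 1300.0
            rows.append((t, "PACED", 1.0))
            rows.append((t + 600.0, "ECTOPIC", 1.0))
        # earlier ectopy that must fall outside the window
        rows.append((30000.0, "ECTOPIC", 1.0))
        # a paced beat separating the singles from the TdP run
        rows.append((176000.0, "PACED", 1.0))
        for j in range(12):
            rows.append((tdp_start + j * 350.0, "ECTOPIC", (-1.0) ** j))
        beats = beats_frame(sorted(rows))
        eps = detect_tdp_episodes(beats)
        blk = BlockDefinition("RVA50", 50.0, 0.0, 200000.0,
                              anchor_to_first_tdp=True)
        s = summarize_block(beats, eps, blk)
        assert s.n_ectopic_beats == 87
        assert s.window_ms == (tdp_start - 120000.0, tdp_start)
        assert s.n_tdp == 1 and s.tdp_score == 12

    def test_rva50_without_tdp_errors(self):
        beats = beats_frame([(0.0, "PACED", 1.0)])
        blk = BlockDefinition("RVA50", 50.0, 0.0, 1000.0,
                              anchor_to_first_tdp=True)
        with pytest.raises(MeasurementError):
            summarize_block(beats, [], blk)
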