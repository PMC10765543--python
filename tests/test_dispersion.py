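import math

import numpy as np
import pytest

from conftest import make_wall_grid, random_toy_grid
from oracles import brute_sdr
from sdrmap.dispersion import (RTField, SDROrientation, interventricular_drt,
                               polar_map_export, sdr_orientation, sdr_summary,
                               wall_summaries)
from sdrmap.errors import AnalysisError
from sdrmap.grid import N_DEPTHS, Wall, build_default_grid


def full_field(grid, value_fn, rr_ms=600.0, timepoint=None):
    rt = {(n.needle_id, d): value_fn(n, d)
          for n in grid.needles for d in range(N_DEPTHS)}
    return RTField(grid=grid, rt_ms=rt, rr_ms=rr_ms, timepoint=timepoint)


def random_field(grid, rng, keep=1.0):
    rt = {}
    for n in grid.needles:
        for d in range(N_DEPTHS):
            if rng.random() <= keep:
                rt[(n.needle_id, d)] = float(rng.normal(400.0, 40.0))
    return RTField(grid=grid, rt_ms=rt, rr_ms=600.0)


class TestOrientationUnits:
    def test_uniform_field_all_orientations_zero(self, default_grid):
        f = full_field(default_grid, lambda n, d: 400.0)
        for o in SDROrientation:
            res = sdr_orientation(f, o)
            assert res.mean_ms == 0.0 and res.n_units > 0

    def test_single_needle_transmural_range(self):
        g = make_wall_grid(n_levels=1, n_cols=1)
        rts = {(0, 0): 300.0, (0, 1): 310.0, (0, 2): 320.0, (0, 3): 340.0}
        f = RTField(grid=g, rt_ms=rts)
        res = sdr_orientation(f, SDROrientation.TRANSMURAL)
        assert res.unit_values == (40.0,)

    def test_empty_result_is_explicit_not_zero(self):
        g = make_wall_grid(n_levels=1, n_cols=2)  # no squares possible
        f = full_field(g, lambda n, d: 400.0)
        res = sdr_orientation(f, SDROrientation.CUBIC)
        assert res.is_empty and res.mean_ms is None and res.n_units == 0

    @pytest.mark.parametrize("orientation", list(SDROrientation))
    def test_matches_bruteforce_oracle_on_random_lattices(self, orientation):
        """100 random toy lattices with random dropout: every orientation
        mean equals an independent exhaustive enumeration exactly."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            grid = random_toy_grid(rng)
            field = random_field(grid, rng, keep=0.8)
            res = sdr_orientation(field, orientation)
            o_mean, o_n, _ = brute_sdr(grid, field.rt_ms, orientation.value)
            assert res.n_units == o_n, seed
            if o_mean is None:
                assert res.mean_ms is None
            else:
                assert res.mean_ms == pytest.approx(o_mean, abs=1e-9), seed

    def test_shift_invariance(self, default_grid):
        rng = np.random.default_rng(1)
        f = random_field(default_grid, rng)
        shifted = RTField(grid=default_grid,
                          rt_ms={k: v + 123.4 for k, v in f.rt_ms.items()},
                          rr_ms=600.0)
        for o in SDROrientation:
            assert sdr_orientation(f, o).mean_ms == pytest.approx(
                sdr_orientation(shifted, o).mean_ms, abs=1e-9)
        assert interventricular_drt(f) == pytest.approx(
            interventricular_drt(shifted), abs=1e-9)

    def test_cubic_unit_dominates_member_units(self, default_grid):
        """Per square: the cubic max-min is >= each member needle's
        transmural value and each member pair's value."""
        rng = np.random.default_rng(2)
        f = random_field(default_grid, rng)
        cubic = sdr_orientation(f, SDROrientation.CUBIC)
        trans = dict(zip([u[0] for u in sdr_orientation(
            f, SDROrientation.TRANSMURAL).unit_ids],
            sdr_orientation(f, SDROrientation.TRANSMURAL).unit_values))
        pair_vals = {}
        for o in (SDROrientation.VERTICAL, SDROrientation.HORIZONTAL):
            res = sdr_orientation(f, o)
            pair_vals.update(dict(zip(res.unit_ids, res.unit_values)))
        for unit, val in zip(cubic.unit_ids, cubic.unit_values):
            members = set(unit)
            for nid in members:
                assert val >= trans[nid] - 1e-12
            for pair, pv in pair_vals.items():
                if set(pair) <= members:
                    assert val >= pv - 1e-12

    def test_rejections_never_manufacture_units(self, default_grid):
        rng = np.random.default_rng(3)
        f = random_field(default_grid, rng)
        keys = sorted(f.rt_ms)
        rng.shuffle(keys)
        prev = {o: sdr_orientation(f, o).n_units for o in SDROrientation}
        reduced = dict(f.rt_ms)
        for k in keys[:120]:
            del reduced[k]
            g = RTField(grid=default_grid, rt_ms=reduced, rr_ms=600.0)
            now = {o: sdr_orientation(g, o).n_units for o in SDROrientation}
            for o in SDROrientation:
                assert now[o] <= prev[o]
            prev = now


class TestWallMetrics:
    def test_drt_from_wall_means(self, default_grid):
        f = full_field(default_grid,
                       lambda n, d: {Wall.LV: 453.0, Wall.RV: 363.0,
                                     Wall.SEPTUM: 400.0}[n.wall])
        assert interventricular_drt(f) == pytest.approx(90.0)
        f2 = full_field(default_grid,
                        lambda n, d: {Wall.LV: 363.0, Wall.RV: 330.0,
                                      Wall.SEPTUM: 345.0}[n.wall])
        assert interventricular_drt(f2) == pytest.approx(33.0)

    def test_identical_walls_zero_drt(self, default_grid):
        f = full_field(default_grid, lambda n, d: 400.0)
        assert interventricular_drt(f) == 0.0

    def test_one_ventricle_fully_rejected_names_empty_side(self, default_grid):
        rt = {(n.needle_id, d): 400.0 for n in default_grid.needles
              for d in range(N_DEPTHS) if n.wall is not Wall.RV}
        f = RTField(grid=default_grid, rt_ms=rt)
        with pytest.raises(AnalysisError, match="RV"):
            interventricular_drt(f)

    def test_wall_means_exact_and_septum_separate(self, default_grid):
        f = full_field(default_grid,
                       lambda n, d: {Wall.LV: 480.0, Wall.RV: 403.0,
                                     Wall.SEPTUM: 440.0}[n.wall])
        walls = wall_summaries(f)
        assert walls[Wall.LV].rt_mean_ms == pytest.approx(480.0)
        assert walls[Wall.RV].rt_mean_ms == pytest.approx(403.0)
        assert walls[Wall.SEPTUM].rt_mean_ms == pytest.approx(440.0)

    def test_septum_only_field_has_no_ventricular_summaries(self):
        g = make_wall_grid(wall=Wall.SEPTUM, n_levels=2, n_cols=2)
        f = full_field(g, lambda n, d: 400.0)
        walls = wall_summaries(f)
        assert Wall.RV not in walls and Wall.LV not in walls
        with pytest.raises(AnalysisError):
            interventricular_drt(f)

    def test_single_electrode_wall_sd_zero_with_flag(self):
        g = make_wall_grid(wall=Wall.LV, n_levels=1, n_cols=1)
        f = RTField(grid=g, rt_ms={(0, 0): 412.0})
        s = wall_summaries(f)[Wall.LV]
        assert s.n == 1 and s.rt_sd_ms == 0.0 and s.single_electrode


class TestPolarMaps:
    def test_uniform_field_yields_zero_gradients(self, default_grid):
        f = full_field(default_grid, lambda n, d: 400.0, timepoint="RVA100")
        pmap = polar_map_export(f)
        for panel in pmap.panels.values():
            assert all(v == 400.0 for v in panel["cells"].values())
            assert all(dv == 0.0 for _, _, dv in panel["deltas"])

    def test_hot_needle_gradient_to_each_neighbor(self, default_grid):
        hot = default_grid.needles[10].needle_id
        f = full_field(default_grid,
                       lambda n, d: 500.0 if n.needle_id == hot else 400.0)
        pmap = polar_map_export(f)
        site = default_grid.needle(hot)
        panel = pmap.panels[site.wall.code]
        hot_cell = (site.level, site.column)
        touching = [dv for a, b, dv in panel["deltas"]
                    if hot_cell in (a, b)]
        assert touching and all(dv == pytest.approx(100.0) for dv in touching)

    def test_corrected_map_is_constant_shift_at_fixed_rr(self, default_grid):
        """At RR 600 the Van de Water correction adds 0.087 x 400 = 34.8 ms
        to every cell; gradient annotations are untouched."""
        rng = np.random.default_rng(4)
        f = random_field(default_grid, rng)
        raw = polar_map_export(f, use_corrected=False)
        cor = polar_map_export(f, use_corrected=True)
        for wall in raw.panels:
            for cell, v in raw.panels[wall]["cells"].items():
                assert cor.panels[wall]["cells"][cell] - v == pytest.approx(
                    34.8, abs=1e-9)
            for (a0, b0, d0), (a1, b1, d1) in zip(raw.panels[wall]["deltas"],
                                                  cor.panels[wall]["deltas"]):
                assert (a0, b0) == (a1, b1)
                assert d0 == pytest.approx(d1, abs=1e-9)

    def test_layout_json_serializes(self, default_grid):
        import json
        f = full_field(default_grid, lambda n, d: 400.0)
        parsed = json.loads(polar_map_export(f).to_json())
        assert set(parsed["panels"]) == {"RV", "LV", "SEP"}


def test_summary_bundle_contains_all_orientations(default_grid):
    rng = np.random.default_rng(5)
    f = random_field(default_grid, rng)
    s = sdr_summary(f)
    assert s.cubic.n_units == len(default_grid.squares)
    assert s.drt_ms is not None
    assert set(s.walls) == {Wall.RV, Wall.LV, Wall.SEPTUM}
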