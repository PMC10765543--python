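"""Independent brute-force oracles used to cross-check the implementation.

These re-derive the dispersion units and episode runs directly from first
principles (nested loops over wall/level/column coordinates, plain list
scans), deliberately sharing no code with the package's adjacency or
run-length machinery.
"""

from collections import defaultdict

from sdrmap.grid import MappingGrid, Wall

RING_WALLS = {Wall.RV, Wall.LV}
MIN_PER_NEEDLE = 2
MIN_TOTAL = {"transmural": 2, "vertical": 4, "horizontal": 4, "cubic": 8}


def _coord_values(grid: MappingGrid, rt_by_key):
    """(wall, level, column) -> list of accepted electrode values."""
    out = defaultdict(list)
    for (nid, depth), v in rt_by_key.items():
        n = grid.needle(nid)
        out[(n.wall, n.level, n.column)].append(v)
    return out


def _col_pairs(wall, cols_present, ncols, wrap):
    pairs = set()
    if wrap and wall in RING_WALLS and ncols >= 2:
        for c in range(ncols):
            c2 = (c + 1) % ncols
            if c in cols_present and c2 in cols_present and c != c2:
                pairs.add(frozenset((c, c2)))
    else:
        for c in range(ncols - 1):
            if c in cols_present and (c + 1) in cols_present:
                pairs.add(frozenset((c, c + 1)))
    return [tuple(sorted(p)) for p in sorted(pairs, key=sorted)]


def brute_sdr(grid: MappingGrid, rt_by_key, orientation: str):
    """Mean, unit count and unit values for one orientation, by exhaustive
    enumeration over lattice coordinates."""
    vals_at = _coord_values(grid, rt_by_key)
    walls = sorted({n.wall for n in grid.needles}, key=lambda w: w.code)
    ncols = {w: max((n.column for n in grid.needles if n.wall is w),
                    default=-1) + 1 for w in walls}
    levels = {w: sorted({n.level for n in grid.needles if n.wall is w})
              for w in walls}
    units = []
    for w in walls:
        for lvl in levels[w]:
            cols_here = {c for (w2, l2, c) in vals_at if w2 is w and l2 == lvl}
            cols_in_wall = {n.column for n in grid.needles if n.wall is w}
            if orientation == "transmural":
                for c in sorted(cols_in_wall):
                    units.append([(w, lvl, c)])
            elif orientation == "vertical":
                for c in sorted(cols_in_wall):
                    units.append([(w, lvl, c), (w, lvl + 1, c)])
            elif orientation == "horizontal":
                for c, c2 in _col_pairs(w, cols_in_wall, ncols[w], grid.wrap):
                    units.append([(w, lvl, c), (w, lvl, c2)])
            elif orientation == "cubic":
                for c, c2 in _col_pairs(w, cols_in_wall, ncols[w], grid.wrap):
                    units.append([(w, lvl, c), (w, lvl, c2),
                                  (w, lvl + 1, c), (w, lvl + 1, c2)])
    results = []
    seen = set()
    for unit in units:
        key = frozenset(unit)
        if key in seen or len(key) != len(unit):
            continue
        # every coordinate must exist as a needle in the grid
        coords = {(n.wall, n.level, n.column) for n in grid.needles}
        if any(u not in coords for u in unit):
            continue
        seen.add(key)
        member_vals = [vals_at.get(u, []) for u in unit]
        if any(len(v) < MIN_PER_NEEDLE for v in member_vals):
            continue
        pool = [x for v in member_vals for x in v]
        if len(pool) < MIN_TOTAL[orientation]:
            continue
        results.append(max(pool) - min(pool))
    mean = sum(results) / len(results) if results else None
    return mean, len(results), results


def brute_episode_scan(beat_rows, min_run=5):
    """Run-length scan over (time, class, morphology) tuples; returns
    (start, end, n_beats) for qualifying polymorphic runs."""
    runs = []
    current = []
    for t, cls, m in sorted(beat_rows):
        if cls == "ECTOPIC":
            current.append((t, m))
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    episodes = []
    for run in runs:
        if len(run) < min_run:
            continue
        signs = [1 if m > 0 else -1 for _, m in run if m != 0]
        if any(a != b for a, b in zip(signs, signs[1:])):
            episodes.append((run[0][0], run[-1][0], len(run)))
    return episodes
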