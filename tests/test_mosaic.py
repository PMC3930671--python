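"""Patch delineation, disk-union geometry, gap morphology, summaries."""

import numpy as np
import pytest

from icomosaic.core import PlotWindow, StemMap
from icomosaic.mosaic import (Gap, delineate_gaps, delineate_patches,
                              filter_edge_gaps, patch_geometry,
                              summarize_gaps, summarize_mosaic)

from conftest import make_tree, random_crowned_map


def crowned_map(window, specs):
    """specs: iterable of (x, y, crown_radius)."""
    return StemMap(window, [
        make_tree(i, x, y, crown_radius=r) for i, (x, y, r) in enumerate(specs)
    ])


def oracle_partition(stemmap):
    """Brute-force pairwise union-find over all live crowned trees."""
    live = [t for t in stemmap.trees if t.status == "live"]
    parent = list(range(len(live)))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(len(live)):
        for j in range(i + 1, len(live)):
            d = np.hypot(live[i].x - live[j].x, live[i].y - live[j].y)
            if d < live[i].crown_radius + live[j].crown_radius:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(len(live)):
        comps.setdefault(find(i), set()).add(live[i].id)
    return {frozenset(c) for c in comps.values()}


class TestDelineatePatches:
    def test_overlap_threshold(self, window200):
        # radii 3 and 2: centres 6 m apart do not touch, 4.9 m overlap
        apart = crowned_map(window200, [(50, 50, 3.0), (56, 50, 2.0)])
        near = crowned_map(window200, [(50, 50, 3.0), (54.9, 50, 2.0)])
        tangent = crowned_map(window200, [(50, 50, 3.0), (55, 50, 2.0)])
        assert len(delineate_patches(apart).patches) == 0
        assert len(delineate_patches(apart).singles) == 2
        assert delineate_patches(near).patches[0].n_trees == 2
        # strict inequality: tangent crowns are not a patch
        assert len(delineate_patches(tangent).patches) == 0

    def test_chain_transitivity(self, window200):
        sm = crowned_map(window200,
                         [(50, 50, 3.0), (55, 50, 3.0), (60, 50, 3.0)])
        part = delineate_patches(sm)
        assert len(part.patches) == 1 and part.patches[0].n_trees == 3

    def test_matches_bruteforce_oracle(self, window200):
        from icomosaic.core import partition_by_buffer

        sm = random_crowned_map(window200, 300, seed=5)
        part = delineate_patches(sm, geometry=False)
        expect = oracle_partition(sm)
        buffer_ids = {t.id for t, lbl in zip(sm.trees, partition_by_buffer(sm))
                      if lbl == "buffer"}
        # every patch's full component must be an oracle component, with the
        # member list being its interior part
        for p in part.patches:
            comp = frozenset(t.id for t in p.geometry_members)
            assert comp in expect
            assert {t.id for t in p.members} == set(comp) - buffer_ids
        # every single tree is the lone interior member of its component
        for t in part.singles:
            comp = next(c for c in expect if t.id in c)
            assert len(set(comp) - buffer_ids) == 1
        # conservation against the oracle's interior count
        n_interior = sum(len(set(c) - buffer_ids) > 0 and
                         len(set(c) - buffer_ids) or 0 for c in expect)
        assert part.n_interior_live == n_interior

    def test_conservation_of_interior_live_trees(self, window200):
        from icomosaic.core import partition_by_buffer

        sm = random_crowned_map(window200, 400, seed=9)
        lbl = partition_by_buffer(sm)
        n_interior = int((lbl == "interior").sum())
        part = delineate_patches(sm, geometry=False)
        assert part.n_interior_live == n_interior

    def test_missing_crowns_rejected(self, window200):
        sm = StemMap(window200, [make_tree(0, 10, 10), make_tree(1, 12, 10)])
        with pytest.raises(ValueError):
            delineate_patches(sm)

    def test_empty_map(self, window200):
        part = delineate_patches(StemMap(window200, []))
        assert part.patches == [] and part.singles == []


class TestPatchGeometry:
    def test_two_circle_union_lens_formula(self):
        r, d = 3.0, 2.0
        members = [make_tree(0, 50, 50, crown_radius=r),
                   make_tree(1, 52, 50, crown_radius=r)]
        _, area, _ = patch_geometry(members)
        half = d / 2.0
        lens = 2 * r * r * np.arccos(half / r) - half * np.sqrt(r * r - half * half) * 2
        expect = 2 * np.pi * r * r - lens
        assert area == pytest.approx(expect, rel=0.005)

    def test_coincident_disks(self):
        members = [make_tree(0, 50, 50, crown_radius=4.0),
                   make_tree(1, 50, 50, crown_radius=4.0)]
        _, area, _ = patch_geometry(members)
        assert area == pytest.approx(np.pi * 16.0, rel=0.005)

    def test_union_bounded_by_disk_sum(self, window200):
        sm = random_crowned_map(window200, 50, seed=3)
        part = delineate_patches(sm)
        for p in part.patches:
            disk_sum = sum(np.pi * t.crown_radius**2
                           for t in p.geometry_members)
            assert p.area <= disk_sum + 1e-9

    def test_monte_carlo_darts(self, window200):
        rng = np.random.default_rng(1)
        members = [make_tree(i, rng.uniform(40, 60), rng.uniform(40, 60),
                             crown_radius=rng.uniform(1, 4))
                   for i in range(12)]
        _, area, _ = patch_geometry(members)
        darts = rng.uniform(30, 70, size=(200_000, 2))
        centres = np.array([[t.x, t.y] for t in members])
        radii = np.array([t.crown_radius for t in members])
        d2 = ((darts[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
        hit = (d2 <= radii**2).any(axis=1).mean()
        mc_area = hit * 40.0 * 40.0
        assert area == pytest.approx(mc_area, rel=0.01)


class TestSummaries:
    def test_category_counting(self, window200):
        """Patch sizes {2,3,5,10,12} land in categories 2-4:2, 5-9:1, 10+:2."""
        specs = []
        x0 = 20.0
        for size in (2, 3, 5, 10, 12):
            for k in range(size):
                specs.append((x0 + 1.5 * k, 100.0, 1.0))
            x0 += 40.0
        sm = crowned_map(window200, specs)
        part = delineate_patches(sm)
        tab = summarize_mosaic(part)["categories"]
        assert tab.loc["2-4", "n_patches"] == 2
        assert tab.loc["5-9", "n_patches"] == 1
        assert tab.loc["10+", "n_patches"] == 2
        assert tab.loc["2", "n_patches"] == 1

    def test_proportions_sum_to_one(self, window200):
        sm = random_crowned_map(window200, 300, seed=12)
        part = delineate_patches(sm)
        tabs = summarize_mosaic(part)
        total = (tabs["categories"].loc[["2-4", "5-9", "10+"],
                                        "prop_trees_pct"].sum()
                 + tabs["singles"]["prop_trees_pct"].iloc[0])
        assert total == pytest.approx(100.0)

    def test_hand_worked_toy_map(self):
        """10-tree map: one 3-patch, one 2-patch, five singles (checked by hand)."""
        w = PlotWindow(0, 0, 100, 100, buffer_width=5)
        specs = [
            (20, 20, 2.0), (23, 20, 2.0), (26, 20, 2.0),   # 3-tree chain
            (60, 60, 3.0), (64, 60, 3.0),                  # 2-tree patch
            (20, 80, 1.0), (50, 20, 1.0), (80, 80, 1.0),
            (40, 90, 1.0), (90, 40, 1.0),                  # singles
        ]
        sm = crowned_map(w, specs)
        part = delineate_patches(sm)
        assert sorted(p.n_trees for p in part.patches) == [2, 3]
        assert len(part.singles) == 5
        p3 = next(p for p in part.patches if p.n_trees == 3)
        assert p3.density == pytest.approx(3 / (p3.area / 1e4))
        dbh = p3.dbh
        assert dbh.mean() == pytest.approx(20.0)
        tabs = summarize_mosaic(part)
        assert tabs["singles"]["n_trees"].iloc[0] == 5
        assert tabs["stand"]["n_patches"].iloc[0] == 2
        assert tabs["stand"]["trees_per_patch_mean"].iloc[0] == 2.5


class TestGapMorphology:
    def test_empty_canopy_single_gap(self, window100):
        gaps = delineate_gaps(StemMap(window100, []), cell=0.5)
        assert len(gaps) == 1
        assert gaps[0].area == pytest.approx(window100.area, rel=0.01)

    def test_full_canopy_no_gaps(self, window100):
        specs = [(x, y, 6.0) for x in range(0, 105, 7)
                 for y in range(0, 105, 7)]
        gaps = delineate_gaps(crowned_map(window100, specs), cell=0.5)
        assert gaps == []

    def test_small_crown_absorbed(self, window100):
        """A radius-1 m isolated crown dissolves at the 2 m gap threshold."""
        gaps = delineate_gaps(crowned_map(window100, [(50, 50, 1.0)]),
                              cell=0.25)
        assert len(gaps) == 1
        assert gaps[0].area == pytest.approx(window100.area, rel=0.01)

    def test_larger_crown_leaves_hole(self, window100):
        gaps = delineate_gaps(crowned_map(window100, [(50, 50, 8.0)]),
                              cell=0.25)
        assert len(gaps) == 1
        assert gaps[0].area < window100.area - np.pi * 36  # hole survives

    def test_narrow_corridor_rejected(self):
        """A 10 m open corridor fails the 12 m spur threshold."""
        w = PlotWindow(0, 0, 100, 100, buffer_width=5)
        specs = []
        for x in np.arange(2, 99, 4):
            for y in np.arange(2, 43, 4):
                specs.append((float(x), float(y), 3.0))
            for y in np.arange(57, 99, 4):
                specs.append((float(x), float(y), 3.0))
        gaps = delineate_gaps(crowned_map(w, specs), cell=0.5)
        # corridor from y≈45 to y≈55 is ~10 m wide -> removed
        assert gaps == []

    def test_wide_corridor_kept(self):
        w = PlotWindow(0, 0, 100, 100, buffer_width=5)
        specs = []
        for x in np.arange(2, 99, 4):
            for y in np.arange(2, 39, 4):
                specs.append((float(x), float(y), 3.0))
            for y in np.arange(61, 99, 4):
                specs.append((float(x), float(y), 3.0))
        gaps = delineate_gaps(crowned_map(w, specs), cell=0.5)
        assert len(gaps) == 1  # ~16 m corridor survives

    def test_monotone_in_canopy(self, window100):
        base = [(30, 30, 5.0), (60, 70, 6.0)]
        g1 = delineate_gaps(crowned_map(window100, base), cell=0.5)
        g2 = delineate_gaps(crowned_map(window100, base + [(45, 50, 5.0)]),
                            cell=0.5)
        a1 = sum(g.area for g in g1)
        a2 = sum(g.area for g in g2)
        assert a2 <= a1 + 1.0  # raster tolerance

    def test_resolution_convergence(self, window100):
        rng = np.random.default_rng(4)
        specs = [(rng.uniform(0, 100), rng.uniform(0, 100),
                  rng.uniform(2, 5)) for _ in range(60)]
        a_coarse = sum(g.area for g in
                       delineate_gaps(crowned_map(window100, specs), cell=0.5))
        a_fine = sum(g.area for g in
                     delineate_gaps(crowned_map(window100, specs), cell=0.25))
        assert abs(a_coarse - a_fine) / a_fine < 0.01

    def test_cell_size_guard(self, window100):
        with pytest.raises(ValueError):
            delineate_gaps(StemMap(window100, []), cell=1.0)


class TestEdgeGapFilter:
    def test_mode_behaviour_on_constructed_gaps(self):
        interior = Gap(1, 100.0, 40.0, 0.0, 0.0)
        half_edge = Gap(2, 100.0, 40.0, 0.5, 0.3)
        split = Gap(3, 100.0, 40.0, 0.05, 0.15)  # kept by perimeter, cut by area
        gaps = [interior, half_edge, split]
        kept_p, edge_p = filter_edge_gaps(gaps, mode="perimeter")
        kept_a, edge_a = filter_edge_gaps(gaps, mode="area")
        assert interior in kept_p and interior in kept_a
        assert half_edge in edge_p and half_edge in edge_a
        assert split in kept_p and split in edge_a

    def test_raster_overlap_fractions(self):
        """A gap hugging one plot edge overlaps the buffer ring on one side."""
        w = PlotWindow(0, 0, 100, 100, buffer_width=5)
        # canopy filling all but a 20 m band along x in [0, 20]
        specs = [(x, y, 3.5) for x in np.arange(24, 99, 4)
                 for y in np.arange(2, 99, 4)]
        gaps = delineate_gaps(crowned_map(w, specs), cell=0.5)
        band = [g for g in gaps if g.edge_overlap_area > 0]
        assert band, "expected a gap touching the buffer"
        g = band[0]
        # band spans x in [0, ~20]: buffer ring share of area ≈ (5*100 + 2·5·15)/2000
        assert 0.1 < g.edge_overlap_area < 0.5
        assert g.edge_overlap_perimeter > 0.3

    def test_summary_with_and_without(self, window100):
        gaps = [Gap(1, 200.0, 60.0, 0.0, 0.0), Gap(2, 300.0, 80.0, 0.5, 0.4)]
        tab = summarize_gaps(gaps, window100)
        assert tab.loc["with", "n_gaps"] == 2
        assert tab.loc["without", "n_gaps"] == 1
        assert tab.loc["without", "pct_area_in_gaps"] == pytest.approx(
            100.0 * 200.0 / window100.area)
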