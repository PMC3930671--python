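"""Patch / single-tree / gap decomposition of a crowned stem map.

Two or more live trees whose projected crown disks overlap (strict
centre-distance < rᵢ + rⱼ; tangency does not connect) form a *patch*
(connected component of the crown-overlap graph); a live tree overlapping
no other crown is a *single tree*.  Canopy *gaps* are contiguous treeless
openings surviving a two-parameter morphological filter: canopy slivers
thinner than the gap threshold (2 m) are absorbed into the surrounding
opening, and open corridors thinner than the spur threshold (12 m) are
removed.

Edge bookkeeping: trees whose stems fall in the window's 5 m inner buffer
contribute crown geometry (so patch shapes and gaps near the edge are
right) but are excluded from patch-membership counts and single-tree
tables; a component is a patch when it has ≥ 2 *interior* members and
contributes a single tree when it has exactly one.  Gaps are delineated
over the full window (they may reach the boundary); gaps overlapping the
buffer ring by more than 10% of their perimeter (or area, both modes
implemented) are flagged as edge gaps and summaries are reported with and
without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, box
from shapely.ops import unary_union
from skimage import measure

from .core import PlotWindow, StemMap, TreeRecord, partition_by_buffer

__all__ = [
    "Patch",
    "MosaicPartition",
    "Gap",
    "CATEGORY_EDGES",
    "delineate_patches",
    "patch_geometry",
    "summarize_mosaic",
    "delineate_gaps",
    "filter_edge_gaps",
    "summarize_gaps",
]

#: Trees-per-patch category labels and membership test edges.
CATEGORY_EDGES: tuple[tuple[str, int, int], ...] = (
    ("2-4", 2, 4),
    ("5-9", 5, 9),
    ("10+", 10, 10**9),
)

_QUAD_SEGS = 48  # vertices per quarter-circle in crown-disk polygons


@dataclass
class Patch:
    """A crown-overlap patch: ≥2 interior member trees plus attributes."""

    members: list[TreeRecord]
    geometry_members: list[TreeRecord]
    polygon: object | None = None
    area: float = np.nan  # m², union of member crown disks (clipped to window)
    perimeter: float = np.nan

    @property
    def n_trees(self) -> int:
        return len(self.members)

    @property
    def dbh(self) -> np.ndarray:
        return np.array([t.dbh for t in self.members])

    @property
    def basal_area(self) -> float:
        """Σ member basal areas, m² per patch."""
        return float(sum(t.basal_area for t in self.members))

    @property
    def density(self) -> float:
        """Stems per hectare of crown-union area."""
        return self.n_trees / (self.area / 1e4)

    @property
    def basal_area_per_ha(self) -> float:
        return self.basal_area / (self.area / 1e4)

    def category(self) -> str:
        for label, lo, hi in CATEGORY_EDGES:
            if lo <= self.n_trees <= hi:
                return label
        raise ValueError("patch below minimum size")


@dataclass
class MosaicPartition:
    """Patches, single trees, and the buffer-excluded remainder of a plot."""

    window: PlotWindow
    patches: list[Patch]
    singles: list[TreeRecord]
    buffer_trees: list[TreeRecord]

    @property
    def n_interior_live(self) -> int:
        return sum(p.n_trees for p in self.patches) + len(self.singles)


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def delineate_patches(stemmap: StemMap, geometry: bool = True) -> MosaicPartition:
    """Decompose a crowned stem map into patches and single trees.

    Requires ``crown_radius`` on live trees (see
    :func:`icomosaic.allometry.assign_crowns`).  Components are computed
    over *all* crowned trees (buffer included) so near-edge geometry is
    correct; membership and single-tree status count interior trees only.
    With ``geometry=False`` polygons/areas are left unset (cheap mode for
    large simulation sweeps).
    """
    live = [t for t in stemmap.trees if t.status == "live"]
    missing = [t.id for t in live if t.crown_radius is None]
    if live and missing:
        raise ValueError(f"live trees without crown radius: {missing[:5]}...")
    buffer_lbl = partition_by_buffer(stemmap)
    is_buffer = {t.id: lbl == "buffer"
                 for t, lbl in zip(stemmap.trees, buffer_lbl)}
    buffer_trees = [t for t, lbl in zip(stemmap.trees, buffer_lbl)
                    if lbl == "buffer"]
    if not live:
        return MosaicPartition(stemmap.window, [], [], buffer_trees)

    xy = np.array([[t.x, t.y] for t in live])
    r = np.array([t.crown_radius for t in live])
    tree = cKDTree(xy)
    dsu = _DSU(len(live))
    pairs = tree.query_pairs(r=2.0 * r.max(), output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        overlap = d < r[pairs[:, 0]] + r[pairs[:, 1]]  # strict: tangency excluded
        for a, b in pairs[overlap]:
            dsu.union(int(a), int(b))

    comps: dict[int, list[int]] = {}
    for i in range(len(live)):
        comps.setdefault(dsu.find(i), []).append(i)

    patches: list[Patch] = []
    singles: list[TreeRecord] = []
    for idx in comps.values():
        trees = [live[i] for i in idx]
        interior = [t for t in trees if not is_buffer[t.id]]
        if len(interior) >= 2:
            p = Patch(members=interior, geometry_members=trees)
            if geometry:
                p.polygon, p.area, p.perimeter = patch_geometry(
                    trees, stemmap.window
                )
            patches.append(p)
        elif len(interior) == 1:
            singles.append(interior[0])
    return MosaicPartition(stemmap.window, patches, singles, buffer_trees)


def patch_geometry(members: list[TreeRecord], window: PlotWindow | None = None):
    """Union-of-crown-disks polygon with area (m²) and perimeter (m).

    Disks are polygonal approximations with 4×48 vertices (area error
    ≪ 0.1%); crown parts extending beyond the window are clipped off.
    Returns (polygon, area, perimeter).
    """
    disks = [Point(t.x, t.y).buffer(t.crown_radius, quad_segs=_QUAD_SEGS)
             for t in members if t.crown_radius is not None]
    if not disks:
        raise ValueError("no crowned members")
    poly = unary_union(disks)
    if window is not None:
        poly = poly.intersection(
            box(window.x_min, window.y_min, window.x_max, window.y_max)
        )
    return poly, poly.area, poly.length


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return np.nan, np.nan
    se = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else np.nan
    return float(values.mean()), se


def summarize_mosaic(partition: MosaicPartition) -> dict[str, pd.DataFrame]:
    """Attribute tables for the patch categories, single trees, and stand.

    Proportions are of interior live trees; '% area in patches' and the
    patch density are relative to the full window area.  Empty categories
    are reported with N = 0 and NaN means.
    """
    n_total = partition.n_interior_live
    area_ha = partition.window.area / 1e4

    rows = []
    cats = [("2", 2, 2)] + list(CATEGORY_EDGES)
    for label, lo, hi in cats:
        sel = [p for p in partition.patches if lo <= p.n_trees <= hi]
        dens = np.array([p.density for p in sel])
        ba = np.array([p.basal_area_per_ha for p in sel])
        ar = np.array([p.area for p in sel])
        ntrees = sum(p.n_trees for p in sel)
        dm, dse = _mean_se(dens)
        bm, bse = _mean_se(ba)
        am, ase = _mean_se(ar)
        rows.append({
            "category": label,
            "n_patches": len(sel),
            "prop_trees_pct": 100.0 * ntrees / n_total if n_total else np.nan,
            "density_mean": dm, "density_se": dse,
            "basal_area_mean": bm, "basal_area_se": bse,
            "area_mean": am, "area_se": ase,
        })
    categories = pd.DataFrame(rows).set_index("category")

    sd = np.array([t.dbh for t in partition.singles])
    dbh_m, dbh_se = _mean_se(sd)
    singles = pd.DataFrame([{
        "n_trees": len(partition.singles),
        "prop_trees_pct": 100.0 * len(partition.singles) / n_total
        if n_total else np.nan,
        "dbh_mean": dbh_m, "dbh_se": dbh_se,
        "basal_area_per_ha":
            sum(t.basal_area for t in partition.singles) / area_ha,
    }])

    tpp = np.array([p.n_trees for p in partition.patches])
    tm, tse = _mean_se(tpp)
    patch_areas = np.array([p.area for p in partition.patches])
    stand = pd.DataFrame([{
        "n_patches": len(partition.patches),
        "trees_per_patch_mean": tm, "trees_per_patch_se": tse,
        "patches_per_ha": len(partition.patches) / area_ha,
        "pct_area_in_patches":
            100.0 * np.nansum(patch_areas) / partition.window.area,
    }])
    return {"categories": categories, "singles": singles, "stand": stand}


# ---------------------------------------------------------------------------
# Gap delineation (raster morphology)


@dataclass
class Gap:
    """One canopy gap: raster component with area/perimeter and edge overlap."""

    label: int
    area: float  # m²
    perimeter: float  # m
    edge_overlap_perimeter: float  # fraction of boundary in the buffer ring
    edge_overlap_area: float  # fraction of area in the buffer ring
    polygon: object | None = None

    def edge_overlap(self, mode: str) -> float:
        if mode == "perimeter":
            return self.edge_overlap_perimeter
        if mode == "area":
            return self.edge_overlap_area
        raise ValueError(f"unknown edge-overlap mode {mode!r}")


def _open_disk(mask: np.ndarray, r_px: float) -> np.ndarray:
    """Morphological opening with a Euclidean disk via distance transforms.

    Exact-disk erosion (distance to background > r) followed by exact-disk
    dilation; avoids discretized structuring-element asymmetry.
    """
    if r_px <= 0 or not mask.any():
        return mask.copy()
    if mask.all():
        return mask.copy()
    eroded = ndimage.distance_transform_edt(mask) > r_px
    if not eroded.any():
        return np.zeros_like(mask)
    return ndimage.distance_transform_edt(~eroded) <= r_px


def delineate_gaps(
    stemmap: StemMap,
    cell: float = 0.25,
    gap_threshold: float = 2.0,
    spur_threshold: float = 12.0,
    polygons: bool = False,
) -> list[Gap]:
    """Morphological canopy-gap delineation over the full window.

    Rasterizes the union of live-crown disks at ``cell`` resolution
    (≤ 0.5 m so 2 m features are resolved), absorbs canopy slivers
    thinner than ``gap_threshold`` (opening of the canopy with a disk of
    radius threshold/2), removes open corridors thinner than
    ``spur_threshold`` (opening of the remaining open space), and labels
    the surviving open components.  The world beyond the window is
    treated as closed (canopy): openings are measured by their extent
    inside the plot, which truncates gaps at the boundary — the reason
    the summaries are also reported without edge gaps.
    """
    if cell > 0.5:
        raise ValueError("cell size must be <= 0.5 m to resolve 2 m features")
    w = stemmap.window
    nx = int(round(w.width / cell))
    ny = int(round(w.height / cell))
    pad = int(np.ceil(max(gap_threshold, spur_threshold) / 2.0 / cell)) + 2

    canopy = np.zeros((nx + 2 * pad, ny + 2 * pad), dtype=bool)
    # cell centres (world coords): x = x_min + (i - pad + 0.5) * cell
    for t in stemmap.trees:
        if t.status != "live" or t.crown_radius is None:
            continue
        cx = (t.x - w.x_min) / cell + pad - 0.5
        cy = (t.y - w.y_min) / cell + pad - 0.5
        rr = t.crown_radius / cell
        i0, i1 = int(np.floor(cx - rr)), int(np.ceil(cx + rr)) + 1
        j0, j1 = int(np.floor(cy - rr)), int(np.ceil(cy + rr)) + 1
        i0, j0 = max(i0, 0), max(j0, 0)
        i1, j1 = min(i1, canopy.shape[0]), min(j1, canopy.shape[1])
        ii = np.arange(i0, i1)[:, None] - cx
        jj = np.arange(j0, j1)[None, :] - cy
        canopy[i0:i1, j0:j1] |= ii * ii + jj * jj <= rr * rr

    # closed world: everything beyond the window counts as canopy
    outside = np.ones_like(canopy)
    outside[pad:pad + nx, pad:pad + ny] = False
    canopy |= outside

    canopy = _open_disk(canopy, gap_threshold / 2.0 / cell)  # absorb slivers
    open_space = ~canopy
    open_space = _open_disk(open_space, spur_threshold / 2.0 / cell)

    inside = open_space[pad:pad + nx, pad:pad + ny]
    labels, n_lab = ndimage.label(inside, structure=np.ones((3, 3), dtype=int))

    # buffer-ring mask (window cells within buffer_width of the boundary)
    b_px = w.buffer_width / cell
    ix = np.arange(nx)[:, None] + 0.5
    jy = np.arange(ny)[None, :] + 0.5
    d_edge = np.minimum(np.minimum(ix, nx - ix), np.minimum(jy, ny - jy))
    in_ring = (d_edge < b_px) * np.ones((nx, ny), dtype=bool)

    gaps: list[Gap] = []
    for lab in range(1, n_lab + 1):
        region = labels == lab
        npix = int(region.sum())
        # boundary pixels: gap pixel with a 4-neighbour outside the gap
        # or on the raster edge
        interior = ndimage.binary_erosion(region, border_value=0)
        boundary = region & ~interior
        nb = int(boundary.sum())
        perim = measure.perimeter(region, neighborhood=4) * cell
        gap = Gap(
            label=lab,
            area=npix * cell * cell,
            perimeter=float(perim),
            edge_overlap_perimeter=float((boundary & in_ring).sum()) / nb
            if nb else 0.0,
            edge_overlap_area=float((region & in_ring).sum()) / npix,
        )
        if polygons:
            gap.polygon = _region_polygon(region, w, cell)
        gaps.append(gap)
    return gaps


def _region_polygon(region: np.ndarray, window: PlotWindow, cell: float):
    """Marching-squares outline of a raster region in world coordinates."""
    from shapely.geometry import Polygon

    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    polys = []
    for c in contours:
        xs = window.x_min + (c[:, 0] - 1 + 0.5) * cell
        ys = window.y_min + (c[:, 1] - 1 + 0.5) * cell
        if len(xs) >= 4:
            polys.append(Polygon(np.column_stack([xs, ys])))
    if not polys:
        return None
    polys.sort(key=lambda p: p.area, reverse=True)
    outer = polys[0]
    for hole in polys[1:]:
        if outer.contains(hole):
            outer = outer.difference(hole)
    return outer


def filter_edge_gaps(
    gaps: list[Gap],
    overlap_limit: float = 0.10,
    mode: str = "perimeter",
) -> tuple[list[Gap], list[Gap]]:
    """Partition gaps into (kept, edge) by buffer overlap.

    A gap is an *edge gap* iff more than ``overlap_limit`` of its
    perimeter (mode 'perimeter') or area (mode 'area') lies inside the
    window's buffer ring.
    """
    kept, edge = [], []
    for g in gaps:
        (edge if g.edge_overlap(mode) > overlap_limit else kept).append(g)
    return kept, edge


def summarize_gaps(gaps: list[Gap], window: PlotWindow,
                   overlap_limit: float = 0.10,
                   mode: str = "perimeter") -> pd.DataFrame:
    """Gap summary with and without edge gaps: N, % area, mean size ± SE."""
    kept, _ = filter_edge_gaps(gaps, overlap_limit, mode)
    rows = []
    for which, sel in (("with", gaps), ("without", kept)):
        areas = np.array([g.area for g in sel])
        m, se = _mean_se(areas)
        rows.append({
            "edge_gaps": which,
            "n_gaps": len(sel),
            "pct_area_in_gaps": 100.0 * areas.sum() / window.area
            if len(sel) else 0.0,
            "gap_size_mean": m, "gap_size_se": se,
        })
    return pd.DataFrame(rows).set_index("edge_gaps")
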