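"""Hexagonal tessellation of a slide domain and per-hexagon aggregation.

A flat-top hexagonal grid of side ``s`` (default 65 µm) is laid over the
bounding box of the slide.  Axial coordinates ``(q, r)`` address hexagons;
the center of hexagon (q, r) sits at::

    x = origin_x + 1.5 * s * q
    y = origin_y + sqrt(3) * s * (r + q / 2)

with the origin at the lower-left corner of the bounding box.  Every pixel
of the segmentation raster contributes its area to exactly one hexagon
(assignment by pixel-center location), and every detected cell increments
exactly one hexagon's count, so areas and counts are conserved by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import TISSUE_CODES, SegmentationScene

SQRT3 = math.sqrt(3.0)

#: axial offsets of the six neighbors of a flat-top hexagon
AXIAL_NEIGHBORS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1),
)

DEFAULT_HEX_SIDE_UM = 65.0


class OutOfDomainError(ValueError):
    """A query point lies outside the union of grid hexagons."""


@dataclass(frozen=True)
class HexGrid:
    """Flat-top axial hexagonal grid covering a rectangular domain.

    Parameters
    ----------
    side_um
        Hexagon side length in µm.  The regular-hexagon area is
        ``(3*sqrt(3)/2) * side_um**2``.
    origin_um
        (x, y) of the lower-left bbox corner; hexagon (0, 0) is centered
        there.
    bbox_um
        (xmin, ymin, xmax, ymax) of the covered domain.
    """

    side_um: float
    origin_um: tuple[float, float]
    bbox_um: tuple[float, float, float, float]
    q_range: tuple[int, int] = field(init=False)

    def __post_init__(self):
        if not (self.side_um > 0):
            raise ValueError(f"hexagon side must be positive, got {self.side_um}")
        x0, y0, x1, y1 = self.bbox_um
        if not (x1 > x0 and y1 > y0):
            raise ValueError("bounding box must have positive extent")
        q_max = math.ceil((x1 - x0) / (1.5 * self.side_um)) + 1
        object.__setattr__(self, "q_range", (-1, q_max))

    # -- geometry -----------------------------------------------------------

    @property
    def hex_area_um2(self) -> float:
        return 1.5 * SQRT3 * self.side_um ** 2

    def r_bounds(self, q: np.ndarray | int):
        """Inclusive r-index range of column q (covers the bbox y-extent)."""
        _, y0, _, y1 = self.bbox_um
        h = SQRT3 * self.side_um
        q = np.asarray(q)
        r_min = np.floor(-q / 2.0).astype(int) - 1
        r_max = np.ceil((y1 - y0) / h - q / 2.0).astype(int) + 1
        return r_min, r_max

    def contains_index(self, q, r) -> np.ndarray:
        q = np.asarray(q)
        r = np.asarray(r)
        r_min, r_max = self.r_bounds(q)
        return (q >= self.q_range[0]) & (q <= self.q_range[1]) & (r >= r_min) & (r <= r_max)

    def centers(self, q, r):
        """Cartesian centers (µm) of hexagons (q, r)."""
        q = np.asarray(q, dtype=float)
        r = np.asarray(r, dtype=float)
        x = self.origin_um[0] + 1.5 * self.side_um * q
        y = self.origin_um[1] + SQRT3 * self.side_um * (r + q / 2.0)
        return x, y

    def all_indices(self) -> np.ndarray:
        """(n, 2) array of every (q, r) in the grid."""
        out = []
        for q in range(self.q_range[0], self.q_range[1] + 1):
            r_min, r_max = self.r_bounds(q)
            rs = np.arange(int(r_min), int(r_max) + 1)
            out.append(np.column_stack([np.full_like(rs, q), rs]))
        return np.concatenate(out, axis=0)


def build_grid(bbox_um, side_um: float = DEFAULT_HEX_SIDE_UM) -> HexGrid:
    """Build a flat-top hexagonal grid whose union covers ``bbox_um``.

    Parameters
    ----------
    bbox_um : tuple
        (xmin, ymin, xmax, ymax) in µm.
    side_um : float
        Hexagon side length in µm (default 65).
    """
    x0, y0, x1, y1 = map(float, bbox_um)
    return HexGrid(side_um=float(side_um), origin_um=(x0, y0), bbox_um=(x0, y0, x1, y1))


def _axial_round(qf: np.ndarray, rf: np.ndarray):
    """Round fractional axial coordinates to the nearest hexagon (cube rounding)."""
    sf = -qf - rf
    q = np.rint(qf)
    r = np.rint(rf)
    s = np.rint(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


def assign_points(grid: HexGrid, x_um, y_um, check_domain: bool = True):
    """Map points to hexagons by nearest center.

    Cube rounding finds the owning hexagon; a local refinement over the six
    neighbors then guarantees the *nearest-center* contract exactly, with
    boundary ties broken toward the lexicographically smallest ``(q, r)``.

    Returns (q, r) int64 arrays.  Raises :class:`OutOfDomainError` when
    ``check_domain`` and a point falls outside the grid union.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    s = grid.side_um
    px = (x - grid.origin_um[0]) / s
    py = (y - grid.origin_um[1]) / s
    qf = (2.0 / 3.0) * px
    rf = -px / 3.0 + (SQRT3 / 3.0) * py
    q0, r0 = _axial_round(qf, rf)

    # nearest-center refinement with deterministic lexicographic tie-break
    best_q, best_r = q0.copy(), r0.copy()
    cx, cy = grid.centers(q0, r0)
    best_d = (x - cx) ** 2 + (y - cy) ** 2
    tol = 1e-9 * s ** 2
    for dq, dr in AXIAL_NEIGHBORS:
        q1, r1 = q0 + dq, r0 + dr
        cx, cy = grid.centers(q1, r1)
        d = (x - cx) ** 2 + (y - cy) ** 2
        closer = d < best_d - tol
        tie = (np.abs(d - best_d) <= tol) & (
            (q1 < best_q) | ((q1 == best_q) & (r1 < best_r))
        )
        take = closer | tie
        best_q = np.where(take, q1, best_q)
        best_r = np.where(take, r1, best_r)
        best_d = np.where(closer, d, best_d)

    if check_domain:
        ok = grid.contains_index(best_q, best_r)
        if not np.all(ok):
            bad = np.argwhere(~np.atleast_1d(ok)).ravel()[:5]
            raise OutOfDomainError(
                f"{int((~np.atleast_1d(ok)).sum())} point(s) outside grid union "
                f"(first offenders at flat indices {bad.tolist()})"
            )
    return best_q, best_r


def assign_point(grid: HexGrid, x_um: float, y_um: float) -> tuple[int, int]:
    """Axial index of the hexagon owning a single point (nearest center)."""
    q, r = assign_points(grid, np.atleast_1d(x_um), np.atleast_1d(y_um))
    return int(q[0]), int(r[0])


# -- aggregation ------------------------------------------------------------

_CHUNK = 1_000_000  # pixels per assignment chunk


def _hex_key(grid: HexGrid, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Flat integer key for (q, r) suitable for bincount."""
    r_min, _ = grid.r_bounds(q)
    # normalize r to a nonnegative offset; width large enough for any column
    _, y0, _, y1 = grid.bbox_um
    n_r = int(math.ceil((y1 - y0) / (SQRT3 * grid.side_um))) + 4
    return (q - grid.q_range[0]) * n_r + (r - r_min)


def rasterize_areas(scene: SegmentationScene, grid: HexGrid) -> pd.DataFrame:
    """Per-hexagon tissue-class areas and majority compartment.

    Every pixel contributes ``um_per_pixel**2`` to exactly one hexagon's
    class area; hexagon compartment is the majority compartment among its
    non-background pixels ('excluded' when the hexagon has no tissue pixels).
    """
    upp = scene.um_per_pixel
    h, w = scene.tissue.shape
    n_classes = 3
    area_px = upp * upp

    idx = grid.all_indices()
    key_of = _hex_key(grid, idx[:, 0], idx[:, 1])
    n_keys = int(key_of.max()) + 1
    areas = np.zeros((n_keys, n_classes))
    comp_counts = np.zeros((n_keys, 3))  # excluded / tumor / liver tissue-pixel counts

    flat_t = scene.tissue.ravel()
    flat_c = scene.compartment.ravel()
    n_px = h * w
    for start in range(0, n_px, _CHUNK):
        stop = min(start + _CHUNK, n_px)
        lin = np.arange(start, stop)
        row = lin // w
        col = lin % w
        x = (col + 0.5) * upp
        y = (row + 0.5) * upp
        q, r = assign_points(grid, x, y, check_domain=False)
        key = _hex_key(grid, q, r)
        t = flat_t[start:stop]
        c = flat_c[start:stop]
        for cls in range(n_classes):
            np.add.at(areas[:, cls], key[t == cls], area_px)
        tissue = t != TISSUE_CODES["background"]
        for comp in range(3):
            sel = tissue & (c == comp)
            np.add.at(comp_counts[:, comp], key[sel], 1.0)

    occupied = areas.sum(axis=1) > 0
    keys = np.flatnonzero(occupied)
    # invert keys back to (q, r)
    key_to_idx = {int(k): (int(q), int(r)) for (q, r), k in zip(idx, key_of)}
    qs = np.array([key_to_idx[int(k)][0] for k in keys])
    rs = np.array([key_to_idx[int(k)][1] for k in keys])
    comp = comp_counts[keys]
    majority = np.where(comp.sum(axis=1) == 0, 0, comp.argmax(axis=1))
    comp_names = np.array(["excluded", "tumor", "liver"])[majority.astype(int)]
    cx, cy = grid.centers(qs, rs)
    return pd.DataFrame({
        "q": qs,
        "r": rs,
        "center_x_um": cx,
        "center_y_um": cy,
        "background_area_um2": areas[keys, TISSUE_CODES["background"]],
        "epithelium_area_um2": areas[keys, TISSUE_CODES["epithelium"]],
        "stroma_area_um2": areas[keys, TISSUE_CODES["stroma"]],
        "compartment": comp_names,
    })


def count_cells(grid: HexGrid, cells: pd.DataFrame, aggs: pd.DataFrame,
                phenotype_positive: str = "CD8") -> pd.DataFrame:
    """Add per-hexagon CD8+ and other-phenotype counts to an aggregate table.

    Cells outside the grid union are dropped (counted in the log by callers).
    Non-CD8 phenotypes are tallied in ``other_count`` for diagnostics only.
    """
    out = aggs.copy()
    out["cd8_count"] = 0
    out["other_count"] = 0
    if len(cells) == 0:
        return out
    q, r = assign_points(grid, cells["x_um"].to_numpy(), cells["y_um"].to_numpy(),
                         check_domain=False)
    inside = grid.contains_index(q, r)
    key = _hex_key(grid, q, r)
    pos = cells["phenotype"].to_numpy() == phenotype_positive
    agg_key = _hex_key(grid, out["q"].to_numpy(), out["r"].to_numpy())
    n = max(int(key[inside].max(initial=0)), int(agg_key.max(initial=0))) + 1
    cd8 = np.bincount(key[inside & pos], minlength=n)
    oth = np.bincount(key[inside & ~pos], minlength=n)
    out["cd8_count"] = cd8[agg_key]
    out["other_count"] = oth[agg_key]
    return out


def aggregate_scene(scene: SegmentationScene, cells: pd.DataFrame,
                    grid: HexGrid) -> pd.DataFrame:
    """Aggregate a segmentation scene and a cell table onto a hexagonal grid.

    Returns the per-hexagon table (one row per occupied hexagon) with
    columns q, r, center_x_um, center_y_um, epithelium/stroma/background
    areas (µm²), cd8_count, other_count and majority compartment.

    Raises ``ValueError`` when cell coordinates fall outside the scene
    domain by more than one hexagon (symptom of a µm/pixel unit mismatch).
    """
    if len(cells):
        x = cells["x_um"].to_numpy()
        y = cells["y_um"].to_numpy()
        x0, y0, x1, y1 = grid.bbox_um
        margin = 2 * grid.side_um
        if (x.min() < x0 - margin or x.max() > x1 + margin
                or y.min() < y0 - margin or y.max() > y1 + margin):
            raise ValueError(
                "cell coordinates extend far outside the scene domain; "
                "check the µm-per-pixel scale of the cell table"
            )
    areas = rasterize_areas(scene, grid)
    return count_cells(grid, cells, areas)
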