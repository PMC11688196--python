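"""Depth-resolved cell densities on a nonlinear grid.

Cell density is profiled as a function of percentage cortical depth by
splitting the S1HL polygon into a curvilinear lattice of 10 columns and
20 rows: the pia-side and white-matter-side boundary polylines are
resampled uniformly by arc length, rows follow their linear blend (so
they mimic the shape of both boundaries and reduce to straight lines for
a rectangle), and columns are straight segments joining top and bottom
points at equal arc-length fractions.  The construction is only valid
for convex S1HL quadrilaterals; concave slices are refused, mirroring
their exclusion from the analysis.

Counts per bin are converted to cells/mm^3 with the slice thickness,
optionally weighting each cell by its stereological inclusion
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import substring
from shapely.strtree import STRtree

from nisslcolumn.io_formats import RegionSet
from nisslcolumn.stereology import ExclusionResult

__all__ = [
    "DepthGrid",
    "DepthProfile",
    "filter_in_polygon",
    "check_convex",
    "build_depth_grid",
    "bin_densities",
    "row_densities",
    "depth_profile",
]

#: Arc-length resampling resolution of the boundary polylines (segments).
_RESAMPLE_M = 200


class ConcaveRegionError(ValueError):
    """The S1HL quadrilateral is concave; the nonlinear grid is undefined."""


@dataclass
class DepthGrid:
    """A curvilinear partition of the S1HL polygon.

    ``polygons[col][row]`` is the bin at horizontal position ``col`` and
    depth index ``row`` (row 0 at the pia).  After :func:`bin_densities`,
    ``counts`` and ``density_cells_mm3`` carry the (effective) cell
    counts and densities on the same (col, row) layout.
    """

    n_cols: int
    n_rows: int
    polygons: list[list[Polygon]]
    bin_area_um2: np.ndarray
    thickness_um: float = 50.0
    counts: np.ndarray | None = None
    density_cells_mm3: np.ndarray | None = None

    @property
    def depth_percent(self) -> np.ndarray:
        """Row bin centers as percentage depth (2.5, 7.5, ..., 97.5)."""
        return (np.arange(self.n_rows) + 0.5) / self.n_rows * 100.0


@dataclass
class DepthProfile:
    """Across-image density profile versus percentage cortical depth."""

    depth_percent: np.ndarray
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_images: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth_percent": self.depth_percent,
            "mean_density": self.mean_density,
            "sd_density": self.sd_density,
            "n_images": self.n_images,
        })


def filter_in_polygon(cells: pd.DataFrame, polygon: Polygon) -> pd.DataFrame:
    """Retain cells whose centroid lies inside or on the polygon boundary."""
    keep = shapely.intersects_xy(
        polygon, cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float)
    )
    return cells.loc[keep].reset_index(drop=True)


def check_convex(corners: np.ndarray) -> bool:
    """Whether the quadrilateral TL-TR-BR-BL is convex.

    All cross products of consecutive edges must share a sign; zero
    (collinear corners) is allowed.  Repeated points are an error.
    """
    pts = np.asarray(corners, float)
    if pts.shape != (4, 2):
        raise ValueError("expected 4 corner points")
    if len({tuple(p) for p in pts.tolist()}) < 4:
        raise ValueError("repeated corner points")
    crosses = []
    for i in range(4):
        a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
        e1, e2 = b - a, c - b
        crosses.append(e1[0] * e2[1] - e1[1] * e2[0])
    crosses = np.array(crosses)
    return bool((crosses >= 0).all() or (crosses <= 0).all())


def _ring_path(ring: LineString, s_from: float, s_to: float,
               avoid: list[float]) -> np.ndarray:
    """Boundary path from arc position ``s_from`` to ``s_to`` avoiding others.

    Walks the closed exterior ring forward (wrapping) unless an avoided
    arc position falls inside that stretch, in which case the opposite
    walk is taken and reversed so the result still runs s_from -> s_to.
    """
    total = ring.length

    def forward_contains(a: float, b: float, s: float) -> bool:
        return ((s - a) % total) < ((b - a) % total)

    def forward_path(a: float, b: float) -> np.ndarray:
        if (b - a) % total == 0:
            raise ValueError("degenerate boundary path")
        if b >= a:
            seg = substring(ring, a, b)
            return np.asarray(seg.coords)
        first = np.asarray(substring(ring, a, total).coords)
        second = np.asarray(substring(ring, 0.0, b).coords)
        return np.vstack([first, second[1:]])

    if not any(forward_contains(s_from, s_to, s) for s in avoid):
        return forward_path(s_from, s_to)
    return forward_path(s_to, s_from)[::-1]


def _resample(coords: np.ndarray, m: int) -> np.ndarray:
    """Resample a polyline to m+1 points uniform in arc length."""
    line = LineString(coords)
    s = np.linspace(0.0, line.length, m + 1)
    return np.asarray([line.interpolate(si).coords[0] for si in s])


def _polygonal(geom) -> Polygon:
    """Largest polygonal component of a clip result."""
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        return Polygon()
    return max(polys, key=lambda p: p.area)


def build_depth_grid(regions: RegionSet, n_cols: int = 10,
                     n_rows: int = 20) -> DepthGrid:
    """Construct the nonlinear depth grid inside the S1HL polygon.

    Refuses concave corner quadrilaterals with
    :class:`ConcaveRegionError`.  For an axis-aligned rectangle the grid
    degenerates to uniform rectangular binning.
    """
    corners = regions.corner_array()  # TL, TR, BR, BL
    if not check_convex(corners):
        raise ConcaveRegionError("concave S1HL: nonlinear grid refused")
    ring = LineString(regions.s1hl.exterior.coords)
    s = {name: ring.project(regions.corners[name])
         for name in ("TL", "TR", "BR", "BL")}
    top = _resample(_ring_path(ring, s["TL"], s["TR"], [s["BL"], s["BR"]]),
                    _RESAMPLE_M)
    bottom = _resample(_ring_path(ring, s["BL"], s["BR"], [s["TL"], s["TR"]]),
                       _RESAMPLE_M)
    per_col = _RESAMPLE_M // n_cols
    if per_col * n_cols != _RESAMPLE_M:
        raise ValueError("n_cols must divide the resampling resolution")

    def row_polyline(t: float) -> np.ndarray:
        return (1.0 - t) * top + t * bottom

    rows = [row_polyline(j / n_rows) for j in range(n_rows + 1)]
    polygons: list[list[Polygon]] = []
    areas = np.zeros((n_cols, n_rows))
    for i in range(n_cols):
        lo, hi = i * per_col, (i + 1) * per_col
        col_bins = []
        for j in range(n_rows):
            ringpts = np.vstack([rows[j][lo:hi + 1], rows[j + 1][lo:hi + 1][::-1]])
            raw = Polygon(ringpts)
            if not raw.is_valid:
                raw = raw.buffer(0)
            clipped = _polygonal(raw.intersection(regions.s1hl))
            col_bins.append(clipped)
            areas[i, j] = clipped.area
        polygons.append(col_bins)
    return DepthGrid(n_cols=n_cols, n_rows=n_rows, polygons=polygons,
                     bin_area_um2=areas)


def _assign_bins(grid: DepthGrid, cells: pd.DataFrame) -> np.ndarray:
    """Map each cell to exactly one (col, row) bin (boundary-inclusive)."""
    flat = [grid.polygons[i][j] for i in range(grid.n_cols)
            for j in range(grid.n_rows)]
    tree = STRtree(flat)
    pts = shapely.points(cells[["x_um", "y_um"]].to_numpy(float))
    assign = np.full(len(cells), -1, dtype=int)
    hit_cell, hit_bin = tree.query(pts, predicate="intersects")
    for c, b in zip(hit_cell, hit_bin):
        if assign[c] == -1:  # ties on shared edges: first bin wins
            assign[c] = b
    missing = np.flatnonzero(assign == -1)
    for c in missing:  # clipping slivers: snap to the nearest bin
        assign[c] = int(np.argmin([flat[b].distance(pts[c]) for b in range(len(flat))]))
    return assign


def bin_densities(grid: DepthGrid, cells: pd.DataFrame,
                  thickness_um: float = 50.0,
                  exclusion: ExclusionResult | None = None) -> DepthGrid:
    """Count cells per bin and convert to densities (cells/mm^3).

    With an exclusion result the count of a bin is the sum of per-cell
    inclusion weights 1 - P(excluded), i.e. the bootstrap mean over
    exclusion realizations.  Zero-area bins report a missing (NaN)
    density, never infinity.
    """
    weights = np.ones(len(cells))
    if exclusion is not None:
        if len(exclusion.per_cell_exclusion_probability) != len(cells):
            raise ValueError("exclusion result does not match the cell table")
        weights = exclusion.included_weight()
    assign = _assign_bins(grid, cells)
    counts = np.zeros((grid.n_cols, grid.n_rows))
    np.add.at(counts, (assign // grid.n_rows, assign % grid.n_rows), weights)
    volume_mm3 = grid.bin_area_um2 * thickness_um * 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(volume_mm3 > 0, counts / volume_mm3, np.nan)
    return DepthGrid(
        n_cols=grid.n_cols, n_rows=grid.n_rows, polygons=grid.polygons,
        bin_area_um2=grid.bin_area_um2, thickness_um=thickness_um,
        counts=counts, density_cells_mm3=density,
    )


def row_densities(grid: DepthGrid) -> np.ndarray:
    """Per-row densities of one image: mean over the columns of each row."""
    if grid.density_cells_mm3 is None:
        raise ValueError("grid has no densities; run bin_densities first")
    return np.nanmean(grid.density_cells_mm3, axis=0)


def depth_profile(per_image_rows: list) -> DepthProfile:
    """Across-image mean and sd of the per-row densities.

    Each entry is either a density-filled :class:`DepthGrid` or a vector
    of row densities; rows are averaged over columns within an image
    before any across-image statistics (each image contributes one
    curve).  The sd uses the n-1 denominator and is zero, flagged by
    ``n_images=1``, for a single image.
    """
    if not per_image_rows:
        raise ValueError("at least one image required")
    vectors = [row_densities(g) if isinstance(g, DepthGrid) else np.asarray(g, float)
               for g in per_image_rows]
    n_rows = len(vectors[0])
    if any(len(v) != n_rows for v in vectors):
        raise ValueError("inconsistent row counts across images")
    stack = np.vstack(vectors)
    n = len(vectors)
    return DepthProfile(
        depth_percent=(np.arange(n_rows) + 0.5) / n_rows * 100.0,
        mean_density=stack.mean(axis=0),
        sd_density=stack.std(axis=0, ddof=1) if n > 1 else np.zeros(n_rows),
        n_images=n,
    )
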