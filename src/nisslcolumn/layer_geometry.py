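"""Per-layer alpha-concave hulls, densities and layer heights.

Once every cell carries a (predicted) layer, the extent of each layer is
taken as the smallest polygon containing all its cells, built with the
alpha-shape construction: the union of Delaunay triangles whose
circumradius is below 1/alpha.  In this characteristic-scale convention
alpha -> 0 recovers the convex hull and larger alpha values tighten the
outline.  The defaults are alpha = 0.05 for all layers and one tenth of
that (0.005) for the sparse Layer I.  Hull area times slice thickness
gives the layer volume, and the enclosed (effective) cell count its
density.

Layer heights are estimated per grid column: the boundary between two
adjacent layers along a column's depth axis is the split depth that best
separates their predicted labels (the midpoint between the last cell of
the upper layer and the first of the lower, in the noise-free limit),
and a layer's height is the distance between its two boundaries,
aggregated as mean ± sd over columns and images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from shapely.ops import unary_union

from nisslcolumn.depth_density import DepthGrid, _assign_bins
from nisslcolumn.io_formats import LAYER_ORDER
from nisslcolumn.stereology import ExclusionResult

__all__ = [
    "ALPHA_GENERAL",
    "ALPHA_LAYER1",
    "LayerHull",
    "LayerHeights",
    "alpha_hull",
    "select_alpha",
    "layer_density",
    "layer_heights",
]

ALPHA_GENERAL = 0.05
ALPHA_LAYER1 = 0.005


class DegenerateGeometryError(ValueError):
    """Fewer than three non-collinear points: no areal hull exists."""


@dataclass
class LayerHull:
    """One layer's alpha-concave outline with volume and density."""

    label: str
    alpha: float
    polygon: Polygon
    area_um2: float
    volume_mm3: float
    n_cells: float
    density_cells_mm3: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "alpha": self.alpha,
            "area_um2": self.area_um2,
            "volume_mm3": self.volume_mm3,
            "n_cells": self.n_cells,
            "density_cells_mm3": self.density_cells_mm3,
        }


@dataclass
class LayerHeights:
    """Per-layer height estimates aggregated over columns and images."""

    per_layer: pd.DataFrame  # index = layer; columns mean_um, sd_um, n_columns
    total_height_um: float

    def to_dict(self) -> dict:
        return {
            "per_layer": self.per_layer.to_dict(orient="index"),
            "total_height_um": self.total_height_um,
        }


def _triangles(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay triangles of the point set and their circumradii."""
    tri = Delaunay(points)
    simplices = tri.simplices
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    return simplices, circumradius


def alpha_hull(points: np.ndarray, alpha: float) -> Polygon:
    """Alpha-shape boundary polygon of a 2-D point set.

    Triangles of the Delaunay triangulation with circumradius < 1/alpha
    are kept; alpha = 0 keeps everything (convex hull).  The largest
    connected region is returned, interior holes filled so that the
    result is the outline polygon.
    """
    pts = np.unique(np.asarray(points, float), axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 distinct points")
    try:
        simplices, circumradius = _triangles(pts)
    except Exception as exc:  # qhull failure on collinear input
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    keep = circumradius < (np.inf if alpha == 0 else 1.0 / alpha)
    if not keep.any():
        return Polygon()
    tris = [Polygon(pts[s]) for s in simplices[keep]]
    union = unary_union(tris)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda p: p.area)
    return Polygon(union.exterior)


def select_alpha(points: np.ndarray, candidate_alphas) -> float:
    """Smallest admissible hull: tightest alpha rejecting no point.

    Among the candidates (any order), returns the one whose hull has
    minimal area subject to all points lying inside or on the hull.  If
    no candidate is admissible the convex hull (alpha = 0) is returned
    with a warning.
    """
    import warnings

    pts = np.asarray(points, float)
    geoms = shapely.points(pts)
    best_alpha, best_area = None, np.inf
    for alpha in sorted(candidate_alphas):
        hull = alpha_hull(pts, alpha)
        if hull.is_empty:
            continue
        prepared = shapely.prepared.prep(hull)
        if all(prepared.intersects(g) for g in geoms):
            if hull.area < best_area:
                best_alpha, best_area = alpha, hull.area
    if best_alpha is None:
        warnings.warn("no candidate alpha encloses all points; "
                      "falling back to the convex hull (alpha = 0)")
        return 0.0
    return best_alpha


def layer_density(cells: pd.DataFrame, label: str,
                  alpha: float | None = None, thickness_um: float = 50.0,
                  exclusion: ExclusionResult | None = None,
                  layer_column: str = "predicted_layer") -> LayerHull:
    """Alpha-hull density of one layer's cells.

    ``alpha`` defaults to the Layer-I value for LI and the general value
    otherwise.  With an exclusion result, the count is the sum of
    per-cell inclusion weights over the layer's cells (cells on the hull
    boundary count as inside).
    """
    if alpha is None:
        alpha = ALPHA_LAYER1 if label == "LI" else ALPHA_GENERAL
    mask = (cells[layer_column] == label).to_numpy()
    pts = cells.loc[mask, ["x_um", "y_um"]].to_numpy(float)
    hull = alpha_hull(pts, alpha)
    if hull.area <= 0:
        raise DegenerateGeometryError(f"zero-area hull for layer {label}")
    # count the cells within the hull polygon (boundary-inclusive); a
    # too-tight alpha may reject cells, which then do not count
    within = shapely.intersects_xy(hull.buffer(1e-9), pts[:, 0], pts[:, 1])
    if exclusion is not None:
        if len(exclusion.per_cell_exclusion_probability) != len(cells):
            raise ValueError("exclusion result does not match the cell table")
        n_eff = float(exclusion.included_weight()[mask][within].sum())
    else:
        n_eff = float(within.sum())
    volume_mm3 = hull.area * thickness_um * 1e-9
    return LayerHull(
        label=label, alpha=alpha, polygon=hull, area_um2=hull.area,
        volume_mm3=volume_mm3, n_cells=n_eff,
        density_cells_mm3=n_eff / volume_mm3,
    )


def _column_boundary(depth: np.ndarray, labels: np.ndarray,
                     upper: str, lower: str) -> float | None:
    """Majority-switch boundary depth between two layers in one column.

    Considers only cells of the two layers, sorted by depth, and returns
    the midpoint of the split minimizing misplaced cells (upper-layer
    cells below the split plus lower-layer cells above it).  Reduces to
    the midpoint between the last upper cell and the first lower cell
    when the labels are perfectly ordered.
    """
    sel = np.isin(labels, (upper, lower))
    if not sel.any() or upper not in labels[sel] or lower not in labels[sel]:
        return None
    d = depth[sel]
    lab = labels[sel]
    order = np.argsort(d, kind="stable")
    d, lab = d[order], lab[order]
    is_upper = lab == upper
    n = len(d)
    # cost(i) = lower-layer cells above the split plus upper-layer cells below it
    lower_above = np.concatenate([[0], np.cumsum(~is_upper)])
    upper_below = np.concatenate([np.cumsum(is_upper[::-1])[::-1], [0]])
    cost = lower_above + upper_below
    i = int(np.argmin(cost))
    if i == 0:
        return float(d[0])  # boundary above every cell of the pair
    if i == n:
        return float(d[-1])
    return float((d[i - 1] + d[i]) / 2.0)


def layer_heights(cells: pd.DataFrame, grid: DepthGrid,
                  layer_column: str = "predicted_layer",
                  depth_column: str = "dist_pia_um",
                  layers: tuple[str, ...] = LAYER_ORDER) -> LayerHeights:
    """Estimate layer heights from predicted labels along grid columns.

    For each of the grid's columns, the boundary depth between every
    pair of adjacent layers is the majority label switch; the top of the
    first layer is the pia (depth 0) and the bottom of the last layer is
    its deepest cell.  A layer absent from a column contributes no
    estimate there.  Heights are aggregated as mean ± sd over columns.
    """
    assign = _assign_bins(grid, cells)
    col_of_cell = assign // grid.n_rows
    depth_all = cells[depth_column].to_numpy(float)
    labels_all = cells[layer_column].to_numpy()
    present = [l for l in layers if l in labels_all]
    records: dict[str, list[float]] = {l: [] for l in present}
    for col in range(grid.n_cols):
        sel = col_of_cell == col
        if not sel.any():
            continue
        depth, labels = depth_all[sel], labels_all[sel]
        boundaries: list[float | None] = [0.0]
        for upper, lower in zip(present[:-1], present[1:]):
            boundaries.append(_column_boundary(depth, labels, upper, lower))
        in_last = labels == present[-1]
        boundaries.append(float(depth[in_last].max()) if in_last.any() else None)
        for layer, top, bottom in zip(present, boundaries[:-1], boundaries[1:]):
            if top is not None and bottom is not None and bottom > top:
                records[layer].append(bottom - top)
    rows = {}
    for layer in present:
        vals = np.asarray(records[layer])
        rows[layer] = {
            "mean_um": float(vals.mean()) if len(vals) else np.nan,
            "sd_um": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n_columns": int(len(vals)),
        }
    per_layer = pd.DataFrame.from_dict(rows, orient="index")
    total = float(np.nansum(per_layer["mean_um"])) if len(per_layer) else np.nan
    return LayerHeights(per_layer=per_layer, total_height_um=total)
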