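"""Reading and writing detection-measurement tables and GeoJSON regions.

Cell measurements travel as tab-separated tables in the dialect produced
by QuPath detection exports (``Image``, ``Name``, ``Centroid X µm`` ...).
Header matching is deliberately tolerant — case, surrounding whitespace
and the µ/μ/u spelling all vary between QuPath versions — and canonical
internal column names are fixed here.  Region annotations (slice contour,
S1HL region of interest, pia contour and the four S1HL corner reference
points) travel as a GeoJSON FeatureCollection with planar coordinates in
micrometres, the classification name in ``properties.classification.name``
or ``properties.name`` (checked in that order).

Internally a cell table is a plain :class:`pandas.DataFrame` with the
canonical columns of :data:`CELL_COLUMNS`; unknown columns are preserved
verbatim.  The image frame has y increasing downward.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape
from shapely.geometry.polygon import orient

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RegionError",
    "CELL_COLUMNS",
    "LAYER_LABELS",
    "RegionSet",
    "read_cell_table",
    "write_cell_table",
    "read_regions",
    "write_regions",
    "ensure_area",
    "validate_cell_table",
]


class SchemaError(ValueError):
    """A table or FeatureCollection does not match the expected schema."""


class RegionError(ValueError):
    """A region annotation is missing or geometrically invalid."""


#: Canonical internal column names and their on-disk header spellings.
CELL_COLUMNS: dict[str, str] = {
    "image_id": "Image",
    "cell_id": "Name",
    "x_um": "Centroid X µm",
    "y_um": "Centroid Y µm",
    "d_max_um": "Cell maximum diameter µm",
    "d_min_um": "Cell minimum diameter µm",
    "area_um2": "Area µm^2",
    "dist_pia_um": "Distance to annotation with Outside Pia µm",
    "layer_label": "Classification",
    "z_um": "Z µm",
    "excluded": "Excluded",
}

MANDATORY_COLUMNS = ("image_id", "cell_id", "x_um", "y_um",
                     "d_max_um", "d_min_um", "dist_pia_um")
NUMERIC_COLUMNS = ("x_um", "y_um", "d_max_um", "d_min_um",
                   "area_um2", "dist_pia_um", "z_um")

#: Closed layer vocabulary, ordered pia -> white matter.
LAYER_LABELS = ("LI", "LII", "LIII", "LII/III", "LIV", "LV", "LVIa", "LVIb", "none")

#: Depth order used for adjacency computations (merged LII/III excluded).
LAYER_ORDER = ("LI", "LII", "LIII", "LIV", "LV", "LVIa", "LVIb")

_LAYER_SYNONYMS = {
    "layer i": "LI", "li": "LI", "l1": "LI",
    "layer ii": "LII", "lii": "LII", "l2": "LII",
    "layer iii": "LIII", "liii": "LIII", "l3": "LIII",
    "layer ii iii": "LII/III", "lii iii": "LII/III", "l2 3": "LII/III",
    "layer iv": "LIV", "liv": "LIV", "l4": "LIV",
    "layer v": "LV", "lv": "LV", "l5": "LV",
    "layer via": "LVIa", "lvia": "LVIa", "l6a": "LVIa",
    "layer vib": "LVIb", "lvib": "LVIb", "l6b": "LVIb",
    "": "none", "none": "none", "nan": "none",
}


def _norm(header: str) -> str:
    """Normalize a header: casefold, µ/μ -> u, punctuation -> spaces."""
    s = str(header).casefold().replace("µ", "u").replace("μ", "u")
    s = re.sub(r"[^a-z0-9]+", " ", s)
    return " ".join(s.split())


# Matchers on the normalized header, tried in order for each canonical name.
_HEADER_MATCHERS: dict[str, tuple[re.Pattern, ...]] = {
    "image_id": (re.compile(r"^image( id| name)?$"),),
    "cell_id": (re.compile(r"^(name|object id|cell id)$"),),
    "x_um": (re.compile(r"centroid.*\bx\b"),),
    "y_um": (re.compile(r"centroid.*\by\b"),),
    "d_max_um": (re.compile(r"max(imum)? diameter"),),
    "d_min_um": (re.compile(r"min(imum)? diameter"),),
    "area_um2": (re.compile(r"^(cell )?area( um( 2)?)?$"),),
    "dist_pia_um": (re.compile(r"distance.*pia"),),
    "layer_label": (re.compile(r"^(classification|class|(predicted )?layer( label)?)$"),),
    "z_um": (re.compile(r"^z( um)?$"),),
    "excluded": (re.compile(r"^excluded$"),),
}


def _map_columns(headers: list[str]) -> dict[str, str]:
    """Map on-disk headers to canonical names; first match wins."""
    out: dict[str, str] = {}
    for col in headers:
        n = _norm(col)
        for canon, pats in _HEADER_MATCHERS.items():
            if canon not in out.values() and any(p.search(n) for p in pats):
                out[col] = canon
                break
    return out


def normalize_layer_label(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "none"
    if value in LAYER_LABELS:
        return str(value)
    key = _norm(str(value))
    if key in _LAYER_SYNONYMS:
        return _LAYER_SYNONYMS[key]
    raise SchemaError(f"unknown layer label: {value!r}")


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical invariants of a cell table; returns the table.

    Raises :class:`SchemaError` on a missing mandatory column, non-finite
    coordinates, negative distance-to-pia, inverted diameters, a
    non-positive area or a label outside the closed vocabulary.
    """
    for canon in MANDATORY_COLUMNS:
        if canon not in cells.columns:
            raise SchemaError(f"missing mandatory column: {CELL_COLUMNS[canon]!r}")
    if len(cells):
        if not np.isfinite(cells[["x_um", "y_um"]].to_numpy(float)).all():
            raise SchemaError("non-finite centroid coordinate")
        if (cells["dist_pia_um"].to_numpy(float) < 0).any():
            raise SchemaError("negative distance to pia")
        if (cells["d_min_um"].to_numpy(float) > cells["d_max_um"].to_numpy(float) + 1e-9).any():
            raise SchemaError("d_min_um exceeds d_max_um")
        if "area_um2" in cells.columns:
            area = cells["area_um2"].to_numpy(float)
            if (area[np.isfinite(area)] <= 0).any():
                raise SchemaError("non-positive area_um2")
        if "layer_label" in cells.columns:
            cells = cells.copy()
            cells["layer_label"] = [normalize_layer_label(v) for v in cells["layer_label"]]
    return cells


def ensure_area(cells: pd.DataFrame) -> pd.DataFrame:
    """Back-fill missing soma areas from the mean diameter.

    Missing ``area_um2`` is filled as pi * ((d_max + d_min) / 4)^2 (circle
    of the representative diameter) and flagged in ``area_backfilled``.
    """
    cells = cells.copy()
    d_rep = (cells["d_max_um"].to_numpy(float) + cells["d_min_um"].to_numpy(float)) / 2.0
    circle = np.pi * (d_rep / 2.0) ** 2
    if "area_um2" not in cells.columns:
        cells["area_um2"] = circle
        cells["area_backfilled"] = True
    else:
        area = cells["area_um2"].to_numpy(float)
        miss = ~np.isfinite(area)
        cells["area_um2"] = np.where(miss, circle, area)
        cells["area_backfilled"] = miss
    return cells


def read_cell_table(path, strict: bool = True) -> pd.DataFrame:
    """Read a tab-separated detection-measurement table.

    Parameters
    ----------
    path
        TSV file with a header row in the QuPath-export dialect.
    strict
        If True a non-numeric value in a numeric column is an error;
        otherwise the offending rows are dropped and counted in the log.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = _map_columns(list(raw.columns))
    cells = raw.rename(columns=colmap)
    for canon in MANDATORY_COLUMNS:
        if canon not in cells.columns:
            raise SchemaError(
                f"missing mandatory column: {CELL_COLUMNS[canon]!r} "
                f"(have: {list(raw.columns)})"
            )
    bad = np.zeros(len(cells), dtype=bool)
    for canon in NUMERIC_COLUMNS:
        if canon not in cells.columns:
            continue
        vals = pd.to_numeric(
            cells[canon].replace("", np.nan), errors="coerce"
        )
        invalid = vals.isna() & (cells[canon].astype(str).str.strip() != "")
        if invalid.any():
            if strict:
                row = int(np.flatnonzero(invalid)[0])
                raise SchemaError(
                    f"non-numeric value {cells[canon].iloc[row]!r} in column "
                    f"{CELL_COLUMNS[canon]!r}, row {row}"
                )
            bad |= invalid.to_numpy()
        cells[canon] = vals
    if bad.any():
        logger.warning("dropped %d rows with unparseable numeric fields", int(bad.sum()))
        cells = cells.loc[~bad].reset_index(drop=True)
    if "excluded" in cells.columns:
        cells["excluded"] = (
            cells["excluded"].astype(str).str.strip().str.casefold().isin(("true", "1"))
        )
    if "layer_label" not in cells.columns:
        cells["layer_label"] = "none"
    return validate_cell_table(cells)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table as tab-separated UTF-8 with '.' decimals.

    Canonical columns are written under their export header names; extra
    columns keep their own names.  A ``layer_label`` of ``"none"`` is
    serialized as an empty cell.
    """
    out = cells.copy()
    if "layer_label" in out.columns:
        out["layer_label"] = out["layer_label"].replace("none", "")
    out = out.rename(columns={c: CELL_COLUMNS[c] for c in out.columns if c in CELL_COLUMNS})
    out.to_csv(path, sep="\t", index=False, encoding="utf-8", float_format="%.10g")


# ---------------------------------------------------------------------------
# Regions


@dataclass
class RegionSet:
    """Named annotation geometries for one image, coordinates in µm.

    ``corners`` maps TL/TR/BL/BR to the four S1HL reference points; TL/TR
    sit on the pia-side edge and BL/BR on the white-matter-side edge.
    """

    s1hl: Polygon
    outside_pia: LineString | Polygon | None = None
    slice_contour: Polygon | None = None
    corners: dict[str, Point] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def validate(self, tol_um: float = 1.0) -> "RegionSet":
        if self.s1hl is None:
            raise RegionError("missing S1HL region")
        if not self.s1hl.is_valid or not self.s1hl.is_simple:
            raise RegionError("S1HL polygon is self-intersecting")
        boundary = self.s1hl.exterior
        for name, pt in self.corners.items():
            if boundary.distance(pt) > tol_um:
                raise RegionError(
                    f"corner point {name} is {boundary.distance(pt):.2f} µm "
                    f"from the S1HL boundary (tolerance {tol_um} µm)"
                )
        return self

    def corner_array(self) -> np.ndarray:
        """Corners as a (4, 2) array in TL, TR, BR, BL order."""
        try:
            pts = [self.corners[k] for k in ("TL", "TR", "BR", "BL")]
        except KeyError as exc:
            raise RegionError(f"missing corner point {exc}") from exc
        return np.array([[p.x, p.y] for p in pts], dtype=float)


_CORNER_NAMES = {
    "s1hl top left point": "TL",
    "s1hl top right point": "TR",
    "s1hl bottom left point": "BL",
    "s1hl bottom right point": "BR",
    "top left": "TL", "top right": "TR", "bottom left": "BL", "bottom right": "BR",
    "tl": "TL", "tr": "TR", "bl": "BL", "br": "BR",
}


def _feature_name(props: Mapping) -> str | None:
    cls = props.get("classification")
    if isinstance(cls, Mapping) and cls.get("name"):
        return str(cls["name"])
    if isinstance(cls, str) and cls:
        return cls
    if props.get("name"):
        return str(props["name"])
    return None


def read_regions(path) -> RegionSet:
    """Read a GeoJSON FeatureCollection of region annotations.

    Geometries are indexed by classification name; polygon exteriors are
    normalized counter-clockwise.  An absent or self-intersecting S1HL
    feature is an error.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    s1hl = pia = contour = None
    corners: dict[str, Point] = {}
    metadata: dict = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        name = _feature_name(props)
        if name is None:
            continue
        geom = shape(feat["geometry"])
        key = _norm(name)
        if key == "s1hl":
            s1hl = orient(Polygon(geom.exterior) if isinstance(geom, Polygon) else geom)
            for meta_key in ("distance_to_midline_mm", "analyze_flag"):
                if meta_key in props:
                    metadata[meta_key] = props[meta_key]
        elif key in ("outside pia", "outsidepia"):
            pia = geom
        elif key in ("slicecontour", "slice contour"):
            contour = orient(geom) if isinstance(geom, Polygon) else geom
        elif key in _CORNER_NAMES:
            corners[_CORNER_NAMES[key]] = Point(geom.coords[0] if geom.geom_type == "Point" else geom.centroid.coords[0])
    if s1hl is None:
        raise RegionError("FeatureCollection has no 'S1HL' feature")
    return RegionSet(s1hl=s1hl, outside_pia=pia, slice_contour=contour,
                     corners=corners, metadata=metadata).validate()


def write_regions(regions: RegionSet, path) -> None:
    """Write a RegionSet back to a GeoJSON FeatureCollection."""

    def feature(name: str, geom, extra: Mapping | None = None) -> dict:
        props = {"classification": {"name": name}}
        if extra:
            props.update(extra)
        return {"type": "Feature", "geometry": mapping(geom), "properties": props}

    feats = [feature("S1HL", orient(regions.s1hl), regions.metadata or None)]
    if regions.outside_pia is not None:
        feats.append(feature("Outside Pia", regions.outside_pia))
    if regions.slice_contour is not None:
        geom = regions.slice_contour
        feats.append(feature("SliceContour", orient(geom) if isinstance(geom, Polygon) else geom))
    long_name = {"TL": "S1HL top-left point", "TR": "S1HL top-right point",
                 "BL": "S1HL bottom-left point", "BR": "S1HL bottom-right point"}
    for key, pt in regions.corners.items():
        feats.append(feature(long_name.get(key, key), pt))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
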