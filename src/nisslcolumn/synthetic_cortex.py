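"""Synthetic layered cortical columns.

Generates the geometry and cell point pattern of a curved cortical band
partitioned into layers, in the same formats the I/O layer reads, so the
whole quantification pipeline can be exercised without image data.

The model: the pia is a circular arc of adjustable bow (sagitta); each
layer is the annular band between two offsets of the pia at constant
normal distance, so a cell's depth coordinate coincides with its distance
to the pia.  Within a band, cells form a homogeneous Poisson point
process with the layer's intensity (cells/mm^3, using the slice thickness
for the third dimension), and soma diameters are drawn from a 2-component
Gaussian mixture truncated below at a physical floor.  Default layer
parameters (heights, densities, mixture means/sds) are the juvenile-rat
S1HL values shipped in ``data/s1hl_reference_layers.json``; mixture weights are
not part of that reference set and default to 0.5.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from nisslcolumn.io_formats import RegionSet

__all__ = [
    "LayerSpec",
    "ColumnSpec",
    "reference_layers",
    "default_column_spec",
    "make_geometry",
    "sample_cells",
    "make_column",
    "sample_diameters",
    "MIN_DIAMETER_UM",
]

#: Truncation floor for sampled soma diameters (µm) — the smallest soma
#: diameter observed in juvenile-rat S1HL Nissl data.
MIN_DIAMETER_UM = 0.39

#: Points used to discretize each pia-offset polyline.
_ARC_POINTS = 256


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer: band thickness, Poisson intensity, diameter mixture."""

    label: str
    height_um: float
    density_cells_mm3: float
    pop1_mean_um: float
    pop1_sd_um: float
    pop2_mean_um: float
    pop2_sd_um: float
    pop1_weight: float = 0.5

    def __post_init__(self):
        if self.height_um <= 0:
            raise ValueError("height_um must be positive")
        if self.density_cells_mm3 < 0:
            raise ValueError("density must be non-negative")
        if min(self.pop1_sd_um, self.pop2_sd_um) <= 0:
            raise ValueError("mixture sds must be positive")
        if not 0.0 <= self.pop1_weight <= 1.0:
            raise ValueError("pop1_weight must be in [0, 1]")


@dataclass(frozen=True)
class ColumnSpec:
    """A cortical column: ordered layers (pia -> white matter) and geometry."""

    layers: tuple[LayerSpec, ...]
    column_width_um: float = 1000.0
    curvature_um: float = 0.0
    thickness_um: float = 50.0
    seed: int = 0
    image_id: str = "synthetic_column"

    def __post_init__(self):
        if not self.layers:
            raise ValueError("at least one layer required")
        if self.column_width_um <= 0 or self.thickness_um <= 0:
            raise ValueError("degenerate column spec")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_height_um(self) -> float:
        return float(sum(l.height_um for l in self.layers))


def reference_layers(pop1_weight: float = 0.5) -> tuple[LayerSpec, ...]:
    """The packaged per-layer reference parameters (juvenile rat S1HL)."""
    ref = resources.files("nisslcolumn").joinpath("data/s1hl_reference_layers.json")
    rows = json.loads(ref.read_text(encoding="utf-8"))["layers"]
    return tuple(LayerSpec(pop1_weight=pop1_weight, **row) for row in rows)


def default_column_spec(seed: int = 0, **overrides) -> ColumnSpec:
    """A full seven-layer column with the packaged reference parameters."""
    return ColumnSpec(layers=reference_layers(), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Geometry


def _arc_params(spec: ColumnSpec) -> tuple[float, float]:
    """Radius and half-angle of the pia arc; curvature is the sagitta."""
    c, half_w = spec.curvature_um, spec.column_width_um / 2.0
    radius = (half_w**2 + c**2) / (2.0 * c)
    half_angle = np.arcsin(half_w / radius)
    return radius, half_angle


def _offset_polyline(spec: ColumnSpec, depth: float, n: int = _ARC_POINTS) -> np.ndarray:
    """The pia offset at constant normal distance ``depth``, left to right."""
    w = spec.column_width_um
    if spec.curvature_um == 0.0:
        x = np.linspace(0.0, w, n)
        return np.column_stack([x, np.full(n, depth)])
    radius, half_angle = _arc_params(spec)
    theta = np.linspace(-half_angle, half_angle, n)
    r = radius + depth
    return np.column_stack([w / 2.0 + r * np.sin(theta), radius - r * np.cos(theta)])


def make_geometry(spec: ColumnSpec) -> RegionSet:
    """Build the region annotations of a synthetic column.

    The S1HL polygon is bounded above by the pia polyline, below by its
    offset at the total layer height, and laterally by the straight (for
    curvature 0) or radial side edges.  With curvature 0 it is an
    axis-aligned rectangle of width x total height.  The four corner
    reference points are the polyline endpoints.
    """
    top = _offset_polyline(spec, 0.0)
    bottom = _offset_polyline(spec, spec.total_height_um)
    ring = np.vstack([top, bottom[::-1]])
    s1hl = Polygon(ring)
    corners = {
        "TL": Point(top[0]), "TR": Point(top[-1]),
        "BL": Point(bottom[0]), "BR": Point(bottom[-1]),
    }
    return RegionSet(
        s1hl=s1hl,
        outside_pia=LineString(top),
        corners=corners,
        metadata={"analyze_flag": True},
    ).validate()


def _band_area_um2(spec: ColumnSpec, d0: float, d1: float) -> float:
    if spec.curvature_um == 0.0:
        return spec.column_width_um * (d1 - d0)
    radius, half_angle = _arc_params(spec)
    return half_angle * ((radius + d1) ** 2 - (radius + d0) ** 2)


def _sample_in_band(spec: ColumnSpec, d0: float, d1: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the band between pia offsets d0 and d1."""
    if spec.curvature_um == 0.0:
        x = rng.uniform(0.0, spec.column_width_um, n)
        y = rng.uniform(d0, d1, n)
        return np.column_stack([x, y])
    radius, half_angle = _arc_params(spec)
    theta = rng.uniform(-half_angle, half_angle, n)
    r = np.sqrt(rng.uniform((radius + d0) ** 2, (radius + d1) ** 2, n))
    return np.column_stack(
        [spec.column_width_um / 2.0 + r * np.sin(theta), radius - r * np.cos(theta)]
    )


def sample_diameters(layer: LayerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from the layer's 2-component mixture, truncated at the floor."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        comp = rng.random(todo.size) >= layer.pop1_weight
        mean = np.where(comp, layer.pop2_mean_um, layer.pop1_mean_um)
        sd = np.where(comp, layer.pop2_sd_um, layer.pop1_sd_um)
        draw = rng.normal(mean, sd)
        out[todo] = draw
        todo = todo[draw < MIN_DIAMETER_UM]
    return out


def _layer_rng(spec: ColumnSpec, layer: LayerSpec) -> np.random.Generator:
    # named sub-stream: stable under edits to the rest of the layer list
    tag = zlib.crc32(layer.label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((spec.seed, tag)))


def sample_cells(spec: ColumnSpec, geometry: RegionSet | None = None) -> pd.DataFrame:
    """Sample the cell table of a synthetic column.

    Per layer, the cell count is Poisson(density x band area x slice
    thickness); positions are uniform in the band; diameters come from
    the layer mixture; ``dist_pia_um`` is the Euclidean distance from the
    centroid to the pia polyline; ``area_um2`` assumes a circular soma of
    the representative diameter.  Deterministic given ``spec.seed``.
    """
    if geometry is None:
        geometry = make_geometry(spec)
    pia = geometry.outside_pia
    frames = []
    d0 = 0.0
    for layer in spec.layers:
        d1 = d0 + layer.height_um
        rng = _layer_rng(spec, layer)
        volume_mm3 = _band_area_um2(spec, d0, d1) * spec.thickness_um * 1e-9
        n = int(rng.poisson(layer.density_cells_mm3 * volume_mm3))
        xy = _sample_in_band(spec, d0, d1, n, rng)
        diam = sample_diameters(layer, n, rng)
        ecc = rng.uniform(0.0, 0.15, n)  # symmetric about the mean diameter
        dist = np.array([pia.distance(Point(p)) for p in xy]) if n else np.empty(0)
        frames.append(pd.DataFrame({
            "image_id": spec.image_id,
            "cell_id": [f"{layer.label}_{i}" for i in range(n)],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "d_max_um": diam * (1.0 + ecc),
            "d_min_um": diam * (1.0 - ecc),
            "area_um2": np.pi * (diam / 2.0) ** 2,
            "dist_pia_um": dist,
            "layer_label": layer.label,
        }))
        d0 = d1
    return pd.concat(frames, ignore_index=True)


def make_column(spec: ColumnSpec) -> tuple[RegionSet, pd.DataFrame]:
    """Convenience: geometry plus sampled cells for one column."""
    geometry = make_geometry(spec)
    return geometry, sample_cells(spec, geometry)


def column_spec_to_json(spec: ColumnSpec) -> str:
    doc = asdict(spec)
    doc["layers"] = [asdict(l) for l in spec.layers]
    return json.dumps(doc, indent=2)


def column_spec_from_json(text: str) -> ColumnSpec:
    doc = json.loads(text)
    doc["layers"] = tuple(LayerSpec(**l) for l in doc["layers"])
    return ColumnSpec(**doc)
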