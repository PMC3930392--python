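"""ROI lattice over an annotated slide, plus per-tile heat maps.

The slide is partitioned into an axis-aligned grid of square tiles of
physical edge ``tile_size_mm`` (0.25 mm by convention here), anchored at
the image origin, in half-open pixel intervals. Hand-drawn annotation
polygons (GeoJSON) mark regions to keep or discard: if any include-polygon
is present, tissue is its union; otherwise the whole image is tissue; all
exclude-polygons are subtracted. A tile is retained when the fraction of
its pixels falling in tissue reaches ``min_valid_fraction``.

Pixel conventions: origin top-left, x rightward, y downward, 0-based;
pixel (row, col) covers [col, col+1) x [row, row+1) and its center sits at
(col + 0.5, row + 0.5). Polygon membership is decided by pixel-center
inclusion.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon, shape as shapely_shape, mapping

from .image import RgbImage

logger = logging.getLogger(__name__)


class EmptyGridError(ValueError):
    """No tile survived annotation filtering."""


@dataclass(frozen=True)
class Annotation:
    polygon: Polygon
    role: str  # "include" | "exclude"

    def __post_init__(self) -> None:
        if self.role not in ("include", "exclude"):
            raise ValueError(f"annotation role must be include|exclude, got {self.role!r}")
        if len(self.polygon.exterior.coords) < 4:  # closed ring: >=3 vertices
            raise ValueError("polygon needs at least 3 vertices")
        if self.polygon.area == 0:
            raise ValueError("polygon has zero area")


@dataclass(frozen=True)
class AnnotationSet:
    annotations: tuple[Annotation, ...] = ()

    @property
    def includes(self) -> list[Polygon]:
        return [a.polygon for a in self.annotations if a.role == "include"]

    @property
    def excludes(self) -> list[Polygon]:
        return [a.polygon for a in self.annotations if a.role == "exclude"]

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AnnotationSet":
        data = json.loads(Path(path).read_text())
        anns = []
        for feat in data.get("features", []):
            geom = shapely_shape(feat["geometry"])
            role = feat.get("properties", {}).get("role", "exclude")
            anns.append(Annotation(geom, role))
        return cls(tuple(anns))

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(a.polygon),
                "properties": {"role": a.role},
            }
            for a in self.annotations
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        )


def rasterize_mask(shape: tuple[int, int], annotations: AnnotationSet | None) -> np.ndarray:
    """Boolean tissue mask by pixel-center inclusion.

    Tissue = union of include-polygons (whole image if there are none)
    minus the union of exclude-polygons.
    """
    h, w = shape
    if annotations is None or not annotations.annotations:
        return np.ones((h, w), dtype=bool)
    includes = annotations.includes
    if includes:
        mask = np.zeros((h, w), dtype=bool)
        for poly in includes:
            mask |= _polygon_hits(poly, shape)
    else:
        mask = np.ones((h, w), dtype=bool)
    for poly in annotations.excludes:
        mask &= ~_polygon_hits(poly, shape)
    return mask


def _polygon_hits(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers fall inside a polygon, restricted to its bbox."""
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx - 0.5)) + 1, w)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy - 0.5)) + 1, h)
    out = np.zeros((h, w), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return out
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    path = MplPath(np.asarray(poly.exterior.coords))
    inside = path.contains_points(centers).reshape(rows.shape)
    for ring in poly.interiors:
        hole = MplPath(np.asarray(ring.coords))
        inside &= ~hole.contains_points(centers).reshape(rows.shape)
    out[r0:r1, c0:c1] = inside
    return out


@dataclass(frozen=True)
class Tile:
    """One grid cell: half-open pixel box [x0,x1) x [y0,y1)."""

    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    valid_fraction: float

    @property
    def roi_id(self) -> str:
        return f"r{self.row}_c{self.col}"

    @property
    def n_pixels(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass(frozen=True)
class RoiGrid:
    """Retained ROI tiles over an image, with provenance parameters."""

    tiles: tuple[Tile, ...]
    all_tiles: tuple[Tile, ...]
    tile_size_mm: float
    microns_per_pixel: float
    image_shape: tuple[int, int]
    min_valid_fraction: float

    @property
    def tile_px(self) -> int:
        return int(round(self.tile_size_mm * 1000.0 / self.microns_per_pixel))

    def tile_by_id(self, roi_id: str) -> Tile:
        for t in self.tiles:
            if t.roi_id == roi_id:
                return t
        raise KeyError(roi_id)


def build_grid(
    image: RgbImage | tuple[int, int],
    annotations: AnnotationSet | None = None,
    tile_size_mm: float = 0.25,
    min_valid_fraction: float = 0.5,
    microns_per_pixel: float | None = None,
) -> RoiGrid:
    """Lay the tile lattice over an image and filter by annotations.

    Edge tiles smaller than the full tile size are kept with their true
    pixel extent. Raises :class:`EmptyGridError` if nothing survives.
    """
    if isinstance(image, RgbImage):
        shape = image.shape
        mpp = image.microns_per_pixel
    else:
        shape = tuple(image)
        if microns_per_pixel is None:
            raise ValueError("microns_per_pixel required when passing a bare shape")
        mpp = microns_per_pixel
    h, w = shape
    tile_px = int(round(tile_size_mm * 1000.0 / mpp))
    if tile_px < 1:
        raise ValueError("tile size is below one pixel at this resolution")
    if tile_px >= max(h, w):
        warnings.warn(
            "tile size exceeds image extent; grid degenerates to edge tiles",
            stacklevel=2,
        )
    mask = rasterize_mask(shape, annotations)
    all_tiles: list[Tile] = []
    retained: list[Tile] = []
    for row, y0 in enumerate(range(0, h, tile_px)):
        y1 = min(y0 + tile_px, h)
        for col, x0 in enumerate(range(0, w, tile_px)):
            x1 = min(x0 + tile_px, w)
            vf = float(mask[y0:y1, x0:x1].mean())
            tile = Tile(row, col, x0, y0, x1, y1, vf)
            all_tiles.append(tile)
            if vf >= min_valid_fraction:
                retained.append(tile)
    if not retained:
        raise EmptyGridError("no tile meets min_valid_fraction")
    return RoiGrid(
        tuple(retained), tuple(all_tiles), tile_size_mm, mpp, (h, w), min_valid_fraction
    )


def sample_rois(grid: RoiGrid, n: int, seed: int | np.random.Generator) -> list[Tile]:
    """Uniform sample of retained tiles without replacement, seed-reproducible."""
    if n > len(grid.tiles):
        raise ValueError(f"requested {n} ROIs but only {len(grid.tiles)} retained")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(len(grid.tiles), size=n, replace=False)
    return [grid.tiles[i] for i in sorted(idx)]


def grid_to_frame(grid: RoiGrid):
    """Retained tiles as a DataFrame (roi_id keyed), for CSV output."""
    import pandas as pd

    return pd.DataFrame(
        {
            "roi_id": [t.roi_id for t in grid.tiles],
            "row": [t.row for t in grid.tiles],
            "col": [t.col for t in grid.tiles],
            "x0": [t.x0 for t in grid.tiles],
            "y0": [t.y0 for t in grid.tiles],
            "x1": [t.x1 for t in grid.tiles],
            "y1": [t.y1 for t in grid.tiles],
            "valid_fraction": [t.valid_fraction for t in grid.tiles],
        }
    )


@dataclass(frozen=True)
class HeatmapSpec:
    """Rendering parameters for the per-tile heat map."""

    cmap: str = "Reds"
    excluded_color: tuple[int, int, int] = (200, 200, 200)
    missing_color: tuple[int, int, int] = (120, 160, 220)


def render_heatmap(
    grid: RoiGrid,
    values: dict[str, float],
    spec: HeatmapSpec = HeatmapSpec(),
) -> RgbImage:
    """Paint each retained tile by its value through a monotone color ramp.

    The min/max of the finite values map to the ramp ends; excluded tiles
    are neutral gray; tiles with non-finite values get a distinct missing
    color and a logged warning.
    """
    missing_ids = [t.roi_id for t in grid.tiles if not np.isfinite(values.get(t.roi_id, np.nan))]
    if missing_ids:
        logger.warning("heat map: %d tile(s) with non-finite values: %s",
                       len(missing_ids), ", ".join(missing_ids[:10]))
    finite = [values[t.roi_id] for t in grid.tiles
              if t.roi_id not in set(missing_ids) and t.roi_id in values]
    lo = min(finite) if finite else 0.0
    hi = max(finite) if finite else 1.0
    span = hi - lo if hi > lo else 1.0
    cmap = matplotlib.colormaps[spec.cmap]
    img = np.empty((*grid.image_shape, 3), dtype=np.uint8)
    img[...] = spec.excluded_color
    missing = set(missing_ids)
    for t in grid.tiles:
        if t.roi_id in missing or t.roi_id not in values:
            color = spec.missing_color
        else:
            frac = (values[t.roi_id] - lo) / span
            color = tuple(int(round(255 * c)) for c in cmap(frac)[:3])
        img[t.slices()] = color
    return RgbImage(img, grid.microns_per_pixel)
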