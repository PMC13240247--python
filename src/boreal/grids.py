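"""Grid and geometry primitives shared by the spatial modules.

All geometry lives in one projected, equal-area coordinate system with
metre units (e.g., Canada Albers).  A :class:`RasterGrid` is a plain numpy
array with an affine anchor (upper-left origin, square cells); vector
features are shapely geometries tagged with a feature class and, for
fires, a year.  Area statistics are cell counts: a cell belongs to a
polygon when its *center* falls inside it, and to a line when its center
lies within half a cell diagonal of the line.  These conventions are
deliberate, simple and testable; they are documented rather than claimed
to match any particular GIS workflow.

I/O is plain text: ESRI ASCII grid (``.asc``) for rasters and GeoJSON for
feature sets, so fixtures and outputs stay diffable and portable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("road", "mine", "fire", "other_anthro")

#: default cell edge, metres; a 500 m buffer spans >= 2 cells at this size
DEFAULT_RESOLUTION_M = 250.0


class CRSMismatchError(ValueError):
    """Raised when two layers do not share a coordinate reference label."""


@dataclass(frozen=True)
class RasterGrid:
    """A single-band raster on a square grid in projected coordinates.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; dtype is caller's choice (bool, int, float).
    resolution : float
        Cell edge length in metres (> 0).
    origin : (float, float)
        (x, y) of the *upper-left corner* of the grid.
    nodata_mask : ndarray of bool, same shape
        True where the cell carries no data; excluded from all area math.
    crs : str
        Free-form label for the projected equal-area CRS; layers must
        agree on it before they are combined.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    crs: str = "local-albers"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        vals = np.asarray(self.values)
        object.__setattr__(self, "values", vals)
        if self.nodata_mask is None:
            object.__setattr__(self, "nodata_mask", np.zeros(vals.shape, dtype=bool))
        else:
            mask = np.asarray(self.nodata_mask, dtype=bool)
            if mask.shape != vals.shape:
                raise ValueError(
                    f"nodata_mask shape {mask.shape} != values shape {vals.shape}"
                )
            object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) arrays of cell-center coordinates, shape (nrows, ncols)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.resolution
        ys = y0 - (np.arange(nrows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        return replace(
            self,
            values=values,
            nodata_mask=self.nodata_mask if nodata_mask is None else nodata_mask,
        )

    def bounds(self) -> tuple[float, float, float, float]:
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.resolution, x0 + ncols * self.resolution, y0)


@dataclass(frozen=True)
class Feature:
    geometry: BaseGeometry
    feature_class: str
    year: int | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class {self.feature_class!r} not one of {FEATURE_CLASSES}"
            )
        if self.feature_class == "fire" and self.year is None:
            raise ValueError("fire features must carry a year")
        geom = self.geometry
        if not geom.is_valid:
            # zero-width buffer repairs self-intersections; warn, don't fail
            logger.warning("auto-repairing invalid %s geometry", self.feature_class)
            object.__setattr__(self, "geometry", geom.buffer(0))


@dataclass(frozen=True)
class FeatureSet:
    """A bag of classed vector features sharing one CRS."""

    features: tuple[Feature, ...]
    crs: str = "local-albers"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def select(self, *classes: str) -> "FeatureSet":
        return FeatureSet(
            tuple(f for f in self.features if f.feature_class in classes), crs=self.crs
        )

    def union_geometry(self) -> BaseGeometry:
        if not self.features:
            return shapely.GeometryCollection()
        return unary_union([f.geometry for f in self.features])

    def merge(self, other: "FeatureSet") -> "FeatureSet":
        if other.crs != self.crs:
            raise CRSMismatchError(f"cannot merge CRS {self.crs!r} with {other.crs!r}")
        return FeatureSet(self.features + other.features, crs=self.crs)


@dataclass(frozen=True)
class RangePolygon:
    """Boundary of one local caribou population (e.g., Missisa)."""

    boundary: BaseGeometry
    name: str = "range"
    crs: str = "local-albers"

    def __post_init__(self) -> None:
        geom = self.boundary
        if not geom.is_valid:
            logger.warning("auto-repairing invalid range polygon %r", self.name)
            geom = geom.buffer(0)
            object.__setattr__(self, "boundary", geom)
        if geom.area <= 0:
            raise ValueError(f"range {self.name!r} must have positive area")


# ---------------------------------------------------------------------------
# core operations


def rasterize(features: FeatureSet | BaseGeometry, grid: RasterGrid) -> RasterGrid:
    """Burn features onto ``grid`` as a boolean mask.

    A cell is True when its center falls inside a polygon, or lies within
    half a cell diagonal of a line or point feature.  An empty feature set
    yields an all-False raster.
    """
    if isinstance(features, FeatureSet):
        if features.crs != grid.crs:
            raise CRSMismatchError(
                f"feature CRS {features.crs!r} != grid CRS {grid.crs!r}"
            )
        geoms = [f.geometry for f in features]
    else:
        geoms = [features]
    out = np.zeros(grid.shape, dtype=bool)
    if not geoms or all(g.is_empty for g in geoms):
        return grid.with_values(out)

    xs, ys = grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    half_diag = grid.resolution * np.sqrt(2.0) / 2.0
    hit = np.zeros(pts.shape, dtype=bool)
    for geom in geoms:
        if geom.is_empty:
            continue
        # split collections so the polygon/line rule applies per part
        parts = getattr(geom, "geoms", [geom])
        for part in parts:
            if part.geom_type in ("Polygon", "MultiPolygon"):
                hit |= shapely.contains_xy(part, xs.ravel(), ys.ravel())
            else:
                todo = ~hit
                if todo.any():
                    hit[todo] |= shapely.dwithin(pts[todo], part, half_diag)
    return grid.with_values(hit.reshape(grid.shape))


def buffer_features(features: FeatureSet, width: float, quad_segs: int = 16) -> FeatureSet:
    """Minkowski-dilate every geometry by ``width`` metres, keeping classes.

    ``width == 0`` returns the features unchanged (a true zero-dilation —
    lines keep their zero-area footprint).
    """
    if width < 0:
        raise ValueError(f"buffer width must be >= 0, got {width}")
    if width == 0:
        return features
    return FeatureSet(
        tuple(
            Feature(f.geometry.buffer(width, quad_segs=quad_segs), f.feature_class, f.year)
            for f in features
        ),
        crs=features.crs,
    )


def area_fraction(mask: RasterGrid, range_poly: RangePolygon) -> float:
    """Percent (0-100) of the range's valid cells that are True in ``mask``."""
    if mask.crs != range_poly.crs:
        raise CRSMismatchError(
            f"mask CRS {mask.crs!r} != range CRS {range_poly.crs!r}"
        )
    in_range = rasterize(range_poly.boundary, mask).values
    valid = in_range & ~mask.nodata_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(
            f"range {range_poly.name!r} covers no valid grid cells"
        )
    n_true = int((np.asarray(mask.values, dtype=bool) & valid).sum())
    return 100.0 * n_true / n_valid


def grid_for_range(
    range_poly: RangePolygon,
    resolution: float = DEFAULT_RESOLUTION_M,
    pad_cells: int = 2,
) -> RasterGrid:
    """Build an empty boolean grid covering the range plus a small pad."""
    minx, miny, maxx, maxy = range_poly.boundary.bounds
    pad = pad_cells * resolution
    x0 = np.floor((minx - pad) / resolution) * resolution
    y1 = np.ceil((maxy + pad) / resolution) * resolution
    ncols = int(np.ceil((maxx + pad - x0) / resolution))
    nrows = int(np.ceil((y1 - (miny - pad)) / resolution))
    return RasterGrid(
        np.zeros((nrows, ncols), dtype=bool),
        resolution=resolution,
        origin=(float(x0), float(y1)),
        crs=range_poly.crs,
    )


# ---------------------------------------------------------------------------
# plain-text I/O: ESRI ASCII grids and GeoJSON feature sets


def write_ascii_grid(grid: RasterGrid, path: str | Path, nodata_value: float = -9999.0) -> None:
    path = Path(path)
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    vals = np.asarray(grid.values, dtype=float).copy()
    vals[grid.nodata_mask] = nodata_value
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0 - nrows * grid.resolution}\n"
        f"cellsize {grid.resolution}\n"
        f"NODATA_value {nodata_value}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path: str | Path, crs: str = "local-albers") -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", -9999.0)
    res = header["cellsize"]
    nrows = int(header["nrows"])
    origin = (header["xllcorner"], header["yllcorner"] + nrows * res)
    mask = vals == nodata
    return RasterGrid(vals, resolution=res, origin=origin, nodata_mask=mask, crs=crs)


def write_feature_set(features: FeatureSet, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "crs_label": features.crs,
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {"feature_class": f.feature_class, "year": f.year},
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_feature_set(path: str | Path) -> FeatureSet:
    doc = json.loads(Path(path).read_text())
    feats = tuple(
        Feature(
            shapely_shape(item["geometry"]),
            item["properties"]["feature_class"],
            item["properties"].get("year"),
        )
        for item in doc["features"]
    )
    return FeatureSet(feats, crs=doc.get("crs_label", "local-albers"))


def write_range_polygon(range_poly: RangePolygon, path: str | Path) -> None:
    doc = {
        "type": "Feature",
        "geometry": mapping(range_poly.boundary),
        "properties": {"name": range_poly.name, "crs_label": range_poly.crs},
    }
    Path(path).write_text(json.dumps(doc))


def read_range_polygon(path: str | Path) -> RangePolygon:
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    return RangePolygon(
        shapely_shape(doc["geometry"]),
        name=props.get("name", "range"),
        crs=props.get("crs_label", "local-albers"),
    )
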