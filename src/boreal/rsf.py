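"""Resource-selection surfaces from published coefficient tables.

An RSF here is a linear predictor η = Σ βᵢ·xᵢ over predictor rasters
(moving-window land-cover proportions, road density), pushed through
either the exponential form w = exp(η) — standard for use–availability
RSFs, defined up to a multiplicative constant — or the logistic form
w = 1/(1+e^(−η)), and then rescaled by its maximum over valid cells to a
0–1 relative probability of use.  Coefficients are applied as published;
no fitting happens in this module.

Cross-range transferability is diagnosed by applying a neighbouring
range's table to the same predictor stack and correlating the two
surfaces cell by cell (Pearson r over the shared valid cells), with the
paired values retained for scatterplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import shapely
from shapely.geometry import box

from .grids import FeatureSet, RasterGrid
from .synthetic import LandscapeStack

SEASONS = ("spring", "summer", "fall", "winter")
TRANSFORMS = ("exponential", "logistic")

#: default moving-window radius for habitat-availability predictors
DEFAULT_WINDOW_RADIUS_M = 5000.0


@dataclass(frozen=True)
class RSFCoefficientTable:
    range_name: str
    season: str
    terms: tuple[tuple[str, float], ...]
    transform: str = "exponential"
    provenance: str = "illustrative"

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        names = [n for n, _ in self.terms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate predictor names in table: {names}")
        if not self.terms:
            raise ValueError("coefficient table needs at least one term")


@dataclass(frozen=True)
class PredictorStack:
    """Named, co-registered predictor rasters on one grid."""

    layers: Mapping[str, RasterGrid]

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if not grids:
            raise ValueError("empty predictor stack")
        ref = grids[0]
        for g in grids[1:]:
            if g.shape != ref.shape or g.origin != ref.origin or g.resolution != ref.resolution:
                raise ValueError("predictor layers are not co-registered")
        object.__setattr__(self, "layers", dict(self.layers))

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def combined_nodata(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        return mask


@dataclass(frozen=True)
class RSFSurface:
    values: RasterGrid      # relative probability of use in [0, 1]
    season: str
    source_range: str


@dataclass(frozen=True)
class TransferabilityReport:
    pearson_r: float
    paired_values: np.ndarray    # shape (n, 2): (reference, transferred)
    season: str
    reference_range: str
    transferred_range: str
    zero_variance: bool = False


def _circular_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 <= radius_cells**2).astype(float)


def moving_window_proportion(
    indicator: np.ndarray, radius_cells: float
) -> np.ndarray:
    """Fraction of cells in a circular window (by center distance) that are 1."""
    kernel = _circular_kernel(radius_cells)
    counts = ndimage.convolve(
        indicator.astype(float), kernel, mode="constant", cval=0.0
    )
    denom = ndimage.convolve(
        np.ones_like(indicator, dtype=float), kernel, mode="constant", cval=0.0
    )
    return counts / denom


def road_length_per_cell(roads: FeatureSet, grid: RasterGrid) -> np.ndarray:
    """Exact road length (m) clipped to each cell's square footprint."""
    out = np.zeros(grid.shape, dtype=float)
    lines = [f.geometry for f in roads if f.geometry.geom_type.startswith(("Line", "MultiLine"))]
    if not lines:
        return out
    res = grid.resolution
    x0, y0 = grid.origin
    nrows, ncols = grid.shape
    tree = shapely.STRtree(lines)
    for row in range(nrows):
        ytop = y0 - row * res
        for col in range(ncols):
            cell = box(x0 + col * res, ytop - res, x0 + (col + 1) * res, ytop)
            for idx in tree.query(cell):
                seg = lines[idx].intersection(cell)
                if not seg.is_empty:
                    out[row, col] += seg.length
    return out


def derive_predictors(
    landscape: LandscapeStack,
    scenario: FeatureSet,
    window_radius_m: float = DEFAULT_WINDOW_RADIUS_M,
    classes: Sequence[str] | None = None,
) -> PredictorStack:
    """Build the predictor stack: per-class window proportions + road density.

    For each land-cover class, the layer ``prop_<class>`` is the fraction
    of cells within a circular window (radius ``window_radius_m``, cell
    membership by center distance) in that class.  ``road_density`` is
    total road length within the window divided by window area, in
    km/km².  Edge windows are truncated at the grid boundary.
    """
    lc = landscape.landcover
    radius_cells = window_radius_m / lc.resolution
    names = classes if classes is not None else landscape.class_names
    layers: dict[str, RasterGrid] = {}
    for code, name in enumerate(landscape.class_names):
        if name not in names:
            continue
        indicator = (np.asarray(lc.values) == code).astype(float)
        layers[f"prop_{name}"] = lc.with_values(
            moving_window_proportion(indicator, radius_cells)
        )

    roads = scenario.select("road")
    length_m = road_length_per_cell(roads, lc)
    kernel = _circular_kernel(radius_cells)
    window_len = ndimage.convolve(length_m, kernel, mode="constant", cval=0.0)
    n_cells = ndimage.convolve(
        np.ones_like(length_m), kernel, mode="constant", cval=0.0
    )
    window_area_km2 = n_cells * (lc.resolution / 1000.0) ** 2
    layers["road_density"] = lc.with_values(
        (window_len / 1000.0) / window_area_km2
    )
    return PredictorStack(layers)


def apply_rsf(table: RSFCoefficientTable, predictors: PredictorStack) -> RSFSurface:
    """Evaluate the linear predictor and transform to a 0–1 use surface.

    The exponential transform makes the surface invariant to adding a
    constant to η (the max-rescale cancels it); nodata in any predictor
    propagates to the output.
    """
    missing = [n for n, _ in table.terms if n not in predictors.layers]
    if missing:
        raise KeyError(
            f"predictors missing from stack: {missing}; "
            f"available: {sorted(predictors.layers)}"
        )
    grid = predictors.grid
    eta = np.zeros(grid.shape, dtype=float)
    for name, beta in table.terms:
        eta += beta * np.asarray(predictors.layers[name].values, dtype=float)
    nodata = predictors.combined_nodata()
    valid = ~nodata
    if not valid.any():
        raise ValueError("all cells are nodata; cannot build an RSF surface")
    if table.transform == "exponential":
        # subtract max(eta) before exp for overflow safety; rescale absorbs it
        w = np.exp(eta - eta[valid].max())
    else:
        w = 1.0 / (1.0 + np.exp(-eta))
    w = w / w[valid].max()
    w[nodata] = np.nan
    return RSFSurface(
        values=grid.with_values(w, nodata_mask=nodata),
        season=table.season,
        source_range=table.range_name,
    )


def compare_surfaces(
    reference: RSFSurface,
    transferred: RSFSurface,
    max_pairs: int | None = None,
    seed: int = 0,
) -> TransferabilityReport:
    """Cell-wise comparison of two use surfaces on their shared valid cells.

    Pearson r plus the paired (reference, transferred) values for
    scatterplotting, optionally thinned to ``max_pairs`` with a fixed
    seed.  A zero-variance surface leaves r undefined (NaN, flagged).
    """
    ref_g, tr_g = reference.values, transferred.values
    if ref_g.shape != tr_g.shape or ref_g.origin != tr_g.origin:
        raise ValueError("surfaces are not on a shared grid")
    if reference.season != transferred.season:
        raise ValueError(
            f"seasons differ: {reference.season} vs {transferred.season}"
        )
    valid = ~(ref_g.nodata_mask | tr_g.nodata_mask)
    a = np.asarray(ref_g.values, dtype=float)[valid]
    b = np.asarray(tr_g.values, dtype=float)[valid]
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError(f"only {a.size} shared valid cells; need >= 3")
    zero_var = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    r = float("nan") if zero_var else float(stats.pearsonr(a, b).statistic)
    pairs = np.column_stack([a, b])
    if max_pairs is not None and pairs.shape[0] > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(pairs.shape[0], size=max_pairs, replace=False)
        pairs = pairs[np.sort(idx)]
    return TransferabilityReport(
        pearson_r=r,
        paired_values=pairs,
        season=reference.season,
        reference_range=reference.source_range,
        transferred_range=transferred.source_range,
        zero_variance=zero_var,
    )


# ---------------------------------------------------------------------------
# coefficient CSV schema: range,season,predictor,coefficient,transform


def load_coefficient_tables(path: str | Path) -> list[RSFCoefficientTable]:
    df = pd.read_csv(path)
    required = {"range", "season", "predictor", "coefficient", "transform"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"coefficient CSV must have columns {sorted(required)}, "
            f"got {sorted(df.columns)}"
        )
    tables = []
    for (rng_name, season), grp in df.groupby(["range", "season"], sort=True):
        transforms = grp["transform"].unique()
        if len(transforms) != 1:
            raise ValueError(
                f"mixed transforms for {rng_name}/{season}: {list(transforms)}"
            )
        tables.append(
            RSFCoefficientTable(
                range_name=str(rng_name),
                season=str(season),
                terms=tuple(
                    (str(p), float(c))
                    for p, c in zip(grp["predictor"], grp["coefficient"])
                ),
                transform=str(transforms[0]),
            )
        )
    return tables


def default_coefficient_tables() -> list[RSFCoefficientTable]:
    """Illustrative seasonal tables shipped with the package."""
    from importlib.resources import files
    import io

    text = files("boreal").joinpath("data/rsf_coefficients.csv").read_text()
    return load_coefficient_tables(io.StringIO(text))  # type: ignore[arg-type]
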