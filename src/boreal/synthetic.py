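"""Seeded synthetic landscapes, disturbance scenarios and demographic truth.

Everything downstream (disturbance summaries, RSF projection, demography,
population simulation) is exercisable on these fixtures with no external
data.  Land cover is generated as spatially autocorrelated patches by
thresholding a Gaussian-smoothed noise field at the quantiles that yield
the requested class proportions; fires are random disc polygons with ages
drawn uniformly over a configurable window; scenarios are nested feature
sets (base ⊆ roads-only ⊆ roads-and-mines) whose buffered footprints can
be calibrated by bisection to hit target percent-disturbed values.

These landscapes make no ecological-realism claims (no hydrology, no
succession); they exist so the computational chain is testable end to end
and so study-like conditions — sparse linear features, clustered mining
claims, a few percent of recent fire — can be dialed in deterministically
from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box

from .grids import (
    Feature,
    FeatureSet,
    RangePolygon,
    RasterGrid,
    area_fraction,
    buffer_features,
    grid_for_range,
    rasterize,
)

DEFAULT_LANDCOVER = (
    ("conifer", 0.45),
    ("peatland", 0.35),
    ("mixedwood", 0.15),
    ("water", 0.05),
)


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for one synthetic landscape.

    extent_km is (width, height); class proportions must sum to 1.
    ``correlation_length_m`` sets the patch scale of the smoothed-noise
    land-cover field.
    """

    extent_km: tuple[float, float] = (40.0, 40.0)
    resolution_m: float = 250.0
    landcover_classes: tuple[tuple[str, float], ...] = DEFAULT_LANDCOVER
    fire_fraction: float = 0.04
    fire_age_range: tuple[int, int] = (0, 40)
    correlation_length_m: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_km
        if w <= 0 or h <= 0 or self.resolution_m <= 0:
            raise ValueError("extent and resolution must be positive")
        total = sum(p for _, p in self.landcover_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if not 0.0 <= self.fire_fraction <= 1.0:
            raise ValueError("fire_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """One land-use scenario: total road length plus a mined-area fraction.

    Scenario feature sets nest: the roads-only scenario contains every
    base feature, and roads-and-mines contains every roads-only feature.
    """

    name: str
    road_total_length_km: float = 0.0
    mine_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.road_total_length_km < 0:
            raise ValueError("road_total_length_km must be >= 0")
        if not 0.0 <= self.mine_fraction <= 1.0:
            raise ValueError("mine_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LandscapeStack:
    """Co-registered landscape layers: land cover, fires, range boundary."""

    landcover: RasterGrid          # integer class codes
    class_names: tuple[str, ...]
    fires: FeatureSet
    range_poly: RangePolygon

    @property
    def crs(self) -> str:
        return self.landcover.crs


def generate_landscape(spec: LandscapeSpec) -> LandscapeStack:
    """Build a seeded landscape: autocorrelated land cover, disc fires, range.

    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    width_m = spec.extent_km[0] * 1000.0
    height_m = spec.extent_km[1] * 1000.0
    ncols = int(round(width_m / spec.resolution_m))
    nrows = int(round(height_m / spec.resolution_m))
    if ncols < 1 or nrows < 1:
        raise ValueError("extent smaller than one cell")

    # autocorrelated field -> classify at target-proportion quantiles
    noise = rng.standard_normal((nrows, ncols))
    sigma = spec.correlation_length_m / spec.resolution_m
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    names = tuple(name for name, _ in spec.landcover_classes)
    props = np.array([p for _, p in spec.landcover_classes])
    if len(names) == 1:
        codes = np.zeros((nrows, ncols), dtype=np.int16)
    else:
        cuts = np.quantile(smooth, np.cumsum(props)[:-1])
        codes = np.searchsorted(cuts, smooth, side="right").astype(np.int16)

    landcover = RasterGrid(
        codes, resolution=spec.resolution_m, origin=(0.0, height_m)
    )

    # range polygon: an irregular blob inset from the extent so that edge
    # cells exist outside the range (a real range never fills its raster)
    cx, cy = width_m / 2.0, height_m / 2.0
    angles = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    base_r = 0.42 * min(width_m, height_m)
    radii = base_r * (1.0 + 0.12 * rng.uniform(-1.0, 1.0, size=angles.size))
    ring = [(cx + r * np.cos(a), cy + r * np.sin(a)) for a, r in zip(angles, radii)]
    range_poly = RangePolygon(Polygon(ring), name="synthetic-range")

    fires = _generate_fires(spec, rng, landscape_grid=landcover, range_poly=range_poly)
    return LandscapeStack(landcover, names, fires, range_poly)


def _generate_fires(
    spec: LandscapeSpec,
    rng: np.random.Generator,
    landscape_grid: RasterGrid,
    range_poly: RangePolygon,
) -> FeatureSet:
    """Disc-shaped burns until the rasterized in-range fraction reaches target."""
    if spec.fire_fraction == 0:
        return FeatureSet((), crs=landscape_grid.crs)
    target = 100.0 * spec.fire_fraction
    minx, miny, maxx, maxy = range_poly.boundary.bounds
    mean_r = 5.0 * spec.resolution_m
    feats: list[Feature] = []
    grid = landscape_grid.with_values(np.zeros(landscape_grid.shape, dtype=bool))
    lo_age, hi_age = spec.fire_age_range

    def measure(fts: list[Feature]) -> float:
        burned = rasterize(FeatureSet(tuple(fts), crs=grid.crs), grid)
        return area_fraction(burned, range_poly)

    last = None
    for _ in range(500):  # hard cap; typical targets need far fewer discs
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        r = rng.uniform(0.5 * mean_r, 1.5 * mean_r)
        year_offset = int(rng.integers(lo_age, hi_age + 1))
        last = (x, y, r, -year_offset)
        feats.append(Feature(Point(x, y).buffer(r, quad_segs=8), "fire", year=last[3]))
        if measure(feats) >= target:
            break
    # the final disc overshoots by up to its own footprint; bisect its
    # radius so the realized fraction lands close to the target
    if last is not None and len(feats) > 0:
        x, y, r_hi, year = last
        base = feats[:-1]
        r_lo = 0.0
        for _ in range(12):
            r_mid = (r_lo + r_hi) / 2.0
            trial = base + [Feature(Point(x, y).buffer(max(r_mid, 1e-6), quad_segs=8), "fire", year=year)]
            got = measure(trial)
            if abs(got - target) < 0.1:
                feats = trial
                break
            if got < target:
                r_lo = r_mid
            else:
                r_hi = r_mid
        else:
            feats = base + [Feature(Point(x, y).buffer(max((r_lo + r_hi) / 2, 1e-6), quad_segs=8), "fire", year=year)]
    return FeatureSet(tuple(feats), crs=grid.crs)


def _road_path(
    range_poly: RangePolygon, rng: np.random.Generator, n_vertices: int = 8
) -> np.ndarray:
    """A wiggly corridor crossing the range west to east, unit-parameterized."""
    minx, miny, maxx, maxy = range_poly.boundary.bounds
    xs = np.linspace(minx, maxx, n_vertices)
    mid = (miny + maxy) / 2.0
    amp = 0.15 * (maxy - miny)
    ys = mid + amp * rng.uniform(-1.0, 1.0, size=n_vertices)
    return np.column_stack([xs, ys])


def generate_scenarios(
    landscape: LandscapeStack, specs: Sequence[ScenarioSpec]
) -> list[FeatureSet]:
    """Build nested scenario feature sets from road/mine intensity specs.

    Specs must be ordered by non-decreasing intensity; each scenario's
    features are a superset of the previous one's, so buffered disturbance
    fractions are monotone by construction.  Roads are connected polylines
    crossing the range; mines are square claims clustered along the roads.
    """
    crs = landscape.crs
    prev_road = -1.0
    prev_mine = -1.0
    for s in specs:
        if s.road_total_length_km < prev_road or s.mine_fraction < prev_mine:
            raise ValueError("scenario specs must be nested (non-decreasing intensity)")
        prev_road, prev_mine = s.road_total_length_km, s.mine_fraction
    range_area = landscape.range_poly.boundary.area
    max_mine = max(s.mine_fraction for s in specs) if specs else 0.0
    if max_mine > 0.8:
        raise ValueError(f"mine_fraction {max_mine} cannot fit in the range")

    out: list[FeatureSet] = []
    for s in specs:
        rng = np.random.default_rng(s.seed)  # layout shared across nesting levels
        feats: list[Feature] = []
        path = _road_path(landscape.range_poly, rng)
        if s.road_total_length_km > 0:
            feats.extend(_roads_of_length(path, s.road_total_length_km * 1000.0, rng))
        if s.mine_fraction > 0:
            feats.extend(
                _mines_of_area(path, s.mine_fraction * range_area, rng)
            )
        out.append(FeatureSet(tuple(feats), crs=crs))
    return out


def _roads_of_length(
    path: np.ndarray, total_m: float, rng: np.random.Generator
) -> list[Feature]:
    """Main corridor trimmed/extended with parallel spurs to hit total length."""
    main = LineString(path)
    feats: list[Feature] = []
    if total_m <= main.length:
        frac = total_m / main.length
        # keep the central portion so the road still crosses the range core
        start = (1.0 - frac) / 2.0
        pts = [
            main.interpolate((start + frac * t), normalized=True)
            for t in np.linspace(0.0, 1.0, path.shape[0] * 4)
        ]
        feats.append(Feature(LineString(pts), "road"))
        return feats
    feats.append(Feature(main, "road"))
    remaining = total_m - main.length
    i = 0
    while remaining > 1.0 and i < 50:
        i += 1
        dy = 2000.0 * i * (1 if i % 2 else -1)
        spur = LineString(path + np.array([0.0, dy]))
        if spur.length >= remaining:
            frac = remaining / spur.length
            start = (1.0 - frac) / 2.0  # central sub-segment of length `remaining`
            pts = [
                spur.interpolate(start + frac * t, normalized=True)
                for t in np.linspace(0.0, 1.0, 40)
            ]
            feats.append(Feature(LineString(pts), "road"))
            remaining = 0.0
        else:
            feats.append(Feature(spur, "road"))
            remaining -= spur.length
    return feats


def _mines_of_area(
    path: np.ndarray, total_area_m2: float, rng: np.random.Generator
) -> list[Feature]:
    """Square claims centred on road vertices, grown until area target met."""
    centers = path[1:-1] if path.shape[0] > 2 else path
    n = centers.shape[0]
    per_claim = total_area_m2 / n
    half = np.sqrt(per_claim) / 2.0
    feats = []
    for cx, cy in centers:
        jitter = rng.uniform(-half, half, size=2) * 0.3
        feats.append(
            Feature(
                box(cx - half + jitter[0], cy - half + jitter[1],
                    cx + half + jitter[0], cy + half + jitter[1]),
                "mine",
            )
        )
    return feats


def calibrate_scenarios(
    landscape: LandscapeStack,
    target_pct_anthro: Sequence[float],
    buffer_width: float = 500.0,
    tol_pct: float = 0.5,
    seed: int = 0,
    max_iter: int = 40,
) -> tuple[list[ScenarioSpec], list[FeatureSet]]:
    """Find nested scenario specs whose buffered footprints hit target percents.

    The first target is met with roads alone if possible; later targets add
    mine area on top of the previous scenario's roads.  Bisection on road
    length / mine fraction; tolerance ``tol_pct`` percentage points.
    """
    grid = grid_for_range(landscape.range_poly, landscape.landcover.resolution)

    def measure(spec: ScenarioSpec) -> float:
        fs = generate_scenarios(landscape, [spec])[0]
        buffered = buffer_features(fs, buffer_width)
        return area_fraction(rasterize(buffered, grid), landscape.range_poly)

    specs: list[ScenarioSpec] = []
    feature_sets: list[FeatureSet] = []
    prev_road = 0.0
    prev_mine = 0.0
    names = [f"scenario_{i}" for i in range(len(target_pct_anthro))]
    for name, target in zip(names, target_pct_anthro):
        if target <= 0:
            spec = ScenarioSpec(name, prev_road, prev_mine, seed=seed)
        elif not specs or target <= 3.0:
            # small targets: roads only (linear features buffered)
            lo, hi = prev_road, prev_road + 400.0
            spec = None
            for _ in range(max_iter):
                mid = (lo + hi) / 2.0
                cand = ScenarioSpec(name, mid, prev_mine, seed=seed)
                got = measure(cand)
                if abs(got - target) <= tol_pct:
                    spec = cand
                    break
                if got < target:
                    lo = mid
                else:
                    hi = mid
            if spec is None:
                spec = ScenarioSpec(name, (lo + hi) / 2.0, prev_mine, seed=seed)
        else:
            # large targets: add polygonal claims on top of existing roads
            lo, hi = prev_mine, 0.75
            spec = None
            for _ in range(max_iter):
                mid = (lo + hi) / 2.0
                cand = ScenarioSpec(name, prev_road, mid, seed=seed)
                got = measure(cand)
                if abs(got - target) <= tol_pct:
                    spec = cand
                    break
                if got < target:
                    lo = mid
                else:
                    hi = mid
            if spec is None:
                spec = ScenarioSpec(name, prev_road, (lo + hi) / 2.0, seed=seed)
        specs.append(spec)
        feature_sets.append(generate_scenarios(landscape, [spec])[0])
        prev_road = spec.road_total_length_km
        prev_mine = spec.mine_fraction
    return specs, feature_sets


def generate_demographic_truth(
    model,
    covariates,
    n_pops: int,
    years: int,
    seed: int,
    interannual_precision: float = 200.0,
):
    """Draw synthetic survival/recruitment observations from the demographic
    generative model at known covariates, returning (records, truth).

    Each population gets a persistent beta quantile; each population-year
    draws annual rates around the population mean with the given
    interannual precision.  Supports parameter-recovery and Monte-Carlo
    tests of the demography machinery.
    """
    from . import demography as dm

    if n_pops < 1 or years < 1:
        raise ValueError("n_pops and years must be >= 1")
    exp = dm.expected_rates(model, covariates)
    quantiles = dm.sample_population_quantiles(n_pops, seed=seed, stratified=False)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE]))
    records = []
    for pq in quantiles:
        S_pop, R_pop = dm.rates_at_quantile(model, covariates, pq)
        for t in range(years):
            S_t = dm.beta_draw(S_pop, interannual_precision, rng)
            R_t = dm.beta_draw(R_pop, interannual_precision, rng)
            records.append(
                {
                    "population_id": pq.population_id,
                    "year": t,
                    "survival": S_t,
                    "recruitment": R_t,
                }
            )
    truth = {
        "S_bar": exp.S_bar,
        "R_bar": exp.R_bar,
        "lambda_bar": exp.lambda_bar,
        "quantiles": quantiles,
    }
    return records, truth
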