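"""Range-level disturbance summaries for land-use scenarios.

For one range and one scenario the summary holds four percentages of the
range's area:

* ``pct_anthro`` — anthropogenic features (roads, mines, other human
  footprint) buffered by 500 m;
* ``pct_fire`` — area burned within the last 40 years, *not* buffered
  (only the anthropogenic footprint gets the buffer);
* ``pct_total`` — the union of the two;
* ``pct_fire_excl_anthro`` — burned area lying outside the buffered
  anthropogenic footprint.

By set algebra the union satisfies
``pct_total = pct_anthro + pct_fire_excl_anthro`` exactly; the summary is
computed from cell masks so the identity holds to machine precision.
Buffering happens in vector space before rasterization, so the footprint
does not depend on how a road is split into segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import (
    FeatureSet,
    RangePolygon,
    RasterGrid,
    area_fraction,
    buffer_features,
    grid_for_range,
    rasterize,
)

DEFAULT_BUFFER_M = 500.0
DEFAULT_FIRE_HORIZON_Y = 40


@dataclass(frozen=True)
class DisturbanceSummary:
    pct_anthro: float
    pct_fire: float
    pct_total: float
    pct_fire_excl_anthro: float

    def __post_init__(self) -> None:
        for name in ("pct_anthro", "pct_fire", "pct_total", "pct_fire_excl_anthro"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.pct_total > self.pct_anthro + self.pct_fire + 1e-9:
            raise ValueError("union cannot exceed sum of parts")
        if self.pct_fire_excl_anthro > self.pct_fire + 1e-9:
            raise ValueError("fire outside the footprint cannot exceed all fire")


def summarize_disturbance(
    anthro: FeatureSet,
    fire: FeatureSet,
    range_poly: RangePolygon,
    buffer_width: float = DEFAULT_BUFFER_M,
    fire_horizon: int = DEFAULT_FIRE_HORIZON_Y,
    reference_year: int = 0,
    grid: RasterGrid | None = None,
) -> DisturbanceSummary:
    """Compute the four disturbance percentages for one scenario × range.

    Fire features older than ``fire_horizon`` years at ``reference_year``
    are dropped; remaining burns are rasterized unbuffered.  Anthropogenic
    features are buffered by ``buffer_width`` metres before rasterization.
    """
    if grid is None:
        grid = grid_for_range(range_poly)
    recent = []
    for f in fire:
        if f.year is None:
            raise ValueError("fire features must carry a year")
        if reference_year - f.year <= fire_horizon:
            recent.append(f)
    fire_recent = FeatureSet(tuple(recent), crs=fire.crs)

    anthro_mask = rasterize(buffer_features(anthro, buffer_width), grid).values
    fire_mask = rasterize(fire_recent, grid).values

    base = grid.with_values(anthro_mask)
    pct_anthro = area_fraction(base, range_poly)
    pct_fire = area_fraction(grid.with_values(fire_mask), range_poly)
    pct_total = area_fraction(grid.with_values(anthro_mask | fire_mask), range_poly)
    pct_fire_excl = area_fraction(
        grid.with_values(fire_mask & ~anthro_mask), range_poly
    )
    return DisturbanceSummary(
        pct_anthro=pct_anthro,
        pct_fire=pct_fire,
        pct_total=pct_total,
        pct_fire_excl_anthro=pct_fire_excl,
    )


def scenario_table(
    scenarios: Sequence[tuple[str, FeatureSet]],
    fire: FeatureSet,
    range_poly: RangePolygon,
    buffer_width: float = DEFAULT_BUFFER_M,
    fire_horizon: int = DEFAULT_FIRE_HORIZON_Y,
    reference_year: int = 0,
    grid: RasterGrid | None = None,
) -> pd.DataFrame:
    """One DisturbanceSummary row per scenario, identical fire inputs.

    Columns: scenario, pct_anthro, pct_fire, pct_total, pct_fire_excl_anthro.
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    labels = [label for label, _ in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scenario labels: {labels}")
    if grid is None:
        grid = grid_for_range(range_poly)
    rows = []
    for label, fs in scenarios:
        s = summarize_disturbance(
            fs, fire, range_poly,
            buffer_width=buffer_width,
            fire_horizon=fire_horizon,
            reference_year=reference_year,
            grid=grid,
        )
        rows.append(
            {
                "scenario": label,
                "pct_anthro": s.pct_anthro,
                "pct_fire": s.pct_fire,
                "pct_total": s.pct_total,
                "pct_fire_excl_anthro": s.pct_fire_excl_anthro,
            }
        )
    return pd.DataFrame(rows)


def write_scenario_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Emit the scenario table with percentages rounded to 2 decimals."""
    out = table.copy()
    for col in out.columns:
        if col.startswith("pct_"):
            out[col] = out[col].round(2)
    out.to_csv(path, index=False)
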