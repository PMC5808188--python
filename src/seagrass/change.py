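"""Interannual habitat dynamics: areas, percent change, trends, change maps.

Per-class areas are pixel counts scaled to hectares; percent change uses the
earlier epoch as baseline denominator; trend slopes come from an OLS of area
against calendar year (years may be unevenly spaced); and per-pixel change
maps code gain / no-change / loss / absent for one target class between two
dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import NODATA_LABEL, HabitatMap, require_same_grid

__all__ = [
    "ChangeCode",
    "ChangeMap",
    "TrendResult",
    "class_area",
    "area_series",
    "percent_change",
    "area_trend",
    "change_map",
    "transition_matrix",
]


class ChangeCode(IntEnum):
    """Per-pixel change codes; the five codes partition every pixel."""

    MASKED = 0
    GAIN = 1
    NO_CHANGE_PRESENT = 2
    LOSS = 3
    ABSENT_BOTH = 4


@dataclass
class ChangeMap:
    """Gain / no-change / loss map for one class between two epochs."""

    codes: np.ndarray
    target_class: int
    grid: object
    year_start: int | None = None
    year_end: int | None = None

    def counts(self) -> dict[str, int]:
        return {
            code.name.lower(): int(np.count_nonzero(self.codes == code))
            for code in ChangeCode
        }


@dataclass(frozen=True)
class TrendResult:
    slope_ha_per_yr: float
    intercept_ha: float
    r_squared: float


def class_area(habitat: HabitatMap) -> dict[int, float]:
    """Per-class area in hectares: pixel count x pixel_size^2 / 10^4.

    Masked (nodata) pixels are excluded and do not appear in the result.
    """
    per_px = habitat.grid.pixel_area_ha
    return {c: n * per_px for c, n in habitat.class_counts().items()}


def area_series(maps: dict[int, HabitatMap]) -> pd.DataFrame:
    """Tidy (class, year, area_ha) table for a year-keyed map collection."""
    rows = []
    for year in sorted(maps):
        for c, a in class_area(maps[year]).items():
            rows.append({"class": c, "year": year, "area_ha": a})
    return pd.DataFrame(rows)


def percent_change(area_start: float, area_end: float) -> float:
    """Signed percent change relative to the starting (baseline) area."""
    if area_start <= 0:
        raise ValueError("baseline area must be positive")
    return 100.0 * (area_end - area_start) / area_start


def area_trend(years, areas_ha) -> TrendResult:
    """OLS slope of area (ha) against calendar year; needs >= 2 distinct years."""
    years = np.asarray(years, dtype=float)
    areas = np.asarray(areas_ha, dtype=float)
    if years.shape != areas.shape:
        raise ValueError("years and areas must have equal length")
    if np.unique(years).size < 2:
        raise ValueError("need at least 2 distinct years")
    res = stats.linregress(years, areas)
    r2 = float(res.rvalue**2) if np.ptp(areas) > 0 else 1.0
    return TrendResult(
        slope_ha_per_yr=float(res.slope), intercept_ha=float(res.intercept), r_squared=r2
    )


def change_map(
    map_t0: HabitatMap,
    map_t1: HabitatMap,
    target_class: int,
    year_start: int | None = None,
    year_end: int | None = None,
) -> ChangeMap:
    """Per-pixel gain / no-change / loss of ``target_class`` between epochs.

    A pixel masked (nodata) in either epoch is coded MASKED; otherwise gain
    is absent-to-present, loss present-to-absent, and the remaining pixels
    split into present-in-both and absent-in-both.
    """
    grid = require_same_grid(map_t0, map_t1)
    if target_class not in map_t0.class_table:
        raise ValueError(f"unknown target class {target_class}")
    masked = (map_t0.labels == NODATA_LABEL) | (map_t1.labels == NODATA_LABEL)
    p0 = map_t0.labels == target_class
    p1 = map_t1.labels == target_class
    codes = np.full(grid.shape, ChangeCode.ABSENT_BOTH, dtype=np.uint8)
    codes[~p0 & p1] = ChangeCode.GAIN
    codes[p0 & p1] = ChangeCode.NO_CHANGE_PRESENT
    codes[p0 & ~p1] = ChangeCode.LOSS
    codes[masked] = ChangeCode.MASKED
    return ChangeMap(
        codes=codes,
        target_class=target_class,
        grid=grid,
        year_start=year_start,
        year_end=year_end,
    )


def transition_matrix(map_t0: HabitatMap, map_t1: HabitatMap) -> pd.DataFrame:
    """Cross-class pixel-count transitions between two epochs (rows = from,
    columns = to); pixels masked in either epoch are excluded."""
    require_same_grid(map_t0, map_t1)
    classes = sorted(map_t0.class_table)
    ok = (map_t0.labels != NODATA_LABEL) & (map_t1.labels != NODATA_LABEL)
    a = map_t0.labels[ok].astype(int)
    b = map_t1.labels[ok].astype(int)
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (np.vectorize(pos.get)(a), np.vectorize(pos.get)(b)), 1)
    names = [map_t0.class_table[c] for c in classes]
    return pd.DataFrame(counts, index=names, columns=names)
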