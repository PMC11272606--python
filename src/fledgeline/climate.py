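"""Temperature threshold exceedance-day climatology on a gridded product.

For each grid cell and year, the exceedance day is the first day of year in
a spring/early-summer search window on which the daily mean temperature
strictly exceeds a threshold.  Cells are grouped into two elevational bands
(default centres 1500 m and 2200 m, +/-100 m); the band statistic is the
median exceedance day over cells, the yearly comparison is the high-band
minus low-band difference, and the headline figure per threshold is the
median of those yearly differences, with an OLS trend per decade as a
climate-change check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Default day-of-year search window: 1 Jan - 31 Jul ("spring or early
#: summer").  A January warm spell can therefore register for low
#: thresholds; that is deliberate, documented behaviour.
DEFAULT_WINDOW = (1, 212)

#: Default threshold sweep, degrees C.
DEFAULT_THRESHOLDS = tuple(range(-5, 16))

GRID_COLUMNS = ("cell_id", "elevation_m", "year", "doy", "tmean_c")


@dataclass
class ExceedanceResult:
    """Per-threshold elevational comparison of exceedance days."""

    threshold: float
    yearly_difference: dict[int, float] = field(default_factory=dict)
    median_difference: float = np.nan
    trend_per_decade: float = np.nan
    n_years_used: int = 0
    n_years_dropped: int = 0


def read_temperature_grid(path) -> pd.DataFrame:
    """Read a long-format grid CSV (cell_id, elevation_m, date, tmean_c)."""
    df = pd.read_csv(path)
    missing = [c for c in ("cell_id", "elevation_m", "date", "tmean_c") if c not in df.columns]
    if missing:
        raise ValueError(f"temperature grid missing columns: {missing}")
    dates = pd.to_datetime(df["date"], format="ISO8601")
    df = df.assign(year=dates.dt.year.astype(int), doy=dates.dt.dayofyear.astype(int))
    return df[list(GRID_COLUMNS)]


def write_temperature_grid(grid: pd.DataFrame, path) -> None:
    """Write a grid table back to the long-format CSV schema."""
    out = grid.copy()
    base = pd.to_datetime(out["year"].astype(str)) + pd.to_timedelta(out["doy"] - 1, unit="D")
    out["date"] = base.dt.strftime("%Y-%m-%d")
    out[["cell_id", "elevation_m", "date", "tmean_c"]].to_csv(path, index=False)


def exceedance_day(
    doy: np.ndarray,
    tmean: np.ndarray,
    threshold: float,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> float:
    """First day of year on which ``tmean`` strictly exceeds ``threshold``.

    ``doy``/``tmean`` are one cell-year of daily values.  The scan is
    restricted to the closed ``window``; NaN when the threshold is never
    exceeded there.  Equality is not an exceedance.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty search window {window}")
    doy = np.asarray(doy)
    tmean = np.asarray(tmean, dtype=float)
    in_win = (doy >= lo) & (doy <= hi)
    if not in_win.any():
        raise ValueError(f"window {window} outside the series' doy range")
    d, t = doy[in_win], tmean[in_win]
    order = np.argsort(d)
    d, t = d[order], t[order]
    hits = np.nonzero(t > threshold)[0]
    return float(d[hits[0]]) if hits.size else np.nan


def band_cells(grid: pd.DataFrame, band_center: float, halfwidth: float = 100.0) -> list:
    """Cell ids whose elevation lies within +/-halfwidth of the centre."""
    cells = (
        grid.drop_duplicates("cell_id")
        .loc[lambda d: (d["elevation_m"] - band_center).abs() <= halfwidth, "cell_id"]
        .tolist()
    )
    return cells


def band_median_day(
    grid: pd.DataFrame,
    year: int,
    threshold: float,
    band_center: float,
    halfwidth: float = 100.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    max_missing_frac: float = 0.5,
) -> float:
    """Median exceedance day over the band's cells for one year.

    Cells where the threshold is never exceeded are excluded; when more
    than ``max_missing_frac`` of the band's cells are missing the band
    median itself is NaN for that year/threshold (logged).  The median of
    an even number of values is the mean of the two central ones.
    """
    cells = band_cells(grid, band_center, halfwidth)
    if not cells:
        raise ValueError(f"no grid cells in band {band_center}+/-{halfwidth} m")
    sub = grid[(grid["cell_id"].isin(cells)) & (grid["year"] == year)]
    days = []
    n_missing = 0
    for _, cell_df in sub.groupby("cell_id"):
        day = exceedance_day(
            cell_df["doy"].to_numpy(), cell_df["tmean_c"].to_numpy(), threshold, window
        )
        if np.isnan(day):
            n_missing += 1
        else:
            days.append(day)
    n_total = len(days) + n_missing
    if n_total == 0 or n_missing > max_missing_frac * n_total:
        if n_total:
            logger.info(
                "band %s m, year %d, threshold %s: %d/%d cells missing -> band median undefined",
                band_center, year, threshold, n_missing, n_total,
            )
        return np.nan
    return float(np.median(days))


def trend_per_decade(yearly_difference: dict[int, float]) -> float:
    """OLS slope of the yearly band difference on year, in days/decade.

    NaN with fewer than 3 usable years.
    """
    years = np.array(sorted(y for y, v in yearly_difference.items() if np.isfinite(v)))
    if years.size < 3:
        return np.nan
    vals = np.array([yearly_difference[int(y)] for y in years], dtype=float)
    slope = stats.linregress(years.astype(float), vals).slope
    return float(slope * 10.0)


def median_band_difference(
    grid: pd.DataFrame,
    years,
    threshold: float,
    low_center: float = 1500.0,
    high_center: float = 2200.0,
    halfwidth: float = 100.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> ExceedanceResult:
    """High-band minus low-band exceedance-day difference per year, summarized.

    The headline value is the median of the yearly differences over all
    years where both band medians are defined; years lacking either are
    dropped and counted.
    """
    result = ExceedanceResult(threshold=threshold)
    for year in years:
        low = band_median_day(grid, year, threshold, low_center, halfwidth, window)
        high = band_median_day(grid, year, threshold, high_center, halfwidth, window)
        result.yearly_difference[int(year)] = float(high - low)
    usable = [v for v in result.yearly_difference.values() if np.isfinite(v)]
    result.n_years_used = len(usable)
    result.n_years_dropped = len(result.yearly_difference) - len(usable)
    if not usable:
        raise ValueError(
            f"no year has both band medians defined for threshold {threshold} C"
        )
    result.median_difference = float(np.median(usable))
    result.trend_per_decade = trend_per_decade(result.yearly_difference)
    return result


def exceedance_profile(
    grid: pd.DataFrame,
    years,
    thresholds=DEFAULT_THRESHOLDS,
    low_center: float = 1500.0,
    high_center: float = 2200.0,
    halfwidth: float = 100.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, list[ExceedanceResult]]:
    """Sweep thresholds (-5..+15 C by default) and tabulate the comparison.

    Thresholds never exceeded in one band are flagged (NaN row), never
    fabricated; the others are still produced.
    """
    results: list[ExceedanceResult] = []
    rows = []
    for thr in thresholds:
        try:
            res = median_band_difference(
                grid, years, thr, low_center, high_center, halfwidth, window
            )
        except ValueError as err:
            logger.warning("threshold %s C skipped: %s", thr, err)
            res = ExceedanceResult(threshold=thr, n_years_used=0)
        results.append(res)
        rows.append(
            {
                "threshold_c": float(thr),
                "median_difference_days": res.median_difference,
                "trend_days_per_decade": res.trend_per_decade,
                "n_years": res.n_years_used,
                "n_years_dropped": res.n_years_dropped,
            }
        )
    return pd.DataFrame(rows), results


def yearly_table(results: list[ExceedanceResult]) -> pd.DataFrame:
    """Long-format per-year differences for all thresholds."""
    rows = [
        {"threshold_c": res.threshold, "year": yr, "difference_days": val}
        for res in results
        for yr, val in sorted(res.yearly_difference.items())
    ]
    return pd.DataFrame(rows)
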