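"""Seasonal climate variables and their spatial/temporal decomposition.

Four variables summarize climatic harshness on each transect in each analysis
year: spring onset (first day of year with a trailing 7-day mean snow depth of
zero), mean spring temperature (March–May), winter onset (first day with a
trailing 7-day mean snow depth above zero, scanned July–June so autumn onsets
sort monotonically across the calendar boundary) and mean winter temperature
(December of the previous calendar year plus January–February).

Each variable is split into a spatial harshness gradient CS (per-transect mean
over the analysis years) and temporal anomalies CT (yearly deviations from
CS), and both are centred and scaled to one standard deviation before entering
the growth model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .data_model import DailyClimateRecord

__all__ = [
    "CLIMATE_VARIABLES",
    "CovariateTable",
    "rolling_mean",
    "spring_onset",
    "winter_onset",
    "seasonal_mean_temp",
    "split_spatial_temporal",
    "standardize",
    "orient_harshness",
    "derive_climate_variables",
    "build_covariate_table",
]

CLIMATE_VARIABLES = ("spring_onset", "spring_temp", "winter_onset", "winter_temp")

#: snow depths below this (cm) count as bare ground
SNOW_TOL = 1e-9


@dataclass
class CovariateTable:
    """Standardized covariates for the growth model.

    ``cs`` is indexed by transect, ``ct`` and ``harvest`` by (transect, year).
    ``scalers`` stores the (mean, sd) pairs used for standardization so effects
    can be back-transformed to natural units.
    """

    variable: str
    cs: pd.Series
    ct: pd.Series
    harvest: Optional[pd.Series] = None
    scalers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, col in (("cs", self.cs), ("ct", self.ct)):
            vals = np.asarray(col, dtype=float)
            if abs(vals.mean()) > 1e-10 or abs(vals.std(ddof=1) - 1.0) > 1e-10:
                raise ValueError(f"{name} is not standardized")


def rolling_mean(series, window: int = 7) -> np.ndarray:
    """Trailing moving average; positions before the first full window are NaN."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size < window:
        raise ValueError(f"series length {x.size} shorter than window {window}")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(x.size, np.nan)
    out[window - 1:] = (csum[window:] - csum[:-window]) / window
    return out


def _first_window_day(snow, window: int, above: bool, start_day: int) -> Optional[int]:
    means = rolling_mean(snow, window)
    with np.errstate(invalid="ignore"):
        hit = (means > SNOW_TOL) if above else (np.abs(means) <= SNOW_TOL)
    hit &= ~np.isnan(means)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    return start_day + int(idx[0])


def spring_onset(snow, window: int = 7, start_day: int = 1) -> Optional[int]:
    """First day whose trailing ``window``-day mean snow depth is zero.

    ``snow`` holds consecutive daily depths starting at calendar day
    ``start_day``; returns a day-of-year, or ``None`` if the snow never clears.
    """
    snow = np.asarray(snow, dtype=float)
    if np.isnan(snow).any():
        raise ValueError("snow series contains gaps")
    return _first_window_day(snow, window, above=False, start_day=start_day)


def winter_onset(snow, window: int = 7, start_day: int = 1) -> Optional[int]:
    """First day whose trailing ``window``-day mean snow depth is above zero.

    Intended to be applied to a July-through-June window so that onsets either
    side of New Year stay monotone; ``start_day`` then indexes days since the
    window start and the caller converts to calendar day-of-year for display.
    """
    snow = np.asarray(snow, dtype=float)
    if np.isnan(snow).any():
        raise ValueError("snow series contains gaps")
    return _first_window_day(snow, window, above=True, start_day=start_day)


_SEASON_MONTHS = {"spring": (3, 4, 5), "winter": (12, 1, 2)}


def seasonal_mean_temp(temps: pd.Series, season: str, year: int) -> float:
    """Mean daily temperature over MAM of ``year`` or DJF ending in ``year``.

    ``temps`` is indexed by date.  Winter uses December of the preceding
    calendar year so that the season precedes the August survey of ``year``.
    All season days must be present.
    """
    if season not in _SEASON_MONTHS:
        raise ValueError(f"season must be 'spring' or 'winter', got {season!r}")
    idx = pd.DatetimeIndex(temps.index)
    if season == "spring":
        mask = (idx.year == year) & idx.month.isin((3, 4, 5))
        expected = pd.date_range(f"{year}-03-01", f"{year}-05-31").size
    else:
        mask = ((idx.year == year - 1) & (idx.month == 12)) | (
            (idx.year == year) & idx.month.isin((1, 2))
        )
        expected = pd.date_range(f"{year - 1}-12-01", f"{year}-02-28").size
        # leap Februaries add a day
        if pd.Timestamp(f"{year}-01-01").is_leap_year:
            expected += 1
    sel = temps[mask]
    if sel.size < expected:
        raise ValueError(
            f"{season} {year}: {expected - sel.size} of {expected} season days missing"
        )
    return float(np.asarray(sel, dtype=float).mean())


def split_spatial_temporal(values: pd.DataFrame, years: Iterable[int]):
    """Split a transect × year table into its spatial mean and anomalies.

    Returns ``(cs_raw, ct_raw)`` where ``cs_raw[i]`` is the per-transect mean
    over ``years`` and ``ct_raw[i, t] = values[i, t] − cs_raw[i]``, so the
    anomalies of every transect sum to zero over the analysis window.
    """
    years = list(years)
    sub = values[years].astype(float)
    cs_raw = sub.mean(axis=1)
    ct_raw = sub.sub(cs_raw, axis=0)
    return cs_raw, ct_raw


def standardize(x) -> tuple[pd.Series, tuple[float, float]]:
    """Centre and scale to unit standard deviation (ddof=1).

    Returns the scaled values and the ``(mean, sd)`` pair used, for
    back-transformation.  A constant input has no scale and raises.
    """
    s = pd.Series(x, dtype=float)
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError("cannot standardize a constant (degenerate) covariate")
    return (s - mean) / sd, (mean, sd)


def orient_harshness(variable: str, values):
    """Apply the reporting-time sign convention for effect displays.

    Spring-onset effects are negated so that, for every variable, larger
    values mean more benign conditions (earlier springs, later and warmer
    winters/springs).  Model-time covariates are never passed through this.
    """
    if variable not in CLIMATE_VARIABLES:
        raise ValueError(f"unknown climate variable {variable!r}")
    arr = np.asarray(values, dtype=float)
    return -arr if variable == "spring_onset" else +arr


def derive_climate_variables(
    records: Iterable[DailyClimateRecord],
    years: Iterable[int],
    window: int = 7,
    max_gap_days: int = 0,
) -> dict[str, pd.DataFrame]:
    """Compute the four seasonal variables from daily series.

    Returns one transect × year DataFrame per variable.  Onsets are scanned
    within a July(t−1)–June(t) window per analysis year; winter onsets are
    reported as days since July 1 so that autumn dates sort monotonically.
    Gaps up to ``max_gap_days`` consecutive days are linearly interpolated;
    longer gaps raise.
    """
    years = list(years)
    df = pd.DataFrame(
        [(r.transect_id, pd.Timestamp(r.date), r.temp_c, r.snow_cm) for r in records],
        columns=["transect_id", "date", "temp_c", "snow_cm"],
    )
    out = {v: {} for v in CLIMATE_VARIABLES}
    for tid, g in df.groupby("transect_id", sort=True):
        g = g.set_index("date").sort_index()
        full = pd.date_range(g.index.min(), g.index.max())
        g = g.reindex(full)
        if g["temp_c"].isna().any():
            if max_gap_days <= 0:
                raise ValueError(f"transect {tid}: gaps in daily climate series")
            g = g.interpolate(limit=max_gap_days, limit_area="inside")
            if g["temp_c"].isna().any():
                raise ValueError(f"transect {tid}: gap longer than {max_gap_days} days")
        temps = g["temp_c"]
        for year in years:
            win = g.loc[f"{year - 1}-07-01": f"{year}-06-30"]
            snow = win["snow_cm"].to_numpy()
            out["winter_onset"][(tid, year)] = winter_onset(snow, window, start_day=1)
            spring_win = g.loc[f"{year}-01-01": f"{year}-06-30", "snow_cm"].to_numpy()
            out["spring_onset"][(tid, year)] = spring_onset(spring_win, window, start_day=1)
            out["spring_temp"][(tid, year)] = seasonal_mean_temp(temps, "spring", year)
            out["winter_temp"][(tid, year)] = seasonal_mean_temp(temps, "winter", year)
    tables = {}
    for var, d in out.items():
        s = pd.Series(d, dtype=float)
        s.index = pd.MultiIndex.from_tuples(s.index, names=["transect_id", "year"])
        tables[var] = s.unstack("year")
    return tables


def build_covariate_table(
    values: pd.DataFrame,
    years: Iterable[int],
    variable: str,
    harvest: Optional[pd.DataFrame] = None,
) -> CovariateTable:
    """Decompose one climate variable into standardized CS and CT columns."""
    if variable not in CLIMATE_VARIABLES:
        raise ValueError(f"unknown climate variable {variable!r}")
    years = list(years)
    cs_raw, ct_raw = split_spatial_temporal(values, years)
    cs, cs_scale = standardize(cs_raw)
    ct_flat = ct_raw.stack()
    ct, ct_scale = standardize(ct_flat)
    scalers = {"cs": cs_scale, "ct": ct_scale}
    harvest_s = None
    if harvest is not None:
        hflat = harvest[years].stack()
        harvest_s, h_scale = standardize(hflat)
        scalers["harvest"] = h_scale
    return CovariateTable(variable=variable, cs=cs, ct=ct, harvest=harvest_s, scalers=scalers)
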