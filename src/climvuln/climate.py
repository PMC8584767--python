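"""Extreme temperature and precipitation indices from daily weather series.

Implements the seven Climdex-style indicators used for homoclimatic zoning:

====== ==========================================================
TXx    block maximum of daily maximum temperature (degC)
TNx    block maximum of daily minimum temperature (degC)
TX90p  share of days with tmax above its calendar-day 90th
       percentile (%% of days, "warm days")
TN90p  same for tmin ("warm nights")
DTR    mean diurnal temperature range (degC)
CDD    longest run of consecutive dry days (< 1 mm)
R99p   mean annual precipitation total on extremely wet days
       (above the wet-day 99th percentile, mm)
====== ==========================================================

Each index reduces a multi-year daily series to one scalar per region:
TXx/TNx are means of annual block maxima, CDD and R99p means of annual
values, TX90p/TN90p percentages over all days of the record, and DTR the
mean of monthly means.  Percentile thresholds for the exceedance indices
are computed per calendar day from a centered window across all years of
the base period, with linear-interpolation empirical quantiles.

Input is a long-format table with columns ``region_id, date, tmax, tmin,
precip``; missing observations are NaN (empty fields in CSV), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateConfig",
    "read_daily_series",
    "validate_series",
    "block_maximum_index",
    "exceedance_percentage",
    "daily_temperature_range",
    "longest_dry_spell",
    "extreme_wet_total",
    "compute_extreme_indices",
    "categorize_quantiles",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ["txx", "tnx", "tx90p", "tn90p", "dtr", "cdd", "r99p"]


@dataclass(frozen=True)
class ClimateConfig:
    """Tunable conventions for the extreme indices.

    base_period
        (start, end) ISO dates bounding the percentile base period;
        ``None`` uses the full record (base period = analysis period).
    wet_threshold_mm
        a day is "wet" when precip >= this value (Climdex convention).
    percentile_window_days
        width of the centered calendar-day window for TX90p/TN90p
        thresholds (must be odd).
    missing_tolerance
        a month/year with a larger fraction of missing days for the
        relevant variable is excluded from aggregation.
    """

    base_period: tuple[str, str] | None = None
    wet_threshold_mm: float = 1.0
    percentile_window_days: int = 5
    missing_tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.percentile_window_days % 2 != 1:
            raise ValueError("percentile_window_days must be odd")
        if not 0 <= self.missing_tolerance < 1:
            raise ValueError("missing_tolerance must be in [0, 1)")


def read_daily_series(path) -> pd.DataFrame:
    """Read a long-format daily series CSV (empty field = missing)."""
    df = pd.read_csv(path, parse_dates=["date"])
    validate_series(df)
    return df


def read_gridded_series(path, region_mapping) -> pd.DataFrame:  # pragma: no cover
    """Placeholder for a gridded (NetCDF) reader mapping grid points to
    regions; only the long-format CSV path is currently supported."""
    raise NotImplementedError(
        "gridded input is not supported; supply a long-format CSV "
        "(region_id,date,tmax,tmin,precip) via read_daily_series"
    )


def validate_series(df: pd.DataFrame) -> None:
    required = {"region_id", "date", "tmax", "tmin", "precip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"daily series missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("daily series is empty")
    for _, grp in df.groupby("region_id", sort=False):
        d = pd.to_datetime(grp["date"])
        if not d.is_monotonic_increasing or d.duplicated().any():
            raise ValueError("dates must be strictly increasing per region")
    both = df["tmax"].notna() & df["tmin"].notna()
    if (df.loc[both, "tmax"] < df.loc[both, "tmin"]).any():
        raise ValueError("tmax < tmin encountered")
    if (df["precip"].dropna() < 0).any():
        raise ValueError("negative precipitation encountered")


def _one_region(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        raise ValueError("empty daily series")
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    return out


def _clip_base(df: pd.DataFrame, base_period: tuple[str, str] | None) -> pd.DataFrame:
    if base_period is None:
        return df
    start, end = pd.Timestamp(base_period[0]), pd.Timestamp(base_period[1])
    sub = df[(df["date"] >= start) & (df["date"] <= end)]
    if len(sub) == 0:
        raise ValueError("base period not contained in series")
    return sub


def block_maximum_index(
    df: pd.DataFrame,
    variable: str,
    block: str = "year",
    missing_tolerance: float = 0.2,
) -> float:
    """Mean over blocks (months or years) of the within-block maximum.

    Blocks with all values missing are skipped with a warning; blocks
    with more than ``missing_tolerance`` missing are excluded silently
    (they do not represent the block's true extreme).
    """
    df = _one_region(df)
    if variable not in ("tmax", "tmin"):
        raise ValueError("variable must be 'tmax' or 'tmin'")
    if block == "month":
        keys = df["date"].dt.to_period("M")
    elif block == "year":
        keys = df["date"].dt.year
    else:
        raise ValueError("block must be 'month' or 'year'")
    maxima = []
    for key, grp in df.groupby(keys):
        vals = grp[variable]
        if vals.notna().sum() == 0:
            warnings.warn(f"block {key}: all {variable} missing, skipped")
            continue
        if vals.isna().mean() > missing_tolerance:
            continue
        maxima.append(vals.max())
    if not maxima:
        raise ValueError(f"no usable block for {variable}")
    return float(np.mean(maxima))


def _calendar_doy(dates: pd.Series) -> np.ndarray:
    # nominal day-of-year on a fixed leap calendar, so 29 Feb aligns
    months = dates.dt.month.to_numpy()
    days = dates.dt.day.to_numpy()
    table = np.zeros((13, 32), dtype=int)
    for m in range(1, 13):
        for d in range(1, 32):
            try:
                table[m, d] = pd.Timestamp(2000, m, d).dayofyear
            except ValueError:
                table[m, d] = 0
    return table[months, days]


def calendar_day_thresholds(
    df: pd.DataFrame,
    variable: str,
    q: float = 90.0,
    base_period: tuple[str, str] | None = None,
    window_days: int = 5,
) -> dict[int, float]:
    """Per-calendar-day percentile thresholds from a centered window.

    For each nominal day-of-year the threshold is the q-th linear
    interpolation percentile of all base-period values whose calendar
    day falls within the centered window (circular across new year).
    """
    df = _one_region(df)
    base = _clip_base(df, base_period)
    span_days = (base["date"].max() - base["date"].min()).days + 1
    if span_days < 365:
        raise ValueError("base period must cover at least one full year")
    vals = base[variable].to_numpy(dtype=float)
    doy = _calendar_doy(base["date"])
    half = window_days // 2
    thresholds: dict[int, float] = {}
    for day in np.unique(doy):
        delta = np.abs(doy - day)
        delta = np.minimum(delta, 366 - delta)
        pool = vals[(delta <= half) & ~np.isnan(vals)]
        if pool.size:
            thresholds[int(day)] = float(np.percentile(pool, q))
    return thresholds


def exceedance_percentage(
    df: pd.DataFrame,
    variable: str,
    q: float = 90.0,
    base_period: tuple[str, str] | None = None,
    window_days: int = 5,
) -> float:
    """Percent of non-missing days strictly above the calendar-day q-th
    percentile (TX90p/TN90p definition; strict '>')."""
    df = _one_region(df)
    thr = calendar_day_thresholds(df, variable, q, base_period, window_days)
    doy = _calendar_doy(df["date"])
    vals = df[variable].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    thr_arr = np.array([thr.get(int(d), np.nan) for d in doy])
    exceed = ok & ~np.isnan(thr_arr) & (vals > thr_arr)
    n_obs = int(ok.sum())
    if n_obs == 0:
        raise ValueError(f"no non-missing {variable} observations")
    return 100.0 * float(exceed.sum()) / n_obs


def daily_temperature_range(df: pd.DataFrame, missing_tolerance: float = 0.2) -> float:
    """Mean over months of the monthly mean of (tmax - tmin)."""
    df = _one_region(df)
    diff = df["tmax"] - df["tmin"]
    monthly = []
    for key, grp in df.assign(_d=diff).groupby(df["date"].dt.to_period("M")):
        d = grp["_d"]
        if d.notna().sum() == 0:
            warnings.warn(f"month {key}: no paired tmax/tmin, skipped")
            continue
        if d.isna().mean() > missing_tolerance:
            continue
        monthly.append(d.mean())
    if not monthly:
        raise ValueError("no usable month for DTR")
    return float(np.mean(monthly))


def _max_run(dry: np.ndarray) -> int:
    best = cur = 0
    for flag in dry:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


def longest_dry_spell(
    df: pd.DataFrame,
    wet_threshold: float = 1.0,
    missing_tolerance: float = 0.2,
) -> float:
    """Mean over years of the longest run of days with precip < wet_threshold.

    Missing precipitation days terminate a run (a dry spell cannot be
    asserted across an unobserved day); years with more than
    ``missing_tolerance`` missing are excluded.
    """
    df = _one_region(df)
    annual = []
    for year, grp in df.groupby(df["date"].dt.year):
        p = grp["precip"].to_numpy(dtype=float)
        if np.isnan(p).all():
            warnings.warn(f"year {year}: all precip missing, skipped")
            continue
        if np.isnan(p).mean() > missing_tolerance:
            continue
        dry = ~np.isnan(p) & (p < wet_threshold)
        annual.append(_max_run(dry))
    if not annual:
        raise ValueError("no usable year for CDD")
    return float(np.mean(annual))


def extreme_wet_total(
    df: pd.DataFrame,
    q: float = 99.0,
    base_period: tuple[str, str] | None = None,
    wet_threshold: float = 1.0,
    region_id: str | None = None,
) -> float:
    """Mean annual precipitation total on days strictly above the
    wet-day q-th percentile of the base period (R99p)."""
    df = _one_region(df)
    base = _clip_base(df, base_period)
    wet = base.loc[base["precip"] >= wet_threshold, "precip"].dropna()
    if len(wet) == 0:
        who = f" in region {region_id}" if region_id is not None else ""
        raise ValueError(f"no wet day (>= {wet_threshold} mm) in base period{who}")
    threshold = float(np.percentile(wet.to_numpy(), q))
    totals = []
    for _, grp in df.groupby(df["date"].dt.year):
        p = grp["precip"].dropna()
        totals.append(float(p[p > threshold].sum()))
    return float(np.mean(totals))


def compute_extreme_indices(
    series: pd.DataFrame, config: ClimateConfig = ClimateConfig()
) -> pd.DataFrame:
    """All seven indices, one row per region.

    Returns columns ``region_id`` + txx, tnx, tx90p, tn90p, dtr, cdd, r99p.
    """
    validate_series(series)
    rows = []
    for region, grp in series.groupby("region_id", sort=True):
        grp = grp.reset_index(drop=True)
        rows.append(
            {
                "region_id": region,
                "txx": block_maximum_index(grp, "tmax", "year", config.missing_tolerance),
                "tnx": block_maximum_index(grp, "tmin", "year", config.missing_tolerance),
                "tx90p": exceedance_percentage(
                    grp, "tmax", 90.0, config.base_period, config.percentile_window_days
                ),
                "tn90p": exceedance_percentage(
                    grp, "tmin", 90.0, config.base_period, config.percentile_window_days
                ),
                "dtr": daily_temperature_range(grp, config.missing_tolerance),
                "cdd": longest_dry_spell(
                    grp, config.wet_threshold_mm, config.missing_tolerance
                ),
                "r99p": extreme_wet_total(
                    grp, 99.0, config.base_period, config.wet_threshold_mm, str(region)
                ),
            }
        )
    return pd.DataFrame(rows)


def categorize_quantiles(
    index_table: pd.DataFrame,
    n_categories: int = 5,
    items: list[str] | None = None,
) -> pd.DataFrame:
    """Code each index into cross-region quantile categories 1..L.

    Category bounds are the (100 j / L)-th linear-interpolation
    percentiles of the item's cross-region distribution; a region lands
    in category 1 + (number of bounds its value strictly exceeds).  If
    ties leave a category empty (and values are not all identical),
    categories are re-assigned by rank with a stable region_id
    tie-break, with a warning.  All-identical values yield category 1
    everywhere, with a warning.
    """
    items = items or [c for c in INDEX_COLUMNS if c in index_table.columns]
    tbl = index_table.sort_values("region_id", kind="stable").reset_index(drop=True)
    records = []
    for item in items:
        vals = tbl[item].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values in index {item}")
        n = len(vals)
        if np.all(vals == vals[0]):
            warnings.warn(f"item {item}: all regions identical, category 1 for all")
            cats = np.ones(n, dtype=int)
        else:
            bounds = np.percentile(
                vals, [100 * j / n_categories for j in range(1, n_categories)]
            )
            cats = 1 + (vals[:, None] > bounds[None, :]).sum(axis=1)
            if len(np.unique(cats)) < min(n_categories, n):
                warnings.warn(
                    f"item {item}: ties collapsed a category; rank tie-break used"
                )
                order = np.argsort(vals, kind="stable")  # stable on region_id order
                ranks = np.empty(n, dtype=int)
                ranks[order] = np.arange(1, n + 1)
                cats = np.ceil(ranks * n_categories / n).astype(int)
        for region, cat in zip(tbl["region_id"], cats):
            records.append({"region_id": region, "item_id": item, "category": int(cat)})
    return pd.DataFrame(records)
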