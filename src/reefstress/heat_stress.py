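"""Satellite-style heat-stress metrics for coral reef pixels.

Implements the NOAA Coral Reef Watch conventions for instantaneous and
accumulated marine heat stress on reefs:

* **HotSpot** — the instantaneous SST anomaly relative to the pixel's
  maximum-monthly-mean (MMM) climatology, in degrees C.
* **Degree Heating Week (DHW)** — accumulated heat stress over the trailing
  12 weeks (84 days), in degrees C-weeks.  Only days whose HotSpot is at
  least 1.0 degC contribute, each adding ``hotspot / 7`` to the sum.
* **Bleaching Alert Level** — ordinal severity category 0-5 keyed to DHW
  thresholds at 4, 8, 12, 16 and 20 degC-weeks.

Heat stress is summarized over *bleaching years*, the June 1 - May 31
periods that bracket each global pulse of heat stress, and over multi-year
bleaching events (e.g. the third global event, June 2014 - May 2017).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PixelSeries",
    "HeatStressSeries",
    "BleachingYear",
    "YearlyMax",
    "DHW_WINDOW_DAYS",
    "HOTSPOT_CUTOFF",
    "ALERT_THRESHOLDS",
    "EVENT_PERIODS",
    "compute_hotspot",
    "compute_dhw",
    "compute_heat_stress",
    "classify_alert",
    "bleaching_year_of",
    "bleaching_year_label",
    "list_bleaching_years",
    "yearly_max",
    "all_yearly_maxima",
    "event_alert_histogram",
    "repeat_exposure",
    "annual_threshold_fractions",
]

#: Length of the DHW accumulation window in days (12 weeks).
DHW_WINDOW_DAYS = 84
#: Minimum HotSpot (degC) for a day to contribute to DHW accumulation.
HOTSPOT_CUTOFF = 1.0
#: Lower DHW bounds (degC-weeks) of Bleaching Alert Levels 1..5.
ALERT_THRESHOLDS = np.array([4.0, 8.0, 12.0, 16.0, 20.0])
#: Fraction of missing window days above which a DHW value is quality-flagged.
MISSING_FLAG_FRACTION = 0.10

#: Global bleaching event analysis periods (start, end inclusive).
EVENT_PERIODS = {
    "GCBE1": (np.datetime64("1997-06-01"), np.datetime64("1999-05-31")),
    "GCBE2": (np.datetime64("2009-06-01"), np.datetime64("2011-05-31")),
    "GCBE3": (np.datetime64("2014-06-01"), np.datetime64("2017-05-31")),
}


def _as_days(dates) -> np.ndarray:
    arr = np.asarray(dates, dtype="datetime64[D]")
    if arr.ndim != 1:
        raise ValueError("dates must be one-dimensional")
    return arr


@dataclass
class PixelSeries:
    """Daily SST plus climatology for one grid pixel.

    Parameters
    ----------
    pixel_id
        Opaque identifier (typically the flat grid index).
    lat, lon
        Pixel center, degrees; lon normalized to [-180, 180).
    dates
        Contiguous daily calendar dates.
    sst
        Daily sea-surface temperature, degC; NaN marks missing days.
    mmm
        Maximum-monthly-mean climatology for the pixel, degC.
    is_reef, is_ocean
        Mask membership flags.
    """

    pixel_id: int
    lat: float
    lon: float
    dates: np.ndarray
    sst: np.ndarray
    mmm: float
    is_reef: bool = False
    is_ocean: bool = True

    def __post_init__(self) -> None:
        self.dates = _as_days(self.dates)
        self.sst = np.asarray(self.sst, dtype=float)
        if self.sst.shape != self.dates.shape:
            raise ValueError("sst and dates must have equal length")
        if len(self.dates) > 1:
            step = np.diff(self.dates.astype("datetime64[D]").astype(int))
            if not np.all(step == 1):
                raise ValueError("dates must be strictly increasing daily with no gaps")
        if self.is_ocean and not np.isfinite(self.mmm):
            raise ValueError(
                f"pixel {self.pixel_id}: MMM climatology missing on an ocean pixel"
            )


@dataclass
class HeatStressSeries:
    """HotSpot, DHW and Alert Level series derived from one :class:`PixelSeries`."""

    pixel_id: int
    dates: np.ndarray
    hotspot: np.ndarray
    dhw: np.ndarray | None = None
    alert_level: np.ndarray | None = None
    missing_days: np.ndarray | None = None  # per-value count of missing window days
    quality_flag: np.ndarray | None = None  # warm-up or >10% missing window days
    is_reef: bool = False
    lat: float = np.nan
    lon: float = np.nan

    def __post_init__(self) -> None:
        self.dates = _as_days(self.dates)


def compute_hotspot(series: PixelSeries) -> HeatStressSeries:
    """Instantaneous heat stress: ``hotspot(d) = sst(d) - mmm``.

    Missing SST days yield missing (NaN) HotSpot.  Negative values are kept
    (they are excluded later by the DHW accumulation cutoff).
    """
    if not np.isfinite(series.mmm):
        raise ValueError(
            f"pixel {series.pixel_id}: MMM climatology missing; cannot compute HotSpot"
        )
    hotspot = series.sst - series.mmm
    return HeatStressSeries(
        pixel_id=series.pixel_id,
        dates=series.dates,
        hotspot=hotspot,
        is_reef=series.is_reef,
        lat=series.lat,
        lon=series.lon,
    )


def compute_dhw(series: HeatStressSeries) -> HeatStressSeries:
    """Accumulate DHW over the trailing 84-day window.

    ``dhw(t)`` sums ``hotspot(d) / 7`` over the 84 days ending at *t*,
    counting only days with ``hotspot >= 1.0`` degC.  Missing HotSpot days
    contribute zero and are tallied per value in ``missing_days``.  The
    first 83 values cover a partial window (absent days treated as zero
    stress) and are quality-flagged, as are values whose window has more
    than 10% missing days.
    """
    hs = series.hotspot
    n = len(hs)
    contrib = np.where(np.isfinite(hs) & (hs >= HOTSPOT_CUTOFF), hs / 7.0, 0.0)
    missing = (~np.isfinite(hs)).astype(float)

    kernel = np.ones(DHW_WINDOW_DAYS)
    # trailing windowed sums; partial windows at the start
    dhw = np.convolve(contrib, kernel)[:n]
    miss_count = np.convolve(missing, kernel)[:n]

    warmup = np.arange(n) < DHW_WINDOW_DAYS - 1
    window_len = np.minimum(np.arange(n) + 1, DHW_WINDOW_DAYS)
    flagged = warmup | (miss_count > MISSING_FLAG_FRACTION * window_len)

    dhw = np.maximum(dhw, 0.0)  # guard tiny negative fp residue
    return HeatStressSeries(
        pixel_id=series.pixel_id,
        dates=series.dates,
        hotspot=series.hotspot,
        dhw=dhw,
        alert_level=classify_alert(dhw),
        missing_days=miss_count.astype(int),
        quality_flag=flagged,
        is_reef=series.is_reef,
        lat=series.lat,
        lon=series.lon,
    )


def compute_heat_stress(series: PixelSeries) -> HeatStressSeries:
    """Full chain: HotSpot, DHW, and Alert Level for one pixel."""
    return compute_dhw(compute_hotspot(series))


def classify_alert(dhw):
    """Bleaching Alert Level 0-5 for a DHW value or array.

    Level 0 below 4 degC-weeks, then one level per 4 degC-weeks band,
    capped at level 5 for DHW >= 20.
    """
    arr = np.asarray(dhw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative DHW is not a valid heat-stress value")
    level = np.digitize(arr, ALERT_THRESHOLDS, right=False)
    if np.isscalar(dhw) or arr.ndim == 0:
        return int(level)
    return level.astype(int)


@dataclass(frozen=True)
class BleachingYear:
    """A June 1 - May 31 analysis year, labelled e.g. ``'2014-15'``."""

    label: str
    start: np.datetime64
    end: np.datetime64


def bleaching_year_label(start_year: int) -> str:
    return f"{start_year}-{(start_year + 1) % 100:02d}"


def bleaching_year_of(date) -> BleachingYear:
    """Map any calendar date to its bleaching year (June through May)."""
    d = np.datetime64(date, "D")
    y, m = [int(x) for x in str(np.datetime64(d, "M")).split("-")]
    start_year = y if m >= 6 else y - 1
    return BleachingYear(
        label=bleaching_year_label(start_year),
        start=np.datetime64(f"{start_year}-06-01"),
        end=np.datetime64(f"{start_year + 1}-05-31"),
    )


def list_bleaching_years(start: np.datetime64, end: np.datetime64) -> list[BleachingYear]:
    """All bleaching years whose window intersects [start, end]."""
    years = []
    year = bleaching_year_of(start)
    while year.start <= np.datetime64(end, "D"):
        years.append(year)
        year = bleaching_year_of(year.end + np.timedelta64(1, "D"))
    return years


@dataclass(frozen=True)
class YearlyMax:
    """Bleaching-year maximum DHW for one pixel and the first date it is attained."""

    pixel_id: int
    bleaching_year: str
    max_dhw: float
    max_date: np.datetime64


def yearly_max(series: HeatStressSeries, year: BleachingYear) -> YearlyMax:
    """Maximum DHW within the bleaching year; ties resolved to the earliest date."""
    if series.dhw is None:
        raise ValueError("DHW not computed; call compute_dhw first")
    mask = (series.dates >= year.start) & (series.dates <= year.end)
    if not mask.any():
        raise ValueError(
            f"pixel {series.pixel_id}: no data in bleaching year {year.label}"
        )
    dhw = series.dhw[mask]
    dates = series.dates[mask]
    idx = int(np.argmax(dhw))  # argmax returns the first of tied maxima
    return YearlyMax(
        pixel_id=series.pixel_id,
        bleaching_year=year.label,
        max_dhw=float(dhw[idx]),
        max_date=dates[idx],
    )


def all_yearly_maxima(
    pixels: Iterable[HeatStressSeries],
    years: Sequence[BleachingYear],
) -> pd.DataFrame:
    """Per-pixel per-year maxima as a tidy frame (pixel_id, bleaching_year, max_dhw, max_date, is_reef)."""
    rows = []
    for hs in pixels:
        for year in years:
            ym = yearly_max(hs, year)
            rows.append(
                (ym.pixel_id, ym.bleaching_year, ym.max_dhw, ym.max_date, hs.is_reef)
            )
    return pd.DataFrame(
        rows, columns=["pixel_id", "bleaching_year", "max_dhw", "max_date", "is_reef"]
    )


def event_alert_histogram(
    pixels: Iterable[HeatStressSeries],
    period: tuple[np.datetime64, np.datetime64],
) -> pd.DataFrame:
    """Distribution of period-maximum Alert Levels over reef pixels.

    Returns one row per level 0-5 with the fraction of reef-containing
    pixels whose maximum DHW over ``period`` falls in that level, plus the
    cumulative fraction at-or-above each level.
    """
    start, end = (np.datetime64(period[0], "D"), np.datetime64(period[1], "D"))
    levels = []
    for hs in pixels:
        if not hs.is_reef:
            continue
        if hs.dhw is None:
            raise ValueError("DHW not computed for all pixels")
        mask = (hs.dates >= start) & (hs.dates <= end)
        if not mask.any():
            raise ValueError(f"pixel {hs.pixel_id}: no data within the event period")
        levels.append(classify_alert(float(np.max(hs.dhw[mask]))))
    if not levels:
        raise ValueError("no reef pixels in input")
    levels = np.asarray(levels)
    counts = np.bincount(levels, minlength=6)[:6]
    frac = counts / counts.sum()
    at_or_above = frac[::-1].cumsum()[::-1]
    return pd.DataFrame(
        {
            "alert_level": np.arange(6),
            "n_pixels": counts,
            "fraction": frac,
            "fraction_at_or_above": at_or_above,
        }
    )


def repeat_exposure(yearly_maxima: pd.DataFrame, level_threshold: float) -> float | None:
    """Fraction of threshold-reaching pixels that reached it in >= 2 bleaching years.

    ``yearly_maxima`` is the tidy frame from :func:`all_yearly_maxima`.
    Returns None (undefined) when no pixel reached the threshold at all.
    """
    if yearly_maxima["bleaching_year"].nunique() < 2:
        raise ValueError("repeat exposure needs at least two bleaching years")
    reached = yearly_maxima[yearly_maxima["max_dhw"] >= level_threshold]
    years_per_pixel = reached.groupby("pixel_id")["bleaching_year"].nunique()
    if len(years_per_pixel) == 0:
        return None
    return float((years_per_pixel >= 2).sum() / len(years_per_pixel))


def annual_threshold_fractions(
    yearly_maxima: pd.DataFrame,
    thresholds: Sequence[float] = (4.0, 8.0),
) -> pd.DataFrame:
    """Per-bleaching-year fraction of reef pixels with max DHW >= each threshold."""
    reef = yearly_maxima[yearly_maxima["is_reef"]] if "is_reef" in yearly_maxima else yearly_maxima
    rows = []
    for year, grp in reef.groupby("bleaching_year"):
        row = {"bleaching_year": year, "n_pixels": len(grp)}
        for thr in thresholds:
            row[f"frac_ge_{thr:g}"] = float((grp["max_dhw"] >= thr).mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("bleaching_year").reset_index(drop=True)
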