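"""Join harmonized surveys to their heat-stress exposure and virtual station.

Each survey is snapped to the nearest valid ocean pixel (surveys on or next
to coastlines often fall in land pixels of the SST grid), then matched to a
DHW exposure value:

* **bleaching** surveys taken before the date of the bleaching-year maximum
  DHW are compared against the *contemporary* DHW on the survey date; those
  on or after the maximum's date are compared against the *yearly maximum*;
* **mortality** surveys are always compared against the yearly maximum, and
  those recorded before the peak are flagged for exclusion from the
  mortality analysis (the death they record cannot yet reflect the peak).

Surveys are also assigned to a Regional Virtual Station (a named reef
region polygon/box) used as the random-effect grouping in the response
models; points inside several stations go to the smallest one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geodesy import geodesic_km
from .heat_stress import HeatStressSeries, YearlyMax

__all__ = [
    "Grid",
    "VirtualStation",
    "UNASSIGNED_STATION",
    "nearest_ocean_pixel",
    "match_bleaching_dhw",
    "match_mortality_dhw",
    "assign_station",
    "match_surveys",
]

UNASSIGNED_STATION = "UNASSIGNED"


@dataclass
class Grid:
    """Regular lat/lon pixel grid with ocean and reef masks.

    Pixel ids are row-major flat indices: ``id = i_lat * nlon + i_lon``.
    """

    lats: np.ndarray  # 1D pixel-center latitudes, ascending
    lons: np.ndarray  # 1D pixel-center longitudes in [-180, 180), ascending
    ocean: np.ndarray  # (nlat, nlon) bool
    reef: np.ndarray  # (nlat, nlon) bool

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.ocean = np.asarray(self.ocean, dtype=bool)
        self.reef = np.asarray(self.reef, dtype=bool)
        if self.ocean.shape != (len(self.lats), len(self.lons)):
            raise ValueError("ocean mask shape mismatch")
        if self.reef.shape != self.ocean.shape:
            raise ValueError("reef mask shape mismatch")

    @property
    def nlat(self) -> int:
        return len(self.lats)

    @property
    def nlon(self) -> int:
        return len(self.lons)

    def pixel_id(self, i_lat: int, i_lon: int) -> int:
        return int(i_lat * self.nlon + i_lon)

    def pixel_latlon(self, pixel_id: int) -> tuple[float, float]:
        i, j = divmod(int(pixel_id), self.nlon)
        return float(self.lats[i]), float(self.lons[j])

    def containing_pixel(self, lat: float, lon: float) -> int:
        lon = float(np.mod(lon + 180.0, 360.0) - 180.0)
        i = int(np.argmin(np.abs(self.lats - lat)))
        dlon = np.abs(np.mod(self.lons - lon + 180.0, 360.0) - 180.0)
        j = int(np.argmin(dlon))
        return self.pixel_id(i, j)


def nearest_ocean_pixel(
    lat: float,
    lon: float,
    grid: Grid,
    max_radius_deg: float = 0.25,
) -> tuple[int, float] | None:
    """Nearest valid ocean pixel and snap distance in km.

    The containing pixel, if ocean, matches at distance zero.  Otherwise
    all ocean pixels within ``max_radius_deg`` (per-axis, longitude
    wrapped) are ranked by geodesic distance to their centers; ties break
    to the smallest pixel id.  Returns None when no ocean pixel lies within
    the radius.
    """
    lon = float(np.mod(lon + 180.0, 360.0) - 180.0)
    pid = grid.containing_pixel(lat, lon)
    i, j = divmod(pid, grid.nlon)
    if grid.ocean[i, j]:
        return pid, 0.0

    lat_ok = np.abs(grid.lats - lat) <= max_radius_deg
    dlon = np.abs(np.mod(grid.lons - lon + 180.0, 360.0) - 180.0)
    lon_ok = dlon <= max_radius_deg
    ii, jj = np.nonzero(np.outer(lat_ok, lon_ok) & grid.ocean)
    if len(ii) == 0:
        return None
    dists = geodesic_km(lat, lon, grid.lats[ii], grid.lons[jj])
    dists = np.atleast_1d(dists)
    ids = ii * grid.nlon + jj
    best = np.lexsort((ids, dists))[0]  # min distance, tie -> smallest id
    return int(ids[best]), float(dists[best])


def match_bleaching_dhw(
    survey_date,
    heat: HeatStressSeries,
    ymax: YearlyMax,
    missing_day_tolerance: int = 3,
) -> tuple[float, str, bool] | None:
    """DHW exposure for a bleaching survey: (dhw_used, rule, fallback_flag).

    Surveys dated before the date of the yearly maximum use the
    contemporary DHW on the survey date (nearest available day within
    ``missing_day_tolerance`` if that day is missing, flagged); surveys on
    or after it use the yearly maximum.  Returns None when no DHW value is
    available near the survey date.
    """
    d = np.datetime64(survey_date, "D")
    if d >= ymax.max_date:
        return float(ymax.max_dhw), "yearly_max", False
    if heat.dhw is None:
        raise ValueError("DHW not computed for matched pixel")
    idx = np.searchsorted(heat.dates, d)
    if idx < len(heat.dates) and heat.dates[idx] == d and np.isfinite(heat.dhw[idx]):
        return float(heat.dhw[idx]), "contemporary", False
    # fall back to the nearest available day within tolerance
    offsets = np.abs((heat.dates - d).astype(int))
    ok = (offsets <= missing_day_tolerance) & np.isfinite(heat.dhw)
    if not ok.any():
        return None
    best = int(np.nonzero(ok)[0][np.argmin(offsets[ok])])
    return float(heat.dhw[best]), "contemporary", True


def match_mortality_dhw(survey_date, ymax: YearlyMax) -> tuple[float, bool]:
    """DHW exposure for a mortality survey: always the yearly maximum.

    Returns (dhw_used, excluded) where ``excluded`` marks surveys dated
    before the peak, which the mortality analysis drops.
    """
    d = np.datetime64(survey_date, "D")
    return float(ymax.max_dhw), bool(d < ymax.max_date)


@dataclass(frozen=True)
class VirtualStation:
    """A Regional Virtual Station as a lat/lon bounding box."""

    station_id: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    @property
    def area_deg2(self) -> float:
        return (self.lat_max - self.lat_min) * (self.lon_max - self.lon_min)

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lat_min <= lat <= self.lat_max
            and self.lon_min <= lon <= self.lon_max
        )


def assign_station(lat: float, lon: float, stations: Sequence[VirtualStation]) -> str:
    """Station containing the point; overlaps resolve to the smallest area.

    Points outside every station get the sentinel ``UNASSIGNED`` id.
    """
    hits = [s for s in stations if s.contains(lat, lon)]
    if not hits:
        return UNASSIGNED_STATION
    hits.sort(key=lambda s: (s.area_deg2, s.station_id))
    return hits[0].station_id


def match_surveys(
    surveys: pd.DataFrame,
    heat: Mapping[int, HeatStressSeries],
    yearly_maxima: Mapping[tuple[int, str], YearlyMax],
    grid: Grid,
    stations: Sequence[VirtualStation],
    max_radius_deg: float = 0.25,
) -> pd.DataFrame:
    """Join every harmonized survey to its exposure and station.

    ``heat`` maps pixel_id -> heat-stress series (ocean pixels only);
    ``yearly_maxima`` maps (pixel_id, bleaching_year_label) -> YearlyMax.
    Unmatched surveys (no ocean pixel within radius, or no DHW near the
    survey date) are returned with ``matched = False``.  The result is
    deterministic and independent of input row order.
    """
    rows = []
    for _, s in surveys.iterrows():
        rec = {
            "survey_id": s["survey_id"],
            "basin": s["basin"],
            "bleaching_year": s["bleaching_year"],
            "depth_m": s.get("depth_m", np.nan),
            "lat": s["lat"],
            "lon": s["lon"],
            "moderate_bleach": s.get("moderate_bleach"),
            "severe_bleach": s.get("severe_bleach"),
            "moderate_mortality": s.get("moderate_mortality"),
            "severe_mortality": s.get("severe_mortality"),
            "matched": False,
            "pixel_id": -1,
            "snap_distance_km": np.nan,
            "dhw_used": np.nan,
            "dhw_rule": None,
            "dhw_fallback_day": False,
            "yearly_max_dhw": np.nan,
            "mortality_dhw": np.nan,
            "mortality_excluded": pd.NA,
            "station_id": assign_station(s["lat"], s["lon"], stations),
        }
        snap = nearest_ocean_pixel(s["lat"], s["lon"], grid, max_radius_deg)
        if snap is None:
            rows.append(rec)
            continue
        pid, dist = snap
        key = (pid, s["bleaching_year"])
        if key not in yearly_maxima or pid not in heat:
            rows.append(rec)
            continue
        ymax = yearly_maxima[key]
        bleach = match_bleaching_dhw(s["date"], heat[pid], ymax)
        if bleach is None:
            rows.append(rec)
            continue
        dhw_used, rule, fallback = bleach
        mort_dhw, mort_excl = match_mortality_dhw(s["date"], ymax)
        rec.update(
            matched=True,
            pixel_id=pid,
            snap_distance_km=dist,
            dhw_used=dhw_used,
            dhw_rule=rule,
            dhw_fallback_day=fallback,
            yearly_max_dhw=ymax.max_dhw,
            mortality_dhw=mort_dhw,
            mortality_excluded=mort_excl,
        )
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("survey_id", kind="mergesort").reset_index(drop=True)
    return out
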