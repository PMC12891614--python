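"""Synthetic worlds for end-to-end testing of the heat-stress pipeline.

Real inputs to the pipeline are satellite SST grids, reef masks, and a
global survey database — none of which ship with the package.  This module
generates statistically controlled stand-ins for all of them:

* **SST grids** with a seasonal climatology and injected multi-week marine
  heatwaves of chosen intensity, footprint and duration, plus Gaussian
  noise, on a regular lat/lon grid whose MMM climatology is derived from
  the same deterministic seasonal cycle;
* **a reef mask** scattered over the ocean, partitioned into the three
  longitude basins, contiguous reporting regions, and box-shaped virtual
  stations covering every reef pixel;
* **survey databases** in the raw CSV layout, whose binary outcomes are
  Bernoulli draws from a *known* logistic function of matched DHW with
  basin/year coefficient structure and station-level random intercepts
  (the truth record), so parameter recovery can be scored exactly.

Percent synthesis is invertible: the drawn percentage exceeds 10 (or the
colony proportion does) exactly when the drawn moderate outcome is true,
so harmonization reproduces the generated outcomes bit-for-bit.

All randomness flows from a single seed split into named substreams, so
e.g. changing the survey count does not perturb the SST fields.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import survey_db
from .heat_stress import (
    BleachingYear,
    HeatStressSeries,
    PixelSeries,
    YearlyMax,
    all_yearly_maxima,
    compute_heat_stress,
    list_bleaching_years,
)
from .matching import Grid, VirtualStation, assign_station, match_surveys
from .projection import global_fraction, project_event
from .response_models import (
    FittedResponseModel,
    ModelSpec,
    analysis_table,
    fit_model,
)
from .survey_db import assign_basin

__all__ = [
    "HeatwaveEvent",
    "WorldConfig",
    "TruthRecord",
    "SurveyDesign",
    "SyntheticWorld",
    "default_world_config",
    "default_truth",
    "generate_sst",
    "generate_world",
    "build_world",
    "generate_surveys",
    "generate_survey_database",
    "harmonize_raw",
    "recovery_experiment",
]


def _rng(seed: int, *stage: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stage path)."""
    keys = [seed] + [zlib.crc32(s.encode()) for s in stage]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class HeatwaveEvent:
    """One injected marine heatwave.

    ``profile='triangular'`` ramps linearly up to ``peak_anomaly_c`` at
    ``center`` and back down over ``duration_days``; ``'flat'`` holds the
    peak for the whole duration (useful for analytic DHW checks).
    The footprint is a lat/lon box.
    """

    center: str  # ISO date of peak
    duration_days: int
    peak_anomaly_c: float
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    profile: str = "triangular"

    def anomaly(self, dates: np.ndarray) -> np.ndarray:
        c = np.datetime64(self.center, "D")
        dt = (dates - c).astype(int)
        half = self.duration_days / 2.0
        if self.profile == "flat":
            shape = (np.abs(dt) <= half).astype(float)
        else:
            shape = np.clip(1.0 - np.abs(dt) / half, 0.0, None)
        return self.peak_anomaly_c * shape

    def covers(self, lat: float, lon: float) -> bool:
        return (
            self.lat_min <= lat <= self.lat_max
            and self.lon_min <= lon <= self.lon_max
        )


@dataclass
class WorldConfig:
    """Layout and physics of a synthetic world.

    Defaults give a small world — 20 x 20 pixels spanning the tropics and
    all three basins, 200 reef pixels, 6 regions, 12 stations, and the
    three June-May bleaching years of a three-year event — sized so the
    full generate-fit-project loop runs in seconds.
    """

    lat_min: float = -20.0
    lat_max: float = 20.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    nlat: int = 20
    nlon: int = 20
    n_reef_pixels: int = 200
    land_fraction: float = 0.05
    n_regions: int = 6
    n_stations: int = 12
    start: str = "2014-06-01"  # first day of the first bleaching year
    end: str = "2017-05-31"
    sst_mean_c: float = 27.0
    lat_gradient_c_per_deg: float = -0.05  # cooler away from the equator
    seasonal_amplitude_c: float = 2.0
    noise_sd_c: float = 0.15
    events: tuple[HeatwaveEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nlat <= 0 or self.nlon <= 0:
            raise ValueError("grid must be non-empty")
        if self.n_reef_pixels < 1:
            raise ValueError("need at least one reef pixel")

    @property
    def lats(self) -> np.ndarray:
        step = (self.lat_max - self.lat_min) / self.nlat
        return self.lat_min + step * (np.arange(self.nlat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        step = (self.lon_max - self.lon_min) / self.nlon
        lons = self.lon_min + step * (np.arange(self.nlon) + 0.5)
        return np.mod(lons + 180.0, 360.0) - 180.0

    @property
    def dates(self) -> np.ndarray:
        """Daily dates including the 84-day DHW warm-up before ``start``."""
        start = np.datetime64(self.start, "D") - np.timedelta64(84, "D")
        end = np.datetime64(self.end, "D")
        return np.arange(start, end + np.timedelta64(1, "D"))

    @property
    def bleaching_years(self) -> list[BleachingYear]:
        return list_bleaching_years(np.datetime64(self.start), np.datetime64(self.end))


def default_world_config(seed: int = 0) -> WorldConfig:
    """The default study conditions: three bleaching years, heatwaves of
    escalating intensity hitting different longitude bands each year."""
    events = (
        # 2014-15: moderate stress in the central Pacific and the Caribbean
        HeatwaveEvent("2014-10-01", 90, 2.4, lon_min=120.0, lon_max=180.0),
        HeatwaveEvent("2015-02-15", 70, 1.8, lon_min=-100.0, lon_max=-20.0),
        # 2015-16: the global peak — broad, intense events in all basins
        HeatwaveEvent("2015-10-15", 110, 3.4, lon_min=100.0, lon_max=180.0),
        HeatwaveEvent("2016-01-20", 100, 3.0, lon_min=-180.0, lon_max=-100.0),
        HeatwaveEvent("2016-03-01", 80, 2.6, lon_min=20.0, lon_max=100.0),
        HeatwaveEvent("2015-09-10", 80, 2.2, lon_min=-100.0, lon_max=-20.0),
        # 2016-17: stress persists in the Indo-Pacific, eases in the Atlantic
        HeatwaveEvent("2016-11-05", 95, 2.8, lon_min=60.0, lon_max=160.0),
        HeatwaveEvent("2017-02-10", 75, 2.0, lon_min=-180.0, lon_max=-120.0),
        HeatwaveEvent("2017-03-15", 60, 1.5, lon_min=-80.0, lon_max=-30.0),
    )
    return WorldConfig(events=events, seed=seed)


def _seasonal(lats: np.ndarray, dates: np.ndarray, cfg: WorldConfig) -> np.ndarray:
    """Deterministic seasonal SST, shape (npix_lat, ndays)."""
    doy = (dates - dates.astype("datetime64[Y]").astype("datetime64[D]")).astype(int)
    base = cfg.sst_mean_c + cfg.lat_gradient_c_per_deg * np.abs(lats)
    peak_doy = np.where(lats >= 0, 250.0, 60.0)  # local late-summer peak
    phase = 2 * np.pi * (doy[None, :] - peak_doy[:, None]) / 365.2425
    return base[:, None] + cfg.seasonal_amplitude_c * np.cos(phase)


def _mmm(lats: np.ndarray, cfg: WorldConfig) -> np.ndarray:
    """Maximum monthly mean of the deterministic climatology, per latitude."""
    year = np.arange(
        np.datetime64("2013-01-01"), np.datetime64("2014-01-01"), dtype="datetime64[D]"
    )
    clim = _seasonal(lats, year, cfg)
    months = year.astype("datetime64[M]").astype(int)
    mmm = np.full(len(lats), -np.inf)
    for m in np.unique(months):
        mmm = np.maximum(mmm, clim[:, months == m].mean(axis=1))
    return mmm


def generate_sst(cfg: WorldConfig, grid: Grid) -> dict[int, PixelSeries]:
    """Daily SST series for every ocean pixel: seasonal climatology plus
    injected heatwaves plus Gaussian noise; MMM from the noise-free cycle."""
    rng = _rng(cfg.seed, "sst")
    dates = cfg.dates
    seasonal = _seasonal(grid.lats, dates, cfg)  # (nlat, ndays)
    mmm = _mmm(grid.lats, cfg)

    event_time = [ev.anomaly(dates) for ev in cfg.events]  # each (ndays,)

    pixels: dict[int, PixelSeries] = {}
    for i, lat in enumerate(grid.lats):
        for j, lon in enumerate(grid.lons):
            if not grid.ocean[i, j]:
                continue
            pid = i * grid.nlon + j
            sst = seasonal[i].copy()
            for ev, anom in zip(cfg.events, event_time):
                if ev.covers(lat, lon):
                    sst = sst + anom
            if cfg.noise_sd_c > 0:
                sst = sst + rng.normal(0.0, cfg.noise_sd_c, size=len(dates))
            pixels[pid] = PixelSeries(
                pixel_id=pid,
                lat=float(lat),
                lon=float(lon),
                dates=dates,
                sst=sst,
                mmm=float(mmm[i]),
                is_reef=bool(grid.reef[i, j]),
                is_ocean=True,
            )
    return pixels


def generate_world(cfg: WorldConfig) -> tuple[Grid, pd.DataFrame, list[VirtualStation]]:
    """Grid with ocean/reef masks, region lookup, and station boxes.

    Reef pixels are scattered uniformly over the ocean; regions are
    contiguous longitude bands with (near-)equal reef pixel counts; the
    stations tile the whole domain so every reef pixel lies in exactly one.
    """
    rng = _rng(cfg.seed, "world")
    nlat, nlon = cfg.nlat, cfg.nlon
    ocean = np.ones((nlat, nlon), dtype=bool)
    n_land = int(round(cfg.land_fraction * nlat * nlon))
    if n_land:
        flat = rng.choice(nlat * nlon, size=n_land, replace=False)
        ocean.flat[flat] = False
    n_ocean = int(ocean.sum())
    if cfg.n_reef_pixels > n_ocean:
        raise ValueError("more reef pixels requested than ocean pixels available")
    reef = np.zeros_like(ocean)
    ocean_ids = np.flatnonzero(ocean.ravel())
    reef_ids = np.sort(rng.choice(ocean_ids, size=cfg.n_reef_pixels, replace=False))
    reef.flat[reef_ids] = True
    grid = Grid(lats=cfg.lats, lons=cfg.lons, ocean=ocean, reef=reef)

    # regions: longitude-ordered equal-count bands of reef pixels
    lons = np.array([grid.pixel_latlon(p)[1] for p in reef_ids])
    order = np.argsort(lons, kind="mergesort")
    bands = np.array_split(reef_ids[order], cfg.n_regions)
    rows = []
    for r, members in enumerate(bands):
        for pid in members:
            lat, lon = grid.pixel_latlon(int(pid))
            rows.append(
                {
                    "pixel_id": int(pid),
                    "region_id": f"R{r:02d}",
                    "basin": assign_basin(lon),
                    "lat": lat,
                    "lon": lon,
                }
            )
    regions = pd.DataFrame(rows).sort_values("pixel_id").reset_index(drop=True)

    # stations: tile the domain with a 3 x (n/3) box grid (covers everything)
    n_lat_boxes = max(1, min(3, cfg.n_stations))
    n_lon_boxes = max(1, cfg.n_stations // n_lat_boxes)
    lat_edges = np.linspace(cfg.lat_min, cfg.lat_max, n_lat_boxes + 1)
    lon_edges = np.linspace(cfg.lon_min, cfg.lon_max, n_lon_boxes + 1)
    stations = [
        VirtualStation(
            station_id=f"VS{a * n_lon_boxes + b:03d}",
            lat_min=float(lat_edges[a]),
            lat_max=float(lat_edges[a + 1]),
            lon_min=float(lon_edges[b]),
            lon_max=float(lon_edges[b + 1]),
        )
        for a in range(n_lat_boxes)
        for b in range(n_lon_boxes)
    ]
    return grid, regions, stations


@dataclass
class TruthRecord:
    """The generative model behind synthetic surveys.

    Coefficients are named in the same vocabulary as the fitted design
    columns ("(Intercept)", "dhw", "basin[CA]", "dhw:year[2015-16]", ...),
    so the truth is directly comparable to fitted coefficient vectors.
    ``station_effects`` holds the realized station random intercepts
    (drawn from N(0, sigma_u^2) when the world is built).

    Severe bleaching has no independent response curve: given a moderate
    outcome, the percent draw is uniform, which fixes
    P(severe | moderate) = 49.5 / 89.99 under the >10 / >50 rules.
    """

    bleach_coefficients: dict = field(default_factory=dict)
    mortality_coefficients: dict = field(default_factory=dict)
    sigma_u: float = 0.5
    station_effects: dict = field(default_factory=dict)

    def _eta(self, coeffs: Mapping[str, float], dhw, basin: str, year: str) -> float:
        eta = 0.0
        for name, val in coeffs.items():
            parts = name.split(":") if name != "(Intercept)" else []
            if name == "(Intercept)":
                eta += val
                continue
            ok = True
            scale = 1.0
            for part in parts:
                if part == "dhw":
                    scale = dhw
                elif part.startswith("basin["):
                    ok = ok and (part == f"basin[{basin}]")
                elif part.startswith("year["):
                    ok = ok and (part == f"year[{year}]")
                else:
                    raise ValueError(f"bad truth coefficient name {name!r}")
            if ok:
                eta += val * scale
        return eta

    def linear_predictor(
        self, outcome: str, dhw, basin: str, year: str, station_id: str | None = None
    ) -> float:
        coeffs = (
            self.mortality_coefficients
            if "mortality" in outcome
            else self.bleach_coefficients
        )
        eta = self._eta(coeffs, dhw, basin, year)
        if station_id is not None:
            eta += self.station_effects.get(station_id, 0.0)
        return eta

    def prob(self, outcome, dhw, basin, year, station_id=None) -> float:
        from scipy.special import expit

        return float(expit(self.linear_predictor(outcome, dhw, basin, year, station_id)))

    def beta_vector(self, names: Sequence[str], outcome: str = "moderate_bleach") -> np.ndarray:
        """Truth coefficients arranged in a fitted design's column order.

        Raises if the truth contains a term the design cannot express.
        """
        coeffs = (
            self.mortality_coefficients if "mortality" in outcome else self.bleach_coefficients
        )
        missing = set(coeffs) - set(names)
        if missing:
            raise ValueError(f"truth terms not expressible in design: {sorted(missing)}")
        return np.array([coeffs.get(n, 0.0) for n in names])


def default_truth(sigma_u: float = 0.5) -> TruthRecord:
    """Study-condition response curves: baseline bleaching odds rise ~0.45
    logits per degC-week, the Caribbean/Atlantic most heat-sensitive and
    2015-16 the most sensitive year; mortality rarer and flatter, with a
    near-flat Caribbean mortality response."""
    return TruthRecord(
        bleach_coefficients={
            "(Intercept)": -2.2,
            "dhw": 0.45,
            "basin[CA]": 0.30,
            "basin[IM]": 0.10,
            "year[2015-16]": 0.20,
            "year[2016-17]": -0.30,
            "dhw:basin[CA]": 0.10,
            "dhw:basin[IM]": 0.05,
            "dhw:year[2015-16]": 0.08,
            "dhw:year[2016-17]": -0.10,
        },
        mortality_coefficients={
            "(Intercept)": -3.0,
            "dhw": 0.30,
            "basin[CA]": 0.20,
            "dhw:basin[CA]": -0.28,
            "dhw:basin[IM]": -0.05,
        },
        sigma_u=sigma_u,
    )


@dataclass
class SyntheticWorld:
    """A fully built world: grid, masks, SST, heat stress and lookups."""

    config: WorldConfig
    grid: Grid
    regions: pd.DataFrame
    stations: list[VirtualStation]
    pixels: dict[int, PixelSeries]
    heat: dict[int, HeatStressSeries]
    yearly_maxima: pd.DataFrame
    ymax_lookup: dict[tuple[int, str], YearlyMax]

    @property
    def reef_pixel_ids(self) -> np.ndarray:
        return self.regions["pixel_id"].to_numpy()


def build_world(cfg: WorldConfig, truth: TruthRecord | None = None) -> SyntheticWorld:
    """Generate the world and precompute heat stress for every ocean pixel.

    If a truth record is given, its station random intercepts are drawn
    here (one per station, N(0, sigma_u^2)) from the 'stations' substream.
    """
    grid, regions, stations = generate_world(cfg)
    pixels = generate_sst(cfg, grid)
    heat = {pid: compute_heat_stress(ps) for pid, ps in pixels.items()}
    years = cfg.bleaching_years
    reef_heat = [heat[p] for p in regions["pixel_id"]]
    yearly_maxima = all_yearly_maxima(reef_heat, years)
    ymax_lookup = {}
    for hs in heat.values():
        for year in years:
            from .heat_stress import yearly_max as _ym

            ym = _ym(hs, year)
            ymax_lookup[(ym.pixel_id, ym.bleaching_year)] = ym
    if truth is not None:
        rng = _rng(cfg.seed, "stations")
        truth.station_effects = {
            s.station_id: float(rng.normal(0.0, truth.sigma_u)) for s in stations
        }
    return SyntheticWorld(
        config=cfg,
        grid=grid,
        regions=regions,
        stations=stations,
        pixels=pixels,
        heat=heat,
        yearly_maxima=yearly_maxima,
        ymax_lookup=ymax_lookup,
    )


@dataclass
class SurveyDesign:
    """Sampling design of a synthetic survey campaign.

    ``bias_exponent`` controls heat-seeking survey placement: pixels are
    drawn with probability proportional to (1 + yearly max DHW)^exponent,
    0 meaning unbiased.  A fraction of surveys use colony counts instead of
    percent cover, a fraction arrive as replicate transect groups, and a
    fraction carry month-only dates (generated on the 15th, so day
    imputation is exact).
    """

    n_surveys: int = 600
    bias_exponent: float = 0.0
    colony_fraction: float = 0.3
    replicate_fraction: float = 0.1
    month_only_fraction: float = 0.05
    mortality_fraction: float = 0.5  # fraction of surveys also reporting mortality
    depth_mean_m: float = 6.0
    depth_sd_m: float = 3.0


def _draw_pct(rng: np.random.Generator, moderate: bool, integer: bool) -> float:
    """Percent consistent with the binary outcome: >10 iff moderate.

    Continuous draws: U(10.01, 100) given moderate, U(0, 10) otherwise.
    Integer draws (colony counts of N=100): uniform on {11..100} / {0..10}.
    """
    if integer:
        return float(rng.integers(11, 101) if moderate else rng.integers(0, 11))
    return float(rng.uniform(10.01, 100.0) if moderate else rng.uniform(0.0, 10.0))


def generate_surveys(
    world: SyntheticWorld,
    truth: TruthRecord,
    design: SurveyDesign,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey database in the raw CSV layout plus the per-survey truth table.

    Pixels are sampled (with the design's heat bias) within each bleaching
    year; outcomes are Bernoulli draws from the truth logistic evaluated at
    the DHW value the matching rules would assign (contemporary before the
    peak, yearly max on/after); percentages are synthesized invertibly from
    the outcomes.  Returns ``(raw_records, truth_table)`` joined by
    ``source_id``.
    """
    rng = _rng(seed, "surveys")
    years = world.config.bleaching_years
    reef_ids = world.reef_pixel_ids
    res_lat = (world.config.lat_max - world.config.lat_min) / world.config.nlat
    res_lon = (world.config.lon_max - world.config.lon_min) / world.config.nlon

    raw_rows: list[dict] = []
    truth_rows: list[dict] = []
    for k in range(design.n_surveys):
        year = years[int(rng.integers(len(years)))]
        weights = np.array(
            [
                (1.0 + world.ymax_lookup[(int(p), year.label)].max_dhw)
                ** design.bias_exponent
                for p in reef_ids
            ]
        )
        weights = weights / weights.sum()
        pid = int(rng.choice(reef_ids, p=weights))
        lat0, lon0 = world.grid.pixel_latlon(pid)
        lat = lat0 + float(rng.uniform(-0.2, 0.2)) * res_lat
        lon = lon0 + float(rng.uniform(-0.2, 0.2)) * res_lon

        month_only = rng.random() < design.month_only_fraction
        n_days = int((year.end - year.start).astype(int)) + 1
        if month_only:
            # month-only records are generated on the 15th so imputation is exact
            month = np.datetime64(str(year.start)[:7], "M") + rng.integers(0, 12)
            date = np.datetime64(str(month) + "-15", "D")
            date_str = str(month)
        else:
            date = year.start + np.timedelta64(int(rng.integers(n_days)), "D")
            date_str = str(date)

        ymax = world.ymax_lookup[(pid, year.label)]
        heat = world.heat[pid]
        if date >= ymax.max_date:
            dhw_used = ymax.max_dhw
        else:
            idx = int(np.searchsorted(heat.dates, date))
            dhw_used = float(heat.dhw[idx])
        basin = assign_basin(lon)  # basin of the survey point, as harmonization sees it
        station = assign_station(lat, lon, world.stations)

        p_bleach = truth.prob("moderate_bleach", dhw_used, basin, year.label, station)
        moderate = bool(rng.random() < p_bleach)
        colony = rng.random() < design.colony_fraction
        pct_b = _draw_pct(rng, moderate, integer=colony)

        report_mort = rng.random() < design.mortality_fraction
        p_mort = truth.prob("moderate_mortality", ymax.max_dhw, basin, year.label, station)
        mort_moderate = bool(rng.random() < p_mort) if report_mort else None
        pct_m = _draw_pct(rng, mort_moderate, integer=colony) if report_mort else None

        depth = round(max(0.5, rng.normal(design.depth_mean_m, design.depth_sd_m)), 1)
        source_id = f"S{k:06d}"
        n_rows = 1
        if rng.random() < design.replicate_fraction:
            n_rows = int(rng.integers(2, 4))
        for _ in range(n_rows):
            row = {
                "source_id": source_id,
                "lat": round(lat, 5),
                "lon": round(lon, 5),
                "date": date_str,
                "depth_m": depth,
                "pct_cover_bleached": None if colony else round(pct_b, 3),
                "colonies_bleached_n": int(pct_b) if colony else None,
                "colonies_total_N": 100 if colony else None,
                "pct_cover_dead": (
                    None if (colony or pct_m is None) else round(pct_m, 3)
                ),
                "colonies_dead_n": (
                    int(pct_m) if (colony and pct_m is not None) else None
                ),
                "method": "colony_count" if colony else "percent_cover",
                "program": "SYNTH",
            }
            raw_rows.append(row)
        truth_rows.append(
            {
                "source_id": source_id,
                "pixel_id": pid,
                "station_id": station,
                "basin": basin,
                "bleaching_year": year.label,
                "date": date,
                "dhw_used": dhw_used,
                "yearly_max_dhw": ymax.max_dhw,
                "p_bleach": p_bleach,
                "moderate_bleach": moderate,
                "severe_bleach": (pct_b > 50.0) if moderate is not None else None,
                "p_mortality": p_mort if report_mort else None,
                "moderate_mortality": mort_moderate,
            }
        )
    raw = pd.DataFrame(raw_rows)
    # shuffle row order to exercise permutation invariance downstream
    raw = raw.sample(frac=1.0, random_state=int(_rng(seed, "shuffle").integers(2**31))).reset_index(
        drop=True
    )
    return raw, pd.DataFrame(truth_rows)


def generate_survey_database(
    n_surveys: int,
    rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A large raw survey database with directly specified outcome rates.

    A synthetic stand-in for a real global survey compilation: outcomes are
    drawn from the given marginal rates (``moderate_bleaching``,
    ``severe_bleaching``, ``moderate_mortality``, ``severe_mortality``;
    severe nested within moderate) rather than from a heat-stress model.
    Useful for exercising the harmonizer and its summary at scale.
    """
    if rates is None:
        rates = {
            "moderate_bleaching": 0.80,
            "severe_bleaching": 0.31,
            "moderate_mortality": 0.35,
            "severe_mortality": 0.06,
        }
    rng = _rng(seed, "database")

    def draw_pcts(p_mod: float, p_sev: float, n: int) -> np.ndarray:
        u = rng.random(n)
        pct = np.empty(n)
        sev = u < p_sev
        mod = u < p_mod
        pct[sev] = rng.uniform(50.01, 100.0, size=sev.sum())
        pct[mod & ~sev] = rng.uniform(10.01, 50.0, size=(mod & ~sev).sum())
        pct[~mod] = rng.uniform(0.0, 10.0, size=(~mod).sum())
        return pct

    n = n_surveys
    lat = rng.uniform(-25.0, 25.0, n).round(5)
    lon = rng.uniform(-180.0, 180.0, n).round(5)
    day = rng.integers(0, 1096, n)
    dates = np.datetime64("2014-06-01", "D") + day.astype("timedelta64[D]")
    df = pd.DataFrame(
        {
            "source_id": [f"DB{k:06d}" for k in range(n)],
            "lat": lat,
            "lon": lon,
            "date": dates.astype(str),
            "depth_m": rng.uniform(1.0, 15.0, n).round(1),
            "pct_cover_bleached": draw_pcts(
                rates["moderate_bleaching"], rates["severe_bleaching"], n
            ).round(3),
            "pct_cover_dead": draw_pcts(
                rates["moderate_mortality"], rates["severe_mortality"], n
            ).round(3),
            "method": "percent_cover",
            "program": "SYNTHDB",
        }
    )
    return df


def harmonize_raw(raw: pd.DataFrame) -> pd.DataFrame:
    """Run raw records through the real CSV reader and harmonizer."""
    buf = io.StringIO()
    raw.to_csv(buf, index=False)
    buf.seek(0)
    records, _ = survey_db.parse_surveys(buf)
    return survey_db.harmonize(records)


def recovery_experiment(
    cfg: WorldConfig,
    truth: TruthRecord,
    design: SurveyDesign,
    fit_spec: ModelSpec,
    n_replicates: int,
    seed: int,
    agq_points: int = 1,
) -> dict:
    """Parameter- and extent-recovery study over replicate survey campaigns.

    The world (SST, masks, stations, station effects) is built once from
    the config seed; each replicate redraws the survey campaign, runs the
    full harmonize-match-fit pipeline, and (for the bleaching outcome)
    projects global extent.  Reports per-coefficient bias, RMSE and 95%
    Wald coverage, sigma_u recovery, and the global-extent absolute error
    of the model projection vs the raw surveyed fraction against the known
    truth.  Replicates where any stage fails are logged and skipped.
    """
    world = build_world(cfg, truth)
    years = [y.label for y in cfg.bleaching_years]
    basins = tuple(sorted(world.regions["basin"].unique(), key=lambda b: (b != "AP", b)))

    # truth global extent: mean true probability over reef pixel-years
    reef = world.yearly_maxima.merge(world.regions[["pixel_id", "basin"]], on="pixel_id")
    true_p = np.array(
        [
            truth.prob(
                "moderate_bleach",
                r.max_dhw,
                r.basin,
                r.bleaching_year,
                assign_station(*world.grid.pixel_latlon(r.pixel_id), world.stations),
            )
            for r in reef.itertuples()
        ]
    )
    truth_extent = float(true_p.mean())

    est, se, sigmas, proj_err, raw_err, failures = [], [], [], [], [], []
    expected = None
    coef_names: list[str] | None = None
    for rep in range(n_replicates):
        rep_seed = int(_rng(seed, f"rep{rep}").integers(2**31))
        try:
            raw, _tt = generate_surveys(world, truth, design, rep_seed)
            harmonized = harmonize_raw(raw)
            matched = match_surveys(
                harmonized, world.heat, world.ymax_lookup, world.grid, world.stations
            )
            obs = analysis_table(matched, fit_spec.outcome)
            model = fit_model(
                obs, fit_spec, agq_points=agq_points,
                basin_levels=basins, year_levels=years,
            )
            if expected is None:
                expected = truth.beta_vector(model.names, fit_spec.outcome)
                coef_names = list(model.names)
            est.append(model.beta)
            # a numerically non-PSD Hessian yields NaN SEs; those count as
            # non-covered below, which is the conservative direction
            with np.errstate(invalid="ignore"):
                se.append(np.sqrt(np.diag(model.vcov)))
            sigmas.append(model.sigma_u)
            _, summary = project_event(model, world.yearly_maxima,
                                       world.regions[["pixel_id", "region_id", "basin"]])
            per_year = summary["bleaching"]["per_year"]
            proj_extent = float(np.mean([per_year[y] for y in years]))
            raw_extent = float(obs["y"].mean())
            proj_err.append(abs(proj_extent - truth_extent))
            raw_err.append(abs(raw_extent - truth_extent))
        except Exception as exc:  # noqa: BLE001 — a replicate may fail; log it
            failures.append(f"replicate {rep}: {exc!r}")
    est = np.array(est)
    se = np.array(se)
    covered = np.abs(est - expected) <= 1.959963984540054 * se
    proj_err = np.array(proj_err)
    raw_err = np.array(raw_err)
    return {
        "n_replicates": n_replicates,
        "n_completed": len(est),
        "failures": failures,
        "coef_names": coef_names,
        "truth_beta": expected,
        "beta_bias": est.mean(axis=0) - expected,
        "beta_rmse": np.sqrt(((est - expected) ** 2).mean(axis=0)),
        "coverage": covered.mean(axis=0),
        "coverage_overall": float(covered.mean()),
        "sigma_u_mean": float(np.mean(sigmas)),
        "sigma_u_truth": truth.sigma_u,
        "truth_extent": truth_extent,
        "projection_abs_error": proj_err,
        "raw_fraction_abs_error": raw_err,
        "projection_beats_raw_fraction": float((proj_err < raw_err).mean()),
    }
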