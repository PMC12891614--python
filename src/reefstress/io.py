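"""Readers and writers for the pipeline's on-disk formats.

Gridded fields travel as NetCDF (classic format via xarray's scipy
backend): SST cubes with ``sst(time, lat, lon)``, ``mmm(lat, lon)`` and
``reef_mask(lat, lon)``, and heat-stress cubes with ``dhw`` and
``alert_level``.  Tabular data (surveys, matches, yearly maxima, regions,
station boxes) travel as CSV; model objects as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .heat_stress import HeatStressSeries, PixelSeries
from .matching import Grid, VirtualStation
from .response_models import FittedResponseModel

__all__ = [
    "write_sst_netcdf",
    "read_sst_netcdf",
    "write_heat_stress_netcdf",
    "write_stations_csv",
    "read_stations_csv",
    "write_model_json",
    "read_model_json",
]

_ENGINE = "scipy"  # classic NetCDF; no netCDF4 dependency


def write_sst_netcdf(
    path, pixels: Mapping[int, PixelSeries], grid: Grid
) -> None:
    """Write per-pixel SST series back onto the grid as a NetCDF cube."""
    some = next(iter(pixels.values()))
    dates = some.dates
    nlat, nlon, nt = grid.nlat, grid.nlon, len(dates)
    sst = np.full((nt, nlat, nlon), np.nan, dtype=np.float32)
    mmm = np.full((nlat, nlon), np.nan, dtype=np.float32)
    for pid, ps in pixels.items():
        i, j = divmod(pid, nlon)
        sst[:, i, j] = ps.sst
        mmm[i, j] = ps.mmm
    ds = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst, {"units": "degC"}),
            "mmm": (("lat", "lon"), mmm, {"units": "degC"}),
            "reef_mask": (("lat", "lon"), grid.reef.astype(np.int8)),
            "ocean_mask": (("lat", "lon"), grid.ocean.astype(np.int8)),
        },
        coords={
            "time": dates.astype("datetime64[ns]"),
            "lat": grid.lats,
            "lon": grid.lons,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_sst_netcdf(path) -> tuple[dict[int, PixelSeries], Grid]:
    """Read an SST cube into per-pixel series plus the grid/masks."""
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        lats = ds["lat"].values.astype(float)
        lons = ds["lon"].values.astype(float)
        ocean = ds["ocean_mask"].values.astype(bool) if "ocean_mask" in ds else np.isfinite(
            ds["mmm"].values
        )
        reef = ds["reef_mask"].values.astype(bool)
        grid = Grid(lats=lats, lons=lons, ocean=ocean, reef=reef)
        dates = ds["time"].values.astype("datetime64[D]")
        sst = ds["sst"].values
        mmm = ds["mmm"].values
    pixels: dict[int, PixelSeries] = {}
    for i in range(grid.nlat):
        for j in range(grid.nlon):
            if not ocean[i, j]:
                continue
            pid = grid.pixel_id(i, j)
            pixels[pid] = PixelSeries(
                pixel_id=pid,
                lat=float(lats[i]),
                lon=float(lons[j]),
                dates=dates,
                sst=sst[:, i, j].astype(float),
                mmm=float(mmm[i, j]),
                is_reef=bool(reef[i, j]),
                is_ocean=True,
            )
    return pixels, grid


def write_heat_stress_netcdf(
    path, heat: Mapping[int, HeatStressSeries], grid: Grid
) -> None:
    some = next(iter(heat.values()))
    dates = some.dates
    nlat, nlon, nt = grid.nlat, grid.nlon, len(dates)
    dhw = np.full((nt, nlat, nlon), np.nan, dtype=np.float32)
    alert = np.full((nt, nlat, nlon), -1, dtype=np.int8)
    for pid, hs in heat.items():
        i, j = divmod(pid, nlon)
        dhw[:, i, j] = hs.dhw
        alert[:, i, j] = hs.alert_level
    ds = xr.Dataset(
        {
            "dhw": (("time", "lat", "lon"), dhw, {"units": "degC-weeks"}),
            "alert_level": (("time", "lat", "lon"), alert),
        },
        coords={
            "time": dates.astype("datetime64[ns]"),
            "lat": grid.lats,
            "lon": grid.lons,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def write_stations_csv(path, stations: Sequence[VirtualStation]) -> None:
    pd.DataFrame(
        [
            {
                "station_id": s.station_id,
                "lat_min": s.lat_min,
                "lat_max": s.lat_max,
                "lon_min": s.lon_min,
                "lon_max": s.lon_max,
            }
            for s in stations
        ]
    ).to_csv(path, index=False)


def read_stations_csv(path) -> list[VirtualStation]:
    df = pd.read_csv(path)
    return [
        VirtualStation(
            station_id=str(r.station_id),
            lat_min=float(r.lat_min),
            lat_max=float(r.lat_max),
            lon_min=float(r.lon_min),
            lon_max=float(r.lon_max),
        )
        for r in df.itertuples()
    ]


def write_model_json(path, model: FittedResponseModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_model_json(path) -> FittedResponseModel:
    return FittedResponseModel.from_dict(json.loads(Path(path).read_text()))
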