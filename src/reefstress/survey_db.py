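"""Ingestion and harmonization of heterogeneous bleaching/mortality surveys.

Field surveys of coral bleaching arrive in many dialects: percent of coral
cover bleached, colony counts (n bleached of N surveyed), categorical
severity ranges, with full or month-only dates, possibly as multiple
transects/quadrats per site.  This module deduplicates and harmonizes them
into one analysis schema:

* a *survey* is a unique combination of coordinates, date, and depth;
  replicate transects within a few days at the same depth (+-1 m) are
  combined (mean percent cover, or pooled colony proportion sum(n)/sum(N));
* month-only dates are imputed to the 15th;
* categorical ranges are replaced by their midpoints;
* each survey is assigned an ocean basin by longitude — Asia-Pacific (AP,
  100E across the antimeridian to 100W), Caribbean/Atlantic (CA, 100W
  across the prime meridian to 20E), Indian Ocean/Middle East (IM,
  20E-100E) — and a June-May bleaching year;
* percentages are binarized into moderate (>10%) and severe (>50%)
  bleaching/mortality outcomes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .heat_stress import bleaching_year_of

__all__ = [
    "RAW_COLUMNS",
    "MODERATE_THRESHOLD",
    "SEVERE_THRESHOLD",
    "parse_surveys",
    "impute_day",
    "combine_replicates",
    "colony_to_area",
    "midpoint_of_category",
    "apply_category_midpoints",
    "assign_basin",
    "binarize_outcomes",
    "harmonize",
    "survey_summary",
]

log = logging.getLogger(__name__)

#: Column dictionary of the raw survey CSV layout (Supplementary-Data-1 style).
RAW_COLUMNS = {
    "source_id": "free-text identifier from the contributing program",
    "lat": "latitude, decimal degrees [-90, 90]",
    "lon": "longitude, decimal degrees; normalized to [-180, 180)",
    "date": "ISO date YYYY-MM-DD, or YYYY-MM when only the month is known",
    "depth_m": "survey depth in meters (midpoint of range if a range)",
    "pct_cover_bleached": "percent of coral cover bleached [0, 100]",
    "colonies_bleached_n": "number of colonies bleached",
    "colonies_total_N": "total number of colonies surveyed",
    "pct_cover_dead": "percent of coral cover recently dead [0, 100]",
    "colonies_dead_n": "number of colonies recently dead",
    "method": "survey method (e.g. transect, quadrat, aerial)",
    "program": "contributing program (selects the category dialect)",
}

MODERATE_THRESHOLD = 10.0  # strictly greater-than, percent
SEVERE_THRESHOLD = 50.0

_OUTCOME_FIELDS = [
    "pct_cover_bleached",
    "colonies_bleached_n",
    "pct_cover_dead",
    "colonies_dead_n",
]


def impute_day(partial_date: str) -> str:
    """Full ISO date for a possibly month-only date: missing day becomes the 15th."""
    s = str(partial_date).strip()
    if len(s) == 7:  # YYYY-MM
        return f"{s}-15"
    return s


def parse_surveys(path_or_buf, dialects=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the raw survey CSV into typed records.

    Returns ``(records, rejected)``.  Rows with out-of-range coordinates or
    unparseable dates, and rows missing every outcome measure, are moved to
    ``rejected`` with a ``reject_reason`` column; counts are logged.
    ``dialects`` (program -> {category code -> (lo, hi)}) converts
    categorical severity codes to range midpoints before any rejection.
    """
    df = pd.read_csv(path_or_buf, dtype={"date": str})
    missing_cols = [c for c in ("lat", "lon", "date") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"survey CSV missing required columns: {missing_cols}")
    for col in RAW_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if dialects:
        df = apply_category_midpoints(df, dialects)

    reasons = pd.Series("", index=df.index)
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 360)
    reasons[bad_coord] = "invalid coordinates"

    imputed = df["date"].map(impute_day)
    parsed_date = pd.to_datetime(imputed, format="%Y-%m-%d", errors="coerce")
    bad_date = parsed_date.isna() & (reasons == "")
    reasons[bad_date] = "invalid date"

    has_outcome = pd.DataFrame(
        {c: pd.to_numeric(df[c], errors="coerce") for c in _OUTCOME_FIELDS}
    ).notna().any(axis=1)
    no_outcome = ~has_outcome & (reasons == "")
    reasons[no_outcome] = "no outcome measure"

    rejected = df[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    ok = df[reasons == ""].copy()
    ok["lat"] = lat[reasons == ""]
    ok["lon"] = np.mod(lon[reasons == ""] + 180.0, 360.0) - 180.0
    ok["date"] = parsed_date[reasons == ""]
    ok["date_was_imputed"] = (df["date"].str.len() == 7)[reasons == ""]
    for col in (
        "depth_m",
        "pct_cover_bleached",
        "colonies_bleached_n",
        "colonies_total_N",
        "pct_cover_dead",
        "colonies_dead_n",
    ):
        ok[col] = pd.to_numeric(ok[col], errors="coerce")
    if len(rejected):
        log.info(
            "parse_surveys: rejected %d of %d rows (%s)",
            len(rejected),
            len(df),
            rejected["reject_reason"].value_counts().to_dict(),
        )
    return ok.reset_index(drop=True), rejected.reset_index(drop=True)


def midpoint_of_category(lo: float, hi: float) -> float:
    """Midpoint of a categorical percent range; a point value is its own midpoint."""
    if not (0 <= lo <= hi <= 100):
        raise ValueError(f"invalid category range [{lo}, {hi}]")
    return (lo + hi) / 2.0


def apply_category_midpoints(
    df: pd.DataFrame,
    dialects: Mapping[str, Mapping[str, tuple[float, float]]],
    category_col: str = "bleach_category",
    target_col: str = "pct_cover_bleached",
) -> pd.DataFrame:
    """Replace per-program category codes with configured range midpoints.

    ``dialects`` maps program name -> {category code -> (lo, hi)}.  Rows whose
    program has no configured dialect, or whose code is unknown, are left
    untouched.
    """
    if category_col not in df.columns:
        return df

    def norm(code) -> str:
        # "2", 2 and 2.0 are the same category code
        s = str(code).strip()
        try:
            f = float(s)
            if f == int(f):
                return str(int(f))
        except ValueError:
            pass
        return s

    out = df.copy()
    col = out[category_col].map(norm, na_action="ignore")
    for program, ranges in dialects.items():
        sel = (out.get("program") == program) & col.notna()
        for code, (lo, hi) in ranges.items():
            hit = sel & (col == norm(code))
            out.loc[hit, target_col] = midpoint_of_category(float(lo), float(hi))
    return out


def colony_to_area(per_colony_pct: Sequence[float], colony_areas: Sequence[float]) -> float:
    """Area-weighted site percentage from per-colony percentages and sizes.

    sum(p_i * A_i) / sum(A_i); the site-level percent of total coral area
    affected when each colony reports its own percent and size dimensions.
    """
    p = np.asarray(per_colony_pct, dtype=float)
    a = np.asarray(colony_areas, dtype=float)
    if np.any(a <= 0):
        raise ValueError("colony areas must be positive")
    total = a.sum()
    if total <= 0:
        raise ValueError("zero total colony area")
    return float(np.sum(p * a) / total)


def assign_basin(lon: float):
    """Ocean basin from longitude: AP, CA or IM (see module docstring)."""
    arr = np.mod(np.asarray(lon, dtype=float) + 180.0, 360.0) - 180.0
    out = np.where(
        (arr >= 100.0) | (arr < -100.0),
        "AP",
        np.where((arr >= 20.0) & (arr < 100.0), "IM", "CA"),
    )
    if out.ndim == 0:
        return str(out)
    return out


def binarize_outcomes(
    pct,
    thresholds: tuple[float, float] = (MODERATE_THRESHOLD, SEVERE_THRESHOLD),
):
    """Strict-threshold binary outcomes: moderate iff pct > 10, severe iff pct > 50.

    Missing percentages give missing (pd.NA) outcomes.  Works on scalars or
    Series; returns (moderate, severe).
    """
    moderate_thr, severe_thr = thresholds
    s = pd.Series(pct, dtype="Float64") if not isinstance(pct, pd.Series) else pct.astype("Float64")
    if ((s < 0) | (s > 100)).any():
        raise ValueError("percentages must lie in [0, 100]")
    moderate = (s > moderate_thr).astype("boolean").mask(s.isna())
    severe = (s > severe_thr).astype("boolean").mask(s.isna())
    if np.isscalar(pct):
        return (
            None if s.isna().iloc[0] else bool(moderate.iloc[0]),
            None if s.isna().iloc[0] else bool(severe.iloc[0]),
        )
    return moderate, severe


def _group_pct(grp: pd.DataFrame, pct_col: str, n_col: str | None, N_col: str | None):
    """Combined percentage for one replicate group: prefer area-based mean,
    else pooled colony proportion sum(n)/sum(N)."""
    pct = grp[pct_col].dropna()
    if len(pct):
        return float(pct.mean()), "area"
    if n_col is not None and N_col is not None:
        n = grp[n_col]
        N = grp[N_col]
        ok = n.notna() & N.notna() & (N > 0)
        if ok.any():
            return float(100.0 * n[ok].sum() / N[ok].sum()), "colony"
    return np.nan, None


def combine_replicates(
    records: pd.DataFrame,
    window_days: int = 3,
    depth_tol_m: float = 1.0,
    coord_decimals: int = 4,
) -> pd.DataFrame:
    """Collapse replicate transects/quadrats into unique surveys.

    Records sharing coordinates (rounded to ``coord_decimals`` places,
    ~11 m at 4), taken within ``window_days`` of each other at depths within
    ``depth_tol_m``, form one survey.  Percent-cover measures are averaged;
    colony counts are pooled (sum n / sum N); when a group mixes both, the
    area-based measure is retained.  The survey date is the group's
    earliest; ``n_replicates_combined`` records the group size.
    """
    df = records.copy()
    df["_rlat"] = df["lat"].round(coord_decimals)
    df["_rlon"] = df["lon"].round(coord_decimals)
    df["_depth_key"] = df["depth_m"].fillna(-999.0)

    rows = []
    # fast path: sites with a single record need no replicate clustering
    site_sizes = df.groupby(["_rlat", "_rlon"], sort=False)["lat"].transform("size")
    singles = df[site_sizes == 1]
    for rec in singles.itertuples():
        has_pct_b = pd.notna(rec.pct_cover_bleached)
        has_col_b = (
            pd.notna(rec.colonies_bleached_n)
            and pd.notna(rec.colonies_total_N)
            and rec.colonies_total_N > 0
        )
        has_pct_m = pd.notna(rec.pct_cover_dead)
        has_col_m = (
            pd.notna(rec.colonies_dead_n)
            and pd.notna(rec.colonies_total_N)
            and rec.colonies_total_N > 0
        )
        rows.append(
            {
                "lat": float(rec.lat),
                "lon": float(rec.lon),
                "date": rec.date,
                "depth_m": float(rec.depth_m) if pd.notna(rec.depth_m) else np.nan,
                "pct_bleached": (
                    float(rec.pct_cover_bleached)
                    if has_pct_b
                    else 100.0 * rec.colonies_bleached_n / rec.colonies_total_N
                    if has_col_b
                    else np.nan
                ),
                "pct_mortality": (
                    float(rec.pct_cover_dead)
                    if has_pct_m
                    else 100.0 * rec.colonies_dead_n / rec.colonies_total_N
                    if has_col_m
                    else np.nan
                ),
                "bleach_measure": "area" if has_pct_b else ("colony" if has_col_b else None),
                "mortality_measure": "area" if has_pct_m else ("colony" if has_col_m else None),
                "n_replicates_combined": 1,
                "program": getattr(rec, "program", None),
                "method": getattr(rec, "method", None),
                "source_id": getattr(rec, "source_id", None),
            }
        )
    df = df[site_sizes > 1]
    for (rlat, rlon), site in df.groupby(["_rlat", "_rlon"], sort=True):
        site = site.sort_values(["date", "_depth_key"], kind="mergesort")
        assigned = np.full(len(site), -1)
        anchors: list[tuple[pd.Timestamp, float]] = []
        for i, (_, rec) in enumerate(site.iterrows()):
            for gid, (g_date, g_depth) in enumerate(anchors):
                # missing depths carry a sentinel, so they only group together
                if (rec["date"] - g_date).days <= window_days and abs(
                    rec["_depth_key"] - g_depth
                ) <= depth_tol_m:
                    assigned[i] = gid
                    break
            if assigned[i] < 0:
                anchors.append((rec["date"], rec["_depth_key"]))
                assigned[i] = len(anchors) - 1
        site = site.assign(_gid=assigned)
        for gid, grp in site.groupby("_gid"):
            pct_b, method_b = _group_pct(
                grp, "pct_cover_bleached", "colonies_bleached_n", "colonies_total_N"
            )
            pct_m, method_m = _group_pct(
                grp, "pct_cover_dead", "colonies_dead_n", "colonies_total_N"
            )
            depth = grp["depth_m"].dropna()
            rows.append(
                {
                    "lat": float(grp["lat"].iloc[0]),
                    "lon": float(grp["lon"].iloc[0]),
                    "date": grp["date"].min(),
                    "depth_m": float(depth.mean()) if len(depth) else np.nan,
                    "pct_bleached": pct_b,
                    "pct_mortality": pct_m,
                    "bleach_measure": method_b,
                    "mortality_measure": method_m,
                    "n_replicates_combined": int(len(grp)),
                    "program": grp.get("program", pd.Series([None])).iloc[0],
                    "method": grp.get("method", pd.Series([None])).iloc[0],
                    "source_id": grp.get("source_id", pd.Series([None])).iloc[0],
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["lat", "lon", "date"], kind="mergesort").reset_index(drop=True)
    return out


def harmonize(
    records: pd.DataFrame,
    window_days: int = 3,
    depth_tol_m: float = 1.0,
    thresholds: tuple[float, float] = (MODERATE_THRESHOLD, SEVERE_THRESHOLD),
) -> pd.DataFrame:
    """Full harmonization: combine replicates, assign basin/bleaching year,
    binarize outcomes.  Input is the typed frame from :func:`parse_surveys`."""
    surveys = combine_replicates(records, window_days=window_days, depth_tol_m=depth_tol_m)
    if not len(surveys):
        return surveys
    surveys["survey_id"] = np.arange(len(surveys))
    surveys["basin"] = assign_basin(surveys["lon"].to_numpy())
    surveys["bleaching_year"] = [
        bleaching_year_of(d.date()).label for d in surveys["date"]
    ]
    mb, sb = binarize_outcomes(surveys["pct_bleached"], thresholds)
    mm, sm = binarize_outcomes(surveys["pct_mortality"], thresholds)
    surveys["moderate_bleach"] = mb
    surveys["severe_bleach"] = sb
    surveys["moderate_mortality"] = mm
    surveys["severe_mortality"] = sm
    return surveys


def survey_summary(surveys: pd.DataFrame) -> dict:
    """Fractions of surveys with moderate/severe bleaching and mortality.

    Each fraction is computed over surveys that report the relevant measure
    (missing excluded); denominators are included so the all-surveys
    denominator can be recovered.
    """
    out: dict = {"n_surveys": int(len(surveys))}
    for key, col in [
        ("moderate_bleaching", "moderate_bleach"),
        ("severe_bleaching", "severe_bleach"),
        ("moderate_mortality", "moderate_mortality"),
        ("severe_mortality", "severe_mortality"),
    ]:
        vals = surveys[col]
        denom = int(vals.notna().sum())
        out[f"n_reporting_{key.split('_', 1)[1]}"] = denom
        out[f"frac_{key}"] = float(vals.dropna().astype(bool).mean()) if denom else None
        out[f"frac_{key}_all_surveys"] = (
            float(vals.fillna(False).astype(bool).mean()) if len(surveys) else None
        )
    return out
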