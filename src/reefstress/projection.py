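"""Model-based projection of bleaching/mortality extent across all reef pixels.

Surveyed reefs are a small, potentially heat-biased sample of the world's
reef pixels.  To estimate the event's global footprint without that bias,
the fitted fixed-effects response curves are applied to *every*
reef-containing pixel's bleaching-year maximum DHW, and the resulting
probabilities are summed: two pixels with a 30% probability of bleaching
contribute the same expected extent as one pixel at 60%.  Station random
effects are excluded (many reef pixels fall in stations without surveys).

Extent is aggregated per reporting region and per bleaching year, and the
probability that a pixel was affected in *any* year of a multi-year event
is combined across years under independence: P(any) = 1 - prod_y (1 - p_y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .response_models import FittedResponseModel

__all__ = [
    "predict_pixel",
    "regional_extent",
    "global_fraction",
    "mortality_display_filter",
    "project_event",
]

MORTALITY_DISPLAY_MIN_PIXELS = 500


def predict_pixel(model: FittedResponseModel, dhw, basin, year) -> np.ndarray:
    """Fixed-effects-only probability for pixels at their yearly max DHW.

    Raises on basin/year levels the model was not fitted with.
    """
    return model.predict(dhw, basin, year, station_id=None)


def regional_extent(
    pixel_probs: pd.DataFrame,
    year: str | None = None,
) -> pd.DataFrame:
    """Expected affected pixels per region (and year): sum of probabilities.

    ``pixel_probs`` is a tidy frame with columns ``region_id``,
    ``bleaching_year``, ``max_dhw`` and one or both of ``p_bleach`` /
    ``p_mortality``.  Returns one row per region x year with the summed
    expected pixels, the regional maximum DHW, and the pixel count.
    Regions with zero pixels never appear with nonzero extent; callers may
    outer-join a region table to surface empty regions with n_pixels 0.
    """
    df = pixel_probs if year is None else pixel_probs[pixel_probs["bleaching_year"] == year]
    rows = []
    for (region, by), grp in df.groupby(["region_id", "bleaching_year"]):
        row = {
            "region_id": region,
            "bleaching_year": by,
            "n_pixels": int(len(grp)),
            "region_max_dhw": float(grp["max_dhw"].max()),
        }
        if "p_bleach" in grp:
            row["expected_bleached_pixels"] = float(grp["p_bleach"].sum())
        if "p_mortality" in grp:
            row["expected_mortality_pixels"] = float(grp["p_mortality"].sum())
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["region_id", "bleaching_year"], kind="mergesort")
        .reset_index(drop=True)
    )


def global_fraction(per_year_probs: Mapping[str, np.ndarray]) -> dict:
    """Global fraction of reef pixels affected, per year and in any year.

    ``per_year_probs`` maps bleaching-year label -> per-pixel probability
    array (one entry per reef pixel, consistent ordering across years).
    The any-year combination assumes independence across years:
    P(any) = 1 - prod_y (1 - p_y).
    """
    years = sorted(per_year_probs)
    if not years:
        return {"per_year": {}, "any_year": None}
    probs = np.vstack([np.asarray(per_year_probs[y], dtype=float) for y in years])
    p_any = 1.0 - np.prod(1.0 - probs, axis=0)
    return {
        "per_year": {y: float(np.mean(probs[k])) for k, y in enumerate(years)},
        "any_year": float(np.mean(p_any)),
        "n_pixels": int(probs.shape[1]),
    }


def mortality_display_filter(
    projections: pd.DataFrame,
    min_pixels: float = MORTALITY_DISPLAY_MIN_PIXELS,
) -> pd.DataFrame:
    """Suppress mortality extent where it does not exceed ``min_pixels``.

    Mirrors the display rule that hides mortality sub-areas too small to
    be meaningful (about 0.1% of global reef pixels).  Suppressed values
    become NaN; idempotent.
    """
    out = projections.copy()
    if "expected_mortality_pixels" in out:
        small = out["expected_mortality_pixels"] <= min_pixels
        out.loc[small, "expected_mortality_pixels"] = np.nan
    return out


def project_event(
    bleach_model: FittedResponseModel,
    yearly_maxima: pd.DataFrame,
    regions: pd.DataFrame,
    mortality_model: FittedResponseModel | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Project fitted models onto every reef pixel for every bleaching year.

    ``yearly_maxima`` is the tidy per-pixel per-year frame (pixel_id,
    bleaching_year, max_dhw, is_reef) from the heat-stress module;
    ``regions`` maps pixel_id -> region_id (and carries the pixel's basin).
    Returns the per-region projection table and the global summary dict.
    A mortality model with a negative DHW slope in some cell is used as-is
    (with a warning) rather than clamped.
    """
    reef = yearly_maxima[yearly_maxima["is_reef"]].merge(regions, on="pixel_id")
    known = reef["bleaching_year"].isin(bleach_model.info.years)
    if not known.all():
        skipped = sorted(reef.loc[~known, "bleaching_year"].unique())
        warnings.warn(
            f"skipping bleaching years without fitted coefficients: {skipped}"
        )
        reef = reef[known]
    reef = reef.sort_values(["pixel_id", "bleaching_year"], kind="mergesort")
    out = reef.rename(columns={"max_dhw": "max_dhw"}).copy()
    out["p_bleach"] = predict_pixel(
        bleach_model,
        reef["max_dhw"].to_numpy(float),
        reef["basin"].to_numpy(),
        reef["bleaching_year"].to_numpy(),
    )
    per_year_b = {
        y: g.sort_values("pixel_id")["p_bleach"].to_numpy()
        for y, g in out.groupby("bleaching_year")
    }
    summary = {"bleaching": global_fraction(per_year_b)}
    if mortality_model is not None:
        _warn_negative_slopes(mortality_model)
        out["p_mortality"] = predict_pixel(
            mortality_model,
            reef["max_dhw"].to_numpy(float),
            reef["basin"].to_numpy(),
            reef["bleaching_year"].to_numpy(),
        )
        per_year_m = {
            y: g.sort_values("pixel_id")["p_mortality"].to_numpy()
            for y, g in out.groupby("bleaching_year")
        }
        summary["mortality"] = global_fraction(per_year_m)
    regional = regional_extent(out)
    return regional, summary


def _warn_negative_slopes(model: FittedResponseModel) -> None:
    beta = dict(zip(model.names, model.beta))
    base = beta.get("dhw", 0.0)
    for b in model.info.basins:
        for y in model.info.years:
            slope = base
            slope += beta.get(f"dhw:basin[{b}]", 0.0)
            slope += beta.get(f"dhw:year[{y}]", 0.0)
            slope += beta.get(f"dhw:basin[{b}]:year[{y}]", 0.0)
            if slope < 0:
                warnings.warn(
                    f"mortality model has a negative DHW slope in {b}/{y}; "
                    "projected as-is (no clamping)"
                )
                return
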