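"""Tests of survey ingestion, deduplication and harmonization rules."""

import io

import numpy as np
import pandas as pd
import pytest

from reefstress.survey_db import (
    apply_category_midpoints,
    assign_basin,
    binarize_outcomes,
    colony_to_area,
    combine_replicates,
    harmonize,
    impute_day,
    midpoint_of_category,
    parse_surveys,
    survey_summary,
)


def records_frame(rows):
    """Typed records like parse_surveys produces, from compact tuples
    (lat, lon, date, depth, pct_b, n_b, N, pct_m)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "lat", "lon", "date", "depth_m", "pct_cover_bleached",
            "colonies_bleached_n", "colonies_total_N", "pct_cover_dead",
        ],
    )
    df["date"] = pd.to_datetime(df["date"])
    df["colonies_dead_n"] = np.nan
    df["source_id"] = [f"r{i}" for i in range(len(df))]
    df["program"] = "T"
    df["method"] = "t"
    return df


class TestParse:
    CSV = """source_id,lat,lon,date,depth_m,pct_cover_bleached,colonies_bleached_n,colonies_total_N,pct_cover_dead,colonies_dead_n,method,program
a,10.0,100.0,2015-03-01,5,20,,,,,transect,P1
b,10.0,100.0,2015-03,5,30,,,,,transect,P1
c,95.0,100.0,2015-03-01,5,20,,,,,transect,P1
d,10.0,100.0,not-a-date,5,20,,,,,transect,P1
e,10.0,101.0,2015-03-02,5,,5,20,,,colony,P1
f,-5.0,55.0,2016-04-07,8,,,,12,,transect,P2
g,-5.0,55.0,2016-04-08,8,0,,,,,transect,P2
h,20.0,-80.0,2015-09-01,3,60,,,30,,transect,P3
i,20.0,-80.0,2015-09-02,3,80,,,40,,transect,P3
j,0.0,170.0,2016-01-15,10,5,,,,,transect,P4
k,0.0,190.0,2016-01-15,10,15,,,,,transect,P4
l,0.0,170.0,2016-01-15,10,,,,,,transect,P4
"""

    def test_fixture_of_12_rows_keeps_10_rejects_2_plus_empty(self):
        records, rejected = parse_surveys(io.StringIO(self.CSV))
        # 2 malformed (lat 95, bad date) and 1 with no outcome at all
        assert len(records) == 9
        assert len(rejected) == 3
        reasons = rejected["reject_reason"].value_counts().to_dict()
        assert reasons["invalid coordinates"] == 1
        assert reasons["invalid date"] == 1
        assert reasons["no outcome measure"] == 1

    def test_month_only_dates_imputed_to_fifteenth(self):
        records, _ = parse_surveys(io.StringIO(self.CSV))
        b = records[records["source_id"] == "b"].iloc[0]
        assert b["date"] == pd.Timestamp("2015-03-15")
        assert bool(b["date_was_imputed"])

    def test_longitudes_normalized(self):
        records, _ = parse_surveys(io.StringIO(self.CSV))
        k = records[records["source_id"] == "k"].iloc[0]
        assert k["lon"] == pytest.approx(-170.0)


class TestImputeDay:
    @pytest.mark.parametrize(
        "given,expected",
        [("2016-04", "2016-04-15"), ("2015-02", "2015-02-15"),
         ("2016-04-02", "2016-04-02")],
    )
    def test_rule(self, given, expected):
        assert impute_day(given) == expected


class TestCombineReplicates:
    def test_mean_of_percent_cover(self):
        df = records_frame([
            (1.0, 2.0, "2015-01-01", 5.0, 40.0, np.nan, np.nan, np.nan),
            (1.0, 2.0, "2015-01-01", 5.0, 60.0, np.nan, np.nan, np.nan),
        ])
        out = combine_replicates(df)
        assert len(out) == 1
        assert out.loc[0, "pct_bleached"] == 50.0
        assert out.loc[0, "n_replicates_combined"] == 2

    def test_pooled_colony_counts(self):
        df = records_frame([
            (1.0, 2.0, "2015-01-01", 5.0, np.nan, 5, 20, np.nan),
            (1.0, 2.0, "2015-01-01", 5.0, np.nan, 15, 20, np.nan),
        ])
        out = combine_replicates(df)
        assert out.loc[0, "pct_bleached"] == 50.0  # 20/40 pooled
        assert out.loc[0, "bleach_measure"] == "colony"

    def test_records_beyond_window_stay_separate(self):
        df = records_frame([
            (1.0, 2.0, "2015-01-01", 5.0, 40.0, np.nan, np.nan, np.nan),
            (1.0, 2.0, "2015-01-05", 5.0, 60.0, np.nan, np.nan, np.nan),  # 4 days later
        ])
        out = combine_replicates(df, window_days=3)
        assert len(out) == 2

    def test_depth_tolerance(self):
        df = records_frame([
            (1.0, 2.0, "2015-01-01", 5.0, 40.0, np.nan, np.nan, np.nan),
            (1.0, 2.0, "2015-01-01", 5.9, 60.0, np.nan, np.nan, np.nan),
            (1.0, 2.0, "2015-01-01", 8.0, 20.0, np.nan, np.nan, np.nan),
        ])
        out = combine_replicates(df, depth_tol_m=1.0)
        assert sorted(out["pct_bleached"]) == [20.0, 50.0]

    def test_area_preferred_over_colony_in_mixed_group(self):
        df = records_frame([
            (1.0, 2.0, "2015-01-01", 5.0, 30.0, np.nan, np.nan, np.nan),
            (1.0, 2.0, "2015-01-01", 5.0, np.nan, 90, 100, np.nan),
        ])
        out = combine_replicates(df)
        assert out.loc[0, "pct_bleached"] == 30.0
        assert out.loc[0, "bleach_measure"] == "area"

    def test_group_date_is_earliest(self):
        df = records_frame([
            (1.0, 2.0, "2015-01-03", 5.0, 40.0, np.nan, np.nan, np.nan),
            (1.0, 2.0, "2015-01-01", 5.0, 60.0, np.nan, np.nan, np.nan),
        ])
        out = combine_replicates(df)
        assert out.loc[0, "date"] == pd.Timestamp("2015-01-01")

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(12):
            n = int(rng.integers(1, 4))
            for _ in range(n):
                rows.append((
                    round(float(rng.uniform(-5, 5)), 4), round(float(rng.uniform(100, 120)), 4),
                    "2015-01-01", 5.0, float(rng.uniform(0, 100)), np.nan, np.nan, np.nan,
                ))
        df = records_frame(rows)
        out1 = combine_replicates(df)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        out2 = combine_replicates(shuffled)
        pd.testing.assert_frame_equal(
            out1.drop(columns="source_id"), out2.drop(columns="source_id")
        )
        # idempotence: re-running on harmonized output changes nothing
        again = combine_replicates(
            out1.rename(columns={"pct_bleached": "pct_cover_bleached",
                                 "pct_mortality": "pct_cover_dead"})
            .assign(colonies_bleached_n=np.nan, colonies_total_N=np.nan,
                    colonies_dead_n=np.nan)
        )
        assert len(again) == len(out1)
        assert np.allclose(
            np.sort(again["pct_bleached"]), np.sort(out1["pct_bleached"])
        )


class TestColonyToArea:
    def test_area_weighting(self):
        assert colony_to_area([100.0, 0.0], [1.0, 3.0]) == 25.0

    def test_identity_when_uniform(self):
        assert colony_to_area([100.0] * 5, [0.3, 1, 2, 5, 9]) == pytest.approx(100.0)

    def test_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 100, 40)
        a = rng.uniform(0.1, 10, 40)
        assert colony_to_area(p, a) == pytest.approx(float(np.average(p, weights=a)))

    def test_zero_total_area_errors(self):
        with pytest.raises(ValueError):
            colony_to_area([10.0], [0.0])

    def test_pooled_proportion_equals_area_conversion_with_equal_areas(self):
        # colony proportion sum(n)/sum(N) == area-weighted mean of 0/100 flags
        flags = np.array([100.0, 0.0, 100.0, 100.0, 0.0])
        pooled = 100.0 * np.sum(flags > 0) / len(flags)
        assert colony_to_area(flags, np.ones(5)) == pytest.approx(pooled)


class TestCategories:
    @pytest.mark.parametrize("lo,hi,mid", [(11, 30, 20.5), (51, 100, 75.5), (40, 40, 40.0)])
    def test_midpoints(self, lo, hi, mid):
        assert midpoint_of_category(lo, hi) == mid

    def test_invalid_range_errors(self):
        with pytest.raises(ValueError):
            midpoint_of_category(30, 10)

    def test_dialect_lookup_applies_configured_ranges(self):
        df = pd.DataFrame({
            "program": ["RB", "RB", "XX"],
            "bleach_category": ["2", "4", "2"],
            "pct_cover_bleached": [np.nan, np.nan, np.nan],
        })
        dialects = {"RB": {"1": (1, 10), "2": (11, 30), "3": (31, 50), "4": (51, 100)}}
        out = apply_category_midpoints(df, dialects)
        assert out.loc[0, "pct_cover_bleached"] == 20.5
        assert out.loc[1, "pct_cover_bleached"] == 75.5
        assert np.isnan(out.loc[2, "pct_cover_bleached"])  # unknown program untouched


class TestBasins:
    @pytest.mark.parametrize(
        "lon,basin",
        [(150.0, "AP"), (180.0, "AP"), (-150.0, "AP"), (100.0, "AP"),
         (60.0, "IM"), (20.0, "IM"), (99.9, "IM"),
         (-80.0, "CA"), (0.0, "CA"), (-100.0, "CA"), (19.9, "CA")],
    )
    def test_boundary_membership(self, lon, basin):
        assert assign_basin(lon) == basin

    def test_vectorized(self):
        assert list(assign_basin(np.array([150.0, 60.0, -80.0]))) == ["AP", "IM", "CA"]


class TestBinarize:
    @pytest.mark.parametrize(
        "pct,mod,sev",
        [(10.0, False, False), (10.1, True, False), (50.0, True, False),
         (51.0, True, True), (0.0, False, False), (100.0, True, True)],
    )
    def test_strict_thresholds(self, pct, mod, sev):
        m, s = binarize_outcomes(pct)
        assert m is mod and s is sev

    def test_missing_gives_missing(self):
        m, s = binarize_outcomes(pd.Series([np.nan, 20.0]))
        assert m.isna().iloc[0] and bool(m.iloc[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_outcomes(pd.Series([101.0]))


class TestSummary:
    def test_arithmetic(self):
        df = pd.DataFrame({
            "moderate_bleach": pd.array([True] * 8 + [False] * 2, dtype="boolean"),
            "severe_bleach": pd.array([True] * 3 + [False] * 7, dtype="boolean"),
            "moderate_mortality": pd.array([None] * 10, dtype="boolean"),
            "severe_mortality": pd.array([None] * 10, dtype="boolean"),
        })
        out = survey_summary(df)
        assert out["frac_moderate_bleaching"] == 0.8
        assert out["frac_severe_bleaching"] == 0.3
        assert out["frac_moderate_mortality"] is None
        assert out["n_reporting_mortality"] == 0

    def test_denominator_excludes_missing(self):
        df = pd.DataFrame({
            "moderate_bleach": pd.array([True, None, False, True], dtype="boolean"),
            "severe_bleach": pd.array([False, None, False, False], dtype="boolean"),
            "moderate_mortality": pd.array([True, True, None, None], dtype="boolean"),
            "severe_mortality": pd.array([False, False, None, None], dtype="boolean"),
        })
        out = survey_summary(df)
        assert out["frac_moderate_bleaching"] == pytest.approx(2 / 3)
        assert out["frac_moderate_mortality"] == 1.0
        assert out["frac_moderate_bleaching_all_surveys"] == 0.5


class TestHarmonizedInvariants:
    def test_severe_implies_moderate_and_unique_basin_year(self, harmonized):
        sb = harmonized["severe_bleach"].fillna(False).astype(bool)
        mb = harmonized["moderate_bleach"].fillna(False).astype(bool)
        assert not (sb & ~mb).any()
        sm = harmonized["severe_mortality"].fillna(False).astype(bool)
        mm = harmonized["moderate_mortality"].fillna(False).astype(bool)
        assert not (sm & ~mm).any()
        assert harmonized["basin"].isin(["AP", "CA", "IM"]).all()
        assert harmonized["bleaching_year"].isin(["2014-15", "2015-16", "2016-17"]).all()

    def test_percentages_in_range(self, harmonized):
        p = harmonized["pct_bleached"].dropna()
        assert ((p >= 0) & (p <= 100)).all()
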