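"""Harmonize a heterogeneous batch of raw bleaching surveys.

The eight raw records below mix percent-cover and colony-count methods,
include replicate transects at one site, and one month-only date.  The
harmonizer combines replicates, imputes the missing day, assigns basins
and bleaching years, and binarizes outcomes at the >10% / >50% thresholds.
"""

import io

from reefstress.survey_db import harmonize, parse_surveys, survey_summary

RAW = """source_id,lat,lon,date,depth_m,pct_cover_bleached,colonies_bleached_n,colonies_total_N,pct_cover_dead,colonies_dead_n,method,program
a1,-5.1,150.2,2015-02-20,5,40,,,10,,transect,DemoA
a2,-5.1,150.2,2015-02-21,5,60,,,14,,transect,DemoA
b1,16.8,-88.1,2015-09,8,,18,60,,3,colony,DemoB
c1,-12.3,46.5,2016-04-02,3,8,,,0,,transect,DemoC
d1,21.4,-157.9,2015-08-14,12,85,,,55,,aerial,DemoD
e1,-17.5,178.0,2016-02-28,6,,70,100,,20,colony,DemoB
f1,5.5,73.2,2016-05-01,4,12,,,,,transect,DemoC
g1,25.1,-80.3,2014-09-15,2,30,,,5,,transect,DemoA
"""

records, rejected = parse_surveys(io.StringIO(RAW))
surveys = harmonize(records)
print(surveys[["lat", "lon", "date", "basin", "bleaching_year", "pct_bleached",
               "moderate_bleach", "severe_bleach", "n_replicates_combined"]].to_string())
print()
summary = survey_summary(surveys)
print(f"surveys after combining replicates: {summary['n_surveys']}")
print(f"moderate bleaching (>10%):          {summary['frac_moderate_bleaching']:.0%}")
print(f"severe bleaching (>50%):            {summary['frac_severe_bleaching']:.0%}")
# The two DemoA transects (40% and 60%, one day apart, same depth) merge to
# one 50% survey; the colony-count records use pooled n/N percentages.
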