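#!/usr/bin/env python
"""Statistical evaluation of motion features against NOTSS ratings.

Averages the 12-item ratings across raters, screens features for
normality (Lilliefors KS), estimates interrater reliability (two-way mixed
consistency ICC, mean measures), correlates each feature with the total
NOTSS score (Spearman), and fits covariate-adjusted regressions (bypass
minutes, 30-day morbidity) for the significant features.  Writes
associations.csv, regressions.csv and summary.json under results/pipeline/.
"""

import json
from pathlib import Path

from teammotion.io import read_covariates_csv, read_feature_table, read_ratings_csv
from teammotion.pipeline import PipelineConfig, _write_stats_outputs, run_stats

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "pipeline"


def main() -> None:
    features = read_feature_table(OUT / "features.csv")
    ratings = read_ratings_csv(COHORT / "ratings.csv")
    covariates = read_covariates_csv(COHORT / "covariates.csv")
    cfg = PipelineConfig(out_dir=str(OUT))
    result = run_stats(features, ratings, covariates, cfg)
    _write_stats_outputs(OUT, result)

    s = result["summary"]
    icc = s["icc"]["all_raters"]
    print(f"n = {s['n_cases']} cases; mean total NOTSS = "
          f"{s['notss_means']['total']:.2f}")
    print(f"ICC(3,k) over {icc['n_raters']} raters: {icc['icc']:.3f} "
          f"(95% CI {icc['ci_low']:.3f} to {icc['ci_high']:.3f}, "
          f"p = {icc['p_value']:.2g})")
    print("feature associations with total NOTSS (Spearman):")
    for a in s["associations"]:
        star = " *" if a["significant"] else ""
        print(f"  {a['feature']:28s} rho = {a['coefficient']:+.3f}  "
              f"p = {a['p_value']:.4f}{star}")
    if s["regressions"]:
        print("adjusted regressions (bypass minutes + 30-day morbidity):")
        for r in s["regressions"]:
            coef = r["params"][r["feature"]]
            print(f"  {r['feature']:28s} coef = {coef:+.4g}  "
                  f"adj R^2 = {r['adj_r2']:.3f}")


if __name__ == "__main__":
    main()
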