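#!/usr/bin/env python
"""From keypoints to per-case motion features.

Reads the simulated cohort's OpenPose-dialect files, associates anonymous
detections into per-member neck tracks, cleans them (confidence floor,
median+MAD outlier removal, bounded linear interpolation), and computes the
six per-case team motion features.  Writes tracks.csv and features.csv
under results/pipeline/.
"""

from pathlib import Path

import pandas as pd

from teammotion.io import write_feature_table, write_track_csv
from teammotion.pipeline import PipelineConfig, compute_features, extract_sessions
from teammotion.tracking import session_to_track_df

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "pipeline"


def main() -> None:
    cfg = PipelineConfig(keypoints_dir=str(COHORT / "keypoints"),
                         out_dir=str(OUT))
    sessions = extract_sessions(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    tracks = pd.concat([session_to_track_df(s) for s in sessions],
                       ignore_index=True)
    write_track_csv(tracks, OUT / "tracks.csv")
    features = compute_features(sessions, cfg)
    write_feature_table(features, OUT / "features.csv")
    print(f"extracted {len(sessions)} cases "
          f"({len(tracks)} cleaned samples) -> {OUT / 'tracks.csv'}")
    print(f"feature table -> {OUT / 'features.csv'}")
    with pd.option_context("display.width", 120):
        print(features.drop(columns="case_id").describe().loc[
            ["mean", "std", "min", "max"]].round(3))


if __name__ == "__main__":
    main()
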