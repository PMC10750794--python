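#!/usr/bin/env python
"""Extract both feature sets from the simulated cohort.

Per-exercise 15-feature vectors (time statistics + symptom-band powers of
the movement norm) feed the correlation analysis; sliding-window
(2.56 s / 50% overlap) multi-channel features feed the exploratory
embedding. Reads results/cohort/, writes results/features.csv and
results/windowed_features.csv.
"""

from pathlib import Path

import pandas as pd

from wristpd.features import segment_feature_table, windowed_features
from wristpd.io import read_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_cohort(ROOT / "cohort" / "sessions")
    seg = segment_feature_table(trials)
    seg.to_csv(ROOT / "features.csv", index=False, float_format="%.12g",
               lineterminator="\n")
    print(f"segment features: {len(seg)} rows "
          f"({seg.label_code.nunique()} exercise labels) -> features.csv")

    win = pd.concat([windowed_features(t) for t in trials], ignore_index=True)
    win.to_csv(ROOT / "windowed_features.csv", index=False, float_format="%.12g",
               lineterminator="\n")
    scored = win[win.score_item != ""]
    print(f"windowed features: {len(win)} windows, {win.shape[1] - 6} features, "
          f"{len(scored)} windows carry an item score -> windowed_features.csv")


if __name__ == "__main__":
    main()
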