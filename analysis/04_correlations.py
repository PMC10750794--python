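#!/usr/bin/env python
"""Correlate the digital indicators with the clinical item scores.

Pearson r (and two-sided p) between every per-segment feature and the
MDS-UPDRS item paired with its exercise, over the PD subjects' trials
(controls carry no clinical variance on most items and are excluded here,
matching a supervised-group analysis). Writes results/correlations.csv and
a heat-map of |r|; prints the strongest associations.
"""

from pathlib import Path

import pandas as pd

from wristpd.analysis import correlation_matrix, correlation_pivot
from wristpd.plots import correlation_heatmap

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "features.csv")
    supervised = table[table.group == "supervised"]
    tidy = correlation_matrix(supervised)
    tidy.to_csv(ROOT / "correlations.csv", index=False, float_format="%.12g",
                lineterminator="\n")
    correlation_heatmap(correlation_pivot(tidy, absolute=True),
                        ROOT / "correlations_heatmap.png")

    print(f"{len(tidy)} feature-item cells -> correlations.csv (+ heat map)")
    print("\nrest tremor (exercise 1 vs item 3.17), strongest features:")
    rest = tidy[tidy.exercise == 1].sort_values("r", key=abs, ascending=False)
    print(rest.head(5)[["feature", "r", "p", "n"]].to_string(index=False))
    print("\npronation-supination (exercise 6 vs item 3.6), strongest features:")
    prono = tidy[tidy.exercise == 6].sort_values("r", key=abs, ascending=False)
    print(prono.head(5)[["feature", "r", "p", "n"]].to_string(index=False))


if __name__ == "__main__":
    main()
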