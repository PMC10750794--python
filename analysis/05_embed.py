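#!/usr/bin/env python
"""Exploratory 2-D t-SNE embeddings of the windowed features.

Two views, brushed by clinical score: (A) rest-tremor windows mapped by the
rest-tremor item 3.17 (PD trials only), and (B) pronation-supination
windows mapped by the bradykinesia item 3.6 (PD + control trials, controls
at score 0). Writes results/embedding_*.csv and scatter plots.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wristpd.analysis import tsne_embed
from wristpd.features import SEGMENT_SCORE_ITEM
from wristpd.plots import embedding_scatter

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026

META = {"trial_id", "subject_id", "label_code", "window_index",
        "score_item", "score"}


def embed_view(win: pd.DataFrame, item: str, name: str) -> None:
    labels = [k for k, v in SEGMENT_SCORE_ITEM.items() if v == item]
    rows = win[win.label_code.isin(labels)].reset_index(drop=True)
    cols = [c for c in rows.columns if c not in META]
    res = tsne_embed(rows, cols, mapping_item=item, seed=SEED)
    df = res.coords.copy()
    df.insert(0, "row_id", np.arange(len(df)))
    df.to_csv(ROOT / f"embedding_{name}.csv", index=False, float_format="%.12g",
              lineterminator="\n")
    embedding_scatter(res.coords, ROOT / f"embedding_{name}.png",
                      title=f"t-SNE of {name} windows (brushed by item {item})")
    spread = df.groupby("score")[["dim1", "dim2"]].mean()
    print(f"{name}: embedded {len(df)} windows over scores "
          f"{sorted(df.score.dropna().unique())} -> embedding_{name}.csv")
    print(spread.round(1).to_string())


def main() -> None:
    win = pd.read_csv(ROOT / "windowed_features.csv", keep_default_na=False,
                      na_values=[""])
    win["score"] = pd.to_numeric(win["score"], errors="coerce")
    embed_view(win, "3.17", "rest_tremor")
    embed_view(win, "3.6", "pronosup")


if __name__ == "__main__":
    main()
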