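"""Severity-agreement statistics and exploratory embedding.

Two analyses quantify how well the digital indicators track clinical
severity:

* Pearson correlation between each per-segment feature and the MDS-UPDRS
  item score of the paired exercise (rest tremor <-> item 3.17, postural
  tremor <-> 3.15, finger tapping <-> 3.4, hand movements <-> 3.5,
  pronation-supination <-> 3.6, gait <-> 3.10). Hand-to-chest reaches have
  no standardized item and the sit-to-stand task yields too little signal,
  so both are excluded by default. p-values come from the t statistic with
  n-2 degrees of freedom, two-sided, and are reported unadjusted (a
  Benjamini-Hochberg option exists but defaults off).

* A 2-D t-SNE embedding of the windowed feature set, standardized per
  column, with the clinical score as the brushing variable for the plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.manifold import TSNE

#: Default exercise <-> clinical-item pairing for the correlation matrix.
EXERCISE_ITEM_PAIRING: dict[int, str] = {
    1: "3.17", 2: "3.15", 4: "3.4", 5: "3.5", 6: "3.6", 8: "3.10",
}

#: Exercises excluded from correlation (no standard item / too little data).
EXCLUDED_EXERCISES: tuple[int, ...] = (3, 7)


class UndefinedCorrelationError(ValueError):
    """Raised when one variable has zero variance (r undefined)."""


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p for paired samples.

    Pairs with a missing value in either variable are dropped; at least 3
    complete pairs and non-zero variance in both variables are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r, p = spstats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    exercise: int
    item: str
    r: float
    p: float
    n: int


def correlation_matrix(features: pd.DataFrame,
                       feature_cols: list[str] | None = None,
                       pairing: dict[int, str] = EXERCISE_ITEM_PAIRING,
                       exclude: tuple[int, ...] = EXCLUDED_EXERCISES,
                       bh_adjust: bool = False) -> pd.DataFrame:
    """Feature x paired-exercise Pearson matrix over a per-segment table.

    ``features`` is the per-segment feature table (one row per trial x
    exercise, with columns ``label_code``, ``score`` and the feature
    columns). Cells with zero score variance or fewer than 3 trials are
    marked missing (NaN r/p), never silently zero.

    Returns a tidy frame with columns feature, exercise, item, r, p, n.
    """
    if feature_cols is None:
        meta = {"trial_id", "subject_id", "group", "label_code", "score_item", "score"}
        feature_cols = [c for c in features.columns if c not in meta]
    rows = []
    for exercise, item in pairing.items():
        if exercise in exclude:
            continue
        sub = features[features["label_code"] == exercise]
        for feat in feature_cols:
            x = sub[feat].to_numpy(dtype=float)
            y = sub["score"].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            n = int(keep.sum())
            try:
                r, p = pearson(x, y)
            except (ValueError, UndefinedCorrelationError):
                r, p = np.nan, np.nan
            rows.append({"feature": feat, "exercise": exercise, "item": item,
                         "r": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def correlation_pivot(tidy: pd.DataFrame, absolute: bool = False) -> pd.DataFrame:
    """Feature-by-exercise r matrix (optionally |r|) for heat-map rendering."""
    mat = tidy.pivot(index="feature", columns="exercise", values="r")
    return mat.abs() if absolute else mat


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # columns: dim1, dim2, score
    mapping_item: str
    seed: int
    perplexity: float


def tsne_embed(features: pd.DataFrame, feature_cols: list[str],
               mapping_item: str = "3.17", *, seed: int = 0,
               perplexity: float = 30.0) -> EmbeddingResult:
    """Standardize the feature columns and embed in 2-D with t-SNE.

    ``features`` must carry a ``score`` column (healthy-control rows carry
    score 0). Deterministic under a fixed seed. Requires at least
    3 * perplexity rows (t-SNE's neighborhood constraint); the error
    suggests a feasible perplexity otherwise.
    """
    n = len(features)
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} rows is too few for perplexity {perplexity}; "
            f"use perplexity <= {max(1, (n - 1) // 3)}"
        )
    X = features[feature_cols].to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, col_mean)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                learning_rate="auto", max_iter=1000, random_state=seed)
    coords = tsne.fit_transform(X)
    out = pd.DataFrame({
        "dim1": coords[:, 0],
        "dim2": coords[:, 1],
        "score": features["score"].to_numpy() if "score" in features else np.nan,
    }, index=features.index)
    return EmbeddingResult(coords=out, mapping_item=mapping_item,
                           seed=seed, perplexity=perplexity)
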