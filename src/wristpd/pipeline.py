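"""End-to-end pipeline: simulate -> validate -> extract -> label ->
correlate -> embed, with file-based handoff between stages so each stage
can also run standalone on real session directories.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .analysis import correlation_matrix, correlation_pivot, tsne_embed
from .features import (
    DEFAULT_BANDS,
    WindowingConfig,
    segment_feature_table,
    windowed_features,
)
from .preprocess import FilterSpec, movement_norm
from .simulate import SimulationConfig, config_from_dict, config_to_dict, simulate_cohort
from .tremor import (
    TremorLabelConfig,
    calibrate_threshold,
    cohort_rest_window_powers,
    label_tremor,
)

log = logging.getLogger("wristpd")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    tremor: TremorLabelConfig = field(default_factory=TremorLabelConfig)
    calibrate_tremor_threshold: bool = True
    tsne_perplexity: float = 30.0
    tsne_mapping_item: str = "3.17"

    def validate(self) -> None:
        self.filter.validate(self.simulation.sampling_rate_hz)


_SECTION_KEYS = {"seed", "simulation", "filter", "windowing", "tremor",
                 "calibrate_tremor_threshold", "tsne_perplexity", "tsne_mapping_item"}


def config_from_json(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a nested dict, rejecting unknown keys."""
    unknown = set(d) - _SECTION_KEYS
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")

    def load_section(cls, section: dict):
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - known
        if bad:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
        return cls(**section)

    cfg = PipelineConfig(
        seed=int(d.get("seed", 0)),
        simulation=config_from_dict(d.get("simulation", {})),
        filter=load_section(FilterSpec, d.get("filter", {})),
        windowing=load_section(WindowingConfig, d.get("windowing", {})),
        calibrate_tremor_threshold=bool(d.get("calibrate_tremor_threshold", True)),
        tsne_perplexity=float(d.get("tsne_perplexity", 30.0)),
        tsne_mapping_item=str(d.get("tsne_mapping_item", "3.17")),
    )
    tremor_section = dict(d.get("tremor", {}))
    band = tremor_section.pop("band", None)
    tl = TremorLabelConfig(**tremor_section)
    if band is not None:
        from .features import BandDefinition
        tl.band = BandDefinition("tremor", float(band[0]), float(band[1]))
    cfg.tremor = tl
    # the global seed overrides the simulation section's seed
    cfg.simulation.seed = cfg.seed
    cfg.validate()
    return cfg


def config_to_json(cfg: PipelineConfig) -> dict:
    return {
        "seed": cfg.seed,
        "simulation": config_to_dict(cfg.simulation),
        "filter": dataclasses.asdict(cfg.filter),
        "windowing": dataclasses.asdict(cfg.windowing),
        "tremor": {
            "band": [cfg.tremor.band.f_lo, cfg.tremor.band.f_hi],
            "window_samples": cfg.tremor.window_samples,
            "overlap_fraction": cfg.tremor.overlap_fraction,
            "threshold": cfg.tremor.threshold,
            "min_duration_s": cfg.tremor.min_duration_s,
            "merge_gap_s": cfg.tremor.merge_gap_s,
        },
        "calibrate_tremor_threshold": cfg.calibrate_tremor_threshold,
        "tsne_perplexity": cfg.tsne_perplexity,
        "tsne_mapping_item": cfg.tsne_mapping_item,
    }


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write all artifacts under ``out_dir``.

    Returns the run report (also written as ``report.json``). Deterministic
    under a fixed seed: every data artifact is byte-identical across reruns.
    Stage timings go to ``timings.json`` so the data artifacts stay
    reproducible byte-for-byte.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(
        json.dumps(config_to_json(cfg), indent=1, sort_keys=True) + "\n")
    timings: dict[str, float] = {}

    def stage(name):
        log.info(json.dumps({"stage": name, "status": "start"}))
        return time.perf_counter()

    # --- simulate ---------------------------------------------------------
    t0 = stage("simulate")
    cohort = simulate_cohort(cfg.simulation, out_dir=out)
    timings["simulate"] = time.perf_counter() - t0

    # --- validate ---------------------------------------------------------
    t0 = stage("validate")
    problems = []
    sessions = out / "sessions"
    manifest = json.loads((sessions / "manifest.json").read_text())
    for d in manifest["trials"]:
        problems += sio.validate_trial_dir(sessions / d)
    if problems:
        raise RuntimeError("validate stage failed: " + "; ".join(problems))
    trials = [t for t, _ in cohort]
    timings["validate"] = time.perf_counter() - t0

    # --- extract ----------------------------------------------------------
    t0 = stage("extract")
    seg_table = segment_feature_table(trials, DEFAULT_BANDS, cfg.filter)
    _write_csv(seg_table, out / "features.csv")
    win_table = pd.concat(
        [windowed_features(t, cfg.windowing, bands=DEFAULT_BANDS,
                           filter_spec=cfg.filter) for t in trials],
        ignore_index=True)
    _write_csv(win_table, out / "windowed_features.csv")
    timings["extract"] = time.perf_counter() - t0

    # --- label ------------------------------------------------------------
    t0 = stage("label")
    tcfg = cfg.tremor
    calibrated_threshold = None
    if cfg.calibrate_tremor_threshold:
        powers, truth = cohort_rest_window_powers(cohort, tcfg, cfg.filter)
        if truth.any() and not truth.all():
            calibrated_threshold, _j = calibrate_threshold(powers, truth)
            tcfg = dataclasses.replace(tcfg, threshold=calibrated_threshold)
    labels_dir = out / "labels"
    labels_dir.mkdir(exist_ok=True)
    for trial in trials:
        trial_intervals = []
        for seg in trial.segments:
            if seg.label_code != 1 or seg.n_samples < tcfg.window_samples:
                continue
            norm = movement_norm(trial.signal.slice(seg.start, seg.end), cfg.filter)
            res = label_tremor(norm, tcfg)
            trial_intervals += [{"start_s": round(a, 6), "end_s": round(b, 6)}
                                for a, b in res.intervals]
        (labels_dir / f"{trial.trial_id}.json").write_text(
            json.dumps(trial_intervals, indent=1) + "\n")
    timings["label"] = time.perf_counter() - t0

    # --- correlate --------------------------------------------------------
    t0 = stage("correlate")
    tidy = correlation_matrix(seg_table)
    _write_csv(tidy, out / "correlations.csv")
    from .plots import correlation_heatmap
    correlation_heatmap(correlation_pivot(tidy, absolute=True),
                        out / "correlations_heatmap.png")
    timings["correlate"] = time.perf_counter() - t0

    # --- embed ------------------------------------------------------------
    t0 = stage("embed")
    item = cfg.tsne_mapping_item
    from .features import SEGMENT_SCORE_ITEM
    target_labels = [k for k, v in SEGMENT_SCORE_ITEM.items() if v == item]
    rows = win_table[win_table["label_code"].isin(target_labels)].reset_index(drop=True)
    meta_cols = {"trial_id", "subject_id", "label_code", "window_index",
                 "score_item", "score"}
    feat_cols = [c for c in rows.columns if c not in meta_cols]
    emb = tsne_embed(rows, feat_cols, mapping_item=item, seed=cfg.seed,
                     perplexity=min(cfg.tsne_perplexity, max(2.0, (len(rows) - 1) / 3)))
    emb_df = emb.coords.copy()
    emb_df.insert(0, "row_id", np.arange(len(emb_df)))
    _write_csv(emb_df, out / "embedding.csv")
    from .plots import embedding_scatter
    embedding_scatter(emb.coords, out / "embedding.png")
    timings["embed"] = time.perf_counter() - t0

    # --- report -----------------------------------------------------------
    all_labels = np.concatenate([t.labels() for t in trials])
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(all_labels, return_counts=True))}
    total = int(all_labels.size)
    rate = cfg.simulation.sampling_rate_hz
    share = {str(k): 100.0 * v / total for k, v in sorted(counts.items())}
    report = {
        "n_trials": len(trials),
        "n_subjects": len({t.subject_id for t in trials}),
        "samples_per_label": {str(k): v for k, v in sorted(counts.items())},
        "label_share_pct": share,
        "label_share_sum_pct": float(sum(share.values())),
        "hours_of_data": total / rate / 3600.0,
        "tremor_threshold": tcfg.threshold,
        "tremor_threshold_calibrated": calibrated_threshold is not None,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    (out / "timings.json").write_text(json.dumps(timings, indent=1) + "\n")
    log.info(json.dumps({"stage": "done", "report": report}))
    return report
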