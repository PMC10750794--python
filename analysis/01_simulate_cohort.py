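#!/usr/bin/env python
"""Generate the study-structured synthetic cohort.

Builds a cohort shaped like the monitored study population: 6 PD subjects
(supervised group, 46 weekly trials in total) plus 7 healthy controls
(56 trials), 102 single trials from 13 subjects. Each trial is one pass
through the 8-exercise protocol with rest and transition intervals,
severity-linked rest tremor and pronation-supination slowing, and paired
0-4 item scores. Output: session directories + manifest + ground truth
under results/cohort/.
"""

from pathlib import Path

from wristpd.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 2026

# 46 supervised trials over 6 PD subjects, 56 over 7 controls
SCHEDULE = [8, 8, 8, 8, 7, 7] + [8] * 7


def main() -> None:
    cfg = SimulationConfig(seed=SEED, n_subjects=6, n_controls=7,
                           trials_schedule=SCHEDULE)
    cohort = simulate_cohort(cfg, out_dir=OUT)
    n_pd = sum(t.group == "supervised" for t, _ in cohort)
    n_hc = sum(t.group == "control" for t, _ in cohort)
    hours = sum(len(t.signal) for t, _ in cohort) / cfg.sampling_rate_hz / 3600
    print(f"wrote {len(cohort)} trials ({n_pd} PD, {n_hc} control) "
          f"from {len({t.subject_id for t, _ in cohort})} subjects "
          f"({hours:.1f} h of signal) to {OUT}")


if __name__ == "__main__":
    main()
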