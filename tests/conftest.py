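import numpy as np
import pytest

from wristpd.simulate import SimulationConfig, simulate_cohort, simulate_trial

ZERO_SEVERITIES = {"3.17": 0, "3.15": 0, "3.4": 0, "3.5": 0, "3.6": 0, "3.10": 0}


def severities(**overrides):
    out = dict(ZERO_SEVERITIES)
    for item, score in overrides.items():
        out[item.replace("_", ".")] = score
    return out


@pytest.fixture(scope="session")
def recovery_cohort():
    """40-trial cohort with uniform severity spread, used for correlation
    recovery checks (simulated once per session)."""
    cfg = SimulationConfig(seed=11, n_subjects=10, trials_per_subject=4,
                           severity_probs=(0.2, 0.2, 0.2, 0.2, 0.2))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def two_class_cohort():
    """PD + control cohort for tremor-threshold calibration checks."""
    cfg = SimulationConfig(seed=7, n_subjects=6, n_controls=6, trials_per_subject=2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_tremor_trial():
    """Severity-4 rest tremor at exactly 5 Hz with zero sensor noise."""
    cfg = SimulationConfig(seed=3, n_subjects=1, trials_per_subject=1,
                           noise_sd=0.0, tremor_freq_hz=5.0)
    return simulate_trial(cfg, "s0", severities(**{"3_17": 4}))


def longest_rest_segment(trial):
    return max((s for s in trial.segments if s.label_code == 1),
               key=lambda s: s.n_samples)
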