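import numpy as np
import pytest
from scipy.signal import periodogram

from conftest import ZERO_SEVERITIES, longest_rest_segment, severities
from wristpd.features import segment_feature_table
from wristpd.io import read_cohort, read_trial
from wristpd.preprocess import movement_norm
from wristpd.simulate import SimulationConfig, simulate_cohort, simulate_trial


def rest_norm(trial):
    seg = longest_rest_segment(trial)
    return movement_norm(trial.signal.slice(seg.start, seg.end))


class TestSimulateTrial:
    def test_zero_severity_zero_noise_rest_is_pure_gravity(self):
        cfg = SimulationConfig(seed=1, noise_sd=0.0)
        trial, truth = simulate_trial(cfg, "s0", dict(ZERO_SEVERITIES))
        seg = longest_rest_segment(trial)
        g = np.linalg.norm(cfg.gravity_vector)
        raw = trial.signal.axes[seg.start:seg.end]
        np.testing.assert_allclose(np.linalg.norm(raw, axis=1), g, atol=1e-12)
        assert np.max(np.abs(rest_norm(trial).a)) < 1e-6
        assert truth.tremor_intervals == []

    def test_static_segment_variance_below_1e6(self):
        cfg = SimulationConfig(seed=2, noise_sd=0.0)
        trial, _ = simulate_trial(cfg, "s0", dict(ZERO_SEVERITIES))
        for seg in trial.segments:
            if seg.label_code != 1:
                continue
            norm = movement_norm(trial.signal.slice(seg.start, seg.end))
            assert norm.a.var() < 1e-6

    def test_severity4_tremor_power_concentrates_in_band(self, noise_free_tremor_trial):
        trial, truth = noise_free_tremor_trial
        assert truth.tremor_freq_hz == 5.0
        norm = rest_norm(trial)
        f, p = periodogram(norm.a, fs=trial.signal.sampling_rate_hz)
        frac = p[(f >= 4) & (f < 6)].sum() / p.sum()
        assert frac >= 0.95

    def test_same_seed_identical_streams(self):
        cfg = SimulationConfig(seed=42)
        sev = severities(**{"3_17": 2, "3_6": 3})
        t1, _ = simulate_trial(cfg, "s0", sev)
        t2, _ = simulate_trial(cfg, "s0", sev)
        np.testing.assert_array_equal(t1.signal.axes, t2.signal.axes)
        assert t1.segments == t2.segments

    def test_invalid_severity_rejected(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError):
            simulate_trial(cfg, "s0", severities(**{"3_17": 5}))
        with pytest.raises(ValueError):
            simulate_trial(cfg, "s0", {"3.17": -1})

    def test_nonpositive_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(sampling_rate_hz=0)
        with pytest.raises(ValueError):
            SimulationConfig(rest_between_s=-1)
        with pytest.raises(ValueError):
            SimulationConfig(exercise_durations_s={1: 0.0})

    def test_severity_map_invariants(self):
        cfg = SimulationConfig()
        assert cfg.severity_to_tremor_amp(0) == 0.0
        amps = [cfg.severity_to_tremor_amp(s) for s in range(5)]
        assert all(b >= a for a, b in zip(amps, amps[1:]))
        rates = [cfg.severity_to_cycle_rate(s) for s in range(5)]
        assert all(b < a for a, b in zip(rates, rates[1:]))

    def test_tremor_band_power_monotone_in_severity(self):
        from wristpd.features import BandDefinition, band_power

        band = BandDefinition("tremor", 3.5, 7.5)
        powers = []
        for score in range(5):
            cfg = SimulationConfig(seed=5, noise_sd=0.0, tremor_freq_hz=5.5)
            trial, _ = simulate_trial(cfg, "s0", severities(**{"3_17": score}))
            powers.append(band_power(rest_norm(trial), band))
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        assert powers[0] == pytest.approx(0.0, abs=1e-10)
        assert powers[4] > 100 * max(powers[0], 1e-12)

    def test_protocol_structure(self):
        cfg = SimulationConfig(seed=9)
        trial, _ = simulate_trial(cfg, "s0", dict(ZERO_SEVERITIES))
        codes = [s.label_code for s in trial.segments]
        for ex in range(2, 9):
            assert codes.count(ex) == 1
        assert codes.count(0) == 8  # one transition before each exercise
        # exercise durations respected
        rate = cfg.sampling_rate_hz
        for seg in trial.segments:
            if seg.label_code >= 2:
                expected = cfg.exercise_durations_s[seg.label_code]
                assert seg.n_samples == pytest.approx(expected * rate, abs=1)


class TestSimulateCohort:
    def test_single_trial_on_disk_with_manifest(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_subjects=1, trials_per_subject=1)
        simulate_cohort(cfg, out_dir=tmp_path)
        trials = read_cohort(tmp_path / "sessions")
        assert len(trials) == 1
        assert (tmp_path / "ground_truth.json").exists()

    def test_fig6b_cohort_sizes(self):
        # 6 PD subjects contributing 46 trials + 7 controls contributing 56
        # = 102 single trials from 13 subjects
        schedule = [8, 8, 8, 8, 7, 7] + [8] * 7
        cfg = SimulationConfig(seed=2, n_subjects=6, n_controls=7,
                               trials_schedule=schedule)
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 102
        subjects = {t.subject_id for t, _ in cohort}
        assert len(subjects) == 13
        pd_trials = [t for t, _ in cohort if t.group == "supervised"]
        hc_trials = [t for t, _ in cohort if t.group == "control"]
        assert len(pd_trials) == 46
        assert len(hc_trials) == 56
        assert all(t.scores["3.17"] == 0 for t in hc_trials)

    def test_byte_identical_files_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_subjects=1, trials_per_subject=2,
                               exercise_durations_s={k: 4.0 for k in range(1, 9)},
                               rest_between_s=3.0)
        simulate_cohort(cfg, out_dir=tmp_path / "a")
        simulate_cohort(cfg, out_dir=tmp_path / "b")
        for sub in sorted((tmp_path / "a" / "sessions").iterdir()):
            if sub.is_dir():
                other = tmp_path / "b" / "sessions" / sub.name
                assert (sub / "samples.csv").read_bytes() == \
                       (other / "samples.csv").read_bytes()

    def test_round_trip_preserves_features(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_subjects=1, trials_per_subject=1)
        cohort = simulate_cohort(cfg, out_dir=tmp_path)
        back = read_cohort(tmp_path / "sessions")
        tab_mem = segment_feature_table([t for t, _ in cohort])
        tab_disk = segment_feature_table(back)
        import pandas as pd

        pd.testing.assert_frame_equal(tab_mem, tab_disk)

    def test_severities_persist_across_weeks_without_jitter(self):
        cfg = SimulationConfig(seed=5, n_subjects=2, trials_per_subject=3,
                               week_jitter_p=0.0)
        cohort = simulate_cohort(cfg)
        by_subject = {}
        for t, _ in cohort:
            by_subject.setdefault(t.subject_id, []).append(t.scores)
        for scores in by_subject.values():
            assert all(s == scores[0] for s in scores)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(severity_probs=(0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            SimulationConfig(severity_probs=(-1, 1, 0, 0, 0))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(n_subjects=0, n_controls=0))
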