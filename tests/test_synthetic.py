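import numpy as np
import pytest

from hapticube.errors import GenerationError
from hapticube.preprocess import resample_trial, trim_trial
from hapticube.synthetic import (
    GroupPreset,
    calibrated_cell_pmf,
    generate_cohort,
    generate_session,
    published_presets,
)
from hapticube.touch import classify_explorative, count_touches, mean_active_cells, mean_smc
from hapticube.rotation import amount_of_rotation, relative_labels_per_sample
from hapticube.transitions import build_episodes


def _trial_frames(samples, ann):
    times = np.array([s.t for s in samples])
    lo = int(np.searchsorted(times, ann.t_start))
    hi = int(np.searchsorted(times, ann.t_end, side="right"))
    grid, _ = trim_trial(resample_trial(samples[lo:hi]))
    return grid, classify_explorative(grid)


class TestDeterminism:
    def test_same_seed_same_session(self):
        preset = published_presets()["LB"]
        s1, a1, _ = generate_session(preset, n_trials=1, seed=5)
        s2, a2, _ = generate_session(preset, n_trials=1, seed=5)
        assert len(s1) == len(s2)
        assert all(x == y for x, y in zip(s1, s2))
        assert a1 == a2

    def test_different_seed_differs(self):
        preset = published_presets()["LB"]
        s1, _, _ = generate_session(preset, n_trials=1, seed=5)
        s2, _, _ = generate_session(preset, n_trials=1, seed=6)
        assert any(x != y for x, y in zip(s1, s2))

    def test_cohort_reproducible(self):
        c1 = generate_cohort(n_per_group={"CB": 2, "SI": 2}, seed=9, n_trials=1)
        c2 = generate_cohort(n_per_group={"CB": 2, "SI": 2}, seed=9, n_trials=1)
        for (s1, _, sc1), (s2, _, sc2) in zip(c1, c2):
            assert sc1.participant_id == sc2.participant_id
            assert all(x == y for x, y in zip(s1, s2))


class TestPresetValidation:
    def test_smc_one_rejected(self):
        with pytest.raises(GenerationError):
            GroupPreset(target_active_cells=4.0, target_smc=1.0, total_rotation=100.0).validate()

    def test_smc_incompatible_with_cell_count(self):
        with pytest.raises(GenerationError, match="incompatible with target_active_cells"):
            GroupPreset(target_active_cells=2.0, target_smc=0.7, total_rotation=100.0).validate()

    def test_nonpositive_rotation_speed_rejected(self):
        with pytest.raises(GenerationError):
            GroupPreset(
                target_active_cells=4.0, target_smc=0.8, total_rotation=100.0, rotation_speed=0.0
            ).validate()

    def test_published_presets_carry_published_targets(self):
        presets = published_presets()
        assert presets["CB"].target_active_cells == 5.24
        assert presets["LB"].target_smc == 0.81
        assert presets["SI"].total_rotation == 710.0
        assert presets["CB"].accuracy == 0.72


class TestCalibration:
    def test_truncated_poisson_mean_is_exact(self):
        for target in (2.0, 4.32, 8.0, 12.0):
            pmf = calibrated_cell_pmf(target)
            assert pmf @ np.arange(1, 17) == pytest.approx(target, abs=1e-8)
            assert pmf.min() >= 0 and pmf.sum() == pytest.approx(1.0)


class TestParameterRecovery:
    def test_single_preset_recovery(self):
        preset = GroupPreset(
            target_active_cells=5.24, target_smc=0.77, total_rotation=150.0,
            n_episodes=6, trial_duration=900.0,
        )
        samples, anns, _ = generate_session(preset, n_trials=1, seed=11)
        _, frames = _trial_frames(samples, anns[0])
        assert frames.any_explored.sum() >= 2000
        assert mean_active_cells(frames) == pytest.approx(5.24, abs=0.15)
        assert mean_smc(frames) == pytest.approx(0.77, abs=0.02)


class TestNoiseFreeGroundTruth:
    def test_episode_sequence_recovered_exactly(self):
        preset = GroupPreset(
            target_active_cells=5.0, target_smc=0.8, total_rotation=400.0,
            n_episodes=8, trial_duration=40.0,
        )
        samples, anns, script = generate_session(preset, n_trials=1, seed=4, regular_sampling=True)
        for ann, trial in zip(anns, script.trials):
            grid, frames = _trial_frames(samples, ann)
            labels = relative_labels_per_sample(grid)
            episodes = build_episodes(frames, labels)
            measured = [e.face for e in episodes]
            assert measured == trial.faces

    def test_touch_onset_count_recovered(self):
        # large rotation target: every episode is preceded by a reorientation
        # phase, so activation and clearing events land on separate frames
        preset = GroupPreset(
            target_active_cells=5.0, target_smc=0.8, total_rotation=2000.0,
            n_episodes=8, trial_duration=40.0,
        )
        samples, anns, script = generate_session(preset, n_trials=1, seed=4, regular_sampling=True)
        for ann, trial in zip(anns, script.trials):
            _, frames = _trial_frames(samples, ann)
            assert count_touches(frames) == trial.onset_count

    def test_exploration_duration_near_scripted(self):
        preset = GroupPreset(
            target_active_cells=5.0, target_smc=0.8, total_rotation=300.0,
            n_episodes=6, trial_duration=60.0,
        )
        samples, anns, script = generate_session(preset, n_trials=1, seed=2)
        grid, _ = _trial_frames(samples, anns[0])
        from hapticube.touch import exploration_duration

        # scripted touched interval: trial minus the two 1 s low-activity ends
        scripted = script.trials[0].t_end - script.trials[0].t_start - 2.0
        assert exploration_duration(grid) == pytest.approx(scripted, abs=1.0)


class TestRotationControl:
    def test_monotone_in_scripted_total_rotation(self):
        measured = []
        for total in (100.0, 300.0, 500.0):
            preset = GroupPreset(
                target_active_cells=5.0, target_smc=0.8, total_rotation=total,
                n_episodes=8, trial_duration=60.0,
            )
            samples, anns, _ = generate_session(preset, n_trials=1, seed=13)
            grid, _ = _trial_frames(samples, anns[0])
            measured.append(amount_of_rotation(grid))
        assert measured[0] < measured[1] < measured[2]

    def test_script_records_axis_cumulative(self):
        preset = GroupPreset(
            target_active_cells=5.0, target_smc=0.8, total_rotation=300.0,
            n_episodes=6, trial_duration=60.0,
        )
        samples, anns, script = generate_session(preset, n_trials=1, seed=1)
        grid, _ = _trial_frames(samples, anns[0])
        measured = amount_of_rotation(grid)
        scripted = script.trials[0].max_axis_cumulative
        # the grid measurement composes consecutive motion segments inside one
        # 0.2 s step, so it can only lose path length relative to the script
        assert measured <= scripted * 1.01
        assert measured == pytest.approx(scripted, rel=0.10)


class TestCohort:
    def test_default_cohort_sizes(self, cohort42):
        groups = [script.group for _, _, script in cohort42]
        assert groups.count("CB") == 6 and groups.count("LB") == 10 and groups.count("SI") == 16

    def test_centered_jitter_realizes_group_targets(self, cohort42):
        presets = published_presets()
        for g in ("CB", "LB", "SI"):
            cells = [
                sc.preset.target_active_cells for _, _, sc in cohort42 if sc.group == g
            ]
            assert np.mean(cells) == pytest.approx(presets[g].target_active_cells, abs=1e-6)
            assert np.std(cells) > 0  # spread retained

    def test_duration_coupling_plants_negative_relation(self):
        base = GroupPreset(
            target_active_cells=4.5, target_smc=0.8, total_rotation=150.0,
            n_episodes=5, trial_duration=30.0,
        )
        cohort = generate_cohort(
            n_per_group={"SI": 10}, seed=3, presets={"SI": base},
            n_trials=1, jitter_sd=0.10, duration_cell_coupling=2.0,
        )
        cells = [sc.preset.target_active_cells for _, _, sc in cohort]
        durations = [sc.preset.trial_duration for _, _, sc in cohort]
        assert np.corrcoef(cells, durations)[0, 1] < -0.9
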