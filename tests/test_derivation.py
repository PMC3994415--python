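import math

import numpy as np
import pandas as pd
import pytest

from emgsynergy.derivation import (
    DegenerateDataError,
    JointMapping,
    MappingError,
    NormalizationError,
    RecordedTrial,
    fit_sinusoids,
    joint_space_error,
    map_joints,
    normalize_time,
    pca_contributions,
    synthesize_trials,
)
from emgsynergy.synergy import SynergyParams


def _wrap(d):
    return (d + math.pi) % (2 * math.pi) - math.pi


class TestSynthesizeTrials:
    def test_deterministic_given_seed(self, params):
        a = synthesize_trials(params, n_trials=3, seed=9)
        b = synthesize_trials(params, n_trials=3, seed=9)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.data, tb.data)

    def test_no_jitter_no_noise_trials_identical(self, params):
        trials = synthesize_trials(
            params, n_trials=4, speed_jitter=0.0, noise_sd=0.0, seed=0
        )
        n = min(len(t.data) for t in trials)
        for t in trials[1:]:
            pd.testing.assert_frame_equal(
                t.data.iloc[:n], trials[0].data.iloc[:n]
            )

    def test_zero_amplitude_joint_is_constant(self, params):
        (trial,) = synthesize_trials(params, n_trials=1, noise_sd=0.0, seed=0)
        col = trial.data["TJ3"]
        assert col.std() == pytest.approx(0.0, abs=1e-12)
        assert col.iloc[0] == pytest.approx(1.257)

    def test_minimum_cycles_enforced(self, params):
        with pytest.raises(ValueError):
            synthesize_trials(params, n_cycles=1)


class TestNormalizeTime:
    def test_double_speed_trial_matches_after_normalization(self, params):
        slow = synthesize_trials(
            params, n_trials=1, n_cycles=4, speed_jitter=0.0, noise_sd=0.0,
            seed=0, base_cadence=1.0,
        )
        fast = synthesize_trials(
            params, n_trials=1, n_cycles=4, speed_jitter=0.0, noise_sd=0.0,
            seed=0, base_cadence=2.0,
        )
        norm = normalize_time(slow + fast)
        a, b = norm[0].data, norm[1].data
        assert len(a) == len(b)
        assert np.max(np.abs(a.to_numpy() - b.to_numpy())) < 5e-3

    def test_already_normalized_trial_passes_through(self, params):
        trials = synthesize_trials(
            params, n_trials=1, n_cycles=4, speed_jitter=0.0, noise_sd=0.0, seed=0
        )
        norm = normalize_time(trials)
        # resampling the unit-cadence trial reproduces the same sinusoid
        t = np.arange(len(norm[0].data)) / norm[0].sampling_rate
        k = params.index("x_F2")
        expected = (
            params.amplitude[k] * np.sin(2 * math.pi * t + params.phase[k])
            + params.offset[k]
        )
        assert np.max(np.abs(norm[0].data["FJ2"].to_numpy() - expected)) < 5e-3

    def test_constant_column_survives_normalization(self, params):
        trials = synthesize_trials(params, n_trials=2, noise_sd=0.0, seed=0)
        norm = normalize_time(trials)
        for tr in norm:
            assert tr.data["TJ3"].std() == pytest.approx(0.0, abs=1e-9)

    def test_too_few_cycles_raises(self, params):
        trials = synthesize_trials(params, n_trials=1, n_cycles=2, seed=0)
        short = RecordedTrial(
            data=trials[0].data.iloc[:30].reset_index(drop=True),
            sampling_rate=trials[0].sampling_rate,
        )
        with pytest.raises(NormalizationError):
            normalize_time([short])


class TestPCA:
    def test_two_uncorrelated_equal_variance_joints_split_evenly(self, rng):
        n = 20000
        data = pd.DataFrame(
            {"a": rng.normal(0, 1.0, n), "b": rng.normal(0, 1.0, n)}
        )
        res = pca_contributions([RecordedTrial(data=data, sampling_rate=40.0)])
        np.testing.assert_allclose(res.variance_fractions, [0.5, 0.5], atol=0.02)

    def test_contributions_sum_to_hundred(self, params):
        trials = synthesize_trials(params, n_trials=3, seed=1)
        res = pca_contributions(normalize_time(trials))
        assert res.pc1_contributions.sum() == pytest.approx(100.0)
        assert np.all(res.pc1_contributions >= 0.0)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)

    def test_invariant_to_constant_joint_offsets(self, params):
        trials = synthesize_trials(params, n_trials=2, seed=2)
        shifted = [
            RecordedTrial(data=t.data + 5.0, sampling_rate=t.sampling_rate)
            for t in trials
        ]
        a = pca_contributions(trials)
        b = pca_contributions(shifted)
        np.testing.assert_allclose(
            a.variance_fractions, b.variance_fractions, atol=1e-9
        )
        np.testing.assert_allclose(
            a.pc1_contributions, b.pc1_contributions, atol=1e-6
        )

    def test_matches_sklearn_decomposition(self, params):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        trials = normalize_time(synthesize_trials(params, n_trials=3, seed=3))
        ours = pca_contributions(trials)
        data = pd.concat([t.data for t in trials], ignore_index=True)
        ref = sklearn_pca.PCA().fit(data.to_numpy())
        np.testing.assert_allclose(
            ours.variance_fractions, ref.explained_variance_ratio_, atol=1e-9
        )
        ref_contrib = 100 * np.abs(ref.components_[0]) / np.abs(ref.components_[0]).sum()
        np.testing.assert_allclose(ours.pc1_contributions, ref_contrib, atol=1e-6)

    def test_coordinated_motion_dominates_first_component(self, params):
        trials = synthesize_trials(params, noise_sd=0.01, seed=0)
        res = pca_contributions(normalize_time(trials))
        assert res.variance_fractions[0] > 0.70

    def test_degenerate_input_rejected(self):
        data = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateDataError):
            pca_contributions([RecordedTrial(data=data, sampling_rate=40.0)])


class TestFitSinusoids:
    def test_noiseless_data_recovered_exactly(self, params):
        trials = normalize_time(
            synthesize_trials(params, n_trials=2, noise_sd=0.0, seed=0)
        )
        fit = fit_sinusoids(trials)
        assert fit.frequency == pytest.approx(1.0, abs=1e-4)
        k = params.index("x_F1")
        row = fit.params.loc["FJ1b"]
        assert row["amplitude"] == pytest.approx(params.amplitude[k], abs=1e-4)
        assert _wrap(row["phase"] - params.phase[k]) == pytest.approx(0.0, abs=1e-3)
        assert row["offset"] == pytest.approx(params.offset[k], abs=1e-5)

    def test_constant_column_fits_with_zero_amplitude(self):
        tau = np.arange(400) / 100.0
        data = pd.DataFrame(
            {
                "ref": np.sin(2 * math.pi * tau),
                "const": np.full_like(tau, 0.7),
            }
        )
        fit = fit_sinusoids([RecordedTrial(data=data, sampling_rate=100.0)])
        row = fit.params.loc["const"]
        assert row["amplitude"] == pytest.approx(0.0, abs=1e-9)
        assert row["phase"] == pytest.approx(0.0)
        assert row["offset"] == pytest.approx(0.7)

    def test_residual_shrinks_with_noise(self, params):
        def resid(noise):
            trials = normalize_time(
                synthesize_trials(params, n_trials=3, noise_sd=noise, seed=5)
            )
            return fit_sinusoids(trials).residual_norm

        assert resid(0.0) < resid(0.01) < resid(0.05)


class TestJointSpaceError:
    def test_perfect_model_has_zero_error(self, params):
        trials = normalize_time(
            synthesize_trials(params, n_trials=1, noise_sd=0.0, seed=0)
        )
        fit = fit_sinusoids(trials)
        err = joint_space_error(fit, trials)
        assert err["FJ1b"] == pytest.approx(0.0, abs=1e-4)

    def test_ten_percent_bias_reads_point_one(self):
        tau = np.arange(500) / 100.0
        y = 0.5 * np.sin(2 * math.pi * tau) + 1.0
        data = pd.DataFrame({"j": y / 1.1})
        fit = fit_sinusoids(
            [RecordedTrial(data=pd.DataFrame({"j": y}), sampling_rate=100.0)]
        )
        err = joint_space_error(fit, [RecordedTrial(data=data, sampling_rate=100.0)])
        assert err["j"] == pytest.approx(0.10, abs=1e-3)

    def test_noisy_fit_error_small_for_well_offset_joints(self, params):
        trials = normalize_time(
            synthesize_trials(params, n_trials=5, noise_sd=0.02, seed=1)
        )
        fit = fit_sinusoids(trials)
        err = joint_space_error(fit, trials)
        # joints whose trajectories stay away from zero: the relative
        # metric is well conditioned there
        assert err["FJ1b"] < 0.05
        assert err["FJ2"] < 0.05


class TestMapJoints:
    def test_thumb_and_finger_assignments(self, params):
        trials = normalize_time(
            synthesize_trials(params, n_trials=2, noise_sd=0.0, seed=0)
        )
        fit = fit_sinusoids(trials)
        mapped = map_joints(fit)
        k = mapped.index("x_T1")
        kt = params.index("x_T1")
        assert mapped.amplitude[k] == pytest.approx(params.amplitude[kt], abs=1e-3)
        # constant-posture thumb joints carry configured offsets, zero motion
        for joint, offset in [("x_T3", 1.257), ("x_T4", 0.450)]:
            k = mapped.index(joint)
            assert mapped.amplitude[k] == 0.0
            assert mapped.offset[k] == offset
        # unmapped glove joints are dropped
        assert "FJ3" not in mapped.joints
        assert "FJ1a" not in mapped.joints

    def test_missing_source_joint_raises(self, params):
        trials = normalize_time(
            synthesize_trials(params, n_trials=1, noise_sd=0.0, seed=0)
        )
        fit = fit_sinusoids(trials)
        bad = JointMapping(pairs=(("nope", "x_F1"),))
        with pytest.raises(MappingError):
            map_joints(fit, bad)

    def test_duplicate_robot_targets_rejected(self):
        with pytest.raises(ValueError):
            JointMapping(pairs=(("FJ2", "x_F1"), ("FJ1b", "x_F1")))


class TestRoundTrip:
    def test_pipeline_recovers_the_generating_family(self, params):
        """Headline property: synthesize -> normalize -> fit -> map lands
        back on the generating amplitudes, phases and offsets."""
        trials = synthesize_trials(
            params, n_trials=10, n_cycles=5, speed_jitter=0.2,
            noise_sd=0.02, seed=17,
        )
        rec = map_joints(fit_sinusoids(normalize_time(trials)))
        for joint in ("x_F1", "x_F2", "x_T1", "x_T2"):
            k, kt = rec.index(joint), params.index(joint)
            assert rec.amplitude[k] == pytest.approx(
                params.amplitude[kt], rel=0.05
            )
            assert abs(_wrap(rec.phase[k] - params.phase[kt])) < 0.05
            assert rec.offset[k] == pytest.approx(params.offset[kt], abs=0.01)

    def test_trial_csv_roundtrip(self, params, tmp_path):
        (trial,) = synthesize_trials(params, n_trials=1, seed=4)
        path = tmp_path / "trial.csv"
        trial.to_csv(path)
        back = RecordedTrial.from_csv(path)
        assert back.sampling_rate == pytest.approx(trial.sampling_rate)
        np.testing.assert_allclose(
            back.data.to_numpy(), trial.data.to_numpy(), atol=1e-10
        )
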