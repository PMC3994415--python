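import copy
import math

import numpy as np
import pytest

from emgsynergy import run_trial, synthesize_emg
from emgsynergy.control import Gains
from emgsynergy.emg import BurstEvent
from emgsynergy.taskbench import (
    STUDY_GROUP_MEANS_S,
    backward_rotation_events,
    grip_cycle_schedule,
    percent_improvement,
    predicted_completion_time,
    reported_improvements,
    rhythmic_schedule,
    run_baseline_trial,
    summarize,
    sustained_schedule,
)


class TestPercentImprovement:
    @pytest.mark.parametrize(
        "t_ref, t_new, denom, expected",
        [
            ((11.04 + 11.69) / 2, 4.10, "new", 177),
            (6.06, 3.73, "new", 62),
            (6.06, 4.58, "new", 32),
            (4.58, 3.73, "reference", 19),
            (5.17, 4.10, "reference", 21),
            (5.04, 3.73, "reference", 26),
            (5.04, 4.58, "reference", 9),
        ],
    )
    def test_published_group_mean_arithmetic(self, t_ref, t_new, denom, expected):
        assert percent_improvement(t_ref, t_new, denominator=denom) == expected

    @pytest.mark.parametrize("denom", ["new", "reference"])
    def test_identity_is_zero(self, denom):
        assert percent_improvement(3.0, 3.0, denominator=denom) == 0

    def test_rounding_to_nearest_integer_both_signs(self):
        assert percent_improvement(2.6, 2.0, denominator="new") == 30
        assert percent_improvement(2.049, 2.0, denominator="new") == 2  # 2.45 -> 2
        assert percent_improvement(2.052, 2.0, denominator="new") == 3  # 2.6 -> 3
        assert percent_improvement(2.0, 2.6, denominator="new") == -23  # -23.08

    def test_rejects_nonpositive_times_and_bad_denominator(self):
        with pytest.raises(ValueError):
            percent_improvement(0.0, 1.0)
        with pytest.raises(ValueError):
            percent_improvement(1.0, -1.0)
        with pytest.raises(ValueError):
            percent_improvement(1.0, 1.0, denominator="mean")

    def test_reported_improvements_reproduce_printed_values(self):
        assert reported_improvements() == {
            "able_bodied_improvement_pct": 177,
            "threshold_vs_prosthesis_pct": 62,
            "rhythmic_vs_prosthesis_pct": 32,
            "threshold_vs_rhythmic_pct": 19,
            "force_feedback_improvement_pct": 21,
            "threshold_vs_myoelectric_pct": 26,
            "rhythmic_vs_myoelectric_pct": 9,
            "able_bodied_prosthesis_mean_s": 11.37,
        }


class TestBackwardEvents:
    def test_monotone_trace_has_none(self):
        assert backward_rotation_events(np.linspace(0, 6, 100)) == 0

    def test_single_dip_counts_once(self):
        trace = np.concatenate([np.linspace(0, 2, 50), [1.9], np.linspace(2, 3, 50)])
        assert backward_rotation_events(trace, tolerance=0.02) == 1

    def test_dip_within_tolerance_ignored(self):
        trace = np.concatenate([np.linspace(0, 2, 50), [1.99], np.linspace(2, 3, 50)])
        assert backward_rotation_events(trace, tolerance=0.02) == 0

    def test_two_separated_dips_count_twice(self):
        trace = np.concatenate(
            [np.linspace(0, 2, 30), [1.5], np.linspace(2, 4, 30), [3.2, 3.1], [4.5]]
        )
        assert backward_rotation_events(trace, tolerance=0.02) == 2

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            backward_rotation_events([0.0, 1.0], tolerance=0.0)


class TestSummarize:
    def _result(self, t):
        from emgsynergy.taskbench import TrialResult

        return TrialResult(
            completion_time=t,
            timed_out=t is None,
            beta_trace=np.array([0.0]),
            time=np.array([0.0]),
            backward_events=0,
            mapping_used="threshold",
        )

    def test_single_trial_has_zero_sd(self):
        table = summarize([self._result(2.0)], ["a"])
        assert table.loc[0, "sd_s"] == 0.0
        assert table.loc[0, "n"] == 1

    def test_group_means(self):
        table = summarize(
            [self._result(2.0), self._result(4.0), self._result(5.0)],
            ["a", "a", "b"],
        )
        assert len(table) == 2
        assert table.set_index("condition").loc["a", "mean_s"] == pytest.approx(3.0)

    def test_all_timeouts_in_group_rejected(self):
        with pytest.raises(ValueError):
            summarize([self._result(None)], ["a"])


class TestClosedLoop:
    def test_zero_emg_times_out_with_cylinder_untouched(self, config):
        trace = synthesize_emg([], duration=2.0, noise_sd=0.0, seed=0)
        res = run_trial(config, trace, mapping="threshold", timeout=2.0)
        assert res.timed_out
        assert res.completion_time is None
        # beta stays at zero up to micro-settling of the parked grip
        assert abs(res.final_beta) < 1e-3

    def test_trials_are_deterministic(self, config):
        trace = synthesize_emg(sustained_schedule(20.0), 20.0, noise_sd=0.02, seed=5)
        a = run_trial(config, trace, mapping="threshold")
        b = run_trial(config, trace, mapping="threshold")
        assert a.completion_time == b.completion_time
        np.testing.assert_array_equal(a.beta_trace, b.beta_trace)

    def test_threshold_completion_matches_geometry_oracle(
        self, config, threshold_trial
    ):
        predicted = predicted_completion_time(config)
        assert not threshold_trial.timed_out
        assert threshold_trial.completion_time == pytest.approx(predicted, rel=0.10)

    def test_threshold_beta_monotone_up_to_tolerance(self, threshold_trial):
        beta = threshold_trial.beta_trace
        drop = np.maximum.accumulate(beta) - beta
        assert drop.max() <= 0.02

    def test_faster_threshold_speed_completes_sooner(self, config):
        times = []
        for omega in (2.0, 3.0, 4.5):
            cfg = copy.deepcopy(config)
            cfg.synergy.omega = omega
            trace = synthesize_emg(sustained_schedule(40.0), 40.0, noise_sd=0.0, seed=0)
            times.append(run_trial(cfg, trace, mapping="threshold").completion_time)
        assert times[0] > times[1] > times[2]

    def test_rhythmic_cycles_complete_the_task(self, config):
        trace = synthesize_emg(rhythmic_schedule(60.0), 60.0, noise_sd=0.02, seed=3)
        res = run_trial(config, trace, mapping="rhythmic")
        assert not res.timed_out

    def test_poorly_timed_contraction_causes_backward_rotation(self, config):
        """An aborted mid-stroke contraction retraces the contact stroke
        backwards under the Rhythmic mapping — the failure mode the
        Threshold mapping is immune to."""
        # ramp up only to mid-stroke (|omega*E| < 1), then let go
        half = [
            BurstEvent("extensor", 0.2, 1.2, amplitude=0.25, rise_time=0.8),
        ]
        trace = synthesize_emg(half, duration=4.0, noise_sd=0.0, seed=0)
        res = run_trial(config, trace, mapping="rhythmic", timeout=4.0)
        assert res.backward_events >= 1
        trace2 = synthesize_emg(half, duration=4.0, noise_sd=0.0, seed=0)
        res2 = run_trial(config, trace2, mapping="threshold", timeout=4.0)
        assert res2.backward_events == 0

    def test_force_feedback_reduces_peak_tendon_force(self, config):
        def peak(k_gain):
            cfg = copy.deepcopy(config)
            cfg.gains = Gains(n=cfg.synergy.n, K=k_gain)
            trace = synthesize_emg(sustained_schedule(15.0), 15.0, noise_sd=0.0, seed=0)
            res = run_trial(
                cfg, trace, mapping="threshold", timeout=15.0, record_joints=True
            )
            return res.tendon_trace.max()

        peaks = [peak(k) for k in (0.0, 0.02, 0.05)]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_unknown_mapping_rejected(self, config):
        trace = synthesize_emg([], 0.1, seed=0)
        with pytest.raises(ValueError):
            run_trial(config, trace, mapping="telepathy")


class TestBaselines:
    @pytest.mark.parametrize("law", ["open_loop", "mc_hybrid"])
    def test_grip_cycles_complete_but_slower_than_synergy(
        self, config, law, threshold_trial
    ):
        trace = synthesize_emg(grip_cycle_schedule(60.0), 60.0, noise_sd=0.02, seed=5)
        res = run_baseline_trial(config, trace, law=law)
        assert not res.timed_out
        assert res.completion_time > threshold_trial.completion_time

    def test_zero_emg_baseline_never_rotates(self, config):
        trace = synthesize_emg([], duration=2.0, noise_sd=0.0, seed=0)
        res = run_baseline_trial(config, trace, law="open_loop", timeout=2.0)
        assert res.timed_out
        assert res.final_beta == 0.0


class TestCLI:
    def test_simulate_reports_completion(self, tmp_path):
        from click.testing import CliRunner

        from emgsynergy.cli import main

        runner = CliRunner()
        out = tmp_path / "trial.csv"
        result = runner.invoke(
            main,
            ["simulate", "--mapping", "threshold", "--seed", "1", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert "completed in" in result.output
        assert out.exists()

    def test_derive_writes_synergy_yaml(self, tmp_path, params):
        from click.testing import CliRunner

        from emgsynergy.cli import main
        from emgsynergy.derivation import synthesize_trials
        from emgsynergy.synergy import SynergyParams

        trials_dir = tmp_path / "trials"
        trials_dir.mkdir()
        for tr in synthesize_trials(params, n_trials=4, seed=0):
            tr.to_csv(trials_dir / f"trial_{tr.trial}.csv")
        out = tmp_path / "synergy.yaml"
        runner = CliRunner()
        result = runner.invoke(
            main, ["derive", "--trials", str(trials_dir), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        fitted = SynergyParams.from_yaml(out)
        k = fitted.index("x_F1")
        assert fitted.amplitude[k] == pytest.approx(0.635, rel=0.05)
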