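#!/usr/bin/env python
"""Gain-tuning sweep for the sliding-mode synergy controller.

The shipped defaults (K_P=8, K_I=2, K_D=0.2, C=12 V, epsilon=0.05,
K=0.02 rad/N) were frozen from this sweep on the nominal simulated plant:
for each candidate gain set it reports the free-space steady-state RMS
tracking error at the default Threshold speed and whether the closed task
loop completes.  Run it after changing plant constants to re-check that
the defaults still track inside the boundary layer:

    python scripts/tune_gains.py
"""

from __future__ import annotations

import copy
import itertools

import numpy as np

from emgsynergy import Gains, load_config, run_trial, synthesize_emg
from emgsynergy.taskbench import sustained_schedule


def rms_tracking_error(cfg) -> float:
    trace = synthesize_emg(sustained_schedule(15.0), 15.0, noise_sd=0.0, seed=0)
    res = run_trial(
        cfg, trace, mapping="threshold", timeout=15.0, target=1e9,
        record_joints=True, with_object=False,
    )
    err = res.desired_trace[3000:] - res.joint_trace[3000:]
    return float(np.sqrt((err**2).mean()))


def completes(cfg) -> bool:
    trace = synthesize_emg(sustained_schedule(30.0), 30.0, noise_sd=0.0, seed=0)
    return not run_trial(cfg, trace, mapping="threshold", timeout=30.0).timed_out


def main() -> None:
    base = load_config()
    print(f"{'K_P':>5} {'K_I':>5} {'K_D':>5} {'C':>5} | {'rms_err':>9} task")
    for k_p, k_i, k_d, c in itertools.product(
        (4.0, 8.0, 16.0), (0.0, 2.0), (0.0, 0.2), (6.0, 12.0)
    ):
        cfg = copy.deepcopy(base)
        cfg.gains = Gains(n=cfg.synergy.n, K=0.02, K_I=k_i, K_P=k_p, K_D=k_d, C=c)
        err = rms_tracking_error(cfg)
        ok = "ok" if completes(cfg) else "TIMEOUT"
        print(f"{k_p:5.1f} {k_i:5.1f} {k_d:5.1f} {c:5.1f} | {err:9.5f} {ok}")


if __name__ == "__main__":
    main()
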