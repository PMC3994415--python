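"""Two-channel surface-EMG envelope model.

The controller consumes the rectified, low-pass-filtered envelopes of an
antagonistic forearm muscle pair (extensor digitorum communis and flexor
carpi radialis).  Each channel is calibrated so that the envelope is 0 at
rest and 1 at a nominal contraction level; the two envelopes are then
differenced into a dual-polarity drive signal

    E = E_E - E_F

which is positive for extensor-dominant and negative for flexor-dominant
activity.  The synthesizer stands in for hardware preamplifier output: it
produces deterministic, seedable envelope traces (first-order rise/decay
toward scheduled plateaus plus truncated Gaussian noise) at the 1 kHz rate
the controller samples at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InvalidSignalError",
    "CalibrationError",
    "ScheduleError",
    "BurstEvent",
    "EMGTrace",
    "dual_polarity",
    "normalize_channel",
    "synthesize_emg",
    "load_schedule",
    "save_schedule",
]

CHANNELS = ("extensor", "flexor")

#: default envelope time constant (s); emulates rectify-and-low-pass dynamics
DEFAULT_RISE_TIME = 0.05


class InvalidSignalError(ValueError):
    """A non-finite sample was fed to a signal operation."""


class CalibrationError(ValueError):
    """Channel calibration levels are inconsistent (nominal <= rest)."""


class ScheduleError(ValueError):
    """An activity schedule contains contradictory overlapping entries."""


def dual_polarity(e_extensor, e_flexor):
    """Difference the two channel envelopes into the signed drive signal.

    Parameters may be scalars or arrays; the result is ``e_extensor -
    e_flexor``.  Raises :class:`InvalidSignalError` on non-finite input.
    """
    e_extensor = np.asarray(e_extensor, dtype=float)
    e_flexor = np.asarray(e_flexor, dtype=float)
    if not (np.all(np.isfinite(e_extensor)) and np.all(np.isfinite(e_flexor))):
        raise InvalidSignalError("EMG envelopes must be finite")
    out = e_extensor - e_flexor
    return float(out) if out.ndim == 0 else out


def normalize_channel(raw, rest_level: float, nominal_level: float):
    """Map a raw channel voltage onto the [0, 1] envelope scale.

    0 corresponds to the relaxed muscle (``rest_level``), 1 to the
    predetermined nominal contraction (``nominal_level``); values outside
    the calibration range are clipped.
    """
    if not nominal_level > rest_level:
        raise CalibrationError(
            f"nominal_level ({nominal_level}) must exceed rest_level ({rest_level})"
        )
    raw = np.asarray(raw, dtype=float)
    out = np.clip((raw - rest_level) / (nominal_level - rest_level), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BurstEvent:
    """One scheduled contraction: a plateau on a single channel."""

    channel: str
    onset: float
    offset: float
    amplitude: float
    rise_time: float = DEFAULT_RISE_TIME

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ScheduleError(f"unknown channel {self.channel!r}")
        if not (0.0 <= self.onset < self.offset):
            raise ScheduleError("burst must satisfy 0 <= onset < offset")
        if self.amplitude < 0 or self.rise_time <= 0:
            raise ScheduleError("amplitude must be >= 0 and rise_time > 0")


@dataclass
class EMGTrace:
    """Uniformly sampled two-channel envelope recording.

    ``channel_calibration`` keeps the rest/nominal voltage pair per channel
    so raw recordings can be re-normalized; synthesized traces are already
    on the normalized scale and carry the identity calibration.
    """

    sampling_rate: float
    e_extensor: np.ndarray
    e_flexor: np.ndarray
    channel_calibration: dict = field(
        default_factory=lambda: {c: (0.0, 1.0) for c in CHANNELS}
    )

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.e_extensor = np.asarray(self.e_extensor, dtype=float)
        self.e_flexor = np.asarray(self.e_flexor, dtype=float)
        if self.e_extensor.shape != self.e_flexor.shape:
            raise ValueError("channel arrays must have equal length")

    def __len__(self) -> int:
        return len(self.e_extensor)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate

    @property
    def e_diff(self) -> np.ndarray:
        """Dual-polarity signal E = E_E - E_F for every frame."""
        return dual_polarity(self.e_extensor, self.e_flexor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "e_extensor": self.e_extensor,
                "e_flexor": self.e_flexor,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EMGTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace samples must be uniformly spaced")
        return cls(
            sampling_rate=1.0 / dt[0],
            e_extensor=df["e_extensor"].to_numpy(),
            e_flexor=df["e_flexor"].to_numpy(),
        )


def _check_overlaps(events: Sequence[BurstEvent]) -> None:
    by_channel: dict[str, list[BurstEvent]] = {c: [] for c in CHANNELS}
    for ev in events:
        by_channel[ev.channel].append(ev)
    for channel, evs in by_channel.items():
        evs = sorted(evs, key=lambda e: e.onset)
        for a, b in zip(evs, evs[1:]):
            if b.onset < a.offset and not np.isclose(a.amplitude, b.amplitude):
                raise ScheduleError(
                    f"overlapping bursts with different amplitudes on {channel!r}"
                )


def synthesize_emg(
    profile: Sequence[BurstEvent],
    duration: float,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> EMGTrace:
    """Generate a deterministic two-channel envelope trace.

    Each scheduled burst drives its channel toward the plateau amplitude
    through a first-order lag (time constant = the burst's ``rise_time``;
    decay back to rest uses :data:`DEFAULT_RISE_TIME`).  Additive Gaussian
    noise (sd ``noise_sd``) is truncated at zero so rest segments stay
    non-negative with mean below ``noise_sd``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    _check_overlaps(profile)

    n = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate
    t = np.arange(n) * dt

    channels = {}
    for channel in CHANNELS:
        target = np.zeros(n)
        tau = np.full(n, DEFAULT_RISE_TIME)
        for ev in profile:
            if ev.channel != channel:
                continue
            mask = (t >= ev.onset) & (t < ev.offset)
            target[mask] = ev.amplitude
            tau[mask] = ev.rise_time
        env = np.empty(n)
        level = 0.0
        for i in range(n):
            level += (dt / tau[i]) * (target[i] - level)
            env[i] = level
        channels[channel] = env

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for channel in CHANNELS:
            noisy = channels[channel] + rng.normal(0.0, noise_sd, size=n)
            channels[channel] = np.maximum(noisy, 0.0)

    return EMGTrace(
        sampling_rate=sampling_rate,
        e_extensor=channels["extensor"],
        e_flexor=channels["flexor"],
    )


def save_schedule(events: Sequence[BurstEvent], path) -> None:
    """Write an activity schedule as YAML."""
    payload = [
        {
            "channel": ev.channel,
            "onset_s": float(ev.onset),
            "offset_s": float(ev.offset),
            "amplitude": float(ev.amplitude),
            "rise_time_s": float(ev.rise_time),
        }
        for ev in events
    ]
    Path(path).write_text(yaml.safe_dump({"schedule": payload}, sort_keys=False))


def load_schedule(path) -> list[BurstEvent]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        BurstEvent(
            channel=item["channel"],
            onset=item["onset_s"],
            offset=item["offset_s"],
            amplitude=item["amplitude"],
            rise_time=item.get("rise_time_s", DEFAULT_RISE_TIME),
        )
        for item in payload["schedule"]
    ]
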