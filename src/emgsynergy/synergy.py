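"""Sinusoidal grasp synergy and the two EMG-to-synergy mappings.

The synergy couples the six controlled joints of the hand (two first-finger
flexion joints and four thumb joints) to a single phase-like input E_M.
Every joint follows an equal-frequency sinusoid

    x_d[k] = A_k * sin(E_M + phi_k) + b_k

so one scalar drives temporally coordinated motion of the whole digit pair.
Two mappings turn the dual-polarity EMG signal into E_M:

* **Rhythmic** — contraction level sets the position along the stroke
  (E_R = pi*sat(omega*E) in the contact half); a switching bit delta,
  driven by a measured reference joint, remaps relaxation onto the return
  stroke so each contract-relax cycle ratchets the phase forward by 2*pi.
* **Threshold** — any activity above a deadband gamma advances (extensor
  dominant) or reverses (flexor dominant) an accumulated driver E_T at a
  fixed rate; the synergy input is omega*E_T, so omega alone sets speed.

The default parameter set shipped with the package is the sinusoid family
derived from human bottle-cap unscrewing recordings (see the derivation
module); amplitudes/phases/offsets are in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "JOINT_ORDER",
    "ConfigurationError",
    "SynergyParams",
    "RhythmicState",
    "ThresholdState",
    "desired_joints",
    "rhythmic_map",
    "update_delta",
    "threshold_update",
    "stroke_phase",
]

#: canonical joint ordering: first-finger PIP, MCP, then thumb IP, MCP
#: flexion and the two constant CMC posture joints.
JOINT_ORDER = ("x_F1", "x_F2", "x_T1", "x_T2", "x_T3", "x_T4")

# Default sinusoid family for the unscrewing synergy (rad).  x_T3/x_T4 are
# constant offsets that position the thumb opposite the first finger.
_DEFAULT_TABLE = {
    # joint: (amplitude, phase, offset)
    "x_F1": (0.635, -0.9425, 0.975),
    "x_F2": (0.319, 1.571, 0.900),
    "x_T1": (0.490, 1.971, 0.350),
    "x_T2": (0.400, 1.856, 0.000),
    "x_T3": (0.000, 0.000, 1.257),
    "x_T4": (0.000, 0.000, 0.450),
}

TWO_PI = 2.0 * math.pi


class ConfigurationError(ValueError):
    """Synergy/mapping configuration is inconsistent."""


@dataclass
class SynergyParams:
    """Per-joint sinusoid parameters plus the speed scaling ``omega``.

    ``omega`` is dimensionless contraction-to-phase scaling for the
    Rhythmic mapping and the phase rate (rad/s) for the Threshold mapping.
    """

    joints: tuple = JOINT_ORDER
    amplitude: np.ndarray = None
    phase: np.ndarray = None
    offset: np.ndarray = None
    omega: float = 3.0

    def __post_init__(self):
        if self.amplitude is None:
            self.amplitude = np.array([_DEFAULT_TABLE[j][0] for j in self.joints])
        if self.phase is None:
            self.phase = np.array([_DEFAULT_TABLE[j][1] for j in self.joints])
        if self.offset is None:
            self.offset = np.array([_DEFAULT_TABLE[j][2] for j in self.joints])
        self.joints = tuple(self.joints)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        n = len(self.joints)
        if not (self.amplitude.shape == self.phase.shape == self.offset.shape == (n,)):
            raise ConfigurationError("parameter arrays must match the joint list")
        if np.any(self.amplitude < 0):
            raise ConfigurationError("amplitudes must be non-negative")
        if not self.omega > 0:
            raise ConfigurationError("omega must be positive")

    @property
    def n(self) -> int:
        return len(self.joints)

    def index(self, joint: str) -> int:
        try:
            return self.joints.index(joint)
        except ValueError:
            raise ConfigurationError(f"unknown joint {joint!r}") from None

    def joint_value(self, joint: str, e_m: float) -> float:
        """Evaluate a single joint's sinusoid at synergy input ``e_m``."""
        k = self.index(joint)
        return float(
            self.amplitude[k] * math.sin(e_m + self.phase[k]) + self.offset[k]
        )

    def to_yaml(self, path) -> None:
        payload = {
            "omega": float(self.omega),
            "joints": [
                {
                    "joint": j,
                    "amplitude_rad": float(self.amplitude[k]),
                    "phase_rad": float(self.phase[k]),
                    "offset_rad": float(self.offset[k]),
                }
                for k, j in enumerate(self.joints)
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SynergyParams":
        payload = yaml.safe_load(Path(path).read_text())
        rows = payload["joints"]
        return cls(
            joints=tuple(r["joint"] for r in rows),
            amplitude=np.array([r["amplitude_rad"] for r in rows]),
            phase=np.array([r["phase_rad"] for r in rows]),
            offset=np.array([r["offset_rad"] for r in rows]),
            omega=float(payload.get("omega", 3.0)),
        )


def desired_joints(e_m: float, params: SynergyParams) -> np.ndarray:
    """Desired joint-angle vector x_d at synergy input ``e_m`` (rad).

    Componentwise ``A_k*sin(e_m + phi_k) + b_k``; 2*pi-periodic in ``e_m``
    and bounded by ``b_k +/- A_k`` per joint.
    """
    return params.amplitude * np.sin(e_m + params.phase) + params.offset


def _sat(v: float) -> float:
    return -1.0 if v < -1.0 else (1.0 if v > 1.0 else v)


def rhythmic_map(e: float, omega: float, delta: int) -> float:
    """Map the dual-polarity signal onto the synergy phase (Rhythmic mode).

    delta = 0 maps contraction level onto the contact half-stroke,
    delta = 1 remaps it onto the return half so that relaxing the muscle
    completes the cycle instead of retracing it::

        E_R = pi * sat(omega*e)                    (delta = 0)
        E_R = 2*pi*sgn(e) - pi*sat(omega*e)        (delta = 1)

    The result always lies in [-2*pi, 2*pi].
    """
    if delta not in (0, 1):
        raise ConfigurationError("delta must be 0 or 1")
    s = _sat(omega * e)
    if delta == 0:
        return math.pi * s
    sgn = 0.0 if e == 0 else math.copysign(1.0, e)
    return TWO_PI * sgn - math.pi * s


@dataclass
class RhythmicState:
    """Switching state for the Rhythmic mapping.

    ``delta`` alternates as the measured reference joint reaches the level
    it holds at synergy phase pi (contact-stroke end; 0 -> 1) and the level
    it holds at phase 0 (cycle start; 1 -> 0).  For a reference sinusoid
    with phi = -pi/2 these are exactly its maximum b+A and minimum b-A.
    Switches are edge-triggered (the joint must *enter* the tolerance band)
    so the state cannot chatter while parked at an extreme.
    """

    delta: int = 0
    e_r: float = 0.0
    reference_joint: str = "x_F2"
    switch_tolerance: float | None = None  # rad; default 2% of peak-to-peak
    _was_in_end: bool = field(default=False, repr=False)
    _was_in_start: bool = field(default=False, repr=False)
    _initialized: bool = field(default=False, repr=False)


def _switch_levels(state: RhythmicState, params: SynergyParams):
    k = params.index(state.reference_joint)
    a = params.amplitude[k]
    if a <= 0:
        raise ConfigurationError(
            "Rhythmic reference joint must have non-zero amplitude"
        )
    end_level = a * math.sin(math.pi + params.phase[k]) + params.offset[k]
    start_level = a * math.sin(params.phase[k]) + params.offset[k]
    tol = state.switch_tolerance
    if tol is None:
        tol = 0.02 * 2.0 * a
    return end_level, start_level, tol


def update_delta(
    x_ref_measured: float, state: RhythmicState, params: SynergyParams
) -> int:
    """Advance the delta switch from the measured reference joint angle.

    Returns the updated delta (also stored on ``state``).  Raises
    :class:`ConfigurationError` if the reference joint has zero amplitude.
    """
    end_level, start_level, tol = _switch_levels(state, params)
    in_end = abs(x_ref_measured - end_level) <= tol
    in_start = abs(x_ref_measured - start_level) <= tol
    if not state._initialized:
        # arm the bands: no switch fires until the joint first leaves and
        # re-enters a band (prevents a spurious switch at the rest pose)
        state._was_in_end = in_end
        state._was_in_start = in_start
        state._initialized = True
        return state.delta
    if state.delta == 0 and in_end and not state._was_in_end:
        state.delta = 1
    elif state.delta == 1 and in_start and not state._was_in_start:
        state.delta = 0
    state._was_in_end = in_end
    state._was_in_start = in_start
    return state.delta


@dataclass
class ThresholdState:
    """Accumulated phase driver for the Threshold mapping.

    ``e_t`` is time-like: it advances by ``step`` (default one 1 kHz sample
    period) whenever the channel difference magnitude exceeds the deadband
    ``gamma``, in the direction of the dominant channel.  The synergy input
    is ``omega * e_t``.
    """

    e_t: float = 0.0
    gamma: float = 0.1
    step: float = 1e-3

    def __post_init__(self):
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.step <= 0:
            raise ConfigurationError("step must be positive")


def threshold_update(
    e_extensor: float, e_flexor: float, state: ThresholdState
) -> float:
    """One deadband-gated increment of the Threshold driver E_T.

    Inside the deadband (|E_E - E_F| <= gamma) the driver holds; otherwise
    it moves one ``step`` toward the dominant channel.  Returns the updated
    ``e_t`` (also stored on ``state``).
    """
    diff = e_extensor - e_flexor
    if abs(diff) > state.gamma:
        state.e_t += state.step if diff > 0 else -state.step
    return state.e_t


def stroke_phase(e_m: float) -> str:
    """Classify a synergy phase as ``"contact"`` or ``"return"``.

    The contact stroke occupies phases [0, pi) mod 2*pi, the return stroke
    [pi, 2*pi); the half-open convention assigns each stroke boundary to
    exactly one stroke.
    """
    return "contact" if (e_m % TWO_PI) < math.pi else "return"
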