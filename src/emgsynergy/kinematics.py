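"""Planar forward kinematics of the digits and Cartesian fingertip paths.

Each digit is treated as a serial planar two-link chain in the digit's
sagittal plane: coordinates are (x, z) mm with the digit base at the
origin, extension along +x and palm-ward flexion rotating toward -z
(``flexion_sign = -1``).  Driving the joints along the synergy sinusoids
sweeps the fingertip around a closed, roughly elliptical curve; the halves
traversed during phases [0, pi) and [pi, 2*pi) are the contact and return
strokes, and their shared endpoints A (phase 0) and B (phase pi) bound the
arc over which the digit can engage the grasped object.

Segment lengths are configuration, not measurement: every property the
package verifies (closure, periodicity, frame independence, stroke
partition) holds for any positive lengths, and the defaults are simply
human-plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synergy import SynergyParams

__all__ = [
    "DigitGeometry",
    "FingertipPath",
    "finger_fk",
    "digit_jacobian",
    "fingertip_path",
]


@dataclass
class DigitGeometry:
    """Planar two-link digit: lengths in mm, base pose in the palm frame.

    ``joint_names`` gives (proximal, distal) synergy joints driving the
    chain; the default is the first finger's MCP (x_F2) and PIP (x_F1).
    For the thumb use x_T2/x_T1 with the constant CMC posture angles
    (x_T3, x_T4) folded into ``base_orientation``/``base_position``.
    """

    link_lengths: tuple = (45.0, 25.0)
    base_position: tuple = (0.0, 0.0)
    base_orientation: float = 0.0
    flexion_sign: int = -1
    joint_names: tuple = ("x_F2", "x_F1")

    def __post_init__(self):
        if any(l <= 0 for l in self.link_lengths):
            raise ValueError("link lengths must be positive")
        if self.flexion_sign not in (-1, 1):
            raise ValueError("flexion_sign must be +1 or -1")
        if len(self.link_lengths) != 2 or len(self.joint_names) != 2:
            raise ValueError("digit model is a two-link chain")

    def to_yaml(self, path) -> None:
        payload = {
            "link_lengths_mm": [float(l) for l in self.link_lengths],
            "base_position_mm": [float(v) for v in self.base_position],
            "base_orientation_rad": float(self.base_orientation),
            "flexion_sign": int(self.flexion_sign),
            "joint_names": list(self.joint_names),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "DigitGeometry":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            link_lengths=tuple(payload["link_lengths_mm"]),
            base_position=tuple(payload["base_position_mm"]),
            base_orientation=float(payload["base_orientation_rad"]),
            flexion_sign=int(payload["flexion_sign"]),
            joint_names=tuple(payload["joint_names"]),
        )


def finger_fk(x_proximal, x_distal, geom: DigitGeometry) -> np.ndarray:
    """Fingertip (x, z) position in mm for given flexion angles (rad).

    ``x_proximal`` rotates the whole chain about the digit base (MCP),
    ``x_distal`` adds distal flexion (PIP); both rotate palm-ward per
    ``geom.flexion_sign``.  Accepts scalars (returns shape ``(2,)``) or
    arrays (returns ``(n, 2)``).
    """
    l1, l2 = geom.link_lengths
    s = geom.flexion_sign
    th1 = geom.base_orientation + s * np.asarray(x_proximal, dtype=float)
    th2 = th1 + s * np.asarray(x_distal, dtype=float)
    x = geom.base_position[0] + l1 * np.cos(th1) + l2 * np.cos(th2)
    z = geom.base_position[1] + l1 * np.sin(th1) + l2 * np.sin(th2)
    return np.stack([x, z], axis=-1)


def digit_jacobian(x_proximal: float, x_distal: float, geom: DigitGeometry) -> np.ndarray:
    """2x2 Jacobian d(tip)/d(x_proximal, x_distal) in mm/rad."""
    l1, l2 = geom.link_lengths
    s = geom.flexion_sign
    th1 = geom.base_orientation + s * x_proximal
    th2 = th1 + s * x_distal
    d1 = np.array([-np.sin(th1), np.cos(th1)]) * l1
    d2 = np.array([-np.sin(th2), np.cos(th2)]) * l2
    col_prox = s * (d1 + d2)
    col_dist = s * d2
    return np.column_stack([col_prox, col_dist])


@dataclass
class FingertipPath:
    """Closed fingertip curve over one synergy cycle.

    ``points[i]`` is the tip at ``phases[i]``; the first and last points
    coincide.  ``endpoint_a``/``endpoint_b`` are sampled exactly at phases
    0 and pi — the shared endpoints of the contact and return arcs.
    """

    phases: np.ndarray
    points: np.ndarray
    endpoint_a: np.ndarray
    endpoint_b: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase_rad": self.phases,
                "x_mm": self.points[:, 0],
                "z_mm": self.points[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _digit_angles(params: SynergyParams, geom: DigitGeometry, phases):
    kp = params.index(geom.joint_names[0])
    kd = params.index(geom.joint_names[1])
    phases = np.asarray(phases, dtype=float)
    prox = params.amplitude[kp] * np.sin(phases + params.phase[kp]) + params.offset[kp]
    dist = params.amplitude[kd] * np.sin(phases + params.phase[kd]) + params.offset[kd]
    return prox, dist


def fingertip_path(
    params: SynergyParams, geom: DigitGeometry, n_samples: int = 256
) -> FingertipPath:
    """Sample the fingertip curve over one full synergy cycle.

    ``n_samples`` phase steps span [0, 2*pi]; the closing sample at 2*pi
    is appended so the returned curve is explicitly closed.  Endpoints A
    and B are evaluated exactly at phases 0 and pi, independent of the
    sampling density.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    phases = np.linspace(0.0, 2.0 * np.pi, n_samples + 1)
    prox, dist = _digit_angles(params, geom, phases)
    points = finger_fk(prox, dist, geom)

    def _tip_at(phase: float) -> np.ndarray:
        p, d = _digit_angles(params, geom, phase)
        return finger_fk(float(p), float(d), geom)

    return FingertipPath(
        phases=phases,
        points=points,
        endpoint_a=_tip_at(0.0),
        endpoint_b=_tip_at(np.pi),
    )
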