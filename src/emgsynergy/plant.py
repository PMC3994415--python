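"""Simulated tendon-driven hand plant and the rotatable task cylinder.

The physical study plant (a tendon-driven anthropomorphic hand turning a
35 mm cylinder on a potentiometer) is replaced by the minimal simulator
that exposes every signal the controller consumes: joint angles x, joint
velocities x_dot, tendon forces F_k and the cylinder angle beta.

* Joints are decoupled linear second-order systems,
  ``x_ddot = k_m*v - b_v*x_dot + tau_contact/J``, integrated with a
  semi-implicit Euler step (damping treated implicitly) at the 1 kHz EMG
  sampling rate for stability under stiff contact.
* Contact is kinematic no-slip: while the fingertip is inside the
  engagement band around the cylinder surface during a contact stroke,
  the tangential tip displacement rolls the cylinder,
  ``dbeta = s / r_cyl``.  Penetration of the surface produces a radial
  spring force that is reflected to the joints through the digit Jacobian
  and read out as non-negative tendon tensions.
* ``beta`` is the potentiometer angle; positive is the unscrewing
  direction and the timed task completes at ``beta >= 6`` rad.

All plant constants are stand-ins (none are published for the hardware);
closed-loop behaviour is therefore verified through properties and the
geometry oracle, never against hardware timings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import DigitGeometry, digit_jacobian, finger_fk, fingertip_path
from .synergy import SynergyParams

__all__ = [
    "IntegrationError",
    "PlantParams",
    "PlantState",
    "Cylinder",
    "Contact",
    "place_cylinder",
    "evaluate_contact",
    "step",
    "cylinder_update",
    "task_complete",
]


class IntegrationError(RuntimeError):
    """The plant state became non-finite."""


@dataclass
class PlantParams:
    """Per-joint dynamics and contact constants (mm / N / s units).

    ``inertia`` is J in kg*mm^2, ``damping`` b_v in 1/s, ``motor_gain``
    k_m in rad/s^2 per volt; with constant voltage an unloaded joint's
    velocity converges to ``k_m*v/b_v``.  ``contact_stiffness`` (N/mm)
    converts surface penetration into the radial contact force and
    ``tendon_moment_arm`` (mm) converts joint torque into tendon tension.
    """

    n: int = 6
    inertia: float = 1.0
    damping: float = 20.0
    motor_gain: float = 40.0
    voltage_limit: float = 12.0
    cylinder_radius: float = 17.5
    engagement_band: float = 3.0
    contact_stiffness: float = 0.1
    tendon_moment_arm: float = 10.0

    def __post_init__(self):
        for name in (
            "inertia",
            "damping",
            "motor_gain",
            "voltage_limit",
            "cylinder_radius",
            "engagement_band",
            "contact_stiffness",
            "tendon_moment_arm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantState:
    """Joint angles/velocities, tendon forces, cylinder angle and time."""

    x: np.ndarray
    x_dot: np.ndarray
    f: np.ndarray
    beta: float = 0.0
    t: float = 0.0

    @classmethod
    def at_rest(cls, x0) -> "PlantState":
        x0 = np.asarray(x0, dtype=float)
        return cls(
            x=x0.copy(),
            x_dot=np.zeros_like(x0),
            f=np.zeros_like(x0),
        )


@dataclass
class Cylinder:
    """Task object: center (x, z) mm, radius mm, and rotation sign.

    ``rotation_sign`` orients beta so that traversing the contact stroke
    in the direction of increasing synergy phase rotates the cylinder
    positive (unscrewing); screwing runs beta negative.
    """

    center: np.ndarray
    radius: float = 17.5
    rotation_sign: float = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def place_cylinder(
    params: SynergyParams,
    geom: DigitGeometry,
    radius: float = 17.5,
    bite: float = 2.5,
    anchor_phase: float = math.pi / 2.0,
) -> Cylinder:
    """Place the cylinder against the contact-stroke fingertip arc.

    The center is the least-squares fit of a circle of the given radius to
    the ideal contact-stroke path (so the whole arc grazes the surface),
    then nudged radially until the deepest path/surface interference does
    not exceed ``bite`` mm — the nominal grip depth that generates contact
    force.  The rotation sign is chosen so that forward traversal of the
    contact stroke (increasing synergy phase from ``anchor_phase``) yields
    positive beta, i.e. unscrewing.
    """
    path = fingertip_path(params, geom, n_samples=720)
    arc = path.points[path.phases < math.pi]

    from scipy.optimize import least_squares

    fit = least_squares(
        lambda c: np.linalg.norm(arc - c, axis=1) - radius, x0=arc.mean(axis=0)
    )
    center = fit.x
    for _ in range(8):  # cap the interference depth at `bite`
        dist = np.linalg.norm(arc - center, axis=1)
        deepest = int(np.argmin(dist))
        excess = (radius - dist[deepest]) - bite
        if excess <= 1e-9:
            break
        center = center - excess * (arc[deepest] - center) / dist[deepest]

    idx = int(np.argmin(np.abs(path.phases - anchor_phase)))
    p = path.points[idx]
    tangent = path.points[idx + 1] - path.points[idx - 1]
    radial = p - center
    spin = radial[0] * tangent[1] - radial[1] * tangent[0]
    rotation_sign = 1.0 if spin >= 0 else -1.0
    return Cylinder(center=center, radius=radius, rotation_sign=rotation_sign)


@dataclass
class Contact:
    """Instantaneous contact evaluation at the current joint state."""

    tip: np.ndarray
    engaged: bool = False
    penetration: float = 0.0
    force: np.ndarray = field(default_factory=lambda: np.zeros(2))
    torque: np.ndarray | None = None
    tendon: np.ndarray | None = None


def evaluate_contact(
    x: np.ndarray,
    params: SynergyParams,
    geom: DigitGeometry,
    cyl: Cylinder,
    plant: PlantParams,
    in_contact_stroke: bool,
    was_engaged: bool = False,
) -> Contact:
    """Fingertip/cylinder interaction at joint configuration ``x``.

    Engagement requires a contact-stroke phase and the tip near the
    cylinder *surface*, with hysteresis: contact starts when the tip
    touches or penetrates the surface by at most ``engagement_band``
    (``radius - band <= dist <= radius``) and persists while the tip
    stays within the band on either side.  A tip far inside the rim is
    treated as slipping past out of the contact plane, not as crushing
    the object.  Penetration produces a radial spring force
    ``contact_stiffness * depth`` mapped to joint torques through the
    digit Jacobian; the tendon readout is the load carried by the flexion
    tendon, ``max(0, -torque) / tendon_moment_arm`` — non-negative, since
    tendons pull but never push.
    """
    kp = params.index(geom.joint_names[0])
    kd = params.index(geom.joint_names[1])
    tip = finger_fk(x[kp], x[kd], geom)
    contact = Contact(tip=tip, torque=np.zeros(plant.n), tendon=np.zeros(plant.n))
    if not in_contact_stroke:
        return contact
    offset = tip - cyl.center
    dist = float(np.linalg.norm(offset))
    if dist == 0.0:
        return contact
    band = plant.engagement_band
    touching = cyl.radius - band <= dist <= cyl.radius
    near = abs(dist - cyl.radius) <= band
    if not (touching or (was_engaged and near)):
        return contact
    contact.engaged = True
    pen = max(0.0, cyl.radius - dist)
    contact.penetration = pen
    if pen > 0.0:
        normal = offset / dist
        force = plant.contact_stiffness * pen * normal  # pushes tip outward
        contact.force = force
        jac = digit_jacobian(x[kp], x[kd], geom)
        tau = jac.T @ force  # (proximal, distal) joint torques, N*mm
        contact.torque[kp] = tau[0]
        contact.torque[kd] = tau[1]
        contact.tendon[kp] = max(0.0, -tau[0]) / plant.tendon_moment_arm
        contact.tendon[kd] = max(0.0, -tau[1]) / plant.tendon_moment_arm
    return contact


def step(
    state: PlantState,
    v: np.ndarray,
    dt: float,
    params: PlantParams,
    contact: Contact | None = None,
) -> PlantState:
    """Advance the joint dynamics one semi-implicit Euler step.

    Voltages are clamped to ``+/- voltage_limit``.  Damping is treated
    implicitly (unconditionally stable for the free response); contact
    torque from ``contact`` enters explicitly.  Deterministic.
    """
    if not (0.0 < dt <= 0.010):
        raise ValueError("dt must be in (0, 10 ms]")
    if not (np.all(np.isfinite(state.x)) and np.all(np.isfinite(state.x_dot))):
        raise IntegrationError("plant state is non-finite")
    v = np.clip(np.asarray(v, dtype=float), -params.voltage_limit, params.voltage_limit)
    tau = contact.torque if contact is not None and contact.torque is not None else 0.0
    accel = params.motor_gain * v + tau / params.inertia
    x_dot = (state.x_dot + dt * accel) / (1.0 + dt * params.damping)
    x = state.x + dt * x_dot
    f = (
        contact.tendon.copy()
        if contact is not None and contact.tendon is not None
        else np.zeros_like(x)
    )
    return PlantState(x=x, x_dot=x_dot, f=f, beta=state.beta, t=state.t + dt)


def cylinder_update(
    state: PlantState,
    contact: Contact,
    tip_prev: np.ndarray,
    cyl: Cylinder,
) -> float:
    """Roll the cylinder under no-slip contact; returns the new beta.

    While engaged, the component of the fingertip displacement tangential
    to the cylinder surface advances beta by ``s / radius`` (signed by the
    cylinder's rotation convention); otherwise beta is unchanged.
    """
    if not contact.engaged:
        return state.beta
    offset = contact.tip - cyl.center
    dist = float(np.linalg.norm(offset))
    if dist == 0.0:
        return state.beta
    radial = offset / dist
    disp = contact.tip - tip_prev
    s = radial[0] * disp[1] - radial[1] * disp[0]
    return state.beta + cyl.rotation_sign * s / cyl.radius


def task_complete(state: PlantState, target: float = 6.0) -> bool:
    """True once the cylinder has rotated through the full task angle."""
    if target <= 0:
        raise ValueError("target must be positive")
    return state.beta >= target
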