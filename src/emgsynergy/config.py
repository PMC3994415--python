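"""Assembled simulation configuration and YAML (de)serialization.

A :class:`SimConfig` bundles everything a closed-loop trial needs: the
synergy parameter family, controller gains, plant constants, finger
geometry, cylinder placement, EMG-mapping settings and task constants.
The package ships its defaults in ``data/default_config.yaml``; user
configs only need to override the keys they change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .control import Gains, MCControllerConfig, OpenLoopConfig
from .kinematics import DigitGeometry
from .plant import Cylinder, PlantParams, place_cylinder
from .synergy import SynergyParams

__all__ = ["MappingConfig", "TaskConfig", "BaselineConfig", "SimConfig", "load_config"]


@dataclass
class MappingConfig:
    """EMG-to-synergy mapping settings shared by both modes."""

    gamma: float = 0.1
    reference_joint: str = "x_F2"
    switch_tolerance: float | None = None  # rad; None -> 2% of peak-to-peak


@dataclass
class TaskConfig:
    """Timed-rotation task constants."""

    target: float = 6.0
    timeout: float = 60.0
    backward_tolerance: float = 0.02


@dataclass
class BaselineConfig:
    """One-DOF baseline hands: control laws plus the wrench-style arm model.

    With a single-DOF hand the object can only be rotated by gripping it
    and turning the whole arm; ``arm_rate`` (rad/s) and ``wrist_excursion``
    (rad per re-grasp) model that outer loop.
    """

    open_loop: OpenLoopConfig = field(default_factory=OpenLoopConfig)
    mc: MCControllerConfig = field(default_factory=MCControllerConfig)
    arm_rate: float = 1.0
    wrist_excursion: float = 1.0
    grip_threshold: float = 1.0
    closure_max: float = 1.2
    grip_stiffness: float = 20.0  # N per unit closure beyond the grip point


@dataclass
class SimConfig:
    """Complete closed-loop simulation configuration."""

    synergy: SynergyParams = field(default_factory=SynergyParams)
    gains: Gains = field(default_factory=Gains)
    plant: PlantParams = field(default_factory=PlantParams)
    finger: DigitGeometry = field(default_factory=DigitGeometry)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    baselines: BaselineConfig = field(default_factory=BaselineConfig)
    cylinder_bite: float = 2.5
    cylinder_anchor_phase: float = math.pi / 2.0
    deriv_tau: float = 0.02

    def make_cylinder(self) -> Cylinder:
        """Place the task cylinder against the nominal fingertip path."""
        return place_cylinder(
            self.synergy,
            self.finger,
            radius=self.plant.cylinder_radius,
            bite=self.cylinder_bite,
            anchor_phase=self.cylinder_anchor_phase,
        )


def _synergy_from_dict(d: dict) -> SynergyParams:
    rows = d["joints"]
    return SynergyParams(
        joints=tuple(r["joint"] for r in rows),
        amplitude=np.array([r["amplitude_rad"] for r in rows]),
        phase=np.array([r["phase_rad"] for r in rows]),
        offset=np.array([r["offset_rad"] for r in rows]),
        omega=float(d.get("omega", 3.0)),
    )


def _config_from_dict(d: dict) -> SimConfig:
    cfg = SimConfig()
    if "synergy" in d:
        cfg.synergy = _synergy_from_dict(d["synergy"])
    if "controller" in d:
        c = d["controller"]
        cfg.gains = Gains(
            n=cfg.synergy.n,
            K=c.get("K", 0.02),
            K_I=c.get("K_I", 2.0),
            K_P=c.get("K_P", 8.0),
            K_D=c.get("K_D", 0.2),
            C=c.get("C", 12.0),
            epsilon=c.get("epsilon", 0.05),
        )
        cfg.deriv_tau = float(c.get("deriv_tau_s", 0.02))
    else:
        cfg.gains = Gains(n=cfg.synergy.n)
    if "plant" in d:
        p = d["plant"]
        cfg.plant = PlantParams(
            n=cfg.synergy.n,
            inertia=p.get("inertia", 1.0),
            damping=p.get("damping", 20.0),
            motor_gain=p.get("motor_gain", 40.0),
            voltage_limit=p.get("voltage_limit", 12.0),
            cylinder_radius=p.get("cylinder_radius_mm", 17.5),
            engagement_band=p.get("engagement_band_mm", 3.0),
            contact_stiffness=p.get("contact_stiffness_n_per_mm", 0.1),
            tendon_moment_arm=p.get("tendon_moment_arm_mm", 10.0),
        )
    else:
        cfg.plant = PlantParams(n=cfg.synergy.n)
    if "finger" in d:
        g = d["finger"]
        cfg.finger = DigitGeometry(
            link_lengths=tuple(g.get("link_lengths_mm", (45.0, 25.0))),
            base_position=tuple(g.get("base_position_mm", (0.0, 0.0))),
            base_orientation=float(g.get("base_orientation_rad", 0.0)),
            flexion_sign=int(g.get("flexion_sign", -1)),
            joint_names=tuple(g.get("joint_names", ("x_F2", "x_F1"))),
        )
    if "mapping" in d:
        m = d["mapping"]
        tol = m.get("switch_tolerance_rad")
        cfg.mapping = MappingConfig(
            gamma=float(m.get("gamma", 0.1)),
            reference_joint=m.get("reference_joint", "x_F2"),
            switch_tolerance=None if tol is None else float(tol),
        )
    if "task" in d:
        t = d["task"]
        cfg.task = TaskConfig(
            target=float(t.get("target_rad", 6.0)),
            timeout=float(t.get("timeout_s", 60.0)),
            backward_tolerance=float(t.get("backward_tolerance_rad", 0.02)),
        )
    if "cylinder" in d:
        c = d["cylinder"]
        cfg.cylinder_bite = float(c.get("bite_mm", 2.5))
        cfg.cylinder_anchor_phase = float(c.get("anchor_phase_rad", math.pi / 2.0))
    if "baselines" in d:
        b = d["baselines"]
        cfg.baselines = BaselineConfig(
            open_loop=OpenLoopConfig(C_IL=float(b.get("open_loop", {}).get("C_IL", 10.0))),
            mc=MCControllerConfig(
                C_MC=float(b.get("mc", {}).get("C_MC", 10.0)),
                weights=tuple(b.get("mc", {}).get("weights", (-1.0, 0.0, 0.05, 0.02))),
                epsilon_MC=float(b.get("mc", {}).get("epsilon_MC", 0.2)),
            ),
            arm_rate=float(b.get("arm_rate_rad_s", 1.0)),
            wrist_excursion=float(b.get("wrist_excursion_rad", 1.0)),
            grip_threshold=float(b.get("grip_threshold", 1.0)),
            closure_max=float(b.get("closure_max", 1.2)),
            grip_stiffness=float(b.get("grip_stiffness_n", 20.0)),
        )
    return cfg


def load_config(path=None) -> SimConfig:
    """Load a YAML config; with no path, load the packaged defaults."""
    if path is None:
        text = (
            resources.files("emgsynergy").joinpath("data/default_config.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return _config_from_dict(yaml.safe_load(text) or {})
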