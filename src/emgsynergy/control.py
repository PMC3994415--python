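"""Control laws: PID sliding-mode synergy tracking and the two baselines.

The synergy controller drives each joint toward its sinusoid with a
saturated sliding-mode law on a PID manifold,

    e = x_d - x - K*F          (tendon-force feedback backs the digit off)
    V = -C * sat(K_I*int(e) + K_P*e + K_D*de/dt)

where sat(s) = clamp(s/epsilon, -1, 1) realizes a boundary layer of width
epsilon that linearizes the law near the manifold and suppresses chatter.
|V| is bounded by the per-joint voltage cap C by construction.  The force
gain K (rad/N) converts measured tendon tension into a position back-off,
increasing closed-loop compliance on contact.

Two baseline laws are included for benchmarking: a proportional open-loop
drive (V = C_IL * E) as used on multi-articulated prostheses without
sensor feedback, and a configurable hybrid force-velocity sliding-mode
form (V = -C_MC * sat(S_MC)) whose manifold is a weighted sum of EMG,
position, velocity and grip-force terms.  The published description of the
latter gives only this outer form, so the manifold weights are explicit
configuration rather than fixed constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gains",
    "MCControllerConfig",
    "OpenLoopConfig",
    "error_vector",
    "sat",
    "sliding_mode_voltage",
    "open_loop_voltage",
    "mc_hybrid_voltage",
    "SlidingModeController",
]


def _diag(value, n: int) -> np.ndarray:
    """Broadcast a scalar or per-joint sequence to an (n,) gain vector."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"gain vector must be scalar or length {n}")
    return arr.copy()


@dataclass
class Gains:
    """Diagonal gain set for the synergy sliding-mode controller.

    All entries are per-joint (scalars broadcast).  Defaults were tuned
    once on the nominal simulated plant and frozen (see
    ``scripts/tune_gains.py``); they are reproducibility anchors, not
    hardware values.
    """

    n: int = 6
    K: np.ndarray = 0.02      # tendon-force feedback, rad/N
    K_I: np.ndarray = 2.0
    K_P: np.ndarray = 8.0
    K_D: np.ndarray = 0.2
    C: np.ndarray = 12.0      # voltage bound, V
    epsilon: np.ndarray = 0.05  # boundary-layer width

    def __post_init__(self):
        for name in ("K", "K_I", "K_P", "K_D", "C", "epsilon"):
            setattr(self, name, _diag(getattr(self, name), self.n))
        if np.any(self.C <= 0) or np.any(self.epsilon <= 0):
            raise ValueError("C and epsilon must be positive")
        for name in ("K", "K_I", "K_P", "K_D"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MCControllerConfig:
    """Stand-in manifold for the hybrid force-velocity baseline.

    ``weights`` multiply (E, x, x_dot, F_N) into the scalar manifold S_MC.
    """

    C_MC: float = 10.0
    weights: tuple = (-1.0, 0.0, 0.05, 0.02)
    epsilon_MC: float = 0.2

    def __post_init__(self):
        if self.C_MC <= 0 or self.epsilon_MC <= 0:
            raise ValueError("C_MC and epsilon_MC must be positive")


@dataclass
class OpenLoopConfig:
    """Proportional open-loop EMG drive (volts per unit dual-polarity EMG)."""

    C_IL: float = 10.0

    def __post_init__(self):
        if self.C_IL <= 0:
            raise ValueError("C_IL must be positive")


def error_vector(x_d, x, f, gains: Gains) -> np.ndarray:
    """Tracking error with tendon-force feedback: e = x_d - x - K*f."""
    x_d = np.asarray(x_d, dtype=float)
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if not (x_d.shape == x.shape == f.shape == (gains.n,)):
        raise ValueError("x_d, x, f must all have shape (n,)")
    return x_d - x - gains.K * f


def sat(s, epsilon):
    """Boundary-layer saturation: clamp(s/epsilon, -1, 1) (elementwise)."""
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any(epsilon <= 0):
        raise ValueError("epsilon must be positive")
    out = np.clip(np.asarray(s, dtype=float) / epsilon, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def sliding_mode_voltage(e, e_int, e_dot, gains: Gains) -> np.ndarray:
    """Stateless evaluation of the sliding-mode law.

    V = -C * sat(K_I*e_int + K_P*e + K_D*e_dot), elementwise per joint.
    """
    e = np.asarray(e, dtype=float)
    e_int = np.asarray(e_int, dtype=float)
    e_dot = np.asarray(e_dot, dtype=float)
    manifold = gains.K_I * e_int + gains.K_P * e + gains.K_D * e_dot
    return -gains.C * sat(manifold, gains.epsilon)


def open_loop_voltage(e: float, cfg: OpenLoopConfig) -> float:
    """Open-loop baseline: V = C_IL * E."""
    return cfg.C_IL * e


def mc_hybrid_voltage(
    e_emg: float, x_m1: float, x_m1_dot: float, f_n: float, cfg: MCControllerConfig
) -> float:
    """Hybrid force-velocity baseline: V = -C_MC * sat(S_MC).

    S_MC is the configured weighted sum of the EMG drive, measured
    position, velocity and normal grip force; |V| <= C_MC always.
    """
    w_e, w_x, w_v, w_f = cfg.weights
    s_mc = w_e * e_emg + w_x * x_m1 + w_v * x_m1_dot + w_f * f_n
    return -cfg.C_MC * sat(s_mc, cfg.epsilon_MC)


class SlidingModeController:
    """Stateful wrapper: integrator with anti-windup + filtered derivative.

    The integrator only accumulates while the manifold is inside the
    boundary layer (integration halts under saturation, preventing windup
    limit cycles at stroke reversals).  The error derivative is a filtered
    finite difference with time constant ``deriv_tau`` (default 20 ms).
    ``drive_polarity`` is the sign applied when the voltage law is wired
    to a plant whose positive motor gain increases the joint angle; the
    law itself is V = -C*sat(.), so the drive stage flips the sign.
    """

    def __init__(
        self,
        gains: Gains,
        dt: float,
        deriv_tau: float = 0.02,
        drive_polarity: int = -1,
    ):
        if dt <= 0 or deriv_tau <= 0:
            raise ValueError("dt and deriv_tau must be positive")
        self.gains = gains
        self.dt = dt
        self.deriv_tau = deriv_tau
        self.drive_polarity = drive_polarity
        self.reset()

    def reset(self) -> None:
        n = self.gains.n
        self.e_int = np.zeros(n)
        self.e_dot = np.zeros(n)
        self._e_prev: np.ndarray | None = None

    def step(self, x_d, x, f) -> np.ndarray:
        """One control-law evaluation; returns the voltage law V (n,)."""
        g = self.gains
        e = error_vector(x_d, x, f, g)
        if self._e_prev is None:
            raw_dot = np.zeros(g.n)
        else:
            raw_dot = (e - self._e_prev) / self.dt
        self._e_prev = e
        self.e_dot += (self.dt / self.deriv_tau) * (raw_dot - self.e_dot)
        manifold = g.K_I * self.e_int + g.K_P * e + g.K_D * self.e_dot
        inside = np.abs(manifold) < g.epsilon
        self.e_int += self.dt * e * inside
        return -g.C * np.clip(manifold / g.epsilon, -1.0, 1.0)

    def command(self, x_d, x, f) -> np.ndarray:
        """Voltage actually sent to the plant (drive polarity applied)."""
        return self.drive_polarity * self.step(x_d, x, f)
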