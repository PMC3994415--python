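"""Synergy derivation pipeline: from joint-angle recordings to sinusoids.

The controller's sinusoid family originates from data-glove recordings of
able-bodied subjects unscrewing a bottle cap.  This module implements that
pipeline end to end on 40 Hz multi-trial joint-angle recordings:

1. :func:`synthesize_trials` — a first-class generator of glove-style
   recordings from a known sinusoid family (per-trial cadence jitter plus
   Gaussian angle noise), so the pipeline is testable without hardware.
2. :func:`normalize_time` — per-trial cycle-rate estimation (peak counting
   on a reference joint, refined by a single-sinusoid frequency fit) and
   uniform resampling so every trial runs at one cycle per unit of
   normalized time.
3. :func:`pca_contributions` — mean-centred covariance PCA; per-component
   variance fractions and first-PC loading percentages rank how much each
   joint contributes to the coordinated motion.
4. :func:`fit_sinusoids` — one shared cycle frequency (grid search +
   scalar refinement on the dominant joint) and per-joint (A, phi, b) by
   linear least squares at that frequency.
5. :func:`joint_space_error` — mean absolute relative error between the
   fitted sinusoids and the recordings.
6. :func:`map_joints` — project the fitted human joints onto the robot
   joint set (glove FJ/TJ names -> x_F/x_T names), emitting the constant
   thumb posture joints with zero amplitude.

Glove column conventions: finger joints FJ1a/FJ1b (DIP/PIP), FJ2 (MCP
flexion), FJ3 (MCP abduction); thumb joints TJ1 (IP), TJ2 (MCP), TJ3/TJ4
(CMC abduction/circumduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .synergy import JOINT_ORDER, SynergyParams

__all__ = [
    "NormalizationError",
    "DegenerateDataError",
    "MappingError",
    "RecordedTrial",
    "PCAResult",
    "SinusoidFit",
    "JointMapping",
    "GLOVE_COLUMNS",
    "DEFAULT_MAPPING",
    "synthesize_trials",
    "normalize_time",
    "pca_contributions",
    "fit_sinusoids",
    "joint_space_error",
    "map_joints",
]

GLOVE_COLUMNS = ("FJ1a", "FJ1b", "FJ2", "FJ3", "TJ1", "TJ2", "TJ3", "TJ4")

#: glove-to-robot assignment used to derive the shipped synergy; the
#: thumb CMC joints become constant posture offsets on the robot.
DEFAULT_MAPPING_PAIRS = (
    ("FJ1b", "x_F1"),
    ("FJ2", "x_F2"),
    ("TJ1", "x_T1"),
    ("TJ2", "x_T2"),
)
DEFAULT_CONSTANT_OFFSETS = {"x_T3": 1.257, "x_T4": 0.450}

#: relative-error floor: samples with |recorded| below this (rad) are
#: excluded so the relative metric stays finite near zero crossings
RELATIVE_ERROR_FLOOR = 0.05


class NormalizationError(ValueError):
    """Too few cycles detected to normalize a trial."""


class DegenerateDataError(ValueError):
    """Joint data carry no variance to decompose."""


class MappingError(KeyError):
    """A required source joint is missing from the fit."""


@dataclass
class RecordedTrial:
    """One uniformly sampled multi-joint recording.

    ``data`` holds one named angle column (rad) per joint; ``sampling_rate``
    is in Hz for raw recordings and in samples per normalized-time unit
    after :func:`normalize_time`.  ``orientation_angle`` records the
    object-to-forearm angle of the protocol (pi/2 by default).
    """

    data: pd.DataFrame
    sampling_rate: float = 40.0
    orientation_angle: float = math.pi / 2.0
    subject: str = "S0"
    trial: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.isna().any().any():
            raise ValueError("recordings must have no missing samples")

    @property
    def joints(self) -> tuple:
        return tuple(self.data.columns)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "time_s", np.arange(len(out)) / self.sampling_rate)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RecordedTrial":
        df = pd.read_csv(path)
        t = df.pop("time_s").to_numpy()
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trial samples must be uniformly spaced")
        return cls(data=df, sampling_rate=1.0 / dt[0], **kwargs)


@dataclass
class PCAResult:
    """Variance fractions per component and first-PC joint percentages."""

    variance_fractions: np.ndarray
    pc1_contributions: pd.Series


@dataclass
class SinusoidFit:
    """Shared-frequency sinusoid fit over all joints.

    ``frequency`` is in cycles per unit of (normalized) trial time;
    ``params`` has one row per joint with columns amplitude/phase/offset
    (A >= 0, phi wrapped to (-pi, pi]); ``relative_error`` is the
    per-joint mean absolute relative error of the fit.
    """

    frequency: float
    params: pd.DataFrame
    relative_error: pd.Series
    residual_norm: float


@dataclass
class JointMapping:
    """Human-to-robot joint assignment plus constant-offset joints."""

    pairs: tuple = DEFAULT_MAPPING_PAIRS
    constant_offsets: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSTANT_OFFSETS)
    )

    def __post_init__(self):
        robots = [r for _, r in self.pairs] + list(self.constant_offsets)
        if len(robots) != len(set(robots)):
            raise ValueError("each robot joint may be mapped at most once")


def _glove_truth(params: SynergyParams) -> dict:
    """Invert the default mapping: robot sinusoids as glove-named truth."""
    truth = {}
    for glove, robot in DEFAULT_MAPPING_PAIRS:
        k = params.index(robot)
        truth[glove] = (params.amplitude[k], params.phase[k], params.offset[k])
    # near-constant CMC posture columns and small nuisance finger motion
    truth["TJ3"] = (0.0, 0.0, 1.257)
    truth["TJ4"] = (0.0, 0.0, 0.450)
    truth["FJ1a"] = (0.05, -0.6, 0.40)
    truth["FJ3"] = (0.03, 0.8, 0.10)
    return truth


def synthesize_trials(
    params: SynergyParams,
    n_trials: int = 10,
    n_cycles: int = 5,
    speed_jitter: float = 0.2,
    noise_sd: float = 0.02,
    seed: int = 0,
    sampling_rate: float = 40.0,
    base_cadence: float = 1.0,
) -> list[RecordedTrial]:
    """Generate glove-style recordings from a known sinusoid family.

    Each trial evaluates the truth family at a per-trial cycle rate
    ``base_cadence * (1 + U(-speed_jitter, speed_jitter))`` Hz over
    ``n_cycles`` cycles, adds white Gaussian angle noise (sd ``noise_sd``
    rad), and is deterministic given ``seed``.  Unmapped glove columns
    carry small-amplitude nuisance motion so the recording has the full
    glove column set.
    """
    if n_cycles < 2:
        raise ValueError("trials must span at least 2 cycles")
    rng = np.random.default_rng(seed)
    truth = _glove_truth(params)
    trials = []
    for i in range(n_trials):
        cadence = base_cadence * (1.0 + speed_jitter * rng.uniform(-1.0, 1.0))
        duration = n_cycles / cadence
        t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
        cols = {}
        for name in GLOVE_COLUMNS:
            a, phi, b = truth[name]
            clean = a * np.sin(2.0 * math.pi * cadence * t + phi) + b
            cols[name] = clean + rng.normal(0.0, noise_sd, size=len(t))
        trials.append(
            RecordedTrial(
                data=pd.DataFrame(cols),
                sampling_rate=sampling_rate,
                subject="synthetic",
                trial=i,
            )
        )
    return trials


def _estimate_cycle_rate(y: np.ndarray, fs: float) -> float:
    """Cycle rate (Hz) of a periodic signal: peak spacing + LS refinement."""
    y = np.asarray(y, dtype=float)
    span = float(np.ptp(y))
    if span <= 0:
        raise NormalizationError("reference joint is constant")
    peaks, _ = find_peaks(y, prominence=0.5 * span, distance=3)
    if len(peaks) < 2:
        raise NormalizationError("fewer than 2 cycles detected")
    f0 = fs * (len(peaks) - 1) / (peaks[-1] - peaks[0])
    t = np.arange(len(y)) / fs

    def residual(f):
        basis = np.column_stack(
            [np.sin(2 * math.pi * f * t), np.cos(2 * math.pi * f * t), np.ones_like(t)]
        )
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return float(np.sum((y - basis @ coef) ** 2))

    res = minimize_scalar(residual, bounds=(0.8 * f0, 1.2 * f0), method="bounded")
    return float(res.x)


def normalize_time(
    trials: list[RecordedTrial],
    reference_joint: str = "FJ2",
    samples_per_cycle: int = 100,
) -> list[RecordedTrial]:
    """Resample every trial to a common cadence of 1 cycle per time unit.

    The per-trial cycle rate is estimated on ``reference_joint`` and the
    time axis rescaled so all trials share the same cycles-per-unit rate;
    every output trial is cropped to the minimum whole number of cycles
    across trials and linearly resampled to equal length.
    """
    rates = []
    for tr in trials:
        if reference_joint not in tr.data.columns:
            raise NormalizationError(f"missing reference joint {reference_joint!r}")
        rates.append(_estimate_cycle_rate(tr.data[reference_joint].to_numpy(), tr.sampling_rate))
    n_cycles = min(
        int(math.floor(len(tr.data) / tr.sampling_rate * rate))
        for tr, rate in zip(trials, rates)
    )
    if n_cycles < 2:
        raise NormalizationError("fewer than 2 common cycles across trials")
    n_out = n_cycles * samples_per_cycle
    tau_out = np.arange(n_out) / samples_per_cycle  # normalized time
    out = []
    for tr, rate in zip(trials, rates):
        t = np.arange(len(tr.data)) / tr.sampling_rate
        tau = t * rate
        # cubic interpolation: linear resampling would bias sinusoid
        # amplitudes down by O((samples/cycle)^-2)
        cols = {
            c: CubicSpline(tau, tr.data[c].to_numpy())(tau_out)
            for c in tr.data.columns
        }
        out.append(
            RecordedTrial(
                data=pd.DataFrame(cols),
                sampling_rate=float(samples_per_cycle),
                orientation_angle=tr.orientation_angle,
                subject=tr.subject,
                trial=tr.trial,
            )
        )
    return out


def _stack(trials: list[RecordedTrial]) -> pd.DataFrame:
    return pd.concat([tr.data for tr in trials], ignore_index=True)


def pca_contributions(trials: list[RecordedTrial]) -> PCAResult:
    """Covariance PCA of the concatenated, mean-centred joint matrix.

    Returns per-component variance fractions (descending) and the first
    principal component's loading magnitudes rescaled to percentages
    summing to 100 — the per-joint contribution ranking.
    """
    data = _stack(trials)
    if data.shape[1] < 2 or data.shape[0] < 3:
        raise DegenerateDataError("need at least 2 joints and 3 samples")
    centred = data.to_numpy() - data.to_numpy().mean(axis=0)
    cov = centred.T @ centred / (len(centred) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(evals.sum())
    if total <= 0:
        raise DegenerateDataError("joint data carry no variance")
    loadings = np.abs(evecs[:, 0])
    contributions = 100.0 * loadings / loadings.sum()
    return PCAResult(
        variance_fractions=evals / total,
        pc1_contributions=pd.Series(contributions, index=data.columns),
    )


def _wrap_phase(phi: float) -> float:
    """Wrap to (-pi, pi]."""
    phi = (phi + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if phi == -math.pi else phi


def fit_sinusoids(
    trials: list[RecordedTrial],
    frequency_bounds: tuple = (0.5, 1.5),
    grid_points: int = 101,
) -> SinusoidFit:
    """Fit one shared-frequency sinusoid family to normalized trials.

    A single cycle frequency (cycles per normalized-time unit) is found by
    grid search plus bounded scalar refinement on the highest-variance
    joint; per-joint (A, phi, b) then follow from linear least squares on
    a sin/cos/constant basis at that frequency.  Amplitudes are forced
    non-negative by phase flip and phases wrapped to (-pi, pi].
    """
    data = _stack(trials)
    fs = trials[0].sampling_rate
    # per-trial time axes concatenated (trials are equal-length after
    # normalization, and each restarts at tau = 0)
    tau = np.concatenate([np.arange(len(tr.data)) / fs for tr in trials])
    dominant = data.var().idxmax()
    y_dom = data[dominant].to_numpy()

    def residual(f: float) -> float:
        basis = np.column_stack(
            [
                np.sin(2 * math.pi * f * tau),
                np.cos(2 * math.pi * f * tau),
                np.ones_like(tau),
            ]
        )
        coef, *_ = np.linalg.lstsq(basis, y_dom, rcond=None)
        return float(np.sum((y_dom - basis @ coef) ** 2))

    grid = np.linspace(*frequency_bounds, grid_points)
    f0 = grid[int(np.argmin([residual(f) for f in grid]))]
    span = grid[1] - grid[0]
    res = minimize_scalar(
        residual, bounds=(f0 - span, f0 + span), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError("shared-frequency search did not converge")
    freq = float(res.x)

    basis = np.column_stack(
        [
            np.sin(2 * math.pi * freq * tau),
            np.cos(2 * math.pi * freq * tau),
            np.ones_like(tau),
        ]
    )
    rows, errs = {}, {}
    sq_resid = 0.0
    for joint in data.columns:
        y = data[joint].to_numpy()
        (a_s, a_c, b), *_ = np.linalg.lstsq(basis, y, rcond=None)
        amp = math.hypot(a_s, a_c)
        if amp < 1e-9:  # constant column: amplitude 0, phase 0 by convention
            amp, phi = 0.0, 0.0
        else:
            phi = math.atan2(a_c, a_s)
        model = basis @ np.array([a_s, a_c, b])
        sq_resid += float(np.sum((y - model) ** 2))
        keep = np.abs(y) >= RELATIVE_ERROR_FLOOR
        errs[joint] = (
            float(np.mean(np.abs((model[keep] - y[keep]) / y[keep])))
            if keep.any()
            else float("nan")
        )
        rows[joint] = (amp, _wrap_phase(phi), b)
    params = pd.DataFrame(rows, index=["amplitude", "phase", "offset"]).T
    return SinusoidFit(
        frequency=freq,
        params=params,
        relative_error=pd.Series(errs),
        residual_norm=math.sqrt(sq_resid),
    )


def joint_space_error(fit: SinusoidFit, trials: list[RecordedTrial]) -> pd.Series:
    """Mean absolute relative error of the fit against the recordings.

    Samples with |recorded| below :data:`RELATIVE_ERROR_FLOOR` are
    excluded; a joint with no usable samples reports NaN.
    """
    data = _stack(trials)
    fs = trials[0].sampling_rate
    tau = np.concatenate([np.arange(len(tr.data)) / fs for tr in trials])
    out = {}
    for joint in data.columns:
        a, phi, b = fit.params.loc[joint]
        model = a * np.sin(2 * math.pi * fit.frequency * tau + phi) + b
        y = data[joint].to_numpy()
        keep = np.abs(y) >= RELATIVE_ERROR_FLOOR
        out[joint] = (
            float(np.mean(np.abs((model[keep] - y[keep]) / y[keep])))
            if keep.any()
            else float("nan")
        )
    return pd.Series(out)


def map_joints(
    fit: SinusoidFit,
    mapping: JointMapping | None = None,
    omega: float = 3.0,
) -> SynergyParams:
    """Project a fitted human sinusoid family onto the robot joint set.

    Mapped joints copy their fitted (A, phi, b); constant-posture joints
    are emitted with zero amplitude and the configured offsets; glove
    joints not referenced by the mapping are dropped.
    """
    mapping = mapping or JointMapping()
    values = {}
    for glove, robot in mapping.pairs:
        if glove not in fit.params.index:
            raise MappingError(f"source joint {glove!r} missing from fit")
        a, phi, b = fit.params.loc[glove]
        values[robot] = (a, phi, b)
    for robot, offset in mapping.constant_offsets.items():
        values[robot] = (0.0, 0.0, offset)
    joints = tuple(j for j in JOINT_ORDER if j in values)
    extra = tuple(j for j in values if j not in joints)
    joints = joints + extra
    return SynergyParams(
        joints=joints,
        amplitude=np.array([values[j][0] for j in joints]),
        phase=np.array([values[j][1] for j in joints]),
        offset=np.array([values[j][2] for j in joints]),
        omega=omega,
    )
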