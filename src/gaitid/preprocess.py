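"""From raw sensor-frame signals to the gait-aligned global frame.

The pipeline mirrors the standard strapdown approach for body-worn IMUs:

1. *Inclination*: while the subject stands still the accelerometer measures
   only gravity, which pins down the sensor's tilt (but not its yaw).
2. *Orientation integration*: during walking the orientation is propagated by
   integrating the gyroscope, solving ``dR/dt = R [w]x`` with per-sample
   axis-angle increments (exact for piecewise-constant angular velocity).
3. *Leveling*: rotating the specific force into the leveled frame and adding
   g = (0, 0, -9.81) m/s² yields free acceleration; the angular velocity is
   rotated with the same matrices.
4. *Heading*: trapezoidal integration of free acceleration gives velocity;
   the mean velocity over the first full walking cycle defines the walking
   direction, and a yaw rotation aligns +x with it (y points left, z up).
5. *Angular acceleration* is the time derivative of the global angular
   velocity (central differences, one-sided at the ends).

Gait cycles are detected from peaks of the across-sensor summary signal
sum_i(||a_i|| + ||w_i||); one stride spans two successive same-foot peaks,
i.e. every second accepted peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation as _Rot

from .trial_io import SensorRecording, Trial

__all__ = [
    "GRAVITY",
    "LeveledSignals",
    "GlobalSignals",
    "GaitCycles",
    "PreprocessedTrial",
    "estimate_static_inclination",
    "integrate_orientation",
    "level_and_remove_gravity",
    "estimate_heading",
    "apply_heading",
    "angular_acceleration",
    "detect_walking_cycles",
    "detect_static_interval",
    "preprocess_trial",
]

GRAVITY = 9.81  # m/s², magnitude of gravitational acceleration


@dataclass
class LeveledSignals:
    """Signals in the leveled frame: vertical axis up, yaw still arbitrary."""

    acc: np.ndarray  # (n, 3) free acceleration, gravity removed, m/s²
    gyr: np.ndarray  # (n, 3) angular velocity, rad/s
    vel: np.ndarray  # (n, 3) velocity from trapezoidal integration, m/s
    fs: float


@dataclass
class GlobalSignals:
    """Signals in the gait frame: x = walking direction, y = left, z = up."""

    acc: np.ndarray      # (n, 3) m/s²
    gyr: np.ndarray      # (n, 3) rad/s
    angacc: np.ndarray   # (n, 3) rad/s²
    heading: float       # yaw applied to reach this frame, rad, in (-pi, pi]
    fs: float


@dataclass
class GaitCycles:
    """Stride-cycle boundaries as sample indices (cycle k = [b[k], b[k+1]))."""

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if len(self.boundaries) < 2 or np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("cycle boundaries must be >= 2 and strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1


@dataclass
class PreprocessedTrial:
    """Gait-frame signals of every sensor, cut to the analysis window."""

    signals: dict[str, GlobalSignals]
    cycles: GaitCycles
    window: tuple[int, int]      # sample range (in original indices) used
    fs: float
    headings: dict[str, float]   # per-sensor estimated heading, rad
    trial: Trial = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def estimate_static_inclination(static_acc_mean: np.ndarray) -> np.ndarray:
    """Shortest-arc rotation mapping the mean static specific force to +z.

    The heading (yaw) component of the sensor orientation is unobservable
    from gravity alone and is resolved later from the walking direction.
    """
    v = np.asarray(static_acc_mean, dtype=float)
    norm = float(np.linalg.norm(v))
    if not (0.5 * GRAVITY <= norm <= 1.5 * GRAVITY):
        raise ValueError(
            f"static acceleration magnitude {norm:.3f} m/s^2 outside "
            f"[{0.5 * GRAVITY:.2f}, {1.5 * GRAVITY:.2f}]: "
            "sensor not static or miscalibrated"
        )
    u = v / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    if c < -1.0 + 1e-12:  # pointing straight down: rotate half-turn about x
        return _Rot.from_rotvec([np.pi, 0.0, 0.0]).as_matrix()
    axis = np.cross(u, z)
    s = float(np.linalg.norm(axis))
    if s < 1e-15:
        return np.eye(3)
    angle = np.arctan2(s, c)
    return _Rot.from_rotvec(axis / s * angle).as_matrix()


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product for scalar-last quaternions, broadcasting over rows."""
    x1, y1, z1, w1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    x2, y2, z2, w2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    return np.stack(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ],
        axis=-1,
    )


def _quat_scan(dq: np.ndarray) -> np.ndarray:
    """Inclusive left-to-right prefix products of quaternion increments.

    Uses a Hillis–Steele scan (composition is associative), so the whole
    series is propagated in O(log n) vectorized passes.
    """
    p = dq.copy()
    n = len(p)
    offset = 1
    while offset < n:
        left = p[:-offset]
        p = np.concatenate([p[:offset], _quat_mul(left, p[offset:])], axis=0)
        p /= np.linalg.norm(p, axis=-1, keepdims=True)
        offset *= 2
    return p


def integrate_orientation(R0: np.ndarray, gyr: np.ndarray, fs: float) -> np.ndarray:
    """Propagate orientation through the gyroscope series.

    Solves ``dR/dt = R [w]x`` with per-step increments
    ``R[k+1] = R[k] @ exp([w_mid]x dt)`` where ``w_mid`` is the midpoint
    angular rate; exact for constant rates, free of first-order drift.
    Returns an (n, 3, 3) series of orthonormal matrices with ``R[0] = R0``.
    """
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    gyr = np.asarray(gyr, dtype=float)
    if not np.isfinite(gyr).all():
        raise ValueError("non-finite gyroscope samples")
    n = len(gyr)
    out = np.empty((n, 3, 3))
    out[0] = R0
    if n == 1:
        return out
    dt = 1.0 / fs
    w_mid = 0.5 * (gyr[:-1] + gyr[1:])
    dq = _Rot.from_rotvec(w_mid * dt).as_quat()
    prefix = _quat_scan(dq)
    out[1:] = np.einsum("ij,njk->nik", R0, _Rot.from_quat(prefix).as_matrix())
    return out


# ---------------------------------------------------------------------------
# Leveling, heading, derivatives
# ---------------------------------------------------------------------------

def level_and_remove_gravity(
    rec: SensorRecording,
    R_series: np.ndarray,
    fs: float,
    v_reset_index: int | None = None,
) -> LeveledSignals:
    """Rotate to the leveled frame, cancel gravity and integrate velocity.

    ``a(t) = R(t) s(t) + (0, 0, -9.81)``; velocity is the trapezoidal
    integral of free acceleration from rest.  When ``v_reset_index`` is
    given (normally the end of the static interval) the velocity is zeroed
    there, which is where the subject is known to be at rest.
    """
    if len(R_series) != rec.n_samples:
        raise ValueError("rotation series length does not match recording")
    acc = np.einsum("nij,nj->ni", R_series, rec.acc)
    acc[:, 2] -= GRAVITY
    gyr = np.einsum("nij,nj->ni", R_series, rec.gyr)
    vel = cumulative_trapezoid(acc, dx=1.0 / fs, axis=0, initial=0.0)
    if v_reset_index is not None:
        vel = vel - vel[v_reset_index]
    return LeveledSignals(acc=acc, gyr=gyr, vel=vel, fs=fs)


def estimate_heading(vel: np.ndarray, first_cycle: tuple[int, int]) -> float:
    """Signed walking-direction angle from the first-cycle mean velocity.

    The magnitude agrees with the inner-product (arccos) form; the sign is
    taken from the leftward (y) component, i.e. a two-argument arctangent,
    because a yaw correction needs a signed angle.
    """
    s, e = first_cycle
    if not (0 <= s < e <= len(vel)):
        raise ValueError("first cycle outside velocity series")
    mean_v = np.mean(vel[s:e], axis=0)
    speed = float(np.hypot(mean_v[0], mean_v[1]))
    if speed < 0.1:
        raise ValueError(
            f"mean horizontal speed {speed:.3f} m/s too small: "
            "walking direction undefined"
        )
    return float(np.arctan2(mean_v[1], mean_v[0]))


def apply_heading(signals: LeveledSignals, theta: float) -> GlobalSignals:
    """Yaw all signals so that +x points along the walking direction.

    Vertical components are untouched; the angular acceleration is derived
    from the rotated angular velocity.
    """
    if not np.isfinite(theta):
        raise ValueError("heading must be finite")
    c, s = np.cos(theta), np.sin(theta)

    def rot(v: np.ndarray) -> np.ndarray:
        out = v.copy()
        out[:, 0] = c * v[:, 0] + s * v[:, 1]
        out[:, 1] = -s * v[:, 0] + c * v[:, 1]
        return out

    acc = rot(signals.acc)
    gyr = rot(signals.gyr)
    return GlobalSignals(
        acc=acc,
        gyr=gyr,
        angacc=angular_acceleration(gyr, signals.fs),
        heading=float(np.arctan2(np.sin(theta), np.cos(theta))),
        fs=signals.fs,
    )


def angular_acceleration(gyr: np.ndarray, fs: float) -> np.ndarray:
    """alpha = dw/dt: central differences inside, one-sided at the ends."""
    gyr = np.asarray(gyr, dtype=float)
    if len(gyr) < 3:
        raise ValueError("need at least 3 samples for angular acceleration")
    return np.gradient(gyr, 1.0 / fs, axis=0)


# ---------------------------------------------------------------------------
# Gait cycles and static interval
# ---------------------------------------------------------------------------

def detect_walking_cycles(
    summary: np.ndarray,
    fs: float,
    min_distance_s: float = 0.4,
    prominence_frac: float = 0.5,
) -> GaitCycles:
    """Stride boundaries from peaks of sum_i(||a_i|| + ||w_i||).

    Peaks occur once per step; a stride (same foot to same foot) spans two
    steps, so every second accepted peak is taken as a cycle boundary.
    Peak acceptance: minimum distance ``min_distance_s``, and prominence of
    at least ``prominence_frac`` times the median prominence of the
    distance-spaced candidate peaks (a scale that one large gait-initiation
    transient cannot inflate, unlike a plain signal percentile).
    """
    summary = np.asarray(summary, dtype=float)
    if len(summary) < fs:
        raise ValueError("summary shorter than one second: no gait detected")
    distance = max(1, int(round(min_distance_s * fs)))
    candidates, props = find_peaks(summary, distance=distance, prominence=0.0)
    if len(candidates) == 0:
        raise ValueError("summary signal is flat: no gait detected")
    scale = float(np.median(props["prominences"]))
    if scale <= 1e-12:
        raise ValueError("summary signal is flat: no gait detected")
    peaks, _ = find_peaks(
        summary, distance=distance, prominence=prominence_frac * scale
    )
    # drop leading gait-initiation transients: a genuine step train has a
    # regular inter-peak interval, so leading peaks followed by a gap well
    # above the median step interval are not steps
    while len(peaks) >= 4 and peaks[1] - peaks[0] > 1.5 * np.median(np.diff(peaks)):
        peaks = peaks[1:]
    boundaries = peaks[::2]
    if len(boundaries) < 2:
        raise ValueError("fewer than 2 stride peaks: no gait detected")
    return GaitCycles(boundaries)


def detect_static_interval(
    trial: Trial,
    min_duration_s: float = 1.0,
    gyro_threshold: float = 0.1,
) -> tuple[int, int]:
    """Longest prefix with gyro magnitude below ``gyro_threshold`` rad/s on
    every sensor; requires at least ``min_duration_s`` seconds."""
    mags = np.max(
        [np.linalg.norm(rec.gyr, axis=1) for rec in trial.sensors], axis=0
    )
    moving = np.nonzero(mags >= gyro_threshold)[0]
    end = int(moving[0]) if len(moving) else trial.n_samples
    if end < min_duration_s * trial.fs:
        raise ValueError("no static prefix of at least "
                         f"{min_duration_s:.1f} s found")
    return 0, end


# ---------------------------------------------------------------------------
# Whole-trial pipeline
# ---------------------------------------------------------------------------

def _circular_median(angles: np.ndarray) -> float:
    """Angle among the candidates minimizing summed circular distance."""
    angles = np.asarray(angles, dtype=float)
    diffs = np.angle(np.exp(1j * (angles[None, :] - angles[:, None])))
    costs = np.sum(np.abs(diffs), axis=1)
    return float(angles[int(np.argmin(costs))])


def preprocess_trial(
    trial: Trial,
    n_cycles_used: int = 3,
    heading_mode: str = "per_sensor",
    heading_offset: float = 0.0,
    min_distance_s: float = 0.4,
    prominence_frac: float = 0.5,
) -> PreprocessedTrial:
    """Run the full preprocessing chain on every sensor of a trial.

    Parameters
    ----------
    n_cycles_used:
        Number of leading walking cycles kept for feature extraction
        (1 to 3; the method is designed around 3).
    heading_mode:
        ``"per_sensor"`` (default) estimates the walking direction from each
        sensor's own velocity, which absorbs arbitrary mounting yaw;
        ``"median"`` applies the circular median of all per-sensor headings
        to every sensor.
    heading_offset:
        Extra yaw (rad) added to every heading; used for sensitivity
        analyses of the walking-direction estimate.
    """
    if not 1 <= n_cycles_used:
        raise ValueError("n_cycles_used must be >= 1")
    s0, s1 = trial.static_interval
    leveled: dict[str, LeveledSignals] = {}
    for rec in trial.sensors:
        static_mean = rec.acc[s0:s1].mean(axis=0)
        R0 = estimate_static_inclination(static_mean)
        R_series = integrate_orientation(R0, rec.gyr, trial.fs)
        leveled[rec.sensor_id] = level_and_remove_gravity(
            rec, R_series, trial.fs, v_reset_index=max(s1 - 1, 0)
        )

    summary = np.sum(
        [
            np.linalg.norm(lev.acc, axis=1) + np.linalg.norm(lev.gyr, axis=1)
            for lev in leveled.values()
        ],
        axis=0,
    )
    cycles = detect_walking_cycles(
        summary, trial.fs, min_distance_s=min_distance_s,
        prominence_frac=prominence_frac,
    )
    first_cycle = (int(cycles.boundaries[0]), int(cycles.boundaries[1]))

    headings = {
        sid: estimate_heading(lev.vel, first_cycle) for sid, lev in leveled.items()
    }
    if heading_mode == "median":
        common = _circular_median(np.array(list(headings.values())))
        applied = {sid: common for sid in headings}
    elif heading_mode == "per_sensor":
        applied = dict(headings)
    else:
        raise ValueError(f"unknown heading mode {heading_mode!r}")

    n_use = min(n_cycles_used, cycles.n_cycles)
    if n_use < n_cycles_used:
        warnings.warn(
            f"only {cycles.n_cycles} cycles detected, using {n_use}",
            stacklevel=2,
        )
    w0 = int(cycles.boundaries[0])
    w1 = int(cycles.boundaries[n_use])

    signals: dict[str, GlobalSignals] = {}
    for sid, lev in leveled.items():
        glob = apply_heading(lev, applied[sid] + heading_offset)
        signals[sid] = GlobalSignals(
            acc=glob.acc[w0:w1],
            gyr=glob.gyr[w0:w1],
            angacc=glob.angacc[w0:w1],
            heading=glob.heading,
            fs=trial.fs,
        )
    return PreprocessedTrial(
        signals=signals,
        cycles=cycles,
        window=(w0, w1),
        fs=trial.fs,
        headings=applied,
        trial=trial,
    )
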