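"""Synthetic walking trials with the statistical structure gait-IMU
identification exploits.

The generator is not a musculoskeletal simulation.  It produces, for every
body segment, a gait-frame kinematic signal model that reproduces the
*ordinal and phase structure* the identification method relies on:

* a static standing prefix, then a smooth gait-initiation transient that
  brings the whole body to the walking speed along an arbitrary heading;
* per-segment oscillatory accelerations at the stride frequency (with
  left/right limbs in anti-phase) and at the step frequency (common phase),
  with amplitude tiers calibrated so that the six leg sensors always have
  the largest acceleration RMS, followed by the arm chain and the trunk;
* per-segment angular motion about a fixed segment axis, giving exactly
  consistent gyroscope and orientation trajectories (a single-axis rotation
  has a closed form), with pelvis and sternum roll phase-locked to the
  ipsilateral limb swing with the sign that makes "largest correlation with
  trunk roll -> right side" true;
* an arbitrary (by default fully random) mounting rotation per sensor,
  accelerometer bias and white measurement noise.

Sensor outputs are the exact specific force ``R_ws^T (a_world - g)`` and
body-frame angular rate of this model, so the full preprocessing chain
(inclination from the static prefix, gyroscope strapdown, heading from the
first-cycle velocity) recovers the constructed gait-frame signals.

What the model does not emulate: soft-tissue artifacts, double-support
asymmetries, turning, pathological gait beyond parameter jitter, and
realistic joint trajectories.  Segment amplitude tiers are fixed constants
(see ``SEGMENT_MODEL``); their absolute values are unimportant as long as
the orderings hold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation as _Rot

from .preprocess import GRAVITY
from .trial_io import (
    ConfigurationSpec,
    SegmentLabel,
    SensorRecording,
    Trial,
    full_body,
)

__all__ = ["GaitParams", "SimulatedTrial", "simulate_trial", "make_corpus",
           "SEGMENT_MODEL"]

#: Axis phase offsets (rad) of the stride-frequency acceleration component.
_AXIS_PHASE = np.array([0.0, np.pi / 2, 2 * np.pi / 5])
#: Axis phase offsets of the step-frequency (double stride rate) component.
_AXIS_PHASE2 = np.array([0.9, 1.7, 2.4])

#: Per-segment-class signal constants.  ``acc_f0``/``acc_2f0``: acceleration
#: amplitudes (m/s², x/y/z) at stride and step frequency.  ``swing_axis``
#: and ``swing_amp`` (rad): the fixed rotation axis and stride-frequency
#: angular amplitude.  ``chain`` selects the left/right phase convention:
#: legs swing in anti-phase with each other, arms in anti-phase with the
#: ipsilateral leg, midline segments follow dedicated roll phases.
#: Amplitude tiers are strictly ordered so that per-trial feature rankings
#: are stable under the corpus jitter: acceleration RMS orders the chains
#: foot > lower leg > upper leg > hand > forearm > upper arm > pelvis >
#: shoulder > sternum > head (legs always above every non-leg sensor), and
#: angular-rate RMS orders them foot > lower leg > hand > forearm >
#: upper leg > upper arm > shoulder > pelvis > sternum > head.
SEGMENT_MODEL: dict[str, dict] = {
    "foot":      dict(acc_f0=(5.0, 1.5, 4.0), acc_2f0=(2.0, 0.8, 2.5),
                      swing_axis=(0.15, 1.0, 0.1), swing_amp=0.60, chain="leg"),
    "lower_leg": dict(acc_f0=(4.0, 1.2, 2.8), acc_2f0=(1.5, 0.6, 1.8),
                      swing_axis=(0.1, 1.0, 0.1), swing_amp=0.45, chain="leg"),
    "upper_leg": dict(acc_f0=(2.6, 1.0, 1.8), acc_2f0=(1.0, 0.5, 1.2),
                      swing_axis=(0.1, 1.0, 0.15), swing_amp=0.22, chain="leg"),
    "hand":      dict(acc_f0=(1.6, 1.2, 1.4), acc_2f0=(0.5, 0.4, 0.5),
                      swing_axis=(0.2, 1.0, 0.2), swing_amp=0.38, chain="arm"),
    "forearm":   dict(acc_f0=(1.3, 0.9, 1.1), acc_2f0=(0.4, 0.3, 0.4),
                      swing_axis=(0.15, 1.0, 0.2), swing_amp=0.28, chain="arm"),
    "upper_arm": dict(acc_f0=(0.9, 0.6, 0.8), acc_2f0=(0.3, 0.2, 0.3),
                      swing_axis=(0.1, 1.0, 0.25), swing_amp=0.18, chain="arm"),
    "shoulder":  dict(acc_f0=(0.35, 0.3, 0.45), acc_2f0=(0.3, 0.2, 0.35),
                      swing_axis=(0.3, 1.0, 0.3), swing_amp=0.10, chain="arm"),
    "pelvis":    dict(acc_f0=(0.3, 0.4, 0.25), acc_2f0=(0.4, 0.25, 0.7),
                      swing_axis=(1.0, 0.25, 0.15), swing_amp=0.06, chain="mid"),
    "sternum":   dict(acc_f0=(0.2, 0.25, 0.15), acc_2f0=(0.3, 0.15, 0.5),
                      swing_axis=(1.0, 0.2, 0.1), swing_amp=0.04, chain="mid"),
    "head":      dict(acc_f0=(0.1, 0.15, 0.1), acc_2f0=(0.2, 0.1, 0.45),
                      swing_axis=(1.0, 0.3, 0.2), swing_amp=0.03, chain="mid"),
}


@dataclass(frozen=True)
class GaitParams:
    """Study conditions of a simulated walking trial.

    Defaults correspond to normal over-ground walking at about 5 km/h,
    recorded at 120 Hz after a few seconds of quiet standing, with modest
    consumer-IMU measurement noise and fully arbitrary sensor mounting.
    """

    walking_speed: float = 1.39        # m/s (about 5 km/h)
    stride_period: float = 1.1         # s per gait cycle (two steps)
    n_cycles: int = 3                  # complete strides generated
    static_duration: float = 3.0       # s of quiet standing before gait
    transition_duration: float = 0.25  # s of gait initiation
    fs: float = 120.0                  # Hz
    arm_swing_amplitude: float = 1.0   # scale on arm-chain motion (0 = none)
    pelvis_roll_amplitude: float = 1.0 # scale on trunk roll coupling
    noise_sigma_acc: float = 0.02      # m/s² white accelerometer noise
    noise_sigma_gyr: float = 0.01      # rad/s white gyroscope noise
    acc_bias: float = 0.0              # m/s² constant accelerometer bias
    heading_deg: float = 0.0           # walking direction in the world frame
    mounting: str = "random"           # "random" | "well_mounted" | "identity"
    amp_jitter: float = 0.0            # per-sensor amplitude jitter fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 20:
            raise ValueError("sampling frequency must be at least 20 Hz")
        if self.n_cycles < 1:
            raise ValueError("need at least one walking cycle")
        for name in ("walking_speed", "stride_period", "arm_swing_amplitude",
                     "pelvis_roll_amplitude", "noise_sigma_acc",
                     "noise_sigma_gyr", "acc_bias", "amp_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulatedTrial:
    """A labelled trial plus the simulator's ground truth."""

    trial: Trial
    params: GaitParams
    true_boundaries: np.ndarray       # stride-start sample indices
    gait_frame_acc: dict[str, np.ndarray]  # per sensor, constructed a(t)
    gait_frame_gyr: dict[str, np.ndarray]

    @property
    def labels(self) -> dict[str, SegmentLabel]:
        return self.trial.labels


def _smoothstep(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C1 ramp 0 -> 1 on [0, 1] and its derivative (with respect to u)."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3 - 2 * u), 6 * u * (1 - u)


def _side_phase(chain: str, side: str) -> float:
    """Stride-frequency phase convention: right leg = 0, left leg = pi;
    arms swing with the contralateral leg; midline uses the right-leg
    reference."""
    if chain == "leg":
        return 0.0 if side == "right" else np.pi
    if chain == "arm":
        return np.pi if side == "right" else 0.0
    return 0.0


def _mounting_rotation(mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "random":
        return _Rot.random(rng=rng).as_matrix()
    if mode == "well_mounted":
        rotvec = rng.normal(0.0, np.deg2rad(10.0), 3)
        return _Rot.from_rotvec(rotvec).as_matrix()
    if mode == "identity":
        return np.eye(3)
    raise ValueError(f"unknown mounting mode {mode!r}")


def simulate_trial(
    params: GaitParams,
    config: ConfigurationSpec | None = None,
    trial_id: str = "sim",
) -> SimulatedTrial:
    """Generate one labelled synthetic walking trial.

    Deterministic under ``params.seed``; the same parameters always yield
    bit-identical trials.
    """
    if config is None:
        config = full_body()
    rng = np.random.default_rng(params.seed)
    fs, T = params.fs, params.stride_period
    f0 = 1.0 / T
    w0 = 2 * np.pi * f0

    t_static = params.static_duration
    t_trans = params.transition_duration
    t0 = t_static + t_trans                   # walking-time origin
    duration = t0 + (params.n_cycles + 1.1) * T
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tau = t - t0                              # time since steady walking

    S, dS_du = _smoothstep((t - t_static) / t_trans)
    Sdot = dS_du / t_trans

    # The world heading only re-expresses signals in a frame the sensors
    # cannot observe (gravity is yaw-invariant), so it cancels analytically
    # in the specific force; signals are generated directly in the gait
    # frame and heading_deg is kept as trial metadata.
    g_up = np.array([0.0, 0.0, GRAVITY])

    # sensor ids are a random permutation so position in the file never
    # leaks the segment identity
    order = rng.permutation(config.n_sensors)
    sensor_ids = [f"imu{order[i]:02d}" for i in range(config.n_sensors)]

    sensors: list[SensorRecording] = []
    labels: dict[str, SegmentLabel] = {}
    gait_acc: dict[str, np.ndarray] = {}
    gait_gyr: dict[str, np.ndarray] = {}

    for seg, sid in zip(config.segments, sensor_ids):
        model = SEGMENT_MODEL[seg.segment_class]
        chain = model["chain"]
        psi = _side_phase(chain, seg.side)
        jitter = 1.0 + params.amp_jitter * rng.uniform(-1.0, 1.0)
        # the swing scale controls active limb motion (stride frequency);
        # the step-frequency bounce is transmitted through the trunk and
        # persists even for a subject who barely swings the arms
        scale_f0 = jitter * (params.arm_swing_amplitude if chain == "arm" else 1.0)
        scale_2f0 = jitter

        # --- linear motion: velocity waveform, acceleration its derivative
        vel = np.zeros((n, 3))
        acc = np.zeros((n, 3))
        vel[:, 0] += params.walking_speed * S
        acc[:, 0] += params.walking_speed * Sdot
        for freq_mult, amps, phases, scale in (
            (1.0, model["acc_f0"], _AXIS_PHASE + psi, scale_f0),
            (2.0, model["acc_2f0"], _AXIS_PHASE2, scale_2f0),
        ):
            w = freq_mult * w0
            for ax in range(3):
                A = scale * amps[ax]
                u_osc = -(A / w) * np.cos(w * tau + phases[ax])
                vel[:, ax] += S * u_osc
                acc[:, ax] += Sdot * u_osc + S * A * np.sin(w * tau + phases[ax])

        # --- angular motion: single fixed axis, closed-form orientation
        axis = np.asarray(model["swing_axis"], dtype=float)
        axis = axis / np.linalg.norm(axis)
        A1 = model["swing_amp"] * scale_f0
        if chain == "mid":
            A1 *= params.pelvis_roll_amplitude
            # trunk roll is phase-locked to the ipsilateral limb's vertical
            # acceleration so that the larger trunk-roll correlation always
            # marks the right side: the pelvis follows the right leg, the
            # sternum the right arm
            ref = np.pi if seg.segment_class == "sternum" else 0.0
            p_sw = ref + _AXIS_PHASE[2]
        else:
            p_sw = psi - np.pi / 2  # |w| peaks coincide with the |a| peaks
        A2 = 0.25 * A1
        phi = S * (A1 * np.sin(w0 * tau + p_sw)
                   + A2 * np.sin(2 * w0 * tau + 0.7))
        phidot = (Sdot * (A1 * np.sin(w0 * tau + p_sw)
                          + A2 * np.sin(2 * w0 * tau + 0.7))
                  + S * (A1 * w0 * np.cos(w0 * tau + p_sw)
                         + A2 * 2 * w0 * np.cos(2 * w0 * tau + 0.7)))
        omega_gait = phidot[:, None] * axis[None, :]
        R_seg = _Rot.from_rotvec(phi[:, None] * axis[None, :]).as_matrix()

        # --- project to the sensor frame
        R_mount = _mounting_rotation(params.mounting, rng)
        # specific force: R_ws^T (a_world - g); the heading rotation cancels
        # against its transpose for the horizontal terms and leaves the
        # vertical untouched, so it is applied implicitly
        spec_force_gait = acc + g_up[None, :]
        s_sensor = np.einsum(
            "ji,nj->ni",
            R_mount,
            np.einsum("nji,nj->ni", R_seg, spec_force_gait),
        )
        # single-axis rotation leaves its own axis invariant:
        # R_seg^T omega = omega
        w_sensor = omega_gait @ R_mount  # == R_mount.T applied row-wise

        if params.acc_bias > 0:
            bias_dir = rng.normal(size=3)
            bias_dir /= np.linalg.norm(bias_dir)
            s_sensor = s_sensor + params.acc_bias * bias_dir
        if params.noise_sigma_acc > 0:
            s_sensor = s_sensor + rng.normal(0, params.noise_sigma_acc, (n, 3))
        if params.noise_sigma_gyr > 0:
            w_sensor = w_sensor + rng.normal(0, params.noise_sigma_gyr, (n, 3))

        sensors.append(SensorRecording(sid, s_sensor, w_sensor))
        labels[sid] = seg
        gait_acc[sid] = acc
        gait_gyr[sid] = omega_gait

    boundaries = np.round((t0 + T / 4 + T * np.arange(params.n_cycles + 1)) * fs)
    trial = Trial(
        sensors=sensors,
        fs=fs,
        static_interval=(0, int(t_static * fs)),
        config=config,
        labels=labels,
        trial_id=trial_id,
    )
    return SimulatedTrial(
        trial=trial,
        params=params,
        true_boundaries=boundaries.astype(int),
        gait_frame_acc=gait_acc,
        gait_frame_gyr=gait_gyr,
    )


def make_corpus(
    n_trials: int,
    seed: int = 0,
    config: ConfigurationSpec | None = None,
    base_params: GaitParams | None = None,
    speed_jitter: float = 0.1,
    stride_jitter: float = 0.1,
    amp_jitter: float = 0.03,
) -> list[SimulatedTrial]:
    """A corpus of jittered trials, mirroring a multi-subject recording
    session: per-trial walking speed, stride period, heading, amplitudes and
    mounting orientations vary; everything is deterministic under ``seed``.
    """
    if n_trials < 2:
        raise ValueError("a corpus needs at least 2 trials")
    base = base_params or GaitParams()
    master = np.random.default_rng(seed)
    trials: list[SimulatedTrial] = []
    for i in range(n_trials):
        p = replace(
            base,
            walking_speed=base.walking_speed
            * (1 + speed_jitter * master.uniform(-1, 1)),
            stride_period=base.stride_period
            * (1 + stride_jitter * master.uniform(-1, 1)),
            heading_deg=master.uniform(-180.0, 180.0),
            amp_jitter=amp_jitter,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        trials.append(simulate_trial(p, config=config, trial_id=f"sim{i:03d}"))
    return trials
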