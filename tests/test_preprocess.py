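"""Orientation integration, leveling, heading alignment and cycle detection."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from gaitid import preprocess as pp
from gaitid.gaitsim import GaitParams, simulate_trial
from gaitid.trial_io import SensorRecording, Trial


def _planar_yaw_error_deg(true_xy: np.ndarray, rec_xy: np.ndarray) -> float:
    """Least-squares planar rotation angle between two 2D signal sets."""
    num = np.sum(true_xy[:, 0] * rec_xy[:, 1] - true_xy[:, 1] * rec_xy[:, 0])
    den = np.sum(true_xy[:, 0] * rec_xy[:, 0] + true_xy[:, 1] * rec_xy[:, 1])
    return float(np.degrees(np.arctan2(num, den)))


# ---------------------------------------------------------------------------
# static inclination
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vec",
    [
        (0.0, 0.0, 9.81),
        (9.81, 0.0, 0.0),
        (0.0, 6.937, 6.937),
        (0.0, 0.0, -9.81),  # upside-down mounting
    ],
)
def test_static_inclination_aligns_gravity_with_up(vec):
    v = np.array(vec)
    R = pp.estimate_static_inclination(v)
    np.testing.assert_allclose(R @ v, [0, 0, np.linalg.norm(v)], atol=1e-9)
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_static_inclination_identity_when_level():
    np.testing.assert_allclose(
        pp.estimate_static_inclination([0, 0, 9.81]), np.eye(3), atol=1e-12
    )


def test_static_inclination_rejects_non_static():
    with pytest.raises(ValueError, match="not static"):
        pp.estimate_static_inclination([0, 0, 2.0])
    with pytest.raises(ValueError, match="not static"):
        pp.estimate_static_inclination([20.0, 0, 0])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1, 1), min_size=3, max_size=3), st.floats(0.6, 1.4))
def test_static_inclination_property(direction, scale):
    v = np.array(direction)
    n = np.linalg.norm(v)
    if n < 1e-3:
        return
    v = v / n * (scale * 9.81)
    R = pp.estimate_static_inclination(v)
    np.testing.assert_allclose(R @ v, [0, 0, np.linalg.norm(v)], atol=1e-8)
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)


# ---------------------------------------------------------------------------
# orientation integration
# ---------------------------------------------------------------------------

def test_integration_zero_rate_is_constant():
    R0 = Rotation.from_euler("xyz", [0.3, -0.2, 1.0]).as_matrix()
    series = pp.integrate_orientation(R0, np.zeros((240, 3)), 120.0)
    np.testing.assert_allclose(series, np.broadcast_to(R0, (240, 3, 3)), atol=1e-12)


@pytest.mark.parametrize(
    "omega, duration",
    [((0.0, 0.0, 1.0), 1.0), ((np.pi / 2, 0.0, 0.0), 1.0), ((0.4, -0.7, 0.2), 2.0)],
)
def test_integration_matches_matrix_exponential(omega, duration):
    """Constant rate: R(t) = R0 exp([w]x t) in closed form."""
    fs = 120.0
    n = int(duration * fs) + 1
    gyr = np.tile(omega, (n, 1))
    R0 = Rotation.from_euler("zx", [0.5, -0.3]).as_matrix()
    series = pp.integrate_orientation(R0, gyr, fs)
    expected = R0 @ Rotation.from_rotvec(np.array(omega) * duration).as_matrix()
    np.testing.assert_allclose(series[-1], expected, atol=1e-6)


def test_integration_stays_orthonormal(rng):
    gyr = rng.normal(0, 2.0, size=(1000, 3))
    series = pp.integrate_orientation(np.eye(3), gyr, 120.0)
    prods = np.einsum("nji,njk->nik", series, series)
    np.testing.assert_allclose(prods, np.broadcast_to(np.eye(3), (1000, 3, 3)),
                               atol=1e-9)


def test_integration_rejects_nonfinite():
    gyr = np.zeros((10, 3))
    gyr[3, 0] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        pp.integrate_orientation(np.eye(3), gyr, 120.0)


# ---------------------------------------------------------------------------
# leveling and gravity removal
# ---------------------------------------------------------------------------

def test_gravity_cancels_for_static_sensor(rng):
    R_mount = Rotation.random(rng=rng).as_matrix()
    n = 360
    acc = np.tile(R_mount.T @ [0, 0, 9.81], (n, 1))
    rec = SensorRecording("s", acc, np.zeros((n, 3)))
    R0 = pp.estimate_static_inclination(acc[:120].mean(axis=0))
    series = pp.integrate_orientation(R0, rec.gyr, 120.0)
    lev = pp.level_and_remove_gravity(rec, series, 120.0)
    np.testing.assert_allclose(lev.acc, 0.0, atol=1e-9)


def test_direct_subtraction_with_identity_rotation():
    n = 240
    rec = SensorRecording("s", np.tile([1.0, 0.0, 9.81], (n, 1)), np.zeros((n, 3)))
    series = np.broadcast_to(np.eye(3), (n, 3, 3))
    lev = pp.level_and_remove_gravity(rec, series, 120.0)
    np.testing.assert_allclose(lev.acc, np.tile([1.0, 0, 0], (n, 1)), atol=1e-12)


def test_velocity_is_trapezoidal_integral():
    fs, dur = 120.0, 2.0
    n = int(fs * dur) + 1
    rec = SensorRecording(
        "s", np.tile([0.1, 0.0, 9.81], (n, 1)), np.zeros((n, 3))
    )
    series = np.broadcast_to(np.eye(3), (n, 3, 3))
    lev = pp.level_and_remove_gravity(rec, series, fs)
    np.testing.assert_allclose(lev.vel[-1], [0.2, 0, 0], atol=1e-9)


# ---------------------------------------------------------------------------
# heading
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mean_v, expected",
    [((1.4, 0.0), 0.0), ((0.0, 1.4), np.pi / 2), ((1.0, -1.0), -np.pi / 4)],
)
def test_heading_is_signed_angle_of_mean_velocity(mean_v, expected):
    vel = np.tile([mean_v[0], mean_v[1], 0.37], (50, 1))
    assert pp.estimate_heading(vel, (0, 50)) == pytest.approx(expected, abs=1e-12)


def test_heading_rejects_near_zero_speed():
    vel = np.full((50, 3), 0.01)
    with pytest.raises(ValueError, match="undefined"):
        pp.estimate_heading(vel, (0, 50))


def test_apply_heading_zero_is_identity(rng):
    sig = pp.LeveledSignals(
        acc=rng.normal(size=(100, 3)), gyr=rng.normal(size=(100, 3)),
        vel=np.zeros((100, 3)), fs=120.0,
    )
    out = pp.apply_heading(sig, 0.0)
    np.testing.assert_allclose(out.acc, sig.acc, atol=1e-12)
    np.testing.assert_allclose(out.gyr, sig.gyr, atol=1e-12)


def test_apply_heading_aligns_and_preserves_z(rng):
    acc = rng.normal(size=(200, 3))
    vel = np.tile([1.0, 1.0, 0.0], (200, 1))
    sig = pp.LeveledSignals(acc=acc, gyr=acc.copy(), vel=vel, fs=120.0)
    theta = pp.estimate_heading(vel, (0, 200))
    out = pp.apply_heading(sig, theta)
    # the rotation that maps the velocity onto +x maps (1,1,0) to (sqrt2,0,0)
    rot_v = np.array([
        np.cos(theta) * 1 + np.sin(theta) * 1,
        -np.sin(theta) * 1 + np.cos(theta) * 1,
    ])
    np.testing.assert_allclose(rot_v, [np.sqrt(2), 0], atol=1e-12)
    np.testing.assert_allclose(out.acc[:, 2], acc[:, 2], atol=1e-12)


# ---------------------------------------------------------------------------
# angular acceleration
# ---------------------------------------------------------------------------

def test_angular_acceleration_constant_rate_is_zero():
    gyr = np.tile([0.3, -0.1, 0.8], (100, 1))
    np.testing.assert_allclose(pp.angular_acceleration(gyr, 120.0), 0.0, atol=1e-12)


def test_angular_acceleration_exact_for_linear_ramp():
    t = np.arange(300) / 120.0
    gyr = np.zeros((300, 3))
    gyr[:, 2] = t
    alpha = pp.angular_acceleration(gyr, 120.0)
    np.testing.assert_allclose(alpha[1:-1, 2], 1.0, atol=1e-10)
    np.testing.assert_allclose(alpha[:, :2], 0.0, atol=1e-12)


def test_angular_acceleration_sine_error_within_taylor_bound():
    # central difference of sin(2 pi t) at 120 Hz: exact error
    # 2 pi (1 - sinc(2 pi /120)) = 2.87e-3, the h^2/6 ||w'''|| bound
    fs = 120.0
    t = np.arange(int(2 * fs)) / fs
    gyr = np.zeros((len(t), 3))
    gyr[:, 1] = np.sin(2 * np.pi * t)
    alpha = pp.angular_acceleration(gyr, fs)
    true = 2 * np.pi * np.cos(2 * np.pi * t)
    err = np.abs(alpha[1:-1, 1] - true[1:-1]).max()
    assert err < (2 * np.pi) ** 3 / (6 * fs**2) * 1.01


def test_angular_acceleration_needs_three_samples():
    with pytest.raises(ValueError, match="3 samples"):
        pp.angular_acceleration(np.zeros((2, 3)), 120.0)


# ---------------------------------------------------------------------------
# cycle detection
# ---------------------------------------------------------------------------

def test_flat_summary_means_no_gait():
    with pytest.raises(ValueError, match="no gait"):
        pp.detect_walking_cycles(np.ones(1200), 120.0)


def test_cycles_recovered_from_constructed_waveform():
    fs, stride = 120.0, 1.1
    step = stride / 2
    t = np.arange(int(6 * fs)) / fs
    # one peak per step: |sin(pi t / step)| peaks at t = step/2 + k step
    summary = 50 + 40 * np.abs(np.sin(np.pi * t / step))
    cycles = pp.detect_walking_cycles(summary, fs)
    # stride boundaries are every second step peak
    expected = np.arange(step / 2, 6.0, stride) * fs
    got = cycles.boundaries[: len(expected)]
    np.testing.assert_allclose(got, expected[: len(got)], atol=2)


def test_simulated_trial_yields_requested_cycle_count(nf_pre, nf_sim):
    assert nf_pre.cycles.n_cycles == nf_sim.params.n_cycles
    strides = np.diff(nf_pre.cycles.boundaries) / nf_sim.trial.fs
    np.testing.assert_allclose(strides, nf_sim.params.stride_period, atol=0.05)


def test_static_interval_detection(nf_sim):
    start, end = pp.detect_static_interval(nf_sim.trial)
    assert start == 0
    # static prefix is 3 s; gait initiation follows shortly after
    assert 2.5 * 120 <= end <= 3.5 * 120


# ---------------------------------------------------------------------------
# whole-pipeline properties
# ---------------------------------------------------------------------------

def test_frame_recovery_noise_free(nf_sim, nf_pre):
    """Recovered global-frame signals match the constructed gait frame to
    well under a degree of residual yaw for every sensor."""
    w0, w1 = nf_pre.window
    for sid, sig in nf_pre.signals.items():
        err = _planar_yaw_error_deg(
            nf_sim.gait_frame_acc[sid][w0:w1, :2], sig.acc[:, :2]
        )
        assert abs(err) < 1.0


def test_frame_recovery_under_accelerometer_bias(nf_params):
    sim = simulate_trial(replace(nf_params, acc_bias=0.02, seed=5))
    pre = pp.preprocess_trial(sim.trial)
    w0, w1 = pre.window
    for sid, sig in pre.signals.items():
        err = _planar_yaw_error_deg(
            sim.gait_frame_acc[sid][w0:w1, :2], sig.acc[:, :2]
        )
        assert abs(err) < 4.0


def test_pipeline_equivariant_to_common_sensor_rotation(nf_sim, nf_pre, rng):
    """Rotating all raw sensor data by one fixed rotation only re-mounts the
    sensors; inclination and heading estimation absorb it."""
    Q = Rotation.random(rng=rng).as_matrix()
    t = nf_sim.trial
    rotated = Trial(
        sensors=[
            SensorRecording(r.sensor_id, r.acc @ Q.T, r.gyr @ Q.T)
            for r in t.sensors
        ],
        fs=t.fs,
        static_interval=t.static_interval,
        config=t.config,
        labels=t.labels,
        trial_id=t.trial_id,
    )
    pre2 = pp.preprocess_trial(rotated)
    assert pre2.window == nf_pre.window
    for sid in nf_pre.signals:
        np.testing.assert_allclose(
            pre2.signals[sid].acc, nf_pre.signals[sid].acc, atol=1e-6
        )
        np.testing.assert_allclose(
            pre2.signals[sid].gyr, nf_pre.signals[sid].gyr, atol=1e-6
        )


def test_gravity_conservation_during_static(noisy_sim):
    """After leveling, the mean residual acceleration over the static
    interval stays below a few noise standard deviations."""
    t = noisy_sim.trial
    s0, s1 = t.static_interval
    sigma = noisy_sim.params.noise_sigma_acc
    for rec in t.sensors:
        R0 = pp.estimate_static_inclination(rec.acc[s0:s1].mean(axis=0))
        series = pp.integrate_orientation(R0, rec.gyr, t.fs)
        lev = pp.level_and_remove_gravity(rec, series, t.fs)
        mean_residual = np.linalg.norm(lev.acc[s0:s1].mean(axis=0))
        assert mean_residual < 3 * sigma
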