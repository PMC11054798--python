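"""Synthetic split-belt treadmill walking sessions with ground truth.

Generates sagittal-plane rigid-body walking data — four IMU streams (thigh
and shank of each leg), vertical heel-marker trajectories, and ground-truth
gait phase and heel-strike events — under a configurable schedule of
walking conditions (constant speed, stride-length changes, speed sweeps and
jumps, belt asymmetry, stop-and-go).

Model summary
-------------
Each leg's gait phase integrates a cadence that grows with that leg's belt
speed (stride frequency = a*sqrt(v) + b strides/s, divided by the
condition's stride-length scale); the left leg runs half a cycle ahead so
heel strikes interleave. Hip and knee angles are smooth per-subject
templates of phase (two-harmonic series, plus a swing-phase bump for the
knee). Segment orientations, angular rates, and sensor-point accelerations
(including gravity, 9.81 m/s^2 downward) follow from rigid-body forward
kinematics with the hip fixed in space. A 50 ms damped-sinusoid transient
is added to the shank (and, attenuated, thigh) accelerometer at each heel
strike, mimicking impact; white noise is added to all inertial channels.
During zero-belt-speed intervals the phase is frozen and flagged invalid.

World frame: x forward, y left, z up. Thigh/shank sensors are mounted
anatomically aligned: sensor x mediolateral (pointing left), z proximal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .calibration import SegmentCalibration
from .labeling import GaitEvents, PhaseSeries

__all__ = [
    "GaitCondition",
    "SubjectParams",
    "ImuStream",
    "SyntheticSession",
    "make_protocol",
    "joint_trajectories",
    "simulate_imu",
    "generate_dataset",
    "default_calibrations",
    "make_calibration_stream",
    "CONDITION_NAMES",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2, downward
SENSOR_NAMES = ("thigh_r", "shank_r", "thigh_l", "shank_l")

CONDITION_NAMES = frozenset({
    "normal_stride", "short_stride", "long_stride", "speed_sweep",
    "speed_jump", "asymmetric_left", "asymmetric_right", "stop_go",
})


@dataclass(frozen=True)
class GaitCondition:
    """One treadmill condition: a per-belt speed profile over a duration.

    The profile is piecewise over knots at fractions of the duration;
    ``interp`` is ``"linear"`` for ramps or ``"step"`` for holds (the value
    at a knot applies until the next knot).
    """

    name: str
    duration: float
    knots: tuple[float, ...]  # fractions of duration in [0, 1]
    v_left: tuple[float, ...]  # m/s at each knot
    v_right: tuple[float, ...]
    interp: str = "linear"
    stride_length_scale: float = 1.0

    def __post_init__(self):
        if self.name not in CONDITION_NAMES:
            raise ValueError(
                f"unknown condition name '{self.name}'; "
                f"valid: {sorted(CONDITION_NAMES)}"
            )
        if self.duration <= 0:
            raise ValueError("condition duration must be positive")
        if not (len(self.knots) == len(self.v_left) == len(self.v_right)):
            raise ValueError("knots and speed lists must have equal length")
        speeds = np.concatenate([self.v_left, self.v_right])
        if np.any(speeds < 0) or np.any(speeds > 2.0):
            raise ValueError("belt speeds must lie within [0, 2.0] m/s")
        if self.interp not in ("linear", "step"):
            raise ValueError("interp must be 'linear' or 'step'")
        if self.name.startswith("asymmetric") and np.array_equal(
            self.v_left, self.v_right
        ):
            raise ValueError("asymmetric conditions need unequal belt profiles")
        if self.stride_length_scale <= 0:
            raise ValueError("stride_length_scale must be positive")

    def belt_speeds(self, t_rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Left/right belt speed at times relative to condition onset."""
        x = np.clip(np.asarray(t_rel, dtype=float) / self.duration, 0.0, 1.0)
        k = np.asarray(self.knots)
        if self.interp == "linear":
            vl = np.interp(x, k, self.v_left)
            vr = np.interp(x, k, self.v_right)
        else:
            idx = np.clip(np.searchsorted(k, x, side="right") - 1, 0, len(k) - 1)
            vl = np.asarray(self.v_left)[idx]
            vr = np.asarray(self.v_right)[idx]
        return vl, vr


@dataclass(frozen=True)
class SubjectParams:
    """Anthropometry, gait-template, and noise parameters of one subject."""

    thigh_length: float = 0.42  # m
    shank_length: float = 0.41  # m
    sensor_offset_thigh: float = 0.21  # m from hip along thigh
    sensor_offset_shank: float = 0.20  # m from knee along shank
    cadence_a: float = 0.55  # strides/s per sqrt(m/s)
    cadence_b: float = 0.25  # strides/s intercept
    hip_coeffs: tuple[float, ...] = (0.15, 0.35, 0.0, 0.05, 0.15)
    # (mean, amp1, phase1, amp2, phase2) of the hip-angle harmonic template
    knee_coeffs: tuple[float, ...] = (0.30, 0.18, 0.60, 0.08, 0.15, 0.75, 0.72, 12.0)
    # (mean, amp1, phase1, amp2, phase2, bump_amp, bump_center, bump_kappa)
    heel_lift: float = 0.15  # m, swing-phase heel clearance
    noise_std_accel: float = 0.25  # m/s^2
    noise_std_gyro: float = 0.015  # rad/s
    rng_seed: int = 0

    def __post_init__(self):
        if self.thigh_length <= 0 or self.shank_length <= 0:
            raise ValueError("segment lengths must be positive")
        if not (0 < self.sensor_offset_thigh <= self.thigh_length):
            raise ValueError("thigh sensor offset outside segment")
        if not (0 < self.sensor_offset_shank <= self.shank_length):
            raise ValueError("shank sensor offset outside segment")
        if self.noise_std_accel < 0 or self.noise_std_gyro < 0:
            raise ValueError("noise levels must be non-negative")

    def cadence(self, belt_speed: np.ndarray, stride_scale: float | np.ndarray = 1.0):
        """Stride frequency (strides/s): (a*sqrt(v) + b)/scale, 0 when stopped."""
        v = np.asarray(belt_speed, dtype=float)
        f = (self.cadence_a * np.sqrt(np.maximum(v, 0.0)) + self.cadence_b)
        f = f / np.asarray(stride_scale, dtype=float)
        return np.where(v > 1e-9, f, 0.0)

    def hip_angle(self, phi, amp_scale=1.0):
        m, a1, p1, a2, p2 = self.hip_coeffs
        s = np.asarray(amp_scale, dtype=float)
        return m + s * (
            a1 * np.cos(2 * np.pi * (np.asarray(phi) - p1))
            + a2 * np.cos(4 * np.pi * (np.asarray(phi) - p2))
        )

    def hip_angle_dphi(self, phi, amp_scale=1.0):
        _, a1, p1, a2, p2 = self.hip_coeffs
        s = np.asarray(amp_scale, dtype=float)
        return s * (
            -2 * np.pi * a1 * np.sin(2 * np.pi * (np.asarray(phi) - p1))
            - 4 * np.pi * a2 * np.sin(4 * np.pi * (np.asarray(phi) - p2))
        )

    def knee_angle(self, phi, amp_scale=1.0):
        m, a1, p1, a2, p2, ba, bc, bk = self.knee_coeffs
        phi = np.asarray(phi)
        s = np.asarray(amp_scale, dtype=float)
        bump = ba * np.exp(bk * (np.cos(2 * np.pi * (phi - bc)) - 1.0))
        return m + s * (
            a1 * np.cos(2 * np.pi * (phi - p1))
            + a2 * np.cos(4 * np.pi * (phi - p2))
            + bump
        )

    def knee_angle_dphi(self, phi, amp_scale=1.0):
        _, a1, p1, a2, p2, ba, bc, bk = self.knee_coeffs
        phi = np.asarray(phi)
        s = np.asarray(amp_scale, dtype=float)
        dbump = (
            ba
            * np.exp(bk * (np.cos(2 * np.pi * (phi - bc)) - 1.0))
            * (-bk * 2 * np.pi * np.sin(2 * np.pi * (phi - bc)))
        )
        return s * (
            -2 * np.pi * a1 * np.sin(2 * np.pi * (phi - p1))
            - 4 * np.pi * a2 * np.sin(4 * np.pi * (phi - p2))
            + dbump
        )

    def heel_height(self, phi):
        """Heel-marker height template: strict minimum at phase 0."""
        phi = np.asarray(phi)
        # swing-clearance bump (decayed to ~0 before heel strike) and a
        # narrow impact dip: minimum, and a sharp peak of the vertical
        # acceleration, exactly at phi = 0
        swing = np.exp(20.0 * (np.cos(2 * np.pi * (phi - 0.78)) - 1.0))
        dip = 0.012 * np.exp(25.0 * (np.cos(2 * np.pi * phi) - 1.0))
        return 0.03 + self.heel_lift * swing - dip


@dataclass
class ImuStream:
    """Timestamped tri-axial accel/gyro and orientation for one sensor.

    ``quat`` rows are (w, x, y, z) unit quaternions mapping sensor-frame
    vectors into the world frame.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray

    def __post_init__(self):
        n = self.t.size
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro must be (N, 3)")
        if self.quat.shape != (n, 4):
            raise ValueError("quat must be (N, 4) in wxyz order")


@dataclass
class SyntheticSession:
    """One simulated treadmill session with full ground truth."""

    imu: dict[str, ImuStream]
    heel_z: dict[str, np.ndarray]
    truth_phase: PhaseSeries
    truth_events: dict[str, GaitEvents]
    schedule: list[GaitCondition]
    subject: SubjectParams
    fs: float = 100.0
    subject_id: str = "synthetic"

    @property
    def time(self) -> np.ndarray:
        return self.imu["thigh_r"].t

    def condition_index(self) -> np.ndarray:
        """Per-sample index into ``schedule`` (0-based)."""
        t = self.time
        bounds = np.cumsum([c.duration for c in self.schedule])
        return np.clip(np.searchsorted(bounds, t, side="right"), 0,
                       len(self.schedule) - 1)


def _const(name, dur, v, scale=1.0):
    return GaitCondition(name=name, duration=dur, knots=(0.0, 1.0),
                         v_left=(v, v), v_right=(v, v), interp="linear",
                         stride_length_scale=scale)


def make_protocol(
    profile: str | list[GaitCondition] = "paper",
    *,
    duration_scale: float = 1.0,
) -> list[GaitCondition]:
    """Build an ordered condition schedule.

    The ``"paper"`` preset has 8 conditions: normal, short, and long
    strides, then normal again, each at 0.8 m/s; a speed sweep 0.1 -> 1.9
    -> 0.1 m/s; stepped speed holds at 0.2, 0.4, 0.8 m/s; a split-belt
    asymmetric condition (left belt slowed to 0.4 m/s, then the right); and
    alternating full stops with walking at 0.8 m/s. ``duration_scale``
    shrinks every condition proportionally for desk-scale runs.
    """
    if isinstance(profile, list):
        if not profile:
            raise ValueError("explicit condition list must be nonempty")
        return list(profile)
    if profile != "paper":
        raise ValueError(f"unknown preset '{profile}'; valid presets: ['paper']")

    ds = duration_scale
    sweep = GaitCondition(
        name="speed_sweep", duration=120.0 * ds, knots=(0.0, 0.5, 1.0),
        v_left=(0.1, 1.9, 0.1), v_right=(0.1, 1.9, 0.1), interp="linear",
    )
    jump = GaitCondition(
        name="speed_jump", duration=90.0 * ds, knots=(0.0, 1 / 3, 2 / 3),
        v_left=(0.2, 0.4, 0.8), v_right=(0.2, 0.4, 0.8), interp="step",
    )
    # Left belt slowed for the first half, right belt for the second.
    asym = GaitCondition(
        name="asymmetric_left", duration=90.0 * ds, knots=(0.0, 0.5),
        v_left=(0.4, 0.8), v_right=(0.8, 0.4), interp="step",
    )
    # Walk/stop cycles: walk two thirds, stand one third, three cycles.
    k = []
    vl = []
    for i in range(3):
        k += [i / 3, i / 3 + 2 / 9]
        vl += [0.8, 0.0]
    stop_go = GaitCondition(
        name="stop_go", duration=90.0 * ds, knots=tuple(k),
        v_left=tuple(vl), v_right=tuple(vl), interp="step",
    )
    return [
        _const("normal_stride", 45.0 * ds, 0.8),
        _const("short_stride", 45.0 * ds, 0.8, scale=0.75),
        _const("long_stride", 45.0 * ds, 0.8, scale=1.3),
        _const("normal_stride", 45.0 * ds, 0.8),
        sweep,
        jump,
        asym,
        stop_go,
    ]


def _schedule_speeds(schedule, t):
    """Per-sample left/right belt speed and stride-length scale."""
    vl = np.zeros_like(t)
    vr = np.zeros_like(t)
    scale = np.ones_like(t)
    t0 = 0.0
    for cond in schedule:
        sel = (t >= t0) & (t < t0 + cond.duration)
        l, r = cond.belt_speeds(t[sel] - t0)
        vl[sel] = l
        vr[sel] = r
        scale[sel] = cond.stride_length_scale
        t0 += cond.duration
    return vl, vr, scale


def joint_trajectories(
    schedule: list[GaitCondition],
    subject: SubjectParams,
    fs: float = 100.0,
) -> dict:
    """Integrate per-leg phase and evaluate the joint-angle templates.

    Returns a dict with the time grid and, per leg (``"r"``/``"l"``):
    unwrapped phase, wrapped phase, validity mask, heel-strike sample times,
    hip/knee angles and their analytic time derivatives, and per-sample
    cadence. The left leg starts half a stride ahead so heel strikes of the
    two legs interleave.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    total = sum(c.duration for c in schedule)
    n = int(round(total * fs))
    t = np.arange(n) / fs
    if n == 0:
        return {"t": t, "legs": {}}
    vl, vr, scale = _schedule_speeds(schedule, t)

    out = {"t": t, "legs": {}, "amp_scale": scale}
    for leg, v, offset in (("r", vr, 0.0), ("l", vl, 0.5)):
        f = subject.cadence(v, scale)
        phi_u = offset + cumulative_trapezoid(f, t, initial=0.0)
        # Heel strikes at integer crossings of the unwrapped phase,
        # snapped to the nearest sample.
        k0 = int(np.ceil(phi_u[0] + 1e-12))
        crossings = []
        for k in range(k0, int(np.floor(phi_u[-1])) + 1):
            i = int(np.searchsorted(phi_u, k))
            if i == 0 or i >= n:
                continue
            # linear interpolation between samples i-1 and i
            den = phi_u[i] - phi_u[i - 1]
            frac = (k - phi_u[i - 1]) / den if den > 0 else 0.0
            crossings.append((i - 1 + frac) / fs)
        events = np.round(np.asarray(crossings) * fs) / fs
        events = np.unique(events)

        moving = f > 0.0
        # stride-length scale modulates template amplitudes
        out["legs"][leg] = {
            "phi_unwrapped": phi_u,
            "phi": np.mod(phi_u, 1.0),
            "valid": moving,
            "events": events,
            "cadence": f,
            "hip": subject.hip_angle(phi_u, scale),
            "knee": subject.knee_angle(phi_u, scale),
            "hip_dot": subject.hip_angle_dphi(phi_u, scale) * f,
            "knee_dot": subject.knee_angle_dphi(phi_u, scale) * f,
        }
    return out


# Sensor-frame axes at upright posture, expressed in world coordinates:
# sensor x = world y (left), sensor y = -world x (backward), sensor z = up.
_F_MOUNT = np.array([[0.0, -1.0, 0.0],
                     [1.0, 0.0, 0.0],
                     [0.0, 0.0, 1.0]])


def _second_derivative(p: np.ndarray, dt: float) -> np.ndarray:
    """Second time derivative by repeated central differences."""
    v = np.gradient(p, dt, axis=0)
    return np.gradient(v, dt, axis=0)


def _heel_transient(t, events, fs, amp, rng_phase=0.0):
    """Sum of 50 ms damped sinusoids, one per heel strike."""
    out = np.zeros_like(t)
    dur = 0.05
    for te in events:
        i0 = int(round(te * fs))
        i1 = min(len(t), i0 + int(dur * fs) + 1)
        if i0 >= len(t):
            continue
        tau = t[i0:i1] - te
        out[i0:i1] += amp * np.exp(-tau / 0.015) * np.sin(2 * np.pi * 25.0 * tau)
    return out


def simulate_imu(
    traj: dict,
    subject: SubjectParams,
    fs: float = 100.0,
    *,
    rng: np.random.Generator | None = None,
    heel_transient_amp: float = 4.0,
) -> tuple[dict[str, ImuStream], dict[str, np.ndarray]]:
    """Forward-kinematics IMU synthesis from joint-angle trajectories.

    Orientations follow the segment angles exactly; gyroscopes carry the
    analytic angular rate in the sensor frame; accelerometers measure the
    specific force (linear acceleration minus gravity) at the sensor point,
    expressed in the sensor frame, plus the heel-strike transient and white
    noise. Also returns the per-leg vertical heel-marker trajectory.
    """
    if rng is None:
        rng = np.random.default_rng(subject.rng_seed)
    t = traj["t"]
    dt = 1.0 / fs
    hip_point = np.array([0.0, 0.0, subject.thigh_length + subject.shank_length + 0.1])
    g_comp = np.array([0.0, 0.0, GRAVITY])  # -gravity, i.e. specific force at rest

    streams: dict[str, ImuStream] = {}
    heel: dict[str, np.ndarray] = {}
    for leg in ("r", "l"):
        lt = traj["legs"][leg]
        theta_t = lt["hip"]  # thigh pitch, forward positive
        theta_s = theta_t - lt["knee"]  # shank pitch
        omega_t = lt["hip_dot"]
        omega_s = omega_t - lt["knee_dot"]

        other_events = traj["legs"]["l" if leg == "r" else "r"]["events"]
        for seg, theta, omega, offset, trans_amp, contra_amp in (
            ("thigh", theta_t, omega_t, subject.sensor_offset_thigh,
             0.3 * heel_transient_amp, 0.1 * heel_transient_amp),
            ("shank", theta_s, omega_s,
             subject.thigh_length + subject.sensor_offset_shank,
             heel_transient_amp, 0.2 * heel_transient_amp),
        ):
            # sensor position: hip joint, down the thigh, then down the shank
            if seg == "thigh":
                u = np.stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)], 1)
                pos = hip_point - subject.sensor_offset_thigh * u
            else:
                ut = np.stack([np.sin(theta_t), np.zeros_like(theta_t),
                               np.cos(theta_t)], 1)
                us = np.stack([np.sin(theta), np.zeros_like(theta),
                               np.cos(theta)], 1)
                pos = (hip_point - subject.thigh_length * ut
                       - subject.sensor_offset_shank * us)

            rot = (Rotation.from_euler("y", theta[:, None])
                   * Rotation.from_matrix(_F_MOUNT))
            acc_world = _second_derivative(pos, dt)
            acc_sens = rot.inv().apply(acc_world + g_comp)

            # heel-strike transients: strongest on the ipsilateral shank,
            # attenuated on the thigh and contralateral sensors
            transient = (_heel_transient(t, lt["events"], fs, trans_amp)
                         + _heel_transient(t, other_events, fs, contra_amp))
            acc_sens[:, 2] += transient

            gyro = np.zeros_like(acc_sens)
            gyro[:, 0] = omega  # flexion axis = sensor x
            acc_sens = acc_sens + rng.normal(0.0, subject.noise_std_accel,
                                             acc_sens.shape)
            gyro = gyro + rng.normal(0.0, subject.noise_std_gyro, gyro.shape)

            q = rot.as_quat()  # xyzw
            quat = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
            streams[f"{seg}_{leg}"] = ImuStream(
                t=t, accel=acc_sens, gyro=gyro, quat=quat
            )
        heel[leg] = subject.heel_height(lt["phi"])
    return streams, heel


def simulate_session(
    schedule: list[GaitCondition],
    subject: SubjectParams,
    fs: float = 100.0,
    subject_id: str = "synthetic",
) -> SyntheticSession:
    """Run the full simulator for one subject and schedule."""
    traj = joint_trajectories(schedule, subject, fs)
    rng = np.random.default_rng(subject.rng_seed)
    streams, heel = simulate_imu(traj, subject, fs, rng=rng)
    phase = PhaseSeries(
        time=traj["t"],
        phi_r=traj["legs"]["r"]["phi"],
        phi_l=traj["legs"]["l"]["phi"],
        valid_r=traj["legs"]["r"]["valid"],
        valid_l=traj["legs"]["l"]["valid"],
    )
    events = {leg: GaitEvents(traj["legs"][leg]["events"]) for leg in ("r", "l")}
    return SyntheticSession(
        imu=streams, heel_z=heel, truth_phase=phase, truth_events=events,
        schedule=list(schedule), subject=subject, fs=fs, subject_id=subject_id,
    )


def draw_subject(rng: np.random.Generator, seed: int) -> SubjectParams:
    """Draw one subject's parameters from documented population ranges."""
    jitter = lambda lo, hi: float(rng.uniform(lo, hi))
    hip = (jitter(0.10, 0.20), jitter(0.30, 0.40), jitter(-0.03, 0.03),
           jitter(0.03, 0.07), jitter(0.10, 0.20))
    knee = (jitter(0.25, 0.35), jitter(0.14, 0.22), jitter(0.55, 0.65),
            jitter(0.05, 0.11), jitter(0.10, 0.20), jitter(0.65, 0.85),
            jitter(0.70, 0.74), jitter(10.0, 14.0))
    thigh = jitter(0.38, 0.46)
    shank = jitter(0.38, 0.44)
    return SubjectParams(
        thigh_length=thigh,
        shank_length=shank,
        sensor_offset_thigh=jitter(0.4, 0.6) * thigh,
        sensor_offset_shank=jitter(0.4, 0.6) * shank,
        cadence_a=jitter(0.50, 0.60),
        cadence_b=jitter(0.20, 0.30),
        hip_coeffs=hip,
        knee_coeffs=knee,
        heel_lift=jitter(0.12, 0.18),
        noise_std_accel=0.25,
        noise_std_gyro=0.015,
        rng_seed=seed,
    )


def generate_dataset(
    n_subjects: int,
    profile: str | list[GaitCondition] = "paper",
    master_seed: int = 0,
    *,
    duration_scale: float = 1.0,
    fs: float = 100.0,
) -> list[SyntheticSession]:
    """Generate one session per subject, reproducibly from ``master_seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    schedule = make_protocol(profile, duration_scale=duration_scale)
    ss = np.random.SeedSequence(master_seed)
    sessions = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        seed = int(child.generate_state(1)[0] % (2**31))
        subject = draw_subject(rng, seed)
        sessions.append(
            simulate_session(schedule, subject, fs, subject_id=f"S{i:02d}")
        )
    return sessions


def default_calibrations() -> dict[str, SegmentCalibration]:
    """Exact sensor-to-segment calibrations for the simulator's mounting.

    Thigh sensors are already segment-aligned (hip flexion positive about
    sensor +x). For shank sensors the knee flexion axis is -x (knee flexion
    tilts the shank backward), so the segment frame is the sensor frame
    rotated half a turn about z.
    """
    thigh = SegmentCalibration(
        rotation=Rotation.identity(),
        flexion_axis=np.array([1.0, 0.0, 0.0]),
        quality=0.0,
    )
    shank = SegmentCalibration(
        rotation=Rotation.from_euler("z", np.pi),
        flexion_axis=np.array([-1.0, 0.0, 0.0]),
        quality=0.0,
    )
    return {"thigh_r": thigh, "shank_r": shank,
            "thigh_l": thigh, "shank_l": shank}


def make_calibration_stream(
    kind: str,
    fs: float = 100.0,
    *,
    mount: Rotation | None = None,
    noise_std_gyro: float = 0.0,
    noise_std_accel: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a functional-calibration trial for one sensor.

    Returns ``(gyro, accel_still)``: 4 s of flexion-extension angular
    velocity beginning with flexion, and 1 s of still-period accelerometer
    data. ``kind`` is ``"thigh"`` (hip flexion-extension) or ``"shank"``
    (knee flexion-extension). ``mount`` optionally remounts the sensor:
    measured vectors are the anatomical ones rotated by ``mount.inv()``.
    """
    if kind not in ("thigh", "shank"):
        raise ValueError("kind must be 'thigh' or 'shank'")
    rng = np.random.default_rng(seed)
    t = np.arange(int(4 * fs)) / fs
    angle_rate = 0.8 * 2 * np.pi * 0.5 * np.cos(2 * np.pi * 0.5 * t)
    # thigh: hip flexion positive about sensor +x; shank: knee flexion
    # rotates the shank about sensor -x, so the trial starts negative there.
    sign = 1.0 if kind == "thigh" else -1.0
    gyro = np.zeros((t.size, 3))
    gyro[:, 0] = sign * angle_rate
    accel_still = np.tile([0.0, 0.0, GRAVITY], (int(fs), 1))
    if mount is not None:
        gyro = mount.inv().apply(gyro)
        accel_still = mount.inv().apply(accel_still)
    gyro = gyro + rng.normal(0.0, noise_std_gyro, gyro.shape)
    accel_still = accel_still + rng.normal(0.0, noise_std_accel, accel_still.shape)
    return gyro, accel_still
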