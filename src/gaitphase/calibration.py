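"""Sensor-to-segment functional calibration and input feature derivation.

Segment frame convention: x is the flexion (mediolateral) axis, z is the
segment longitudinal axis pointing proximally, y = z cross x. The flexion
axis sign is fixed so that the prescribed calibration movement — which must
begin with flexion (hip flexion for a thigh sensor, knee flexion for a
shank sensor) — produces positive angular velocity about +x. Pitch is the
signed sagittal inclination of the segment longitudinal axis from vertical,
positive in the flexion direction; it is computed from where world-up lands
in the segment frame, so it does not depend on the sensor-fusion heading.

Feature channels per leg (order fixed):
knee_flexion, thigh_pitch, shank_pitch, thigh_a_z, shank_a_z,
thigh_a_xy_mag, shank_a_xy_mag, thigh_w_flex, shank_w_flex, thigh_w_res_mag.
Right-leg channels precede left-leg channels, 20 channels total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter
from scipy.spatial.transform import Rotation

__all__ = [
    "SegmentCalibration",
    "FeatureSeries",
    "functional_calibration",
    "segment_pitch",
    "knee_flexion",
    "filter_accel",
    "extract_feature_channels",
    "CHANNELS_PER_LEG",
    "channel_names",
]

CHANNELS_PER_LEG = [
    "knee_flexion",
    "thigh_pitch",
    "shank_pitch",
    "thigh_a_z",
    "shank_a_z",
    "thigh_a_xy_mag",
    "shank_a_xy_mag",
    "thigh_w_flex",
    "shank_w_flex",
    "thigh_w_res_mag",
]


def channel_names(include_shank_pitch: bool = True) -> list[str]:
    """Ordered feature channel names, right leg then left leg."""
    per_leg = [c for c in CHANNELS_PER_LEG if include_shank_pitch or c != "shank_pitch"]
    return [f"{c}_{leg}" for leg in ("r", "l") for c in per_leg]


class CalibrationError(ValueError):
    """Raised when a calibration stream cannot yield a segment frame."""


@dataclass(frozen=True)
class SegmentCalibration:
    """Rotation aligning one sensor's frame with its segment frame.

    ``rotation`` maps sensor-frame vectors into the segment frame
    (v_segment = rotation.apply(v_sensor)). ``flexion_axis`` is the unit
    flexion axis expressed in the sensor frame; the rotation maps it onto
    segment +x. ``quality`` is the residual angle in degrees between the
    mapped gravity direction and the segment -z axis.
    """

    rotation: Rotation
    flexion_axis: np.ndarray
    quality: float

    def __post_init__(self):
        ax = np.asarray(self.flexion_axis, dtype=float).ravel()
        if ax.shape != (3,) or not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-6):
            raise ValueError("flexion_axis must be a unit 3-vector")
        object.__setattr__(self, "flexion_axis", ax)


@dataclass
class FeatureSeries:
    """100 Hz multichannel feature sequence for both legs."""

    time: np.ndarray
    data: np.ndarray  # (N, C)
    names: list[str]

    def __post_init__(self):
        if self.data.shape != (self.time.size, len(self.names)):
            raise ValueError("feature matrix shape does not match time/names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def _quat_wxyz_to_rotation(q: np.ndarray) -> Rotation:
    """Build a Rotation from (w, x, y, z) quaternion rows, validating norm."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    norms = np.linalg.norm(q, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("quaternions must be unit norm")
    return Rotation.from_quat(q[:, [1, 2, 3, 0]])  # scipy expects xyzw


def functional_calibration(
    gyro: np.ndarray,
    accel_still: np.ndarray,
    fs: float = 100.0,
    *,
    min_peak_rate: float = 1.0,
    energy_percentile: float = 75.0,
) -> SegmentCalibration:
    """Recover the sensor-to-segment rotation from a flexion-extension trial.

    The flexion axis is the principal direction of the angular-velocity
    sample cloud, restricted to samples whose rate magnitude exceeds the
    ``energy_percentile`` percentile (robust against rest periods in the
    trial). Its sign is chosen so the first sustained rotation burst is
    positive, i.e. the movement is assumed to begin with flexion. The
    segment frame is completed by the time-averaged specific-force direction
    during a still period, which points opposite gravity (proximally, along
    segment +z for an upright segment).

    Parameters
    ----------
    gyro : (N, 3) angular velocity in rad/s during the flexion-extension
        movement, in the sensor frame.
    accel_still : (M, 3) accelerometer samples (m/s^2) from a still period.
    min_peak_rate : required peak |omega| in rad/s for the movement to count.
    """
    w = np.atleast_2d(np.asarray(gyro, dtype=float))
    if w.shape[0] < int(2 * fs):
        raise CalibrationError("calibration stream must cover at least 2 s")
    mag = np.linalg.norm(w, axis=1)
    peak = float(mag.max(initial=0.0))
    if peak < min_peak_rate:
        raise CalibrationError(
            f"insufficient rotation energy: peak |omega| = {peak:.3f} rad/s "
            f"< {min_peak_rate} rad/s"
        )

    thresh = np.percentile(mag, energy_percentile)
    active = w[mag >= max(thresh, 1e-12)]
    # Principal direction of the angular-velocity cloud.
    _, _, vt = np.linalg.svd(active, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])

    # Sign: the first sample exceeding half the peak rate defines flexion.
    first = int(np.argmax(mag >= 0.5 * peak))
    if float(w[first] @ axis) < 0.0:
        axis = -axis

    up = np.mean(np.atleast_2d(np.asarray(accel_still, dtype=float)), axis=0)
    up_norm = np.linalg.norm(up)
    if up_norm < 1e-9:
        raise CalibrationError("still-period accelerometer mean is zero")
    up = up / up_norm

    cos_sep = abs(float(up @ axis))
    if cos_sep > np.cos(np.deg2rad(10.0)):
        raise CalibrationError(
            "flexion axis and gravity are nearly parallel "
            f"(separation {np.rad2deg(np.arccos(cos_sep)):.1f} deg)"
        )

    # Right-handed segment basis in sensor coordinates:
    # x = flexion axis, z = gravity-up orthogonalized against x, y = z cross x.
    x = axis
    z = up - (up @ x) * x
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    basis = np.stack([x, y, z], axis=0)  # rows: segment axes in sensor frame
    rot = Rotation.from_matrix(basis)

    residual = np.rad2deg(np.arccos(np.clip(rot.apply(up)[2], -1.0, 1.0)))
    return SegmentCalibration(rotation=rot, flexion_axis=x, quality=float(residual))


def segment_pitch(quat_wxyz: np.ndarray, calib: SegmentCalibration) -> np.ndarray:
    """Sagittal inclination of the segment from vertical, in radians.

    Zero for an upright segment; positive when the segment rotates in the
    flexion-positive sense about segment +x. Heading-invariant: only the
    world-up direction expressed in the segment frame is used,
    pitch = atan2(u_y, u_z).
    """
    r_sw = _quat_wxyz_to_rotation(quat_wxyz)  # sensor -> world
    # world up in sensor frame, then into segment frame
    u_sens = r_sw.inv().apply(np.array([0.0, 0.0, 1.0]))
    u_seg = calib.rotation.apply(u_sens)
    out = np.arctan2(u_seg[:, 1], u_seg[:, 2])
    return out if out.size > 1 else float(out[0])


def knee_flexion(
    thigh_quat_wxyz: np.ndarray,
    shank_quat_wxyz: np.ndarray,
    thigh_calib: SegmentCalibration,
    shank_calib: SegmentCalibration,
) -> np.ndarray:
    """Knee flexion angle from the relative shank-to-thigh orientation.

    The shank longitudinal axis is expressed in the thigh segment frame and
    the flexion angle is the sagittal atan2 of its components:
    0 at full extension, positive in flexion. Out-of-plane (ab/adduction,
    rotation) components only enter through the projection.
    """
    r_thigh = _quat_wxyz_to_rotation(thigh_quat_wxyz)
    r_shank = _quat_wxyz_to_rotation(shank_quat_wxyz)
    # shank-segment -> thigh-segment rotation
    r_ts = thigh_calib.rotation * r_thigh.inv() * r_shank * shank_calib.rotation.inv()
    c = r_ts.apply(np.array([0.0, 0.0, 1.0]))  # shank z in thigh segment frame
    out = np.arctan2(c[:, 1], c[:, 2])
    return out if out.size > 1 else float(out[0])


def filter_accel(
    accel: np.ndarray,
    fs: float = 100.0,
    *,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Causal Butterworth low-pass for accelerometer noise reduction.

    Fourth order, 10 Hz cutoff by default; applied forward-only per axis so
    the group delay matches what a real-time implementation would see.
    """
    a = np.asarray(accel, dtype=float)
    b, aa = butter(order, cutoff_hz, fs=fs)
    return lfilter(b, aa, a, axis=0)


def extract_feature_channels(
    session,
    calibs: dict[str, SegmentCalibration],
    *,
    include_shank_pitch: bool = True,
    prefilter: bool = True,
) -> FeatureSeries:
    """Derive the estimator's input feature channels at 100 Hz.

    Parameters
    ----------
    session : object with ``imu`` mapping sensor names
        (``thigh_r``, ``shank_r``, ``thigh_l``, ``shank_l``) to streams with
        ``t``, ``accel``, ``gyro``, ``quat`` arrays.
    calibs : per-sensor :class:`SegmentCalibration` under the same keys.
    include_shank_pitch : drop the shank pitch channels for the 18-channel
        input variant.
    prefilter : apply :func:`filter_accel` to accelerometer data first.
    """
    for key in ("thigh_r", "shank_r", "thigh_l", "shank_l"):
        if key not in calibs:
            raise ValueError(f"missing calibration for sensor '{key}'")

    t = session.imu["thigh_r"].t
    fs = 1.0 / float(np.mean(np.diff(t)))
    cols: list[np.ndarray] = []
    names = channel_names(include_shank_pitch)

    for leg in ("r", "l"):
        thigh = session.imu[f"thigh_{leg}"]
        shank = session.imu[f"shank_{leg}"]
        cal_t = calibs[f"thigh_{leg}"]
        cal_s = calibs[f"shank_{leg}"]

        knee = knee_flexion(thigh.quat, shank.quat, cal_t, cal_s)
        pitch_t = segment_pitch(thigh.quat, cal_t)
        pitch_s = segment_pitch(shank.quat, cal_s)

        acc_t = filter_accel(thigh.accel, fs) if prefilter else thigh.accel
        acc_s = filter_accel(shank.accel, fs) if prefilter else shank.accel
        acc_t = cal_t.rotation.apply(acc_t)
        acc_s = cal_s.rotation.apply(acc_s)
        gyr_t = cal_t.rotation.apply(thigh.gyro)
        gyr_s = cal_s.rotation.apply(shank.gyro)

        per_leg = {
            "knee_flexion": knee,
            "thigh_pitch": pitch_t,
            "shank_pitch": pitch_s,
            "thigh_a_z": acc_t[:, 2],
            "shank_a_z": acc_s[:, 2],
            "thigh_a_xy_mag": np.hypot(acc_t[:, 0], acc_t[:, 1]),
            "shank_a_xy_mag": np.hypot(acc_s[:, 0], acc_s[:, 1]),
            "thigh_w_flex": gyr_t[:, 0],
            "shank_w_flex": gyr_s[:, 0],
            "thigh_w_res_mag": np.hypot(gyr_t[:, 1], gyr_t[:, 2]),
        }
        for name in CHANNELS_PER_LEG:
            if not include_shank_pitch and name == "shank_pitch":
                continue
            cols.append(np.asarray(per_leg[name], dtype=float))

    data = np.stack(cols, axis=1)
    return FeatureSeries(time=np.asarray(t, dtype=float), data=data, names=names)
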