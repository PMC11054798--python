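"""Session files, run configurations, and model checkpoints.

Sessions are stored as one columnar HDF5 file with an embedded JSON
metadata block (schema version, subject id, sampling rate, condition
schedule, calibration status, subject parameters). Channel data are flat
64-bit float datasets named ``imu_<sensor>_<field>`` with SI units
throughout (m/s^2, rad/s); degrees appear only in reports. Datasets are
written without modification-time tracking so identical content produces
byte-identical files. A CSV export is offered for interoperability
(comma-separated, header row, UTF-8, '.' decimal).
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .labeling import GaitEvents, PhaseSeries
from .models import Network, NetworkSpec
from .synthetic import GaitCondition, ImuStream, SubjectParams, SyntheticSession
from .training import Standardizer

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "RunConfig",
    "read_session",
    "write_session",
    "write_calibrations",
    "read_calibrations",
    "session_to_csv",
    "csv_to_session",
    "save_checkpoint",
    "load_checkpoint",
]

SCHEMA_VERSION = 1
SENSORS = ("thigh_r", "shank_r", "thigh_l", "shank_l")
IMU_FIELDS = ("t", "accel", "gyro", "quat")


class SchemaError(ValueError):
    """A session file violates the documented schema."""


class RunConfig(BaseModel):
    """Full pipeline configuration; defaults are the estimator's stated
    hyperparameters. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # data
    n_subjects: int = 16
    protocol: str = "paper"
    duration_scale: float = 1.0
    master_seed: int = 0
    # features
    include_shank_pitch: bool = True
    accel_cutoff_hz: float = 10.0
    # windows
    short_len: int = 5
    short_rate: float = 50.0
    long_len: int = 20
    long_rate: float = 10.0
    cutoffs: tuple[float, float] = (25.0, 5.0)
    ripple_db: float = 1.0
    stride_step: int = 1
    # model
    architecture: str = "dual_head_4"
    post_merge_layers: int = 4
    # training
    lr0: float = 0.0012
    batch_size: int = 128
    lr_decay_factor: float = 0.2
    val_every: int = 800
    early_stop_patience: int = 2
    max_epochs: int = 10
    seed: int = 0
    standardize: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _metadata(session: SyntheticSession) -> str:
    return json.dumps({
        "schema_version": SCHEMA_VERSION,
        "subject_id": session.subject_id,
        "fs": session.fs,
        "calibrated": False,
        "schedule": [dataclasses.asdict(c) for c in session.schedule],
        "subject": dataclasses.asdict(session.subject),
    }, sort_keys=True)


def write_session(session: SyntheticSession, path) -> None:
    """Write a session file; content-identical sessions yield identical bytes."""
    with h5py.File(path, "w", track_order=False) as fh:
        fh.attrs["metadata"] = _metadata(session)
        dsets: dict[str, np.ndarray] = {}
        for name in SENSORS:
            stream = session.imu[name]
            for fieldname in IMU_FIELDS:
                dsets[f"imu_{name}_{fieldname}"] = getattr(stream, fieldname)
        for leg in ("r", "l"):
            dsets[f"heel_z_{leg}"] = session.heel_z[leg]
            dsets[f"truth_events_{leg}"] = session.truth_events[leg].times
        p = session.truth_phase
        dsets["truth_phi_r"] = p.phi_r
        dsets["truth_phi_l"] = p.phi_l
        dsets["truth_valid_r"] = p.valid_r
        dsets["truth_valid_l"] = p.valid_l
        for name, arr in dsets.items():
            fh.create_dataset(name, data=np.asarray(arr), track_times=False)


def _validate_stream(name: str, stream: ImuStream, fs: float) -> None:
    dt = np.diff(stream.t)
    if dt.size and (np.any(dt <= 0)
                    or not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9)):
        raise SchemaError(f"sensor '{name}': time base not a uniform {fs} Hz grid")
    norms = np.linalg.norm(stream.quat, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise SchemaError(f"sensor '{name}': quaternions not unit norm")


def read_session(path) -> SyntheticSession:
    """Read and validate a session file written by :func:`write_session`."""
    with h5py.File(path, "r") as fh:
        try:
            meta = json.loads(fh.attrs["metadata"])
        except KeyError:
            raise SchemaError("missing metadata block") from None
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {meta.get('schema_version')}")
        fs = float(meta["fs"])

        imu = {}
        for name in SENSORS:
            fields = {}
            for fieldname in IMU_FIELDS:
                key = f"imu_{name}_{fieldname}"
                if key not in fh:
                    raise SchemaError(f"missing channel '{key}'")
                fields[fieldname] = fh[key][()]
            imu[name] = ImuStream(**fields)
            _validate_stream(name, imu[name], fs)

        heel = {leg: fh[f"heel_z_{leg}"][()] for leg in ("r", "l")}
        events = {leg: GaitEvents(fh[f"truth_events_{leg}"][()])
                  for leg in ("r", "l")}
        phase = PhaseSeries(
            time=imu["thigh_r"].t,
            phi_r=fh["truth_phi_r"][()],
            phi_l=fh["truth_phi_l"][()],
            valid_r=fh["truth_valid_r"][()].astype(bool),
            valid_l=fh["truth_valid_l"][()].astype(bool),
        )
        schedule = [GaitCondition(**{**c, "knots": tuple(c["knots"]),
                                     "v_left": tuple(c["v_left"]),
                                     "v_right": tuple(c["v_right"])})
                    for c in meta["schedule"]]
        subj = meta["subject"]
        for k in ("hip_coeffs", "knee_coeffs"):
            subj[k] = tuple(subj[k])
        return SyntheticSession(
            imu=imu, heel_z=heel, truth_phase=phase, truth_events=events,
            schedule=schedule, subject=SubjectParams(**subj), fs=fs,
            subject_id=meta["subject_id"],
        )


def write_calibrations(path, calibs: dict) -> None:
    """Store sensor-to-segment calibrations in a session file's metadata."""
    from scipy.spatial.transform import Rotation  # local: io stays light

    payload = {}
    for name, cal in calibs.items():
        q = Rotation.as_quat(cal.rotation)  # xyzw
        payload[name] = {
            "rotation_wxyz": [float(q[3]), float(q[0]), float(q[1]), float(q[2])],
            "flexion_axis": [float(v) for v in cal.flexion_axis],
            "quality_deg": float(cal.quality),
        }
    with h5py.File(path, "a") as fh:
        meta = json.loads(fh.attrs["metadata"])
        meta["calibrated"] = True
        meta["calibrations"] = payload
        fh.attrs["metadata"] = json.dumps(meta, sort_keys=True)


def read_calibrations(path) -> dict:
    """Load calibrations stored by :func:`write_calibrations`."""
    from scipy.spatial.transform import Rotation

    from .calibration import SegmentCalibration

    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["metadata"])
    if not meta.get("calibrated"):
        raise SchemaError("session has no stored calibrations")
    out = {}
    for name, d in meta["calibrations"].items():
        w, x, y, z = d["rotation_wxyz"]
        out[name] = SegmentCalibration(
            rotation=Rotation.from_quat([x, y, z, w]),
            flexion_axis=np.asarray(d["flexion_axis"]),
            quality=d["quality_deg"],
        )
    return out


def session_to_csv(session: SyntheticSession, path) -> None:
    """Flat CSV export: one row per sample, one column per channel."""
    cols: dict[str, np.ndarray] = {"time_s": session.time}
    for name in SENSORS:
        s = session.imu[name]
        for ax, i in zip("xyz", range(3)):
            cols[f"{name}_a{ax}"] = s.accel[:, i]
            cols[f"{name}_g{ax}"] = s.gyro[:, i]
        for comp, i in zip("wxyz", range(4)):
            cols[f"{name}_q{comp}"] = s.quat[:, i]
    for leg in ("r", "l"):
        cols[f"heel_z_{leg}"] = session.heel_z[leg]
        cols[f"truth_phi_{leg}"] = getattr(session.truth_phase, f"phi_{leg}")
        cols[f"truth_valid_{leg}"] = getattr(
            session.truth_phase, f"valid_{leg}").astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def csv_to_session(csv_path, template: SyntheticSession) -> SyntheticSession:
    """Rebuild a session from a CSV export plus a metadata template.

    The CSV dialect carries no metadata block, so schedule/subject metadata
    are taken from ``template``.
    """
    df = pd.read_csv(csv_path)
    t = df["time_s"].to_numpy()
    imu = {}
    for name in SENSORS:
        imu[name] = ImuStream(
            t=t,
            accel=df[[f"{name}_a{ax}" for ax in "xyz"]].to_numpy(),
            gyro=df[[f"{name}_g{ax}" for ax in "xyz"]].to_numpy(),
            quat=df[[f"{name}_q{c}" for c in "wxyz"]].to_numpy(),
        )
    phase = PhaseSeries(
        time=t,
        phi_r=df["truth_phi_r"].to_numpy(),
        phi_l=df["truth_phi_l"].to_numpy(),
        valid_r=df["truth_valid_r"].to_numpy().astype(bool),
        valid_l=df["truth_valid_l"].to_numpy().astype(bool),
    )
    return SyntheticSession(
        imu=imu,
        heel_z={leg: df[f"heel_z_{leg}"].to_numpy() for leg in ("r", "l")},
        truth_phase=phase,
        truth_events=template.truth_events,
        schedule=template.schedule,
        subject=template.subject,
        fs=template.fs,
        subject_id=template.subject_id,
    )


def save_checkpoint(
    path,
    net: Network,
    standardizer: Standardizer,
    metadata: dict | None = None,
) -> None:
    """Persist architecture spec, parameters, input scaling, and metadata."""
    header = {
        "schema_version": SCHEMA_VERSION,
        "spec": dataclasses.asdict(net.spec),
        "seed": net.seed,
        "metadata": metadata or {},
    }
    with h5py.File(path, "w") as fh:
        fh.attrs["header"] = json.dumps(header, sort_keys=True)
        for key, value in net.state_dict().items():
            fh.create_dataset(f"param/{key}", data=value, track_times=False)
        fh.create_dataset("standardizer/mean", data=standardizer.mean,
                          track_times=False)
        fh.create_dataset("standardizer/std", data=standardizer.std,
                          track_times=False)


def load_checkpoint(path) -> tuple[Network, Standardizer, dict]:
    """Rebuild a trained network and its input standardizer."""
    with h5py.File(path, "r") as fh:
        header = json.loads(fh.attrs["header"])
        if header.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError("unsupported checkpoint schema version")
        spec_d = header["spec"]
        spec = NetworkSpec(**spec_d)
        net = Network(spec, seed=header["seed"])
        state = {k[len("param/"):]: fh[k][()]
                 for k in _walk_keys(fh) if k.startswith("param/")}
        net.load_state_dict(state)
        std = Standardizer(mean=fh["standardizer/mean"][()],
                           std=fh["standardizer/std"][()])
        return net, std, header["metadata"]


def _walk_keys(fh) -> list[str]:
    keys: list[str] = []
    fh.visit(lambda name: keys.append(name)
             if isinstance(fh[name], h5py.Dataset) else None)
    return keys
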