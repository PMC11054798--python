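"""Ground-truth gait-phase labels from heel-marker trajectories.

Gait phase is defined per leg as a sawtooth in [0, 1): zero at each heel
strike, increasing linearly to 1 at the next ipsilateral heel strike.
Because the sawtooth is discontinuous at the stride boundary, targets for
regression are encoded on the unit circle as (cos 2*pi*phi, sin 2*pi*phi).

Intervals between heel strikes longer than 3 s are treated as standing and
the phase there is marked invalid, as are samples before the first and
after the last detected heel strike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "GaitEvents",
    "PhaseSeries",
    "detect_heel_strikes",
    "phase_ramp",
    "encode_phase",
    "decode_phase",
    "MAX_STRIDE_GAP_S",
    "MIN_EVENT_SEPARATION_S",
]

#: Inter-strike gaps longer than this are treated as standing (phase undefined).
MAX_STRIDE_GAP_S = 3.0

#: Physiological floor on the interval between consecutive heel strikes.
MIN_EVENT_SEPARATION_S = 0.2


@dataclass(frozen=True)
class GaitEvents:
    """Ordered heel-strike times for one leg, in seconds."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", t)
        if t.size > 1:
            gaps = np.diff(t)
            if np.any(gaps <= 0):
                raise ValueError("heel-strike times must be strictly increasing")
            if np.any(gaps <= MIN_EVENT_SEPARATION_S):
                raise ValueError(
                    f"inter-event gap below physiological floor of "
                    f"{MIN_EVENT_SEPARATION_S} s"
                )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class PhaseSeries:
    """Per-leg gait phase on a common time grid with validity masks.

    ``phi_r``/``phi_l`` hold the sawtooth phase in [0, 1); samples where the
    phase is undefined (standing, boundaries) are flagged False in
    ``valid_r``/``valid_l`` and their phi values should not be consumed.
    """

    time: np.ndarray
    phi_r: np.ndarray
    phi_l: np.ndarray
    valid_r: np.ndarray
    valid_l: np.ndarray

    def encoding(self) -> np.ndarray:
        """Sinusoidal target (N, 4): (y1R, y2R, y1L, y2L)."""
        y1r, y2r = encode_phase(self.phi_r)
        y1l, y2l = encode_phase(self.phi_l)
        return np.stack([y1r, y2r, y1l, y2l], axis=1)

    @property
    def valid(self) -> np.ndarray:
        """Samples where both legs have a defined phase."""
        return self.valid_r & self.valid_l


def _smooth5(x: np.ndarray) -> np.ndarray:
    """5-point moving average with edge padding."""
    xp = np.pad(x, 2, mode="edge")
    k = np.ones(5) / 5.0
    return np.convolve(xp, k, mode="valid")


def detect_heel_strikes(
    heel_z: np.ndarray,
    fs: float = 100.0,
    *,
    min_depth: float | None = None,
    accel_window_s: float = 0.05,
) -> GaitEvents:
    """Detect heel strikes from the vertical heel-marker trajectory.

    A heel strike is a sample where ``heel_z`` is a local minimum and the
    vertical acceleration of the heel (smoothed second difference of the
    trajectory) has a peak within ``accel_window_s``. Minima closer together
    than the physiological floor are merged, keeping the deeper one.

    Parameters
    ----------
    heel_z : vertical heel position in metres, sampled uniformly.
    fs : sampling rate in Hz.
    min_depth : required prominence of the heel-z minima in metres.
        Defaults to 2% of the signal's peak-to-peak range.
    accel_window_s : half-width of the coincidence window between the
        heel-z minimum and the vertical-acceleration peak.
    """
    z = np.asarray(heel_z, dtype=float).ravel()
    if z.size < int(fs):
        raise ValueError("need at least 1 s of heel trajectory")
    rng = float(np.ptp(z))
    if rng == 0.0:
        return GaitEvents(np.empty(0))
    if min_depth is None:
        min_depth = 0.02 * rng

    zs = _smooth5(z)
    minima, _ = find_peaks(-zs, prominence=min_depth)

    # Heel vertical acceleration: smoothed second central difference.
    dt = 1.0 / fs
    acc = np.gradient(np.gradient(zs, dt), dt)
    acc = _smooth5(acc)
    acc_peaks, _ = find_peaks(acc, height=0.0)

    half = max(1, int(round(accel_window_s * fs)))
    confirmed = [
        m for m in minima
        if acc_peaks.size and np.min(np.abs(acc_peaks - m)) <= half
    ]
    if not confirmed:
        return GaitEvents(np.empty(0))

    # Merge events violating the physiological floor, keeping the deeper minimum.
    min_sep = int(round(MIN_EVENT_SEPARATION_S * fs))
    kept: list[int] = []
    for m in confirmed:
        if kept and m - kept[-1] <= min_sep:
            if zs[m] < zs[kept[-1]]:
                kept[-1] = m
        else:
            kept.append(m)
    return GaitEvents(np.asarray(kept, dtype=float) * dt)


def phase_ramp(
    events: GaitEvents,
    time: np.ndarray,
    *,
    max_gap_s: float = MAX_STRIDE_GAP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear phase ramp between consecutive heel strikes for one leg.

    Returns ``(phi, valid)`` on the query grid. For consecutive events
    ``(T_k, T_{k+1})`` with gap <= ``max_gap_s``, samples in ``[T_k, T_{k+1})``
    get ``phi = (t - T_k) / (T_{k+1} - T_k)``. Longer gaps (standing) and
    samples outside the first/last event are invalid, with phi frozen at 0.
    """
    t = np.asarray(time, dtype=float).ravel()
    phi = np.zeros_like(t)
    valid = np.zeros(t.shape, dtype=bool)
    ev = events.times
    for t0, t1 in zip(ev[:-1], ev[1:]):
        gap = t1 - t0
        if gap > max_gap_s:
            continue
        sel = (t >= t0) & (t < t1)
        phi[sel] = (t[sel] - t0) / gap
        valid[sel] = True
    return phi, valid


def encode_phase(phi: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Map phase in [0, 1) onto the unit circle: (cos 2*pi*phi, sin 2*pi*phi)."""
    a = 2.0 * np.pi * np.asarray(phi, dtype=float)
    return np.cos(a), np.sin(a)


def decode_phase(y1: np.ndarray | float, y2: np.ndarray | float) -> np.ndarray:
    """Invert the sinusoidal encoding via atan2, mapping back into [0, 1).

    The decode is scale invariant: any positive multiple of an encoded pair
    decodes to the same phase. A zero vector has no defined phase and raises.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if np.any((y1 == 0.0) & (y2 == 0.0)):
        raise ValueError("cannot decode phase of the zero vector")
    phi = np.arctan2(y2, y1) / (2.0 * np.pi)
    return np.mod(phi, 1.0)
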