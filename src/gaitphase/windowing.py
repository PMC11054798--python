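"""Anti-aliasing filter bank, decimation, and dual-rate window assembly.

The estimator consumes, at each prediction step, a pair of windows cut from
two causally filtered copies of the 100 Hz feature stream: a *short* window
of 5 samples spaced 20 ms apart (50 Hz branch, 25 Hz anti-alias cutoff)
covering the most recent data, and a *long* window of 20 samples spaced
100 ms apart (10 Hz branch, 5 Hz cutoff) covering the deeper past. The two
windows are non-overlapping — the long window ends where the short window
begins — and together represent 20/10 + 5/50 = 2.10 s over 25 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import cheby1, lfilter

from .labeling import PhaseSeries

__all__ = [
    "WindowConfig",
    "DualWindow",
    "WindowSet",
    "antialias_filter_bank",
    "StreamingFilterBank",
    "decimate",
    "assemble_windows",
]


@dataclass(frozen=True)
class WindowConfig:
    """Dual-rate window geometry and filter-bank parameters."""

    short_len: int = 5
    short_rate: float = 50.0  # Hz
    long_len: int = 20
    long_rate: float = 10.0  # Hz
    cutoffs: tuple[float, float] = (25.0, 5.0)  # Hz: (short branch, long branch)
    ripple_db: float = 1.0  # type-1 Chebyshev passband ripple
    filter_order: int = 2
    input_rate: float = 100.0  # Hz

    @property
    def represented_duration_s(self) -> float:
        """Total time represented: one sample period per window sample."""
        return self.long_len / self.long_rate + self.short_len / self.short_rate

    @property
    def total_samples(self) -> int:
        return self.short_len + self.long_len

    @property
    def short_step(self) -> int:
        return int(round(self.input_rate / self.short_rate))

    @property
    def long_step(self) -> int:
        return int(round(self.input_rate / self.long_rate))

    @property
    def warmup_samples(self) -> int:
        """Input samples needed before the first fully populated window."""
        span = (self.short_len - 1) * self.short_step + self.long_len * self.long_step
        return span + 1


@dataclass
class DualWindow:
    """One paired input snapshot with its target encoding.

    ``short`` is (short_len, C) newest-last at the high rate; ``long`` is
    (long_len, C) at the low rate, immediately preceding the short window.
    ``target`` is (y1R, y2R, y1L, y2L) at ``t_ref``, the time of the most
    recent sample.
    """

    short: np.ndarray
    long: np.ndarray
    t_ref: float
    target: np.ndarray
    target_valid: bool


@dataclass
class WindowSet:
    """Batched windows of one session: arrays over the window axis."""

    short: np.ndarray  # (n, short_len, C)
    long: np.ndarray  # (n, long_len, C)
    t_ref: np.ndarray  # (n,)
    target: np.ndarray  # (n, 4)
    target_valid: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return self.short.shape[0]

    def __getitem__(self, i: int) -> DualWindow:
        return DualWindow(self.short[i], self.long[i], float(self.t_ref[i]),
                          self.target[i], bool(self.target_valid[i]))

    def valid_only(self) -> "WindowSet":
        m = self.target_valid
        return WindowSet(self.short[m], self.long[m], self.t_ref[m],
                         self.target[m], self.target_valid[m])

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        return WindowSet(
            *[np.concatenate([getattr(s, f) for s in sets])
              for f in ("short", "long", "t_ref", "target", "target_valid")]
        )


def _check_uniform(time: np.ndarray, fs: float) -> None:
    dt = np.diff(np.asarray(time, dtype=float))
    if dt.size and not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
        raise ValueError(f"series is not uniformly sampled at {fs} Hz")


def _bank_coeffs(cfg: WindowConfig):
    for cut in cfg.cutoffs:
        yield cheby1(cfg.filter_order, cfg.ripple_db, cut, fs=cfg.input_rate)


def antialias_filter_bank(
    x: np.ndarray,
    cfg: WindowConfig = WindowConfig(),
    *,
    time: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal type-1 Chebyshev low-pass copies of every channel.

    Returns the (25 Hz, 5 Hz)-cutoff branches feeding the short and long
    windows respectively. Batch application here is state-equivalent to
    sample-by-sample streaming through :class:`StreamingFilterBank`.
    """
    x = np.asarray(x, dtype=float)
    if time is not None:
        _check_uniform(time, cfg.input_rate)
    out = []
    for b, a in _bank_coeffs(cfg):
        out.append(lfilter(b, a, x, axis=0))
    return out[0], out[1]


class StreamingFilterBank:
    """Sample-by-sample application of the anti-aliasing filter bank."""

    def __init__(self, n_channels: int, cfg: WindowConfig = WindowConfig()):
        self.cfg = cfg
        self._ba = list(_bank_coeffs(cfg))
        self._zi = [
            np.zeros((max(len(b), len(a)) - 1, n_channels))
            for b, a in self._ba
        ]

    def reset(self) -> None:
        for z in self._zi:
            z[:] = 0.0

    def push(self, sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Filter one (C,) sample; returns the two branch outputs."""
        sample = np.asarray(sample, dtype=float)[None, :]
        outs = []
        for i, (b, a) in enumerate(self._ba):
            y, self._zi[i] = lfilter(b, a, sample, axis=0, zi=self._zi[i])
            outs.append(y[0])
        return outs[0], outs[1]


def decimate(x: np.ndarray, factor: int, *, factors: tuple[int, ...] = (2, 10, 5)) -> np.ndarray:
    """Keep every ``factor``-th sample so the newest sample is retained.

    The caller is responsible for having anti-alias filtered ``x`` with the
    matching branch of the filter bank.
    """
    if factor not in factors:
        raise ValueError(f"decimation factor must be one of {factors}")
    x = np.asarray(x)
    n = x.shape[0]
    idx = np.arange(n - 1, -1, -factor)[::-1]
    return x[idx]


def assemble_windows(
    lp_short: np.ndarray,
    lp_long: np.ndarray,
    labels: PhaseSeries,
    stride_step: int = 1,
    cfg: WindowConfig = WindowConfig(),
) -> WindowSet:
    """Cut dual-rate windows at every prediction step.

    ``lp_short``/``lp_long`` are the filter-bank branches at the full input
    rate; sample selection implements the decimation. One window is emitted
    every ``stride_step`` input samples, starting at the first index with a
    full 2.10 s history (no zero padding). The target is the phase encoding
    at the window's reference time; windows whose label is invalid on
    either leg carry ``target_valid=False``.
    """
    lp_short = np.asarray(lp_short, dtype=float)
    lp_long = np.asarray(lp_long, dtype=float)
    if lp_short.shape != lp_long.shape:
        raise ValueError("filter-bank branches must have equal shapes")
    n = lp_short.shape[0]
    first = cfg.warmup_samples - 1
    if n <= first:
        c = lp_short.shape[1] if lp_short.ndim > 1 else 1
        return WindowSet(
            short=np.empty((0, cfg.short_len, c)),
            long=np.empty((0, cfg.long_len, c)),
            t_ref=np.empty(0), target=np.empty((0, 4)),
            target_valid=np.empty(0, dtype=bool),
        )

    refs = np.arange(first, n, stride_step)
    ss, ls = cfg.short_step, cfg.long_step
    short_off = -ss * np.arange(cfg.short_len - 1, -1, -1)  # oldest..newest
    short_span = (cfg.short_len - 1) * ss
    long_off = -short_span - ls * np.arange(cfg.long_len, 0, -1)

    short = lp_short[refs[:, None] + short_off[None, :]]
    long = lp_long[refs[:, None] + long_off[None, :]]

    enc = labels.encoding()
    target = enc[refs]
    valid = (labels.valid_r & labels.valid_l)[refs]
    t_ref = labels.time[refs]
    return WindowSet(short=short, long=long, t_ref=t_ref,
                     target=target, target_valid=valid)
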