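"""The three gait-phase estimator architectures.

All three networks regress the 4-vector sinusoidal phase encoding
(y1R, y2R, y1L, y2L) from dual-rate feature windows:

* ``single_head_4`` — single-rate baseline: consumes only the long
  (10 Hz) window through one convolutional entry layer and 4 residual
  blocks with dilations 1, 2, 4, 8.
* ``dual_head_1`` — shallow dual-rate: one entry layer and one residual
  block per head; the merged feature map is flattened directly into the
  regression layer.
* ``dual_head_4`` — deep dual-rate: 4 residual blocks per head, heads
  concatenated along time, followed by post-merge convolutional layers and
  the height-collapsing layer before regression.

Each residual block holds two dilated 3x1 convolutions (the first followed
by leaky ReLU and dropout, each by batch normalization) and a 1x1-projected
identity shortcut; every block feeds a 1x1 bottleneck with 4 kernels to
keep the model compact. Time width is preserved through symmetric zero
padding (a causal left-padding variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import decode_phase
from .nn import (
    BatchNorm,
    Dense,
    Dropout,
    Flatten,
    HeightCollapseConv,
    Layer,
    LeakyReLU,
    Param,
    Sequential,
    TimeConv,
)

__all__ = [
    "ResidualBlockSpec",
    "NetworkSpec",
    "ResidualBlock",
    "Network",
    "build_network",
    "predict_phase",
    "ARCHITECTURES",
]

ARCHITECTURES = ("single_head_4", "dual_head_1", "dual_head_4")


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Hyperparameters of one residual convolution block."""

    n_kernels: int = 16
    kernel: int = 3  # taps along the time axis
    dilation: int = 1
    batchnorm_decay: float = 0.1
    leaky_slope: float = 0.01
    dropout_rate: float = 0.5
    bottleneck_kernels: int = 4

    def __post_init__(self):
        if min(self.n_kernels, self.kernel, self.dilation,
               self.bottleneck_kernels) < 1:
            raise ValueError("block spec fields must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture selection and input geometry."""

    architecture: str = "dual_head_4"
    n_channels: int = 20
    long_len: int = 20
    short_len: int = 5
    post_merge_layers: int = 4
    dropout_rate: float = 0.5
    padding: str = "symmetric"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture '{self.architecture}'; "
                f"valid: {list(ARCHITECTURES)}"
            )

    @property
    def residual_layers_per_head(self) -> int:
        return 1 if self.architecture == "dual_head_1" else 4

    @property
    def head_dilations(self) -> tuple[int, ...]:
        return tuple(2**i for i in range(self.residual_layers_per_head))


class ResidualBlock(Layer):
    """Two dilated 3x1 convolutions plus a 1x1-projected shortcut.

    Output has ``spec.n_kernels`` maps and the input's height and width.
    """

    def __init__(self, k_in: int, spec: ResidualBlockSpec,
                 rng: np.random.Generator, drop_rng: np.random.Generator,
                 padding: str = "symmetric"):
        k = spec.n_kernels
        out_bn = BatchNorm(k, spec.batchnorm_decay)
        # start the residual path at zero so each block is initially the
        # identity (projection); speeds up convergence of deep stacks
        out_bn.gamma.value[:] = 0.0
        self.path = Sequential([
            TimeConv(k_in, k, spec.kernel, spec.dilation, rng, padding),
            BatchNorm(k, spec.batchnorm_decay),
            LeakyReLU(spec.leaky_slope),
            Dropout(spec.dropout_rate, drop_rng),
            TimeConv(k, k, spec.kernel, spec.dilation, rng, padding),
            out_bn,
        ])
        self.proj = TimeConv(k_in, k, 1, 1, rng)

    def params(self):
        return self.path.params() + self.proj.params()

    def forward(self, x, train):
        return self.path.forward(x, train) + self.proj.forward(x, train)

    def backward(self, grad):
        return self.path.backward(grad) + self.proj.backward(grad)


def _head(spec: NetworkSpec, block: ResidualBlockSpec,
          rng, drop_rng) -> Sequential:
    """Entry convolution plus the residual/bottleneck stack of one head."""
    layers: list[Layer] = [
        TimeConv(1, block.n_kernels, block.kernel, 1, rng, spec.padding),
        BatchNorm(block.n_kernels, block.batchnorm_decay),
        LeakyReLU(block.leaky_slope),
    ]
    k_in = block.n_kernels
    for d in spec.head_dilations:
        bspec = ResidualBlockSpec(
            n_kernels=block.n_kernels, kernel=block.kernel, dilation=d,
            batchnorm_decay=block.batchnorm_decay,
            leaky_slope=block.leaky_slope,
            dropout_rate=spec.dropout_rate,
            bottleneck_kernels=block.bottleneck_kernels,
        )
        layers.append(ResidualBlock(k_in, bspec, rng, drop_rng, spec.padding))
        layers.append(TimeConv(block.n_kernels, block.bottleneck_kernels, 1, 1, rng))
        k_in = block.bottleneck_kernels
    return Sequential(layers)


class Network:
    """One estimator network: heads, merge, and regression tail."""

    N_OUTPUTS = 4

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng([seed, 0x5EED])
        block = ResidualBlockSpec(dropout_rate=spec.dropout_rate)
        c, wl, ws = spec.n_channels, spec.long_len, spec.short_len
        kb = block.bottleneck_kernels

        self._modules: list[tuple[str, Layer]] = []
        if spec.architecture == "single_head_4":
            self.head_long = _head(spec, block, rng, self.drop_rng)
            self.head_short = None
            self.tail = Sequential([
                HeightCollapseConv(kb, block.n_kernels, c, rng),
                Flatten(),
                Dense(block.n_kernels * wl, self.N_OUTPUTS, rng),
            ])
        else:
            self.head_long = _head(spec, block, rng, self.drop_rng)
            self.head_short = _head(spec, block, rng, self.drop_rng)
            w_merged = wl + ws
            if spec.architecture == "dual_head_1":
                self.tail = Sequential([
                    Flatten(),
                    Dense(kb * c * w_merged, self.N_OUTPUTS, rng),
                ])
            else:  # dual_head_4
                merge: list[Layer] = []
                k_in = kb
                for i in range(spec.post_merge_layers):
                    merge += [
                        TimeConv(k_in, block.n_kernels, block.kernel,
                                 2**i, rng, spec.padding),
                        BatchNorm(block.n_kernels, block.batchnorm_decay),
                        LeakyReLU(block.leaky_slope),
                    ]
                    k_in = block.n_kernels
                merge += [
                    HeightCollapseConv(k_in, block.n_kernels, c, rng),
                    Flatten(),
                    Dense(block.n_kernels * w_merged, self.N_OUTPUTS, rng),
                ]
                self.tail = Sequential(merge)
        self._register()
        self._cache_widths: tuple[int, int] | None = None

    # -- parameter bookkeeping ------------------------------------------------

    def _register(self):
        self._modules = [("head_long", self.head_long), ("tail", self.tail)]
        if self.head_short is not None:
            self._modules.insert(1, ("head_short", self.head_short))

    def params(self) -> list[Param]:
        return [p for _, m in self._modules for p in m.params()]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _walk(self):
        """Yield (path, layer) for every primitive layer."""
        def rec(prefix, layer):
            if isinstance(layer, Sequential):
                for i, sub in enumerate(layer.layers):
                    yield from rec(f"{prefix}.{i}", sub)
            elif isinstance(layer, ResidualBlock):
                yield from rec(f"{prefix}.path", layer.path)
                yield from rec(f"{prefix}.proj", layer.proj)
            else:
                yield prefix, layer
        for name, mod in self._modules:
            yield from rec(name, mod)

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for path, layer in self._walk():
            for attr in ("w", "b", "gamma", "beta"):
                p = getattr(layer, attr, None)
                if isinstance(p, Param):
                    out[f"{path}.{attr}"] = p.value.copy()
            for attr in ("running_mean", "running_var"):
                v = getattr(layer, attr, None)
                if isinstance(v, np.ndarray):
                    out[f"{path}.{attr}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for path, layer in self._walk():
            for attr in ("w", "b", "gamma", "beta"):
                p = getattr(layer, attr, None)
                if isinstance(p, Param):
                    p.value[:] = state[f"{path}.{attr}"]
            for attr in ("running_mean", "running_var"):
                v = getattr(layer, attr, None)
                if isinstance(v, np.ndarray):
                    v[:] = state[f"{path}.{attr}"]

    # -- forward / backward ---------------------------------------------------

    @staticmethod
    def _to_maps(win: np.ndarray) -> np.ndarray:
        """(B, T, C) window -> (B, height=C, width=T, 1 map) tensor."""
        from .nn import DTYPE
        w = np.asarray(win, dtype=DTYPE)
        if w.ndim == 2:
            w = w[None]
        return np.ascontiguousarray(np.transpose(w, (0, 2, 1))[:, :, :, None])

    def forward(self, long: np.ndarray, short: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        """Regress the 4-vector encoding from a batch of windows."""
        if self.head_short is None:
            if short is not None:
                raise ValueError(
                    "single_head_4 consumes only the long window; "
                    "got an unexpected short window"
                )
            z = self.head_long.forward(self._to_maps(long), train)
            self._cache_widths = (z.shape[2], 0)
            return self.tail.forward(z, train)
        if short is None:
            raise ValueError("dual-head networks require the short window")
        zl = self.head_long.forward(self._to_maps(long), train)
        zs = self.head_short.forward(self._to_maps(short), train)
        self._cache_widths = (zl.shape[2], zs.shape[2])
        # deep past first, most recent samples last along the time axis
        return self.tail.forward(np.concatenate([zl, zs], axis=2), train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.tail.backward(grad)
        wl, ws = self._cache_widths
        if self.head_short is None:
            self.head_long.backward(g)
        else:
            self.head_long.backward(g[:, :, :wl, :])
            self.head_short.backward(g[:, :, wl:, :])


def build_network(spec: NetworkSpec | str, seed: int = 0, **kwargs) -> Network:
    """Construct an initialized network; deterministic under a fixed seed."""
    if isinstance(spec, str):
        spec = NetworkSpec(architecture=spec, **kwargs)
    return Network(spec, seed=seed)


def predict_phase(
    net: Network,
    long: np.ndarray,
    short: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evaluate the network and decode per-leg phase estimates.

    Returns ``raw`` (B, 4) outputs, ``phi_r``/``phi_l`` in [0, 1), and
    ``defined_r``/``defined_l`` flags (False where the raw output pair is
    exactly the zero vector, which carries no phase). No unit-norm
    constraint is imposed: the atan2 decode is scale invariant.
    """
    raw = net.forward(long, short, train=False)
    out = {"raw": raw}
    for leg, sl in (("r", slice(0, 2)), ("l", slice(2, 4))):
        y = raw[:, sl]
        defined = ~((y[:, 0] == 0.0) & (y[:, 1] == 0.0))
        phi = np.zeros(len(y))
        if defined.any():
            phi[defined] = decode_phase(y[defined, 0], y[defined, 1])
        out[f"phi_{leg}"] = phi
        out[f"defined_{leg}"] = defined
    return out
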