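"""Densely connected 1-D conv net with residual channel attention.

The classifier consumes an (N, C, L) batch — by default 80 embedding
channels over 29 window positions — and is built from:

* dense blocks: layer l computes ``x_l = Conv(ReLU(BN(concat(x_0..x_{l-1}))))``
  with ``growth_rate`` output channels and same-length padding, and the block
  returns ``concat(x_0..x_L)``;
* transition layers between blocks: BN -> 1x1 conv compressing channels by
  ``compression`` -> average pooling (window 2, stride 2), halving the length;
  there is no initial convolution before the first block;
* channel attention on the final block output.  Global average and max
  pooling over positions give two per-channel vectors; a shared two-layer
  bottleneck network (C -> C/r -> C) scores both, and
  ``mc = sigmoid(FNN(avg) + FNN(max))`` is the classical channel-attention
  weight (CAM).  The residual variant (RCAM) adds a short-circuit term
  ``mr = sigmoid(avg + max)`` computed from the raw pooled statistics, and
  scales each channel by ``mrc = mc + mr`` (elementwise in (0, 2));
* a head: flatten -> hidden fully connected layers with ReLU and dropout ->
  2-way softmax.

Everything is plain NumPy with hand-derived backward passes; training-mode
forward uses batch statistics and dropout masks, evaluation mode uses running
statistics with dropout disabled and is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

__all__ = [
    "ModelConfig",
    "Param",
    "Conv1d",
    "BatchNorm1d",
    "DenseBlock",
    "Transition",
    "ChannelAttention",
    "Linear",
    "KcrModel",
    "ModelSummary",
    "summarize",
    "softmax",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the grid-search winner for the Kcr benchmark: four dense
    blocks of two conv layers each, growth rate 32, transitions compressing
    channels by half, residual channel attention with reduction ratio 8, and
    one 64-unit hidden layer before the softmax.
    """

    n_blocks: int = 4
    layers_per_block: int = 2
    growth_rate: int = 32
    kernel_size: int = 3
    compression: float = 0.5
    attention: Literal["none", "cam", "rcam"] = "rcam"
    reduction_ratio: int = 8
    fc_sizes: list[int] = field(default_factory=lambda: [64])
    dropout: float = 0.5
    input_channels: int = 80
    input_length: int = 29

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.layers_per_block < 1:
            raise ValueError("layers_per_block must be >= 1")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must be in (0, 1]")
        if self.attention not in ("none", "cam", "rcam"):
            raise ValueError(f"unknown attention variant {self.attention!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1d:
    """1-D convolution along positions, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-length padding")
        scale = np.sqrt(2.0 / (c_in * kernel_size))  # He init
        self.weight = Param(rng.standard_normal((c_out, c_in, kernel_size)) * scale, "conv.w")
        self.bias = Param(np.zeros(c_out), "conv.b")
        self.kernel_size = kernel_size
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def _patches(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        N, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        return np.stack([xp[:, :, j : j + L] for j in range(k)], axis=2)  # (N,C,k,L)

    def forward(self, x: np.ndarray) -> np.ndarray:
        patches = self._patches(x)
        y = np.einsum("ocj,ncjl->nol", self.weight.value, patches, optimize=True)
        y += self.bias.value[None, :, None]
        self._cache = (patches, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        patches, x_shape = self._cache
        N, C, L = x_shape
        k = self.kernel_size
        pad = k // 2
        self.weight.grad += np.einsum("nol,ncjl->ocj", dy, patches, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2))
        dpatches = np.einsum("nol,ocj->ncjl", dy, self.weight.value, optimize=True)
        dxp = np.zeros((N, C, L + 2 * pad))
        for j in range(k):
            dxp[:, :, j : j + L] += dpatches[:, :, j, :]
        return dxp[:, :, pad : pad + L] if pad else dxp


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, position) axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            if x.shape[0] < 2:
                raise ValueError("batch normalization requires batch size >= 2 in training mode")
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None] * inv[None, :, None]
        if not train:
            return dy * g
        m = dy.shape[0] * dy.shape[2]
        mean_dy = dy.mean(axis=(0, 2))[None, :, None]
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 2))[None, :, None]
        return g * (dy - mean_dy - xhat * mean_dy_xhat)


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _AvgPool2:
    """Average pooling, window 2, stride 2; a trailing odd position is dropped."""

    def forward(self, x):
        N, C, L = x.shape
        if L < 2:
            raise ValueError(f"average pooling needs length >= 2, got {L}")
        self._L = L
        Lo = L // 2
        return 0.5 * (x[:, :, 0 : 2 * Lo : 2] + x[:, :, 1 : 2 * Lo : 2])

    def backward(self, dy):
        N, C, Lo = dy.shape
        dx = np.zeros((N, C, self._L))
        dx[:, :, 0 : 2 * Lo : 2] = 0.5 * dy
        dx[:, :, 1 : 2 * Lo : 2] = 0.5 * dy
        return dx


class DenseBlock:
    """``layers_per_block`` BN->ReLU->Conv layers with dense concatenation."""

    def __init__(self, c_in: int, layers_per_block: int, growth_rate: int,
                 kernel_size: int, rng: np.random.Generator):
        self.c_in = c_in
        self.growth_rate = growth_rate
        self.layers = []
        c = c_in
        for _ in range(layers_per_block):
            self.layers.append(
                (BatchNorm1d(c), _ReLU(), Conv1d(c, growth_rate, kernel_size, rng))
            )
            c += growth_rate
        self.c_out = c

    def parameters(self):
        ps = []
        for bn, _, conv in self.layers:
            ps += bn.parameters() + conv.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        feats = [x]
        self._widths = [x.shape[1]]
        for bn, relu, conv in self.layers:
            h = np.concatenate(feats, axis=1)
            xl = conv.forward(relu.forward(bn.forward(h, train)))
            feats.append(xl)
            self._widths.append(xl.shape[1])
        return np.concatenate(feats, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # Split the gradient of the final concatenation back onto each x_l,
        # then run layers in reverse, re-splitting each layer's input gradient.
        bounds = np.cumsum(self._widths)
        dfeats = [dy[:, s:e] .copy() for s, e in zip(np.r_[0, bounds[:-1]], bounds)]
        for l in range(len(self.layers) - 1, -1, -1):
            bn, relu, conv = self.layers[l]
            dh = bn.backward(relu.backward(conv.backward(dfeats[l + 1])))
            sub = np.cumsum(self._widths[: l + 1])
            for i, (s, e) in enumerate(zip(np.r_[0, sub[:-1]], sub)):
                dfeats[i] += dh[:, s:e]
        return dfeats[0]


class Transition:
    """BN -> 1x1 conv to ceil(compression*C) channels -> average pooling."""

    def __init__(self, c_in: int, compression: float, rng: np.random.Generator):
        self.c_out = int(np.ceil(compression * c_in))
        self.bn = BatchNorm1d(c_in)
        self.conv = Conv1d(c_in, self.c_out, 1, rng)
        self.pool = _AvgPool2()

    def parameters(self):
        return self.bn.parameters() + self.conv.parameters()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.pool.forward(self.conv.forward(self.bn.forward(x, train)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.bn.backward(self.conv.backward(self.pool.backward(dy)))


class ChannelAttention:
    """Channel attention with an optional residual short-circuit (RCAM).

    ``weights_of`` returns the per-channel vectors (mc, mr, mrc); ``forward``
    scales each channel of the input by mrc.  With ``residual=False`` this is
    the plain CAM ablation: mr is zero and mrc == mc.
    """

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator,
                 residual: bool = True):
        hidden = channels // reduction_ratio
        if hidden < 1:
            raise ValueError(
                f"reduction_ratio {reduction_ratio} leaves no bottleneck units for "
                f"{channels} channels"
            )
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / hidden)
        # shared two-layer bottleneck applied to both pooled vectors
        self.w1 = Param(rng.standard_normal((hidden, channels)) * s1, "att.w1")
        self.b1 = Param(np.zeros(hidden), "att.b1")
        self.w2 = Param(rng.standard_normal((channels, hidden)) * s2, "att.w2")
        self.b2 = Param(np.zeros(channels), "att.b2")
        self.residual = residual
        self._cache = None

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def _fnn(self, v: np.ndarray):
        h_pre = v @ self.w1.value.T + self.b1.value
        h = np.maximum(h_pre, 0.0)
        return h @ self.w2.value.T + self.b2.value, h_pre, h

    def weights_of(self, f: np.ndarray):
        """(mc, mr, mrc) for a batch: each of shape (N, C)."""
        avg = f.mean(axis=2)
        amax = np.argmax(f, axis=2)
        mx = np.take_along_axis(f, amax[:, :, None], axis=2)[:, :, 0]
        fa, ha_pre, ha = self._fnn(avg)
        fm, hm_pre, hm = self._fnn(mx)
        mc = _sigmoid(fa + fm)
        if self.residual:
            mr = _sigmoid(avg + mx)
            mrc = mc + mr
        else:
            mr = np.zeros_like(mc)
            mrc = mc
        self._cache = (f, avg, mx, amax, ha_pre, ha, hm_pre, hm, mc, mr, mrc)
        return mc, mr, mrc

    def forward(self, f: np.ndarray) -> np.ndarray:
        _, _, mrc = self.weights_of(f)
        return mrc[:, :, None] * f

    def _fnn_backward(self, dout: np.ndarray, v: np.ndarray, h_pre: np.ndarray, h: np.ndarray):
        self.w2.grad += dout.T @ h
        self.b2.grad += dout.sum(axis=0)
        dh = (dout @ self.w2.value) * (h_pre > 0)
        self.w1.grad += dh.T @ v
        self.b1.grad += dh.sum(axis=0)
        return dh @ self.w1.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f, avg, mx, amax, ha_pre, ha, hm_pre, hm, mc, mr, mrc = self._cache
        N, C, L = f.shape
        df = mrc[:, :, None] * dy
        dmrc = (dy * f).sum(axis=2)  # (N, C)
        dmc = dmrc
        dpre_mc = dmc * mc * (1.0 - mc)
        davg = self._fnn_backward(dpre_mc, avg, ha_pre, ha)
        dmx = self._fnn_backward(dpre_mc, mx, hm_pre, hm)
        if self.residual:
            dpre_mr = dmrc * mr * (1.0 - mr)
            davg = davg + dpre_mr
            dmx = dmx + dpre_mr
        df += davg[:, :, None] / L
        np.put_along_axis(
            df, amax[:, :, None],
            np.take_along_axis(df, amax[:, :, None], axis=2) + dmx[:, :, None],
            axis=2,
        )
        return df


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Param(rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in), "fc.w")
        self.bias = Param(np.zeros(n_out), "fc.b")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class _Dropout:
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


@dataclass
class ModelSummary:
    """Per-stage output shapes and the trainable-parameter total."""

    stages: list[tuple[str, int, int]]  # (name, channels, length)
    n_parameters: int

    def __str__(self) -> str:
        lines = [f"{name:<14s} {c:>5d} x {l:<3d}" for name, c, l in self.stages]
        lines.append(f"trainable parameters: {self.n_parameters:,}")
        return "\n".join(lines)


class KcrModel:
    """The full classifier; see the module docstring for the pipeline."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        if config.input_length < 2 ** (config.n_blocks - 1):
            raise ValueError(
                f"input length {config.input_length} underflows after "
                f"{config.n_blocks - 1} transitions"
            )
        rng = np.random.default_rng(seed)
        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        c, L = config.input_channels, config.input_length
        for b in range(config.n_blocks):
            blk = DenseBlock(c, config.layers_per_block, config.growth_rate,
                             config.kernel_size, rng)
            self.blocks.append(blk)
            c = blk.c_out
            if b < config.n_blocks - 1:
                tr = Transition(c, config.compression, rng)
                self.transitions.append(tr)
                c = tr.c_out
                L = L // 2
        self.attention: ChannelAttention | None = None
        if config.attention != "none":
            self.attention = ChannelAttention(
                c, config.reduction_ratio, rng, residual=(config.attention == "rcam")
            )
        self.flat_dim = c * L
        self.final_channels, self.final_length = c, L
        self.fcs: list[Linear] = []
        self.relus: list[_ReLU] = []
        self.dropouts: list[_Dropout] = []
        n_in = self.flat_dim
        for width in config.fc_sizes:
            self.fcs.append(Linear(n_in, width, rng))
            self.relus.append(_ReLU())
            self.dropouts.append(_Dropout(config.dropout))
            n_in = width
        self.head = Linear(n_in, 2, rng)

    # ---- parameters ------------------------------------------------------
    def parameters(self) -> list[Param]:
        ps = []
        for blk in self.blocks:
            ps += blk.parameters()
        for tr in self.transitions:
            ps += tr.parameters()
        if self.attention is not None:
            ps += self.attention.parameters()
        for fc in self.fcs:
            ps += fc.parameters()
        ps += self.head.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # ---- forward / backward ---------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.config.input_channels \
                or x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected batch of shape (N, {self.config.input_channels}, "
                f"{self.config.input_length}), got {x.shape}"
            )
        h = x
        for b, blk in enumerate(self.blocks):
            h = blk.forward(h, train)
            if b < len(self.transitions):
                h = self.transitions[b].forward(h, train)
        if self.attention is not None:
            h = self.attention.forward(h)
        self._pre_flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        for fc, relu, drop in zip(self.fcs, self.relus, self.dropouts):
            h = drop.forward(relu.forward(fc.forward(h)), train, rng)
        return self.head.forward(h)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class-probability matrix (N, 2); rows sum to 1."""
        return softmax(self.forward_logits(x, train=train, rng=rng))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.zeros((0, 2))

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        for fc, relu, drop in zip(reversed(self.fcs), reversed(self.relus),
                                  reversed(self.dropouts)):
            dh = fc.backward(relu.backward(drop.backward(dh)))
        dh = dh.reshape(self._pre_flat_shape)
        if self.attention is not None:
            dh = self.attention.backward(dh)
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.transitions):
                dh = self.transitions[b].backward(dh)
            dh = self.blocks[b].backward(dh)

    # ---- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Checkpoint as .npz plus a JSON config sidecar ``<path>.json``."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        stats = {}
        i = 0
        for obj in self._bn_layers():
            stats[f"rm{i}"] = obj.running_mean
            stats[f"rv{i}"] = obj.running_var
            i += 1
        np.savez(path, **arrays, **stats)
        with open(str(path) + ".json", "w") as fh:
            fh.write(self.config.to_json())

    def _bn_layers(self):
        for blk in self.blocks:
            for bn, _, _ in blk.layers:
                yield bn
        for tr in self.transitions:
            yield tr.bn

    @classmethod
    def load(cls, path: str, seed: int = 0) -> "KcrModel":
        with open(str(path) + ".json") as fh:
            config = ModelConfig.from_json(fh.read())
        model = cls(config, seed=seed)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path))
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
        return model


def stage_shapes(config: ModelConfig) -> list[tuple[str, int, int]]:
    """Closed-form channel/length arithmetic for every pipeline stage."""
    stages = [("input", config.input_channels, config.input_length)]
    c, L = config.input_channels, config.input_length
    for b in range(config.n_blocks):
        c = c + config.layers_per_block * config.growth_rate
        stages.append((f"dense_block_{b + 1}", c, L))
        if b < config.n_blocks - 1:
            c = int(np.ceil(config.compression * c))
            L = L // 2
            stages.append((f"transition_{b + 1}", c, L))
    if config.attention != "none":
        stages.append((config.attention, c, L))
    stages.append(("flatten", c * L, 1))
    for i, width in enumerate(config.fc_sizes):
        stages.append((f"fc_{i + 1}", width, 1))
    stages.append(("softmax", 2, 1))
    return stages


def summarize(config: ModelConfig, seed: int = 0) -> ModelSummary:
    """Per-stage shapes (closed form) and the realized parameter count."""
    model = KcrModel(config, seed=seed)
    return ModelSummary(stages=stage_shapes(config), n_parameters=model.n_parameters)
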