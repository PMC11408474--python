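"""Classical time-series baselines: CNN, LSTM, GRU, CNN+LSTM, CNN+GRU.

All baselines share the iP3T forward contract — an M x L window in, a
(sin, cos) pair out — so they drop into the same training loop and
per-phase evaluation.  The CNN is a dual-branch convolutional stack (two
parallel branches with short and long kernels whose pooled features are
concatenated); the recurrent families stack `n_recurrent_blocks` layers
with a configurable hidden width; the hybrids feed `n_cnn_blocks`
convolutional blocks into `n_recurrent_blocks` recurrent blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, avg_pool1d, concat, conv1d

BASELINE_FAMILIES = ("CNN", "LSTM", "GRU", "CNN+LSTM", "CNN+GRU")


@dataclass
class BaselineSpec:
    family: str
    hidden_dim: int = 128
    n_recurrent_blocks: int = 4
    n_cnn_blocks: int = 3
    cnn_channels: int = 32

    def __post_init__(self):
        if self.family not in BASELINE_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {BASELINE_FAMILIES}")
        if min(self.hidden_dim, self.n_recurrent_blocks, self.n_cnn_blocks,
               self.cnn_channels) < 1:
            raise ValueError("all baseline dimensions must be positive")


def _lin(rng, n_in, n_out):
    bound = 1.0 / math.sqrt(n_in)
    return Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)


def _zeros(shape):
    return Tensor(np.zeros(shape), requires_grad=True)


class _ConvBlock:
    """conv1d (stride 1, valid) -> ReLU -> average pool by 2."""

    def __init__(self, rng, c_in, c_out, kernel):
        bound = 1.0 / math.sqrt(c_in * kernel)
        self.w = Tensor(rng.uniform(-bound, bound, (c_out, c_in, kernel)),
                        requires_grad=True)
        self.b = _zeros(c_out)
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return avg_pool1d(conv1d(x, self.w, self.b).relu(), 2)

    def parameters(self):
        return [self.w, self.b]

    def out_len(self, length: int) -> int:
        return (length - self.kernel + 1) // 2


class _RecurrentLayer:
    """One LSTM or GRU layer over a (B, L, C) sequence."""

    def __init__(self, rng, cell: str, c_in: int, hidden: int):
        self.cell = cell
        self.hidden = hidden
        n_gates = 4 if cell == "LSTM" else 3
        self.wx = _lin(rng, c_in, n_gates * hidden)
        self.wh = _lin(rng, hidden, n_gates * hidden)
        self.b = _zeros(n_gates * hidden)

    def parameters(self):
        return [self.wx, self.wh, self.b]

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        B = xs[0].shape[0]
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = []
        for x_t in xs:
            z = x_t @ self.wx + h @ self.wh + self.b
            if self.cell == "LSTM":
                i = z[:, 0:H].sigmoid()
                f = z[:, H:2 * H].sigmoid()
                g = z[:, 2 * H:3 * H].tanh()
                o = z[:, 3 * H:4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
            else:  # GRU
                r = z[:, 0:H].sigmoid()
                u = z[:, H:2 * H].sigmoid()
                # candidate uses the reset-gated recurrent contribution
                n = (x_t @ self.wx[:, 2 * H:3 * H]
                     + r * (h @ self.wh[:, 2 * H:3 * H])
                     + self.b[2 * H:3 * H]).tanh()
                h = (1.0 - u) * n + u * h
            outs.append(h)
        return outs


class BaselineModel:
    """A baseline network with the (B, M, L) -> (B, 2) forward contract."""

    def __init__(self, spec: BaselineSpec, n_channels: int, window_len: int,
                 seed: int = 0):
        self.spec = spec
        self.n_channels = n_channels
        self.window_len = window_len
        rng = np.random.default_rng(seed)
        self._params: list[Tensor] = []
        self.conv_blocks: list[list[_ConvBlock]] = []
        self.recurrent: list[_RecurrentLayer] = []

        feat_dim = 0
        if spec.family == "CNN":
            # dual-branch: short (3) and long (7) kernels in parallel
            for kernel in (3, 7):
                branch, c, length = [], n_channels, window_len
                for _ in range(spec.n_cnn_blocks):
                    blk = _ConvBlock(rng, c, spec.cnn_channels, kernel)
                    length = blk.out_len(length)
                    branch.append(blk)
                    c = spec.cnn_channels
                self.conv_blocks.append(branch)
                feat_dim += c * length
        elif spec.family in ("LSTM", "GRU"):
            c = n_channels
            for _ in range(spec.n_recurrent_blocks):
                self.recurrent.append(_RecurrentLayer(rng, spec.family, c,
                                                      spec.hidden_dim))
                c = spec.hidden_dim
            feat_dim = spec.hidden_dim
        else:  # CNN+LSTM / CNN+GRU: 3 conv blocks feeding 3 recurrent blocks
            cell = spec.family.split("+")[1]
            branch, c, length = [], n_channels, window_len
            for _ in range(spec.n_cnn_blocks):
                blk = _ConvBlock(rng, c, spec.cnn_channels, 3)
                length = blk.out_len(length)
                branch.append(blk)
                c = spec.cnn_channels
            self.conv_blocks.append(branch)
            for _ in range(spec.n_recurrent_blocks):
                self.recurrent.append(_RecurrentLayer(rng, cell, c,
                                                      spec.hidden_dim))
                c = spec.hidden_dim
            feat_dim = spec.hidden_dim

        self.head_w = _lin(rng, feat_dim, 2)
        self.head_b = _zeros(2)
        for branch in self.conv_blocks:
            for blk in branch:
                self._params.extend(blk.parameters())
        for layer in self.recurrent:
            self._params.extend(layer.parameters())
        self._params.extend([self.head_w, self.head_b])

    def parameters(self) -> list[Tensor]:
        return self._params

    def forward_batch(self, x: Tensor, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        B, M, L = x.shape
        if M != self.n_channels or L != self.window_len:
            raise ValueError("window shape does not match baseline configuration")
        if self.spec.family == "CNN":
            feats = []
            for branch in self.conv_blocks:
                z = x
                for blk in branch:
                    z = blk(z)
                feats.append(z.reshape(B, z.shape[1] * z.shape[2]))
            feat = concat(feats, axis=1)
        else:
            z = x
            for branch in self.conv_blocks:
                for blk in branch:
                    z = blk(z)
            # (B, C, L') -> per-time-step inputs for the recurrent stack
            seq = [z[:, :, t] for t in range(z.shape[2])]
            for layer in self.recurrent:
                seq = layer(seq)
            feat = seq[-1]  # last hidden state
        return feat @ self.head_w + self.head_b


def build_baseline(spec: BaselineSpec, n_channels: int, window_len: int,
                   seed: int = 0) -> BaselineModel:
    """Construct a baseline model for M x L windows."""
    return BaselineModel(spec, n_channels, window_len, seed=seed)
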