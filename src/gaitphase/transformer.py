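"""The iP3T network: patch embedding, transformer encoding, cross-attention
channel fusion, and a two-component prediction head.

Each sensor channel is processed independently ("channel independence"):
its length-L window is cut into L/P_l non-overlapping patches of length
P_l, linearly projected to the embedding dimension d, prefixed with a
learnable per-channel token and summed with a learnable positional table.
A post-norm transformer encoder (multi-head self-attention + GELU FFN,
residual connections, LayerNorm after each sub-block) refines the sequence;
the encoded channel token (row 0) summarizes the channel.  A learnable
global query token T' then pools the M channel tokens through dot-product
cross-attention — whose softmax rows are the channel-importance weights —
and an MLP maps the pooled feature to the (sin, cos) phase prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-size configuration (d = 768, 12 heads,
    6 layers, patch length 10, FFN expansion 4d); tests and the synthetic
    experiments use reduced instances.
    """

    n_channels: int = 16
    window_len: int = 100
    patch_len: int = 10
    embed_dim: int = 768
    n_heads: int = 12
    n_layers: int = 6
    ffn_dim: int | None = None  # defaults to 4 * embed_dim
    head_hidden_dims: tuple[int, ...] | None = None  # defaults to (embed_dim,)
    dropout: float = 0.1
    share_patch_projection: bool = True
    per_channel_tokens: bool = True
    # Honour the literal d_k = d attention scaling instead of the standard
    # per-head sqrt(d/h); off by default (see docs/methods.md).
    scale_by_full_d: bool = False

    def __post_init__(self):
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.embed_dim
        if self.head_hidden_dims is None:
            self.head_hidden_dims = (self.embed_dim,)
        if self.window_len % self.patch_len != 0:
            raise ValueError("patch_len must divide window_len")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("n_heads must divide embed_dim")
        for name in ("n_channels", "window_len", "patch_len", "embed_dim",
                     "n_heads", "ffn_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")

    @property
    def n_patches(self) -> int:
        return self.window_len // self.patch_len

    @property
    def seq_len(self) -> int:
        """Patches plus the prepended channel token."""
        return self.n_patches + 1

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def attn_scale(self) -> float:
        return math.sqrt(self.embed_dim if self.scale_by_full_d else self.head_dim)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std)


def _fan_in_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    bound = 1.0 / math.sqrt(shape[0])
    return rng.uniform(-bound, bound, shape)


@dataclass
class ModelParams:
    """All learnable weights, kept as autodiff Tensors."""

    config: ModelConfig
    patch_proj_w: Tensor  # (P_l, d) or (M, P_l, d) when not shared
    patch_proj_b: Tensor  # (1, d)
    channel_tokens: Tensor  # (M, d) or (1, d)
    pos_table: Tensor  # (S, d)
    layers: list[dict[str, Tensor]] = field(default_factory=list)
    cross: dict[str, Tensor] = field(default_factory=dict)
    global_token: Tensor | None = None  # T', (1, d)
    head: list[tuple[Tensor, Tensor]] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        out = [self.patch_proj_w, self.patch_proj_b, self.channel_tokens,
               self.pos_table, self.global_token]
        for layer in self.layers:
            out.extend(layer.values())
        out.extend(self.cross.values())
        for w, b in self.head:
            out.extend([w, b])
        return out

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    """Initialize weights: truncated normal (sigma 0.02) for tokens and
    embedding tables, uniform fan-in for linear maps."""
    rng = np.random.default_rng(seed)
    d, P, S, M = (config.embed_dim, config.patch_len, config.seq_len,
                  config.n_channels)

    def lin(n_in, n_out):
        return Tensor(_fan_in_uniform(rng, (n_in, n_out)), requires_grad=True)

    w_shape = (P, d) if config.share_patch_projection else (M, P, d)
    params = ModelParams(
        config=config,
        patch_proj_w=Tensor(_fan_in_uniform(rng, w_shape), requires_grad=True),
        patch_proj_b=Tensor(np.zeros((1, d)), requires_grad=True),
        channel_tokens=Tensor(
            _trunc_normal(rng, (M if config.per_channel_tokens else 1, d)),
            requires_grad=True),
        pos_table=Tensor(_trunc_normal(rng, (S, d)), requires_grad=True),
        global_token=Tensor(_trunc_normal(rng, (1, d)), requires_grad=True),
    )
    for _ in range(config.n_layers):
        params.layers.append({
            "W_Q": lin(d, d), "W_K": lin(d, d), "W_V": lin(d, d), "W_O": lin(d, d),
            "b_O": Tensor(np.zeros(d), requires_grad=True),
            "W_1": lin(d, config.ffn_dim),
            "b_1": Tensor(np.zeros(config.ffn_dim), requires_grad=True),
            "W_2": lin(config.ffn_dim, d),
            "b_2": Tensor(np.zeros(d), requires_grad=True),
            "ln1_g": Tensor(np.ones(d), requires_grad=True),
            "ln1_b": Tensor(np.zeros(d), requires_grad=True),
            "ln2_g": Tensor(np.ones(d), requires_grad=True),
            "ln2_b": Tensor(np.zeros(d), requires_grad=True),
        })
    params.cross = {"W_Q": lin(d, d), "W_K": lin(d, d), "W_V": lin(d, d),
                    "W_O": lin(d, d),
                    "b_O": Tensor(np.zeros(d), requires_grad=True)}
    dims = (d, *config.head_hidden_dims, 2)
    for n_in, n_out in zip(dims[:-1], dims[1:]):
        params.head.append((lin(n_in, n_out),
                            Tensor(np.zeros(n_out), requires_grad=True)))
    return params


@dataclass
class ForwardTrace:
    """Artifacts of one forward pass (numpy, detached from the tape)."""

    y_pred: np.ndarray  # (B, 2)
    channel_tokens: np.ndarray  # (B, M, d) encoded tokens entering fusion
    cross_attention: np.ndarray  # (B, h, M) softmax rows of T' over channels
    encoder_attention: np.ndarray | None = None  # (B, M, N, h, S, S)


# ---------------------------------------------------------------------------
# batched building blocks (leading axes broadcast through matmul)
# ---------------------------------------------------------------------------

def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    """(..., S, d) -> (..., h, S, d/h)."""
    *lead, S, d = x.shape
    x = x.reshape(*lead, S, n_heads, d // n_heads)
    axes = tuple(range(len(lead))) + (x.ndim - 2, x.ndim - 3, x.ndim - 1)
    return x.transpose(*axes)


def _merge_heads(x: Tensor) -> Tensor:
    """(..., h, S, d/h) -> (..., S, d)."""
    *lead, h, S, dh = x.shape
    axes = tuple(range(len(lead))) + (x.ndim - 2, x.ndim - 3, x.ndim - 1)
    return x.transpose(*axes).reshape(*lead, S, h * dh)


def multi_head_attention(
    q_in: Tensor, kv_in: Tensor, weights: dict[str, Tensor], config: ModelConfig,
    training: bool = False, rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Dot-product multi-head attention.

    Returns the output-projected result and the per-head attention weights
    (shape (..., h, S_q, S_k)).  Self-attention passes q_in = kv_in; the
    channel-fusion cross-attention passes the global token as q_in.
    """
    h = config.n_heads
    q = _split_heads(q_in @ weights["W_Q"], h)
    k = _split_heads(kv_in @ weights["W_K"], h)
    v = _split_heads(kv_in @ weights["W_V"], h)
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / config.attn_scale)
    attn = scores.softmax(axis=-1)
    drop = attn.dropout(config.dropout, rng) if training and rng is not None else attn
    out = _merge_heads(drop @ v) @ weights["W_O"] + weights["b_O"]
    return out, attn


def encoder_layer_batch(
    x: Tensor, layer: dict[str, Tensor], config: ModelConfig,
    training: bool = False, rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """One post-norm encoder layer on (..., S, d); returns (out, attention)."""
    attn_out, attn = multi_head_attention(x, x, layer, config, training, rng)
    a = (x + attn_out).layer_norm(layer["ln1_g"], layer["ln1_b"])
    hmid = (a @ layer["W_1"] + layer["b_1"]).gelu()
    if training and rng is not None:
        hmid = hmid.dropout(config.dropout, rng)
    ffn = hmid @ layer["W_2"] + layer["b_2"]
    out = (a + ffn).layer_norm(layer["ln2_g"], layer["ln2_b"])
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("non-finite activations in encoder layer")
    return out, attn


def embed_batch(x: Tensor, params: ModelParams) -> Tensor:
    """Patch, project and position-encode a (B, M, L) batch -> (B, M, S, d)."""
    cfg = params.config
    B, M, L = x.shape
    if M != cfg.n_channels or L != cfg.window_len:
        raise ValueError(
            f"window shape ({M}, {L}) does not match config "
            f"({cfg.n_channels}, {cfg.window_len})")
    patches = x.reshape(B, M, cfg.n_patches, cfg.patch_len)
    if cfg.share_patch_projection:
        proj = patches @ params.patch_proj_w + params.patch_proj_b
    else:
        # per-channel projection: (B, M, n_p, P) x (M, P, d), broadcast over B
        proj = patches @ params.patch_proj_w.reshape(
            1, M, cfg.patch_len, cfg.embed_dim) + params.patch_proj_b
    tokens = params.channel_tokens.reshape(
        1, -1, 1, cfg.embed_dim) * Tensor(np.ones((B, M, 1, 1)))
    return concat([tokens, proj], axis=2) + params.pos_table


def forward_batch(
    x: Tensor, params: ModelParams, training: bool = False,
    rng: np.random.Generator | None = None, capture_attention: bool = False,
) -> tuple[Tensor, ForwardTrace]:
    """Full iP3T forward pass on a (B, M, L) batch.

    Deterministic in evaluation mode (training=False).  With
    capture_attention=True the per-layer encoder self-attention maps are
    retained in the trace for attention-scope reporting.
    """
    cfg = params.config
    z = embed_batch(x, params)  # (B, M, S, d)
    enc_attn = [] if capture_attention else None
    for layer in params.layers:
        z, attn = encoder_layer_batch(z, layer, cfg, training, rng)
        if capture_attention:
            enc_attn.append(attn.data)  # (B, M, h, S, S)
    tokens = z[:, :, 0, :]  # (B, M, d) encoded channel tokens
    query = params.global_token.reshape(1, 1, cfg.embed_dim) * \
        Tensor(np.ones((x.shape[0], 1, 1)))
    feat, cross_attn = multi_head_attention(
        query, tokens, params.cross, cfg, training, rng)
    y = feat[:, 0, :]  # (B, d)
    for i, (w, b) in enumerate(params.head):
        y = y @ w + b
        if i < len(params.head) - 1:
            y = y.gelu()
            if training and rng is not None:
                y = y.dropout(cfg.dropout, rng)
    trace = ForwardTrace(
        y_pred=y.data,
        channel_tokens=tokens.data,
        cross_attention=cross_attn.data[:, :, 0, :],  # (B, h, M)
        encoder_attention=(
            np.stack(enc_attn, axis=2) if capture_attention and enc_attn
            else (np.empty((x.shape[0], cfg.n_channels, 0, cfg.n_heads,
                            cfg.seq_len, cfg.seq_len))
                  if capture_attention else None)),
    )
    return y, trace


# ---------------------------------------------------------------------------
# single-instance operations (numpy in / numpy out) used by tests and
# interpretation code
# ---------------------------------------------------------------------------

def patch_embed(series: np.ndarray, channel_index: int, params: ModelParams) -> np.ndarray:
    """Embed one channel's length-L window -> (S, d) input sequence.

    Row 0 is the channel token; rows 1..S-1 are the projected patches; the
    positional table is added row-wise.
    """
    cfg = params.config
    series = np.asarray(series, dtype=float)
    if series.shape != (cfg.window_len,):
        raise ValueError(f"series must have length {cfg.window_len}")
    if not 0 <= channel_index < cfg.n_channels:
        raise IndexError("channel_index out of range")
    patches = series.reshape(cfg.n_patches, cfg.patch_len)
    w = (params.patch_proj_w.data if cfg.share_patch_projection
         else params.patch_proj_w.data[channel_index])
    proj = patches @ w + params.patch_proj_b.data
    token = params.channel_tokens.data[
        channel_index if cfg.per_channel_tokens else 0]
    return np.vstack([token, proj]) + params.pos_table.data


def encoder_layer(x: np.ndarray, layer: dict[str, Tensor], config: ModelConfig,
                  capture_attention: bool = False):
    """One encoder layer on an (S, d) sequence (evaluation mode)."""
    out, attn = encoder_layer_batch(Tensor(np.asarray(x, dtype=float)),
                                    layer, config)
    return (out.data, attn.data) if capture_attention else (out.data, None)


def encode_channel(embedded: np.ndarray, params: ModelParams) -> np.ndarray:
    """Apply the N encoder layers and return the encoded channel token."""
    z = Tensor(np.asarray(embedded, dtype=float))
    for layer in params.layers:
        z, _ = encoder_layer_batch(z, layer, params.config)
    return z.data[0]


def cross_attend(t_tokens: np.ndarray, params: ModelParams):
    """Pool M channel tokens with the global query T'.

    Returns (T_feature, weights) where weights has shape (h, M) and every
    row is a stochastic vector.
    """
    cfg = params.config
    t_tokens = np.asarray(t_tokens, dtype=float)
    if t_tokens.ndim != 2 or t_tokens.shape[0] < 1:
        raise ValueError("T_tokens must be a non-empty M x d matrix")
    feat, attn = multi_head_attention(
        params.global_token, Tensor(t_tokens), params.cross, cfg)
    return feat.data[0], attn.data[:, 0, :]


def forward(window: np.ndarray, params: ModelParams,
            capture_attention: bool = False) -> ForwardTrace:
    """Evaluation-mode forward pass for a single M x L window."""
    window = np.asarray(window, dtype=float)
    cfg = params.config
    if window.shape != (cfg.n_channels, cfg.window_len):
        raise ValueError(
            f"window shape {window.shape} does not match config "
            f"({cfg.n_channels}, {cfg.window_len})")
    _, trace = forward_batch(Tensor(window[None]), params,
                             capture_attention=capture_attention)
    return ForwardTrace(
        y_pred=trace.y_pred[0],
        channel_tokens=trace.channel_tokens[0],
        cross_attention=trace.cross_attention[0],
        encoder_attention=(trace.encoder_attention[0]
                           if trace.encoder_attention is not None else None),
    )
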