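"""Interpretability artifacts: channel-importance weights, attention-scope
maps, and attention-guided sensor-channel selection.

The cross-attention softmax row of the global token T' over the M channel
tokens is the model's channel-importance distribution.  Reports average it
over attention heads (arithmetic mean, switchable to per-head) and over
evaluated windows.  Attention-scope maps average the encoder's
self-attention matrices over a chosen layer/head set — by default the last
six heads of the final three layers — exposing which time segments of a
channel the model attends to.  Channel selection ranks channels by mean
weight within each modality and assembles fused 16-channel data sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import IP3TRegressor
from .preprocess import WindowDataset


@dataclass
class ChannelWeightReport:
    """Mean and dispersion of per-channel cross-attention weight."""

    channel_names: list[str]
    mean_weights: np.ndarray  # (M,), sums to ~1
    std_weights: np.ndarray  # (M,) std over windows
    n_windows: int
    head_reduction: str = "mean"
    per_head_means: np.ndarray | None = None  # (h, M) when requested
    modality_of: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channel_names, map(float, self.mean_weights)))


@dataclass
class AttentionScopeMap:
    """Per-channel (S x S) attention maps averaged over layers and heads."""

    channel_names: list[str]
    maps: np.ndarray  # (M, S, S); rows stochastic
    layers_used: tuple[int, ...]
    heads_used: tuple[int, ...]


@dataclass
class ChannelSelection:
    """An attention-ranked fused data source."""

    source_spec: str
    selected: list[str]
    k_per_modality: dict[str, int]

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected channels must be unique")


def channel_weights(
    model: IP3TRegressor, dataset: WindowDataset,
    head_reduction: str = "mean", batch_size: int = 256,
) -> ChannelWeightReport:
    """Cross-attention channel importance averaged over a dataset.

    Per window: softmax rows of T' over channels, one per head, averaged
    over heads ("mean") — the per-head means are retained when
    head_reduction="per-head".  The report mean/std are taken over windows.
    """
    if len(dataset) == 0:
        raise ValueError("cannot compute channel weights on an empty dataset")
    if head_reduction not in ("mean", "per-head"):
        raise ValueError("head_reduction must be 'mean' or 'per-head'")
    if model.config_.n_channels != len(dataset.channel_names) or \
            model.config_.window_len != dataset.window_len:
        raise ValueError("model configuration does not match dataset shape")
    trace = model.forward_trace(dataset.windows, batch_size=batch_size)
    per_window = trace.cross_attention.mean(axis=1)  # (B, M) head average
    return ChannelWeightReport(
        channel_names=list(dataset.channel_names),
        mean_weights=per_window.mean(axis=0),
        std_weights=per_window.std(axis=0),
        n_windows=len(dataset),
        head_reduction=head_reduction,
        per_head_means=(trace.cross_attention.mean(axis=0)
                        if head_reduction == "per-head" else None),
        modality_of=dict(dataset.modality_of),
    )


def attention_scope(
    model: IP3TRegressor, window: np.ndarray,
    layers: tuple[int, ...] | None = None,
    heads: tuple[int, ...] | None = None,
    channel_names: list[str] | None = None,
) -> AttentionScopeMap:
    """Average encoder self-attention over a layer/head set for one window.

    Defaults to the last three layers and the last six heads (clipped to
    the model's depth/width).
    """
    cfg = model.config_
    if layers is None:
        layers = tuple(range(max(0, cfg.n_layers - 3), cfg.n_layers))
    if heads is None:
        heads = tuple(range(max(0, cfg.n_heads - 6), cfg.n_heads))
    if not layers or not heads:
        raise ValueError("layer and head sets must be non-empty")
    if max(layers) >= cfg.n_layers or min(layers) < 0:
        raise IndexError("layer index out of range")
    if max(heads) >= cfg.n_heads or min(heads) < 0:
        raise IndexError("head index out of range")
    window = np.asarray(window, dtype=float)
    trace = model.forward_trace(window[None], capture_attention=True)
    if trace.encoder_attention is None or trace.encoder_attention.shape[2] == 0:
        raise RuntimeError("no trace: encoder attention was not captured")
    att = trace.encoder_attention[0]  # (M, N, h, S, S)
    maps = att[:, layers][:, :, heads].mean(axis=(1, 2))
    return AttentionScopeMap(
        channel_names=channel_names or [f"ch{i}" for i in range(cfg.n_channels)],
        maps=maps, layers_used=tuple(layers), heads_used=tuple(heads),
    )


def _ranked(report: ChannelWeightReport, modality: str) -> list[str]:
    w = report.as_dict()
    names = [c for c in report.channel_names
             if report.modality_of.get(c) == modality]
    # descending weight; exact ties broken by lexicographic channel name
    return sorted(names, key=lambda c: (-w[c], c))


def select_top_channels(
    report: ChannelWeightReport, k_per_modality: dict[str, int],
    source_spec: str = "",
) -> ChannelSelection:
    """Top-k channels per modality by mean cross-attention weight."""
    selected: list[str] = []
    for modality, k in k_per_modality.items():
        ranked = _ranked(report, modality)
        if k > len(ranked):
            raise ValueError(
                f"requested top {k} channels of modality {modality}, "
                f"only {len(ranked)} available")
        selected.extend(ranked[:k])
    return ChannelSelection(
        source_spec=source_spec or "+".join(k_per_modality),
        selected=selected, k_per_modality=dict(k_per_modality))


def build_fused_source_specs(report: ChannelWeightReport) -> list[ChannelSelection]:
    """Assemble the four fused 16-channel data sources.

    IMU+EMG takes the top 8 per modality; Stretch+EMG and IMU+Stretch take
    both stretch channels plus the top 14 of the other modality;
    IMU+Stretch+EMG takes both stretch channels plus the top 7 from IMU
    and EMG each.  Requires a report over the full 34-channel registry
    (16 IMU, 16 EMG, 2 stretch).
    """
    counts = {m: len(_ranked(report, m)) for m in ("IMU", "EMG", "STRETCH")}
    need = {"IMU": 16, "EMG": 16, "STRETCH": 2}
    for m, k in need.items():
        if counts[m] < k:
            raise ValueError(
                f"report must cover {k} {m} channels; found {counts[m]}")
    plans = [
        ("IMU+EMG", {"IMU": 8, "EMG": 8}),
        ("Stretch+EMG", {"STRETCH": 2, "EMG": 14}),
        ("IMU+Stretch", {"STRETCH": 2, "IMU": 14}),
        ("IMU+Stretch+EMG", {"STRETCH": 2, "IMU": 7, "EMG": 7}),
    ]
    out = [select_top_channels(report, k_map, source_spec=name)
           for name, k_map in plans]
    assert all(len(sel.selected) == 16 for sel in out)
    return out
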