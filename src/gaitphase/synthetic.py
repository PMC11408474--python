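"""Stride-periodic synthetic recordings with known ground-truth phase.

Emulates the shape of treadmill gait data: kinematic channels are smooth
harmonics of the gait phase (joint-angle-like), sEMG channels are rectified
noise gated by phase-locked burst envelopes (push-off and swing bursts),
stretch channels are smooth periodic ramps tracking knee flexion, and a
foot-pressure channel is a smooth pulse train peaking exactly at each
stride boundary so the label pipeline can be exercised end to end.
Channels of kind "noise" carry no phase information at all and anchor the
channel-attribution experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    PhaseSeries,
    SensorRecording,
    WindowDataset,
    derive_phase_labels,
    make_windows,
)

CHANNEL_KINDS = ("kinematic-sinusoid", "emg-burst", "stretch-ramp", "noise")


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    modality: str  # IMU | STRETCH | EMG
    kind: str  # one of CHANNEL_KINDS
    phase_offset: float = 0.0  # percent of gait cycle
    snr: float = 0.0  # signal-RMS / noise-std; 0 = noiseless


def default_channels() -> list[ChannelSpec]:
    """A small plausible sensor set: 2 IMU, 1 stretch, 2 EMG, 1 pure noise."""
    return [
        ChannelSpec("shank_angle", "IMU", "kinematic-sinusoid", 0.0, 0.0),
        ChannelSpec("thigh_gyro", "IMU", "kinematic-sinusoid", 25.0, 0.0),
        ChannelSpec("knee_stretch", "STRETCH", "stretch-ramp", 0.0, 0.0),
        ChannelSpec("emg_pushoff", "EMG", "emg-burst", 40.0, 0.0),
        ChannelSpec("emg_swing", "EMG", "emg-burst", 90.0, 0.0),
        ChannelSpec("dead_channel", "IMU", "noise", 0.0, 0.0),
    ]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic recording.

    Parameters
    ----------
    n_strides : int
        Number of gait cycles (>= 2).
    stride_len_mean : int
        Mean stride length in samples (>= 10); 100 samples at 100 Hz
        corresponds to a 1 s stride, a typical treadmill cadence.
    stride_len_jitter : float
        Per-stride uniform length perturbation as a fraction of the mean,
        in [0, 1).
    channels : list of ChannelSpec
    rate_hz : float
    seed : int
    """

    n_strides: int = 20
    stride_len_mean: int = 100
    stride_len_jitter: float = 0.05
    channels: list[ChannelSpec] = field(default_factory=default_channels)
    rate_hz: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_strides < 2:
            raise ValueError("n_strides must be >= 2")
        if self.stride_len_mean < 10:
            raise ValueError("stride_len_mean must be >= 10 samples")
        if not (0.0 <= self.stride_len_jitter < 1.0):
            raise ValueError("stride_len_jitter must lie in [0, 1)")
        if not self.channels:
            raise ValueError("channels must be a non-empty list")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channels must have unique names")
        for c in self.channels:
            if c.kind not in CHANNEL_KINDS:
                raise ValueError(f"channels: unknown kind {c.kind!r} ({c.name})")
            if c.snr < 0:
                raise ValueError(f"channels: snr must be >= 0 ({c.name})")


def _ground_truth_phase(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-sample phase plus the stride-boundary sample indices."""
    jit = spec.stride_len_jitter
    if jit > 0:
        lengths = np.round(
            spec.stride_len_mean * (1.0 + rng.uniform(-jit, jit, spec.n_strides))
        ).astype(int)
        lengths = np.maximum(lengths, 2)
    else:
        lengths = np.full(spec.n_strides, spec.stride_len_mean, dtype=int)
    phase = np.concatenate([100.0 * np.arange(n) / n for n in lengths])
    boundaries = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return phase, boundaries


def _channel_signal(kind: str, phase: np.ndarray, offset: float,
                    rng: np.random.Generator) -> np.ndarray:
    theta = 2.0 * np.pi * (phase - offset) / 100.0
    if kind == "kinematic-sinusoid":
        # first + weaker second harmonic, joint-trajectory-like
        return np.sin(theta) + 0.3 * np.sin(2.0 * theta)
    if kind == "emg-burst":
        # rectified white noise gated by a smooth circular burst envelope
        envelope = np.exp(2.5 * (np.cos(theta) - 1.0))
        return envelope * np.abs(rng.standard_normal(len(phase)))
    if kind == "stretch-ramp":
        # smooth periodic flexion/extension ramp (0..1 and back)
        return np.sin(0.5 * theta) ** 2
    if kind == "noise":
        return rng.standard_normal(len(phase))
    raise ValueError(f"unknown channel kind {kind!r}")


def generate_recording(spec: SyntheticSpec) -> tuple[SensorRecording, PhaseSeries]:
    """Simulate one recording; deterministic for a fixed spec (incl. seed).

    The foot-pressure channel is a smooth circular pulse exp(k(cos θ - 1))
    whose maxima fall exactly on the stride-boundary samples (phase 0).
    The returned :class:`PhaseSeries` is the exact generator phase, valid
    everywhere.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    phase, _ = _ground_truth_phase(spec, rng)

    channels: dict[str, np.ndarray] = {}
    modality_of: dict[str, str] = {}
    for ch in spec.channels:
        sig = _channel_signal(ch.kind, phase, ch.phase_offset, rng)
        if ch.snr > 0 and ch.kind != "noise":
            rms = float(np.sqrt(np.mean(sig**2)))
            sig = sig + rng.standard_normal(len(sig)) * (rms / ch.snr)
        channels[ch.name] = sig
        modality_of[ch.name] = ch.modality

    pressure = np.exp(4.0 * (np.cos(2.0 * np.pi * phase / 100.0) - 1.0))
    rec = SensorRecording(
        channels=channels, rate_hz=spec.rate_hz,
        modality_of=modality_of, foot_pressure=pressure,
    )
    return rec, PhaseSeries(phase=phase, valid_mask=np.ones(len(phase), dtype=bool))


def generate_dataset(
    spec: SyntheticSpec,
    window_len: int = 100,
    stride: int = 1,
    label_source: str = "exact",
    smooth_window: int = 15,
    min_peak_distance: int = 50,
) -> WindowDataset:
    """Simulate a recording and window it.

    label_source "exact" uses the generator's ground-truth phase; "derived"
    runs the foot-pressure label pipeline (smoothing, peak marking, linear
    interpolation) exactly as on real data.
    """
    rec, truth = generate_recording(spec)
    if label_source == "exact":
        phase = truth
    elif label_source == "derived":
        phase = derive_phase_labels(
            rec.foot_pressure, smooth_window=smooth_window,
            min_peak_distance=min_peak_distance,
        )
    else:
        raise ValueError("label_source must be 'exact' or 'derived'")
    ds = make_windows(rec, phase, window_len=window_len, stride=stride)
    ds.label_source = label_source
    return ds
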