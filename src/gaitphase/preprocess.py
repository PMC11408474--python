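"""Raw multichannel gait recordings -> model-ready windows and phase labels.

The continuous gait phase parameterizes the gait cycle as 0-100% between
successive right-foot initial contacts.  Labels are derived from a foot
pressure channel: the signal is smoothed with a centered moving average,
strict local maxima (one per stride) are marked, and the phase ramps
linearly 0 -> 100 between consecutive maxima.  Because 0% and 100% are
kinematically near-identical, phases are regressed in Cartesian form
(sin, cos) of the phase angle and decoded with atan2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal

MODALITIES = ("IMU", "STRETCH", "EMG")

#: The four-way stratification of the gait cycle used for reporting:
#: pre-stance (0-30%), post-stance (31-60%), pre-swing (61-80%),
#: post-swing (81-100%), applied to continuous values with bin edges at
#: the integer boundaries 30, 60 and 80.
PHASE_BINS: tuple["GaitPhaseBin", ...]


class GaitPhaseBin(NamedTuple):
    name: str
    lo: float  # inclusive for the first bin, exclusive otherwise
    hi: float  # inclusive


PHASE_BINS = (
    GaitPhaseBin("pre-stance", 0.0, 30.0),
    GaitPhaseBin("post-stance", 30.0, 60.0),
    GaitPhaseBin("pre-swing", 60.0, 80.0),
    GaitPhaseBin("post-swing", 80.0, 100.0),
)


class PhaseLabel(NamedTuple):
    """Cartesian phase encoding: y0 = sin component, y1 = cos component."""

    y0: float
    y1: float


@dataclass
class SensorRecording:
    """Synchronized named multichannel time series.

    Parameters
    ----------
    channels : dict of str -> 1-D array
        Ordered channel-name -> series map; all series equal length.
    rate_hz : float
        Common sampling rate in Hz.
    modality_of : dict of str -> {"IMU", "STRETCH", "EMG"}
        Sensor modality per channel.
    foot_pressure : 1-D array, optional
        Pressure channel used only to derive phase labels.
    """

    channels: dict[str, np.ndarray]
    rate_hz: float
    modality_of: dict[str, str] = field(default_factory=dict)
    foot_pressure: np.ndarray | None = None

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        lengths = {name: len(np.asarray(s)) for name, s in self.channels.items()}
        if min(lengths.values()) < 1:
            raise ValueError("all series must have length >= 1")
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.foot_pressure is not None:
            self.foot_pressure = np.asarray(self.foot_pressure, dtype=float)
            if len(self.foot_pressure) != self.n_samples:
                raise ValueError("foot_pressure length differs from channels")
        for name, mod in self.modality_of.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod!r} for channel {name!r}")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def as_matrix(self) -> np.ndarray:
        """Channels stacked as an M x T matrix in registry order."""
        return np.stack([self.channels[c] for c in self.channels])


@dataclass
class PhaseSeries:
    """Per-sample gait phase in percent with a validity mask.

    Samples before the first marked stride boundary and after the last one
    carry no stride context and are flagged invalid rather than extrapolated.
    """

    phase: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.phase.shape != self.valid_mask.shape:
            raise ValueError("phase and valid_mask shapes differ")
        v = self.phase[self.valid_mask]
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 100):
            raise ValueError("valid phase values must lie in [0, 100]")


@dataclass
class WindowDataset:
    """Sliding windows (each M x L) with encoded labels and raw phases."""

    windows: np.ndarray  # (n, M, L)
    labels: np.ndarray  # (n, 2) = (sin, cos) at each window's last step
    phases: np.ndarray  # (n,) raw phase in [0, 100]
    channel_names: list[str]
    window_len: int
    stride: int
    modality_of: dict[str, str] = field(default_factory=dict)
    label_source: str = "derived"

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        n = len(self.windows)
        if not (len(self.labels) == len(self.phases) == n):
            raise ValueError("windows, labels and phases must have equal length")
        if n and self.windows.shape[1:] != (len(self.channel_names), self.window_len):
            raise ValueError("window shape does not match channel/window metadata")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx) -> "WindowDataset":
        return WindowDataset(
            self.windows[idx], self.labels[idx], self.phases[idx],
            self.channel_names, self.window_len, self.stride,
            self.modality_of, self.label_source,
        )

    def select_channels(self, names: list[str]) -> "WindowDataset":
        """Restrict to the named channels, preserving the requested order."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in dataset: {missing}")
        pos = [self.channel_names.index(n) for n in names]
        return WindowDataset(
            self.windows[:, pos, :], self.labels, self.phases,
            list(names), self.window_len, self.stride,
            {n: self.modality_of[n] for n in names if n in self.modality_of},
            self.label_source,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def derive_phase_labels(
    pressure: np.ndarray,
    smooth_window: int = 15,
    min_peak_distance: int = 50,
    min_prominence: float | None = None,
) -> PhaseSeries:
    """Turn a foot-pressure pulse train into a 0-100% phase ramp.

    The pressure series is smoothed with a centered moving average, local
    maxima separated by at least `min_peak_distance` samples and exceeding
    `min_prominence` are marked as stride boundaries, and the phase is
    linearly interpolated 0 -> 100 between consecutive boundaries.

    Parameters
    ----------
    min_prominence : float, optional
        Defaults to 10% of the smoothed signal's range.

    Raises
    ------
    ValueError
        If the input is non-finite, too short, or fewer than two stride
        boundaries are found ("insufficient strides").
    """
    pressure = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(pressure)):
        raise ValueError("pressure series contains non-finite values")
    if len(pressure) <= smooth_window:
        raise ValueError("pressure series must be longer than the smoothing window")
    if min_peak_distance < 1:
        raise ValueError("min_peak_distance must be >= 1")

    smoothed = moving_average(pressure, smooth_window)
    if min_prominence is None:
        min_prominence = 0.1 * float(np.ptp(smoothed))
    peaks, _ = signal.find_peaks(
        smoothed, distance=min_peak_distance, prominence=min_prominence or None
    )
    if len(peaks) < 2:
        raise ValueError(
            f"insufficient strides: found {len(peaks)} pressure peak(s), need >= 2"
        )

    phase = np.zeros(len(pressure))
    valid = np.zeros(len(pressure), dtype=bool)
    for a, b in zip(peaks[:-1], peaks[1:]):
        t = np.arange(a, b)
        phase[t] = 100.0 * (t - a) / (b - a)
        valid[t] = True
    phase[peaks[-1]] = 0.0  # start of the last (open) stride
    valid[peaks[-1]] = True
    return PhaseSeries(phase=phase, valid_mask=valid)


def phase_to_cartesian(phase) -> PhaseLabel | np.ndarray:
    """Encode phase (percent) as (sin, cos) of the phase angle.

    Values outside [0, 100] are reduced modulo 100.  Accepts scalars
    (returning a :class:`PhaseLabel`) or arrays (returning an (n, 2) array).
    """
    p = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("phase must be finite")
    theta = 2.0 * np.pi * (p % 100.0) / 100.0
    out = np.stack([np.sin(theta), np.cos(theta)], axis=-1)
    if out.ndim == 1:
        return PhaseLabel(float(out[0]), float(out[1]))
    return out


def cartesian_to_phase(y) -> float | np.ndarray:
    """Decode a (sin, cos) pair back to phase in [0, 100).

    theta = atan2(y0, y1); negative angles are wrapped by +2*pi.  Predictions
    need not be unit-norm; only the angle matters.  The zero vector has no
    defined phase and is rejected.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 1
    y = np.atleast_2d(y)
    if y.shape[-1] != 2:
        raise ValueError("expected (sin, cos) pairs")
    if np.any((y[..., 0] == 0) & (y[..., 1] == 0)):
        raise ValueError("undefined phase: zero (sin, cos) vector")
    theta = np.arctan2(y[..., 0], y[..., 1])
    theta = np.where(theta < 0, theta + 2.0 * np.pi, theta)
    phase = theta * 100.0 / (2.0 * np.pi)
    phase = np.where(phase >= 100.0, phase - 100.0, phase)
    return float(phase[0]) if scalar else phase


def circular_phase_distance(a, b) -> np.ndarray:
    """Shortest distance between phases on the 0-100 circle (<= 50)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 100.0
    return np.minimum(d, 100.0 - d)


def downsample_channel(series: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    """Anti-aliased decimation from `in_rate` to `out_rate` Hz.

    `in_rate` must be an integer multiple of `out_rate` (e.g. 2000 Hz sEMG
    to the common 100 Hz grid).  A zero-phase FIR low-pass is applied before
    keeping every factor-th sample; output length is floor(len / factor).
    """
    series = np.asarray(series, dtype=float)
    factor = in_rate / out_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"in_rate must be an integer multiple of out_rate (got factor {factor})"
        )
    factor = int(round(factor))
    if factor == 1:
        return series.copy()
    # zero-phase Butterworth low-pass at 80% of the output Nyquist: unit DC
    # gain (constants pass exactly), then keep every factor-th sample
    sos = signal.butter(8, 0.8 / factor, output="sos")
    filtered = signal.sosfiltfilt(sos, series)
    return filtered[::factor][: len(series) // factor]


def emg_envelope(series: np.ndarray, in_rate: float, out_rate: float,
                 rms_window_s: float = 0.05) -> np.ndarray:
    """RMS-envelope alternative for sEMG: rectify, RMS-smooth, decimate."""
    series = np.asarray(series, dtype=float)
    w = max(1, int(round(rms_window_s * in_rate)))
    sq = moving_average(series**2, w if w % 2 == 1 else w + 1)
    return downsample_channel(np.sqrt(np.maximum(sq, 0.0)), in_rate, out_rate)


def make_windows(
    recording: SensorRecording,
    phase: PhaseSeries,
    window_len: int = 100,
    stride: int = 1,
) -> WindowDataset:
    """Cut M x L sliding windows ending at every validly labelled time step.

    Window k covers samples [t-L+1, t] for end points t on the stride grid
    {L-1, L-1+stride, ...}; the label encodes the phase at the *last* sample
    (causal alignment).  Windows whose final step is unlabelled are dropped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    T = recording.n_samples
    if T < window_len:
        raise ValueError(f"series too short: {T} samples < window length {window_len}")
    if len(phase.phase) != T:
        raise ValueError("phase series length differs from recording")

    mat = recording.as_matrix()
    ends = np.arange(window_len - 1, T, stride)
    ends = ends[phase.valid_mask[ends]]
    windows = np.stack([mat[:, t - window_len + 1: t + 1] for t in ends]) \
        if len(ends) else np.empty((0, mat.shape[0], window_len))
    phases = phase.phase[ends]
    labels = phase_to_cartesian(phases) if len(ends) else np.empty((0, 2))
    return WindowDataset(
        windows=windows, labels=np.atleast_2d(labels), phases=phases,
        channel_names=recording.channel_names, window_len=window_len,
        stride=stride, modality_of=dict(recording.modality_of),
    )


def assign_phase_bin(phase: float) -> GaitPhaseBin:
    """Map a phase in [0, 100] to its gait-phase bin.

    Bin edges follow the printed integer boundaries applied to continuous
    values: [0, 30] pre-stance, (30, 60] post-stance, (60, 80] pre-swing,
    (80, 100] post-swing.
    """
    if not np.isfinite(phase) or phase < 0 or phase > 100:
        raise ValueError(f"phase {phase} outside [0, 100]")
    for b in PHASE_BINS:
        if (phase >= b.lo if b.lo == 0 else phase > b.lo) and phase <= b.hi:
            return b
    raise AssertionError("unreachable: bins partition [0, 100]")


def assign_phase_bins(phases: np.ndarray) -> np.ndarray:
    """Vectorized bin index (0..3) for an array of phases in [0, 100]."""
    p = np.asarray(phases, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 100):
        raise ValueError("phases outside [0, 100]")
    edges = np.array([b.hi for b in PHASE_BINS[:-1]])
    return np.searchsorted(edges, p, side="left")
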