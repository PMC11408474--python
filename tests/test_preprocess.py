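"""Label pipeline, circular encoding, windowing and phase-bin tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitphase.preprocess import (
    PHASE_BINS,
    PhaseSeries,
    SensorRecording,
    assign_phase_bin,
    assign_phase_bins,
    cartesian_to_phase,
    circular_phase_distance,
    derive_phase_labels,
    downsample_channel,
    make_windows,
    moving_average,
    phase_to_cartesian,
)


class TestCircularEncoding:
    @pytest.mark.parametrize("phase,expected", [
        (0.0, (0.0, 1.0)),
        (25.0, (1.0, 0.0)),
        (50.0, (0.0, -1.0)),
        (75.0, (-1.0, 0.0)),
        (125.0, (1.0, 0.0)),  # reduced modulo 100
    ])
    def test_encode_examples(self, phase, expected):
        y = phase_to_cartesian(phase)
        assert y.y0 == pytest.approx(expected[0], abs=1e-12)
        assert y.y1 == pytest.approx(expected[1], abs=1e-12)
        assert y.y0**2 + y.y1**2 == pytest.approx(1.0)

    @pytest.mark.parametrize("y,expected", [
        ((0.0, 1.0), 0.0),
        ((1.0, 0.0), 25.0),
        ((-1.0, 0.0), 75.0),  # exercises the negative-angle wrap branch
        ((0.0, -0.5), 50.0),  # magnitude does not matter
    ])
    def test_decode_examples(self, y, expected):
        assert cartesian_to_phase(np.array(y)) == pytest.approx(expected)

    def test_decode_rejects_zero_vector(self):
        with pytest.raises(ValueError, match="undefined phase"):
            cartesian_to_phase(np.array([0.0, 0.0]))

    def test_encode_rejects_non_finite(self):
        with pytest.raises(ValueError):
            phase_to_cartesian(np.nan)

    def test_integer_grid_round_trip_is_identity(self):
        p = np.arange(100, dtype=float)
        back = cartesian_to_phase(phase_to_cartesian(p))
        assert np.allclose(circular_phase_distance(back, p), 0.0, atol=1e-9)

    def test_decoded_phase_always_in_range(self, rng):
        y = rng.standard_normal((1000, 2))
        y = y[np.abs(y).sum(axis=1) > 0]
        p = cartesian_to_phase(y)
        assert np.all((p >= 0) & (p < 100))


class TestDerivePhaseLabels:
    def test_moving_average_shrinks_at_edges(self):
        # hand-computed centered mean of [0,0,3,0,0] with window 3
        out = moving_average(np.array([0.0, 0, 3, 0, 0]), 3)
        assert np.allclose(out, [0.0, 1.0, 1.0, 1.0, 0.0])

    def test_linear_ramp_between_peaks(self):
        # peaks 10 samples apart -> midpoint phase is 50
        t = np.arange(200)
        pressure = np.cos(2 * np.pi * t / 10.0)
        ps = derive_phase_labels(pressure, smooth_window=3,
                                 min_peak_distance=5, min_prominence=0.1)
        peaks = np.flatnonzero((ps.phase == 0.0) & ps.valid_mask)
        assert len(peaks) >= 2
        mid = peaks[0] + 5
        assert ps.phase[mid] == pytest.approx(50.0)
        assert ps.phase[peaks[0] + 1] == pytest.approx(10.0)

    def test_samples_outside_first_last_peak_invalid(self):
        t = np.arange(95)
        pressure = np.cos(2 * np.pi * (t - 2) / 30.0)
        ps = derive_phase_labels(pressure, smooth_window=3,
                                 min_peak_distance=10, min_prominence=0.1)
        first = np.flatnonzero(ps.valid_mask)[0]
        assert not ps.valid_mask[:first].any()
        last = np.flatnonzero(ps.valid_mask)[-1]
        assert not ps.valid_mask[last + 1:].any()
        assert ps.phase[last] == pytest.approx(0.0)  # the final marked peak

    def test_constant_pressure_is_insufficient_strides(self):
        with pytest.raises(ValueError, match="insufficient strides"):
            derive_phase_labels(np.ones(500))

    def test_non_finite_pressure_rejected(self):
        x = np.ones(500)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            derive_phase_labels(x)

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            derive_phase_labels(np.ones(10), smooth_window=15)


class TestDownsample:
    def test_factor_20_length(self, rng):
        out = downsample_channel(rng.standard_normal(2000), 2000, 100)
        assert len(out) == 100

    def test_constant_preserved(self):
        out = downsample_channel(np.full(1000, 3.7), 1000, 100)
        assert np.allclose(out, 3.7)

    def test_low_frequency_sinusoid_preserved(self):
        # 5 Hz tone sampled at 2000 Hz, kept well below the 50 Hz Nyquist
        t = np.arange(4000) / 2000.0
        x = np.sin(2 * np.pi * 5.0 * t)
        out = downsample_channel(x, 2000, 100)
        expect = np.sin(2 * np.pi * 5.0 * np.arange(len(out)) / 100.0)
        # ignore filter edge transients
        core = slice(10, -10)
        assert np.max(np.abs(out[core] - expect[core])) < 0.01

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            downsample_channel(np.ones(100), 150, 100)


def _recording(T, n_channels=2):
    return SensorRecording(
        channels={f"c{i}": np.arange(T, dtype=float) for i in range(n_channels)},
        rate_hz=100.0)


class TestMakeWindows:
    def test_window_count_all_valid(self):
        ps = PhaseSeries(np.linspace(0, 99, 120) % 100, np.ones(120, bool))
        ds = make_windows(_recording(120), ps, window_len=100, stride=1)
        assert len(ds) == 21

    def test_single_window_covers_full_series(self):
        ps = PhaseSeries(np.zeros(100), np.ones(100, bool))
        ds = make_windows(_recording(100), ps, window_len=100, stride=1)
        assert len(ds) == 1
        assert np.allclose(ds.windows[0, 0], np.arange(100))

    def test_invalid_tail_labels_drop_windows(self):
        valid = np.ones(120, bool)
        valid[-5:] = False
        ps = PhaseSeries(np.zeros(120), valid)
        ds = make_windows(_recording(120), ps, window_len=100, stride=1)
        assert len(ds) == 16

    def test_label_encodes_final_sample_phase(self):
        phase = np.linspace(0, 99, 120) % 100
        ps = PhaseSeries(phase, np.ones(120, bool))
        ds = make_windows(_recording(120), ps, window_len=100, stride=1)
        assert np.allclose(ds.phases, phase[99:])
        assert np.allclose(ds.labels[:, 0],
                           np.sin(2 * np.pi * phase[99:] / 100))

    def test_too_short_series_rejected(self):
        ps = PhaseSeries(np.zeros(50), np.ones(50, bool))
        with pytest.raises(ValueError, match="too short"):
            make_windows(_recording(50), ps, window_len=100)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(T=st.integers(10, 300), L=st.integers(2, 120),
           stride=st.integers(1, 7))
    def test_window_count_formula(self, T, L, stride):
        if T < L:
            return
        ps = PhaseSeries(np.zeros(T), np.ones(T, bool))
        ds = make_windows(_recording(T, 1), ps, window_len=L, stride=stride)
        assert len(ds) == (T - L) // stride + 1


class TestPhaseBins:
    @pytest.mark.parametrize("phase,name", [
        (15, "pre-stance"), (0, "pre-stance"), (30, "pre-stance"),
        (30.5, "post-stance"), (45, "post-stance"), (60, "post-stance"),
        (61, "pre-swing"), (80, "pre-swing"),
        (81, "post-swing"), (100, "post-swing"),
    ])
    def test_bin_examples(self, phase, name):
        assert assign_phase_bin(phase).name == name

    def test_bins_partition_unit_interval(self):
        grid = np.linspace(0, 100, 5001)
        idx = assign_phase_bins(grid)
        names = [PHASE_BINS[i].name for i in idx]
        for p, n in zip(grid, names):
            assert assign_phase_bin(p).name == n  # scalar agrees w/ vector

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1, np.nan):
            with pytest.raises(ValueError):
                assign_phase_bin(bad)


def test_recording_validates_lengths():
    with pytest.raises(ValueError, match="lengths differ"):
        SensorRecording(channels={"a": np.ones(5), "b": np.ones(4)},
                        rate_hz=100.0)
    with pytest.raises(ValueError, match="positive"):
        SensorRecording(channels={"a": np.ones(5)}, rate_hz=0.0)
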