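"""Channel-weight reports, attention-scope maps, and channel selection."""

import numpy as np
import pytest

from gaitphase import (
    ChannelWeightReport,
    IP3TRegressor,
    attention_scope,
    build_fused_source_specs,
    channel_weights,
    select_top_channels,
)
from gaitphase.preprocess import WindowDataset, phase_to_cartesian


def _fitted_model(dataset, **kw):
    base = dict(embed_dim=16, n_heads=2, n_layers=2, patch_len=10,
                dropout=0.0, learning_rate=1e-3, batch_size=64, epochs=1,
                seed=0)
    base.update(kw)
    est = IP3TRegressor(**base)
    est.fit(dataset.windows, dataset.phases)
    return est


def _dataset(n=40, M=3, L=100, seed=0, names=None, modality=None):
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 100, n)
    names = names or [f"c{i}" for i in range(M)]
    return WindowDataset(
        windows=rng.standard_normal((n, M, L)),
        labels=np.atleast_2d(phase_to_cartesian(phases)),
        phases=phases, channel_names=names, window_len=L, stride=1,
        modality_of=modality or {})


class TestChannelWeights:
    def test_single_channel_weight_one(self):
        ds = _dataset(M=1)
        est = _fitted_model(ds)
        rep = channel_weights(est, ds)
        assert np.allclose(rep.mean_weights, [1.0])

    def test_weights_stochastic(self):
        ds = _dataset(M=4)
        rep = channel_weights(_fitted_model(ds), ds)
        assert rep.mean_weights.sum() == pytest.approx(1.0, abs=1e-3)
        assert np.all(rep.mean_weights >= 0)
        assert rep.n_windows == len(ds)

    def test_identical_channel_tokens_give_uniform_weights(self):
        """If all channels carry identical content and share one token,
        symmetry forces uniform weights."""
        rng = np.random.default_rng(3)
        base = rng.standard_normal((30, 1, 100))
        ds = _dataset(n=30, M=3)
        ds.windows = np.repeat(base, 3, axis=1)
        est = _fitted_model(ds, per_channel_tokens=False)
        rep = channel_weights(est, ds)
        assert np.allclose(rep.mean_weights, 1.0 / 3.0, atol=1e-9)

    def test_report_average_equals_mean_of_per_window_weights(self):
        ds = _dataset(M=3, n=2)
        est = _fitted_model(ds)
        rep = channel_weights(est, ds)
        per_window = est.forward_trace(ds.windows).cross_attention.mean(axis=1)
        assert np.allclose(rep.mean_weights, per_window.mean(axis=0),
                           atol=1e-12)

    def test_empty_dataset_rejected(self):
        ds = _dataset(M=2)
        est = _fitted_model(ds)
        with pytest.raises(ValueError):
            channel_weights(est, ds.subset(np.array([], dtype=int)))


class TestAttentionScope:
    def test_default_scope_last_layers_heads(self):
        ds = _dataset(M=2)
        est = _fitted_model(ds, n_layers=4, n_heads=8, embed_dim=16)
        scope = attention_scope(est, ds.windows[0])
        assert scope.layers_used == (1, 2, 3)
        assert scope.heads_used == (2, 3, 4, 5, 6, 7)
        assert scope.maps.shape == (2, 11, 11)
        assert np.allclose(scope.maps.sum(-1), 1.0, atol=1e-4)

    def test_single_layer_head_equals_raw_attention(self):
        ds = _dataset(M=2)
        est = _fitted_model(ds)
        scope = attention_scope(est, ds.windows[0], layers=(1,), heads=(0,))
        trace = est.forward_trace(ds.windows[:1], capture_attention=True)
        raw = trace.encoder_attention[0][:, 1, 0]
        assert np.allclose(scope.maps, raw, atol=1e-12)

    def test_union_average_is_elementwise_mean(self):
        ds = _dataset(M=2)
        est = _fitted_model(ds)
        a = attention_scope(est, ds.windows[0], layers=(0,), heads=(0, 1)).maps
        b = attention_scope(est, ds.windows[0], layers=(1,), heads=(0, 1)).maps
        ab = attention_scope(est, ds.windows[0], layers=(0, 1),
                             heads=(0, 1)).maps
        assert np.allclose(ab, (a + b) / 2.0, atol=1e-12)

    def test_out_of_range_indices_rejected(self):
        ds = _dataset(M=2)
        est = _fitted_model(ds)
        with pytest.raises(IndexError):
            attention_scope(est, ds.windows[0], layers=(5,))


def _report(weights: dict, modality: dict) -> ChannelWeightReport:
    names = list(weights)
    return ChannelWeightReport(
        channel_names=names,
        mean_weights=np.array([weights[c] for c in names]),
        std_weights=np.zeros(len(names)), n_windows=10,
        modality_of=modality)


class TestSelection:
    def test_top_k_simple(self):
        rep = _report({"a": 0.5, "b": 0.3, "c": 0.2},
                      {c: "IMU" for c in "abc"})
        sel = select_top_channels(rep, {"IMU": 2})
        assert sel.selected == ["a", "b"]

    def test_ties_break_lexicographically(self):
        rep = _report({"z": 0.25, "a": 0.25, "m": 0.25, "b": 0.25},
                      {c: "EMG" for c in "zamb"})
        sel = select_top_channels(rep, {"EMG": 2})
        assert sel.selected == ["a", "b"]
        # idempotent / order-invariant
        assert select_top_channels(rep, {"EMG": 2}).selected == ["a", "b"]

    def test_overdraw_names_modality(self):
        rep = _report({"a": 1.0}, {"a": "IMU"})
        with pytest.raises(ValueError, match="IMU"):
            select_top_channels(rep, {"IMU": 2})

    def test_permutation_invariance(self, rng):
        weights = {f"c{i}": w for i, w in enumerate(
            rng.dirichlet(np.ones(6)))}
        modality = {c: "IMU" for c in weights}
        rep1 = _report(weights, modality)
        shuffled = dict(reversed(list(weights.items())))
        rep2 = _report(shuffled, modality)
        assert (select_top_channels(rep1, {"IMU": 3}).selected ==
                select_top_channels(rep2, {"IMU": 3}).selected)


class TestFusedSources:
    def _full_report(self, seed=0):
        rng = np.random.default_rng(seed)
        names = ([f"imu_{i:02d}" for i in range(16)]
                 + [f"emg_{i:02d}" for i in range(16)]
                 + ["stretch_l", "stretch_r"])
        modality = {}
        for n in names:
            modality[n] = ("IMU" if n.startswith("imu")
                           else "EMG" if n.startswith("emg") else "STRETCH")
        w = rng.dirichlet(np.ones(34))
        return _report(dict(zip(names, w)), modality)

    def test_four_sources_of_sixteen(self):
        sources = build_fused_source_specs(self._full_report())
        assert len(sources) == 4
        assert all(len(s.selected) == 16 for s in sources)
        by_name = {s.source_spec: s for s in sources}
        assert by_name["IMU+EMG"].k_per_modality == {"IMU": 8, "EMG": 8}
        assert by_name["IMU+Stretch+EMG"].k_per_modality == \
            {"STRETCH": 2, "IMU": 7, "EMG": 7}

    def test_stretch_channels_always_included(self):
        sources = build_fused_source_specs(self._full_report())
        for s in sources:
            if "Stretch" in s.source_spec:
                assert {"stretch_l", "stretch_r"} <= set(s.selected)

    def test_selections_subset_of_report(self):
        rep = self._full_report(seed=5)
        for s in build_fused_source_specs(rep):
            assert set(s.selected) <= set(rep.channel_names)

    def test_missing_modality_rejected(self):
        rep = _report({"a": 1.0}, {"a": "IMU"})
        with pytest.raises(ValueError, match="channels"):
            build_fused_source_specs(rep)
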