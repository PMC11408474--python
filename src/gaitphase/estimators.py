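"""Scikit-learn-style estimators for continuous gait-phase regression.

:class:`IP3TRegressor` wraps the patch-transformer network and
:class:`GaitBaselineRegressor` the classical families behind the common
``fit(X, y)`` / ``predict(X)`` surface, where ``X`` is an
``(n_windows, n_channels, window_len)`` array of sensor windows and ``y``
the phase in percent at each window's last sample.  Internally the target
is regressed in Cartesian (sin, cos) form with an MSE loss and decoded
with atan2, so the estimators compose with sklearn model selection on the
decoded-phase scale.

Both estimators z-score each channel with training-partition statistics,
optimize with Adam, and are deterministic for a fixed ``seed``.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import transformer as tr
from .autodiff import Adam, Tensor
from .baselines import BaselineSpec, build_baseline
from .preprocess import WindowDataset, cartesian_to_phase, phase_to_cartesian


def _validate_windows(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError(
            "X must have shape (n_windows, n_channels, window_len); "
            f"got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _encode_targets(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:  # phase in percent
        return np.atleast_2d(phase_to_cartesian(y)), y
    if y.ndim == 2 and y.shape[1] == 2:  # already (sin, cos)
        return y, np.asarray(cartesian_to_phase(y))
    raise ValueError("y must be phases (n,) or Cartesian labels (n, 2)")


class _PhaseRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing; subclasses build the network."""

    def _build(self, n_channels: int, window_len: int):  # -> (model, params)
        raise NotImplementedError

    def _forward(self, X_norm: np.ndarray, training: bool,
                 rng: np.random.Generator | None):
        raise NotImplementedError

    def fit(self, X, y):
        X = _validate_windows(X)
        Y, phases = _encode_targets(y)
        if len(Y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        n, M, L = X.shape
        self.norm_mean_ = X.mean(axis=(0, 2), keepdims=True)
        self.norm_std_ = X.std(axis=(0, 2), keepdims=True)
        self.norm_std_[self.norm_std_ < 1e-12] = 1.0
        Xn = (X - self.norm_mean_) / self.norm_std_

        self._build_model(M, L)
        rng = np.random.default_rng(self.seed)
        opt = Adam(self._parameters(), lr=self.learning_rate)
        bs = min(self.batch_size, n)
        losses = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = Tensor(Xn[idx]), Tensor(Y[idx])
                pred = self._forward(xb, training=True, rng=rng)
                loss = ((pred - yb) ** 2).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged: non-finite loss at epoch "
                        f"{len(losses)}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
        self.loss_trace_ = np.asarray(losses)
        self.n_features_in_ = M * L
        self.n_channels_ = M
        self.window_len_ = L
        return self

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_mean_) / self.norm_std_

    def predict_cartesian(self, X, batch_size: int = 256) -> np.ndarray:
        """Raw (sin, cos) predictions (not necessarily unit-norm)."""
        check_is_fitted(self, "loss_trace_")
        X = _validate_windows(X)
        Xn = self._normalize(X)
        out = [
            self._forward(Tensor(Xn[i:i + batch_size]), training=False,
                          rng=None).data
            for i in range(0, len(Xn), batch_size)
        ]
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, X) -> np.ndarray:
        """Predicted gait phase in [0, 100) percent."""
        yc = self.predict_cartesian(X)
        return np.asarray(cartesian_to_phase(yc))

    def score(self, X, y):
        """R² on the decoded phase scale (plain differences)."""
        from .metrics import r2

        _, phases = _encode_targets(y)
        return r2(phases, self.predict(X))


class IP3TRegressor(_PhaseRegressorBase):
    """Interpretable patch-transformer gait-phase regressor.

    Parameters mirror the full-size architecture (embed_dim 768, 12 heads,
    6 layers, patch length 10) and training protocol (Adam, batch 32,
    learning rate 4e-6, 200 epochs); reduce them for desk-scale work.

    Attributes
    ----------
    params_ : ModelParams
        Learned weights.
    config_ : ModelConfig
        Resolved architecture.
    loss_trace_ : ndarray
        Mean training loss per epoch.
    """

    def __init__(self, patch_len: int = 10, embed_dim: int = 768,
                 n_heads: int = 12, n_layers: int = 6,
                 ffn_dim: int | None = None,
                 head_hidden_dims: tuple[int, ...] | None = None,
                 dropout: float = 0.1, share_patch_projection: bool = True,
                 per_channel_tokens: bool = True, scale_by_full_d: bool = False,
                 learning_rate: float = 4e-6, batch_size: int = 32,
                 epochs: int = 200, seed: int = 0):
        self.patch_len = patch_len
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.ffn_dim = ffn_dim
        self.head_hidden_dims = head_hidden_dims
        self.dropout = dropout
        self.share_patch_projection = share_patch_projection
        self.per_channel_tokens = per_channel_tokens
        self.scale_by_full_d = scale_by_full_d
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _build_model(self, M: int, L: int) -> None:
        self.config_ = tr.ModelConfig(
            n_channels=M, window_len=L, patch_len=self.patch_len,
            embed_dim=self.embed_dim, n_heads=self.n_heads,
            n_layers=self.n_layers, ffn_dim=self.ffn_dim,
            head_hidden_dims=self.head_hidden_dims, dropout=self.dropout,
            share_patch_projection=self.share_patch_projection,
            per_channel_tokens=self.per_channel_tokens,
            scale_by_full_d=self.scale_by_full_d)
        self.params_ = tr.init_params(self.config_, seed=self.seed)

    def _parameters(self):
        return self.params_.parameters()

    def _forward(self, xb: Tensor, training: bool, rng):
        y, _ = tr.forward_batch(xb, self.params_, training=training, rng=rng)
        return y

    def forward_trace(self, X, capture_attention: bool = False,
                      batch_size: int = 256) -> tr.ForwardTrace:
        """Evaluation-mode forward pass retaining attention artifacts."""
        check_is_fitted(self, "loss_trace_")
        X = _validate_windows(X)
        Xn = self._normalize(X)
        traces = [
            tr.forward_batch(Tensor(Xn[i:i + batch_size]), self.params_,
                             capture_attention=capture_attention)[1]
            for i in range(0, len(Xn), batch_size)
        ]
        return tr.ForwardTrace(
            y_pred=np.concatenate([t.y_pred for t in traces]),
            channel_tokens=np.concatenate([t.channel_tokens for t in traces]),
            cross_attention=np.concatenate([t.cross_attention for t in traces]),
            encoder_attention=(
                np.concatenate([t.encoder_attention for t in traces])
                if capture_attention else None),
        )


class GaitBaselineRegressor(_PhaseRegressorBase):
    """CNN / LSTM / GRU / CNN+LSTM / CNN+GRU baseline regressor."""

    def __init__(self, family: str = "CNN", hidden_dim: int = 128,
                 n_recurrent_blocks: int = 4, n_cnn_blocks: int = 3,
                 cnn_channels: int = 32, learning_rate: float = 4e-6,
                 batch_size: int = 32, epochs: int = 200, seed: int = 0):
        self.family = family
        self.hidden_dim = hidden_dim
        self.n_recurrent_blocks = n_recurrent_blocks
        self.n_cnn_blocks = n_cnn_blocks
        self.cnn_channels = cnn_channels
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _build_model(self, M: int, L: int) -> None:
        self.spec_ = BaselineSpec(
            family=self.family, hidden_dim=self.hidden_dim,
            n_recurrent_blocks=self.n_recurrent_blocks,
            n_cnn_blocks=self.n_cnn_blocks, cnn_channels=self.cnn_channels)
        self.model_ = build_baseline(self.spec_, M, L, seed=self.seed)

    def _parameters(self):
        return self.model_.parameters()

    def _forward(self, xb: Tensor, training: bool, rng):
        return self.model_.forward_batch(xb, training=training, rng=rng)


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def chronological_split(
    dataset: WindowDataset, train_fraction: float = 0.7,
    gap: int | None = None,
) -> tuple[WindowDataset, WindowDataset]:
    """Split stride-ordered windows chronologically with an exclusion gap.

    With stride-1 windows a random split leaks near-duplicate windows
    across partitions; the chronological split instead drops
    ceil((L-1)/stride) windows after the boundary so no evaluation window
    overlaps a training window in time.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    if gap is None:
        gap = math.ceil((dataset.window_len - 1) / dataset.stride)
    n_train = int(math.floor(train_fraction * n))
    n_test_start = n_train + gap
    if n_train < 1 or n_test_start >= n:
        raise ValueError(
            f"split leaves an empty partition (n={n}, train={n_train}, gap={gap})")
    return (dataset.subset(np.arange(n_train)),
            dataset.subset(np.arange(n_test_start, n)))


def random_split(
    dataset: WindowDataset, train_fraction: float = 0.7, seed: int = 0,
) -> tuple[WindowDataset, WindowDataset]:
    """Plain random 7:3-style split (windows may overlap across partitions)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(math.floor(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("split leaves an empty partition")
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])
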