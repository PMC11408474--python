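"""Training protocol and per-phase evaluation over WindowDatasets.

Thin wrappers around the estimator classes: :func:`train` applies a
:class:`TrainConfig` to an (unfitted) estimator and a windowed dataset,
and :func:`evaluate_per_phase` produces the four-bin stratified
RMSE / R² table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

from .estimators import (
    _PhaseRegressorBase,
    chronological_split,
    random_split,
)
from .metrics import PhaseMetricsTable, per_phase_metrics
from .preprocess import WindowDataset


@dataclass
class TrainConfig:
    """Training protocol: Adam, batch 32, learning rate 4e-6, 200 epochs,
    7:3 chronological split by default."""

    batch_size: int = 32
    learning_rate: float = 4e-6
    epochs: int = 200
    split_fraction: float = 0.7
    split_mode: str = "chronological"  # or "random"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if min(self.batch_size, self.epochs) < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.split_mode not in ("chronological", "random"):
            raise ValueError("split_mode must be 'chronological' or 'random'")


def split_dataset(dataset: WindowDataset, cfg: TrainConfig):
    if cfg.split_mode == "chronological":
        return chronological_split(dataset, cfg.split_fraction)
    return random_split(dataset, cfg.split_fraction, seed=cfg.seed)


def train(
    estimator: _PhaseRegressorBase,
    dataset: WindowDataset,
    cfg: TrainConfig | None = None,
) -> tuple[_PhaseRegressorBase, np.ndarray, WindowDataset]:
    """Split, fit, and return (fitted estimator, loss trace, eval split).

    The estimator is cloned with the config's optimization settings, so the
    input instance is left untouched.  Deterministic for fixed seeds.
    """
    cfg = cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    train_ds, eval_ds = split_dataset(dataset, cfg)
    est = clone(estimator)
    est.set_params(batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                   epochs=cfg.epochs, seed=cfg.seed)
    est.fit(train_ds.windows, train_ds.phases)
    return est, est.loss_trace_, eval_ds


def evaluate_per_phase(
    estimator: _PhaseRegressorBase, dataset: WindowDataset,
) -> PhaseMetricsTable:
    """Decode predictions to phase and stratify errors by the true bin."""
    if len(dataset) == 0:
        raise ValueError("evaluation dataset is empty")
    pred = estimator.predict(dataset.windows)
    return per_phase_metrics(dataset.phases, pred)
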