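"""Loss and evaluation metrics, and the four-phase stratified report.

RMSE and the coefficient of determination R² are computed on *decoded*
phase values (percent of gait cycle) with plain, non-circular differences.
Near the cycle boundary a prediction of 99.5 against a truth of 0.2 counts
as an error of ~99, not ~0.7 — this deliberately mirrors the boundary
effect visible in per-phase reports on real gait data, where the edge bins
(pre-stance and post-swing) carry large RMSE and even negative R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PHASE_BINS, assign_phase_bins


def mse_loss(y_pred: np.ndarray, y_label: np.ndarray) -> float:
    """Mean squared error over the batch and both (sin, cos) components."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_label = np.asarray(y_label, dtype=float)
    if y_pred.shape != y_label.shape:
        raise ValueError(f"shape mismatch: {y_pred.shape} vs {y_label.shape}")
    return float(np.mean((y_pred - y_label) ** 2))


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error: sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("inputs must be equal-length non-empty series")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("inputs must be equal-length non-empty series")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("undefined R²: target series is constant")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


@dataclass
class PhaseMetricsTable:
    """RMSE / R² stratified by the four gait-phase bins plus overall.

    Bins with fewer than two samples report NaN metrics rather than a
    fabricated value.  `n` per bin sums to the evaluation-set size.
    """

    per_bin: dict[str, dict[str, float]]  # bin name -> {rmse, r2, n}
    overall_rmse: float
    overall_r2: float
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin": name, "rmse": v["rmse"], "r2": v["r2"], "n": int(v["n"])}
            for name, v in self.per_bin.items()
        ]
        rows.append({"bin": "overall", "rmse": self.overall_rmse,
                     "r2": self.overall_r2, "n": self.n_total})
        return pd.DataFrame(rows)


def per_phase_metrics(true_phase: np.ndarray, pred_phase: np.ndarray) -> PhaseMetricsTable:
    """Stratify prediction errors by the TRUE phase's gait-phase bin."""
    true_phase = np.asarray(true_phase, dtype=float)
    pred_phase = np.asarray(pred_phase, dtype=float)
    if true_phase.shape != pred_phase.shape or true_phase.size == 0:
        raise ValueError("need equal-length non-empty phase series")
    bins = assign_phase_bins(true_phase)
    per_bin: dict[str, dict[str, float]] = {}
    for k, b in enumerate(PHASE_BINS):
        mask = bins == k
        n = int(mask.sum())
        if n < 2:
            per_bin[b.name] = {"rmse": float("nan"), "r2": float("nan"), "n": n}
            continue
        yt, yp = true_phase[mask], pred_phase[mask]
        try:
            r2_val = r2(yt, yp)
        except ValueError:
            r2_val = float("nan")
        per_bin[b.name] = {"rmse": rmse(yt, yp), "r2": r2_val, "n": n}
    return PhaseMetricsTable(
        per_bin=per_bin,
        overall_rmse=rmse(true_phase, pred_phase),
        overall_r2=r2(true_phase, pred_phase),
        n_total=int(true_phase.size),
    )
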