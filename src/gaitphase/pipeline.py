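"""End-to-end pipeline: simulate/label -> window -> train -> evaluate ->
explain -> select-channels, driven by one run configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as gio
from .estimators import IP3TRegressor
from .interpret import build_fused_source_specs, channel_weights
from .preprocess import derive_phase_labels, make_windows
from .synthetic import ChannelSpec, SyntheticSpec, generate_recording
from .training import TrainConfig, evaluate_per_phase, train

log = logging.getLogger("gaitphase")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage-specific seed fanned out from one global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One end-to-end run: synthetic source, model, training protocol."""

    out_dir: str
    seed: int = 0
    input_bundle: str | None = None  # if None, simulate from synthetic_spec
    synthetic_spec: dict = field(default_factory=dict)
    window_len: int = 100
    stride: int = 1
    label_source: str = "derived"  # "derived" (pressure pipeline) or "exact"
    smooth_window: int = 15
    min_peak_distance: int = 50
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    channels: list[str] | None = None  # restrict to these channels
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.input_bundle is not None and not Path(self.input_bundle).exists():
            raise FileNotFoundError(
                f"input bundle does not exist: {self.input_bundle}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)


def synthetic_spec_from_dict(raw: dict, seed: int) -> SyntheticSpec:
    raw = dict(raw)
    channels = [ChannelSpec(**c) for c in raw.pop("channels", [])] or None
    kwargs = {**raw, "seed": raw.get("seed", seed)}
    if channels:
        kwargs["channels"] = channels
    return SyntheticSpec(**kwargs)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns a manifest of produced artifacts.

    Any stage failure aborts with the stage name attached to the error.
    """
    logging.basicConfig(level=cfg.verbosity)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}
    stage = "simulate"
    try:
        if cfg.input_bundle:
            rec, truth = gio.read_bundle(cfg.input_bundle)
        else:
            spec = synthetic_spec_from_dict(
                cfg.synthetic_spec, derive_seed(cfg.seed, "simulate"))
            rec, truth = generate_recording(spec)
            bundle = out / "recording.npz"
            gio.write_bundle(rec, bundle, phase=truth)
            manifest["files"]["recording"] = str(bundle)
        manifest["stages"][stage] = {"n_samples": rec.n_samples,
                                     "n_channels": len(rec.channel_names)}

        stage = "label"
        if cfg.label_source == "exact":
            if truth is None:
                raise ValueError("bundle has no ground-truth phase")
            phase = truth
        else:
            if rec.foot_pressure is None:
                raise ValueError("recording has no foot-pressure channel")
            phase = derive_phase_labels(
                rec.foot_pressure, smooth_window=cfg.smooth_window,
                min_peak_distance=cfg.min_peak_distance)
        manifest["stages"][stage] = {
            "n_valid": int(phase.valid_mask.sum()),
            "source": cfg.label_source}

        stage = "window"
        dataset = make_windows(rec, phase, cfg.window_len, cfg.stride)
        if cfg.channels:
            dataset = dataset.select_channels(cfg.channels)
        ds_path = out / "dataset.npz"
        gio.write_dataset(dataset, ds_path)
        manifest["files"]["dataset"] = str(ds_path)
        manifest["stages"][stage] = {"n_windows": len(dataset)}

        stage = "train"
        train_cfg = TrainConfig(**{"seed": derive_seed(cfg.seed, "train"),
                                   **cfg.train})
        est = IP3TRegressor(**cfg.model)
        fitted, losses, eval_ds = train(est, dataset, train_cfg)
        ckpt = out / "checkpoint.npz"
        gio.save_checkpoint(fitted, ckpt)
        manifest["files"]["checkpoint"] = str(ckpt)
        manifest["stages"][stage] = {
            "epochs": len(losses), "final_loss": float(losses[-1]),
            "seed": train_cfg.seed}

        stage = "evaluate"
        table = evaluate_per_phase(fitted, eval_ds)
        metrics_path = out / "metrics.csv"
        gio.write_metrics_report(table, metrics_path)
        manifest["files"]["metrics"] = str(metrics_path)
        manifest["stages"][stage] = {"overall_rmse": table.overall_rmse,
                                     "n_eval": table.n_total}

        stage = "explain"
        report = channel_weights(fitted, eval_ds)
        weights_path = out / "channel_weights.csv"
        gio.write_weight_report(report, weights_path)
        manifest["files"]["channel_weights"] = str(weights_path)
        manifest["stages"][stage] = {"n_windows": report.n_windows}

        stage = "select-channels"
        modalities = set(report.modality_of.values())
        if {"IMU", "EMG", "STRETCH"} <= modalities:
            try:
                selections = build_fused_source_specs(report)
            except ValueError:
                selections = []
        else:
            selections = []
        sel_path = out / "channel_selection.yaml"
        with open(sel_path, "w") as fh:
            yaml.safe_dump(
                [{"source": s.source_spec, "channels": s.selected}
                 for s in selections], fh)
        manifest["files"]["channel_selection"] = str(sel_path)
        manifest["stages"][stage] = {"n_selections": len(selections)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["files"]["manifest"] = str(manifest_path)
    return manifest
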