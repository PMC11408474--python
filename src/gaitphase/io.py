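"""Readers, writers, checkpoints and run configuration.

Formats
-------
* Delimited text recordings: one header row of unique channel names, one
  column per channel, '.' decimal; sampling rate and per-channel modality
  live in a YAML sidecar config (the rate is required).
* Binary array bundle: a single ``.npz`` archive holding the channel
  matrix, optional foot pressure / ground-truth phase, and a JSON metadata
  entry (channel names, modalities, rate).
* Checkpoints: a single ``.npz`` with every weight array plus the model
  configuration embedded as JSON; loading validates shapes.
* Reports: delimited text, fixed column order, full float precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import transformer as tr
from .estimators import IP3TRegressor
from .interpret import ChannelWeightReport
from .metrics import PhaseMetricsTable
from .preprocess import MODALITIES, PhaseSeries, SensorRecording


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_recording_csv(
    path: str | Path, sidecar: str | Path | dict,
    delimiter: str = ",",
) -> SensorRecording:
    """Read a delimited-text recording plus its sidecar config.

    The sidecar (YAML file or dict) must provide ``rate_hz`` and may
    provide ``modalities`` (channel -> IMU/STRETCH/EMG) and
    ``pressure_col`` naming the foot-pressure column.
    """
    path = Path(path)
    if not isinstance(sidecar, dict):
        with open(sidecar) as fh:
            sidecar = yaml.safe_load(fh) or {}
    if "rate_hz" not in sidecar:
        raise ParseError(f"{path}: sidecar config is missing required 'rate_hz'")

    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(delimiter)]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ParseError(f"{path}:1: duplicate column name(s): {sorted(dupes)}")
    ncol = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) != ncol:
            raise ParseError(
                f"{path}:{lineno}: expected {ncol} fields, found {len(fields)}")
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows)

    pressure_col = sidecar.get("pressure_col")
    modalities = dict(sidecar.get("modalities", {}))
    channels, foot_pressure = {}, None
    for j, name in enumerate(header):
        if name == pressure_col:
            foot_pressure = data[:, j]
        else:
            channels[name] = data[:, j]
    if pressure_col is not None and foot_pressure is None:
        raise ParseError(f"{path}: pressure column {pressure_col!r} not found")
    modality_of = {c: modalities[c] for c in channels if c in modalities}
    return SensorRecording(
        channels=channels, rate_hz=float(sidecar["rate_hz"]),
        modality_of=modality_of, foot_pressure=foot_pressure)


def write_recording_csv(recording: SensorRecording, path: str | Path,
                        pressure_col: str = "foot_pressure") -> None:
    df = pd.DataFrame(recording.channels)
    if recording.foot_pressure is not None:
        df[pressure_col] = recording.foot_pressure
    df.to_csv(path, index=False)


def write_bundle(
    recording: SensorRecording, path: str | Path,
    phase: PhaseSeries | None = None,
) -> None:
    """Write the binary array bundle (npz with embedded JSON metadata)."""
    meta = {
        "channel_names": recording.channel_names,
        "modality_of": recording.modality_of,
        "rate_hz": recording.rate_hz,
    }
    arrays = {
        "data": recording.as_matrix(),
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if recording.foot_pressure is not None:
        arrays["foot_pressure"] = recording.foot_pressure
    if phase is not None:
        arrays["phase"] = phase.phase
        arrays["phase_valid"] = phase.valid_mask
    np.savez(path, **arrays)


def read_bundle(path: str | Path) -> tuple[SensorRecording, PhaseSeries | None]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
        data = npz["data"]
        channels = {name: data[i] for i, name in enumerate(meta["channel_names"])}
        rec = SensorRecording(
            channels=channels, rate_hz=float(meta["rate_hz"]),
            modality_of={k: v for k, v in meta["modality_of"].items()
                         if v in MODALITIES},
            foot_pressure=npz["foot_pressure"] if "foot_pressure" in npz else None)
        phase = None
        if "phase" in npz:
            phase = PhaseSeries(phase=npz["phase"], valid_mask=npz["phase_valid"])
    return rec, phase


def write_dataset(dataset, path: str | Path) -> None:
    """Persist a WindowDataset as an npz archive (phases in percent;
    encoded labels are derived on the fly when reading)."""
    meta = {
        "channel_names": dataset.channel_names,
        "modality_of": dataset.modality_of,
        "window_len": dataset.window_len,
        "stride": dataset.stride,
        "label_source": dataset.label_source,
    }
    np.savez(path, windows=dataset.windows, phases=dataset.phases,
             meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def read_dataset(path: str | Path):
    from .preprocess import WindowDataset, phase_to_cartesian

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
        phases = npz["phases"]
        return WindowDataset(
            windows=npz["windows"],
            labels=np.atleast_2d(phase_to_cartesian(phases)),
            phases=phases,
            channel_names=meta["channel_names"],
            window_len=int(meta["window_len"]),
            stride=int(meta["stride"]),
            modality_of=meta["modality_of"],
            label_source=meta["label_source"],
        )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_metrics_report(table: PhaseMetricsTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_metrics_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_weight_report(report: ChannelWeightReport, path: str | Path) -> None:
    pd.DataFrame({
        "channel": report.channel_names,
        "modality": [report.modality_of.get(c, "") for c in report.channel_names],
        "mean_weight": report.mean_weights,
        "std_weight": report.std_weights,
    }).to_csv(path, index=False, float_format="%.17g")


def read_weight_report(path: str | Path,
                       n_windows: int = 0) -> ChannelWeightReport:
    df = pd.read_csv(path, keep_default_na=False)
    return ChannelWeightReport(
        channel_names=list(df["channel"]),
        mean_weights=df["mean_weight"].to_numpy(),
        std_weights=df["std_weight"].to_numpy(),
        n_windows=n_windows,
        modality_of={c: m for c, m in zip(df["channel"], df["modality"]) if m},
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: IP3TRegressor, path: str | Path) -> None:
    """Single-file archive: weights + config + normalization statistics."""
    cfg = dataclasses.asdict(model.config_)
    est_params = model.get_params()
    arrays: dict[str, np.ndarray] = {
        "config_json": np.frombuffer(
            json.dumps({"model": cfg, "estimator": est_params}).encode(),
            dtype=np.uint8),
        "norm_mean": model.norm_mean_,
        "norm_std": model.norm_std_,
        "loss_trace": model.loss_trace_,
        "patch_proj_w": model.params_.patch_proj_w.data,
        "patch_proj_b": model.params_.patch_proj_b.data,
        "channel_tokens": model.params_.channel_tokens.data,
        "pos_table": model.params_.pos_table.data,
        "global_token": model.params_.global_token.data,
    }
    for j, layer in enumerate(model.params_.layers):
        for k, t in layer.items():
            arrays[f"layer{j}_{k}"] = t.data
    for k, t in model.params_.cross.items():
        arrays[f"cross_{k}"] = t.data
    for j, (w, b) in enumerate(model.params_.head):
        arrays[f"head{j}_w"] = w.data
        arrays[f"head{j}_b"] = b.data
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> IP3TRegressor:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["config_json"].tobytes()).decode())
        est_params = meta["estimator"]
        est_params["head_hidden_dims"] = (
            tuple(est_params["head_hidden_dims"])
            if est_params.get("head_hidden_dims") else None)
        model = IP3TRegressor(**est_params)
        cfg_dict = dict(meta["model"])
        cfg_dict["head_hidden_dims"] = tuple(cfg_dict["head_hidden_dims"])
        # ModelConfig re-derives ffn_dim/head dims in __post_init__
        cfg = tr.ModelConfig(**cfg_dict)
        model.config_ = cfg
        model.params_ = tr.init_params(cfg, seed=est_params.get("seed", 0))

        def put(tensor, key):
            arr = npz[key]
            if tensor.data.shape != arr.shape:
                raise ValueError(
                    f"checkpoint shape mismatch for {key}: "
                    f"{arr.shape} vs expected {tensor.data.shape}")
            tensor.data = arr.astype(np.float64)

        put(model.params_.patch_proj_w, "patch_proj_w")
        put(model.params_.patch_proj_b, "patch_proj_b")
        put(model.params_.channel_tokens, "channel_tokens")
        put(model.params_.pos_table, "pos_table")
        put(model.params_.global_token, "global_token")
        for j, layer in enumerate(model.params_.layers):
            for k, t in layer.items():
                put(t, f"layer{j}_{k}")
        for k, t in model.params_.cross.items():
            put(t, f"cross_{k}")
        for j, (w, b) in enumerate(model.params_.head):
            put(w, f"head{j}_w")
            put(b, f"head{j}_b")
        model.norm_mean_ = npz["norm_mean"]
        model.norm_std_ = npz["norm_std"]
        model.loss_trace_ = npz["loss_trace"]
        model.n_channels_ = cfg.n_channels
        model.window_len_ = cfg.window_len
        model.n_features_in_ = cfg.n_channels * cfg.window_len
    return model
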