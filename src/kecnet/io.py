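"""Run configuration, model checkpoints, and report writers."""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .model import (KecNetConfig, KecNetModel, TrainConfig, TrainedModel,
                    build_baseline_cnn, build_kecnet)
from .sinc import WindowSpec

__all__ = ["RunConfig", "save_checkpoint", "load_checkpoint",
           "write_metrics_report", "config_hash"]


@dataclass
class RunConfig:
    """Everything one CLI run needs; defaults are the published values."""

    data_dir: str = "data"
    out_dir: str = "out"
    segment_length: int = 3600
    stride: int | None = None  # None -> non-overlapping (= segment_length)
    fs: float = 360.0
    n_per_class: int = 100
    duration_s: float = 10.0
    snr_list: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 60.0)
    seed: int = 0
    model: KecNetConfig = field(default_factory=KecNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        model_raw = dict(raw.pop("model", {}))
        if "window" in model_raw:
            model_raw["window"] = WindowSpec(**model_raw["window"])
        if "dense_units" in model_raw:
            model_raw["dense_units"] = tuple(model_raw["dense_units"])
        if "class_order" in model_raw:
            model_raw["class_order"] = tuple(model_raw["class_order"])
        train_raw = dict(raw.pop("train", {}))
        if "snr_list" in raw:
            raw["snr_list"] = tuple(raw["snr_list"])
        return cls(model=KecNetConfig(**model_raw), train=TrainConfig(**train_raw),
                   **raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def config_hash(config) -> str:
    """Stable short hash of a (nested) dataclass config."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _model_kind(model: KecNetModel) -> str:
    return "sinc" if model.sinc_layer is not None else "standard"


def save_checkpoint(path, trained: TrainedModel) -> None:
    """Single-file archive: weights, BN statistics, config, history."""
    model = trained.model
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        for name, p in layer.params.items():
            arrays[f"param/{i}/{name}"] = p
        if isinstance(layer, nn.BatchNorm1d):
            arrays[f"state/{i}/running_mean"] = layer.running_mean
            arrays[f"state/{i}/running_var"] = layer.running_var
    meta = {
        "kind": _model_kind(model),
        "config": asdict(model.config),
        "train_config": asdict(trained.train_config),
        "config_hash": config_hash(model.config),
    }
    buf = _io.StringIO()
    trained.history.to_csv(buf, index=False)
    np.savez(
        path,
        **arrays,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        history_csv=np.frombuffer(buf.getvalue().encode(), dtype=np.uint8),
    )


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        history = pd.read_csv(_io.BytesIO(z["history_csv"].tobytes()))
        cfg_raw = dict(meta["config"])
        cfg_raw["window"] = WindowSpec(**cfg_raw["window"])
        cfg_raw["dense_units"] = tuple(cfg_raw["dense_units"])
        cfg_raw["class_order"] = tuple(cfg_raw["class_order"])
        config = KecNetConfig(**cfg_raw)
        builder = build_kecnet if meta["kind"] == "sinc" else build_baseline_cnn
        model = builder(config)
        for i, layer in enumerate(model.layers):
            for name in list(layer.params):
                layer.params[name] = z[f"param/{i}/{name}"].copy()
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = z[f"state/{i}/running_mean"].copy()
                layer.running_var = z[f"state/{i}/running_var"].copy()
    return TrainedModel(model=model, history=history,
                        train_config=TrainConfig(**meta["train_config"]))


def write_metrics_report(out_dir, metrics, seed: int, config) -> None:
    """metrics.json + per-class CSV, stamped with config hash and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "acc": metrics.acc,
        "sen": metrics.sen,
        "pre": metrics.pre,
        "confusion": metrics.confusion.tolist(),
        "seed": seed,
        "config_hash": config_hash(config),
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))
    metrics.per_class.to_csv(out / "metrics_per_class.csv", index=False)
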