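"""Checkpoint and dataset archives (NumPy .npz with a JSON sidecar blob).

A checkpoint holds the full weight state, the architecture config, the
label map and the normalization statistics, so a saved model can be
reloaded and applied to new raw windows without any other context. A
dataset archive holds windows, labels, the label map and the producing
config fingerprint.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .model import ModelConfig, SKSTransformer
from .preprocess import LabelMap, NormStats


def _config_to_json(cfg: ModelConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["kernel_set"] = list(d["kernel_set"])
    return json.dumps(d)


def _config_from_json(blob: str) -> ModelConfig:
    d = json.loads(blob)
    d["kernel_set"] = tuple(d["kernel_set"])
    return ModelConfig(**d)


def save_checkpoint(path, model: SKSTransformer, label_map: LabelMap,
                    stats: NormStats | None = None) -> None:
    state = {f"w::{k}": v for k, v in model.state_dict().items()}
    meta = {"config": _config_to_json(model.cfg),
            "labels": json.dumps(label_map.names)}
    arrays = dict(state)
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if stats is not None:
        arrays["norm_mean"] = stats.mean
        arrays["norm_std"] = stats.std
    np.savez(path, **arrays)


def load_checkpoint(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = _config_from_json(meta["config"])
        model = SKSTransformer(cfg)
        state = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
        model.load_state_dict(state)
        model.eval()
        label_map = LabelMap(json.loads(meta["labels"]))
        stats = None
        if "norm_mean" in z.files:
            stats = NormStats(mean=z["norm_mean"], std=z["norm_std"])
    return model, label_map, stats


def save_dataset(path, x: np.ndarray, y: np.ndarray, label_map: LabelMap,
                 fingerprint: str = "", stats: NormStats | None = None) -> None:
    arrays = {"X": np.asarray(x), "y": np.asarray(y),
              "labels": np.asarray(label_map.names),
              "fingerprint": np.asarray(fingerprint)}
    if stats is not None:
        arrays["norm_mean"] = stats.mean
        arrays["norm_std"] = stats.std
    np.savez(path, **arrays)


def load_dataset(path):
    with np.load(path, allow_pickle=False) as z:
        x = z["X"]
        y = z["y"]
        label_map = LabelMap([str(n) for n in z["labels"]])
        fingerprint = str(z["fingerprint"])
        stats = None
        if "norm_mean" in z.files:
            stats = NormStats(mean=z["norm_mean"], std=z["norm_std"])
    return x, y, label_map, fingerprint, stats
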