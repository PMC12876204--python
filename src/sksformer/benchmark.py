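"""The package's self-contained synthetic benchmark protocols.

Two standard experiments run on the default synthetic dataset:

* ``cross_validation_benchmark`` — stratified 5-fold CV of a reduced
  classifier (latent width 32) trained with Adam 1e-3, batch 64, at most
  30 epochs with early stopping on a 10% validation split;
* ``ablation_benchmark`` — all six ablation variants over three seeds on
  a 75/25 holdout, each trained to convergence (batch 32, Adam 3e-3, at
  most 50 epochs, patience 12 on a 15% validation split).

Problem sizes are deliberately small (≈150 windows of 200×3) so both
experiments complete in minutes on a single CPU.
"""

from __future__ import annotations

import numpy as np

from .ablation import run_ablation, summarize_ablation
from .model import ModelConfig
from .preprocess import windows_from_series, windows_to_arrays
from .synthgen import GeneratorConfig, generate_dataset
from .train_eval import TrainConfig, run_cross_validation


def reduced_model_config(seed: int = 1, k: int = 6) -> ModelConfig:
    """CPU-scale architecture: width 32, otherwise the standard defaults."""
    return ModelConfig(T=200, D=3, K=k, d_model=32, h=4, d_ff=64,
                       c_attn=8, d_s=8, seed=seed)


def cv_train_config(seed: int = 1) -> TrainConfig:
    return TrainConfig(learning_rate=1e-3, batch_size=64, epochs=30,
                       patience=10, val_fraction=0.1, folds=5, seed=seed)


def ablation_train_config(seed: int = 1) -> TrainConfig:
    return TrainConfig(learning_rate=3e-3, batch_size=32, epochs=50,
                       patience=12, val_fraction=0.15, seed=seed)


def default_benchmark_dataset(seed: int = 1):
    """Default synthetic dataset as raw windows (denoised and raw variants)."""
    cfg = GeneratorConfig(seed=seed)
    sessions, manifest = generate_dataset(cfg)
    x_f, y, label_map = windows_to_arrays(
        windows_from_series(sessions, filter_enabled=True))
    x_r, y_r, _ = windows_to_arrays(
        windows_from_series(sessions, filter_enabled=False), label_map)
    assert np.array_equal(y, y_r)
    return {"generator": cfg, "manifest": manifest, "X_filtered": x_f,
            "X_raw": x_r, "y": y, "label_map": label_map}


def cross_validation_benchmark(seed: int = 1, dataset=None):
    data = dataset if dataset is not None else default_benchmark_dataset(seed)
    result = run_cross_validation(
        data["X_filtered"], data["y"],
        reduced_model_config(seed=seed, k=len(data["label_map"])),
        cv_train_config(seed=seed))
    return result, data


def ablation_benchmark(seed: int = 1, seeds=(0, 1, 2), dataset=None):
    data = dataset if dataset is not None else default_benchmark_dataset(seed)
    rows = run_ablation(
        data["X_filtered"], data["X_raw"], data["y"],
        reduced_model_config(seed=seed, k=len(data["label_map"])),
        ablation_train_config(seed=seed), seeds=seeds)
    return rows, summarize_ablation(rows), data
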