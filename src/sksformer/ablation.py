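"""Named model variants for component-removal (ablation) experiments.

Six variants are defined. ``No_Filter`` changes only preprocessing (the
Butterworth + Savitzky–Golay denoising is skipped; segmentation and
normalization are retained); every other variant changes only the
architecture:

* ``FullModel``  — the complete architecture.
* ``No_SK``      — selective-kernel branch removed; the head consumes the
  axial-attention features directly (fusion bypassed, no gate).
* ``No_SEA``     — axial attention removed; the head consumes the
  selective-kernel features directly.
* ``No_Gate``    — both branches retained but fused by a fixed 0.5/0.5
  average; the gate's parameters do not exist in this variant.
* ``No_Attn``    — both branches and the gate removed; the pooled encoder
  output feeds the head.

Where a component is removed, the minimal-surgery reading is used: nothing
is inserted in its place, and the remaining path is left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelConfig, SKSTransformer
from .train_eval import TrainConfig, compute_metrics, evaluate_model, train_model
from .preprocess import fit_normalizer

VARIANT_NAMES = ("FullModel", "No_SK", "No_SEA", "No_Gate", "No_Filter", "No_Attn")


@dataclass
class VariantSpec:
    name: str
    model_cfg: ModelConfig
    filter_enabled: bool = True


def build_variant(name: str, base: ModelConfig) -> VariantSpec:
    """Derive a variant's model config and preprocessing flags from a base."""
    if name == "FullModel":
        return VariantSpec(name, base)
    if name == "No_SK":
        return VariantSpec(name, base.replace(use_sk=False))
    if name == "No_SEA":
        return VariantSpec(name, base.replace(use_sea=False))
    if name == "No_Gate":
        return VariantSpec(name, base.replace(gate_mode="average"))
    if name == "No_Filter":
        return VariantSpec(name, base, filter_enabled=False)
    if name == "No_Attn":
        return VariantSpec(name, base.replace(use_branches=False))
    raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")


def build_model(spec: VariantSpec) -> SKSTransformer:
    return SKSTransformer(spec.model_cfg)


def run_ablation(windows_filtered: np.ndarray, windows_unfiltered: np.ndarray,
                 y: np.ndarray, base: ModelConfig, train_cfg: TrainConfig,
                 variants=VARIANT_NAMES, seeds=(0, 1, 2),
                 test_fraction: float = 0.25) -> list[dict]:
    """Train/evaluate every variant over several seeds on a holdout split.

    ``windows_filtered``/``windows_unfiltered`` are the same raw windows
    conditioned with and without denoising (the ``No_Filter`` variant uses
    the latter). One stratification-free shuffled holdout split per seed
    keeps the experiment affordable; accuracy is averaged over seeds.
    Returns one result row per (variant, seed).
    """
    y = np.asarray(y, dtype=int)
    k = int(y.max()) + 1
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(y))
        n_test = int(round(test_fraction * len(y)))
        te, tr = order[:n_test], order[n_test:]
        for name in variants:
            spec = build_variant(name, base.replace(seed=base.seed + seed))
            x = windows_filtered if spec.filter_enabled else windows_unfiltered
            stats = fit_normalizer(x[tr])
            x_tr = (x[tr] - stats.mean) / stats.std
            x_te = (x[te] - stats.mean) / stats.std
            tc = TrainConfig(**{**vars(train_cfg)})
            tc.seed = train_cfg.seed + 1000 * (seed + 1)
            model = build_model(spec)
            model, _ = train_model(x_tr.astype(np.float32), y[tr],
                                   spec.model_cfg, tc, model=model)
            _, preds = evaluate_model(model, x_te.astype(np.float32), y[te])
            metrics = compute_metrics(y[te], preds, k)
            rows.append({"variant": name, "seed": seed,
                         "params": model.parameter_count(),
                         **metrics.as_dict()})
    return rows


def summarize_ablation(rows: list[dict]) -> dict[str, float]:
    """Mean accuracy per variant across seeds."""
    out: dict[str, list[float]] = {}
    for row in rows:
        out.setdefault(row["variant"], []).append(row["accuracy"])
    return {name: float(np.mean(v)) for name, v in out.items()}
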