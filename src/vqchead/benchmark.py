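"""The head-to-head comparison experiment: quantum versus dense middle block.

Both heads see *identical* data and follow the identical training
schedule; only the middle block differs.  For each head and seed the
experiment records final train/validation losses, the overfitting gap
(validation minus training loss at the last epoch), BACC and AUC on the
validation split, and the middle block's trainable parameter count.
The across-seed means and standard deviations summarize the run.

The gap comparison is a protocol, not a guaranteed inequality: whether
the quantum head overfits less on a given synthetic task is an
empirical question the report answers, not a contract the code
enforces.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np

from .head import HybridHeadClassifier, HybridHeadConfig, TrainingConfig
from .synthetic import SyntheticSpec, generate, generate_splits

__all__ = ["compare_heads"]


def _run_one(X_tr, y_tr, X_val, y_val, config: HybridHeadConfig,
             training: TrainingConfig) -> dict:
    model = HybridHeadClassifier(X_tr, y_tr, config)
    res = model.fit(training, X_val, y_val)
    report = res.evaluate(X_val, y_val)
    return {
        "head_kind": config.head_kind,
        "seed": training.seed,
        "final_train_loss": float(res.train_curve[-1]),
        "final_val_loss": float(res.val_curve[-1]),
        "overfit_gap": res.overfit_gap(),
        "bacc": report.bacc,
        "auc": report.auc,
        "middle_params": config.middle_param_count(),
    }


def compare_heads(spec: SyntheticSpec,
                  head_configs: list[HybridHeadConfig] | None = None,
                  training: TrainingConfig | None = None,
                  n_seeds: int = 3,
                  n_val: int | None = None,
                  out_path=None) -> dict:
    """Train every head on the same splits across ``n_seeds`` seeds.

    ``spec.seed`` and ``training.seed`` act as base seeds; replicate j
    uses base + j for both the data draw and the training randomness,
    so rows are reproducible individually.
    """
    if training is None:
        training = TrainingConfig()
    if head_configs is None:
        n = spec.n_features
        head_configs = [
            HybridHeadConfig(in_dim=n, n_qubits=n, head_kind="vqc"),
            HybridHeadConfig(in_dim=n, n_qubits=n, head_kind="fc"),
        ]
    n_val = n_val if n_val is not None else spec.n_samples // 2
    runs = []
    for j in range(n_seeds):
        data_spec = replace(spec, seed=spec.seed + j)
        (X_tr, y_tr), (X_val, y_val) = generate_splits(data_spec, n_val=n_val)
        for config in head_configs:
            tc = replace(training, seed=training.seed + j)
            runs.append(_run_one(X_tr, y_tr, X_val, y_val, config, tc))

    summary = {}
    for kind in sorted({r["head_kind"] for r in runs}):
        rows = [r for r in runs if r["head_kind"] == kind]
        summary[kind] = {
            "middle_params": rows[0]["middle_params"],
            **{
                f"{key}_{stat}": float(fn([r[key] for r in rows]))
                for key in ("final_train_loss", "final_val_loss",
                            "overfit_gap", "bacc", "auc")
                for stat, fn in (("mean", np.mean), ("std", np.std))
            },
        }
    report = {"spec": asdict(spec), "training": asdict(training),
              "n_seeds": n_seeds, "runs": runs, "summary": summary}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
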