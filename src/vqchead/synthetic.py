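"""Seeded synthetic feature generation for benchmarking classifier heads.

The generator emulates what a vision backbone's penultimate layer hands
to the classification head on a two-class screening task: real-valued
feature vectors with controllable class separability, class imbalance
and label noise.  Two geometries are available:

* ``gaussian_blobs`` — two unit-covariance Gaussians whose means differ
  by a chosen Mahalanobis distance along the first feature axis; the
  linearly separable regime typical of well-trained backbone features.
* ``ring_vs_disc`` — class 0 inside a disc, class 1 on a surrounding
  annulus (first two feature dims; remaining dims are pure noise); a
  radially separable task no linear head can solve, for probing the
  nonlinearity of a quantum head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SyntheticSpec", "generate", "generate_splits", "write_csv"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic split."""

    n_samples: int = 400
    n_features: int = 8
    class_balance: float = 0.5        # P(label = 1) before label noise
    separation: float = 6.0           # Mahalanobis distance between class means
    noise_kind: str = "gaussian_blobs"
    label_noise: float = 0.0          # fraction of labels flipped
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("need n_samples >= 2 and n_features >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(f"class_balance must be in (0,1), got {self.class_balance}")
        if self.separation < 0:
            raise ValueError(f"separation must be nonnegative, got {self.separation}")
        if self.noise_kind not in ("gaussian_blobs", "ring_vs_disc"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(f"label_noise must be in [0, 0.5), got {self.label_noise}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw one split: (X of shape (n, p), y in {0,1}). Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    y = (rng.random(n) < spec.class_balance).astype(int)
    if spec.noise_kind == "gaussian_blobs":
        X = rng.standard_normal((n, p))
        # unit covariance -> Mahalanobis distance = Euclidean mean distance;
        # put it all on feature 1 so a single-feature threshold is Bayes-optimal
        X[:, 0] += np.where(y == 1, spec.separation / 2.0, -spec.separation / 2.0)
    else:  # ring_vs_disc
        # class 0: 2-D Gaussian disc at the origin; class 1: annulus whose
        # mean radius grows with the separation knob
        r_ring = 1.0 + spec.separation / 2.0
        radius = np.where(
            y == 1,
            r_ring + rng.standard_normal(n) * 0.3,
            np.abs(rng.standard_normal(n)) * 0.5,
        )
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        X = rng.standard_normal((n, p)) * 0.3
        X[:, 0] += radius * np.cos(phi)
        if p > 1:
            X[:, 1] += radius * np.sin(phi)
    if spec.label_noise > 0:
        flip = rng.random(n) < spec.label_noise
        y = np.where(flip, 1 - y, y)
    return X, y


def generate_splits(spec: SyntheticSpec,
                    n_val: int | None = None,
                    n_test: int | None = None):
    """Independent train/validation(/test) draws; seeds offset per split."""
    train = generate(spec)
    out = [train]
    for j, n in enumerate((n_val, n_test)):
        if n is None:
            continue
        sub = SyntheticSpec(n, spec.n_features, spec.class_balance,
                            spec.separation, spec.noise_kind, spec.label_noise,
                            seed=spec.seed + 1 + j)
        out.append(generate(sub))
    return tuple(out)


def write_csv(X: np.ndarray, y: np.ndarray, path) -> None:
    """Samples-by-features CSV with a trailing integer ``label`` column."""
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = y.astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
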