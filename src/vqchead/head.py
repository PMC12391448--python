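"""Hybrid quantum-classical classification heads and their training loop.

The head sits where a vision backbone's classifier would: it receives a
real feature vector and emits two class logits.  Two interchangeable
anatomies are provided, identical except for the middle block:

* ``vqc``  — Linear(in_dim -> N) -> quantum encode -> variational
  circuit -> per-qubit <Z> -> Linear(N -> 2).  The middle block carries
  3*K*N trainable rotation angles.
* ``fc``   — Linear(in_dim -> N) -> Linear(N -> N) -> Linear(N -> 2).
  The middle block carries N^2 weights (+ N biases), the dense layer
  the circuit replaces.

Training follows the hybrid transfer-learning protocol: SGD with
momentum 0.9 and weight decay 1e-4 (classical weights only — rotation
angles are periodic, shrinking them toward zero is meaningless), cosine
annealing to zero over 80 epochs, label-smoothed cross entropy, a
class-balanced resampling loader, and two learning-rate groups — the
quantum angles get a 10x larger rate (0.004 vs 0.0004) because the
<Z>-bounded circuit output keeps their gradients small.

The public surface is statsmodels-shaped: build a
:class:`HybridHeadClassifier` from data, call :meth:`fit`, get a
:class:`HybridHeadResults` carrying parameters, per-epoch loss curves,
prediction/evaluation methods and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricsReport, evaluate_scores
from .mitigation import expectations_from_histogram, sample_shots
from .statevector import PureState
from .vqc import (
    VQCParams,
    adjoint_gradients,
    amplitude_adjoint_gradients,
    amplitude_forward_batch,
    angle_forward_batch,
    count_params,
    parameter_shift_grad,
)

__all__ = [
    "HybridHeadConfig",
    "TrainingConfig",
    "HeadWeights",
    "HybridHeadClassifier",
    "HybridHeadResults",
    "head_forward",
    "smoothed_cross_entropy",
    "make_balanced_loader",
    "cosine_lr",
    "overfit_gap",
]


@dataclass(frozen=True)
class HybridHeadConfig:
    """Architecture of the head.

    ``n_qubits`` is the register width N; with angle encoding the middle
    block consumes N features (one per qubit), with amplitude encoding it
    consumes 2**N features packed into the N-qubit state.  ``shots = 0``
    means exact expectations; a positive value Monte-Carlo samples the
    measurement, as hardware would (the study setting is 1000).
    """

    in_dim: int
    n_qubits: int = 8
    n_layers: int = 2
    head_kind: str = "vqc"          # {"vqc", "fc"}
    shots: int = 0
    embedding: str = "angle"        # {"angle", "amplitude"}
    entanglement: str = "ring"      # {"ring", "chain"}

    def __post_init__(self) -> None:
        if self.in_dim < 1 or self.n_qubits < 1 or self.n_layers < 0:
            raise ValueError("in_dim, n_qubits must be >= 1 and n_layers >= 0")
        if self.head_kind not in ("vqc", "fc"):
            raise ValueError(f"head_kind must be 'vqc' or 'fc', got {self.head_kind!r}")
        if self.embedding not in ("angle", "amplitude"):
            raise ValueError(f"embedding must be 'angle' or 'amplitude', "
                             f"got {self.embedding!r}")
        if self.shots < 0:
            raise ValueError("shots must be nonnegative (0 = analytic)")

    @property
    def mid_in_dim(self) -> int:
        """Feature count entering the middle block."""
        if self.head_kind == "vqc" and self.embedding == "amplitude":
            return 2 ** self.n_qubits
        return self.n_qubits

    @property
    def mid_out_dim(self) -> int:
        return self.n_qubits

    def middle_param_count(self) -> int:
        """Trainable parameters of the middle block (FC count includes bias)."""
        if self.head_kind == "vqc":
            return count_params(self.n_qubits, self.n_layers)
        return self.n_qubits ** 2 + self.n_qubits


@dataclass(frozen=True)
class TrainingConfig:
    """The joint training protocol (defaults = the study protocol)."""

    epochs: int = 80
    lr_classical: float = 0.0004
    lr_quantum: float = 0.004
    momentum: float = 0.9
    weight_decay: float = 1e-4
    label_smoothing: float = 0.1
    schedule: str = "cosine"            # {"cosine", "constant"}
    balanced_resampling: bool = True
    batch_size: int = 32
    gradient_mode: str = "adjoint"      # {"adjoint", "parameter_shift"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr_classical < 0 or self.lr_quantum < 0:
            raise ValueError("learning rates must be nonnegative")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.schedule not in ("cosine", "constant"):
            raise ValueError(f"schedule must be 'cosine' or 'constant', "
                             f"got {self.schedule!r}")
        if self.gradient_mode not in ("adjoint", "parameter_shift"):
            raise ValueError(f"unknown gradient_mode {self.gradient_mode!r}")


@dataclass
class HeadWeights:
    """Classical parameters of the head; ``w_mid``/``b_mid`` only for fc."""

    w_in: np.ndarray
    b_in: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    w_mid: np.ndarray | None = None
    b_mid: np.ndarray | None = None

    def copy(self) -> "HeadWeights":
        return HeadWeights(*(None if a is None else a.copy()
                             for a in (self.w_in, self.b_in, self.w_out,
                                       self.b_out, self.w_mid, self.b_mid)))

    def to_dict(self) -> dict:
        d = {"w_in": self.w_in.tolist(), "b_in": self.b_in.tolist(),
             "w_out": self.w_out.tolist(), "b_out": self.b_out.tolist()}
        if self.w_mid is not None:
            d["w_mid"] = self.w_mid.tolist()
            d["b_mid"] = self.b_mid.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HeadWeights":
        return cls(
            np.asarray(d["w_in"]), np.asarray(d["b_in"]),
            np.asarray(d["w_out"]), np.asarray(d["b_out"]),
            np.asarray(d["w_mid"]) if "w_mid" in d else None,
            np.asarray(d["b_mid"]) if "b_mid" in d else None,
        )

    @classmethod
    def init(cls, config: HybridHeadConfig,
             rng: np.random.Generator) -> "HeadWeights":
        """Glorot-normal linear maps, zero biases."""

        def glorot(n_out, n_in):
            scale = np.sqrt(2.0 / (n_in + n_out))
            return rng.normal(0.0, scale, (n_out, n_in))

        w_in = glorot(config.mid_in_dim, config.in_dim)
        w_out = glorot(2, config.mid_out_dim)
        w_mid = b_mid = None
        if config.head_kind == "fc":
            w_mid = glorot(config.n_qubits, config.n_qubits)
            b_mid = np.zeros(config.n_qubits)
        return cls(w_in, np.zeros(config.mid_in_dim), w_out, np.zeros(2),
                   w_mid, b_mid)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def _middle_forward(config: HybridHeadConfig, weights: HeadWeights,
                    vqc_params: VQCParams | None, u: np.ndarray,
                    rng: np.random.Generator | None = None):
    """Middle block on a (B, mid_in_dim) batch -> (z, final_amps or None)."""
    if config.head_kind == "fc":
        return u @ weights.w_mid.T + weights.b_mid, None
    if config.embedding == "angle":
        z, amps = angle_forward_batch(u, vqc_params, config.entanglement)
    else:
        z, amps = amplitude_forward_batch(u, vqc_params, config.entanglement)
    if config.shots > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        z = np.stack([
            expectations_from_histogram(
                sample_shots(PureState(config.n_qubits, a), config.shots, rng))
            for a in amps
        ])
    return z, amps


def forward_batch(config: HybridHeadConfig, weights: HeadWeights,
                  vqc_params: VQCParams | None, X: np.ndarray,
                  rng: np.random.Generator | None = None):
    """Full head on a (B, in_dim) batch.

    Returns (logits (B, 2), u (B, mid_in), z (B, N), amps or None).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != config.in_dim:
        raise ValueError(f"features have dim {X.shape[1]}, expected {config.in_dim}")
    u = X @ weights.w_in.T + weights.b_in
    z, amps = _middle_forward(config, weights, vqc_params, u, rng)
    logits = z @ weights.w_out.T + weights.b_out
    return logits, u, z, amps


def head_forward(config: HybridHeadConfig, weights: HeadWeights,
                 vqc_params: VQCParams | None, features,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Single feature vector -> 2 logits (shot-sampled if config.shots > 0)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logits, *_ = forward_batch(config, weights, vqc_params,
                               np.atleast_2d(features), rng)
    return logits[0]


# ---------------------------------------------------------------------------
# Loss, loader, schedule
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def smoothed_cross_entropy(logits, labels, label_smoothing: float = 0.0,
                           return_grad: bool = False):
    """Label-smoothed cross entropy, averaged over the batch.

    The true class target is ``1 - s/2`` and the other ``s/2`` (two
    classes).  With ``return_grad`` the per-sample dL/dlogits (already
    divided by the batch size) is returned alongside.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    s = label_smoothing
    B = logits.shape[0]
    targets = np.full((B, 2), s / 2.0)
    targets[np.arange(B), labels] = 1.0 - s / 2.0
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    loss = float(-(targets * logp).sum(axis=1).mean())
    if not return_grad:
        return loss
    grad = (_softmax(logits) - targets) / B
    return loss, grad


def make_balanced_loader(labels, n_draws: int,
                         seed: int | np.random.Generator) -> np.ndarray:
    """Index sequence with equal expected class frequencies.

    Each draw picks a class uniformly, then a member of that class
    uniformly with replacement — i.e. the minority class is
    oversampled.  Deterministic under the seed.
    """
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("balanced loader needs both classes present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = [np.flatnonzero(y == c) for c in classes]
    which = rng.integers(0, len(classes), n_draws)
    return np.array([members[c][rng.integers(0, len(members[c]))] for c in which])


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from lr0 (epoch 0) to 0 (epoch = total), no restarts."""
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))


def overfit_gap(train_curve, val_curve) -> tuple[float, np.ndarray]:
    """(final-epoch val - train loss, per-epoch gap series)."""
    t = np.asarray(train_curve, dtype=float)
    v = np.asarray(val_curve, dtype=float)
    if t.shape != v.shape:
        raise ValueError(f"curve lengths differ: {t.shape} vs {v.shape}")
    gap = v - t
    return float(gap[-1]), gap


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------

def _backward(config: HybridHeadConfig, weights: HeadWeights,
              vqc_params: VQCParams | None, X, u, z, amps, dlogits,
              gradient_mode: str = "adjoint"):
    """Gradients of the scalar loss for every trainable tensor."""
    g: dict[str, np.ndarray] = {}
    g["w_out"] = dlogits.T @ z
    g["b_out"] = dlogits.sum(axis=0)
    dz = dlogits @ weights.w_out
    if config.head_kind == "fc":
        g["w_mid"] = dz.T @ u
        g["b_mid"] = dz.sum(axis=0)
        du = dz @ weights.w_mid
    elif gradient_mode == "adjoint":
        if config.embedding == "angle":
            du, g["vqc"] = adjoint_gradients(u, vqc_params, dz, amps,
                                             config.entanglement)
        else:
            du, g["vqc"] = amplitude_adjoint_gradients(u, vqc_params, dz, amps,
                                                       config.entanglement)
    else:  # parameter-shift route (hardware compatible, angle encoding)
        if config.embedding != "angle":
            raise ValueError("parameter_shift gradients require angle encoding")
        du, g["vqc"] = _parameter_shift_backward(config, vqc_params, u, dz)
    g["w_in"] = du.T @ X
    g["b_in"] = du.sum(axis=0)
    return g


def _parameter_shift_backward(config, vqc_params, u, dz):
    """Per-sample two-point shift rule for both circuit and encoding angles."""
    from .embeddings import angle_embed

    B, n = u.shape
    du = np.zeros_like(u)
    dangles = np.zeros_like(vqc_params.angles)
    for b in range(B):
        state = angle_embed(u[b])
        dangles += parameter_shift_grad(vqc_params, state, dz[b],
                                        config.entanglement)
        du[b] = _encoding_shift_grad(config, vqc_params, u[b], dz[b])
    return du, dangles


def _encoding_shift_grad(config, vqc_params, u_row, dz_row):
    """Shift rule on the encoding RY/RZ angles, chained through arctan."""
    xp = np.arctan(u_row)
    n = len(u_row)
    grad = np.zeros(n)
    for q in range(n):
        g_angles = []
        for which in ("ry", "rz"):
            vals = []
            for sgn in (1.0, -1.0):
                ry = xp.copy()
                rz = xp ** 2
                if which == "ry":
                    ry[q] += sgn * np.pi / 2.0
                else:
                    rz[q] += sgn * np.pi / 2.0
                z, _ = _encoded_forward(ry, rz, vqc_params, config.entanglement)
                vals.append(dz_row @ z)
            g_angles.append((vals[0] - vals[1]) / 2.0)
        grad[q] = (g_angles[0] + 2.0 * xp[q] * g_angles[1]) / (1.0 + u_row[q] ** 2)
    return grad


def _encoded_forward(ry_angles, rz_angles, vqc_params, entanglement):
    from .statevector import apply_1q, z_sign_table
    from .vqc import _ry_batch, _rz_batch, layers_forward_batch

    n = len(ry_angles)
    amps = np.full((1, 2 ** n), 1.0 / np.sqrt(2 ** n), dtype=np.complex128)
    for q in range(n):
        amps = apply_1q(amps, _ry_batch(np.array([ry_angles[q]])), q, n)
        amps = apply_1q(amps, _rz_batch(np.array([rz_angles[q]])), q, n)
    amps = layers_forward_batch(amps, vqc_params, entanglement)
    z = (np.abs(amps) ** 2) @ z_sign_table(n).T
    return z[0], amps


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class SGDGroups:
    """SGD with momentum and two learning-rate groups.

    ``quantum_keys`` name the tensors that receive the quantum learning
    rate; weight decay is added to the gradient of every *classical*
    tensor only.  Update: v <- mu v + (g + wd w); w <- w - lr v.
    """

    def __init__(self, shapes: dict[str, tuple], momentum: float,
                 weight_decay: float, quantum_keys: frozenset = frozenset({"vqc"})):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.quantum_keys = quantum_keys
        self.velocity = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr_classical: float, lr_quantum: float) -> None:
        for k, w in params.items():
            if k not in grads:
                continue
            is_q = k in self.quantum_keys
            g = grads[k] if is_q else grads[k] + self.weight_decay * w
            v = self.velocity[k]
            v *= self.momentum
            v += g
            w -= (lr_quantum if is_q else lr_classical) * v


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class HybridHeadClassifier:
    """A trainable classification head bound to a training set.

    Parameters
    ----------
    X, y : array-like
        Training features (n_samples, in_dim) and binary labels.
    config : HybridHeadConfig, optional
        Architecture; defaults to an 8-qubit, 2-layer angle-encoded
        quantum head matched to the feature dimension.
    """

    def __init__(self, X, y, config: HybridHeadConfig | None = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=int).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError(f"{self.X.shape[0]} samples vs {self.y.size} labels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite training features")
        if not np.all(np.isin(self.y, (0, 1))):
            raise ValueError("labels must be binary 0/1")
        if config is None:
            config = HybridHeadConfig(in_dim=self.X.shape[1])
        if config.in_dim != self.X.shape[1]:
            raise ValueError(f"config.in_dim={config.in_dim} but features have "
                             f"dim {self.X.shape[1]}")
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       config: HybridHeadConfig | None = None):
        y = df[label_column].to_numpy(dtype=int)
        X = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(X, y, config)

    @classmethod
    def from_csv(cls, path, label_column: str = "label",
                 config: HybridHeadConfig | None = None):
        return cls.from_dataframe(pd.read_csv(path), label_column, config)

    # -- fitting --------------------------------------------------------
    def fit(self, training: TrainingConfig | None = None,
            X_val=None, y_val=None) -> "HybridHeadResults":
        """Run the joint training protocol; returns the fitted results.

        If no validation split is supplied, a 20% tail split (seeded) is
        held out from the training data.
        """
        tc = training if training is not None else TrainingConfig()
        cfg = self.config
        rng = np.random.default_rng(tc.seed)

        if X_val is None:
            n = self.X.shape[0]
            perm = rng.permutation(n)
            n_val = max(1, n // 5)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr = self.X[tr_idx], self.y[tr_idx]
            X_val, y_val = self.X[val_idx], self.y[val_idx]
        else:
            X_tr, y_tr = self.X, self.y
            X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
            y_val = np.asarray(y_val, dtype=int).ravel()

        weights = HeadWeights.init(cfg, rng)
        vqc_params = (VQCParams.random(cfg.n_qubits, cfg.n_layers, rng)
                      if cfg.head_kind == "vqc" else None)

        params: dict[str, np.ndarray] = {
            "w_in": weights.w_in, "b_in": weights.b_in,
            "w_out": weights.w_out, "b_out": weights.b_out,
        }
        if cfg.head_kind == "fc":
            params["w_mid"] = weights.w_mid
            params["b_mid"] = weights.b_mid
        else:
            params["vqc"] = vqc_params.angles
        opt = SGDGroups({k: v.shape for k, v in params.items()},
                        tc.momentum, tc.weight_decay)

        n_tr = X_tr.shape[0]
        history = []
        for epoch in range(tc.epochs):
            if tc.schedule == "cosine":
                lr_c = cosine_lr(tc.lr_classical, epoch, tc.epochs)
                lr_q = cosine_lr(tc.lr_quantum, epoch, tc.epochs)
            else:
                lr_c, lr_q = tc.lr_classical, tc.lr_quantum
            if tc.balanced_resampling:
                order = make_balanced_loader(y_tr, n_tr, rng)
            else:
                order = rng.permutation(n_tr)
            epoch_loss = 0.0
            for start in range(0, n_tr, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                Xb, yb = X_tr[idx], y_tr[idx]
                logits, u, z, amps = forward_batch(cfg, weights, vqc_params, Xb)
                loss, dlogits = smoothed_cross_entropy(
                    logits, yb, tc.label_smoothing, return_grad=True)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: loss={loss} at epoch {epoch}, "
                        f"batch starting {start} (check learning rates)")
                grads = _backward(cfg, weights, vqc_params, Xb, u, z, amps,
                                  dlogits, tc.gradient_mode)
                opt.step(params, grads, lr_c, lr_q)
                epoch_loss += loss * len(idx)
            train_loss = epoch_loss / n_tr
            val_logits, *_ = forward_batch(cfg, weights, vqc_params, X_val)
            val_loss = smoothed_cross_entropy(val_logits, y_val,
                                              tc.label_smoothing)
            history.append({"epoch": epoch, "lr_classical": lr_c,
                            "lr_quantum": lr_q, "train_loss": train_loss,
                            "val_loss": val_loss})

        return HybridHeadResults(
            config=cfg, training=tc, weights=weights, vqc_params=vqc_params,
            history=pd.DataFrame(history),
            val_data=(X_val, y_val),
        )


@dataclass
class HybridHeadResults:
    """Fitted head: parameters, loss curves and evaluation utilities."""

    config: HybridHeadConfig
    training: TrainingConfig
    weights: HeadWeights
    vqc_params: VQCParams | None
    history: pd.DataFrame
    val_data: tuple | None = None

    # -- curves ---------------------------------------------------------
    @property
    def train_curve(self) -> np.ndarray:
        return self.history["train_loss"].to_numpy()

    @property
    def val_curve(self) -> np.ndarray:
        return self.history["val_loss"].to_numpy()

    def overfit_gap(self) -> float:
        """Final-epoch validation minus training loss."""
        return overfit_gap(self.train_curve, self.val_curve)[0]

    # -- prediction -----------------------------------------------------
    def predict_logits(self, X, shots: int | None = None,
                       seed: int = 0) -> np.ndarray:
        cfg = self.config if shots is None else replace(self.config, shots=shots)
        logits, *_ = forward_batch(cfg, self.weights, self.vqc_params,
                                   X, np.random.default_rng(seed))
        return logits

    def predict_proba(self, X, shots: int | None = None,
                      seed: int = 0) -> np.ndarray:
        """P(class 1) — softmax of the two logits."""
        return _softmax(self.predict_logits(X, shots, seed))[:, 1]

    def predict(self, X, threshold: float = 0.5, **kw) -> np.ndarray:
        return (self.predict_proba(X, **kw) >= threshold).astype(int)

    def evaluate(self, X, y, threshold: float = 0.5, shots: int | None = None,
                 seed: int = 0) -> MetricsReport:
        return evaluate_scores(np.asarray(y, dtype=int),
                               self.predict_proba(X, shots, seed), threshold)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        cfg, tc = self.config, self.training
        gap = self.overfit_gap()
        lines = [
            "Hybrid head training results",
            "=" * 60,
            f"head kind:             {cfg.head_kind}",
            f"in_dim -> middle -> 2: {cfg.in_dim} -> {cfg.mid_in_dim} -> 2",
            f"qubits / layers:       {cfg.n_qubits} / {cfg.n_layers}",
            f"embedding:             {cfg.embedding} ({cfg.entanglement})"
            if cfg.head_kind == "vqc" else "embedding:             n/a (dense)",
            f"middle-block params:   {cfg.middle_param_count()}",
            f"epochs:                {tc.epochs} (schedule: {tc.schedule})",
            f"lr classical/quantum:  {tc.lr_classical} / {tc.lr_quantum}",
            f"final train loss:      {self.train_curve[-1]:.4f}",
            f"final val loss:        {self.val_curve[-1]:.4f}",
            f"overfit gap:           {gap:+.4f}",
        ]
        if self.val_data is not None:
            rep = self.evaluate(*self.val_data)
            lines.append(f"validation metrics:    {rep}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        d = {
            "config": asdict(self.config),
            "training": asdict(self.training),
            "weights": self.weights.to_dict(),
            "vqc_params": (None if self.vqc_params is None
                           else json.loads(self.vqc_params.to_json())),
            "history": self.history.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path) -> "HybridHeadResults":
        d = json.loads(Path(path).read_text())
        vp = d["vqc_params"]
        return cls(
            config=HybridHeadConfig(**d["config"]),
            training=TrainingConfig(**d["training"]),
            weights=HeadWeights.from_dict(d["weights"]),
            vqc_params=(None if vp is None else
                        VQCParams(vp["n_qubits"], vp["n_layers"],
                                  np.asarray(vp["angles"]))),
            history=pd.DataFrame(d["history"]),
        )
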