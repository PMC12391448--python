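"""Classical-to-quantum feature encoding.

Three schemes are provided:

* **angle** (the default throughout the package): one feature per qubit.
  Each raw feature ``x`` is squashed with the arctangent, ``x' =
  arctan(x) in (-pi/2, pi/2)``, then the qubit — prepared in |+> by a
  Hadamard — receives ``RY(x')`` followed by ``RZ(x'^2)``; the squared
  Z-angle is a deliberate extra nonlinearity that enriches the encoded
  phase without touching the measurement probabilities of a single
  qubit.  Constant depth, no entangling gates, hardware friendly.
* **amplitude**: an L2-normalized feature vector written directly into
  the amplitudes of ceil(log2 N) qubits (zero-padded to a power of
  two).  Qubit-efficient but needs O(N)-depth state preparation on
  hardware, so it is implemented here by direct assignment — a
  simulator-only shortcut.
* **basis**: a bit vector mapped to the matching computational basis
  state.  Only meaningful for binary data; included for completeness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .statevector import (
    MAX_QUBITS,
    CapacityError,
    CircuitSpec,
    GateOp,
    PureState,
    plus_state,
    apply_1q,
    ry_matrix,
    rz_matrix,
)

__all__ = [
    "angle_embed",
    "angle_embedding_circuit",
    "amplitude_embed",
    "basis_embed",
    "load_features_csv",
    "EMBEDDINGS",
]

EMBEDDINGS = ("angle", "amplitude", "basis")


def _check_features(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty feature vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains NaN or Inf")
    return x


def angle_embedding_circuit(features) -> CircuitSpec:
    """The explicit gate sequence of the angle encoding (H, RY, RZ per qubit)."""
    x = _check_features(features)
    xp = np.arctan(x)
    spec = CircuitSpec(len(x))
    for i in range(len(x)):
        spec.append(GateOp("H", (i,)))
    for i, a in enumerate(xp):
        spec.append(GateOp("RY", (i,), (float(a),)))
    for i, a in enumerate(xp):
        spec.append(GateOp("RZ", (i,), (float(a) ** 2,)))
    return spec


def angle_embed(features, n_qubits: int | None = None) -> PureState:
    """Encode one real feature per qubit via arctan angles.

    The resulting per-qubit Bloch vector satisfies the closed form
    ``<Z_i> = -sin(arctan x_i)`` regardless of the RZ phase term.
    """
    x = _check_features(features)
    if n_qubits is not None and n_qubits != x.size:
        raise ValueError(
            f"angle embedding needs one qubit per feature: got {x.size} "
            f"features for {n_qubits} qubits"
        )
    n = x.size
    if n > MAX_QUBITS:
        raise CapacityError(f"{n} features exceed the {MAX_QUBITS}-qubit cap")
    xp = np.arctan(x)
    state = plus_state(n)
    amps = state.amplitudes
    for i in range(n):
        amps = apply_1q(amps, ry_matrix(xp[i]), i, n)
        amps = apply_1q(amps, rz_matrix(xp[i] ** 2), i, n)
    return PureState(n, amps)


def amplitude_embed(features) -> PureState:
    """Encode a feature vector as state amplitudes after L2 normalization.

    Non-power-of-two lengths are zero-padded up to the next power of two;
    the register size is ceil(log2 N).
    """
    x = _check_features(features)
    norm = np.linalg.norm(x)
    if norm == 0.0:
        raise ValueError("all-zero vector cannot be L2-normalized")
    n = max(1, int(np.ceil(np.log2(x.size))))
    if n > MAX_QUBITS:
        raise CapacityError(f"{x.size} features exceed the {MAX_QUBITS}-qubit cap")
    amps = np.zeros(2 ** n, dtype=np.complex128)
    amps[: x.size] = x / norm
    return PureState(n, amps)


def basis_embed(bits) -> PureState:
    """Computational basis state |b_{n-1} ... b_0> from a bit vector.

    Bit i of the input addresses qubit i (little-endian), so
    ``[1, 0, 1]`` lands on basis index 1 + 4 = 5.
    """
    b = np.asarray(bits).ravel()
    if b.size == 0:
        raise ValueError("empty bit vector")
    if not np.all(np.isin(b, (0, 1))):
        raise ValueError(f"basis embedding needs binary entries, got {b!r}")
    n = b.size
    if n > MAX_QUBITS:
        raise CapacityError(f"{n} bits exceed the {MAX_QUBITS}-qubit cap")
    idx = int(np.sum(b.astype(int) << np.arange(n)))
    amps = np.zeros(2 ** n, dtype=np.complex128)
    amps[idx] = 1.0
    return PureState(n, amps)


def load_features_csv(path, label_column: str | None = "label"):
    """Read a samples-by-features CSV; returns (X, y) with y=None if unlabeled.

    The label column (default name ``label``) is split off when present;
    all remaining columns must be finite reals.
    """
    df = pd.read_csv(path)
    y = None
    if label_column is not None and label_column in df.columns:
        y = df[label_column].to_numpy(dtype=int)
        df = df.drop(columns=[label_column])
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite feature values in {path}")
    return X, y
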