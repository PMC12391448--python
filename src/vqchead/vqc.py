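"""The trainable variational circuit: K strongly entangling layers.

Each layer puts one general U3 rotation on every qubit (the trainable
part, 3 angles each) followed by a ring of CZ gates entangling qubit i
with qubit i+1 (wrap-around; a chain without the wrap is available as a
config switch).  The circuit reads out the per-qubit Pauli-Z
expectation vector, so an N-qubit circuit maps an encoded feature
vector to N reals in [-1, 1] with only 3*K*N trainable parameters —
linear in width, versus the quadratic N^2 weight count of the dense
linear layer it replaces.

Two gradient routes are implemented:

* :func:`parameter_shift_grad` — the hardware-compatible two-point
  shift rule.  Each U3 angle parameterizes a rotation whose generator
  has eigenvalues +-1/2 (via the RZ(phi) RY(theta) RZ(lam)
  decomposition, global phase immaterial), so
  ``df/da = (f(a + pi/2) - f(a - pi/2)) / 2`` exactly.
* :func:`adjoint_gradients` — analytic reverse-mode differentiation
  through the statevector (one forward pass plus one reverse sweep of
  inverse gates), used by the training loop; also returns gradients
  with respect to the raw input features through the arctan encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .statevector import (
    CircuitSpec,
    GateOp,
    PureState,
    apply_1q,
    apply_cz,
    pauli_z_expectations,
    ry_matrix,
    rz_matrix,
    run_circuit,
    u3_matrix,
    z_sign_table,
)

__all__ = [
    "VQCParams",
    "build_layer",
    "vqc_circuit",
    "vqc_forward",
    "count_params",
    "fc_weight_count",
    "parameter_reduction",
    "parameter_shift_grad",
    "adjoint_gradients",
    "angle_forward_batch",
    "amplitude_forward_batch",
    "amplitude_adjoint_gradients",
    "layers_forward_batch",
    "full_circuit",
    "export_qasm",
]


@dataclass
class VQCParams:
    """Trainable rotation angles: shape (n_layers, n_qubits, 3).

    The last axis holds the (theta, phi, lam) triple of each U3 gate.
    ``n_layers = 0`` is allowed and means the identity circuit (useful
    as the degenerate baseline: the output is then exactly the
    embedding's Z-profile).
    """

    n_qubits: int
    n_layers: int
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        expected = (self.n_layers, self.n_qubits, 3)
        if self.angles.shape != expected:
            raise ValueError(
                f"angles shape {self.angles.shape} != {expected}"
            )
        if self.angles.size and not np.all(np.isfinite(self.angles)):
            raise ValueError("non-finite VQC angles")
        if self.n_qubits < 1 or self.n_layers < 0:
            raise ValueError("need n_qubits >= 1 and n_layers >= 0")

    @classmethod
    def zeros(cls, n_qubits: int, n_layers: int) -> "VQCParams":
        return cls(n_qubits, n_layers, np.zeros((n_layers, n_qubits, 3)))

    @classmethod
    def random(cls, n_qubits: int, n_layers: int,
               rng: np.random.Generator) -> "VQCParams":
        """Angles uniform on [0, 2*pi), the usual init for this ansatz."""
        return cls(n_qubits, n_layers,
                   rng.uniform(0.0, 2.0 * np.pi, (n_layers, n_qubits, 3)))

    @property
    def n_params(self) -> int:
        return 3 * self.n_layers * self.n_qubits

    # layer-major nested lists for checkpointing
    def to_json(self) -> str:
        return json.dumps({"n_qubits": self.n_qubits,
                           "n_layers": self.n_layers,
                           "angles": self.angles.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "VQCParams":
        d = json.loads(text)
        return cls(d["n_qubits"], d["n_layers"], np.asarray(d["angles"]))


def _entangler_pairs(n_qubits: int, entanglement: str) -> list[tuple[int, int]]:
    if entanglement not in ("ring", "chain"):
        raise ValueError(f"entanglement must be 'ring' or 'chain', got {entanglement!r}")
    if n_qubits == 1:
        return []
    if n_qubits == 2:
        return [(0, 1)]  # ring and chain coincide; avoid a duplicate CZ
    pairs = [(i, i + 1) for i in range(n_qubits - 1)]
    if entanglement == "ring":
        pairs.append((n_qubits - 1, 0))
    return pairs


def build_layer(params_layer: np.ndarray, n_qubits: int,
                entanglement: str = "ring") -> CircuitSpec:
    """One variational layer: a U3 per qubit, then the CZ entangler."""
    p = np.asarray(params_layer, dtype=float)
    if p.shape != (n_qubits, 3):
        raise ValueError(f"layer params shape {p.shape} != ({n_qubits}, 3)")
    spec = CircuitSpec(n_qubits)
    for i in range(n_qubits):
        spec.append(GateOp("U3", (i,), tuple(p[i])))
    for q0, q1 in _entangler_pairs(n_qubits, entanglement):
        spec.append(GateOp("CZ", (q0, q1)))
    return spec


def vqc_circuit(params: VQCParams, entanglement: str = "ring") -> CircuitSpec:
    """All K variational layers as one circuit (no embedding gates)."""
    spec = CircuitSpec(params.n_qubits)
    for k in range(params.n_layers):
        spec.ops.extend(
            build_layer(params.angles[k], params.n_qubits, entanglement).ops
        )
    return spec


def vqc_forward(params: VQCParams, embedded: PureState,
                entanglement: str = "ring") -> np.ndarray:
    """Per-qubit <Z> after running the variational layers on an encoded state."""
    if embedded.n_qubits != params.n_qubits:
        raise ValueError(
            f"state has {embedded.n_qubits} qubits, params expect {params.n_qubits}"
        )
    out = run_circuit(vqc_circuit(params, entanglement), embedded)
    return pauli_z_expectations(out)


def count_params(n_qubits: int, n_layers: int) -> int:
    """Trainable angle count 3*K*N (three Euler angles per U3)."""
    if n_qubits < 1 or n_layers < 0:
        raise ValueError("need n_qubits >= 1 and n_layers >= 0")
    return 3 * n_layers * n_qubits


def fc_weight_count(n_qubits: int) -> int:
    """Weight count of the dense N->N linear layer the circuit replaces."""
    return n_qubits * n_qubits


def parameter_reduction(n_qubits: int, n_layers: int) -> float:
    """Fractional reduction 1 - 3KN/N^2 versus the dense layer's weights."""
    return 1.0 - count_params(n_qubits, n_layers) / fc_weight_count(n_qubits)


# ---------------------------------------------------------------------------
# Parameter-shift gradients
# ---------------------------------------------------------------------------

def parameter_shift_grad(params: VQCParams, embedded: PureState,
                         upstream: np.ndarray,
                         entanglement: str = "ring") -> np.ndarray:
    """d<upstream, vqc_forward>/d(angles) by the two-point shift rule.

    Evaluates the circuit at every angle shifted by +-pi/2; exact for
    rotation generators with +-1/2 eigenvalues, hence for each U3 Euler
    angle.  Returns an array shaped like ``params.angles``.
    """
    upstream = np.asarray(upstream, dtype=float)
    if upstream.shape != (params.n_qubits,):
        raise ValueError(
            f"upstream shape {upstream.shape} != ({params.n_qubits},)"
        )
    grad = np.zeros_like(params.angles)
    if not np.any(upstream):
        return grad
    base = params.angles
    for k in range(params.n_layers):
        for i in range(params.n_qubits):
            for a in range(3):
                shifted = base.copy()
                shifted[k, i, a] += np.pi / 2.0
                plus = vqc_forward(
                    VQCParams(params.n_qubits, params.n_layers, shifted),
                    embedded, entanglement)
                shifted[k, i, a] -= np.pi
                minus = vqc_forward(
                    VQCParams(params.n_qubits, params.n_layers, shifted),
                    embedded, entanglement)
                grad[k, i, a] = upstream @ (plus - minus) / 2.0
    return grad


# ---------------------------------------------------------------------------
# Batched analytic engine (angle encoding + layers) used for training
# ---------------------------------------------------------------------------

def _dry(theta: np.ndarray) -> np.ndarray:
    """d RY/d theta, batched: theta (B,) -> (B, 2, 2)."""
    c, s = np.cos(theta / 2.0) / 2.0, np.sin(theta / 2.0) / 2.0
    out = np.empty(theta.shape + (2, 2), dtype=np.complex128)
    out[..., 0, 0] = -s
    out[..., 0, 1] = -c
    out[..., 1, 0] = c
    out[..., 1, 1] = -s
    return out


def _rz_batch(theta: np.ndarray) -> np.ndarray:
    out = np.zeros(theta.shape + (2, 2), dtype=np.complex128)
    out[..., 0, 0] = np.exp(-0.5j * theta)
    out[..., 1, 1] = np.exp(0.5j * theta)
    return out


def _drz(theta: np.ndarray) -> np.ndarray:
    out = np.zeros(theta.shape + (2, 2), dtype=np.complex128)
    out[..., 0, 0] = -0.5j * np.exp(-0.5j * theta)
    out[..., 1, 1] = 0.5j * np.exp(0.5j * theta)
    return out


def _ry_batch(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    out = np.empty(theta.shape + (2, 2), dtype=np.complex128)
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def _du3(theta: float, phi: float, lam: float) -> list[np.ndarray]:
    """[dU/dtheta, dU/dphi, dU/dlam] for a single U3."""
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    ep, el, epl = np.exp(1j * phi), np.exp(1j * lam), np.exp(1j * (phi + lam))
    dth = 0.5 * np.array([[-s, -el * c], [ep * c, -epl * s]])
    dph = np.array([[0.0, 0.0], [1j * ep * s, 1j * epl * c]])
    dla = np.array([[0.0, -1j * el * s], [0.0, 1j * epl * c]])
    return [dth, dph, dla]


def _undo_1q(arr: np.ndarray, mat: np.ndarray, q: int, n: int) -> np.ndarray:
    return apply_1q(arr, np.swapaxes(mat, -1, -2).conj(), q, n)


def layers_forward_batch(amps: np.ndarray, params: VQCParams,
                         entanglement: str = "ring") -> np.ndarray:
    """Apply the K variational layers to a (..., 2**N) amplitude batch."""
    n = params.n_qubits
    pairs = _entangler_pairs(n, entanglement)
    for k in range(params.n_layers):
        for q in range(n):
            amps = apply_1q(amps, u3_matrix(*params.angles[k, q]), q, n)
        for q0, q1 in pairs:
            amps = apply_cz(amps, q0, q1, n)
    return amps


def _layers_adjoint(ket: np.ndarray, bra: np.ndarray, params: VQCParams,
                    entanglement: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse sweep over the variational layers only.

    On entry ``ket`` is the post-layer state and ``bra`` the
    observable-weighted state O|psi_final>.  Returns the pre-layer ket,
    the dragged-back bra, and the (K, N, 3) angle gradient summed over
    the batch.
    """
    n = params.n_qubits
    pairs = _entangler_pairs(n, entanglement)
    dangles = np.zeros_like(params.angles)
    for k in range(params.n_layers - 1, -1, -1):
        for q0, q1 in reversed(pairs):
            ket = apply_cz(ket, q0, q1, n)
            bra = apply_cz(bra, q0, q1, n)
        for q in range(n - 1, -1, -1):
            mat = u3_matrix(*params.angles[k, q])
            ket = _undo_1q(ket, mat, q, n)
            for a, dmat in enumerate(_du3(*params.angles[k, q])):
                dket = apply_1q(ket, dmat, q, n)
                dangles[k, q, a] = 2.0 * float(
                    np.real(np.sum(bra.conj() * dket)))
            bra = _undo_1q(bra, mat, q, n)
    return ket, bra, dangles


def angle_forward_batch(u: np.ndarray, params: VQCParams,
                        entanglement: str = "ring") -> tuple[np.ndarray, np.ndarray]:
    """Arctan-angle-encode a batch and run the layers.

    Parameters
    ----------
    u : (B, N) array
        Raw (pre-encoding) feature values, one row per sample.

    Returns
    -------
    z : (B, N) array of per-qubit <Z> expectations.
    amps : (B, 2**N) final statevectors (kept for the adjoint sweep).
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    B, n = u.shape
    if n != params.n_qubits:
        raise ValueError(f"{n} features vs {params.n_qubits} qubits")
    xp = np.arctan(u)
    dim = 2 ** n
    amps = np.full((B, dim), 1.0 / np.sqrt(dim), dtype=np.complex128)
    for q in range(n):
        amps = apply_1q(amps, _ry_batch(xp[:, q]), q, n)
        amps = apply_1q(amps, _rz_batch(xp[:, q] ** 2), q, n)
    amps = layers_forward_batch(amps, params, entanglement)
    z = (np.abs(amps) ** 2) @ z_sign_table(n).T
    return z, amps


def adjoint_gradients(u: np.ndarray, params: VQCParams, upstream: np.ndarray,
                      amps: np.ndarray | None = None,
                      entanglement: str = "ring") -> tuple[np.ndarray, np.ndarray]:
    """Reverse-mode gradients of ``sum_b <upstream_b, z_b>`` (angle encoding).

    Runs the standard adjoint sweep: undo each gate on the ket while
    dragging the observable-weighted bra backwards; each parameterized
    gate contributes ``2 Re <bra | dU | ket>``.  Returns

    * ``du`` (B, N): gradient with respect to the raw inputs, chained
      through ``theta_RY = arctan u`` and ``theta_RZ = arctan(u)^2``;
    * ``dangles`` (K, N, 3): gradient with respect to the U3 angles,
      summed over the batch.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    upstream = np.atleast_2d(np.asarray(upstream, dtype=float))
    B, n = u.shape
    if amps is None:
        _, amps = angle_forward_batch(u, params, entanglement)
    xp = np.arctan(u)
    signs = z_sign_table(n)
    ket = amps
    bra = (upstream @ signs) * ket  # diagonal observable applied per sample
    ket, bra, dangles = _layers_adjoint(ket, bra, params, entanglement)

    def grad_1q(dmat, q):
        dket = apply_1q(ket, dmat, q, n)
        return 2.0 * np.real(np.einsum("bj,bj->b", bra.conj(), dket))

    # encoding rotations, chained back to the raw inputs
    du = np.zeros_like(u)
    for q in range(n - 1, -1, -1):
        th_rz = xp[:, q] ** 2
        ket = _undo_1q(ket, _rz_batch(th_rz), q, n)
        g_rz = grad_1q(_drz(th_rz), q)
        bra = _undo_1q(bra, _rz_batch(th_rz), q, n)

        th_ry = xp[:, q]
        ket = _undo_1q(ket, _ry_batch(th_ry), q, n)
        g_ry = grad_1q(_dry(th_ry), q)
        bra = _undo_1q(bra, _ry_batch(th_ry), q, n)

        # d theta / du: arctan' = 1/(1+u^2); RZ angle is arctan(u)^2
        du[:, q] = (g_ry + 2.0 * xp[:, q] * g_rz) / (1.0 + u[:, q] ** 2)
    return du, dangles


def amplitude_forward_batch(u: np.ndarray, params: VQCParams,
                            entanglement: str = "ring"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """L2-normalize a (B, 2**N) batch into amplitudes and run the layers.

    Returns (z, final amplitudes).  Rows must be nonzero.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    n = params.n_qubits
    if u.shape[1] != 2 ** n:
        raise ValueError(
            f"amplitude encoding on {n} qubits needs {2 ** n} features, "
            f"got {u.shape[1]}")
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("all-zero row cannot be L2-normalized")
    amps = (u / norms).astype(np.complex128)
    amps = layers_forward_batch(amps, params, entanglement)
    z = (np.abs(amps) ** 2) @ z_sign_table(n).T
    return z, amps


def amplitude_adjoint_gradients(u: np.ndarray, params: VQCParams,
                                upstream: np.ndarray,
                                amps: np.ndarray | None = None,
                                entanglement: str = "ring"
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint gradients for the amplitude-encoded circuit.

    The encoded state is linear in the normalized input, so the input
    gradient is ``2 Re(bra)`` projected through the derivative of the
    L2 normalization map.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    upstream = np.atleast_2d(np.asarray(upstream, dtype=float))
    n = params.n_qubits
    if amps is None:
        _, amps = amplitude_forward_batch(u, params, entanglement)
    signs = z_sign_table(n)
    ket = amps
    bra = (upstream @ signs) * ket
    ket, bra, dangles = _layers_adjoint(ket, bra, params, entanglement)
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    psi = u / norms
    g = 2.0 * np.real(bra)  # dL/d(real initial amplitudes)
    du = (g - np.sum(g * psi, axis=1, keepdims=True) * psi) / norms
    return du, dangles


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def full_circuit(params: VQCParams, embedding_angles: np.ndarray,
                 entanglement: str = "ring") -> CircuitSpec:
    """H column + encoding rotations + variational layers as one CircuitSpec.

    ``embedding_angles`` are the squashed angles x' = arctan(x); each
    qubit receives RY(x') then RZ(x'^2).
    """
    a = np.asarray(embedding_angles, dtype=float).ravel()
    n = params.n_qubits
    if a.size != n:
        raise ValueError(f"{a.size} embedding angles for {n} qubits")
    spec = CircuitSpec(n)
    for i in range(n):
        spec.append(GateOp("H", (i,)))
    for i in range(n):
        spec.append(GateOp("RY", (i,), (float(a[i]),)))
        spec.append(GateOp("RZ", (i,), (float(a[i]) ** 2,)))
    spec.ops.extend(vqc_circuit(params, entanglement).ops)
    return spec


def export_qasm(params: VQCParams, embedding_angles: np.ndarray,
                entanglement: str = "ring") -> str:
    """OpenQASM 2.0 text of the full (encoding + variational) circuit."""
    from .qasm import circuit_to_qasm

    return circuit_to_qasm(full_circuit(params, embedding_angles, entanglement))
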