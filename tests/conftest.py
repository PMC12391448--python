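"""Shared fixtures and the dense Kronecker-product oracle.

The oracle builds the full 2^n x 2^n unitary of every gate by explicit
tensor products of 2x2 factors (and a basis-index sign test for CZ) —
completely independent of the simulator's axis-reshaping fast path —
so circuit equivalence checks have a trusted reference.
"""

from functools import reduce

import numpy as np
import pytest

from vqchead.statevector import CircuitSpec, GateOp, gate_matrix


def dense_gate_matrix(op: GateOp, n_qubits: int) -> np.ndarray:
    """Full-register matrix of one gate, little-endian qubit order."""
    if op.kind == "CZ":
        q0, q1 = op.targets
        idx = np.arange(2 ** n_qubits)
        sign = np.where(((idx >> q0) & 1) & ((idx >> q1) & 1), -1.0, 1.0)
        return np.diag(sign).astype(np.complex128)
    m = gate_matrix(op)
    # kron chains most-significant factor first; qubit q sits at slot n-1-q
    factors = [np.eye(2, dtype=np.complex128)] * n_qubits
    factors[n_qubits - 1 - op.targets[0]] = m
    return reduce(np.kron, factors)


def dense_circuit_matrix(spec: CircuitSpec) -> np.ndarray:
    """Product of the dense gate matrices, rightmost gate applied first."""
    u = np.eye(2 ** spec.n_qubits, dtype=np.complex128)
    for op in spec.ops:
        u = dense_gate_matrix(op, spec.n_qubits) @ u
    return u


def random_gate(rng: np.random.Generator, n_qubits: int) -> GateOp:
    kind = rng.choice(["H", "RY", "RZ", "U3", "CZ"])
    if kind == "CZ" and n_qubits >= 2:
        q0, q1 = rng.choice(n_qubits, 2, replace=False)
        return GateOp("CZ", (int(q0), int(q1)))
    if kind == "CZ":
        kind = "U3"
    q = int(rng.integers(n_qubits))
    n_ang = {"H": 0, "RY": 1, "RZ": 1, "U3": 3}[kind]
    return GateOp(kind, (q,), tuple(rng.uniform(-2 * np.pi, 2 * np.pi, n_ang)))


def random_circuit(rng: np.random.Generator, n_qubits: int,
                   n_gates: int) -> CircuitSpec:
    return CircuitSpec(n_qubits,
                       [random_gate(rng, n_qubits) for _ in range(n_gates)])


def random_state_vector(rng: np.random.Generator, n_qubits: int) -> np.ndarray:
    v = rng.standard_normal(2 ** n_qubits) + 1j * rng.standard_normal(2 ** n_qubits)
    return v / np.linalg.norm(v)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
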