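"""Dense statevector simulation of small qubit registers.

The simulator is exact: an ``n``-qubit pure state is the full complex
amplitude vector of length ``2**n`` and gates act by contracting a 2x2
(or, for CZ, a diagonal sign flip) against the relevant tensor axis.
Qubit 0 is the *least-significant* bit of the basis-state integer index
(little-endian), and every helper in this package sticks to that
convention.

The gate set is the one the target superconducting hardware exposes
natively — U3 and CZ — plus H, RY and RZ which appear in state
preparation and feature encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAX_QUBITS",
    "PureState",
    "GateOp",
    "CircuitSpec",
    "zero_state",
    "plus_state",
    "gate_matrix",
    "apply_gate",
    "run_circuit",
    "pauli_z_expectations",
    "z_sign_table",
]

#: Hard capacity cap: a 24-qubit complex128 vector is 256 MiB; anything
#: larger is almost certainly an accidental ``n`` and should fail fast.
MAX_QUBITS = 24

_ONE_QUBIT_KINDS = frozenset({"H", "RY", "RZ", "U3"})
_TWO_QUBIT_KINDS = frozenset({"CZ"})
_N_ANGLES = {"H": 0, "CZ": 0, "RY": 1, "RZ": 1, "U3": 3}


class CapacityError(ValueError):
    """Requested register exceeds the simulator's qubit cap."""


class UnsupportedGateError(ValueError):
    """Gate kind outside the supported set {H, RY, RZ, U3, CZ}."""


@dataclass(frozen=True)
class GateOp:
    """A single gate instruction.

    Parameters
    ----------
    kind : str
        One of ``H``, ``RY``, ``RZ``, ``U3``, ``CZ``.
    targets : tuple of int
        Qubit indices the gate acts on; 1 for single-qubit gates,
        exactly 2 (control, target — symmetric for CZ) for CZ.
    angles : tuple of float
        0 angles for H/CZ, 1 for RY/RZ, 3 (theta, phi, lam) for U3.
    """

    kind: str
    targets: tuple[int, ...]
    angles: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(int(t) for t in self.targets))
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))
        if self.kind not in _N_ANGLES:
            raise UnsupportedGateError(f"unknown gate kind {self.kind!r}")
        n_tgt = 2 if self.kind in _TWO_QUBIT_KINDS else 1
        if len(self.targets) != n_tgt:
            raise ValueError(
                f"{self.kind} takes {n_tgt} target(s), got {len(self.targets)}"
            )
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"targets must be distinct, got {self.targets}")
        if any(t < 0 for t in self.targets):
            raise ValueError(f"negative qubit index in {self.targets}")
        if len(self.angles) != _N_ANGLES[self.kind]:
            raise ValueError(
                f"{self.kind} takes {_N_ANGLES[self.kind]} angle(s), "
                f"got {len(self.angles)}"
            )
        if not all(np.isfinite(self.angles)):
            raise ValueError(f"non-finite angle in {self.angles}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "targets": list(self.targets),
                "angles": list(self.angles)}

    @classmethod
    def from_dict(cls, d: dict) -> "GateOp":
        return cls(d["kind"], tuple(d["targets"]), tuple(d.get("angles", ())))


@dataclass
class CircuitSpec:
    """An ordered gate list on a fixed-size register."""

    n_qubits: int
    ops: list[GateOp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.n_qubits <= MAX_QUBITS:
            raise CapacityError(
                f"n_qubits must be in [1, {MAX_QUBITS}], got {self.n_qubits}"
            )
        for op in self.ops:
            self._check_op(op)

    def _check_op(self, op: GateOp) -> None:
        if any(t >= self.n_qubits for t in op.targets):
            raise IndexError(
                f"gate {op.kind} targets {op.targets} out of range for "
                f"{self.n_qubits} qubits"
            )

    def append(self, op: GateOp) -> None:
        self._check_op(op)
        self.ops.append(op)

    # -- JSON round trip ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"n_qubits": self.n_qubits, "ops": [op.to_dict() for op in self.ops]}
        )

    @classmethod
    def from_json(cls, text: str) -> "CircuitSpec":
        d = json.loads(text)
        return cls(d["n_qubits"], [GateOp.from_dict(o) for o in d["ops"]])


@dataclass
class PureState:
    """An n-qubit pure state: unit-norm complex vector of length 2**n."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.complex128)
        if self.amplitudes.shape != (2 ** self.n_qubits,):
            raise ValueError(
                f"amplitude vector of length {self.amplitudes.size} does not "
                f"match {self.n_qubits} qubits (expected {2 ** self.n_qubits})"
            )
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"state is not normalized: ||psi|| = {norm!r}")

    @property
    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


def zero_state(n_qubits: int) -> PureState:
    """|0...0>: all amplitude on basis index 0."""
    if not 1 <= n_qubits <= MAX_QUBITS:
        raise CapacityError(
            f"n_qubits must be in [1, {MAX_QUBITS}], got {n_qubits}"
        )
    amps = np.zeros(2 ** n_qubits, dtype=np.complex128)
    amps[0] = 1.0
    return PureState(n_qubits, amps)


def plus_state(n_qubits: int) -> PureState:
    """Uniform superposition |+>^n (H on every qubit of |0...0>)."""
    if not 1 <= n_qubits <= MAX_QUBITS:
        raise CapacityError(
            f"n_qubits must be in [1, {MAX_QUBITS}], got {n_qubits}"
        )
    dim = 2 ** n_qubits
    return PureState(n_qubits, np.full(dim, 1.0 / np.sqrt(dim), dtype=np.complex128))


# ---------------------------------------------------------------------------
# Gate matrices (OpenQASM conventions)
# ---------------------------------------------------------------------------

_H = np.array([[1, 1], [1, -1]], dtype=np.complex128) / np.sqrt(2.0)
_CZ = np.diag([1.0, 1.0, 1.0, -1.0]).astype(np.complex128)


def ry_matrix(theta: float) -> np.ndarray:
    """RY(theta) = exp(-i theta Y / 2)."""
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=np.complex128)


def rz_matrix(theta: float) -> np.ndarray:
    """RZ(theta) = exp(-i theta Z / 2) = diag(e^{-i theta/2}, e^{i theta/2})."""
    return np.array(
        [[np.exp(-0.5j * theta), 0.0], [0.0, np.exp(0.5j * theta)]],
        dtype=np.complex128,
    )


def u3_matrix(theta: float, phi: float, lam: float) -> np.ndarray:
    """General single-qubit rotation, OpenQASM u3 convention.

    U3(0, 0, 0) is the identity; U3(theta, 0, 0) acts on |0> like
    RY(theta) (both send |0> to cos(theta/2)|0> + sin(theta/2)|1>).
    """
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array(
        [
            [c, -np.exp(1j * lam) * s],
            [np.exp(1j * phi) * s, np.exp(1j * (phi + lam)) * c],
        ],
        dtype=np.complex128,
    )


def gate_matrix(op: GateOp) -> np.ndarray:
    """The 2x2 (or 4x4 for CZ) unitary of a gate instruction."""
    if op.kind == "H":
        return _H.copy()
    if op.kind == "CZ":
        return _CZ.copy()
    if op.kind == "RY":
        return ry_matrix(op.angles[0])
    if op.kind == "RZ":
        return rz_matrix(op.angles[0])
    if op.kind == "U3":
        return u3_matrix(*op.angles)
    raise UnsupportedGateError(f"unknown gate kind {op.kind!r}")


# ---------------------------------------------------------------------------
# Gate application on raw amplitude arrays (batched; used by the VQC engine)
# ---------------------------------------------------------------------------

def apply_1q(amps: np.ndarray, mat: np.ndarray, qubit: int, n_qubits: int) -> np.ndarray:
    """Apply a single-qubit unitary to amplitudes of shape (..., 2**n).

    ``mat`` may be (2, 2) (shared) or (batch, 2, 2) (per-sample gates,
    as used by feature-dependent encoding rotations).
    """
    lead = amps.shape[:-1]
    inner = 2 ** qubit
    outer = 2 ** (n_qubits - 1 - qubit)
    a = amps.reshape(lead + (outer, 2, inner))
    if mat.ndim == 2:
        out = np.einsum("ab,...obi->...oai", mat, a)
    else:
        # mat: (batch, 2, 2); amps lead dims must start with that batch
        out = np.einsum("kab,k...obi->k...oai", mat, a)
    return out.reshape(lead + (2 ** n_qubits,))


def cz_mask(q0: int, q1: int, n_qubits: int) -> np.ndarray:
    """Boolean mask of basis indices where both qubit bits are 1."""
    idx = np.arange(2 ** n_qubits)
    return ((idx >> q0) & 1).astype(bool) & ((idx >> q1) & 1).astype(bool)


def apply_cz(amps: np.ndarray, q0: int, q1: int, n_qubits: int) -> np.ndarray:
    out = amps.copy()
    out[..., cz_mask(q0, q1, n_qubits)] *= -1.0
    return out


def apply_gate(state: PureState, op: GateOp) -> PureState:
    """Apply one gate; returns a new state (input untouched)."""
    n = state.n_qubits
    if any(t >= n for t in op.targets):
        raise IndexError(
            f"gate {op.kind} targets {op.targets} out of range for {n} qubits"
        )
    if op.kind == "CZ":
        amps = apply_cz(state.amplitudes, op.targets[0], op.targets[1], n)
    else:
        amps = apply_1q(state.amplitudes, gate_matrix(op), op.targets[0], n)
    return PureState(n, amps)


def run_circuit(spec: CircuitSpec, initial: PureState | None = None) -> PureState:
    """Apply the circuit's gates left to right to ``initial`` (default |0...0>)."""
    if initial is None:
        initial = zero_state(spec.n_qubits)
    if initial.n_qubits != spec.n_qubits:
        raise ValueError(
            f"state has {initial.n_qubits} qubits but circuit expects "
            f"{spec.n_qubits}"
        )
    amps = initial.amplitudes
    n = spec.n_qubits
    for op in spec.ops:
        if op.kind == "CZ":
            amps = apply_cz(amps, op.targets[0], op.targets[1], n)
        else:
            amps = apply_1q(amps, gate_matrix(op), op.targets[0], n)
    return PureState(n, amps)


# ---------------------------------------------------------------------------
# Pauli-Z readout
# ---------------------------------------------------------------------------

_SIGN_CACHE: dict[int, np.ndarray] = {}


def z_sign_table(n_qubits: int) -> np.ndarray:
    """(n, 2**n) array of +/-1: entry [i, b] is +1 if bit i of b is 0."""
    tab = _SIGN_CACHE.get(n_qubits)
    if tab is None:
        idx = np.arange(2 ** n_qubits)
        bits = (idx[None, :] >> np.arange(n_qubits)[:, None]) & 1
        tab = 1.0 - 2.0 * bits
        _SIGN_CACHE[n_qubits] = tab
    return tab


def pauli_z_expectations(state: PureState) -> np.ndarray:
    """Per-qubit <Z_i> = P(bit i = 0) - P(bit i = 1), length n_qubits."""
    probs = state.probabilities
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"state is not normalized: sum p = {total!r}")
    return z_sign_table(state.n_qubits) @ probs
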