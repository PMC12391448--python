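"""Shot sampling and M3-style readout-error mitigation.

Measurement on hardware is corrupted by readout (assignment) errors.
Here the noise is modeled as independent per-qubit confusion matrices
``A_i`` with ``A_i[m, t] = P(measured m | true t)`` — a tensor-product
model, the testable stand-in for correlated-readout calibration data
that real devices would provide.  Mitigation inverts the confusion
system *restricted to the observed bitstrings and their single-bit-flip
neighbors*, mirroring the matrix-free spirit of the M3 method: the full
``2^n x 2^n`` system is never formed, so the cost scales with the
number of distinct observed outcomes rather than with ``4^n``.

The corrected output is a quasi-probability map (entries can dip
slightly below zero); a clipped-and-renormalized variant is provided
for consumers that need a proper distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .statevector import PureState

__all__ = [
    "ShotHistogram",
    "ReadoutCalibration",
    "sample_shots",
    "expectations_from_histogram",
    "apply_readout_noise",
    "mitigate",
    "clip_and_renormalize",
    "total_variation",
]


@dataclass
class ShotHistogram:
    """Bitstring -> count map from repeated measurement.

    Bitstring keys are written most-significant qubit first, i.e. the
    character at position ``-1 - i`` is qubit i — so ``"10"`` on two
    qubits means qubit 1 read 1 and qubit 0 read 0 (basis index 2).
    """

    n_qubits: int
    counts: dict[str, int]
    shots: int

    def __post_init__(self) -> None:
        if self.shots <= 0:
            raise ValueError("shots must be positive")
        total = 0
        for key, c in self.counts.items():
            if len(key) != self.n_qubits or set(key) - {"0", "1"}:
                raise ValueError(f"bad bitstring key {key!r} for {self.n_qubits} qubits")
            if c < 0:
                raise ValueError(f"negative count for {key!r}")
            total += c
        if total != self.shots:
            raise ValueError(f"counts sum to {total}, expected {self.shots}")

    def frequencies(self) -> dict[str, float]:
        return {k: c / self.shots for k, c in self.counts.items()}

    def to_json(self) -> str:
        return json.dumps({"n_qubits": self.n_qubits, "shots": self.shots,
                           "counts": self.counts})

    @classmethod
    def from_json(cls, text: str) -> "ShotHistogram":
        d = json.loads(text)
        return cls(d["n_qubits"], {k: int(v) for k, v in d["counts"].items()},
                   d["shots"])


def _index_to_bitstring(idx: int, n_qubits: int) -> str:
    return format(idx, f"0{n_qubits}b")


def _bitstring_to_index(key: str) -> int:
    return int(key, 2)


@dataclass
class ReadoutCalibration:
    """Per-qubit 2x2 column-stochastic confusion matrices P(measured|true)."""

    matrices: np.ndarray  # (n_qubits, 2, 2)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (2, 2):
            raise ValueError(f"expected (n, 2, 2) matrices, got {self.matrices.shape}")
        if np.any(self.matrices < -1e-12) or np.any(self.matrices > 1 + 1e-12):
            raise ValueError("confusion entries must lie in [0, 1]")
        colsums = self.matrices.sum(axis=1)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"columns must sum to 1, got {colsums}")

    @property
    def n_qubits(self) -> int:
        return self.matrices.shape[0]

    @classmethod
    def uniform_flip(cls, n_qubits: int, p: float) -> "ReadoutCalibration":
        """Symmetric bit-flip noise with probability p on every qubit."""
        m = np.array([[1 - p, p], [p, 1 - p]], dtype=float)
        return cls(np.broadcast_to(m, (n_qubits, 2, 2)).copy())

    def to_json(self) -> str:
        return json.dumps({"matrices": self.matrices.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ReadoutCalibration":
        return cls(np.asarray(json.loads(text)["matrices"]))


# ---------------------------------------------------------------------------
# Sampling and expectations
# ---------------------------------------------------------------------------

def sample_shots(state: PureState, shots: int,
                 seed: int | np.random.Generator = 0) -> ShotHistogram:
    """Multinomial draw of measurement outcomes from |amplitude|^2."""
    if shots <= 0:
        raise ValueError("shots must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = state.probabilities
    probs = probs / probs.sum()  # guard 1e-10-level float drift
    draws = rng.multinomial(shots, probs)
    counts = {
        _index_to_bitstring(i, state.n_qubits): int(c)
        for i, c in enumerate(draws) if c > 0
    }
    return ShotHistogram(state.n_qubits, counts, shots)


def expectations_from_histogram(hist: ShotHistogram) -> np.ndarray:
    """Empirical per-qubit <Z>: (count of bit 0 - count of bit 1) / shots."""
    z = np.zeros(hist.n_qubits)
    for key, c in hist.counts.items():
        for i in range(hist.n_qubits):
            z[i] += c if key[-1 - i] == "0" else -c
    return z / hist.shots


def expectations_from_quasi(quasi: dict[str, float], n_qubits: int) -> np.ndarray:
    """Per-qubit <Z> from a (quasi-)probability map; accepts negative entries."""
    z = np.zeros(n_qubits)
    for key, p in quasi.items():
        for i in range(n_qubits):
            z[i] += p if key[-1 - i] == "0" else -p
    return z


# ---------------------------------------------------------------------------
# Noise injection and mitigation
# ---------------------------------------------------------------------------

def apply_readout_noise(hist: ShotHistogram, calib: ReadoutCalibration,
                        seed: int | np.random.Generator = 0) -> ShotHistogram:
    """Flip each recorded bit independently per its confusion matrix.

    P(flip | true bit t) for qubit i is ``calib.matrices[i, 1 - t, t]``;
    the shot total is preserved exactly.
    """
    if hist.n_qubits != calib.n_qubits:
        raise ValueError(
            f"histogram has {hist.n_qubits} qubits, calibration {calib.n_qubits}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = hist.n_qubits
    p_flip = np.array([[calib.matrices[i, 1, 0], calib.matrices[i, 0, 1]]
                       for i in range(n)])  # [i, t] = P(measured != t | true t)
    noisy: dict[str, int] = {}
    for key, c in sorted(hist.counts.items()):
        true_bits = np.array([int(key[-1 - i]) for i in range(n)])
        flip_p = p_flip[np.arange(n), true_bits]
        flips = rng.random((c, n)) < flip_p[None, :]
        out_bits = flips ^ true_bits.astype(bool)
        idx = out_bits @ (1 << np.arange(n))
        vals, cnts = np.unique(idx, return_counts=True)
        for v, cc in zip(vals, cnts):
            k = _index_to_bitstring(int(v), n)
            noisy[k] = noisy.get(k, 0) + int(cc)
    return ShotHistogram(n, noisy, hist.shots)


def _subspace(keys: list[str], n_qubits: int) -> list[int]:
    """Observed basis indices plus all single-bit-flip neighbors, sorted."""
    seen: set[int] = set()
    for key in keys:
        idx = _bitstring_to_index(key)
        seen.add(idx)
        for i in range(n_qubits):
            seen.add(idx ^ (1 << i))
    return sorted(seen)


def mitigate(hist: ShotHistogram, calib: ReadoutCalibration) -> dict[str, float]:
    """Correct a noisy histogram into a quasi-probability map.

    Solves ``A_sub x = p`` where ``A_sub`` is the tensor-product
    confusion matrix restricted to the observed-plus-neighbor subspace
    and ``p`` the empirical frequencies, then normalizes the solution
    to unit total.  Entries may be slightly negative; see
    :func:`clip_and_renormalize` for a proper distribution.
    """
    if hist.n_qubits != calib.n_qubits:
        raise ValueError(
            f"histogram has {hist.n_qubits} qubits, calibration {calib.n_qubits}"
        )
    n = hist.n_qubits
    for i in range(n):
        if abs(np.linalg.det(calib.matrices[i])) < 1e-8:
            raise np.linalg.LinAlgError(
                f"confusion matrix of qubit {i} is (near-)singular; "
                "readout carries no information to invert"
            )
    idxs = _subspace(list(hist.counts), n)
    m = len(idxs)
    # bits[j, i] = bit i of subspace member j
    bits = (np.asarray(idxs)[:, None] >> np.arange(n)[None, :]) & 1
    A = np.ones((m, m))
    for i in range(n):
        A *= calib.matrices[i][np.ix_(bits[:, i], bits[:, i])]
    p = np.zeros(m)
    pos = {idx: j for j, idx in enumerate(idxs)}
    for key, c in hist.counts.items():
        p[pos[_bitstring_to_index(key)]] = c / hist.shots
    x = np.linalg.solve(A, p)
    x = x / x.sum()
    return {_index_to_bitstring(idx, n): float(v) for idx, v in zip(idxs, x)}


def clip_and_renormalize(quasi: dict[str, float]) -> dict[str, float]:
    """Project a quasi-probability map onto the simplex by clip-at-0 + rescale."""
    clipped = {k: max(v, 0.0) for k, v in quasi.items()}
    total = sum(clipped.values())
    if total == 0.0:
        raise ValueError("all quasi-probabilities clipped to zero")
    return {k: v / total for k, v in clipped.items()}


def total_variation(dist_a: dict[str, float], dist_b: dict[str, float]) -> float:
    """TV distance 0.5 * sum |a - b| between two bitstring distributions."""
    keys = set(dist_a) | set(dist_b)
    return 0.5 * sum(abs(dist_a.get(k, 0.0) - dist_b.get(k, 0.0)) for k in keys)
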