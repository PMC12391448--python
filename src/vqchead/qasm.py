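"""OpenQASM 2.0 export/import for the supported gate set.

Only the gates the simulator speaks — ``h``, ``ry``, ``rz``, ``u3``,
``cz`` — are emitted or parsed, on a single quantum register ``q``.
Angles are printed with ``repr`` so a round trip preserves them to full
double precision.
"""

from __future__ import annotations

import re

from .statevector import CircuitSpec, GateOp

__all__ = ["circuit_to_qasm", "circuit_from_qasm"]

_HEADER = 'OPENQASM 2.0;\ninclude "qelib1.inc";\n'

_GATE_NAMES = {"H": "h", "RY": "ry", "RZ": "rz", "U3": "u3", "CZ": "cz"}
_KIND_BY_NAME = {v: k for k, v in _GATE_NAMES.items()}

_INSTR_RE = re.compile(
    r"^\s*(h|ry|rz|u3|cz)\s*(?:\(([^)]*)\))?\s+"
    r"q\[(\d+)\]\s*(?:,\s*q\[(\d+)\])?\s*;\s*$"
)


def circuit_to_qasm(spec: CircuitSpec) -> str:
    lines = [_HEADER + f"qreg q[{spec.n_qubits}];"]
    for op in spec.ops:
        name = _GATE_NAMES[op.kind]
        args = f"({','.join(repr(a) for a in op.angles)})" if op.angles else ""
        tgts = ",".join(f"q[{t}]" for t in op.targets)
        lines.append(f"{name}{args} {tgts};")
    return "\n".join(lines) + "\n"


def circuit_from_qasm(text: str) -> CircuitSpec:
    n_qubits = None
    ops: list[GateOp] = []
    for raw in text.splitlines():
        line = raw.split("//")[0].strip()
        if not line:
            continue
        if line.startswith(("OPENQASM", "include")):
            continue
        m = re.match(r"^qreg\s+q\[(\d+)\]\s*;$", line)
        if m:
            n_qubits = int(m.group(1))
            continue
        m = _INSTR_RE.match(line)
        if m is None:
            raise ValueError(f"cannot parse QASM line: {raw!r}")
        name, args, t0, t1 = m.groups()
        angles = tuple(float(a) for a in args.split(",")) if args else ()
        targets = (int(t0),) if t1 is None else (int(t0), int(t1))
        ops.append(GateOp(_KIND_BY_NAME[name], targets, angles))
    if n_qubits is None:
        raise ValueError("QASM program has no qreg declaration")
    return CircuitSpec(n_qubits, ops)
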