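"""Random quantum-circuit segment encoder (exact statevector simulation).

A length-n segment is encoded on an n-qubit register in three steps:

1. *Angle encoding* — every qubit starts in |0⟩ and is rotated about the
   Bloch-sphere y-axis by ϕ = π·x̂_k, so a segment value x̂_k ∈ [0, 1]
   maps the qubit between |0⟩ (x̂=0) and |1⟩ (x̂=1).
2. *Random circuit* — a fixed, secret sequence of RX rotations with random
   angles and CNOT gates entangling neighbouring wires is applied.  The
   gate list (the key) is sampled once and shared between sites.
3. *Measurement* — the Pauli-Z expectation ⟨Z⟩ = P(0) − P(1) of each wire
   is read out exactly from the statevector; the n expectations are the
   encoded segment.

Expectation readout is many-to-one (distinct register states can share
identical per-wire ⟨Z⟩), which is the irreversibility argument for this
encoder as opposed to the linear projection.

Conventions: wire 0 is the most significant bit of the basis-state index,
so for n=2 the amplitude order is |00⟩, |01⟩, |10⟩, |11⟩.  Single-qubit
gates are applied in O(2^n) by reshaping the statevector, never by forming
the dense 2^n×2^n matrix (the dense product exists only as a test oracle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .framework import MinMaxStats, SegmentEncoder, ShapeError, ValidationError

__all__ = [
    "GateSpec",
    "QuantumCircuitSpec",
    "init_state",
    "apply_ry",
    "apply_rx",
    "apply_cnot",
    "apply_gate",
    "measure_z",
    "build_random_circuit",
    "quantum_encode_segment",
    "QuantumEncoder",
    "save_circuit_spec",
    "load_circuit_spec",
]


# ---------------------------------------------------------------------------
# Gate and circuit specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One gate: RY/RX on a single wire (with angle) or CNOT on a wire pair."""

    kind: str
    wires: tuple[int, ...]
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("RY", "RX", "CNOT"):
            raise ValidationError(f"unknown gate kind {self.kind!r}")
        wires = tuple(int(w) for w in self.wires)
        if self.kind == "CNOT":
            if len(wires) != 2 or wires[0] == wires[1]:
                raise ValidationError(
                    "CNOT needs an ordered (control, target) pair of distinct wires"
                )
            if self.angle is not None:
                raise ValidationError("CNOT takes no angle")
        else:
            if len(wires) != 1:
                raise ValidationError(f"{self.kind} acts on exactly one wire")
            if self.angle is None or not np.isfinite(self.angle):
                raise ValidationError(f"{self.kind} requires a finite angle")
        if any(w < 0 for w in wires):
            raise ValidationError("wire indices must be >= 0")
        object.__setattr__(self, "wires", wires)


@dataclass(frozen=True)
class QuantumCircuitSpec:
    """The random (secret) part of the encoding circuit.

    Only RX and CNOT gates are stored: the input-encoding RY rotations are
    generated per segment from the data, not from the key.
    """

    n_wires: int
    layers: int
    gates: tuple[GateSpec, ...]
    key_id: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wires < 1:
            raise ValidationError("n_wires must be >= 1")
        gates = tuple(self.gates)
        for g in gates:
            if g.kind not in ("RX", "CNOT"):
                raise ValidationError(
                    "circuit keys store only RX and CNOT gates; "
                    "input RY rotations are data-dependent"
                )
            if any(w >= self.n_wires for w in g.wires):
                raise ValidationError(
                    f"gate {g.kind} on wires {g.wires} exceeds n_wires={self.n_wires}"
                )
        object.__setattr__(self, "gates", gates)


# ---------------------------------------------------------------------------
# Statevector primitives (wire 0 = most significant bit)
# ---------------------------------------------------------------------------

def init_state(n: int) -> np.ndarray:
    """|0…0⟩ on n wires: amplitude 1 at basis index 0."""
    if n < 1:
        raise ValidationError("need at least one wire")
    state = np.zeros(2**n, dtype=complex)
    state[0] = 1.0
    return state


def _n_wires_of(state: np.ndarray) -> int:
    size = state.shape[0]
    n = int(round(np.log2(size)))
    if 2**n != size:
        raise ValidationError(f"statevector length {size} is not a power of two")
    return n


def _apply_single_qubit(state: np.ndarray, wire: int, U: np.ndarray) -> np.ndarray:
    """Apply a 2×2 unitary on one wire in O(2^n) via reshaping."""
    n = _n_wires_of(state)
    if not 0 <= wire < n:
        raise IndexError(f"wire {wire} out of range for {n}-qubit state")
    t = state.reshape(2**wire, 2, 2 ** (n - wire - 1))
    out = np.einsum("ij,ajb->aib", U, t)
    return out.reshape(-1)


def _ry_matrix(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _rx_matrix(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)


def apply_ry(state: np.ndarray, wire: int, phi: float) -> np.ndarray:
    """Rotate one wire about the y-axis: [[cos ϕ/2, −sin ϕ/2],[sin ϕ/2, cos ϕ/2]]."""
    return _apply_single_qubit(np.asarray(state, dtype=complex), wire, _ry_matrix(phi))


def apply_rx(state: np.ndarray, wire: int, phi: float) -> np.ndarray:
    """Rotate one wire about the x-axis: [[cos ϕ/2, −i sin ϕ/2],[−i sin ϕ/2, cos ϕ/2]]."""
    return _apply_single_qubit(np.asarray(state, dtype=complex), wire, _rx_matrix(phi))


def apply_cnot(state: np.ndarray, control: int, target: int) -> np.ndarray:
    """Flip the target bit of every basis state whose control bit is 1."""
    state = np.asarray(state, dtype=complex)
    n = _n_wires_of(state)
    if not (0 <= control < n and 0 <= target < n):
        raise IndexError(f"CNOT wires ({control}, {target}) out of range for n={n}")
    if control == target:
        raise ValidationError("CNOT control and target must differ")
    view = state.reshape((2,) * n).copy()
    sl: list = [slice(None)] * n
    sl[control] = 1
    sub = view[tuple(sl)]
    # slicing removed the control axis, so the target axis shifts down past it
    axis = target if target < control else target - 1
    view[tuple(sl)] = np.flip(sub, axis=axis)
    return view.reshape(-1)


def apply_gate(state: np.ndarray, gate: GateSpec) -> np.ndarray:
    if gate.kind == "RY":
        return apply_ry(state, gate.wires[0], gate.angle)
    if gate.kind == "RX":
        return apply_rx(state, gate.wires[0], gate.angle)
    return apply_cnot(state, gate.wires[0], gate.wires[1])


def measure_z(state: np.ndarray, wire: int) -> float:
    """Pauli-Z expectation on one wire: P(wire=0) − P(wire=1).

    Non-destructive — computed exactly from the statevector, no shots.
    """
    state = np.asarray(state, dtype=complex)
    n = _n_wires_of(state)
    if not 0 <= wire < n:
        raise IndexError(f"wire {wire} out of range for {n}-qubit state")
    probs = np.abs(state) ** 2
    view = probs.reshape((2,) * n)
    return float(view.take(0, axis=wire).sum() - view.take(1, axis=wire).sum())


# ---------------------------------------------------------------------------
# Random circuit construction
# ---------------------------------------------------------------------------

def build_random_circuit(
    n_wires: int, layers: int, seed: int, key_id: str | None = None
) -> QuantumCircuitSpec:
    """Sample the secret circuit: per layer, RX(ϕ~U[0,2π)) on every wire,
    then a CNOT ladder (control i → target i+1) entangling all wires."""
    if n_wires < 2:
        raise ValidationError(
            "need n_wires >= 2: a single wire admits no entangling CNOT ladder"
        )
    if layers < 1:
        raise ValidationError("layers must be >= 1")
    rng = np.random.default_rng(seed)
    gates: list[GateSpec] = []
    for _ in range(layers):
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n_wires)
        for w in range(n_wires):
            gates.append(GateSpec(kind="RX", wires=(w,), angle=float(angles[w])))
        for w in range(n_wires - 1):
            gates.append(GateSpec(kind="CNOT", wires=(w, w + 1)))
    return QuantumCircuitSpec(
        n_wires=n_wires,
        layers=layers,
        gates=tuple(gates),
        key_id=key_id or f"qc-n{n_wires}-L{layers}-s{seed}",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Segment encoding
# ---------------------------------------------------------------------------

def quantum_encode_segment(
    seg: np.ndarray, circuit: QuantumCircuitSpec
) -> np.ndarray:
    """Encode one segment: RY(π·x̂_k) per wire, circuit gates, ⟨Z⟩ per wire."""
    seg = np.asarray(seg, dtype=float)
    if seg.shape != (circuit.n_wires,):
        raise ShapeError(
            f"segment length {seg.shape} does not match circuit wires "
            f"{circuit.n_wires}"
        )
    state = init_state(circuit.n_wires)
    for w, x in enumerate(seg):
        state = apply_ry(state, w, np.pi * x)
    for gate in circuit.gates:
        state = apply_gate(state, gate)
    return np.array(
        [measure_z(state, w) for w in range(circuit.n_wires)], dtype=float
    )


class QuantumEncoder(SegmentEncoder):
    """Segment encoder wrapping a :class:`QuantumCircuitSpec`.

    ``encode_batch`` simulates all segments simultaneously (one vectorized
    statevector array of shape (m, 2^n)), which is what makes encoding
    whole cohorts tractable; it is exactly equivalent to the per-segment
    path.
    """

    method = "quantum"

    def __init__(self, circuit: QuantumCircuitSpec):
        self.circuit = circuit
        self.n = circuit.n_wires
        self.key_id = circuit.key_id

    def encode_segment(self, seg: np.ndarray) -> np.ndarray:
        return quantum_encode_segment(seg, self.circuit)

    def encode_batch(self, segments: np.ndarray) -> np.ndarray:
        segments = np.asarray(segments, dtype=float)
        if segments.ndim != 2 or segments.shape[1] != self.n:
            raise ShapeError(f"expected (m, {self.n}) segment stack")
        m, n = segments.shape
        if m == 0:
            return segments.copy()

        # initial product state from the data-dependent RY rotations:
        # each qubit k is [cos(π x̂_k / 2), sin(π x̂_k / 2)]
        half = np.pi * segments / 2.0
        c, s = np.cos(half), np.sin(half)
        states = np.ones((m, 1), dtype=complex)
        for w in range(n):
            qubit = np.stack([c[:, w], s[:, w]], axis=1)  # (m, 2)
            states = (states[:, :, None] * qubit[:, None, :]).reshape(m, -1)

        for gate in self.circuit.gates:
            if gate.kind == "RX":
                w = gate.wires[0]
                U = _rx_matrix(gate.angle)
                t = states.reshape(m, 2**w, 2, 2 ** (n - w - 1))
                states = np.einsum("ij,majb->maib", U, t).reshape(m, -1)
            else:  # CNOT
                control, target = gate.wires
                view = states.reshape((m,) + (2,) * n).copy()
                sl: list = [slice(None)] * (n + 1)
                sl[1 + control] = 1
                axis = 1 + (target if target < control else target - 1)
                view[tuple(sl)] = np.flip(view[tuple(sl)], axis=axis)
                states = view.reshape(m, -1)

        probs = (np.abs(states) ** 2).reshape((m,) + (2,) * n)
        out = np.empty((m, n), dtype=float)
        for w in range(n):
            p0 = probs.take(0, axis=1 + w).reshape(m, -1).sum(axis=1)
            p1 = probs.take(1, axis=1 + w).reshape(m, -1).sum(axis=1)
            out[:, w] = p0 - p1
        return out


# ---------------------------------------------------------------------------
# Key file I/O
# ---------------------------------------------------------------------------

def save_circuit_spec(
    circuit: QuantumCircuitSpec,
    path: str | Path,
    scaling: MinMaxStats | None = None,
) -> None:
    """Serialize the circuit key (and optional frozen scaling stats) to JSON."""
    payload = {
        "schema": "enctsf/quantum-key/v1",
        "method": "quantum",
        "n_wires": circuit.n_wires,
        "layers": circuit.layers,
        "key_id": circuit.key_id,
        "seed": circuit.seed,
        "gates": [
            {"kind": g.kind, "wires": list(g.wires)}
            | ({"angle": g.angle} if g.angle is not None else {})
            for g in circuit.gates
        ],
    }
    if scaling is not None:
        payload["scaling"] = scaling.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1))


def load_circuit_spec(
    path: str | Path,
) -> tuple[QuantumCircuitSpec, MinMaxStats | None]:
    """Load a circuit key file; returns the spec and any embedded scaling stats."""
    payload = json.loads(Path(path).read_text())
    if payload.get("method") != "quantum":
        raise ValidationError(f"{path} is not a quantum circuit key file")
    gates = tuple(
        GateSpec(
            kind=g["kind"],
            wires=tuple(g["wires"]),
            angle=g.get("angle"),
        )
        for g in payload["gates"]
    )
    spec = QuantumCircuitSpec(
        n_wires=int(payload["n_wires"]),
        layers=int(payload["layers"]),
        gates=gates,
        key_id=str(payload["key_id"]),
        seed=int(payload.get("seed", 0)),
    )
    scaling = (
        MinMaxStats.from_dict(payload["scaling"]) if "scaling" in payload else None
    )
    return spec, scaling
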