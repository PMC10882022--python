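"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive: the quantum oracle forms every gate as a
dense 2^n×2^n matrix (Kronecker products / explicit basis permutation) and
multiplies them out, the AUROC oracle counts discordant pairs exhaustively,
and the Gaussian MI closed form comes from the bivariate normal copula.
They share no code with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np


def dense_single_qubit(U: np.ndarray, wire: int, n: int) -> np.ndarray:
    """Embed a 2×2 unitary on ``wire`` into the full 2^n×2^n space.

    Wire 0 is the most significant bit, so it sits leftmost in the
    Kronecker product chain.
    """
    mat = np.eye(1, dtype=complex)
    for w in range(n):
        mat = np.kron(mat, U if w == wire else np.eye(2, dtype=complex))
    return mat


def dense_cnot(control: int, target: int, n: int) -> np.ndarray:
    """Full-space CNOT built by permuting basis states explicitly."""
    dim = 2**n
    mat = np.zeros((dim, dim), dtype=complex)
    for j in range(dim):
        # wire w holds bit (n-1-w) of the basis index (wire 0 = MSB)
        cbit = (j >> (n - 1 - control)) & 1
        out = j ^ (1 << (n - 1 - target)) if cbit else j
        mat[out, j] = 1.0
    return mat


def dense_ry(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2), np.sin(phi / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def dense_rx(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2), np.sin(phi / 2)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)


def dense_encode_segment(seg: np.ndarray, gates: list) -> np.ndarray:
    """Oracle for the whole encoding: dense unitary product applied to
    |0...0>, then marginal ⟨Z⟩ per wire.

    ``gates`` is a list of ("RX"|"CNOT", wires, angle-or-None) tuples —
    the circuit's stored gates; the data-dependent RY encoding rotations
    are prepended here from ``seg``.
    """
    seg = np.asarray(seg, dtype=float)
    n = seg.shape[0]
    dim = 2**n
    U = np.eye(dim, dtype=complex)
    for w, x in enumerate(seg):
        U = dense_single_qubit(dense_ry(np.pi * x), w, n) @ U
    for kind, wires, angle in gates:
        if kind == "RX":
            G = dense_single_qubit(dense_rx(angle), wires[0], n)
        elif kind == "CNOT":
            G = dense_cnot(wires[0], wires[1], n)
        else:
            raise ValueError(kind)
        U = G @ U
    psi = U[:, 0]  # U |0...0>
    probs = np.abs(psi) ** 2
    out = np.empty(n)
    for w in range(n):
        bit = (np.arange(dim) >> (n - 1 - w)) & 1
        out[w] = probs[bit == 0].sum() - probs[bit == 1].sum()
    return out


def pair_counting_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by exhaustive counting over all label-discordant pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def gaussian_mi_nats(rho: float) -> float:
    """Closed-form MI of a bivariate normal with correlation rho."""
    return -0.5 * np.log(1.0 - rho**2)
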