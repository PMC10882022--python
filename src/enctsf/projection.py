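"""Random-projection segment encoder.

Each length-n segment x̂ is encoded as e = R x̂, where R is an n×n matrix
with i.i.d. N(0, 1/n) entries sampled once and then shared as the secret
key.  With this variance the expected squared norm of R x̂ equals ‖x̂‖²
(the Johnson–Lindenstrauss-style geometry preservation that motivates
random projections), but here n→n: the point is imperceptibility, not
dimensionality reduction.

The transform is linear and the matrix is square, so it is *reversible*
given enough (input, output) pairs — a known weakness relative to the
quantum encoder, demonstrated in the test suite by least-squares recovery
of R.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .framework import MinMaxStats, SegmentEncoder, ShapeError, ValidationError

__all__ = [
    "ProjectionKey",
    "sample_projection_key",
    "project_segment",
    "ProjectionEncoder",
    "save_projection_key",
    "load_projection_key",
]


@dataclass(frozen=True)
class ProjectionKey:
    """An n×n Gaussian projection matrix plus provenance.

    The stored matrix, not the seed, is authoritative: a key loaded from
    file encodes identically regardless of how it was first sampled.
    """

    matrix: np.ndarray
    n: int
    key_id: str
    seed: int = 0

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (self.n, self.n):
            raise ValidationError(
                f"projection matrix must be {self.n}×{self.n}, got {matrix.shape}"
            )
        if not np.all(np.isfinite(matrix)):
            raise ValidationError("projection matrix entries must be finite")
        object.__setattr__(self, "matrix", matrix)


def sample_projection_key(
    n: int, seed: int, key_id: str | None = None
) -> ProjectionKey:
    """Sample an n×n key with i.i.d. N(0, 1/n) entries, reproducibly."""
    if n < 1:
        raise ValidationError("projection dimension n must be >= 1")
    rng = np.random.default_rng(seed)
    matrix = rng.normal(loc=0.0, scale=np.sqrt(1.0 / n), size=(n, n))
    return ProjectionKey(
        matrix=matrix,
        n=n,
        key_id=key_id or f"proj-n{n}-s{seed}",
        seed=seed,
    )


def project_segment(seg: np.ndarray, key: ProjectionKey) -> np.ndarray:
    """Exact matrix–vector product R·x̂; no normalization or rounding."""
    seg = np.asarray(seg, dtype=float)
    if seg.shape != (key.n,):
        raise ShapeError(
            f"segment length {seg.shape} does not match key dimension {key.n}"
        )
    return key.matrix @ seg


class ProjectionEncoder(SegmentEncoder):
    """Segment encoder wrapping a :class:`ProjectionKey`."""

    method = "projection"

    def __init__(self, key: ProjectionKey):
        self.key = key
        self.n = key.n
        self.key_id = key.key_id

    def encode_segment(self, seg: np.ndarray) -> np.ndarray:
        return project_segment(seg, self.key)

    def encode_batch(self, segments: np.ndarray) -> np.ndarray:
        segments = np.asarray(segments, dtype=float)
        if segments.ndim != 2 or segments.shape[1] != self.n:
            raise ShapeError(f"expected (m, {self.n}) segment stack")
        return segments @ self.key.matrix.T


def save_projection_key(
    key: ProjectionKey,
    path: str | Path,
    scaling: MinMaxStats | None = None,
) -> None:
    """Serialize a key (and optional frozen scaling statistics) to JSON."""
    payload = {
        "schema": "enctsf/projection-key/v1",
        "method": "projection",
        "n": key.n,
        "key_id": key.key_id,
        "seed": key.seed,
        "matrix": key.matrix.ravel().tolist(),  # row-major, full precision
    }
    if scaling is not None:
        payload["scaling"] = scaling.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1))


def load_projection_key(
    path: str | Path,
) -> tuple[ProjectionKey, MinMaxStats | None]:
    """Load a key file; returns the key and any embedded scaling stats."""
    payload = json.loads(Path(path).read_text())
    if payload.get("method") != "projection":
        raise ValidationError(f"{path} is not a projection key file")
    n = int(payload["n"])
    key = ProjectionKey(
        matrix=np.asarray(payload["matrix"], dtype=float).reshape(n, n),
        n=n,
        key_id=str(payload["key_id"]),
        seed=int(payload.get("seed", 0)),
    )
    scaling = (
        MinMaxStats.from_dict(payload["scaling"]) if "scaling" in payload else None
    )
    return key, scaling
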