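"""Core data model and segment-wise encoding orchestration.

A multivariate clinical time-series is a grid of F features (vitals, labs,
scores) observed at T uniformly spaced time-steps.  Encoding proceeds
feature by feature: each 1-d signal is cut into fixed-length segments and a
segment encoder — a random projection or a random quantum circuit — is
applied to every segment independently.  Encoded segments are concatenated
back in time order, so the encoded series has exactly the shape of the
input and row i of the output depends only on row i of the input (no
cross-feature mixing, which is what lets the encoded data keep per-feature
semantics).
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "DivisibilityError",
    "ShapeError",
    "MultivariateTimeSeries",
    "Segment",
    "EncodedTimeSeries",
    "FrameworkConfig",
    "MinMaxStats",
    "SegmentEncoder",
    "IdentityEncoder",
    "segment_signal",
    "scale_minmax",
    "compute_minmax_stats",
    "encode_timeseries",
    "write_wide_csv",
    "read_wide_csv",
    "write_long_csv",
    "read_long_csv",
]


class ValidationError(ValueError):
    """Input data violates an invariant (non-finite values, bad shapes...)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (encoder/segment mismatch, missing stats...)."""


class DivisibilityError(ValidationError):
    """Signal length not divisible by the segment length under strict policy."""


class ShapeError(ValidationError):
    """Dimension mismatch between a segment and an encoding key."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultivariateTimeSeries:
    """One example: an F×T real-valued grid of F features over T time-steps.

    Parameters
    ----------
    values
        Array of shape (F, T); every entry must be finite (imputation is an
        upstream concern — encoding NaNs is undefined).
    feature_names
        F unique feature labels.
    example_id
        Stable identifier for the example (e.g. an ICU-stay id).
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    example_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError(
                f"values must be a 2-d F×T array with F,T >= 1, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(
                f"example {self.example_id!r} contains non-finite values; "
                "impute or drop missing data before encoding"
            )
        names = tuple(str(n) for n in self.feature_names)
        if len(names) != values.shape[0]:
            raise ValidationError(
                f"{len(names)} feature names for {values.shape[0]} rows"
            )
        if len(set(names)) != len(names):
            raise ValidationError("feature_names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "example_id", str(self.example_id))

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Segment:
    """A length-n chunk of one 1-d signal; ``index`` is its 1-based position."""

    samples: np.ndarray
    index: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("segment samples must be a non-empty 1-d vector")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("segment contains non-finite samples")
        if self.index < 1:
            raise ValidationError("segment index is 1-based and must be >= 1")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class EncodedTimeSeries:
    """Encoded counterpart of a :class:`MultivariateTimeSeries`.

    Shape is identical to the source series.  For quantum encoding every
    entry is a Pauli-Z expectation and therefore lies in [−1, 1].
    """

    values: np.ndarray
    key_id: str
    method: str
    feature_names: tuple[str, ...] = ()
    example_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("encoded values must be a 2-d F×T array")
        if self.method not in ("projection", "quantum", "identity"):
            raise ValidationError(f"unknown encoding method {self.method!r}")
        if self.method == "quantum" and values.size:
            lo, hi = values.min(), values.max()
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValidationError(
                    f"quantum-encoded values must lie in [-1, 1], got range [{lo}, {hi}]"
                )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))


@dataclass(frozen=True)
class FrameworkConfig:
    """Encoding-run configuration.

    segment_length is the paper-level default n=4; under the strict edge
    policy T must be divisible by it.  ``pad_zero_trim`` zero-pads the
    signal to the next multiple of n before encoding and trims the output
    back to T.  ``minmax_01`` rescales every feature to [0, 1] using frozen
    reference statistics (required for quantum angle encoding so RY angles
    stay in [0, π]).
    """

    segment_length: int = 4
    edge_policy: str = "strict"
    input_scaling: str = "minmax_01"
    key_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_length < 1:
            raise ConfigurationError("segment_length must be >= 1")
        if self.edge_policy not in ("strict", "pad_zero_trim"):
            raise ConfigurationError(f"unknown edge_policy {self.edge_policy!r}")
        if self.input_scaling not in ("none", "minmax_01"):
            raise ConfigurationError(f"unknown input_scaling {self.input_scaling!r}")


# ---------------------------------------------------------------------------
# Min-max scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinMaxStats:
    """Frozen per-feature reference minima/maxima (computed on a training split)."""

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        if mins.shape != maxs.shape or mins.ndim != 1:
            raise ValidationError("mins/maxs must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(mins)) and np.all(np.isfinite(maxs))):
            raise ValidationError("scaling statistics must be finite")
        if np.any(maxs < mins):
            raise ValidationError("per-feature max must be >= min")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MinMaxStats":
        return cls(
            feature_names=tuple(d["feature_names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
        )


def compute_minmax_stats(
    examples: Iterable[MultivariateTimeSeries],
) -> MinMaxStats:
    """Per-feature min/max pooled over a collection of examples."""
    examples = list(examples)
    if not examples:
        raise ValidationError("cannot compute scaling statistics from zero examples")
    names = examples[0].feature_names
    for ex in examples:
        if ex.feature_names != names:
            raise ValidationError("examples have inconsistent feature names")
    stacked = np.stack([ex.values for ex in examples])  # (N, F, T)
    return MinMaxStats(
        feature_names=names,
        mins=stacked.min(axis=(0, 2)),
        maxs=stacked.max(axis=(0, 2)),
    )


def scale_minmax(
    X: MultivariateTimeSeries, stats: MinMaxStats
) -> MultivariateTimeSeries:
    """Affinely map each feature to [0, 1] using reference statistics.

    Constant features (max == min) map to 0.5; values outside the reference
    range are clipped into [0, 1].
    """
    if stats.mins.shape[0] != X.n_features:
        raise ShapeError(
            f"scaling stats cover {stats.mins.shape[0]} features, "
            f"example has {X.n_features}"
        )
    span = stats.maxs - stats.mins
    scaled = np.empty_like(X.values)
    const = span == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (X.values - stats.mins[:, None]) / span[:, None]
    scaled[const, :] = 0.5
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return MultivariateTimeSeries(
        values=scaled, feature_names=X.feature_names, example_id=X.example_id
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _segment_matrix(x: np.ndarray, n: int, edge_policy: str) -> np.ndarray:
    """Segments of ``x`` as a (ceil(T/n), n) matrix, zero-padding if allowed."""
    T = x.shape[0]
    if T % n != 0:
        if edge_policy == "strict":
            raise DivisibilityError(
                f"signal length T={T} is not divisible by segment length n={n} "
                "under the strict edge policy; use pad_zero_trim to zero-pad"
            )
        pad = (-T) % n
        x = np.concatenate([x, np.zeros(pad)])
    return x.reshape(-1, n)


def segment_signal(
    x: Sequence[float] | np.ndarray, n: int, edge_policy: str = "strict"
) -> list[Segment]:
    """Divide a 1-d signal into consecutive segments of length ``n``.

    Concatenating the returned segments in index order reproduces ``x``
    (strict) or ``x`` zero-padded to the next multiple of ``n``
    (pad_zero_trim).
    """
    if n < 1:
        raise ValidationError("segment length n must be >= 1")
    if edge_policy not in ("strict", "pad_zero_trim"):
        raise ConfigurationError(f"unknown edge_policy {edge_policy!r}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("signal must be a non-empty 1-d vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")
    mat = _segment_matrix(x, n, edge_policy)
    return [Segment(samples=row, index=j + 1) for j, row in enumerate(mat)]


# ---------------------------------------------------------------------------
# Segment encoders
# ---------------------------------------------------------------------------

class SegmentEncoder(abc.ABC):
    """A transformation f applied independently to every length-n segment."""

    #: segment length the encoder accepts
    n: int
    #: encoding method tag stored on outputs
    method: str = "identity"
    #: identifier of the key backing this encoder
    key_id: str = ""

    @abc.abstractmethod
    def encode_segment(self, seg: np.ndarray) -> np.ndarray:
        """Encode one length-n segment into a length-n vector."""

    def encode_batch(self, segments: np.ndarray) -> np.ndarray:
        """Encode a (m, n) stack of segments; default loops over rows."""
        segments = np.asarray(segments, dtype=float)
        return np.stack([self.encode_segment(row) for row in segments])


class IdentityEncoder(SegmentEncoder):
    """Null encoder — useful as a framework/control baseline."""

    method = "identity"

    def __init__(self, n: int, key_id: str = "identity"):
        if n < 1:
            raise ValidationError("segment length n must be >= 1")
        self.n = int(n)
        self.key_id = key_id

    def encode_segment(self, seg: np.ndarray) -> np.ndarray:
        seg = np.asarray(seg, dtype=float)
        if seg.shape != (self.n,):
            raise ShapeError(f"expected segment of length {self.n}, got {seg.shape}")
        return seg.copy()

    def encode_batch(self, segments: np.ndarray) -> np.ndarray:
        segments = np.asarray(segments, dtype=float)
        if segments.ndim != 2 or segments.shape[1] != self.n:
            raise ShapeError(f"expected (m, {self.n}) segment stack")
        return segments.copy()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def encode_timeseries(
    X: MultivariateTimeSeries,
    encoder: SegmentEncoder,
    cfg: FrameworkConfig,
    stats: MinMaxStats | None = None,
) -> EncodedTimeSeries:
    """Encode every 1-d signal of ``X`` segment-wise with ``encoder``.

    Each feature row is segmented into chunks of ``cfg.segment_length``,
    each chunk encoded independently, and the encoded chunks concatenated
    back in time order.  The output has exactly the input's F×T shape
    (padding, if any, is trimmed) and row i depends only on input row i.
    """
    if encoder.n != cfg.segment_length:
        raise ConfigurationError(
            f"encoder segment size {encoder.n} != configured "
            f"segment_length {cfg.segment_length}"
        )
    if cfg.input_scaling == "minmax_01":
        if stats is None:
            raise ConfigurationError(
                "input_scaling='minmax_01' requires reference MinMaxStats "
                "(compute them on the training split and freeze them in the key)"
            )
        X = scale_minmax(X, stats)

    F, T = X.values.shape
    n = cfg.segment_length
    if T % n != 0 and cfg.edge_policy == "strict":
        raise DivisibilityError(
            f"T={T} not divisible by n={n} under strict edge policy"
        )
    pad = (-T) % n
    vals = X.values
    if pad:
        vals = np.concatenate([vals, np.zeros((F, pad))], axis=1)
    m = vals.shape[1] // n
    # all segments of all features as one (F*m, n) batch; per-segment
    # independence makes this reshuffle-safe
    segments = vals.reshape(F, m, n).reshape(F * m, n)
    encoded = encoder.encode_batch(segments)
    if encoded.shape != segments.shape:
        raise ShapeError(
            f"encoder returned shape {encoded.shape} for input {segments.shape}; "
            "segment encoders must preserve dimensions"
        )
    out = encoded.reshape(F, m * n)[:, :T]
    return EncodedTimeSeries(
        values=out,
        key_id=encoder.key_id or cfg.key_id,
        method=encoder.method,
        feature_names=X.feature_names,
        example_id=X.example_id,
    )


# ---------------------------------------------------------------------------
# Tabular dataset I/O (wide and long CSV dialects)
# ---------------------------------------------------------------------------

def write_wide_csv(
    examples: Sequence[MultivariateTimeSeries] | Sequence[EncodedTimeSeries],
    path: str | Path,
) -> None:
    """Write examples as wide CSV: example_id, feature, t0 ... t{T-1}."""
    rows = []
    for ex in examples:
        T = ex.values.shape[1]
        for f, name in enumerate(ex.feature_names):
            rows.append(
                {"example_id": ex.example_id, "feature": name}
                | {f"t{t}": ex.values[f, t] for t in range(T)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_wide_csv(path: str | Path) -> list[MultivariateTimeSeries]:
    """Read a wide-format CSV back into a list of examples."""
    df = pd.read_csv(path, dtype={"example_id": str, "feature": str})
    required = {"example_id", "feature"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"wide CSV {path} must contain columns {sorted(required)}"
        )
    tcols = sorted(
        (c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not tcols:
        raise ValidationError(f"wide CSV {path} has no time-step columns t0..")
    out = []
    for ex_id, grp in df.groupby("example_id", sort=True):
        out.append(
            MultivariateTimeSeries(
                values=grp[tcols].to_numpy(dtype=float),
                feature_names=tuple(grp["feature"]),
                example_id=str(ex_id),
            )
        )
    return out


def write_long_csv(
    examples: Sequence[MultivariateTimeSeries] | Sequence[EncodedTimeSeries],
    path: str | Path,
) -> None:
    """Write examples as long CSV: example_id, feature, time, value."""
    frames = []
    for ex in examples:
        F, T = ex.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "example_id": np.repeat(ex.example_id, F * T),
                    "feature": np.repeat(list(ex.feature_names), T),
                    "time": np.tile(np.arange(T), F),
                    "value": ex.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_long_csv(path: str | Path) -> list[MultivariateTimeSeries]:
    """Read a long-format CSV back into a list of examples."""
    df = pd.read_csv(path, dtype={"example_id": str, "feature": str})
    required = {"example_id", "feature", "time", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"long CSV {path} must contain columns {sorted(required)}"
        )
    out = []
    for ex_id, grp in df.groupby("example_id", sort=True):
        pivot = grp.pivot_table(
            index="feature", columns="time", values="value", sort=False
        )
        pivot = pivot[sorted(pivot.columns)]
        out.append(
            MultivariateTimeSeries(
                values=pivot.to_numpy(dtype=float),
                feature_names=tuple(pivot.index),
                example_id=str(ex_id),
            )
        )
    return out
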