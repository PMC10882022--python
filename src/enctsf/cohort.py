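"""Synthetic ICU-style cohort generator.

Emulates the *structure* of credentialed ICU benchmarks (multivariate
vitals/labs grids with a binary outcome, a sex-like binary attribute and an
ethnicity-like multiclass attribute, outcome prevalence around 14%) with a
fully documented generative model, so every encoder and the leakage
harness can be exercised without any data download:

* outcome  y ~ Bernoulli(prevalence);
* each latent attribute is uniform over its classes, independent of y;
* feature f of example i is a sinusoid with a feature-specific frequency
  and phase, plus a linear drift ramp whose per-feature coefficient is
  - ``task_effect_size``·y on a designated 25% of features (outcome
    signal), and
  - a fixed class-specific random coefficient scaled by the attribute's
    effect size on a block of 25% of features that half-overlaps the
    outcome block (latent signal),
  plus i.i.d. Gaussian noise with standard deviation ``noise_sd``.

Both planted effects are linear in the raw features, so a linear probe can
recover them.  Crucially, outcome and attributes share the drift *template*
on overlapping features: a model that extracts temporal drift for the
target task inevitably co-extracts the attribute coefficients, which is
what makes its embedding leak — and makes the leak shrink when encoding
blunts the extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .framework import (
    MultivariateTimeSeries,
    ValidationError,
    read_long_csv,
    read_wide_csv,
    write_long_csv,
    write_wide_csv,
)

__all__ = [
    "AttributeSpec",
    "CohortConfig",
    "CohortDataset",
    "generate_cohort",
    "cohort_to_files",
    "load_cohort",
]


@dataclass(frozen=True)
class AttributeSpec:
    """A latent categorical attribute: name, class count, planted effect size."""

    name: str
    n_classes: int
    effect_size: float

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("attributes need at least 2 classes")
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect_size must be finite")


def _default_attrs() -> tuple[AttributeSpec, ...]:
    return (
        AttributeSpec("sex", 2, 0.8),
        AttributeSpec("ethnicity", 4, 0.8),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration.

    Defaults mirror a PhysioNet-like cohort at desk scale: F=44 features,
    T=48 hourly steps, 14% outcome prevalence, one binary and one 4-class
    latent attribute.
    """

    n_examples: int = 2000
    F: int = 44
    T: int = 48
    prevalence: float = 0.14
    latent_attrs: tuple[AttributeSpec, ...] = field(default_factory=_default_attrs)
    task_effect_size: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)

    def __post_init__(self) -> None:
        if self.n_examples < 1 or self.F < 1 or self.T < 1:
            raise ValidationError("n_examples, F, T must all be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValidationError("split_fractions must sum to 1")
        if any(f < 0 for f in self.split_fractions):
            raise ValidationError("split_fractions must be non-negative")
        object.__setattr__(self, "latent_attrs", tuple(self.latent_attrs))


@dataclass
class CohortDataset:
    """A labelled cohort: examples, outcome labels, latent attributes, splits."""

    examples: list[MultivariateTimeSeries]
    task_labels: np.ndarray
    attributes: dict[str, np.ndarray]
    split: np.ndarray  # per-example tag in {train, validation, test}

    def __post_init__(self) -> None:
        N = len(self.examples)
        self.task_labels = np.asarray(self.task_labels, dtype=int)
        self.split = np.asarray(self.split, dtype=object)
        if self.task_labels.shape != (N,) or self.split.shape != (N,):
            raise ValidationError("labels/split not aligned with examples")
        for name, vals in self.attributes.items():
            vals = np.asarray(vals, dtype=int)
            if vals.shape != (N,):
                raise ValidationError(f"attribute {name!r} not aligned with examples")
            self.attributes[name] = vals
        if N >= 10:
            for tag in ("train", "validation", "test"):
                if not np.any(self.split == tag):
                    raise ValidationError(f"split {tag!r} is empty")

    def __len__(self) -> int:
        return len(self.examples)

    def values_array(self) -> np.ndarray:
        """All examples stacked as (N, F, T)."""
        return np.stack([ex.values for ex in self.examples])

    def mask(self, tag: str) -> np.ndarray:
        return self.split == tag

    def with_examples(self, examples: list[MultivariateTimeSeries]) -> "CohortDataset":
        """Same labels/attributes/splits on a transformed set of examples."""
        if len(examples) != len(self.examples):
            raise ValidationError("replacement example count mismatch")
        return CohortDataset(
            examples=list(examples),
            task_labels=self.task_labels.copy(),
            attributes={k: v.copy() for k, v in self.attributes.items()},
            split=self.split.copy(),
        )


def _blocks(cfg: CohortConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Feature index blocks carrying the outcome and attribute effects.

    Every attribute uses the same block, shifted half a block past the
    outcome block so the two overlap on half their features.
    """
    q = max(1, round(cfg.F / 4))
    task_idx = np.arange(0, min(q, cfg.F))
    start = q // 2
    attr_idx = {a.name: (start + np.arange(q)) % cfg.F for a in cfg.latent_attrs}
    return task_idx, attr_idx


def generate_cohort(cfg: CohortConfig) -> CohortDataset:
    """Sample a cohort from the documented generative model, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    N, F, T = cfg.n_examples, cfg.F, cfg.T

    # fixed per-feature baseline geometry (part of the cohort identity)
    freqs = rng.uniform(1.0, 4.0, size=F)  # cycles over the full window
    phases = rng.uniform(0.0, 2.0 * np.pi, size=F)
    t = np.arange(T) / T
    baseline = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])

    y = (rng.random(N) < cfg.prevalence).astype(int)
    attributes = {
        a.name: rng.integers(0, a.n_classes, size=N) for a in cfg.latent_attrs
    }

    task_idx, attr_idx = _blocks(cfg)
    ramp = np.arange(T) / max(T - 1, 1)  # linear drift template in [0, 1]

    # per-example per-feature drift coefficient: the outcome adds a uniform
    # coefficient on its block; each attribute class adds its own fixed
    # random coefficient pattern on the half-overlapping block
    drift = np.zeros((N, F))
    drift[:, task_idx] += cfg.task_effect_size * y[:, None]
    for a in cfg.latent_attrs:
        block = attr_idx[a.name]
        patterns = rng.normal(0.0, 0.5, size=(a.n_classes, block.size))
        drift[:, block] += a.effect_size * patterns[attributes[a.name], :]

    noise = rng.normal(0.0, cfg.noise_sd, size=(N, F, T))
    values = baseline[None, :, :] + drift[:, :, None] * ramp[None, None, :] + noise

    feature_names = tuple(f"f{j:03d}" for j in range(F))
    examples = [
        MultivariateTimeSeries(
            values=values[i], feature_names=feature_names, example_id=f"ex{i:05d}"
        )
        for i in range(N)
    ]

    # seeded permutation split respecting the fractions
    perm = rng.permutation(N)
    n_train = int(round(cfg.split_fractions[0] * N))
    n_val = int(round(cfg.split_fractions[1] * N))
    split = np.empty(N, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train : n_train + n_val]] = "validation"
    split[perm[n_train + n_val :]] = "test"

    return CohortDataset(
        examples=examples, task_labels=y, attributes=attributes, split=split
    )


# ---------------------------------------------------------------------------
# File round-trip
# ---------------------------------------------------------------------------

def cohort_to_files(
    ds: CohortDataset, directory: str | Path, fmt: str = "wide"
) -> None:
    """Write a cohort as series CSV (wide or long dialect) plus labels CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "wide":
        write_wide_csv(ds.examples, directory / "series_wide.csv")
    elif fmt == "long":
        write_long_csv(ds.examples, directory / "series_long.csv")
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    labels = pd.DataFrame(
        {
            "example_id": [ex.example_id for ex in ds.examples],
            "task_label": ds.task_labels,
            "split": ds.split,
        }
        | {name: vals for name, vals in ds.attributes.items()}
    )
    labels.to_csv(directory / "labels.csv", index=False)


def load_cohort(directory: str | Path) -> CohortDataset:
    """Load a cohort written by :func:`cohort_to_files` (either dialect)."""
    directory = Path(directory)
    wide, long = directory / "series_wide.csv", directory / "series_long.csv"
    if wide.exists():
        examples = read_wide_csv(wide)
    elif long.exists():
        examples = read_long_csv(long)
    else:
        raise ValidationError(f"no series CSV found under {directory}")
    labels_path = directory / "labels.csv"
    if not labels_path.exists():
        raise ValidationError(f"missing labels file {labels_path}")
    labels = pd.read_csv(labels_path, dtype={"example_id": str})
    required = {"example_id", "task_label", "split"}
    if not required.issubset(labels.columns):
        raise ValidationError(
            f"labels CSV must contain columns {sorted(required)}"
        )
    labels = labels.set_index("example_id")
    try:
        labels = labels.loc[[ex.example_id for ex in examples]]
    except KeyError as err:
        raise ValidationError(f"labels missing for some examples: {err}") from err
    attr_cols = [c for c in labels.columns if c not in ("task_label", "split")]
    return CohortDataset(
        examples=examples,
        task_labels=labels["task_label"].to_numpy(dtype=int),
        attributes={c: labels[c].to_numpy(dtype=int) for c in attr_cols},
        split=labels["split"].to_numpy(dtype=object),
    )
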