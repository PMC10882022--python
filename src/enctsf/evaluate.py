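"""Leakage evaluation harness.

Desk-scale protocol for quantifying what a trained model gives away:

1. train a target-task model (binary outcome) that exposes its penultimate
   embedding;
2. *probe* the frozen embedding for latent patient attributes with a single
   dense layer — probe AUROC measures latent information leakage;
3. estimate mutual information (MI) between the model's input (averaged or
   vectorized over time) and the embedding with the Kraskov–Stögbauer–
   Grassberger k-nearest-neighbour estimator — an information-bottleneck
   diagnostic: embeddings that retain less input information should leak
   less;
4. repeat per encoding condition (original / projection / quantum) and over
   seeds, and report relative drops 100·(orig − enc)/orig.

AUROC is computed by the rank-based Mann–Whitney formula with tie
correction; sklearn's implementation is used only as a cross-check in the
test suite.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import rankdata

from .cohort import CohortConfig, CohortDataset, generate_cohort
from .framework import (
    ConfigurationError,
    FrameworkConfig,
    MinMaxStats,
    MultivariateTimeSeries,
    SegmentEncoder,
    ValidationError,
    compute_minmax_stats,
    encode_timeseries,
    scale_minmax,
)
from .projection import ProjectionEncoder, sample_projection_key
from .quantum import QuantumEncoder, build_random_circuit

__all__ = [
    "TrainingError",
    "auroc",
    "macro_auroc",
    "EmbeddingModel",
    "LinearModel",
    "MLPModel",
    "SmallRNNModel",
    "train_target_model",
    "ProbeResult",
    "probe_latent",
    "MIEstimate",
    "estimate_mi",
    "reduce_inputs",
    "encode_cohort",
    "ExperimentConfig",
    "LeakageReport",
    "run_leakage_experiment",
]


class TrainingError(RuntimeError):
    """Model training cannot proceed (e.g. a single-class training split)."""


# ---------------------------------------------------------------------------
# AUROC (rank-based Mann-Whitney with tie correction)
# ---------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic.

    Average ranks handle ties, so tied scores contribute 1/2 per
    discordant pair.  Invariant to any strictly monotone transform of the
    scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-d arrays")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC undefined: need both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def macro_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean of one-vs-rest AUROCs for a multiclass problem.

    ``scores`` has one column per class; classes absent from ``labels``
    are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != labels.size:
        raise ValidationError("scores must be (n, n_classes) aligned with labels")
    vals = []
    for c in range(scores.shape[1]):
        y = (labels == c).astype(int)
        if 0 < y.sum() < y.size:
            vals.append(auroc(scores[:, c], y))
    if not vals:
        raise ValidationError("macro AUROC undefined: no class with both outcomes")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Target-task models exposing a penultimate embedding
# ---------------------------------------------------------------------------

class EmbeddingModel:
    """Contract: fit on (N, F, T) arrays, expose scores and embeddings.

    ``embed`` returns the penultimate representation — whatever feeds the
    final output layer — with a fixed dimension across examples.
    """

    embedding_dim: int

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "EmbeddingModel":
        raise NotImplementedError

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def embed(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @staticmethod
    def _check_labels(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                "training labels contain a single class; cannot fit"
            )
        return y

    @staticmethod
    def _flatten(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return X.reshape(X.shape[0], -1)
        if X.ndim == 2:
            return X
        raise ValidationError("expected (N, F, T) or (N, d) input array")


class LinearModel(EmbeddingModel):
    """Logistic regression on flattened features.

    A purely linear model has no hidden representation: its penultimate
    embedding *is* the flattened input (dimension F·T), which makes it the
    maximal-leakage reference point.
    """

    def __init__(self, seed: int = 0, C: float = 1.0, max_iter: int = 1000):
        self.seed = seed
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y, X_val=None, y_val=None):
        from sklearn.linear_model import LogisticRegression

        Xf = self._flatten(X)
        y = self._check_labels(y)
        self.clf_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.seed
        ).fit(Xf, y)
        self.embedding_dim = Xf.shape[1]
        return self

    def predict_score(self, X):
        return self.clf_.predict_proba(self._flatten(X))[:, 1]

    def embed(self, X):
        return self._flatten(X).copy()


class MLPModel(EmbeddingModel):
    """One-hidden-layer ReLU network trained with Adam + binary cross-entropy.

    Mini-batch size 64, learning rate 1e-3; after every epoch the
    validation AUROC is evaluated and the best-on-validation weights are
    retained.  The 64-unit hidden activation is the penultimate embedding.
    """

    def __init__(
        self,
        hidden: int = 64,
        seed: int = 0,
        max_epochs: int = 30,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        alpha: float = 1e-4,
    ):
        self.hidden = hidden
        self.seed = seed
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.embedding_dim = hidden

    def fit(self, X, y, X_val=None, y_val=None):
        from sklearn.neural_network import MLPClassifier

        Xf = self._flatten(X)
        y = self._check_labels(y)
        clf = MLPClassifier(
            hidden_layer_sizes=(self.hidden,),
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=min(self.batch_size, Xf.shape[0]),
            alpha=self.alpha,
            random_state=self.seed,
            shuffle=True,
        )
        classes = np.array([0, 1])
        best_score, best_weights = -np.inf, None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter per epoch
            for _ in range(self.max_epochs):
                clf.partial_fit(Xf, y, classes=classes)
                if X_val is not None and y_val is not None:
                    score = auroc(
                        clf.predict_proba(self._flatten(X_val))[:, 1], y_val
                    )
                    if score > best_score:
                        best_score = score
                        best_weights = (
                            [c.copy() for c in clf.coefs_],
                            [b.copy() for b in clf.intercepts_],
                        )
        if best_weights is not None:
            clf.coefs_, clf.intercepts_ = best_weights
        self.clf_ = clf
        return self

    def predict_score(self, X):
        return self.clf_.predict_proba(self._flatten(X))[:, 1]

    def embed(self, X):
        Xf = self._flatten(X)
        h = Xf @ self.clf_.coefs_[0] + self.clf_.intercepts_[0]
        return np.maximum(h, 0.0)


class SmallRNNModel(EmbeddingModel):
    """Vanilla tanh recurrent network (32 units) over the time axis.

    Consumes the (N, F, T) grid as T steps of F-dimensional observations;
    the final hidden state is the penultimate embedding.  Trained with
    Adam (lr 1e-3), binary cross-entropy, mini-batches of 64,
    best-on-validation weights retained.
    """

    def __init__(
        self,
        hidden: int = 32,
        seed: int = 0,
        max_epochs: int = 15,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
    ):
        self.hidden = hidden
        self.seed = seed
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.embedding_dim = hidden

    # -- forward/backward ---------------------------------------------------

    def _forward(self, X: np.ndarray):
        """X: (B, F, T) -> hidden states (T, B, H) and final score (B,)."""
        p = self.params_
        B, F, T = X.shape
        H = self.hidden
        hs = np.zeros((T + 1, B, H))
        for t in range(T):
            hs[t + 1] = np.tanh(
                X[:, :, t] @ p["Wx"].T + hs[t] @ p["Wh"].T + p["b"]
            )
        logits = hs[T] @ p["w"] + p["c"]
        return hs, 1.0 / (1.0 + np.exp(-logits))

    def _backward(self, X, y, hs, probs):
        p = self.params_
        B, F, T = X.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (probs - y) / B  # BCE + sigmoid
        grads["w"] = hs[T].T @ dlogit
        grads["c"] = dlogit.sum()
        dh = np.outer(dlogit, p["w"])
        for t in range(T, 0, -1):
            dz = dh * (1.0 - hs[t] ** 2)
            grads["Wx"] += dz.T @ X[:, :, t - 1]
            grads["Wh"] += dz.T @ hs[t - 1]
            grads["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"]
        return grads

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValidationError("recurrent model requires (N, F, T) input")
        y = self._check_labels(y).astype(float)
        rng = np.random.default_rng(self.seed)
        N, F, T = X.shape
        H = self.hidden
        self.params_ = {
            "Wx": rng.normal(0, 1.0 / np.sqrt(F), (H, F)),
            "Wh": rng.normal(0, 1.0 / np.sqrt(H), (H, H)),
            "b": np.zeros(H),
            "w": rng.normal(0, 1.0 / np.sqrt(H), H),
            "c": 0.0,
        }
        # Adam state
        m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params_.items()}
        b1, b2, eps, step = 0.9, 0.999, 1e-8, 0
        best_score, best_params = -np.inf, None
        for _ in range(self.max_epochs):
            order = rng.permutation(N)
            for i0 in range(0, N, self.batch_size):
                idx = order[i0 : i0 + self.batch_size]
                hs, probs = self._forward(X[idx])
                grads = self._backward(X[idx], y[idx], hs, probs)
                step += 1
                for k in self.params_:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params_[k] = self.params_[k] - self.learning_rate * mhat / (
                        np.sqrt(vhat) + eps
                    )
            if X_val is not None and y_val is not None:
                score = auroc(self.predict_score(X_val), y_val.astype(int))
                if score > best_score:
                    best_score = score
                    best_params = copy.deepcopy(self.params_)
        if best_params is not None:
            self.params_ = best_params
        return self

    def predict_score(self, X):
        _, probs = self._forward(np.asarray(X, dtype=float))
        return probs

    def embed(self, X):
        hs, _ = self._forward(np.asarray(X, dtype=float))
        return hs[-1]


_ARCHS = {"linear": LinearModel, "mlp": MLPModel, "recurrent-small": SmallRNNModel}


def train_target_model(
    ds: CohortDataset, arch: str = "mlp", seed: int = 0, **kwargs
) -> EmbeddingModel:
    """Train a target-task model on the cohort's train split, selecting the
    best-on-validation configuration."""
    if arch not in _ARCHS:
        raise ConfigurationError(
            f"unknown architecture {arch!r}; choose from {sorted(_ARCHS)}"
        )
    values = ds.values_array()
    tr, va = ds.mask("train"), ds.mask("validation")
    if not tr.any() or not va.any():
        raise TrainingError("train and validation splits must be non-empty")
    model = _ARCHS[arch](seed=seed, **kwargs)
    return model.fit(
        values[tr], ds.task_labels[tr], values[va], ds.task_labels[va]
    )


# ---------------------------------------------------------------------------
# Latent-attribute probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeResult:
    """AUROC of a single dense layer predicting one latent attribute from
    frozen penultimate embeddings."""

    attribute: str
    metric: float  # AUROC (binary) or macro-AUROC (multiclass, one-vs-rest)
    n_classes: int
    n_train: int
    n_test: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.metric <= 1.0 or np.isnan(self.metric)):
            raise ValidationError("AUROC must lie in [0, 1]")


def probe_latent(
    model: EmbeddingModel,
    ds: CohortDataset,
    attribute: str,
    seed: int = 0,
    eval_split: str = "test",
) -> ProbeResult:
    """Fit a single linear layer on train-split embeddings and report AUROC
    on the held-out split.  No hidden layers, no feature transformations —
    leakage is attributed entirely to the embedding."""
    from sklearn.linear_model import LogisticRegression

    if attribute not in ds.attributes:
        raise ValidationError(f"attribute {attribute!r} not present in cohort")
    labels = ds.attributes[attribute]
    n_classes = int(labels.max()) + 1
    values = ds.values_array()
    tr, te = ds.mask("train"), ds.mask(eval_split)
    emb_tr, emb_te = model.embed(values[tr]), model.embed(values[te])

    if np.allclose(emb_tr.std(axis=0), 0.0):
        warnings.warn(
            "constant embeddings: probe is degenerate, reporting AUROC 0.5",
            RuntimeWarning,
        )
        return ProbeResult(attribute, 0.5, n_classes, int(tr.sum()), int(te.sum()), seed)

    y_tr, y_te = labels[tr], labels[te]
    if n_classes == 2:
        clf = LogisticRegression(max_iter=1000, random_state=seed).fit(emb_tr, y_tr)
        metric = auroc(clf.predict_proba(emb_te)[:, 1], y_te)
    else:
        # one single-layer probe per class, one-vs-rest, macro-averaged
        cols = np.full((emb_te.shape[0], n_classes), np.nan)
        for c in range(n_classes):
            yc = (y_tr == c).astype(int)
            if 0 < yc.sum() < yc.size:
                clf = LogisticRegression(max_iter=1000, random_state=seed).fit(
                    emb_tr, yc
                )
                cols[:, c] = clf.predict_proba(emb_te)[:, 1]
        present = ~np.isnan(cols[0])
        metric = macro_auroc(cols[:, present], _remap(y_te, np.where(present)[0]))
    return ProbeResult(
        attribute, float(metric), n_classes, int(tr.sum()), int(te.sum()), seed
    )


def _remap(y: np.ndarray, kept: np.ndarray) -> np.ndarray:
    """Map class labels onto the column order of the kept classes."""
    lut = {c: i for i, c in enumerate(kept)}
    return np.array([lut.get(v, -1) for v in y])


# ---------------------------------------------------------------------------
# Mutual information (KSG k-NN estimator, variant 1, Chebyshev metric)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIEstimate:
    value: float  # nats
    input_reduction: str  # "averaged" | "vectorized" | "raw"
    k: int
    n: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not np.isfinite(self.value):
            raise ValidationError("MI estimate must be finite")


def reduce_inputs(X: MultivariateTimeSeries | np.ndarray, mode: str) -> np.ndarray:
    """Collapse an F×T example to a vector: per-feature time-average
    (length F) or row-major flattening (length F·T)."""
    values = X.values if isinstance(X, MultivariateTimeSeries) else np.asarray(X)
    if values.ndim != 2:
        raise ValidationError("expected a single F×T example")
    if mode == "averaged":
        return values.mean(axis=1)
    if mode == "vectorized":
        return values.ravel().copy()
    raise ConfigurationError(f"unknown reduction mode {mode!r}")


def _chebyshev_block(A: np.ndarray, B: np.ndarray, col_chunk: int = 256) -> np.ndarray:
    """Pairwise Chebyshev distances between row-blocks, chunked over columns
    to bound peak memory."""
    out = np.zeros((A.shape[0], B.shape[0]))
    d = A.shape[1]
    for j0 in range(0, d, col_chunk):
        j1 = min(j0 + col_chunk, d)
        diff = np.abs(A[:, None, j0:j1] - B[None, :, j0:j1]).max(axis=2)
        np.maximum(out, diff, out=out)
    return out


def estimate_mi(
    embeddings: np.ndarray,
    inputs_reduced: np.ndarray,
    k: int = 3,
    seed: int = 0,
    input_reduction: str = "raw",
) -> MIEstimate:
    """KSG variant-1 MI estimate (nats) between two continuous vector samples.

    Chebyshev (max) metric in both marginals and the joint; strict-
    inequality neighbour counts; duplicate points are broken by a seeded
    jitter of relative scale 1e-10 before estimation is retried.
    """
    X = np.atleast_2d(np.asarray(embeddings, dtype=float))
    Y = np.atleast_2d(np.asarray(inputs_reduced, dtype=float))
    if X.shape[0] == 1 and X.size > 1 and np.asarray(embeddings).ndim == 1:
        X = X.T
    if Y.shape[0] == 1 and Y.size > 1 and np.asarray(inputs_reduced).ndim == 1:
        Y = Y.T
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValidationError("embeddings and inputs must have equal sample counts")
    if n < 2 * k + 2:
        raise ValidationError(f"need at least 2k+2={2*k+2} samples, got {n}")

    for attempt in range(2):
        nx = np.empty(n, dtype=int)
        ny = np.empty(n, dtype=int)
        degenerate = False
        block = max(1, int(4e7 // max(n, 1)))
        for i0 in range(0, n, block):
            i1 = min(i0 + block, n)
            dx = _chebyshev_block(X[i0:i1], X)
            dy = _chebyshev_block(Y[i0:i1], Y)
            dj = np.maximum(dx, dy)
            rows = np.arange(i0, i1)
            dj[rows - i0, rows] = np.inf
            eps = np.partition(dj, k - 1, axis=1)[:, k - 1]
            if np.any(eps == 0.0):
                degenerate = True
                break
            nx[i0:i1] = (dx < eps[:, None]).sum(axis=1) - 1  # excl. self
            ny[i0:i1] = (dy < eps[:, None]).sum(axis=1) - 1
        if not degenerate:
            break
        if attempt == 1:
            raise ValidationError(
                "duplicate points persist after jitter; MI estimate degenerate"
            )
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, 1e-10 * max(X.std(), 1.0), X.shape)
        Y = Y + rng.normal(0.0, 1e-10 * max(Y.std(), 1.0), Y.shape)

    value = float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )
    return MIEstimate(value=value, input_reduction=input_reduction, k=k, n=n)


# ---------------------------------------------------------------------------
# Encoding a whole cohort
# ---------------------------------------------------------------------------

def encode_cohort(
    ds: CohortDataset,
    encoder: SegmentEncoder,
    cfg: FrameworkConfig,
    stats: MinMaxStats | None = None,
) -> CohortDataset:
    """Encode every example, keeping labels/attributes/splits aligned."""
    encoded = []
    for ex in ds.examples:
        e = encode_timeseries(ex, encoder, cfg, stats=stats)
        encoded.append(
            MultivariateTimeSeries(
                values=e.values,
                feature_names=e.feature_names,
                example_id=e.example_id,
            )
        )
    return ds.with_examples(encoded)


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """One leakage experiment: a cohort, an encoding setup, a model family."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    segment_length: int = 4
    layers: int = 2
    arch: str = "mlp"
    key_seed: int = 1234
    mi_k: int = 3
    mi_max_samples: int = 512
    max_epochs: int = 30
    conditions: tuple[str, ...] = ("original", "projection", "quantum")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["latent_attrs"] = [
            list(a) if isinstance(a, (list, tuple)) else [a.name, a.n_classes, a.effect_size]
            for a in self.cohort.latent_attrs
        ]
        return d


@dataclass
class LeakageReport:
    """Per-seed records plus aggregates and relative drops.

    ``records`` is a flat list of dicts (condition, seed, metric,
    attribute, value); ``summary`` holds mean/sd per condition/metric;
    ``relative_drops`` holds 100·(orig − enc)/orig computed per seed and
    then averaged (mean-of-drops).
    """

    config: dict
    seeds: list[int]
    records: list[dict]
    summary: dict
    relative_drops: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "summary": self.summary,
                    "relative_drops": self.relative_drops,
                    "records": self.records,
                },
                indent=1,
                sort_keys=True,
            )
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.records).to_csv(path, index=False)

    def mean(self, condition: str, metric: str, attribute: str = "") -> float:
        vals = [
            r["value"]
            for r in self.records
            if r["condition"] == condition
            and r["metric"] == metric
            and r["attribute"] == attribute
        ]
        if not vals:
            raise KeyError(f"no records for {condition}/{metric}/{attribute}")
        return float(np.mean(vals))


def _prepare_conditions(cfg: ExperimentConfig, ds: CohortDataset):
    """Min-max scale once (train-split stats) and encode per condition."""
    stats = compute_minmax_stats(
        [ex for ex, m in zip(ds.examples, ds.mask("train")) if m]
    )
    scaled = ds.with_examples(
        [scale_minmax(ex, stats) for ex in ds.examples]
    )
    fw = FrameworkConfig(
        segment_length=cfg.segment_length, input_scaling="none"
    )  # inputs already scaled once, shared across conditions
    datasets: dict[str, CohortDataset] = {}
    for cond in cfg.conditions:
        if cond == "original":
            datasets[cond] = scaled
        elif cond == "projection":
            key = sample_projection_key(cfg.segment_length, cfg.key_seed)
            datasets[cond] = encode_cohort(scaled, ProjectionEncoder(key), fw)
        elif cond == "quantum":
            circuit = build_random_circuit(
                cfg.segment_length, cfg.layers, cfg.key_seed + 1
            )
            datasets[cond] = encode_cohort(scaled, QuantumEncoder(circuit), fw)
        elif cond == "identity":
            datasets[cond] = scaled
        else:
            raise ConfigurationError(f"unknown condition {cond!r}")
    return datasets


def run_leakage_experiment(
    cfg: ExperimentConfig, seeds: list[int]
) -> LeakageReport:
    """Train/probe/estimate per condition per seed; aggregate a report.

    The cohort and the encoding keys are fixed by their own seeds in
    ``cfg``; the per-run ``seeds`` vary only model initialisation and
    mini-batch order, mirroring repeated training runs on a fixed dataset.
    """
    if not seeds:
        raise ValidationError("need at least one seed")
    ds = generate_cohort(cfg.cohort)
    datasets = _prepare_conditions(cfg, ds)
    attr_names = list(ds.attributes)

    records: list[dict] = []
    for cond, cond_ds in datasets.items():
        values = cond_ds.values_array()
        te = cond_ds.mask("test")
        # deterministic MI subset: first mi_max_samples test examples
        te_idx = np.where(te)[0][: cfg.mi_max_samples]
        reduced = {
            mode: np.stack([reduce_inputs(values[i], mode) for i in te_idx])
            for mode in ("averaged", "vectorized")
        }
        for seed in seeds:
            try:
                model = train_target_model(
                    cond_ds, arch=cfg.arch, seed=seed, max_epochs=cfg.max_epochs
                ) if cfg.arch == "mlp" else train_target_model(
                    cond_ds, arch=cfg.arch, seed=seed
                )
            except TrainingError as err:
                raise TrainingError(f"[condition={cond}] {err}") from err
            records.append(
                {
                    "condition": cond,
                    "seed": seed,
                    "metric": "task_auroc",
                    "attribute": "",
                    "value": auroc(
                        model.predict_score(values[te]), cond_ds.task_labels[te]
                    ),
                }
            )
            for attr in attr_names:
                res = probe_latent(model, cond_ds, attr, seed=seed)
                records.append(
                    {
                        "condition": cond,
                        "seed": seed,
                        "metric": "probe_auroc",
                        "attribute": attr,
                        "value": res.metric,
                    }
                )
            emb = model.embed(values[te_idx])
            for mode in ("averaged", "vectorized"):
                est = estimate_mi(
                    emb,
                    reduced[mode],
                    k=cfg.mi_k,
                    seed=seed,
                    input_reduction=mode,
                )
                records.append(
                    {
                        "condition": cond,
                        "seed": seed,
                        "metric": f"mi_{mode}",
                        "attribute": "",
                        "value": est.value,
                    }
                )

    summary = _summarize(records)
    drops = _relative_drops(records, cfg.conditions, seeds)
    return LeakageReport(
        config=cfg.to_dict(),
        seeds=list(seeds),
        records=records,
        summary=summary,
        relative_drops=drops,
    )


def _summarize(records: list[dict]) -> dict:
    summary: dict = {}
    keys = sorted({(r["condition"], r["metric"], r["attribute"]) for r in records})
    for cond, metric, attr in keys:
        vals = np.array(
            [
                r["value"]
                for r in records
                if (r["condition"], r["metric"], r["attribute"]) == (cond, metric, attr)
            ]
        )
        name = f"{metric}:{attr}" if attr else metric
        summary.setdefault(cond, {})[name] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "values": vals.tolist(),
        }
    return summary


def _relative_drops(
    records: list[dict], conditions: tuple[str, ...], seeds: list[int]
) -> dict:
    """100·(orig − enc)/orig per seed per metric, then mean ± sd over seeds."""
    if "original" not in conditions:
        return {}

    def val(cond, metric, attr, seed):
        for r in records:
            if (
                r["condition"] == cond
                and r["metric"] == metric
                and r["attribute"] == attr
                and r["seed"] == seed
            ):
                return r["value"]
        raise KeyError((cond, metric, attr, seed))

    metrics = sorted({(r["metric"], r["attribute"]) for r in records})
    drops: dict = {}
    for cond in conditions:
        if cond == "original":
            continue
        drops[cond] = {}
        for metric, attr in metrics:
            per_seed = []
            for seed in seeds:
                v0 = val("original", metric, attr, seed)
                v1 = val(cond, metric, attr, seed)
                if v0 != 0:
                    per_seed.append(100.0 * (v0 - v1) / v0)
            if per_seed:
                name = f"{metric}:{attr}" if attr else metric
                drops[cond][name] = {
                    "mean": float(np.mean(per_seed)),
                    "sd": float(np.std(per_seed, ddof=1)) if len(per_seed) > 1 else 0.0,
                }
    return drops
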