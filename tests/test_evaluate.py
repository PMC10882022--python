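"""Evaluation harness: AUROC, models, probes, MI estimator, experiment driver."""

import numpy as np
import pytest

from enctsf import (
    AttributeSpec,
    CohortConfig,
    MultivariateTimeSeries,
    TrainingError,
    ValidationError,
    auroc,
    estimate_mi,
    macro_auroc,
    probe_latent,
    reduce_inputs,
    run_leakage_experiment,
    train_target_model,
)
from enctsf.cohort import CohortDataset
from enctsf.evaluate import ExperimentConfig
from oracles import gaussian_mi_nats, pair_counting_auroc


class TestAuroc:
    def test_worked_four_example_case(self):
        """Scores (0.9, 0.8, 0.4, 0.2) for labels (1,1,0,0): every positive
        outranks every negative, AUROC 1 by exhaustive pair counting."""
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auroc(scores, labels) == 1.0
        assert pair_counting_auroc(scores, labels) == 1.0

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.integers(0, 5, size=40).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            assert auroc(scores, labels) == pytest.approx(
                pair_counting_auroc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auroc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_macro_is_unweighted_mean_of_one_vs_rest(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 3, size=90)
        scores = rng.random((90, 3))
        expected = np.mean(
            [auroc(scores[:, c], (labels == c).astype(int)) for c in range(3)]
        )
        assert macro_auroc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestReduceInputs:
    def test_examples(self):
        X = MultivariateTimeSeries(
            values=np.array([[1.0, 3.0], [2.0, 4.0]]),
            feature_names=("a", "b"),
            example_id="e",
        )
        assert reduce_inputs(X, "averaged").tolist() == [2.0, 3.0]
        assert reduce_inputs(X, "vectorized").tolist() == [1.0, 3.0, 2.0, 4.0]

    def test_single_step_degenerate(self):
        X = MultivariateTimeSeries(
            values=np.array([[5.0], [7.0]]), feature_names=("a", "b"), example_id="e"
        )
        assert np.array_equal(
            reduce_inputs(X, "averaged"), reduce_inputs(X, "vectorized")
        )


class TestModels:
    def test_separable_cohort_perfect_auroc(self):
        """Linearly separable toy data: every architecture reaches AUROC 1."""
        rng = np.random.default_rng(0)
        N = 200
        y = np.repeat([0, 1], N // 2)
        X = rng.normal(size=(N, 2, 4)) + 6.0 * y[:, None, None]
        split = np.empty(N, dtype=object)
        perm = rng.permutation(N)  # shuffled so every fold sees both classes
        split[perm[:120]] = "train"
        split[perm[120:160]] = "validation"
        split[perm[160:]] = "test"
        ds = CohortDataset(
            examples=[
                MultivariateTimeSeries(X[i], ("a", "b"), f"e{i}") for i in range(N)
            ],
            task_labels=y,
            attributes={},
            split=split,
        )
        te = ds.mask("test")
        for arch in ("linear", "mlp", "recurrent-small"):
            model = train_target_model(ds, arch=arch, seed=0)
            scores = model.predict_score(ds.values_array()[te])
            assert auroc(scores, y[te]) == 1.0, arch

    def test_shuffled_labels_near_chance(self, tiny_cohort):
        rng = np.random.default_rng(12)
        shuffled = tiny_cohort.with_examples(list(tiny_cohort.examples))
        shuffled.task_labels = rng.permutation(shuffled.task_labels)
        model = train_target_model(shuffled, arch="mlp", seed=0)
        te = shuffled.mask("test")
        a = auroc(model.predict_score(shuffled.values_array()[te]), shuffled.task_labels[te])
        assert abs(a - 0.5) < 0.2

    def test_single_class_training_error(self, tiny_cohort):
        broken = tiny_cohort.with_examples(list(tiny_cohort.examples))
        broken.task_labels = np.zeros(len(broken), dtype=int)
        with pytest.raises(TrainingError):
            train_target_model(broken, arch="mlp", seed=0)

    def test_fit_deterministic_given_seed(self, tiny_cohort):
        vals = tiny_cohort.values_array()
        te = tiny_cohort.mask("test")
        runs = []
        for _ in range(2):
            model = train_target_model(tiny_cohort, arch="mlp", seed=3)
            runs.append(model.predict_score(vals[te]))
        assert np.array_equal(runs[0], runs[1])

    def test_embedding_dims(self, tiny_cohort):
        vals = tiny_cohort.values_array()[:5]
        mlp = train_target_model(tiny_cohort, arch="mlp", seed=0)
        assert mlp.embed(vals).shape == (5, 64)
        lin = train_target_model(tiny_cohort, arch="linear", seed=0)
        assert lin.embed(vals).shape == (5, 8 * 12)
        rnn = train_target_model(tiny_cohort, arch="recurrent-small", seed=0)
        assert rnn.embed(vals).shape == (5, 32)


class TestProbe:
    def test_one_hot_embedding_perfect(self, tiny_cohort):
        """If the embedding literally encodes the attribute, AUROC is 1."""
        attr = tiny_cohort.attributes["sex"]

        class Oracle:
            def embed(inner, X):
                n = X.shape[0]
                # order of calls in probe_latent: train then test
                mask = (
                    tiny_cohort.mask("train")
                    if n == tiny_cohort.mask("train").sum()
                    else tiny_cohort.mask("test")
                )
                return np.eye(2)[attr[mask]]

        res = probe_latent(Oracle(), tiny_cohort, "sex", seed=0)
        assert res.metric == 1.0

    def test_independent_embedding_near_chance(self, tiny_cohort):
        rng = np.random.default_rng(7)

        class Noise:
            def embed(inner, X):
                return rng.normal(size=(X.shape[0], 8))

        res = probe_latent(Noise(), tiny_cohort, "sex", seed=0)
        assert abs(res.metric - 0.5) < 0.2

    def test_constant_embedding_degenerate(self, tiny_cohort):
        class Const:
            def embed(inner, X):
                return np.ones((X.shape[0], 4))

        with pytest.warns(RuntimeWarning, match="constant"):
            res = probe_latent(Const(), tiny_cohort, "sex", seed=0)
        assert res.metric == 0.5

    def test_unknown_attribute(self, tiny_cohort):
        class Any:
            def embed(inner, X):
                return np.ones((X.shape[0], 4))

        with pytest.raises(ValidationError):
            probe_latent(Any(), tiny_cohort, "nope", seed=0)


class TestMIEstimator:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2000, 1))
        y = rng.normal(size=(2000, 1))
        est = estimate_mi(x, y, k=3, seed=0)
        assert abs(est.value) < 0.05

    def test_correlated_gaussians_match_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal(
            [0, 0], [[1, rho], [rho, 1]], size=5000
        )
        est = estimate_mi(z[:, :1], z[:, 1:], k=3, seed=0)
        assert abs(est.value - gaussian_mi_nats(rho)) < 0.1

    def test_deterministic_dependence_grows_with_n(self):
        """y = x exactly: the estimate increases with sample size (true MI
        is unbounded for continuous deterministic dependence)."""
        rng = np.random.default_rng(2)
        values = []
        for n in (500, 1000, 2000):
            x = rng.normal(size=(n, 1))
            values.append(estimate_mi(x, x.copy(), k=3, seed=0).value)
        assert values[0] < values[1] < values[2]

    def test_permutation_null_near_zero(self):
        """Shuffling one marginal destroys dependence: estimate ~ 0."""
        rho = 0.9
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2000)
        y_shuf = z[rng.permutation(2000), 1:]
        est = estimate_mi(z[:, :1], y_shuf, k=3, seed=0)
        assert abs(est.value) < 0.05

    def test_duplicates_jittered(self):
        """Heavily tied data triggers the seeded jitter path, not an error."""
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, size=(300, 1)).astype(float)
        y = x + rng.integers(0, 2, size=(300, 1))
        est = estimate_mi(x, y, k=3, seed=0)
        assert np.isfinite(est.value)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            estimate_mi(np.zeros((5, 1)), np.zeros((5, 1)), k=3)


@pytest.fixture(scope="module")
def small_experiment():
    cfg = ExperimentConfig(
        cohort=CohortConfig(
            n_examples=240,
            F=8,
            T=12,
            prevalence=0.3,
            latent_attrs=(AttributeSpec("sex", 2, 0.8),),
            seed=5,
        ),
        mi_max_samples=48,
        max_epochs=8,
    )
    return cfg, run_leakage_experiment(cfg, seeds=[0, 1])


class TestExperimentDriver:

    def test_report_bookkeeping(self, small_experiment):
        """3 conditions x (task + probe per attribute + 2 MI) x 2 seeds."""
        cfg, report = small_experiment
        assert len(report.records) == 3 * (1 + 1 + 2) * 2
        for cond in ("original", "projection", "quantum"):
            assert cond in report.summary
            assert {"task_auroc", "probe_auroc:sex", "mi_averaged", "mi_vectorized"} <= set(
                report.summary[cond]
            )
        assert set(report.relative_drops) == {"projection", "quantum"}

    def test_identity_condition_null_drops(self):
        cfg = ExperimentConfig(
            cohort=CohortConfig(
                n_examples=240,
                F=8,
                T=12,
                prevalence=0.3,
                latent_attrs=(AttributeSpec("sex", 2, 0.8),),
                seed=5,
            ),
            conditions=("original", "identity"),
            mi_max_samples=48,
            max_epochs=8,
        )
        report = run_leakage_experiment(cfg, seeds=[0])
        # identical data in both conditions -> identical models -> zero drops
        for stats in report.relative_drops["identity"].values():
            assert stats["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_report_serialization(self, small_experiment, tmp_path):
        _, report = small_experiment
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["seeds"] == [0, 1]
        assert "summary" in loaded and "relative_drops" in loaded

    def test_no_seeds_rejected(self):
        with pytest.raises(ValidationError):
            run_leakage_experiment(ExperimentConfig(), seeds=[])
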