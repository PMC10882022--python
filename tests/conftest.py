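import numpy as np
import pytest

from enctsf import AttributeSpec, CohortConfig, MultivariateTimeSeries, generate_cohort


@pytest.fixture
def small_mts():
    """3 features × 8 steps, hand-sized for segment bookkeeping checks."""
    rng = np.random.default_rng(11)
    return MultivariateTimeSeries(
        values=rng.random((3, 8)),
        feature_names=("hr", "sbp", "spo2"),
        example_id="ex0",
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but trainable cohort shared by evaluation tests."""
    cfg = CohortConfig(
        n_examples=300,
        F=8,
        T=12,
        prevalence=0.3,
        latent_attrs=(AttributeSpec("sex", 2, 0.8),),
        seed=5,
    )
    return generate_cohort(cfg)
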