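import numpy as np
import pytest

from cardiofair.preprocess import Encoder
from cardiofair.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A complete (no missingness) 120-record cohort."""
    return generate_cohort(CohortSpec(n=120, seed=11, missing_rates={}))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return Encoder().fit_transform(small_cohort)


@pytest.fixture(scope="session")
def tiny_net_config():
    """A fast training configuration for structural tests."""
    from cardiofair.pipeline import RunConfig
    return RunConfig(lstm_units=6, epochs=2, batch_size=32, seed=5, k_folds=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_fit():
    """The tuned-default model trained to convergence on an exactly
    separable n=400 cohort (shared: this is the most expensive fit in the
    suite)."""
    from cardiofair.pipeline import RunConfig, train
    from cardiofair.simulate import strongly_separable_spec

    cohort = generate_cohort(strongly_separable_spec(n=400, seed=3))
    matrix = Encoder().fit_transform(cohort)
    cfg = RunConfig(epochs=100, seed=0, fairness_reweighting=False)
    state, trace = train(matrix.values, matrix.y, cfg,
                         feature_names=matrix.feature_names)
    return state, matrix, trace
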