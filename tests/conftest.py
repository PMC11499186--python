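import numpy as np
import pytest

from brainage import phantom, pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 24^3 cohort shared by read-only tests."""
    cfg = phantom.CohortConfig(n_healthy=30, n_ms=8,
                               grid_shape=(24, 24, 24), seed=42)
    dataset, parc = phantom.generate_cohort(cfg)
    return cfg, dataset, parc


@pytest.fixture(scope="session")
def tiny_run():
    """The full tiny-preset experiment behind acceptance criteria 1-3.

    One training run (~6-8 min on one CPU) shared by every test that
    needs a trained model.
    """
    return pipeline.run_experiment(seed=1)


@pytest.fixture(scope="session")
def tiny_saliency(tiny_run):
    """Saliency maps for held-out subjects plus all healthy subjects."""
    man = tiny_run.manifest
    held = list(tiny_run.predictions["subject_id"])
    healthy = list(man.loc[man["cohort"] == "healthy", "subject_id"])
    ids = sorted(set(held) | set(healthy))
    return pipeline.compute_saliency(tiny_run, ids, n_samples=8, seed=11)


class LinearModel:
    """value_and_input_grad stub: a fixed linear map over voxels."""

    def __init__(self, weights: np.ndarray) -> None:
        self.weights = weights

    def value_and_input_grad(self, vol):
        return float((self.weights * vol).sum()), self.weights.copy()


@pytest.fixture
def linear_model_factory():
    return LinearModel
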