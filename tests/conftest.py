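import numpy as np
import pytest
from scipy.special import expit

from samplecurve.synthetic import GeneratorConfig, generate_dataset
from samplecurve.tabular import FeatureKind, FeatureSchema, TabularDataset


def dataset_from_arrays(X, y) -> TabularDataset:
    """Wrap raw arrays with an all-continuous schema (tests only)."""
    X = np.asarray(X, dtype=float)
    names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
    kinds = tuple(FeatureKind.CONTINUOUS for _ in names)
    return TabularDataset(X=X, y=np.asarray(y), schema=FeatureSchema(names, kinds))


def sparse_signal_dataset(seed: int, n: int = 5000, p: int = 10, beta: float = 1.5):
    """Outcome driven by the first two of p standard-normal features."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < expit(beta * X[:, 0] + beta * X[:, 1])).astype(int)
    return dataset_from_arrays(X, y)


@pytest.fixture(scope="session")
def linear_dataset() -> TabularDataset:
    """Moderate linear signal, mixed feature types, 30% minority class."""
    return generate_dataset(
        GeneratorConfig(
            n=5000, p=10, pct_continuous=50.0, n_informative=3,
            effect_scale=0.8, nonlinear_scale=0.0, minority_target=0.3, seed=11,
        )
    )


@pytest.fixture(scope="session")
def noise_dataset() -> TabularDataset:
    """Outcome independent of every feature (AUC should hover at 0.5)."""
    return generate_dataset(
        GeneratorConfig(
            n=2000, p=6, pct_continuous=50.0, n_informative=0,
            effect_scale=0.0, nonlinear_scale=0.0, minority_target=0.5, seed=7,
        )
    )
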