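import numpy as np
import pandas as pd
import pytest

from tmelearn import synthetic
from tmelearn.io import GeneExpressionMatrix


@pytest.fixture(scope="session")
def priors():
    return synthetic.make_priors(seed=11)


@pytest.fixture(scope="session")
def cohort(priors):
    return synthetic.make_cohort(priors, n_samples=60, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def expr(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort[1]


def make_expr(tpm: dict[str, list[float]], samples: list[str] | None = None,
              counts=None) -> GeneExpressionMatrix:
    """Tiny expression matrix from a {gene: per-sample TPM} mapping."""
    df = pd.DataFrame(tpm).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return GeneExpressionMatrix(tpm=df.astype(float), counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
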