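import numpy as np
import pandas as pd
import pytest

from lichenflux.synthetic import (
    GeneratorConfig,
    PhotosynthesisParams,
    RespirationParams,
    generate_gas_exchange,
)


@pytest.fixture(scope="session")
def noiseless_config() -> GeneratorConfig:
    """Small noise-free campaign with no between-thallus variation."""
    return GeneratorConfig(seed=11, n_thalli=3, noise_sd=0.0, thallus_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_records(noiseless_config) -> pd.DataFrame:
    return generate_gas_exchange(noiseless_config)


@pytest.fixture(scope="session")
def default_params() -> tuple[RespirationParams, PhotosynthesisParams]:
    return RespirationParams(), PhotosynthesisParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
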