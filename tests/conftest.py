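import numpy as np
import pandas as pd
import pytest

from mirvcea import (
    ModelRunner,
    default_trial_spec,
    fit_survival_models,
    generate_km_curves,
    generate_life_table,
    load_config,
)


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def noise_free_curves():
    return generate_km_curves(default_trial_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def fitted_models(noise_free_curves):
    models, rankings = fit_survival_models(noise_free_curves)
    return models


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def runner(config, fitted_models, life_table):
    return ModelRunner.from_config(config, fitted_models, life_table)
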