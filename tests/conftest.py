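import numpy as np
import pytest

from ipra._rng import substream
from ipra.exposure import fit_nanofraction
from ipra.hazard import ExtrapolationModel, fit_all_models, parametric_bootstrap_bmds
from ipra.risk import IpraConfig, IpraModel
from ipra.synthetic import (
    DoseResponseParams,
    SurveyParams,
    generate_dose_response,
    generate_survey,
    load_table1_fixture,
)

#: simulation truth used across the hazard tests: logistic with ED50 = 1000
LOGISTIC_TRUTH = {"a": -2.0, "b": 0.002}


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def small_survey():
    return generate_survey(SurveyParams(n_persons=120, seed=11))


@pytest.fixture(scope="session")
def dr_data():
    return generate_dose_response(
        DoseResponseParams(
            doses=(0.0, 500.0, 1000.0, 2000.0),
            rats_per_group=15,
            true_model="logistic",
            true_params=LOGISTIC_TRUTH,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def seven_fits(dr_data):
    return fit_all_models(dr_data)


@pytest.fixture(scope="session")
def bmd_set(seven_fits, dr_data):
    return parametric_bootstrap_bmds(
        seven_fits, dr_data, reps_per_model=20, rng=substream(1, 0, "bmd")
    )


@pytest.fixture(scope="session")
def extrapolation():
    return ExtrapolationModel.from_constants()


@pytest.fixture(scope="session")
def nanofraction():
    return fit_nanofraction(0.5, 0.8)


@pytest.fixture
def ipra_model(small_survey, table1, bmd_set, extrapolation, nanofraction):
    conc, links = table1

    def build(config=None, survey=None, concentrations=None, bmds=None):
        return IpraModel(
            survey if survey is not None else small_survey,
            concentrations if concentrations is not None else conc,
            links,
            bmds if bmds is not None else bmd_set,
            extrapolation,
            nanofraction,
            config or IpraConfig(outer=10, inner=10_000, master_seed=5),
        )

    return build
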