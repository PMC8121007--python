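import pytest
from hypothesis import settings

from htnsim import ModelParams, make_default_config

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from htnsim.risk import EventTypeSplit, RiskModel, TreatmentEffect


@pytest.fixture(scope="session")
def bundle():
    """The default full-scale config bundle (10,000 per sex, 240 cycles)."""
    return make_default_config()


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced-scale preset: 1,000 individuals per sex, same parameters."""
    b = make_default_config()
    b.population.cohort_size = 1_000
    return b


@pytest.fixture(scope="session")
def params(bundle):
    return ModelParams.from_config(bundle)


@pytest.fixture(scope="session")
def risk_model(bundle):
    return RiskModel(bundle.risk_model)


@pytest.fixture(scope="session")
def event_split(bundle):
    return EventTypeSplit(bundle.event_split)


@pytest.fixture(scope="session")
def treatment_effect(bundle):
    return TreatmentEffect(bundle.treatment_effect)
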