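import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_pz():
    from pzfold.parameters import load_parameter_set

    return load_parameter_set("DNA-PZ")


@pytest.fixture(scope="session")
def params_dna():
    from pzfold.parameters import load_parameter_set

    return load_parameter_set("canonical-DNA")


@pytest.fixture(scope="session")
def em_pz(params_pz):
    from pzfold.energy import EnergyModel

    return EnergyModel(params_pz)


@pytest.fixture(scope="session")
def em_dna(params_dna):
    from pzfold.energy import EnergyModel

    return EnergyModel(params_dna)
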