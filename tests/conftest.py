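import pytest

from zebratk import (
    MCPP,
    BodyComposition,
    ExposureScenario,
    MultiCompartmentParams,
    OneCompartmentParams,
    micromolar_to_mg_per_l,
)


@pytest.fixture(scope="session")
def mcpp():
    return MCPP


@pytest.fixture(scope="session")
def scenario(mcpp):
    """8-h uptake at 5 uM followed by 48 h in clean water."""
    return ExposureScenario(
        c_w=micromolar_to_mg_per_l(5.0, mcpp), t_uptake=8.0, t_depuration=48.0
    )


@pytest.fixture(scope="session")
def onecomp_params():
    """Published whole-body uptake/elimination rates for mCPP."""
    return OneCompartmentParams(k_in=112.9, k_out=0.25)


@pytest.fixture(scope="session")
def multicomp_params():
    """Published eye / rest-of-body rates for mCPP."""
    return MultiCompartmentParams(
        k_in_eyes=325.0, k_out_eyes=0.05, k_in_rest=143.2, k_out_rest=0.8
    )


@pytest.fixture(scope="session")
def body():
    """360 ug larva with a 10% eye mass fraction."""
    return BodyComposition.from_fraction(3.6e-7, 0.10)
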