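import numpy as np
import pytest

from viscomap import MaterialSpec, SLSParameters, sls_from_material


@pytest.fixture(scope="session")
def study_material() -> MaterialSpec:
    """The reference material of the study: E=10 kPa, nu=0.495, g=0.8, tauR=5 s."""
    return MaterialSpec(E=10e3, nu=0.495, g=0.8, tau_R=5.0)


@pytest.fixture(scope="session")
def study_sls(study_material) -> SLSParameters:
    """Equivalent Maxwell-form solid: E1=10 kPa, E2=40 kPa, eta=200 kPa s."""
    return sls_from_material(study_material)


@pytest.fixture(scope="session")
def hold_times() -> np.ndarray:
    """Default hold-phase sampling grid: 0 to 50 s at 0.1 s."""
    return np.round(np.arange(0.0, 50.0 + 1e-9, 0.1), 10)
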