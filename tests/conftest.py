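import numpy as np
import pytest
from hypothesis import settings

from memphase.models import HinderedRotatorModel, LorentzianLifetimeModel

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def lifetime_truth() -> LorentzianLifetimeModel:
    """A realistic distributed lifetime (DPH-like, fluid bilayer)."""
    return LorentzianLifetimeModel(tau_center=3.45, width=0.4, main_fraction=0.98)


@pytest.fixture
def anisotropy_truth() -> HinderedRotatorModel:
    """Weakly hindered rotor (DPH in a fluid DOPC-like bilayer)."""
    return HinderedRotatorModel(r0=0.32, r_inf=0.02, theta1=3.45)


@pytest.fixture
def freq_grid() -> np.ndarray:
    return np.geomspace(2.0, 250.0, 15)
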