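import numpy as np
import pytest

from anionbind.electrostatics import ElectrolyteComposition
from anionbind.transport import HptsCalibration, VesicleSystem


@pytest.fixture
def nacl_0p1() -> ElectrolyteComposition:
    """Symmetric 1:1 electrolyte, 0.1 M NaCl."""
    return ElectrolyteComposition.from_species([("Na", 1, 0.1), ("Cl", -1, 0.1)])


@pytest.fixture
def mixed_electrolyte() -> ElectrolyteComposition:
    """Asymmetric Na2SO4/NaClO4 mixture at 0.2 M ionic-strength scale."""
    return ElectrolyteComposition.from_species(
        [("Na", 1, 0.21), ("SO4", -2, 0.005), ("ClO4", -1, 0.2)])


@pytest.fixture
def calibration() -> HptsCalibration:
    return HptsCalibration(r_min=0.2, r_max=2.0, pka=7.2)


@pytest.fixture
def vesicles() -> VesicleSystem:
    return VesicleSystem()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
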