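import numpy as np
import pytest

from vesselmech import MaterialSpec, ModulusTable, gen_vessel_geometry


@pytest.fixture
def tube():
    """Uniform tube: a = 3 mm, t = 1 mm, L = 50 mm, 1-mm stations."""
    return gen_vessel_geometry(length=50.0, base_radius=3.0, base_thickness=1.0)


@pytest.fixture
def stenotic():
    """Tube with a 40%-severity stenosis at mid-length."""
    return gen_vessel_geometry(
        length=50.0, base_radius=3.0, base_thickness=1.0, stenosis=(25.0, 0.4, 4.0)
    )


@pytest.fixture
def const_mat():
    """Constant-modulus material at the hydrogel working point."""
    return MaterialSpec.constant(0.31, nu=0.4)


@pytest.fixture
def softening_mat():
    """Strain-softening table material (silicone-like working range)."""
    return MaterialSpec.from_table(ModulusTable([0.0, 0.4], [0.36, 0.16]), nu=0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
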