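import numpy as np
import pytest

from cueshift.speciation import AcidBaseSpec
from cueshift.synthdata import GeneratorConfig


@pytest.fixture
def pea_spec():
    """The amine cue's ionisable group (pKa 9.83, base convention)."""
    return AcidBaseSpec(label="PEA", pKa=9.83)


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=20181101)


@pytest.fixture
def rng():
    return np.random.default_rng(20181101)


WATER_XYZ = """3
water, coordinates in Angstrom
O 0.000000 0.000000 0.117300
H 0.000000 0.757200 -0.469200
H 0.000000 -0.757200 -0.469200
"""


@pytest.fixture
def water_xyz_path(tmp_path):
    p = tmp_path / "water.xyz"
    p.write_text(WATER_XYZ)
    return p
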