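import numpy as np
import pytest

from limnoch4.geometry import LakeMorphometry, RadialGeometry
from limnoch4.synthetic import SyntheticLakeSpec, make_lake


@pytest.fixture(scope="session")
def eutrophic_lake():
    return make_lake(SyntheticLakeSpec(preset="eutrophic", seed=7))


@pytest.fixture(scope="session")
def oligotrophic_lake():
    return make_lake(SyntheticLakeSpec(preset="oligotrophic", seed=11))


@pytest.fixture
def disk_morph():
    """A simple analytic lake: r_max = 100 m, pelagic radius 60 m, H = 4 m."""
    r_max, r_s, h = 100.0, 60.0, 4.0
    a_a = np.pi * r_max**2
    a_z = np.pi * r_s**2
    geom = RadialGeometry(r_max=r_max, r_s=r_s, h_sml=h)
    from limnoch4.geometry import sml_volume_of_revolution

    morph = LakeMorphometry(
        a_surface=a_a, a_sediment=a_a - a_z, a_sml_base=a_z,
        v_sml=sml_volume_of_revolution(geom),
    )
    return morph, geom
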