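import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for srkt_oracle

from toricity import IOLConstants, LensCatalog, LensModel, ProbeGrid


@pytest.fixture
def alcon_constants():
    """A-constant calibrated so (AL 21.00, mean K 39.0, plano) -> 34.0 D."""
    return IOLConstants(a_constant=118.8)


@pytest.fixture
def alcon_catalog():
    """Programmatic twin of the shipped Alcon-style catalog."""
    cylinders = {"SN6AT3": 1.50, "SN6AT4": 2.25, "SN6AT5": 3.00, "SN6AT6": 3.75,
                 "SN6AT7": 4.50, "SN6AT8": 5.25, "SN6AT9": 6.00}
    return LensCatalog(
        lenses=tuple(
            LensModel(name=n, cylinder_iol_plane=c, sphere_min=5.0,
                      sphere_max=34.0, a_constant=118.8)
            for n, c in cylinders.items()
        )
    )


@pytest.fixture
def abbott_catalog():
    cylinders = {"ZCT100": 1.00, "ZCT150": 1.50, "ZCT225": 2.25, "ZCT300": 3.00,
                 "ZCT400": 4.00, "ZCT450": 4.50, "ZCT525": 5.25, "ZCT600": 6.00}
    return LensCatalog(
        lenses=tuple(
            LensModel(name=n, cylinder_iol_plane=c, sphere_min=5.0,
                      sphere_max=34.0, a_constant=118.8)
            for n, c in cylinders.items()
        )
    )


@pytest.fixture
def default_grid():
    return ProbeGrid()
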