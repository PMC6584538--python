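import numpy as np
import pytest

from holosperm.core import RITomogram
from holosperm.forward import IlluminationPlan
from holosperm.phantoms import build_phantom
from holosperm.presets import MEDIUM_RI, ho_design


@pytest.fixture(scope="session")
def plan():
    return IlluminationPlan()


@pytest.fixture(scope="session")
def ho_phantom():
    """Holstein-mean phantom with ground-truth compartment labels."""
    tomo, labels = build_phantom(ho_design(), return_labels=True)
    return tomo, labels


def make_slab(dn: float, thickness: float = 2.0, n: int = 64, voxel: float = 0.1) -> RITomogram:
    """Uniform slab of RI elevation ``dn`` normal to z, centred in the grid."""
    vals = np.full((n, n, n), MEDIUM_RI)
    z = (np.arange(n) - n / 2 + 0.5) * voxel
    vals[np.abs(z) <= thickness / 2] += dn
    return RITomogram(vals, (voxel,) * 3, MEDIUM_RI)


def make_sphere(dn: float = 0.01, radius: float = 2.0, n: int = 96, voxel: float = 0.1):
    """Weak sphere phantom; returns (tomogram, inside-mask)."""
    c = (np.arange(n) - n / 2 + 0.5) * voxel
    Z, Y, X = np.meshgrid(c, c, c, indexing="ij")
    inside = Z**2 + Y**2 + X**2 <= radius**2
    vals = np.full((n,) * 3, MEDIUM_RI)
    vals[inside] += dn
    return RITomogram(vals, (voxel,) * 3, MEDIUM_RI), inside
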