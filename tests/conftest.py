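import numpy as np
import pandas as pd
import pytest

from filbundle.formats import AtomicModel
from filbundle.synthgen import build_decorated_volume, make_protomer_model


@pytest.fixture(scope="session")
def protomer():
    return make_protomer_model()


@pytest.fixture(scope="session")
def filament_volume(protomer):
    """Decorated 13-protomer filament at the default scene sampling."""
    return build_decorated_volume(protomer, n_protomers=13, voxel_size=4.4,
                                  resolution=12.0)


@pytest.fixture(scope="session")
def projection_library(filament_volume):
    """The in-plane library used for polarity calls (filament near the image
    plane, spins sampled azimuthally)."""
    from filbundle.polarity import make_library

    return make_library(filament_volume, angular_step=12.0,
                        tilt_range=(74.0, 106.0), psi_range=(0.0, 359.0),
                        box=128, tilt_step=8.0)


def toy_model(coords, chain="A", resnums=None, atom="CA") -> AtomicModel:
    """Build a minimal model from bare coordinates (one atom per residue)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    if resnums is None:
        resnums = np.arange(1, n + 1)
    chains = [chain] * n if isinstance(chain, str) else list(chain)
    return AtomicModel(pd.DataFrame({
        "chain": chains,
        "resnum": resnums,
        "resname": ["GLY"] * n,
        "atom": [atom] * n,
        "element": ["C"] * n,
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "b": 0.0, "occ": 1.0,
    }))
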