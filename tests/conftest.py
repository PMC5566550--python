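import numpy as np
import pytest

from phoslink.builder import Structure
from phoslink.ensemble import Ensemble


@pytest.fixture
def two_atom_ensemble_factory():
    """Build a minimal two-atom ensemble with prescribed A-B distances."""

    def make(distances):
        distances = np.asarray(distances, float)
        coords = np.zeros((len(distances), 2, 3))
        coords[:, 1, 0] = distances
        topo = Structure(["A", "B"], ["H", "H"], ["Man_red"] * 2, coords[0], [(0, 1)])
        return Ensemble(topo, coords, frame_spacing=2.0)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)
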