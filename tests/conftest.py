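import numpy as np
import pytest

from mnox.structure_io import Ligand, MnSite

#: unit directions of an ideal octahedron, order (+x,-x,+y,-y,+z,-z)
OCTA_DIRS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=float)


def make_site(vectors, elements=None, mn=(0.0, 0.0, 0.0)):
    """Build a MnSite from ligand displacement vectors (relative to Mn)."""
    mn = np.asarray(mn, dtype=float)
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    elements = elements or ["O"] * len(vectors)
    ligands = [
        Ligand(element=e, coord=mn + v, distance=float(np.linalg.norm(v)),
               atom_name=f"{e}{i+1}", serial=i + 2)
        for i, (v, e) in enumerate(zip(vectors, elements))
    ]
    return MnSite(mn_coord=mn, ligands=ligands, chain_id="A")


def octa_site(distances, elements=None, mn=(0.0, 0.0, 0.0)):
    """Ideal-geometry octahedral site with the given 6 bond lengths."""
    distances = np.asarray(distances, dtype=float)
    assert distances.shape == (6,)
    return make_site([d * u for d, u in zip(distances, OCTA_DIRS)],
                     elements=elements, mn=mn)


def random_rotation(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
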