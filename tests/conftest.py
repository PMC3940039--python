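import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from conformeq import SceneConfig, make_scene
from conformeq.data import load_fkbp12_noe_table
from conformeq.structure_io import AtomRecord, MethylGroup, ProbeSite, Structure


@pytest.fixture(scope="session")
def fkbp12():
    """The bundled FKBP12 Trp59 methyl-NOE dataset."""
    return load_fkbp12_noe_table()


@pytest.fixture(scope="session")
def scene():
    """Canonical synthetic two-conformer scene (default config, seed 1)."""
    return make_scene(SceneConfig(seed=1))


@pytest.fixture()
def ideal_methyl():
    """Methyl with carbon at the origin, antecedent on -z, ideal protons."""
    ang = math.radians(180.0 - 109.47)
    protons = np.array(
        [
            [1.09 * math.sin(ang) * math.cos(p), 1.09 * math.sin(ang) * math.sin(p),
             1.09 * math.cos(ang)]
            for p in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)
        ]
    )
    return MethylGroup(
        residue=("A", 1, "VAL"),
        carbon_name="CG1",
        carbon=np.zeros(3),
        antecedent=np.array([0.0, 0.0, -1.54]),
        protons=protons,
    )


def axial_probe(distance: float) -> ProbeSite:
    """Probe on the methyl three-fold axis (+z) at a distance from the carbon."""
    pos = np.array([0.0, 0.0, distance])
    return ProbeSite(("A", 9, "TRP"), "HE1", pos, pos + np.array([0.0, 0.98, 0.0]))


@pytest.fixture()
def valine_fragment():
    """Hand-built valine heavy-atom fragment with tetrahedral CB substituents."""
    cb = np.zeros(3)
    ca = np.array([0.0, 0.0, 1.54])
    ang = math.acos(-1.0 / 3.0)  # exact tetrahedral branch angle from CB->CA
    # CG1, CG2 on the tetrahedral cone around CB relative to CA, 120 deg apart
    def branch(phi):
        return 1.54 * np.array(
            [math.sin(ang) * math.cos(phi), math.sin(ang) * math.sin(phi),
             math.cos(ang)]
        )
    cg1 = cb + branch(0.0)
    cg2 = cb + branch(2.0 * math.pi / 3.0)
    atoms = [
        AtomRecord("A", 5, "VAL", "CA", ca),
        AtomRecord("A", 5, "VAL", "CB", cb),
        AtomRecord("A", 5, "VAL", "CG1", cg1),
        AtomRecord("A", 5, "VAL", "CG2", cg2),
    ]
    return Structure("valine-fragment", atoms)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
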