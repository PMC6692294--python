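import warnings

import numpy as np
import pytest

from sprekit.coil_ensemble import central_spre_samples
from sprekit.structure_model import AtomSite, Conformer


def make_conformer(atoms_spec, sequence):
    """Handcrafted conformer; suppresses incomplete-backbone warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atoms = [AtomSite(*spec) for spec in atoms_spec]
        return Conformer(sequence, atoms)


@pytest.fixture
def single_atom():
    return make_conformer([("CA", "C", 1, "GLY", np.zeros(3))], "G")


@pytest.fixture
def toy3():
    return make_conformer(
        [
            ("CA", "C", 1, "GLY", np.array([0.0, 0.0, 0.0])),
            ("C", "C", 1, "GLY", np.array([2.0, 1.0, 0.0])),
            ("N", "N", 1, "GLY", np.array([-1.0, 2.0, 1.0])),
        ],
        "G",
    )


@pytest.fixture(scope="session")
def master_vvavv():
    """600 per-conformer central-residue CA sPREs of AAAVVAVVAAA."""
    return central_spre_samples("VVAVV", 600, seed=101, roles=("CA",))["CA"]
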