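import numpy as np
import pytest

from loopstates import (
    Atom,
    Conformer,
    ConformerEnsemble,
    Residue,
    ToyProteinSpec,
    make_two_state_ensemble,
)


def bead(position, name="CA", element="C", het=False):
    return Atom(name=name, element=element, position=np.asarray(position, float), het=het)


def bead_residue(position, chain="A", number=1, name="GLY"):
    return Residue(chain=chain, number=number, name=name, atoms=[bead(position)])


@pytest.fixture
def s_grid():
    return np.linspace(0.01, 0.35, 100)


@pytest.fixture
def bimodal_spec():
    """Two well-separated loop states (12 / 24 Å modes, 1 Å spread)."""
    return ToyProteinSpec(closed_distance=12.0, open_distance=24.0, jitter_sd=1.0)


@pytest.fixture
def small_pool(bimodal_spec):
    """100-model two-state pool with ground-truth labels, fixed seed."""
    return make_two_state_ensemble(bimodal_spec, 100, 0.5, seed=42)


@pytest.fixture
def three_residue_model():
    residues = [
        bead_residue([0.0, 0.0, 0.0], number=1),
        bead_residue([3.8, 0.0, 0.0], number=2),
        bead_residue([7.6, 0.0, 0.0], number=3),
    ]
    return Conformer(model_id=1, residues=residues)


def single_model_pdb(tmp_path, name="single.pdb"):
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C\n"
        "ATOM      3  C   ALA A   1      10.722   5.211  -4.273  1.00 10.00           C\n"
        "ATOM      4  O   ALA A   1       9.581   4.955  -4.659  1.00 10.00           O\n"
        "ATOM      5  N   GLY A   2      11.222   4.756  -3.123  1.00 11.00           N\n"
        "ATOM      6  CA  GLY A   2      10.442   3.910  -2.213  1.00 11.00           C\n"
        "ATOM      7  C   GLY A   2      10.907   2.459  -2.253  1.00 11.00           C\n"
        "ATOM      8  O   GLY A   2      12.080   2.182  -2.512  1.00 11.00           O\n"
        "ATOM      9  N   SER A   3      10.002   1.533  -1.964  1.00 12.00           N\n"
        "ATOM     10  CA  SER A   3      10.324   0.106  -1.951  1.00 12.00           C\n"
        "END\n"
    )
    path = tmp_path / name
    path.write_text(text)
    return path
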