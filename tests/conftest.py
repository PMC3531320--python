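import numpy as np
import pytest

from allodyn.core import Atom, Ensemble, Residue, Selection, Topology
from allodyn.synthetic import ToyProteinSpec, build_toy_structure, sample_ensemble

# A 3-residue peptide with backbone + one amide hydrogen per residue,
# written as a plain PDB string so the real reader is exercised.
TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H   ALA A   1      -0.900   0.000   0.400  1.00  0.00           H
ATOM      3  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.400   2.400   0.400  1.00  0.00           O
ATOM      6  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      7  H   ALA A   2       3.900   0.700  -0.200  1.00  0.00           H
ATOM      8  CA  ALA A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      9  C   ALA A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM     10  O   ALA A   2       6.100   1.600   0.400  1.00  0.00           O
ATOM     11  N   ALA A   3       6.200   3.700   0.000  1.00  0.00           N
ATOM     12  H   ALA A   3       5.700   4.600   0.200  1.00  0.00           H
ATOM     13  CA  ALA A   3       7.600   3.800   0.000  1.00  0.00           C
ATOM     14  C   ALA A   3       8.200   5.200   0.000  1.00  0.00           C
ATOM     15  O   ALA A   3       7.500   6.200   0.400  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    p = tmp_path_factory.mktemp("toy") / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


def make_ca_topology(n_residues: int, chain: str = "A") -> Topology:
    """Minimal Cα-only topology, residue numbers 1..n."""
    residues = [Residue(chain=chain, number=i + 1, name="GLY") for i in range(n_residues)]
    atoms = [Atom(name="CA", element="C", residue_index=i) for i in range(n_residues)]
    return Topology(residues=residues, atoms=atoms)


def random_ensemble(n_residues: int, n_frames: int, seed: int, scale: float = 1.0) -> Ensemble:
    """Gaussian cloud around a stretched chain: generic statistical input."""
    rng = np.random.default_rng(seed)
    base = np.zeros((n_residues, 3))
    base[:, 0] = 3.8 * np.arange(n_residues)
    base[:, 1] = rng.uniform(-2, 2, n_residues)
    coords = base[None] + scale * rng.standard_normal((n_frames, n_residues, 3))
    return Ensemble(topology=make_ca_topology(n_residues), coords=coords)


def all_ca(topology: Topology) -> Selection:
    idx = [i for i, a in enumerate(topology.atoms) if a.name == "CA"]
    return Selection(np.array(idx), provenance="CA")


@pytest.fixture(scope="session")
def two_block_structure():
    spec = ToyProteinSpec()
    return spec, build_toy_structure(spec)


@pytest.fixture(scope="session")
def two_block_ensemble(two_block_structure):
    spec, st = two_block_structure
    return st, sample_ensemble(st, spec, "apo", 120, seed=11)
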