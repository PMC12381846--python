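import numpy as np
import pytest
from hypothesis import settings

import rotafit as rf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: free amino acids as SMILES; backbone auto-detected from the N-CA-C(=O) motif
AA_SMILES = {
    "ALA": "NC(C)C(=O)O",
    "GLY": "NCC(=O)O",
    "SER": "NC(CO)C(=O)O",
    "CYS": "NC(CS)C(=O)O",
    "THR": "NC(C(O)C)C(=O)O",
    "VAL": "NC(C(C)C)C(=O)O",
    "ILE": "NC(C(C)CC)C(=O)O",
    "LEU": "NC(CC(C)C)C(=O)O",
    "ASP": "NC(CC(=O)O)C(=O)O",
    "ASN": "NC(CC(N)=O)C(=O)O",
    "GLU": "NC(CCC(=O)O)C(=O)O",
    "GLN": "NC(CCC(N)=O)C(=O)O",
    "MET": "NC(CCSC)C(=O)O",
    "LYS": "NC(CCCCN)C(=O)O",
    "ARG": "NC(CCCNC(=N)N)C(=O)O",
    "PHE": "NC(Cc1ccccc1)C(=O)O",
    "TYR": "NC(Cc1ccc(O)cc1)C(=O)O",
    "TRP": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "HIS": "NC(Cc1c[nH]cn1)C(=O)O",
    "PRO": "OC(=O)C1CCCN1",
}


def textbook_dihedral(p0, p1, p2, p3):
    """Independent signed four-atom dihedral (degrees), IUPAC convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    return float(np.degrees(np.arctan2(
        np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)), np.dot(n1, n2))))


@pytest.fixture(scope="session")
def leu_dipeptide():
    spec = rf.load_residue(AA_SMILES["LEU"], "smiles", name="LEU")
    return rf.build_dipeptide(spec)


@pytest.fixture(scope="session")
def leu_chi_defs(leu_dipeptide):
    return rf.derive_chi_definitions(leu_dipeptide)


@pytest.fixture(scope="session")
def leu_small_ensemble(leu_dipeptide):
    """300 scored leucine-dipeptide conformers, shared across tests."""
    ens = rf.generate_conformers(leu_dipeptide, 300, seed=11)
    return rf.score_sidechain_energy(ens)


@pytest.fixture(scope="session")
def two_chi_wells():
    """A leucine-like two-chi ground truth with four unequal wells."""
    return [
        rf.SyntheticWellSpec((-60.0, 180.0), (10.0, 12.0), 0.4),
        rf.SyntheticWellSpec((60.0, 60.0), (8.0, 9.0), 0.3),
        rf.SyntheticWellSpec((180.0, -60.0), (15.0, 10.0), 0.2),
        rf.SyntheticWellSpec((60.0, 180.0), (9.0, 11.0), 0.1),
    ]
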