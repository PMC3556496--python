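import numpy as np
import pytest

from xtalface.structure import (AtomRecord, Chain, CrystalStructure,
                                ResidueRecord)
from xtalface.synthetic import FixtureSpec, make_crystal_fixture


def make_chain(chain_id: str, coords, res_type: str = "ALA",
               atom_name: str = "CA", radius: float = 1.70) -> Chain:
    """One single-atom residue per coordinate; the workhorse toy chain."""
    residues = []
    for i, xyz in enumerate(np.asarray(coords, dtype=float), start=1):
        atom = AtomRecord(name=atom_name, element="C", coords=xyz,
                          vdw_radius=radius)
        residues.append(ResidueRecord(chain_id=chain_id, seq_num=i,
                                      ins_code="", res_type=res_type,
                                      atoms=[atom], is_standard_aa=True))
    return Chain(chain_id=chain_id, residues=residues)


def two_chain_structure(coords_a, coords_b) -> CrystalStructure:
    return CrystalStructure(chains=[make_chain("A", coords_a),
                                    make_chain("B", coords_b)], cell=None)


@pytest.fixture(scope="session")
def slab_spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def slab_pdb(slab_spec):
    text, truth = make_crystal_fixture(slab_spec)
    return text, truth


def dipeptide_atoms():
    """Idealized Ala-Ala heavy atoms: (name, element, xyz, radius)."""
    data = [
        ("N",  "N", (0.00, 0.00, 0.00), 1.55),
        ("CA", "C", (1.46, 0.00, 0.00), 1.70),
        ("C",  "C", (2.00, 1.42, 0.00), 1.70),
        ("O",  "O", (1.25, 2.39, 0.00), 1.52),
        ("CB", "C", (2.00, -0.76, 1.20), 1.70),
        ("N",  "N", (3.33, 1.54, 0.00), 1.55),
        ("CA", "C", (3.97, 2.85, 0.00), 1.70),
        ("C",  "C", (5.48, 2.71, 0.00), 1.70),
        ("O",  "O", (6.00, 1.59, 0.00), 1.52),
        ("CB", "C", (3.55, 3.65, 1.23), 1.70),
    ]
    coords = np.array([xyz for _, _, xyz, _ in data])
    radii = np.array([r for _, _, _, r in data])
    return coords, radii
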