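"""Parsing, symmetry expansion, interface enumeration and clash counting."""

import numpy as np
import pytest

from xtalface.structure import (CrystalCell, CrystalStructure,
                                UnsupportedSpaceGroupError, count_clashes,
                                enumerate_interfaces, expand_lattice,
                                parse_structure)
from xtalface.synthetic import FixtureSpec, make_crystal_fixture

from conftest import make_chain, two_chain_structure

MINIMAL_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA A   1       5.000   5.000   5.000  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40 10.00           C
END
"""

WATER_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA A   1       5.000   5.000   5.000  1.00 10.00           C
HETATM    2  O   HOH A 101       8.000   5.000   5.000  1.00 10.00           O
END
"""


class TestParsing:
    def test_minimal_single_atom(self):
        st = parse_structure(MINIMAL_PDB)
        assert len(st.chains) == 1
        assert len(st.chains[0].residues) == 1
        assert st.chains[0].n_atoms == 1
        assert st.is_crystal
        assert st.cell.space_group in ("P 1", "P1")

    def test_altloc_keeps_highest_occupancy(self):
        st = parse_structure(ALTLOC_PDB)
        chain = st.chains[0]
        assert chain.n_atoms == 1
        np.testing.assert_allclose(chain.coords[0], [1.0, 0.0, 0.0])

    def test_waters_excluded(self):
        st = parse_structure(WATER_PDB)
        assert sum(ch.n_atoms for ch in st.chains) == 1
        assert all(r.res_type != "HOH"
                   for ch in st.chains for r in ch.residues)

    def test_unknown_space_group_raises(self):
        with pytest.raises(UnsupportedSpaceGroupError, match="Q 9"):
            CrystalCell.from_symbol(30, 30, 30, 90, 90, 90, "Q 9")

    def test_garbage_rejected(self):
        with pytest.raises(Exception):
            parse_structure("this is not a structure file")

    def test_mmcif_dialect_round_trip(self, slab_pdb):
        import gemmi
        st_gemmi = gemmi.read_pdb_string(slab_pdb[0])
        st_gemmi.setup_entities()
        cif_text = st_gemmi.make_mmcif_document().as_string()
        from_pdb = parse_structure(slab_pdb[0])
        from_cif = parse_structure(cif_text)
        assert [c.chain_id for c in from_cif.chains] == \
               [c.chain_id for c in from_pdb.chains]
        assert sum(c.n_atoms for c in from_cif.chains) == \
               sum(c.n_atoms for c in from_pdb.chains)
        assert len(enumerate_interfaces(from_cif)) == \
               len(enumerate_interfaces(from_pdb))


class TestSymmetry:
    def test_operator_count_and_identity_first(self):
        cell = CrystalCell.from_symbol(20, 25, 30, 90, 90, 90, "P 21 21 21")
        assert len(cell.operators) == 4
        rot0, tran0 = cell.operators[0]
        assert np.array_equal(rot0, np.eye(3)) and not tran0.any()

    def test_operator_set_closed_under_composition(self):
        cell = CrystalCell.from_symbol(20, 25, 30, 90, 90, 120, "P 32")
        ops = cell.operators
        for r1, t1 in ops:
            for r2, t2 in ops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                assert any(np.allclose(r, rr) and
                           np.allclose(t, tt % 1.0, atol=1e-9)
                           for rr, tt in ops)

    def test_operators_are_isometries(self):
        cell = CrystalCell.from_symbol(20, 25, 30, 90, 100, 90, "P 1 21 1")
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 15, size=(2, 3))
        rot, tran = cell.operators[1]
        frac = pts @ cell.frac.T
        moved = (frac @ rot.T + tran) @ cell.orth.T
        d0 = np.linalg.norm(pts[0] - pts[1])
        d1 = np.linalg.norm(moved[0] - moved[1])
        assert abs(d0 - d1) < 1e-6

    def test_isolated_chain_keeps_identity_only(self, slab_pdb):
        st = parse_structure(slab_pdb[0])
        instances = expand_lattice(st)
        # big padded P1 cell: all periodic images pruned away
        assert all(inst.is_identity for inst in instances)
        assert len(instances) == len(st.chains)


def brute_force_contacts(structure: CrystalStructure, cutoff: float):
    """Independent O(n^2) all-pairs contact scan over identity chains."""
    out = []
    chains = structure.chains
    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            diff = a.coords[:, None, :] - b.coords[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=2))
            pairs = {(ia, ib) for ia, ib in zip(*np.nonzero(dist <= cutoff))}
            if pairs:
                out.append(((a.chain_id, b.chain_id), pairs))
    return out


class TestEnumeration:
    @pytest.mark.parametrize("gap,expected", [(5.0, 1), (5.9, 1),
                                              (6.1, 0), (7.0, 0)])
    def test_six_angstrom_rule(self, gap, expected):
        text, truth = make_crystal_fixture(FixtureSpec(inter_chain_gap=gap))
        st = parse_structure(text)
        interfaces = enumerate_interfaces(st)
        assert len(interfaces) == expected == truth["n_interfaces"]

    @pytest.mark.parametrize("cutoff", [3.0, 4.5, 6.0, 7.2, 8.0])
    def test_matches_bruteforce_all_pairs(self, cutoff):
        text, _ = make_crystal_fixture(FixtureSpec(inter_chain_gap=4.0))
        st = parse_structure(text)
        assert sum(ch.n_atoms for ch in st.chains) <= 500
        expected = brute_force_contacts(st, cutoff)
        interfaces = enumerate_interfaces(st, contact_cutoff=cutoff)
        assert len(interfaces) == len(expected)
        for iface, (_, pairs) in zip(interfaces, expected):
            got = {(ia, ib) for ia, ib, _ in iface.contact_pairs}
            assert got == pairs

    def test_symmetric_lattice_dedup_and_invariance(self):
        # one compact chain in a tight P 21 21 21 cell: several symmetry
        # images make contact, and each interface must be reported once
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 6.5, size=(20, 3))
        chain = make_chain("A", coords)
        cell = CrystalCell.from_symbol(13, 14, 15, 90, 90, 90, "P 21 21 21")
        st = CrystalStructure(chains=[chain], cell=cell)
        interfaces = enumerate_interfaces(st)
        assert interfaces, "expected lattice contacts in a tight cell"
        # dedup: no two interfaces share the residue-pair/distance multiset
        fingerprints = set()
        for iface in interfaces:
            cha, chb = iface.side_a.chain, iface.side_b.chain
            resolved = sorted(
                (tuple(sorted((cha.residues[cha.atom_residue[ia]].key,
                               chb.residues[chb.atom_residue[ib]].key))),
                 round(d, 2))
                for ia, ib, d in iface.contact_pairs)
            fingerprints.add(tuple(resolved))
        assert len(fingerprints) == len(interfaces)
        # identity chain never paired with itself un-transformed
        for iface in interfaces:
            assert not (iface.side_a.is_identity and iface.side_b.is_identity
                        and iface.side_a.chain is iface.side_b.chain)
        # applying operator 1 to the asymmetric unit leaves the multiset of
        # contact distances unchanged
        rot, tran = cell.operators[1]
        moved = ((coords @ cell.frac.T) @ rot.T + tran) @ cell.orth.T
        st2 = CrystalStructure(chains=[make_chain("A", moved)], cell=cell)
        d1 = sorted(round(d, 5) for f in interfaces for _, _, d in f.contact_pairs)
        d2 = sorted(round(d, 5)
                    for f in enumerate_interfaces(st2)
                    for _, _, d in f.contact_pairs)
        assert d1 == pytest.approx(d2, abs=1e-5)


class TestClashes:
    def test_superposed_chains_count_matched_atoms(self):
        coords = np.array([[2.0 * i, 0.0, 0.0] for i in range(10)])
        st = two_chain_structure(coords, coords)
        iface = enumerate_interfaces(st)[0]
        assert count_clashes(iface) == 10
        assert iface.is_suspicious

    @pytest.mark.parametrize("dist,expected", [(1.6, 0), (1.4, 1)])
    def test_single_pair_boundary(self, dist, expected):
        st = two_chain_structure([[0.0, 0.0, 0.0]], [[dist, 0.0, 0.0]])
        iface = enumerate_interfaces(st)[0]
        assert count_clashes(iface) == expected

    def test_tight_fixture_flagged_suspicious(self):
        text, truth = make_crystal_fixture(FixtureSpec(inter_chain_gap=0.5))
        st = parse_structure(text)
        iface = enumerate_interfaces(st)[0]
        assert truth["suspicious"]
        assert count_clashes(iface) == truth["clash_pairs_1p5A"] > 5
        assert iface.is_suspicious
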