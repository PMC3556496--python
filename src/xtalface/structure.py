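"""Crystal structure model: parsing, symmetry expansion, interface enumeration.

A crystal lattice is rebuilt from the asymmetric unit by applying every
space-group operator combined with unit-cell translations in the 27-cell
neighborhood of the origin cell.  Any pair of chain instances with at least
one atom of each side within the contact cutoff (6 A by default) defines a
candidate interface; symmetry-equivalent duplicates are collapsed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import DEFAULT_VDW_RADIUS, STANDARD_AA, THREE_TO_ONE, VDW_RADII

CONTACT_CUTOFF = 6.0     # A; "at least 1 atom of each side within 6 A"
CLASH_CUTOFF = 1.5       # A; atoms closer than this are clashing
MAX_CLASHES = 5          # more than this marks an interface suspicious
BBOX_MARGIN = 3.0        # extra inflation of bounding boxes when pruning


class StructureParseError(ValueError):
    """The file content could not be interpreted as a structure."""


class UnsupportedSpaceGroupError(ValueError):
    """The declared space-group symbol is not in the symmetry library."""


class InvalidCellError(ValueError):
    """The unit cell is degenerate (zero volume)."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray          # (3,) orthonormal A
    occupancy: float = 1.0
    alt_loc: str = ""
    vdw_radius: float = DEFAULT_VDW_RADIUS


@dataclass
class ResidueRecord:
    chain_id: str
    seq_num: int
    ins_code: str
    res_type: str               # 3-letter code
    atoms: list[AtomRecord]
    is_standard_aa: bool

    @property
    def key(self) -> tuple[str, int, str]:
        """Author chain id + author residue number + insertion code."""
        return (self.chain_id, self.seq_num, self.ins_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_type, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueRecord]
    # flat per-atom arrays, parallel to each other
    coords: np.ndarray = field(default=None, repr=False)    # (n_atoms, 3)
    radii: np.ndarray = field(default=None, repr=False)     # (n_atoms,)
    atom_residue: np.ndarray = field(default=None, repr=False)  # (n_atoms,) residue index

    def __post_init__(self):
        self._atoms = [a for r in self.residues for a in r.atoms]
        if self.coords is None:
            self.coords = np.asarray(
                [a.coords for a in self._atoms], dtype=float).reshape(-1, 3)
            self.radii = np.asarray([a.vdw_radius for a in self._atoms])
            self.atom_residue = np.asarray(
                [i for i, r in enumerate(self.residues) for _ in r.atoms],
                dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atom_records(self) -> list[AtomRecord]:
        return self._atoms


@dataclass
class CrystalCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str
    operators: list[tuple[np.ndarray, np.ndarray]]  # (3x3 rot, frac translation)

    def __post_init__(self):
        cell = gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)
        if cell.volume <= 1e-6:
            raise InvalidCellError(
                f"degenerate unit cell {self.a} {self.b} {self.c} "
                f"{self.alpha} {self.beta} {self.gamma}")
        self.orth = np.array(cell.orth.mat.tolist())
        self.frac = np.array(cell.frac.mat.tolist())

    @classmethod
    def from_symbol(cls, a, b, c, alpha, beta, gamma, symbol: str) -> "CrystalCell":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise UnsupportedSpaceGroupError(
                f"unknown space-group symbol: {symbol!r}")
        ops = []
        for op in sg.operations().sym_ops:
            rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
            tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
            ops.append((rot, tran))
        # identity operator first
        ops.sort(key=lambda rt: 0 if (np.array_equal(rt[0], np.eye(3))
                                      and not rt[1].any()) else 1)
        return cls(a, b, c, alpha, beta, gamma, sg.hm, ops)


@dataclass
class CrystalStructure:
    chains: list[Chain]
    cell: CrystalCell | None = None

    @property
    def is_crystal(self) -> bool:
        return self.cell is not None

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)


@dataclass
class ChainInstance:
    """A symmetry-placed copy of a chain: operator + unit-cell shift applied."""

    chain: Chain
    operator_index: int
    cell_shift: tuple[int, int, int]
    coords: np.ndarray          # (n_atoms, 3), transformed orthonormal A

    @property
    def is_identity(self) -> bool:
        return self.operator_index == 0 and self.cell_shift == (0, 0, 0)

    @property
    def label(self) -> str:
        if self.is_identity:
            return self.chain.chain_id
        i, j, k = self.cell_shift
        return f"{self.chain.chain_id}_{self.operator_index}({i},{j},{k})"


@dataclass
class Interface:
    """An ordered pair of chain instances in atomic contact."""

    id: int
    side_a: ChainInstance
    side_b: ChainInstance
    # (atom index into side_a.coords, atom index into side_b.coords, distance A)
    contact_pairs: list[tuple[int, int, float]]
    area: float = 0.0
    clash_count: int = 0

    @property
    def contact_residue_pairs(self) -> set[tuple[tuple, tuple]]:
        out = set()
        for ia, ib, _ in self.contact_pairs:
            ra = self.side_a.chain.residues[self.side_a.chain.atom_residue[ia]]
            rb = self.side_b.chain.residues[self.side_b.chain.atom_residue[ib]]
            out.add((ra.key, rb.key))
        return out

    @property
    def is_suspicious(self) -> bool:
        return self.clash_count > MAX_CLASHES


def _residue_from_gemmi(res: gemmi.Residue, chain_id: str,
                        radii: dict[str, float]) -> ResidueRecord | None:
    """Convert a gemmi residue, resolving alt-locs and dropping hydrogens."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.element.name in ("H", "D"):
            continue
        prev = by_name.get(atom.name)
        # highest occupancy wins; ties keep the first occurrence in the file
        if prev is None or atom.occ > prev.occ + 1e-9:
            by_name[atom.name] = atom
    if not by_name:
        return None
    atoms = []
    for name, atom in by_name.items():
        elem = atom.element.name.upper()
        atoms.append(AtomRecord(
            name=name,
            element=elem,
            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            occupancy=atom.occ,
            alt_loc=atom.altloc or "",
            vdw_radius=radii.get(elem, DEFAULT_VDW_RADIUS),
        ))
    res_type = res.name.upper()
    return ResidueRecord(
        chain_id=chain_id,
        seq_num=res.seqid.num,
        ins_code=res.seqid.icode.strip(),
        res_type=res_type,
        atoms=atoms,
        is_standard_aa=THREE_TO_ONE.get(res_type, "X") in STANDARD_AA,
    )


def _is_amino_acid(name: str) -> bool:
    if name.upper() in THREE_TO_ONE:
        return True
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def parse_structure(file_content: str,
                    vdw_radii: dict[str, float] | None = None) -> CrystalStructure:
    """Parse PDB or mmCIF text into a :class:`CrystalStructure`.

    Polymer protein chains are kept; waters and non-polymer ligands are
    excluded from the interface-bearing atom set.  For atoms with alternate
    locations only the highest-occupancy conformer is retained.  A file
    without a declared cell/space group is accepted as a non-crystal model
    (interfaces are then sought between the given chains only).
    """
    radii = dict(VDW_RADII if vdw_radii is None else vdw_radii)
    text = file_content.lstrip()
    try:
        if text.startswith("data_") or "_atom_site." in text:
            doc = gemmi.cif.read_string(file_content)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_pdb_string(file_content)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError("structure contains no models")
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    for ch in model:
        residues = []
        for res in ch:
            if res.name in ("HOH", "WAT", "DOD"):
                continue
            if not _is_amino_acid(res.name):
                continue
            rec = _residue_from_gemmi(res, ch.name, radii)
            if rec is not None:
                residues.append(rec)
        if residues:
            chains.append(Chain(chain_id=ch.name, residues=residues))
    if not chains:
        raise StructureParseError("no protein chains found")

    cell = None
    gcell = st.cell
    symbol = (st.spacegroup_hm or "").strip()
    if gcell.is_crystal() and gcell.volume > 1e-6:
        if not symbol:
            symbol = "P 1"
        cell = CrystalCell.from_symbol(gcell.a, gcell.b, gcell.c,
                                       gcell.alpha, gcell.beta, gcell.gamma,
                                       symbol)
    elif symbol and symbol not in ("P 1", "P1"):
        # declared symmetry but no usable cell
        raise StructureParseError("space group declared without a valid cell")
    return CrystalStructure(chains=chains, cell=cell)


def _bbox(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return coords.min(axis=0), coords.max(axis=0)


def _boxes_near(lo1, hi1, lo2, hi2, margin: float) -> bool:
    return bool(np.all(lo1 - margin <= hi2) and np.all(lo2 - margin <= hi1))


def expand_lattice(structure: CrystalStructure,
                   contact_cutoff: float = CONTACT_CUTOFF,
                   margin: float = BBOX_MARGIN) -> list[ChainInstance]:
    """Generate symmetry images of every chain in the 27-cell neighborhood.

    Returns the identity instances plus every image whose bounding box comes
    within ``contact_cutoff + margin`` of an identity chain.  For a
    non-crystal model only the identity instances are returned.
    """
    identity = [ChainInstance(ch, 0, (0, 0, 0), ch.coords.copy())
                for ch in structure.chains]
    if structure.cell is None:
        return identity
    cell = structure.cell
    boxes = [_bbox(inst.coords) for inst in identity]
    out = list(identity)
    reach = contact_cutoff + margin
    shifts = [(i, j, k)
              for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for ch in structure.chains:
        frac = ch.coords @ cell.frac.T
        for op_idx, (rot, tran) in enumerate(cell.operators):
            base = frac @ rot.T + tran
            for shift in shifts:
                if op_idx == 0 and shift == (0, 0, 0):
                    continue
                moved = (base + np.asarray(shift, dtype=float)) @ cell.orth.T
                lo, hi = _bbox(moved)
                if any(_boxes_near(lo, hi, blo, bhi, reach)
                       for blo, bhi in boxes):
                    out.append(ChainInstance(ch, op_idx, shift, moved))
    return out


def _contact_pairs(a: ChainInstance, b: ChainInstance,
                   cutoff: float) -> list[tuple[int, int, float]]:
    tree_b = cKDTree(b.coords)
    pairs = []
    for ia, neighbors in enumerate(cKDTree(a.coords).query_ball_tree(tree_b, cutoff)):
        if not neighbors:
            continue
        d = np.linalg.norm(b.coords[neighbors] - a.coords[ia], axis=1)
        for ib, dist in zip(neighbors, d):
            if dist <= cutoff:
                pairs.append((ia, int(ib), float(dist)))
    return pairs


def _fingerprint(interface: Interface) -> frozenset:
    """Symmetry-invariant identity of an interface.

    The sorted multiset of contacting atom identities with distances rounded
    to 0.01 A; the two sides of each pair are order-canonicalized so that
    A-against-image-of-B and B-against-inverse-image-of-A collapse.
    """
    items = []
    cha, chb = interface.side_a.chain, interface.side_b.chain
    for ia, ib, d in interface.contact_pairs:
        ra = cha.residues[cha.atom_residue[ia]]
        rb = chb.residues[chb.atom_residue[ib]]
        ka = (ra.chain_id, ra.seq_num, ra.ins_code, cha.atom_records()[ia].name)
        kb = (rb.chain_id, rb.seq_num, rb.ins_code, chb.atom_records()[ib].name)
        lo, hi = sorted((ka, kb))
        items.append((lo, hi, round(d, 2)))
    return frozenset(items)


def count_clashes(interface: Interface,
                  clash_cutoff: float = CLASH_CUTOFF) -> int:
    """Number of cross-interface atom pairs closer than ``clash_cutoff``."""
    return sum(1 for _, _, d in interface.contact_pairs if d < clash_cutoff)


def enumerate_interfaces(structure: CrystalStructure,
                         contact_cutoff: float = CONTACT_CUTOFF,
                         instances: list[ChainInstance] | None = None
                         ) -> list[Interface]:
    """Find all unique pairwise chain-chain interfaces in the lattice.

    A pair qualifies when at least one atom of each side lies within
    ``contact_cutoff``.  Each interface appears once: symmetry-equivalent
    duplicates (the same contact seen from either partner) are collapsed by
    a contact-multiset fingerprint, keeping the first occurrence.  Interface
    ids are assigned in discovery order; ranking by area is done after
    burial computation.
    """
    if instances is None:
        instances = expand_lattice(structure, contact_cutoff)
    identity = [inst for inst in instances if inst.is_identity]
    images = [inst for inst in instances if not inst.is_identity]
    identity.sort(key=lambda inst: inst.chain.chain_id)

    candidates: list[tuple[ChainInstance, ChainInstance]] = []
    for i, a in enumerate(identity):
        for b in identity[i + 1:]:
            candidates.append((a, b))
        for b in images:
            candidates.append((a, b))

    interfaces: list[Interface] = []
    seen: set[frozenset] = set()
    next_id = 1
    for a, b in candidates:
        lo_a, hi_a = _bbox(a.coords)
        lo_b, hi_b = _bbox(b.coords)
        if not _boxes_near(lo_a, hi_a, lo_b, hi_b, contact_cutoff):
            continue
        pairs = _contact_pairs(a, b, contact_cutoff)
        if not pairs:
            continue
        iface = Interface(id=next_id, side_a=a, side_b=b, contact_pairs=pairs)
        fp = _fingerprint(iface)
        if fp in seen:
            continue
        seen.add(fp)
        iface.clash_count = count_clashes(iface)
        interfaces.append(iface)
        next_id += 1
    return interfaces
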