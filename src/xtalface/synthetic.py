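"""Synthetic mini-crystals and alignments with known ground truth.

The generator emulates the statistical structure the classifier assumes:
a crystal contact between two chains whose interface core is either under
strong purifying selection (conserved columns, a biological interface) or
evolving like the rest of the surface (a packing artifact).

Chains are idealized poly-alanine slabs: residues on a cubic lattice
(one C-alpha per residue) tight enough that interior residues are fully
occluded and the contact face buries almost completely against the
partner.  The geometry is intentionally schematic — accessible areas only
need to be internally consistent for the classification logic, not
physically realistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np

LATTICE_SPACING = 3.5   # A; tight enough for complete interior occlusion
CELL_PADDING = 30.0     # A of empty space so periodic images stay remote

# one representative of each reduced-alphabet class other than alanine's
_MUTATION_PALETTE = ("L", "C", "G", "S", "P", "F", "E", "K", "H")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_chains: int = 2
    chain_length: int = 72          # nx*ny*nz residues on the slab lattice
    slab_shape: tuple[int, int, int] = (2, 6, 6)   # (nx, ny, nz)
    inter_chain_gap: float = 4.5    # A, closest approach between chains
    conserved_positions: frozenset[int] = frozenset()
    background_mutation_rate: float = 0.25
    n_homologs: int = 50
    # per-homolog identity to the query; None -> use the flat background
    # mutation rate for every homolog instead
    planted_identity_range: tuple[float, float] | None = (0.60, 0.95)
    # fraction of non-contact surface conserved in every fixture flavor,
    # emulating functional surface patches (active sites, other interfaces)
    surface_conserved_fraction: float = 0.2

    def __post_init__(self):
        nx, ny, nz = self.slab_shape
        if nx * ny * nz != self.chain_length:
            raise ValueError("slab_shape must multiply to chain_length")
        if self.inter_chain_gap <= 0:
            raise ValueError("inter_chain_gap must be positive")


def _grid_coords(spec: FixtureSpec) -> np.ndarray:
    """Lattice coordinates; residue index = ix*ny*nz + iy*nz + iz."""
    nx, ny, nz = spec.slab_shape
    pts = [(ix, iy, iz)
           for ix in range(nx) for iy in range(ny) for iz in range(nz)]
    return np.asarray(pts, dtype=float) * LATTICE_SPACING


def contact_face(spec: FixtureSpec, side: str) -> frozenset[int]:
    """Residue indices on the face that touches the partner chain.

    Chain A presents its +x face, chain B its -x face.
    """
    nx, ny, nz = spec.slab_shape
    ix = nx - 1 if side == "A" else 0
    return frozenset(ix * ny * nz + iy * nz + iz
                     for iy in range(ny) for iz in range(nz))


def contact_core(spec: FixtureSpec, side: str) -> frozenset[int]:
    """Interior of the contact face: the residues that bury almost fully.

    The face's boundary ring stays partially exposed in the complex and
    lands in the rim, so a conserved-core fixture plants conservation on
    the interior only and leaves the rim free to vary.
    """
    nx, ny, nz = spec.slab_shape
    ix = nx - 1 if side == "A" else 0
    return frozenset(ix * ny * nz + iy * nz + iz
                     for iy in range(1, ny - 1) for iz in range(1, nz - 1))


def make_crystal_fixture(spec: FixtureSpec) -> tuple[str, dict]:
    """Two poly-alanine slab chains in a P1 cell at the requested gap.

    Returns PDB text plus a ground-truth dictionary (closest approach,
    brute-force contact and clash pair counts at the standard cutoffs, and
    the expected number of interfaces).
    """
    coords_a = _grid_coords(spec)
    span_x = coords_a[:, 0].max() - coords_a[:, 0].min()
    shift = span_x + spec.inter_chain_gap
    if not np.isfinite(shift):
        raise ValueError("fixture geometry out of range")
    coords_b = coords_a + np.array([shift, 0.0, 0.0])

    all_coords = np.vstack([coords_a, coords_b])
    extent = all_coords.max(axis=0) - all_coords.min(axis=0)
    cell = extent + CELL_PADDING

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(cell[0], cell[1], cell[2], 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    for cid, coords in zip("AB"[:spec.n_chains],
                           (coords_a, coords_b)[:spec.n_chains]):
        chain = gemmi.Chain(cid)
        for i, xyz in enumerate(coords, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    pdb_text = st.make_pdb_string()

    # brute-force ground truth, independent of the KD-tree search path
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    truth = {
        "closest_approach": float(dist.min()),
        "contact_pairs_6A": int((dist <= 6.0).sum()),
        "clash_pairs_1p5A": int((dist < 1.5).sum()),
        "n_interfaces": int(bool((dist <= 6.0).any())) if spec.n_chains == 2 else 0,
        "suspicious": bool((dist < 1.5).sum() > 5),
    }
    return pdb_text, truth


def make_msa_fixture(spec: FixtureSpec,
                     conserved: frozenset[int] | None = None,
                     rng: np.random.Generator | None = None,
                     query_id: str = "query") -> tuple[list[tuple[str, str]], dict]:
    """Query plus homologs mutated everywhere except the conserved positions.

    Mutations swap alanine for residues of other reduced-alphabet classes,
    so entropy rises exactly where intended.  Per-homolog identities to the
    query are planted inside ``planted_identity_range``; every free
    position is guaranteed to be mutated in at least one homolog so the
    conserved mask round-trips through empirical entropies.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if conserved is None:
        conserved = spec.conserved_positions
    length = spec.chain_length
    query = "A" * length
    free = sorted(set(range(length)) - set(conserved))

    rows: list[list[str]] = []
    mutated_sets: list[set[int]] = []
    for _ in range(spec.n_homologs):
        if spec.planted_identity_range is None:
            rate = spec.background_mutation_rate
        else:
            lo, hi = spec.planted_identity_range
            rate = rng.uniform(1.0 - hi, 1.0 - lo)
        n_mut = min(len(free), int(round(rate * length)))
        positions = set(rng.choice(free, size=n_mut, replace=False)) \
            if n_mut else set()
        mutated_sets.append(positions)

    # guarantee coverage: every free position mutated somewhere, so the
    # conserved mask round-trips through empirical entropies (skipped in
    # the degenerate no-mutation case)
    covered = set().union(*mutated_sets) if mutated_sets else set()
    if not covered:
        free = []
    for pos in free:
        if pos in covered:
            continue
        order = rng.permutation(spec.n_homologs)
        for h in order:
            swappable = mutated_sets[h] - covered
            if swappable:
                out = sorted(swappable)[int(rng.integers(len(swappable)))]
                mutated_sets[h].discard(out)
                mutated_sets[h].add(pos)
                covered.add(pos)
                break
        else:
            mutated_sets[int(order[0])].add(pos)
            covered.add(pos)

    for positions in mutated_sets:
        seq = list(query)
        for pos in sorted(positions):
            seq[pos] = _MUTATION_PALETTE[int(rng.integers(len(_MUTATION_PALETTE)))]
        rows.append(seq)

    alignment = [(query_id, query)] + [
        (f"hom{i:03d}", "".join(seq)) for i, seq in enumerate(rows)]
    truth = {
        "conserved_positions": sorted(conserved),
        "identities": [1.0 - len(s) / length for s in mutated_sets],
    }
    return alignment, truth


@dataclass
class EndToEndFixture:
    structure_text: str
    alignments: dict[str, list[tuple[str, str]]]
    crystal_truth: dict
    conserved_core: bool
    expected: dict = field(default_factory=dict)

    def ground_truth_json(self) -> str:
        return json.dumps({"crystal": self.crystal_truth,
                           "conserved_core": self.conserved_core,
                           "expected": self.expected}, indent=2)


def make_end_to_end_fixture(spec: FixtureSpec,
                            conserved_core: bool = True) -> EndToEndFixture:
    """Structure plus per-chain alignments with a planted selection signal.

    With ``conserved_core`` the residues of each chain's contact face are
    perfectly conserved while the rest of the sequence mutates at the
    background rate, so the evolutionary criteria should call the interface
    biological.  Without it, all positions mutate alike and the interface
    carries no evolutionary signal.
    """
    structure_text, crystal_truth = make_crystal_fixture(spec)
    rng = np.random.default_rng(spec.seed)
    alignments = {}
    for cid in ("A", "B"):
        face = contact_face(spec, cid)
        off_face = sorted(set(range(spec.chain_length)) - face)
        n_patch = int(round(spec.surface_conserved_fraction * len(off_face)))
        patch = set(rng.choice(off_face, size=n_patch, replace=False)) \
            if n_patch else set()
        conserved = frozenset(patch | (set(contact_core(spec, cid))
                                       if conserved_core else set()))
        alignment, _ = make_msa_fixture(spec, conserved=conserved, rng=rng,
                                        query_id=cid)
        alignments[cid] = alignment
    expected = {
        "evolutionary_calls": "BIO" if conserved_core else "XTAL-or-NOPRED",
    }
    return EndToEndFixture(structure_text=structure_text,
                           alignments=alignments,
                           crystal_truth=crystal_truth,
                           conserved_core=conserved_core,
                           expected=expected)
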