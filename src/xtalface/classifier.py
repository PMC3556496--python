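"""Final verdict: combine geometry and evolutionary calls for an interface.

The three indicators (core-size geometry, core-rim entropy ratio,
core-surface entropy score) are merged by a 2-of-3 majority vote, with the
following unconditional overrides and fallbacks:

* a wild-type cross-interface disulfide bridge forces BIO;
* interfaces larger than 2200 A^2 are always biological; smaller than
  400 A^2 always crystal (the low limit does not apply to protein-peptide
  interfaces);
* if both evolutionary criteria are unavailable the geometric call stands;
* if exactly one evolutionary criterion is available and it disagrees with
  geometry, the evolutionary call is preferred.

Engineering artifacts (structure residues mismatching their reference
sequence) produce warnings; too many mismatches among the scored residues
veto the evolutionary criteria entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .evolution import ReferenceMapping
from .geometry import BIO, NOPRED, XTAL
from .structure import Interface

HARD_BIO_AREA = 2200.0    # A^2; above -> always biological
HARD_XTAL_AREA = 400.0    # A^2; below -> always crystal (non-peptide)
PEPTIDE_MAX_RESIDUES = 30  # chains shorter than this count as peptides
DISULFIDE_RANGE = (1.8, 2.5)  # A, S-gamma to S-gamma
MAX_MISMATCH_FRACTION = 0.10  # of scored residues; above -> evolution veto


@dataclass(frozen=True)
class HardLimits:
    bio_area: float = HARD_BIO_AREA
    xtal_area: float = HARD_XTAL_AREA

    def __post_init__(self):
        if self.xtal_area >= self.bio_area:
            raise ValueError("crystal hard limit must be below the bio one")


@dataclass
class InterfaceVerdict:
    interface_id: int
    area: float
    call_geometry: str
    call_core_rim: str
    call_core_surface: str
    final: str
    decision_path: str
    warnings: list[str] = field(default_factory=list)


def apply_hard_limits(area: float, limits: HardLimits = HardLimits(),
                      is_peptide_partner: bool = False) -> str | None:
    """Forced call from the area alone, or None when area is inconclusive."""
    if area > limits.bio_area:
        return BIO
    if area < limits.xtal_area and not is_peptide_partner:
        return XTAL
    return None


def detect_interface_disulfide(interface: Interface,
                               mappings: dict[str, ReferenceMapping] | None = None,
                               bond_range: tuple[float, float] = DISULFIDE_RANGE
                               ) -> bool:
    """True iff a wild-type Cys-Cys disulfide spans the interface.

    A cross-interface S-gamma pair within bond range counts only when
    neither cysteine mismatches its reference sequence (an engineered
    crosslink must not force a biological call).  Chains without a
    reference mapping are taken as wild type.
    """
    lo, hi = bond_range
    cha, chb = interface.side_a.chain, interface.side_b.chain
    atoms_a, atoms_b = cha.atom_records(), chb.atom_records()
    for ia, ib, dist in interface.contact_pairs:
        if not (lo <= dist <= hi):
            continue
        ra = cha.residues[cha.atom_residue[ia]]
        rb = chb.residues[chb.atom_residue[ib]]
        if ra.res_type != "CYS" or rb.res_type != "CYS":
            continue
        if atoms_a[ia].name != "SG" or atoms_b[ib].name != "SG":
            continue
        if _is_mismatched(mappings, cha.chain_id, int(cha.atom_residue[ia])):
            continue
        if _is_mismatched(mappings, chb.chain_id, int(chb.atom_residue[ib])):
            continue
        return True
    return False


def _is_mismatched(mappings, chain_id: str, residue_index: int) -> bool:
    if not mappings:
        return False
    m = mappings.get(chain_id)
    return m is not None and m.ok and residue_index in m.mismatches


@dataclass
class EngineeringResult:
    warnings: list[str]
    veto: bool


def engineering_check(scored: list[tuple[str, int, str]],
                      mappings: dict[str, ReferenceMapping] | None,
                      max_mismatch_fraction: float = MAX_MISMATCH_FRACTION
                      ) -> EngineeringResult:
    """Warn about scored residues that mismatch the reference sequence.

    ``scored`` lists (chain_id, residue_index, residue label) for the
    core+rim residues entering the evolutionary scores.  When the
    mismatched fraction exceeds the threshold, both evolutionary criteria
    are vetoed (forced NOPRED) and the final call falls back to geometry.
    """
    warnings: list[str] = []
    n_mismatch = 0
    for chain_id, residue_index, label in scored:
        if _is_mismatched(mappings, chain_id, residue_index):
            n_mismatch += 1
            warnings.append(
                f"scored residue {label} (chain {chain_id}) mismatches "
                "the reference sequence")
    veto = bool(scored) and n_mismatch > max_mismatch_fraction * len(scored)
    if veto:
        warnings.append(
            f"{n_mismatch}/{len(scored)} scored residues mismatch the "
            "reference; evolutionary criteria disabled")
    return EngineeringResult(warnings=warnings, veto=veto)


def combine(call_geometry: str, call_core_rim: str, call_core_surface: str,
            area: float,
            disulfide: bool = False,
            limits: HardLimits = HardLimits(),
            is_peptide_partner: bool = False,
            interface_id: int = 0,
            warnings: list[str] | None = None) -> InterfaceVerdict:
    """Merge the three calls into a final BIO/XTAL verdict.

    Precedence: disulfide override, hard area limits, then the vote
    (majority when all three are available; geometry fallback when both
    evolutionary calls are missing; preference to a lone evolutionary call
    when it disagrees with geometry).
    """
    calls = (call_geometry, call_core_rim, call_core_surface)
    if call_geometry == NOPRED:
        raise ValueError("the geometric call is always available")

    if disulfide:
        final, path = BIO, "disulfide"
    else:
        forced = apply_hard_limits(area, limits, is_peptide_partner)
        if forced == BIO:
            final, path = BIO, "hard-area-high"
        elif forced == XTAL:
            final, path = XTAL, "hard-area-low"
        else:
            evo = [c for c in (call_core_rim, call_core_surface)
                   if c != NOPRED]
            if len(evo) == 2:
                n_bio = sum(1 for c in calls if c == BIO)
                final, path = (BIO if n_bio >= 2 else XTAL), "majority"
            elif len(evo) == 0:
                final, path = call_geometry, "geometry-fallback"
            else:
                if evo[0] != call_geometry:
                    final, path = evo[0], "evolution-preference"
                else:
                    final, path = call_geometry, "majority"

    return InterfaceVerdict(
        interface_id=interface_id, area=area,
        call_geometry=call_geometry, call_core_rim=call_core_rim,
        call_core_surface=call_core_surface,
        final=final, decision_path=path,
        warnings=list(warnings or []))
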