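"""Interface core/rim partitioning and the geometric biological/crystal call.

Three residue-level core definitions from the interface literature are
implemented:

* Scharer: core residues bury more than a fraction (default 0.95) of their
  uncomplexed ASA.  The count of such residues is the geometric classifier.
* Chakrabarti: core residues have at least one atom that is fully buried on
  complexation.
* Levy: three classes from relative accessibility against a Gly-X-Gly
  extended-tripeptide reference — core (rASA_u > 0.25 and rASA_c < 0.25),
  rim (still exposed in the complex), support (already buried in the
  monomer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .accessibility import BurialRecord
from .constants import GXG_REFERENCE_ASA

SCHARER_CUTOFF = 0.95      # burial fraction for the strict core
SCORING_CUTOFF = 0.70      # relaxed burial used for entropy scoring cores
LEVY_RASA_CUTOFF = 0.25
CORE_SIZE_THRESHOLD = 6    # more than this many core residues -> biological
FULL_BURIAL_TOLERANCE = 0.01   # A^2; atomic ASA below this counts as zero

BIO = "BIO"
XTAL = "XTAL"
NOPRED = "NOPRED"


@dataclass(frozen=True)
class GeometryParams:
    scharer_cutoff: float = SCHARER_CUTOFF
    scoring_cutoff: float = SCORING_CUTOFF
    levy_rasa_cutoff: float = LEVY_RASA_CUTOFF
    core_size_threshold: int = CORE_SIZE_THRESHOLD


@dataclass
class RegionAssignment:
    """Per-residue core/rim(/support) labels under one definition."""

    definition: str
    labels: dict[tuple[str, int], str] = field(default_factory=dict)
    # keys are (side, residue_index); values in {"core", "rim", "support", "none"}

    @property
    def core_size_a(self) -> int:
        return sum(1 for (s, _), lab in self.labels.items()
                   if s == "A" and lab == "core")

    @property
    def core_size_b(self) -> int:
        return sum(1 for (s, _), lab in self.labels.items()
                   if s == "B" and lab == "core")

    @property
    def core_size(self) -> int:
        return self.core_size_a + self.core_size_b

    def core_records(self, burials: list[BurialRecord]) -> list[BurialRecord]:
        return [rec for rec in burials
                if self.labels.get((rec.side, rec.residue_index)) == "core"]

    def rim_records(self, burials: list[BurialRecord]) -> list[BurialRecord]:
        return [rec for rec in burials
                if self.labels.get((rec.side, rec.residue_index)) == "rim"]


def classify_scharer(burials: list[BurialRecord],
                     cutoff: float = SCHARER_CUTOFF) -> RegionAssignment:
    """Core = interface residues burying strictly more than ``cutoff`` of ASA_u."""
    out = RegionAssignment(definition="scharer")
    for rec in burials:
        if not rec.is_interface:
            continue
        out.labels[(rec.side, rec.residue_index)] = (
            "core" if rec.burial_ratio > cutoff else "rim")
    return out


def classify_chakrabarti(burials: list[BurialRecord],
                         tolerance: float = FULL_BURIAL_TOLERANCE
                         ) -> RegionAssignment:
    """Core = interface residues with at least one fully buried atom.

    An atom counts as fully buried when it was exposed in the monomer
    (asa_u > tolerance) and retains no area in the complex
    (asa_c < tolerance); exact zeros are quadrature-fragile.
    """
    out = RegionAssignment(definition="chakrabarti")
    for rec in burials:
        if not rec.is_interface:
            continue
        full = ((rec.atom_asa_u > tolerance) &
                (rec.atom_asa_c < tolerance)).any()
        out.labels[(rec.side, rec.residue_index)] = "core" if full else "rim"
    return out


def classify_levy(burials: list[BurialRecord],
                  reference_asa: dict[str, float] | None = None,
                  cutoff: float = LEVY_RASA_CUTOFF) -> RegionAssignment:
    """Three-class partition by relative accessibility (core/rim/support)."""
    ref = GXG_REFERENCE_ASA if reference_asa is None else reference_asa
    out = RegionAssignment(definition="levy")
    for rec in burials:
        if not rec.is_interface:
            continue
        letter = rec.residue.one_letter
        max_asa = ref.get(letter)
        if max_asa is None or max_asa <= 0:
            warnings.warn(
                f"no reference ASA for residue type {rec.residue.res_type}; "
                "labelling none", stacklevel=2)
            out.labels[(rec.side, rec.residue_index)] = "none"
            continue
        rasa_u = rec.asa_u / max_asa
        rasa_c = rec.asa_c / max_asa
        if rasa_u > cutoff and rasa_c < cutoff:
            label = "core"
        elif rasa_c >= cutoff:
            label = "rim"
        else:
            label = "support"
        out.labels[(rec.side, rec.residue_index)] = label
    return out


def geometry_call(assignment: RegionAssignment,
                  threshold: int = CORE_SIZE_THRESHOLD) -> str:
    """BIO iff the two-side total core size strictly exceeds ``threshold``."""
    return BIO if assignment.core_size > threshold else XTAL
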