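"""Shared physical constants and residue tables.

Van der Waals radii, amino-acid code conversions, the reduced amino-acid
alphabet used for entropy counting, and the Gly-X-Gly reference accessible
surface areas used for relative-accessibility (rASA) computations.
"""

from __future__ import annotations

import json
from importlib import resources

# Element van der Waals radii in angstrom. X-ray structures mostly lack
# hydrogens; they are ignored for contacts and surface areas anyway.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
DEFAULT_VDW_RADIUS: float = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parents
    "MSE": "M", "SEC": "U", "PYL": "O",
}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def load_alphabet(name_or_path: str = "murphy10") -> dict[str, int]:
    """Load a reduced amino-acid alphabet as a residue-letter -> class-index map.

    The default is the 10-class physicochemical grouping of Murphy et al.,
    bundled as a JSON config file; a path to an alternative JSON file with
    the same layout (list of class strings) may be given instead.
    """
    if name_or_path.endswith(".json"):
        with open(name_or_path) as fh:
            classes = json.load(fh)
    else:
        ref = resources.files("xtalface.data").joinpath(f"{name_or_path}.json")
        classes = json.loads(ref.read_text())
    table: dict[str, int] = {}
    for idx, members in enumerate(classes):
        for letter in members:
            table[letter.upper()] = idx
    return table


MURPHY10: dict[str, int] = load_alphabet("murphy10")

# Theoretical maximum ASA (A^2) of residue X in an extended Gly-X-Gly
# tripeptide (Tien et al. 2013), the reference for relative accessibility.
GXG_REFERENCE_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
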