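"""The 20-letter amino-acid alphabet used throughout the package.

Residue types are indexed 0..19 in one-letter alphabetical order; everything
(count tables, energy tables) shares this ordering.
"""

from __future__ import annotations

AA1: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA1)}

N_TYPES: int = len(AA1)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def is_standard(resname: str) -> bool:
    """True if ``resname`` (three-letter PDB code) is one of the 20 standard types."""
    return resname.upper() in THREE_TO_ONE
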