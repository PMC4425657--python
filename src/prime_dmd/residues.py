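"""Amino-acid constants for the 4-sphere-per-residue coarse-grained model.

Each residue is represented by three backbone united spheres (NH, CaH, CO)
and, for all residues except glycine, a single side-chain sphere R placed at
the side-chain centroid.  Masses are reduced with the CH3 united atom
(15.035 amu) as the unit, so alanine's side sphere has mass exactly 1.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: default peptide: the 26-residue C-terminal fragment of amyloid-beta(1-42),
#: residues 17-42 in the conventional numbering
AB17_42 = "LVFFAEDVGSNKGAIIGLMVGGVVIA"
AB17_42_FIRST_RESIDUE = 17

# Backbone united-sphere reduced masses (CH3 = 15.035 amu = 1.0).
MASS_CAH = 0.866
MASS_NH = 0.999
MASS_CO = 1.863

# Side-chain united-sphere reduced masses.  All side-chain heavy atoms plus
# their hydrogens collapse onto one sphere, so the reduced mass is the
# side-chain formula mass over 15.035 (e.g. valine C3H7 = 43.09 -> 2.866).
SIDE_MASS = {
    "A": 1.000, "C": 3.132, "D": 3.860, "E": 4.793, "F": 6.061,
    "H": 5.394, "I": 3.799, "K": 4.865, "L": 3.799, "M": 4.998,
    "N": 3.862, "P": 2.799, "Q": 4.795, "R": 6.728, "S": 2.064,
    "T": 2.997, "V": 2.866, "W": 8.658, "Y": 7.126,
}

# Sphere roles.
ROLE_NH, ROLE_CA, ROLE_CO, ROLE_R = 0, 1, 2, 3
ROLE_NAMES = {ROLE_NH: "NH", ROLE_CA: "CaH", ROLE_CO: "CO", ROLE_R: "R"}


def has_side_sphere(aa: str) -> bool:
    """Glycine's side chain is a single hydrogen and carries no sphere."""
    return aa != "G"


def validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = sorted({c for c in seq if c not in AMINO_ACIDS})
    if bad:
        raise ValueError(f"unknown residue letter(s): {''.join(bad)}")
    return seq
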