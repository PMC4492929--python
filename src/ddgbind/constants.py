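"""Bundled per-residue constants used by the scoring terms.

All tables cover exactly the 20 canonical amino acids (one-letter codes).
Non-canonical residues are rejected upstream, at structure parsing.
"""

from __future__ import annotations

AMINO_ACIDS_1 = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Maximum number of side-chain rotamers per residue type.  Drives the
# surface-weighted conformational entropy estimate S = ln[rSASA*(R-1)+1].
MAX_ROTAMERS = {
    "A": 1, "C": 3, "D": 18, "E": 54, "F": 18,
    "G": 1, "H": 36, "I": 9, "K": 81, "L": 9,
    "M": 27, "N": 36, "P": 2, "Q": 108, "R": 81,
    "S": 3, "T": 3, "V": 3, "W": 36, "Y": 18,
}

# Wimley-White interface hydrophobicity index (dimensionless).  Positive for
# hydrophilic residues, negative for hydrophobic ones, in the convention used
# by the HYDR = sum_j H_j * rSASA_j term.
HYDROPHOBICITY = {
    "A": 0.2, "C": -0.2, "D": 1.2, "E": 1.01, "F": -1.1,
    "G": 0.0, "H": 0.57, "I": -0.3, "K": 1.0, "L": -0.6,
    "M": -0.2, "N": 0.4, "P": 0.5, "Q": 0.6, "R": 0.8,
    "S": 0.1, "T": 0.1, "V": 0.1, "W": -1.9, "Y": -0.9,
}

# Dielectric-class partition of the residue types.  Charged and polar side
# chains are given higher effective dielectric constants to mimic their
# conformational / ionization response that a rigid-body model cannot sample.
CHARGED_RESIDUES = frozenset("DEKRH")
POLAR_RESIDUES = frozenset("STNQY")
OTHER_RESIDUES = frozenset(AMINO_ACIDS_1) - CHARGED_RESIDUES - POLAR_RESIDUES

#: default (charged, polar, other) dielectric constants for polar solvation
DEFAULT_DIELECTRICS = (9.0, 8.0, 7.0)
#: uniform protein dielectric used for the Coulomb (EE) component
DEFAULT_EE_DIELECTRIC = 7.0


def dielectric_class(aa: str) -> str:
    """Return 'charged', 'polar' or 'other' for a one-letter residue code."""
    if aa in CHARGED_RESIDUES:
        return "charged"
    if aa in POLAR_RESIDUES:
        return "polar"
    if aa in OTHER_RESIDUES:
        return "other"
    raise KeyError(f"not a canonical amino acid: {aa!r}")


# Heavy-atom van der Waals radii (Angstrom), Chothia-style values as used by
# NACCESS-like SASA calculators.  Hydrogens never contribute to SASA here.
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "SE": 1.90,
}

#: water probe radius in Angstrom
DEFAULT_PROBE_RADIUS = 1.4
#: quadrature points per atom for Shrake-Rupley SASA
DEFAULT_SPHERE_POINTS = 960

# Theoretical maximum accessible surface area per residue type (Angstrom^2),
# Tien et al. 2013 values; rSASA = SASA / MAX_ASA[aa].
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "V": 174.0, "Y": 263.0,
}

#: Coulomb constant, kcal*Angstrom/(mol*e^2)
COULOMB_CONSTANT = 332.0636

#: |ddG| threshold (kcal/mol) separating small-effect from large-effect
#: mutations; |ddG| >= LARGE_EFFECT_THRESHOLD counts as large.
LARGE_EFFECT_THRESHOLD = 1.0

#: hydrogen-oxygen distance cutoff (Angstrom) for hydrogen-bond counting
HBOND_CUTOFF = 2.4
#: donor-heavy-atom to acceptor cutoff for the hydrogen-free proxy mode
HBOND_HEAVY_PROXY_CUTOFF = 3.4
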