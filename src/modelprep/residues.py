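"""Amino-acid reference data: codes, side-chain topology and ideal geometry.

Everything downstream (chain classification, side-chain graph matching,
Cβ reconstruction, toy-structure generation) draws on the tables here.
"""

from __future__ import annotations

import numpy as np

AA1 = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Modified residues mapped to their parent amino acid.  Chains containing
# these are still protein, and their one-letter sequence uses the parent.
MODIFIED_PARENT = {
    "MSE": "MET",  # selenomethionine
    "CSO": "CYS",  # S-hydroxycysteine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain covalent connectivity (heavy atoms).  The CA-CB bond anchors the
# side chain to the backbone; PRO additionally closes its ring through N.
SIDE_CHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CA", "CB"),),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CG1", "CD1"), ("CB", "CG2")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CD2", "CE3"), ("CE3", "CZ3"), ("CZ3", "CH2"),
            ("CH2", "CZ2"), ("CZ2", "CE2")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CZ", "OH")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
}

STANDARD_AA = frozenset(SIDE_CHAIN_BONDS)

# γ-position atoms, in the retention preference order used when a branched
# side chain is truncated to a single γ atom.
GAMMA_PREFERENCE = ("CG", "CG1", "OG", "OG1", "SG")
GAMMA_ATOMS = frozenset(GAMMA_PREFERENCE) | {"CG2"}


def side_chain_atoms(res_name: str) -> list[str]:
    """Heavy side-chain atom names of a standard residue (CB first)."""
    seen: list[str] = []
    for a, b in SIDE_CHAIN_BONDS[res_name]:
        for x in (a, b):
            if x not in ("N", "CA") and x not in seen:
                seen.append(x)
    return seen


def element_of(atom_name: str) -> str:
    """Infer the element from a heavy-atom PDB name (C/N/O/S/SE/P)."""
    name = atom_name.strip().upper()
    if name in ("SE", "SEG"):
        return "SE"
    return name[0]


# --- Ideal geometry -------------------------------------------------------

# Ideal alanine residue (Å): CA at the origin, N and C in the xy plane.
# Used as the reference for Cβ reconstruction and fixture building.
IDEAL_ALA = {
    "N": np.array([-0.525, 1.362, 0.000]),
    "CA": np.array([0.000, 0.000, 0.000]),
    "C": np.array([1.526, 0.000, 0.000]),
    "O": np.array([2.153, -1.062, 0.000]),
    "CB": np.array([-0.507, -0.778, -1.211]),
}

# Backbone internal coordinates (Engh & Huber-style ideal values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Side-chain internal coordinate recipes:
#   atom: (ref_a, ref_b, ref_c, bond, angle, dihedral)
# places `atom` at distance `bond` from ref_c, with angle(ref_b, ref_c, atom)
# and dihedral(ref_a, ref_b, ref_c, atom), all refs within the same residue.
# CB is placed separately (parameters derived from IDEAL_ALA).
SIDE_CHAIN_ZMAT: dict[str, tuple[tuple[str, str, str, str, float, float, float], ...]] = {
    "ALA": (),
    "ARG": (
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
        ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", 1.33, 124.0, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0),
    ),
    "ASN": (
        ("CG", "N", "CA", "CB", 1.52, 113.0, 180.0),
        ("OD1", "CA", "CB", "CG", 1.23, 121.0, 0.0),
        ("ND2", "CA", "CB", "CG", 1.33, 117.0, 180.0),
    ),
    "ASP": (
        ("CG", "N", "CA", "CB", 1.52, 113.0, 180.0),
        ("OD1", "CA", "CB", "CG", 1.25, 119.0, 0.0),
        ("OD2", "CA", "CB", "CG", 1.25, 119.0, 180.0),
    ),
    "CYS": (("SG", "N", "CA", "CB", 1.81, 114.0, 180.0),),
    "GLN": (
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 112.0, 180.0),
        ("OE1", "CB", "CG", "CD", 1.23, 121.0, 0.0),
        ("NE2", "CB", "CG", "CD", 1.33, 117.0, 180.0),
    ),
    "GLU": (
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 112.0, 180.0),
        ("OE1", "CB", "CG", "CD", 1.25, 119.0, 0.0),
        ("OE2", "CB", "CG", "CD", 1.25, 119.0, 180.0),
    ),
    "GLY": (),
    "HIS": (
        ("CG", "N", "CA", "CB", 1.50, 114.0, 180.0),
        ("ND1", "CA", "CB", "CG", 1.38, 122.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.36, 129.0, -90.0),
        ("CE1", "CB", "CG", "ND1", 1.32, 108.0, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.37, 107.0, 180.0),
    ),
    "ILE": (
        ("CG1", "N", "CA", "CB", 1.53, 110.0, 180.0),
        ("CG2", "N", "CA", "CB", 1.52, 110.0, -60.0),
        ("CD1", "CA", "CB", "CG1", 1.51, 114.0, 180.0),
    ),
    "LEU": (
        ("CG", "N", "CA", "CB", 1.53, 117.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.52, 111.0, 60.0),
        ("CD2", "CA", "CB", "CG", 1.52, 111.0, 180.0),
    ),
    "LYS": (
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
        ("CE", "CB", "CG", "CD", 1.52, 112.0, 180.0),
        ("NZ", "CG", "CD", "CE", 1.49, 112.0, 180.0),
    ),
    "MET": (
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("SD", "CA", "CB", "CG", 1.80, 113.0, 180.0),
        ("CE", "CB", "CG", "SD", 1.79, 101.0, 180.0),
    ),
    "PHE": (
        ("CG", "N", "CA", "CB", 1.50, 114.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.39, 121.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.39, 121.0, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
    ),
    "PRO": (
        ("CG", "N", "CA", "CB", 1.49, 104.0, 30.0),
        ("CD", "CA", "CB", "CG", 1.50, 105.0, -35.0),
    ),
    "SER": (("OG", "N", "CA", "CB", 1.42, 111.0, 180.0),),
    "THR": (
        ("OG1", "N", "CA", "CB", 1.43, 109.0, 180.0),
        ("CG2", "N", "CA", "CB", 1.52, 111.0, -60.0),
    ),
    "TRP": (
        ("CG", "N", "CA", "CB", 1.50, 114.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.37, 127.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.43, 127.0, -90.0),
        ("NE1", "CB", "CG", "CD1", 1.38, 110.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.41, 107.0, 180.0),
        ("CE3", "CB", "CG", "CD2", 1.40, 133.0, 0.0),
        ("CZ2", "CG", "CD2", "CE2", 1.40, 122.0, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.39, 119.0, 180.0),
        ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.0, 0.0),
    ),
    "TYR": (
        ("CG", "N", "CA", "CB", 1.50, 114.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.39, 121.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.39, 121.0, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0),
    ),
    "VAL": (
        ("CG1", "N", "CA", "CB", 1.52, 111.0, 180.0),
        ("CG2", "N", "CA", "CB", 1.52, 111.0, -60.0),
    ),
}
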