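"""Bundled chemical reference data.

Covalent and van der Waals radii (Å) for the elements that occur in
biomolecular structures, heavy-atom bond templates for the 20 standard
amino acids, and the residue-name sets used during curation.
"""

from __future__ import annotations

# Periodic-table symbols accepted for Atom.element (biomolecular subset plus
# common counter-ions/cofactor elements).
ELEMENTS: frozenset[str] = frozenset(
    """H D C N O S P F CL BR I SE B SI
       NA K MG CA MN FE CO NI CU ZN MO CD HG AS LI AL""".split()
)

# Covalent radii (Å), Cordero et al. consensus values rounded to 2 decimals.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "SE": 1.20,
    "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03, "MG": 1.41, "CA": 1.76,
    "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24, "CU": 1.32, "ZN": 1.22,
    "MO": 1.54, "CD": 1.44, "HG": 1.32, "AS": 1.19, "LI": 1.28, "AL": 1.21,
}
DEFAULT_COVALENT_RADIUS = 1.5

# Van der Waals radii (Å), Bondi values; used for hydrophobic contacts.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.8

WATER_RESNAMES: frozenset[str] = frozenset({"HOH", "WAT", "DOD", "H2O"})

STANDARD_AMINO_ACIDS: frozenset[str] = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE
       LEU LYS MET PHE PRO SER THR TRP TYR VAL""".split()
)

STANDARD_NUCLEOTIDES: frozenset[str] = frozenset(
    "A C G U DA DC DG DT DI I".split()
)

_BACKBONE = [("N", "CA"), ("CA", "C"), ("C", "O")]

# Heavy-atom intra-residue bonds, PDB v3 atom names.  Hydrogens are attached
# by the name-based parent rule in structure_io (HB2 -> CB, etc.).
RESIDUE_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": _BACKBONE + [("CA", "CB")],
    "GLY": list(_BACKBONE),
    "SER": _BACKBONE + [("CA", "CB"), ("CB", "OG")],
    "CYS": _BACKBONE + [("CA", "CB"), ("CB", "SG")],
    "THR": _BACKBONE + [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": _BACKBONE + [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
                        ("CG", "CD2")],
    "ILE": _BACKBONE + [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"),
                        ("CG1", "CD1")],
    "MET": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "SD"),
                        ("SD", "CE")],
    "PRO": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
                        ("CD", "N")],
    "PHE": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
                        ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
                        ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
                        ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
                        ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "TRP": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
                        ("CG", "CD2"), ("CD1", "NE1"), ("NE1", "CE2"),
                        ("CD2", "CE2"), ("CD2", "CE3"), ("CE3", "CZ3"),
                        ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "ASP": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"),
                        ("CG", "OD2")],
    "GLU": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
                        ("CD", "OE1"), ("CD", "OE2")],
    "ASN": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"),
                        ("CG", "ND2")],
    "GLN": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
                        ("CD", "OE1"), ("CD", "NE2")],
    "LYS": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
                        ("CD", "CE"), ("CE", "NZ")],
    "ARG": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
                        ("CD", "NE"), ("NE", "CZ"), ("CZ", "NH1"),
                        ("CZ", "NH2")],
    "HIS": _BACKBONE + [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"),
                        ("CG", "CD2"), ("ND1", "CE1"), ("CE1", "NE2"),
                        ("NE2", "CD2")],
    # water: hydrogens named explicitly because the generic H-parent rule
    # special-cases bare H/H1/H2/H3 to the backbone nitrogen
    "HOH": [("O", "H1"), ("O", "H2")],
    "WAT": [("O", "H1"), ("O", "H2")],
}

# Double bonds within template residues (subset of RESIDUE_BONDS pairs).
# The backbone C=O is handled separately; these are side-chain pi systems
# whose torsions are locked when modeled.
RESIDUE_DOUBLE_BONDS: dict[str, list[tuple[str, str]]] = {
    "ASP": [("CG", "OD1")],
    "GLU": [("CD", "OE1")],
    "ASN": [("CG", "OD1")],
    "GLN": [("CD", "OE1")],
    "ARG": [("CZ", "NH1")],
    "HIS": [("CG", "CD2"), ("ND1", "CE1")],
    "PHE": [("CG", "CD1"), ("CD2", "CE2"), ("CE1", "CZ")],
    "TYR": [("CG", "CD1"), ("CD2", "CE2"), ("CE1", "CZ")],
    "TRP": [("CG", "CD1"), ("CD2", "CE2"), ("CE3", "CZ3"), ("CH2", "CZ2")],
}

# Atom names that survive an in-silico alanine substitution: backbone,
# C-beta, and their hydrogens.  Everything else in a residue is "beyond
# C-beta" side chain.
ALANINE_KEPT_NAMES: frozenset[str] = frozenset(
    """N CA C O OXT CB
       H H1 H2 H3 HA HA2 HA3 HB HB1 HB2 HB3""".split()
)
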