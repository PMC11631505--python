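"""Physical and biochemical constants used throughout the pipeline.

All tables are fixed package data so that every computation is
bit-reproducible: van der Waals radii for heavy atoms, standard atomic
masses, the theoretical maximum accessible surface areas used to turn
absolute SASA into relative SASA (RSASA, %), and the Kyte-Doolittle
hydrophobicity scale.
"""

from __future__ import annotations

#: Van der Waals radii (Angstrom) for the heavy-atom elements found in
#: protein structures.  Fixed table; hydrogens are ignored everywhere.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Standard atomic masses (unified atomic mass units) for residue
#: center-of-mass computation.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Theoretical maximum accessible surface area per residue type
#: (Angstrom^2), "theoretical" column of Tien et al. 2013.  RSASA is
#: 100 * SASA / max and may exceed 100% for conformations more exposed
#: than the theoretical tripeptide reference.
MAX_ASA_THEORETICAL: dict[str, float] = {
    "A": 129.0,
    "R": 274.0,
    "N": 195.0,
    "D": 193.0,
    "C": 167.0,
    "E": 223.0,
    "Q": 225.0,
    "G": 104.0,
    "H": 224.0,
    "I": 197.0,
    "L": 201.0,
    "K": 236.0,
    "M": 224.0,
    "F": 240.0,
    "P": 159.0,
    "S": 155.0,
    "T": 172.0,
    "W": 285.0,
    "Y": 263.0,
    "V": 174.0,
}

#: Kyte-Doolittle hydropathy scale, from most hydrophilic (-4.5, Arg)
#: to most hydrophobic (+4.5, Ile).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8,
    "R": -4.5,
    "N": -3.5,
    "D": -3.5,
    "C": 2.5,
    "E": -3.5,
    "Q": -3.5,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "L": 3.8,
    "K": -3.9,
    "M": 1.9,
    "F": 2.8,
    "P": -1.6,
    "S": -0.8,
    "T": -0.7,
    "W": -0.9,
    "Y": -1.3,
    "V": 4.2,
}

#: Positively charged residues (side-chain charge +1 at physiological pH
#: as used for the patch charge descriptors).
POSITIVE_AAS = frozenset("KR")

#: Negatively charged residues (side-chain charge -1).
NEGATIVE_AAS = frozenset("DE")

STANDARD_AAS = frozenset(MAX_ASA_THEORETICAL)

#: Three-letter to one-letter residue code mapping.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A",
    "ARG": "R",
    "ASN": "N",
    "ASP": "D",
    "CYS": "C",
    "GLU": "E",
    "GLN": "Q",
    "GLY": "G",
    "HIS": "H",
    "ILE": "I",
    "LEU": "L",
    "LYS": "K",
    "MET": "M",
    "PHE": "F",
    "PRO": "P",
    "SER": "S",
    "THR": "T",
    "TRP": "W",
    "TYR": "Y",
    "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Default parameters of the patch pipeline.  These mirror the standard
#: protocol: 1.4 A water probe, 960 sphere points for SASA, 20% mean
#: RSASA accessibility cutoff (strict >), 15 A patch radius, 5 residues
#: excluded per chain terminus in flexibility normalization and a 0.50
#: eplet confirmation threshold (inclusive).
PROBE_RADIUS = 1.4
SASA_N_POINTS = 960
RSASA_THRESHOLD = 20.0
PATCH_RADIUS = 15.0
TERMINI_EXCLUDED = 5
EPLET_THRESHOLD = 0.50
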