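"""Amino-acid alphabets and reference tables used across the feature stack.

All per-residue tables are keyed by the PSI-BLAST column order so that
profile-derived and type-derived features share one indexing convention.
"""

from __future__ import annotations

import numpy as np

#: Column order of the 20 standard amino acids in PSI-BLAST ASCII matrices.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Unknown / non-standard residue placeholder.
UNKNOWN_AA = "X"

#: Background amino-acid frequencies of the BLOSUM62 alignment data.
#: Used as q(alpha) in the relative-entropy and Jensen-Shannon scores.
BLOSUM62_BACKGROUND = np.array(
    [
        0.074,  # A
        0.052,  # R
        0.045,  # N
        0.054,  # D
        0.025,  # C
        0.034,  # Q
        0.054,  # E
        0.074,  # G
        0.026,  # H
        0.068,  # I
        0.099,  # L
        0.058,  # K
        0.025,  # M
        0.047,  # F
        0.039,  # P
        0.057,  # S
        0.051,  # T
        0.013,  # W
        0.032,  # Y
        0.073,  # V
    ]
)

#: Theoretical maximum solvent-accessible surface area per residue type (A^2),
#: Tien et al. (2013) theoretical values; used to normalise raw accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Five physicochemical scales (rows follow AA_ORDER):
#   hydrophobicity (Kyte-Doolittle), hydrophilicity (Hopp-Woods),
#   net electrostatic charge, number of potential hydrogen bonds,
#   isoelectric point (Zimmerman).
_HYDROPHOBICITY = [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
                   3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2]
_HYDROPHILICITY = [-0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
                   -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5]
_NET_CHARGE = [0.0, 1.0, 0.0, -1.0, 0.0, 0.0, -1.0, 0.0, 0.1, 0.0,
               0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
_H_BONDS = [0.0, 4.0, 2.0, 1.0, 0.0, 2.0, 1.0, 0.0, 1.0, 0.0,
            0.0, 2.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0]
_ISOELECTRIC = [6.00, 10.76, 5.41, 2.77, 5.05, 5.65, 3.22, 5.97, 7.59, 6.02,
                5.98, 9.74, 5.74, 5.48, 6.30, 5.68, 5.66, 5.89, 5.66, 5.96]

#: Raw 20x5 physicochemical table in AA_ORDER; the feature stack applies a
#: logistic squash so every scale lands in (0, 1).
PHYSCHEM_RAW = np.column_stack(
    [_HYDROPHOBICITY, _HYDROPHILICITY, _NET_CHARGE, _H_BONDS, _ISOELECTRIC]
).astype(float)

PHYSCHEM_NAMES = (
    "hydrophobicity",
    "hydrophilicity",
    "net_charge",
    "h_bond_count",
    "isoelectric_point",
)

#: Three-letter to one-letter protein residue codes.
PROTEIN_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Residue names treated as nucleic-acid monomers when classifying chains.
NUCLEIC_RESNAMES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"}
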