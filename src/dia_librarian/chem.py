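"""Monoisotopic mass constants and the modification table.

Residue masses are the standard monoisotopic masses of the 20 canonical
amino-acid residues (i.e. the amino acid minus water). The phospho neutral
loss is the monoisotopic mass of H3PO4 (nominally "-98 Da").
"""

from __future__ import annotations

PROTON = 1.007276466
WATER = 18.010565
PHOSPHO_NEUTRAL_LOSS = 97.976896

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# UniMod accession -> (name, monoisotopic mass delta in Da)
UNIMOD_TABLE: dict[int, tuple[str, float]] = {
    4: ("Carbamidomethyl", 57.021464),
    21: ("Phospho", 79.966331),
    35: ("Oxidation", 15.994915),
}

MOD_BY_NAME: dict[str, tuple[int, float]] = {
    name: (uid, delta) for uid, (name, delta) in UNIMOD_TABLE.items()
}
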