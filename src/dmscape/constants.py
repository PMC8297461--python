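"""Amino acid alphabets and shared constants.

All positional coordinates in this package are 1-based protein residue
numbers. Nonsense (stop) substitutions are written ``*`` and synonymous
substitutions ``=``, regardless of the input dialect.
"""

# Canonical column/order of the 20 proteinogenic amino acids.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ORDER)

NONSENSE = "*"
SYNONYMOUS = "="

# Three-letter -> one-letter codes for HGVS protein tokens.
AA3_TO_1 = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F",
    "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Leu": "L",
    "Met": "M", "Asn": "N", "Pro": "P", "Gln": "Q", "Arg": "R",
    "Ser": "S", "Thr": "T", "Val": "V", "Trp": "W", "Tyr": "Y",
    "Ter": NONSENSE,
}

# Broad physicochemical groupings used by the synthetic archetype library.
HYDROPHOBIC = frozenset("AVILMFWYC")
POLAR_CHARGED = frozenset("STNQDEKRH")
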