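"""Amino-acid lookup tables used by the variant feature encoder.

Three tables live here:

* an ordinal index for each residue (two dialects: the reference side
  covers the 21 proteinogenic residues including selenocysteine, the
  mutant side adds the non-residue outcomes ``fs``/``Ter``/``del``/``dup``
  that a protein-level change can produce, all coded 22);
* a side-chain polarity code grouping residues into apolar (1.x),
  uncharged-polar (2.x), negatively charged (3.x) and positively charged
  (4.x) families, with 0.0 for every non-residue token;
* the Grantham (1974) amino-acid distance matrix, a physico-chemical
  dissimilarity combining composition, polarity and molecular volume.
  Off-diagonal values span 5 (Leu/Ile) to 215 (Cys/Trp).
"""

from __future__ import annotations

from typing import Mapping

__all__ = [
    "AA3",
    "ONE_TO_THREE",
    "AA_INDEX_REF",
    "AA_INDEX_MUT",
    "NON_RESIDUE_TOKENS",
    "CHEMICAL_VALUE",
    "GRANTHAM",
    "normalize_residue",
]

# Reference-side ordinal codes (Sec = selenocysteine, rank 11).
AA_INDEX_REF: Mapping[str, int] = {
    "Arg": 1, "His": 2, "Lys": 3, "Asp": 4, "Glu": 5,
    "Ser": 6, "Thr": 7, "Asn": 8, "Gln": 9, "Trp": 10,
    "Sec": 11, "Gly": 12, "Pro": 13, "Ala": 14, "Val": 15,
    "Ile": 16, "Leu": 17, "Met": 18, "Phe": 19, "Tyr": 20,
    "Cys": 21,
}

# Non-residue outcomes a mutant allele can encode; all share ordinal 22.
# "dup" is folded into the same class as "del" (an in-frame copy-number
# change of residues rather than a substitution).
NON_RESIDUE_TOKENS = ("fs", "Ter", "del", "dup")

AA_INDEX_MUT: Mapping[str, int] = {**AA_INDEX_REF,
                                   **{tok: 22 for tok in NON_RESIDUE_TOKENS}}

AA3 = tuple(AA_INDEX_REF)

ONE_TO_THREE: Mapping[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "U": "Sec",
}
_THREE_BY_CASEFOLD = {aa.lower(): aa for aa in AA3}


def normalize_residue(token: str) -> str:
    """Map a 1- or 3-letter residue code to its canonical 3-letter form.

    Raises ``ValueError`` for anything that is not a residue code.
    """
    tok = token.strip()
    if len(tok) == 1 and tok.upper() in ONE_TO_THREE:
        return ONE_TO_THREE[tok.upper()]
    canon = _THREE_BY_CASEFOLD.get(tok.lower())
    if canon is None:
        raise ValueError(f"not an amino-acid code: {token!r}")
    return canon


# Side-chain polarity codes.  Sentinels (stop, indels, frameshifts and the
# no-residue placeholder) carry 0.0 so they are distinguishable from every
# residue family.
CHEMICAL_VALUE: Mapping[str, float] = {
    # apolar
    "Ala": 1.1, "Phe": 1.2, "Ile": 1.3, "Leu": 1.4, "Met": 1.5,
    "Pro": 1.6, "Val": 1.7, "Trp": 1.8, "Gly": 1.9,
    # uncharged polar
    "Cys": 2.1, "Asn": 2.3, "Gln": 2.4, "Ser": 2.5, "Thr": 2.6, "Tyr": 2.7,
    # negatively charged
    "Asp": 3.1, "Glu": 3.2,
    # positively charged
    "His": 4.1, "Lys": 4.2, "Arg": 4.3,
    # non-residue outcomes
    "Ter": 0.0, "dup": 0.0, "del": 0.0, "p.?": 0.0, "p.(=)": 0.0,
    "fs": 0.0, "NA": 0.0,
}

# Grantham distance matrix, upper triangle in the published row order.
_GRANTHAM_ORDER = (
    "Ser", "Arg", "Leu", "Pro", "Thr", "Ala", "Val", "Gly", "Ile", "Phe",
    "Tyr", "Cys", "His", "Gln", "Asn", "Lys", "Asp", "Glu", "Met", "Trp",
)
_GRANTHAM_UPPER = (
    (110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177),
    (102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101),
    (98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61),
    (38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147),
    (58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128),
    (64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148),
    (109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88),
    (135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184),
    (21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61),
    (22, 205, 100, 116, 158, 102, 177, 140, 28, 40),
    (194, 83, 99, 143, 85, 160, 122, 36, 37),
    (174, 154, 139, 202, 154, 170, 196, 215),
    (24, 68, 32, 81, 40, 87, 115),
    (46, 53, 61, 29, 101, 130),
    (94, 23, 42, 142, 174),
    (101, 56, 95, 110),
    (45, 160, 181),
    (126, 152),
    (67,),
)


def _build_grantham() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    for i, aa1 in enumerate(_GRANTHAM_ORDER):
        table[(aa1, aa1)] = 0
        row = _GRANTHAM_UPPER[i] if i < len(_GRANTHAM_UPPER) else ()
        for offset, value in enumerate(row):
            aa2 = _GRANTHAM_ORDER[i + 1 + offset]
            table[(aa1, aa2)] = value
            table[(aa2, aa1)] = value
    return table


GRANTHAM: Mapping[tuple[str, str], int] = _build_grantham()
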