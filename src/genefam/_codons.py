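"""Standard genetic code tables shared across modules.

All tables are derived once, at import, from the standard nuclear code.
Codons are uppercase DNA triplets.
"""

from __future__ import annotations

from itertools import product

NUCLEOTIDES = "TCAG"

# Standard genetic code, DNA alphabet. '*' marks stop codons.
GENETIC_CODE: dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_n1, _n2, _n3) in enumerate(product(NUCLEOTIDES, NUCLEOTIDES, NUCLEOTIDES)):
    GENETIC_CODE[_n1 + _n2 + _n3] = _AA_ORDER[_i]

ALL_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
STOP_CODONS: frozenset[str] = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

# Synonymous families: amino acid -> sorted tuple of its codons.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = GENETIC_CODE[_codon]
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] = tuple(sorted(FAMILIES[_aa] + (_codon,)))

AA_OF: dict[str, str] = {c: GENETIC_CODE[c] for c in SENSE_CODONS}
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

# Amino acids with a real synonymous choice (excludes Met and Trp).
DEGENERATE_AAS: frozenset[str] = frozenset(aa for aa, k in DEGENERACY.items() if k >= 2)

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3); stops render as '*'."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
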