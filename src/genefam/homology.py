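"""Duplicate-pair and triplicate-group detection from protein alignments.

All unordered protein pairs are globally aligned (Needleman–Wunsch, affine
gaps) and classified against two stringency standards:

* low stringency:  identity >= 30% over >= 70% coverage
* high stringency: identity >= 50% over >= 90% coverage

Coverage is measured against the longer protein (the conservative reading);
identity is counted over the full alignment length (the EMBOSS-needle
convention — a forced global alignment of unrelated proteins then scores
well below the 30% floor, which a gap-excluded denominator does not
guarantee; the gap-excluded variant remains available via flag).
Triplicate groups are 3-cliques in the duplicate-pair graph. A duplication
mechanism is called tandem when the two genes are near-adjacent on one
chromosome; segmental/large-scale calls require user-supplied collinearity
evidence (whole-genome synteny detection is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseAlignment",
    "ParalogPair",
    "TriplicateGroup",
    "make_aligner",
    "global_align",
    "classify_pair",
    "find_duplicates",
    "find_triplicates",
    "classify_mechanism",
]

LOW_IDENTITY, LOW_COVERAGE = 0.30, 0.70
HIGH_IDENTITY, HIGH_COVERAGE = 0.50, 0.90


@dataclass
class PairwiseAlignment:
    gene_a: str
    gene_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage: float


@dataclass
class ParalogPair:
    genes: tuple[str, str]
    stringency: str  # high | low | none
    identity: float
    coverage: float
    mechanism: str = "unclassified"


@dataclass
class TriplicateGroup:
    genes: tuple[str, str, str]
    member_pairs: tuple[ParalogPair, ParalogPair, ParalogPair]


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    """Global affine-gap aligner; a length-L internal gap costs
    open + (L-1)*extend and terminal gaps are free (the needle default),
    so a length difference reads as an unaligned tail, not internal gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    for attr in (
        "open_left_insertion_score",
        "extend_left_insertion_score",
        "open_right_insertion_score",
        "extend_right_insertion_score",
        "open_left_deletion_score",
        "extend_left_deletion_score",
        "open_right_deletion_score",
        "extend_right_deletion_score",
    ):
        setattr(aligner, attr, 0.0)
    return aligner


def _identity_coverage(
    aligned_a: str, aligned_b: str, len_a: int, len_b: int, gap_excluded: bool = False
) -> tuple[float, float]:
    both_cols = [
        i for i, (x, y) in enumerate(zip(aligned_a, aligned_b)) if x != "-" and y != "-"
    ]
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    denom = len(both_cols) if gap_excluded else len(aligned_a)
    identity = matches / denom if denom else 0.0
    # span: residues of the longer protein inside the non-terminal-gap region
    if both_cols:
        longer_row = aligned_a if len_a >= len_b else aligned_b
        span = sum(
            1
            for i in range(both_cols[0], both_cols[-1] + 1)
            if longer_row[i] != "-"
        )
    else:
        span = 0
    coverage = span / max(len_a, len_b)
    return identity, coverage


def global_align(
    gene_a: str,
    seq_a: str,
    gene_b: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
    gap_excluded_identity: bool = False,
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch alignment with identity and coverage."""
    if not seq_a or not seq_b:
        raise ValueError("empty protein sequence")
    aligner = aligner or make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identity, coverage = _identity_coverage(
        row_a, row_b, len(seq_a), len(seq_b), gap_excluded_identity
    )
    return PairwiseAlignment(
        gene_a=gene_a,
        gene_b=gene_b,
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        identity=identity,
        coverage=coverage,
    )


def classify_pair(aln: PairwiseAlignment) -> str:
    """Stringency class from identity/coverage; thresholds are inclusive."""
    if aln.identity >= HIGH_IDENTITY and aln.coverage >= HIGH_COVERAGE:
        return "high"
    if aln.identity >= LOW_IDENTITY and aln.coverage >= LOW_COVERAGE:
        return "low"
    return "none"


def find_duplicates(
    proteins: dict[str, str], aligner: Align.PairwiseAligner | None = None
) -> list[ParalogPair]:
    """All duplicate pairs among the proteins, canonically ordered (a < b)."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    aligner = aligner or make_aligner()
    pairs = []
    for a, b in combinations(sorted(proteins), 2):
        aln = global_align(a, proteins[a], b, proteins[b], aligner)
        cls = classify_pair(aln)
        if cls != "none":
            pairs.append(
                ParalogPair(
                    genes=(a, b), stringency=cls, identity=aln.identity, coverage=aln.coverage
                )
            )
    return pairs


def find_triplicates(pairs: list[ParalogPair]) -> list[TriplicateGroup]:
    """Every 3-clique in the duplicate-pair graph, in canonical order."""
    by_pair = {tuple(sorted(p.genes)): p for p in pairs}
    genes = sorted({g for p in pairs for g in p.genes})
    groups = []
    for trio in combinations(genes, 3):
        edges = [by_pair.get((trio[0], trio[1])), by_pair.get((trio[0], trio[2])),
                 by_pair.get((trio[1], trio[2]))]
        if all(e is not None for e in edges):
            groups.append(TriplicateGroup(genes=trio, member_pairs=tuple(edges)))
    if len(groups) > 1:
        members = [set(g.genes) for g in groups]
        for i, j in combinations(range(len(groups)), 2):
            if len(members[i] & members[j]) == 2:
                logger.info(
                    "triplicate groups %s and %s share an edge (larger clique present)",
                    groups[i].genes,
                    groups[j].genes,
                )
                break
    return groups


def classify_mechanism(
    pair: ParalogPair,
    positions: dict[str, tuple[str, int]],
    collinear_pairs: set[tuple[str, str]] | None = None,
    max_intervening: int = 5,
    max_span: int = 200_000,
) -> str:
    """Duplication mechanism for one pair.

    tandem: same chromosome, few intervening family genes, within max_span bp.
    segmental_or_large_scale: only with supplied collinearity evidence.
    """
    a, b = pair.genes
    if a not in positions or b not in positions:
        logger.warning("pair %s-%s: missing position, unclassified", a, b)
        return "unclassified"
    chrom_a, start_a = positions[a]
    chrom_b, start_b = positions[b]
    if chrom_a == chrom_b and abs(start_a - start_b) <= max_span:
        lo, hi = sorted((start_a, start_b))
        intervening = sum(
            1
            for g, (c, s) in positions.items()
            if g not in (a, b) and c == chrom_a and lo < s < hi
        )
        if intervening <= max_intervening:
            return "tandem"
    if collinear_pairs and tuple(sorted((a, b))) in {
        tuple(sorted(p)) for p in collinear_pairs
    }:
        return "segmental_or_large_scale"
    return "unclassified"
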