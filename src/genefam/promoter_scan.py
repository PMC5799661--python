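"""Promoter extraction and cis-regulatory element scanning.

Promoters are strand-aware upstream windows ending immediately before the
translation start (default 2 kb). Elements are matched as IUPAC degenerate
consensi (PlantCARE-style presence calls, not weight matrices): a bundled,
editable table covers the bHLH-relevant set (G-box CACGTG, the degenerate
E-box CANNTG, ABRE, MBS, MRE, HSE, LTR, CRT/DRE, P-box, TATC-box).

Matching rules: an N in the *sequence* never matches; overlapping hits are
all reported; a palindromic consensus (e.g. CACGTG) records only its
plus-strand hit so each physical site appears once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ._codons import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "IUPAC",
    "load_motif_table",
    "default_motifs",
    "extract_promoters",
    "scan_motifs",
    "summarize_elements",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self):
        cons = self.consensus.upper()
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC letter(s) {sorted(bad)}")
        if len(cons) < 4:
            raise ValueError(f"motif {self.name}: consensus shorter than 4")
        object.__setattr__(self, "consensus", cons)

    @property
    def is_palindromic(self) -> bool:
        return self.consensus == revcomp(self.consensus)

    def regex(self, reverse: bool = False) -> re.Pattern:
        cons = revcomp(self.consensus) if reverse else self.consensus
        return re.compile("".join(f"[{IUPAC[b]}]" for b in cons))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    position: int  # 1-based offset of the match start within the promoter
    strand: str
    matched_sequence: str


def load_motif_table(source) -> list[MotifDefinition]:
    """Motif definitions from a TSV with columns name, consensus, both_strands."""
    df = pd.read_csv(source, sep="\t", comment="#")
    return [
        MotifDefinition(
            name=row["name"],
            consensus=row["consensus"],
            both_strands=bool(row.get("both_strands", True)),
        )
        for _, row in df.iterrows()
    ]


def default_motifs() -> list[MotifDefinition]:
    """The bundled representative motif table."""
    ref = resources.files("genefam.data").joinpath("motifs.tsv")
    with ref.open() as fh:
        return load_motif_table(fh)


def extract_promoters(
    genome: dict[str, str], models, length: int = 2000
) -> dict[str, tuple[str, bool]]:
    """Per-gene promoter sequences (sequence, clipped_flag).

    The window covers ``length`` nt immediately upstream of the translation
    start on the coding strand; minus-strand promoters are reverse-
    complemented so position 1 is the most distal base. Windows running off
    a contig edge are clipped and flagged.
    """
    out: dict[str, tuple[str, bool]] = {}
    for model in models:
        contig = genome.get(model.chromosome)
        if contig is None:
            logger.warning("%s: contig %s absent from genome, skipped", model.gene_id, model.chromosome)
            continue
        if model.strand == "+":
            end = model.tss - 1  # last genomic base before ATG (1-based)
            start = max(1, end - length + 1)
            seq = contig[start - 1 : end]
            clipped = end - length + 1 < 1
        else:
            start = model.tss + 1
            end = min(len(contig), start + length - 1)
            seq = revcomp(contig[start - 1 : end])
            clipped = start + length - 1 > len(contig)
        if clipped:
            logger.info("%s: promoter clipped to %d nt at contig edge", model.gene_id, len(seq))
        out[model.gene_id] = (seq.upper(), clipped)
    return out


def scan_motifs(
    sequence: str, motifs: list[MotifDefinition], gene_id: str = ""
) -> list[MotifHit]:
    """All consensus matches in a promoter, sorted by position.

    Reverse-strand hits (reported at the + coordinate of the site, strand
    '-') are included for both_strands motifs; palindromic consensi record
    only the plus-strand hit.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        fwd = motif.regex()
        for m in _overlapping(fwd, seq):
            hits.append(MotifHit(gene_id, motif.name, m.start() + 1, "+", m.group()))
        if motif.both_strands and not motif.is_palindromic:
            rev = motif.regex(reverse=True)
            for m in _overlapping(rev, seq):
                hits.append(MotifHit(gene_id, motif.name, m.start() + 1, "-", m.group()))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def _overlapping(pattern: re.Pattern, seq: str):
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


def summarize_elements(
    hits: list[MotifHit],
    gene_set: list[str],
    motif_groups: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Presence/absence matrix over a gene set plus any-of group fractions.

    ``motif_groups`` maps a group label (e.g. "G-box_or_E-box") to motif
    names; the fraction is the share of genes with at least one hit of any
    group member.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    motifs = sorted({h.motif for h in hits})
    present = {g: {m: False for m in motifs} for g in gene_set}
    for h in hits:
        if h.gene_id in present:
            present[h.gene_id][h.motif] = True
    matrix = pd.DataFrame.from_dict(present, orient="index").reindex(gene_set)
    matrix.index.name = "gene_id"
    fractions: dict[str, float] = {}
    for label, members in (motif_groups or {}).items():
        cols = [m for m in members if m in matrix.columns]
        hit_any = matrix[cols].any(axis=1) if cols else pd.Series(False, index=matrix.index)
        fractions[label] = float(hit_any.mean())
    return matrix, fractions
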