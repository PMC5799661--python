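"""Gene-structure analysis: intron phases and exon symmetry from GFF3.

An intron's phase is the position of its 5' boundary relative to codon
boundaries: phase 0 falls between codons, phase 1 after the first base,
phase 2 after the second. An internal exon is *symmetric* when its two
flanking introns share a phase; an excess of symmetric exons and phase-0
introns facilitates exon shuffling. Phases are defined on CDS exons only;
coordinates are GFF3 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "StructureSummary",
    "parse_gene_models",
    "intron_phases",
    "classify_exons",
    "summarize_structures",
    "per_gene_table",
]


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    # transcript order: ascending genomic for '+', descending for '-'
    cds_exons: list[tuple[int, int]]

    @property
    def exon_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.cds_exons]

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def intronless(self) -> bool:
        return len(self.cds_exons) == 1

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first CDS base in transcript order."""
        start, end = self.cds_exons[0]
        return start if self.strand == "+" else end

    def validate(self) -> None:
        spans = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS exons")
        expected = sorted(self.cds_exons, reverse=self.strand == "-")
        if self.cds_exons != expected:
            raise ValueError(f"{self.gene_id}: exons not in transcript order for strand {self.strand}")


@dataclass
class StructureSummary:
    n_genes: int
    n_exons: int
    n_introns: int
    introns_by_phase: dict[int, int]
    symmetric_exons_by_phase: dict[int, int]
    asymmetric_exons: int
    intronless_genes: list[str] = field(default_factory=list)


def parse_gene_models(gff3_text: str, transcript_choice: str = "longest") -> list[GeneModel]:
    """Gene models from GFF3 text (one per gene; longest CDS transcript).

    Models whose CDS length is not divisible by 3 are flagged and excluded
    from phase analysis.
    """
    db = gffutils.create_db(
        gff3_text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        for parent in parents:
            cds = list(db.children(parent, featuretype="CDS", order_by="start"))
            if not cds:
                continue
            exons = [(c.start, c.end) for c in cds]
            if gene.strand == "-":
                exons = exons[::-1]
            model = GeneModel(
                gene_id=gene.id, chromosome=gene.seqid, strand=gene.strand, cds_exons=exons
            )
            model.validate()
            if best is None or model.cds_length > best.cds_length:
                best = model
        if best is None:
            logger.warning("%s: no CDS features, skipped", gene.id)
            continue
        if best.cds_length % 3:
            logger.warning(
                "%s: CDS length %d not divisible by 3; excluded from phase analysis",
                best.gene_id,
                best.cds_length,
            )
            continue
        models.append(best)
    return models


def intron_phases(model: GeneModel) -> list[int]:
    """Phase of each intron: cumulative upstream CDS length mod 3."""
    phases = []
    cumulative = 0
    for length in model.exon_lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return phases


def classify_exons(model: GeneModel, virtual_terminal_phase0: bool = False) -> list[str]:
    """Per-exon class in transcript order.

    Internal exons are ``symmetric_phaseN`` when both flanking introns have
    phase N, ``asymmetric`` otherwise; terminal exons (and the single exon of
    an intron-less gene) are ``terminal``. With ``virtual_terminal_phase0``
    the gene boundaries count as phase-0 flanks, so terminal exons join the
    symmetric/asymmetric tally.
    """
    phases = intron_phases(model)
    boundary = [0] + phases + [0] if virtual_terminal_phase0 else [None] + phases + [None]
    out = []
    for i in range(model.n_exons):
        left, right = boundary[i], boundary[i + 1]
        if left is None or right is None:
            out.append("terminal")
        elif left == right:
            out.append(f"symmetric_phase{left}")
        else:
            out.append("asymmetric")
    return out


def summarize_structures(
    models: list[GeneModel], virtual_terminal_phase0: bool = False
) -> StructureSummary:
    """Family-level exon/intron tallies."""
    if not models:
        raise ValueError("no gene models to summarize")
    introns_by_phase = {0: 0, 1: 0, 2: 0}
    symmetric = {0: 0, 1: 0, 2: 0}
    asym = 0
    intronless = []
    n_exons = 0
    for model in models:
        n_exons += model.n_exons
        if model.intronless:
            intronless.append(model.gene_id)
        for phase in intron_phases(model):
            introns_by_phase[phase] += 1
        for cls in classify_exons(model, virtual_terminal_phase0):
            if cls.startswith("symmetric_phase"):
                symmetric[int(cls[-1])] += 1
            elif cls == "asymmetric":
                asym += 1
    return StructureSummary(
        n_genes=len(models),
        n_exons=n_exons,
        n_introns=n_exons - len(models),
        introns_by_phase=introns_by_phase,
        symmetric_exons_by_phase=symmetric,
        asymmetric_exons=asym,
        intronless_genes=sorted(intronless),
    )


def per_gene_table(models: list[GeneModel]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": m.gene_id,
            "chromosome": m.chromosome,
            "strand": m.strand,
            "n_exons": m.n_exons,
            "phases": ",".join(map(str, intron_phases(m))),
            "intronless": m.intronless,
            "cds_length": m.cds_length,
            "exon_length_mean": m.cds_length / m.n_exons,
        }
        for m in models
    ]
    return pd.DataFrame(rows)
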