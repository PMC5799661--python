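"""Synthetic gene-family generator with known ground truth.

Every input the pipeline consumes can be generated here — CDS collections
with controllable GC3s, paralog pairs and triples with controlled protein
identity and omega, gene models with planted intron phases, promoters with
planted cis-elements, and replicate expression matrices with planted fold
changes — so each analysis stage can be tested by round-trip against the
planted truth, without any external download.

All randomness flows from one seeded ``numpy`` generator per call; the same
spec and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._codons import (
    AA_OF,
    FAMILIES,
    GENETIC_CODE,
    STOP_CODONS,
    codons_of,
    revcomp,
    translate,
)
from .gene_structure import GeneModel
from .promoter_scan import MotifDefinition, default_motifs
from .selection import _codon_sites

__all__ = [
    "SyntheticFamilySpec",
    "SyntheticTruth",
    "FamilyData",
    "generate_cds",
    "diverge_cds",
    "generate_gene_model",
    "generate_promoter",
    "generate_expression",
    "generate_family",
    "write_fasta",
    "write_gff3",
]

_GC_WEIGHT = {True: 1.0, False: 0.0}
_DEGENERATE_CODING_AAS = sorted(FAMILIES)  # all 20, uniform amino-acid usage


# ---------------------------------------------------------------------------
# CDS generation


def _sample_codon(aa: str, gc3_target: float, rng: np.random.Generator) -> str:
    codons = FAMILIES[aa]
    t = gc3_target
    weights = np.array([t if c[2] in "GC" else 1 - t for c in codons], float)
    if weights.sum() == 0:
        weights = np.ones(len(codons))
    return codons[rng.choice(len(codons), p=weights / weights.sum())]


def generate_cds(
    n: int,
    length_range: tuple[int, int],
    gc3_target: float,
    seed: int,
    id_prefix: str = "G",
    id_start: int = 1,
) -> dict[str, str]:
    """Random CDSs (ATG start, no internal stop, length divisible by 3).

    Synonymous codons are chosen with a weight ``t`` on G/C-ending codons
    (``1-t`` otherwise), which makes the realized GC3s track ``gc3_target``
    for every family with an equal G/C vs A/T-ending codon split (all but
    Ile under the standard code).
    """
    if not 0 <= gc3_target <= 1:
        raise ValueError("gc3_target must be in [0,1]")
    if length_range[0] < 10:
        raise ValueError("minimum length is 10 codons")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i in range(n):
        n_codons = int(rng.integers(length_range[0], length_range[1] + 1))
        codons = ["ATG"]
        for _ in range(n_codons - 1):
            aa = _DEGENERATE_CODING_AAS[rng.integers(len(_DEGENERATE_CODING_AAS))]
            codons.append(_sample_codon(aa, gc3_target, rng))
        out[f"{id_prefix}{id_start + i:03d}"] = "".join(codons)
    return out


# ---------------------------------------------------------------------------
# Divergence with controlled omega


def _jc_p(d: float) -> float:
    """Expected raw proportion of differing sites at JC distance d."""
    return 0.75 * (1 - math.exp(-4 * d / 3))


def diverge_cds(
    cds: str,
    target_omega: float,
    target_ks: float,
    seed: int,
    max_proposals_factor: int = 400,
) -> tuple[str, list[tuple[int, str, str, str]]]:
    """A diverged copy of a CDS with planted Ka/Ks on the Nei–Gojobori scale.

    Single-nucleotide changes are proposed at random and accepted while the
    synonymous and nonsynonymous quotas (derived from target_ks and
    target_omega * target_ks via the inverse Jukes-Cantor map over the
    sequence's fractional site counts) remain open; stop-creating changes
    are rejected and each position mutates at most once. Returns the copy
    and a log of (nt_position, from, to, syn|nonsyn) per accepted change.
    """
    if target_ks <= 0:
        raise ValueError("target_ks must be > 0")
    if target_omega < 0:
        raise ValueError("target_omega must be >= 0")
    cods = codons_of(cds.upper())
    sites = [_codon_sites(c) for c in cods]
    s_sites = sum(s for s, _ in sites)
    n_sites = sum(n for _, n in sites)
    ps, pn = _jc_p(target_ks), _jc_p(target_omega * target_ks)
    if ps >= 0.75 or pn >= 0.75:
        raise ValueError("requested divergence beyond Jukes-Cantor saturation")
    quota_s = round(ps * s_sites)
    quota_n = round(pn * n_sites)

    rng = np.random.default_rng(seed)
    work = list(cods)
    mutated: set[int] = set()
    log: list[tuple[int, str, str, str]] = []
    proposals = 0
    limit = max_proposals_factor * len(cds)
    while (quota_s > 0 or quota_n > 0) and proposals < limit:
        proposals += 1
        pos = int(rng.integers(3, len(cds)))  # keep the ATG start intact
        if pos in mutated:
            continue
        ci, off = divmod(pos, 3)
        old_codon = work[ci]
        old_nt = old_codon[off]
        new_nt = "ACGT"[rng.integers(4)]
        if new_nt == old_nt:
            continue
        new_codon = old_codon[:off] + new_nt + old_codon[off + 1 :]
        if new_codon in STOP_CODONS:
            continue
        syn = GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]
        if syn and quota_s > 0:
            quota_s -= 1
        elif not syn and quota_n > 0:
            quota_n -= 1
        else:
            continue
        work[ci] = new_codon
        mutated.add(pos)
        log.append((pos, old_nt, new_nt, "syn" if syn else "nonsyn"))
    if quota_s > 0 or quota_n > 0:
        achieved = len([e for e in log if e[3] == "syn"]) / s_sites if s_sites else 0.0
        raise ValueError(
            f"divergence saturated before reaching targets (achieved pS={achieved:.3f})"
        )
    return "".join(work), log


def mutate_protein_identity(
    cds: str,
    identity_target: float,
    seed: int,
    forbidden_codons: set[int] | None = None,
) -> tuple[str, set[int]]:
    """Copy of a CDS with a fraction (1 - identity) of residues substituted.

    Substitutions replace the whole codon by a codon of a different amino
    acid; the start codon is never touched. Returns the copy and the set of
    mutated codon indices (usable to keep a second copy's mutations disjoint).
    """
    if not 0 <= identity_target <= 1:
        raise ValueError("identity_target must be in [0,1]")
    rng = np.random.default_rng(seed)
    cods = codons_of(cds.upper())
    n_mut = round((1 - identity_target) * (len(cods) - 1))
    candidates = [
        i for i in range(1, len(cods)) if not (forbidden_codons and i in forbidden_codons)
    ]
    if n_mut > len(candidates):
        raise ValueError("identity target unreachable with disjoint positions")
    chosen = rng.choice(len(candidates), size=n_mut, replace=False)
    positions = {candidates[i] for i in chosen}
    aas = sorted(FAMILIES)
    for i in positions:
        old_aa = AA_OF[cods[i]]
        new_aa = old_aa
        while new_aa == old_aa:
            new_aa = aas[rng.integers(len(aas))]
        fam = FAMILIES[new_aa]
        cods[i] = fam[rng.integers(len(fam))]
    return "".join(cods), positions


# ---------------------------------------------------------------------------
# Gene models


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _intron(length: int, rng: np.random.Generator) -> str:
    if length < 4:
        raise ValueError("intron length must be >= 4 (GT...AG)")
    return "GT" + _random_dna(length - 4, 0.35, rng) + "AG"


def generate_gene_model(
    cds: str,
    intron_phases: list[int],
    intron_length: int,
    chromosome: str,
    strand: str,
    offset: int,
    seed: int,
    gene_id: str = "gene",
) -> tuple[GeneModel, str]:
    """A gene model with the requested intron phases plus its genomic fragment.

    The fragment is plus-strand genomic sequence whose spliced CDS exons
    reproduce the input CDS exactly; ``offset`` is the 1-based genomic
    coordinate where the fragment starts. Cut points are placed at evenly
    spread positions consistent with the requested phases.
    """
    rng = np.random.default_rng(seed)
    cds = cds.upper()
    length = len(cds)
    cuts: list[int] = []
    prev = 0
    k = len(intron_phases)
    for i, phase in enumerate(intron_phases):
        target = length * (i + 1) // (k + 1)
        # nearest c > prev, c < length with c mod 3 == phase
        base = max(prev + 1, 3)
        candidates = [c for c in range(base, length) if c % 3 == phase and c > prev]
        if not candidates:
            raise ValueError(f"no insertion point for intron {i + 1} (phase {phase})")
        cuts.append(min(candidates, key=lambda c: abs(c - target)))
        prev = cuts[-1]
    pieces = []
    bounds = [0] + cuts + [length]
    for a, b in zip(bounds, bounds[1:]):
        pieces.append(cds[a:b])

    oriented = pieces[0]
    exon_spans_t: list[tuple[int, int]] = [(0, len(pieces[0]) - 1)]
    for piece in pieces[1:]:
        oriented += _intron(intron_length, rng)
        start = len(oriented)
        oriented += piece
        exon_spans_t.append((start, start + len(piece) - 1))

    frag_len = len(oriented)
    if strand == "+":
        fragment = oriented
        exons = [(offset + a, offset + b) for a, b in exon_spans_t]
    elif strand == "-":
        fragment = revcomp(oriented)
        last = offset + frag_len - 1
        exons = [(last - b, last - a) for a, b in exon_spans_t]
    else:
        raise ValueError("strand must be '+' or '-'")
    model = GeneModel(gene_id=gene_id, chromosome=chromosome, strand=strand, cds_exons=exons)
    model.validate()
    return model, fragment


# ---------------------------------------------------------------------------
# Promoters


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    from .promoter_scan import IUPAC

    return "".join(ch[rng.integers(len(ch))] for ch in (IUPAC[b] for b in consensus.upper()))


def generate_promoter(
    length: int,
    planted: list[tuple[str, int, str]],
    background_gc: float,
    seed: int,
    motif_table: list[MotifDefinition] | None = None,
) -> tuple[str, list[tuple[str, int, str]]]:
    """Background promoter sequence with planted motif instances.

    ``planted`` holds (motif name, 1-based position, strand) triples; motifs
    must fit within the sequence without mutual overlap. Returns the
    sequence and the recorded truth positions.
    """
    motifs = {m.name: m for m in (motif_table or default_motifs())}
    rng = np.random.default_rng(seed)
    seq = list(_random_dna(length, background_gc, rng))
    occupied: list[tuple[int, int]] = []
    for name, pos, strand in planted:
        motif = motifs[name]
        span = (pos, pos + len(motif.consensus) - 1)
        if span[0] < 1 or span[1] > length:
            raise ValueError(f"motif {name} at {pos} does not fit in length {length}")
        for a, b in occupied:
            if span[0] <= b and a <= span[1]:
                raise ValueError(f"planted motifs overlap at {pos}")
        occupied.append(span)
        instance = _instantiate(motif.consensus, rng)
        if strand == "-":
            instance = revcomp(instance)
        seq[span[0] - 1 : span[1]] = list(instance)
    return "".join(seq), list(planted)


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    genes: list[str],
    conditions: list[tuple[str, int]],
    fold_map: dict[tuple[str, str], float],
    base_range: tuple[float, float],
    noise_cv: float,
    seed: int,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Replicate expression matrix with planted fold changes.

    The first condition is the control; replicate i of any other condition
    derives from control replicate i times the planted fold times mean-one
    multiplicative log-normal noise, matching the paired structure the DE
    test assumes. All intensities are positive.
    """
    if base_range[0] <= 0 or base_range[1] <= 0:
        raise ValueError("base_range must be positive")
    if any(n < 2 for _, n in conditions):
        raise ValueError("every condition needs >= 2 replicates")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + noise_cv**2))

    def noise(size):
        if sigma == 0:
            return np.ones(size)
        return np.exp(rng.normal(-sigma**2 / 2, sigma, size=size))

    ctrl_name, n_ctrl = conditions[0]
    lo, hi = math.log(base_range[0]), math.log(base_range[1])
    base = np.exp(rng.uniform(lo, hi, size=len(genes)))
    control = base[:, None] * noise((len(genes), n_ctrl))
    columns: dict[str, np.ndarray] = {
        f"{ctrl_name}_{i + 1}": control[:, i] for i in range(n_ctrl)
    }
    truth: dict[tuple[str, str], float] = {}
    for cond, n_reps in conditions[1:]:
        if n_reps != n_ctrl:
            raise ValueError("paired design requires equal replicate counts")
        folds = np.array([fold_map.get((g, cond), 1.0) for g in genes])
        for g, f in zip(genes, folds):
            truth[(g, cond)] = float(f)
        values = control * folds[:, None] * noise((len(genes), n_reps))
        for i in range(n_reps):
            columns[f"{cond}_{i + 1}"] = values[:, i]
    matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return matrix, truth


# ---------------------------------------------------------------------------
# Whole-family orchestration


@dataclass
class SyntheticFamilySpec:
    """Conditions for a full synthetic gene family.

    Defaults emulate the scale of a mid-size plant transcription-factor
    family study: ~94 genes once duplicates and triplicates are included,
    CDS of 100-400 codons around GC3s 0.45, nine triplicated groups, paired
    triplicate control/treatment expression with 3 replicates.
    """

    n_genes: int = 56
    cds_length_range: tuple[int, int] = (100, 400)
    gc3_target: float = 0.45
    duplicate_specs: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.85, 1.0)] * 8 + [(0.40, 0.95)] * 8
    )
    triplicate_specs: list[float] = field(default_factory=lambda: [0.85] * 9)
    omega_targets: list[float] = field(default_factory=lambda: [0.2] * 4)
    seed: int = 0
    promoter_length: int = 2000
    intron_length: int = 200
    expression_conditions: list[tuple[str, int]] = field(
        default_factory=lambda: [("ck", 3), ("treat", 3)]
    )
    expression_noise_cv: float = 0.2
    expression_base_range: tuple[float, float] = (20.0, 2000.0)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.gc3_target <= 1:
            raise ValueError("gc3_target must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticFamilySpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cds_length_range", "expression_base_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "duplicate_specs" in raw:
            raw["duplicate_specs"] = [tuple(x) for x in raw["duplicate_specs"]]
        if "expression_conditions" in raw:
            raw["expression_conditions"] = [tuple(x) for x in raw["expression_conditions"]]
        return cls(**raw)


@dataclass
class SyntheticTruth:
    planted_duplicate_pairs: dict[tuple[str, str], str]
    planted_triplicate_groups: list[tuple[str, str, str]]
    planted_omega: dict[tuple[str, str], float]
    planted_motif_positions: dict[tuple[str, str], list[tuple[int, str]]]
    planted_fold: dict[tuple[str, str], float]
    planted_intron_phases: dict[str, list[int]]

    def validate(self, gene_ids: set[str]) -> None:
        referenced = (
            {g for p in self.planted_duplicate_pairs for g in p}
            | {g for t in self.planted_triplicate_groups for g in t}
            | {g for p in self.planted_omega for g in p}
            | {g for g, _ in self.planted_motif_positions}
            | {g for g, _ in self.planted_fold}
            | set(self.planted_intron_phases)
        )
        unknown = referenced - gene_ids
        if unknown:
            raise ValueError(f"truth references unknown genes: {sorted(unknown)[:5]}")


@dataclass
class FamilyData:
    spec: SyntheticFamilySpec
    cds: dict[str, str]
    proteins: dict[str, str]
    models: dict[str, GeneModel]
    genome: dict[str, str]
    expression: pd.DataFrame
    truth: SyntheticTruth

    @property
    def positions(self) -> dict[str, tuple[str, int]]:
        return {
            g: (m.chromosome, min(s for s, _ in m.cds_exons)) for g, m in self.models.items()
        }


def _expected_class(identity: float, coverage: float) -> str:
    if identity >= 0.50 and coverage >= 0.90:
        return "high"
    if identity >= 0.30 and coverage >= 0.70:
        return "low"
    return "none"


def generate_family(spec: SyntheticFamilySpec) -> FamilyData:
    """One synthetic family with every planted truth recorded.

    Layout: base genes are unrelated random CDSs; each duplicate spec adds a
    protein-level mutated copy of a base gene (a random tail lowers coverage
    below 1); each triplicate spec adds two copies of one base gene mutated
    at disjoint residue sets (pairwise copy identity = 2 * identity - 1);
    each omega target adds a nucleotide-level diverged copy at Ks 0.3.
    Genes are laid out promoter-first on two synthetic chromosomes; about
    two thirds of promoters carry a planted G-box and one third an ABRE;
    roughly a fifth of genes get a planted expression fold of 4.
    """
    rng = np.random.default_rng(spec.seed)
    cds = generate_cds(
        spec.n_genes, spec.cds_length_range, spec.gc3_target, seed=int(rng.integers(2**31))
    )
    base_ids = list(cds)
    next_id = spec.n_genes + 1
    dup_pairs: dict[tuple[str, str], str] = {}
    omega_truth: dict[tuple[str, str], float] = {}
    triples: list[tuple[str, str, str]] = []

    def new_id() -> str:
        nonlocal next_id
        gid = f"G{next_id:03d}"
        next_id += 1
        return gid

    for i, (identity, coverage) in enumerate(spec.duplicate_specs):
        base = base_ids[i % len(base_ids)]
        copy, _ = mutate_protein_identity(cds[base], identity, seed=int(rng.integers(2**31)))
        if coverage < 1.0:
            extra_codons = round(len(copy) / 3 * (1 / coverage - 1))
            tail = generate_cds(
                1, (max(10, extra_codons), max(10, extra_codons)), spec.gc3_target,
                seed=int(rng.integers(2**31)),
            )
            copy = copy + next(iter(tail.values()))[3 : 3 * (extra_codons + 1)]
        gid = new_id()
        cds[gid] = copy
        dup_pairs[tuple(sorted((base, gid)))] = _expected_class(identity, coverage)

    for j, identity in enumerate(spec.triplicate_specs):
        base = base_ids[(len(spec.duplicate_specs) + j) % len(base_ids)]
        copy1, used = mutate_protein_identity(cds[base], identity, seed=int(rng.integers(2**31)))
        copy2, _ = mutate_protein_identity(
            cds[base], identity, seed=int(rng.integers(2**31)), forbidden_codons=used
        )
        g1, g2 = new_id(), new_id()
        cds[g1], cds[g2] = copy1, copy2
        triples.append(tuple(sorted((base, g1, g2))))
        for pair in ((base, g1), (base, g2), (g1, g2)):
            pair_identity = identity if base in pair else 2 * identity - 1
            dup_pairs[tuple(sorted(pair))] = _expected_class(pair_identity, 1.0)

    for k, omega in enumerate(spec.omega_targets):
        base = base_ids[-(k % len(base_ids)) - 1]
        diverged, _ = diverge_cds(cds[base], omega, target_ks=0.3, seed=int(rng.integers(2**31)))
        gid = new_id()
        cds[gid] = diverged
        omega_truth[tuple(sorted((base, gid)))] = omega
        # an omega pair is itself a paralog pair; record its realized class
        prot_base, prot_copy = translate(cds[base]), translate(diverged)
        realized = sum(a == b for a, b in zip(prot_base, prot_copy)) / len(prot_base)
        dup_pairs[tuple(sorted((base, gid)))] = _expected_class(realized, 1.0)

    proteins = {g: translate(s).rstrip("*") for g, s in cds.items()}

    # gene models, promoters and genome layout
    models: dict[str, GeneModel] = {}
    phases_truth: dict[str, list[int]] = {}
    motif_truth: dict[tuple[str, str], list[tuple[int, str]]] = {}
    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_cursor = {"chr1": 0, "chr2": 0}
    for idx, gid in enumerate(sorted(cds)):
        chrom = "chr1" if idx % 2 == 0 else "chr2"
        strand = "+" if rng.integers(2) == 0 else "-"
        n_introns = int(rng.integers(0, 4))
        max_introns = len(cds[gid]) // 3 - 1
        n_introns = min(n_introns, max_introns)
        phases = [int(rng.integers(3)) for _ in range(n_introns)]

        planted: list[tuple[str, int, str]] = []
        if rng.random() < 2 / 3:
            planted.append(("G-box", int(rng.integers(50, spec.promoter_length - 200)), "+"))
        if rng.random() < 1 / 3:
            pos = int(rng.integers(50, spec.promoter_length - 200))
            if all(abs(pos - p) > 20 for _, p, _ in planted):
                planted.append(("ABRE", pos, "+"))
        promoter, _ = generate_promoter(
            spec.promoter_length, planted, background_gc=0.35, seed=int(rng.integers(2**31))
        )
        for name, pos, pstrand in planted:
            motif_truth.setdefault((gid, name), []).append((pos, pstrand))

        cursor = chrom_cursor[chrom]
        if strand == "+":
            chrom_seqs[chrom].append(promoter)
            body_offset = cursor + spec.promoter_length + 1
            model, fragment = generate_gene_model(
                cds[gid], phases, spec.intron_length, chrom, strand, body_offset,
                seed=int(rng.integers(2**31)), gene_id=gid,
            )
            chrom_seqs[chrom].append(fragment)
            chrom_cursor[chrom] += spec.promoter_length + len(fragment)
        else:
            body_offset = cursor + 1
            model, fragment = generate_gene_model(
                cds[gid], phases, spec.intron_length, chrom, strand, body_offset,
                seed=int(rng.integers(2**31)), gene_id=gid,
            )
            chrom_seqs[chrom].append(fragment)
            chrom_seqs[chrom].append(revcomp(promoter))
            chrom_cursor[chrom] += spec.promoter_length + len(fragment)
        spacer = _random_dna(300, 0.3, rng)
        chrom_seqs[chrom].append(spacer)
        chrom_cursor[chrom] += 300
        models[gid] = model
        phases_truth[gid] = phases

    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}

    fold_truth_input: dict[tuple[str, str], float] = {}
    gene_list = sorted(cds)
    for cond, _ in spec.expression_conditions[1:]:
        for gid in gene_list:
            if rng.random() < 0.2:
                fold_truth_input[(gid, cond)] = 4.0
    expression, fold_truth = generate_expression(
        gene_list,
        spec.expression_conditions,
        fold_truth_input,
        spec.expression_base_range,
        spec.expression_noise_cv,
        seed=int(rng.integers(2**31)),
    )

    truth = SyntheticTruth(
        planted_duplicate_pairs={p: c for p, c in dup_pairs.items() if c != "none"},
        planted_triplicate_groups=triples,
        planted_omega=omega_truth,
        planted_motif_positions=motif_truth,
        planted_fold=fold_truth,
        planted_intron_phases=phases_truth,
    )
    truth.validate(set(cds))
    return FamilyData(
        spec=spec,
        cds=cds,
        proteins=proteins,
        models=models,
        genome=genome,
        expression=expression,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Writers (plain text, deterministic)


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(models: dict[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(models):
            m = models[gid]
            start = min(s for s, _ in m.cds_exons)
            end = max(e for _, e in m.cds_exons)
            fh.write(
                f"{m.chromosome}\tgenefam\tgene\t{start}\t{end}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.chromosome}\tgenefam\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            phase = 0
            for s, e in m.cds_exons:
                fh.write(
                    f"{m.chromosome}\tgenefam\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={gid}.cds;Parent={gid}.t1\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3
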