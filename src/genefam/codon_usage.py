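"""Codon-usage-bias statistics for a gene family.

Implements the classical bias indices — GC, GC3s, RSCU, Wright's effective
number of codons (ENC), and the reference-set indices CAI, FOP and CBI —
plus the ENC-plot expected curve and a cross-gene feature correlation table.

Conventions
-----------
* GC3s is the G+C fraction at third positions of *synonymously degenerate*
  codons only: Met (ATG), Trp (TGG) and stop codons are excluded, so GC3s is
  undefined (``None``) for a gene with no degenerate codon.
* ENC is clamped to [20, 61]: 20 means one codon effectively used per amino
  acid, 61 means synonymous codons are used randomly.
* CAI/FOP/CBI require an explicit reference: either user-supplied weights or
  weights derived from a designated (e.g. highly expressed) gene set with
  +0.5 pseudocounts. There is no silent organism default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._codons import (
    AA_OF,
    DEGENERACY,
    DEGENERATE_AAS,
    FAMILIES,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    codons_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodonCounts",
    "CodonUsageStats",
    "ReferenceWeights",
    "count_codons",
    "rscu",
    "gc_content",
    "gc3s",
    "enc_observed",
    "enc_expected",
    "reference_weights_from_counts",
    "cai",
    "fop",
    "cbi",
    "compute_stats",
    "stats_table",
    "correlate_features",
    "enc_plot_table",
]


@dataclass
class CodonCounts:
    """Per-gene counts over the 61 sense codons; stops tracked separately."""

    gene_id: str
    counts: dict[str, int]
    total_codons: int
    stop_counts: dict[str, int] = field(default_factory=dict)
    skipped_ambiguous: int = 0

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in FAMILIES[aa]}


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w per sense codon, max 1 within each family."""

    w: dict[str, float]
    optimal_set: frozenset[str]


@dataclass
class CodonUsageStats:
    gene_id: str
    gc: float
    gc3s: float | None
    rscu: dict[str, float | None]
    enc_obs: float
    enc_exp: float | None
    fop: float | None
    cbi: float | None
    cai: float | None
    length_nt: int
    exon_length_mean: float | None = None


def count_codons(cds: str, gene_id: str = "") -> CodonCounts:
    """Count codons of a CDS (length divisible by 3).

    A single trailing stop codon is recorded in ``stop_counts`` and excluded
    from the sense-codon total. Codons containing ambiguous bases are skipped
    and tallied in ``skipped_ambiguous``.
    """
    cds = cds.upper().replace("U", "T")
    cods = codons_of(cds)
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    skipped = 0
    for codon in cods:
        if codon in STOP_CODONS:
            stops[codon] = stops.get(codon, 0) + 1
        elif codon in GENETIC_CODE:
            counts[codon] = counts.get(codon, 0) + 1
        else:
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d ambiguous codon(s)", gene_id, skipped)
    internal_stops = sum(stops.values()) - (1 if cods and cods[-1] in STOP_CODONS else 0)
    if internal_stops > 0:
        logger.warning("%s: %d internal stop codon(s)", gene_id, internal_stops)
    return CodonCounts(
        gene_id=gene_id,
        counts=counts,
        total_codons=sum(counts.values()),
        stop_counts=stops,
        skipped_ambiguous=skipped,
    )


def rscu(counts: CodonCounts) -> dict[str, float | None]:
    """Relative synonymous codon usage: k * x_j / sum(family x).

    Codons of families never observed in the gene are ``None`` (undefined),
    not zero.
    """
    out: dict[str, float | None] = {}
    for aa, codons in FAMILIES.items():
        fam_total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = None if fam_total == 0 else k * counts.counts.get(c, 0) / fam_total
    return out


def gc_content(cds: str) -> float:
    cds = cds.upper().replace("U", "T")
    if not cds:
        raise ValueError("empty sequence")
    return sum(1 for b in cds if b in "GC") / len(cds)


def gc3s(source: CodonCounts | str) -> float | None:
    """G+C at third positions of synonymously degenerate codons.

    Returns ``None`` (flagged) when the gene has no degenerate codons.
    """
    if isinstance(source, str):
        source = count_codons(source)
    num = den = 0
    for codon, n in source.counts.items():
        if AA_OF[codon] in DEGENERATE_AAS:
            den += n
            if codon[2] in "GC":
                num += n
    if den == 0:
        logger.warning("%s: GC3s undefined (no synonymous sites)", source.gene_id)
        return None
    return num / den


# Degeneracy classes of the standard code: 9 two-fold, 1 three-fold (Ile),
# 5 four-fold, 3 six-fold families.
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}
_CLASS_ORDER = (2, 3, 4, 6)


def _family_homozygosity(fam_counts: dict[str, int]) -> float | None:
    n = sum(fam_counts.values())
    if n < 2:
        return None
    p2 = sum((x / n) ** 2 for x in fam_counts.values())
    return (n * p2 - 1) / (n - 1)


def enc_observed(counts: CodonCounts) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where each F-bar is the mean codon
    homozygosity of the families in that degeneracy class. Families with
    fewer than two codons counted are omitted; a wholly missing class is
    imputed from the mean of its available neighbouring classes.
    """
    class_f: dict[int, float | None] = {}
    for k in _CLASS_ORDER:
        fs = []
        for aa, deg in DEGENERACY.items():
            if deg != k:
                continue
            f = _family_homozygosity(counts.family_counts(aa))
            if f is not None:
                fs.append(f)
        class_f[k] = float(np.mean(fs)) if fs else None

    # impute wholly missing classes from neighbouring classes
    for i, k in enumerate(_CLASS_ORDER):
        if class_f[k] is None:
            neighbours = [
                class_f[_CLASS_ORDER[j]]
                for j in (i - 1, i + 1)
                if 0 <= j < len(_CLASS_ORDER) and class_f[_CLASS_ORDER[j]] is not None
            ]
            if neighbours:
                class_f[k] = float(np.mean(neighbours))
                logger.info(
                    "%s: degeneracy class %d unobserved; F imputed from neighbours",
                    counts.gene_id,
                    k,
                )
    if counts.total_codons < 30:
        logger.info("%s: <30 codons, ENC is low-confidence", counts.gene_id)

    enc = 2.0
    for k, n_fam in _CLASS_SIZES.items():
        f = class_f[k]
        if f is None or f <= 0:
            return 61.0  # no usable signal in some class: no detectable bias
        enc += n_fam / f
    return min(61.0, max(20.0, enc))


def enc_expected(s: float) -> float:
    """Expected ENC under mutation-drift alone at GC3s = s (Wright's curve)."""
    if not 0 < s < 1:
        raise ValueError(f"s must be in (0,1), got {s}")
    return 2.0 + s + 29.0 / (s**2 + (1 - s) ** 2)


def reference_weights_from_counts(
    ref_counts: list[CodonCounts] | CodonCounts, pseudocount: float = 0.5
) -> ReferenceWeights:
    """Relative adaptiveness from a designated reference gene set.

    Within each synonymous family, w = (x + pseudocount) / (x_max + pseudocount);
    the optimal set holds the argmax codon per degenerate family (ties broken
    lexicographically and logged).
    """
    if isinstance(ref_counts, CodonCounts):
        ref_counts = [ref_counts]
    pooled: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
    for cc in ref_counts:
        for c, n in cc.counts.items():
            pooled[c] += n
    w: dict[str, float] = {}
    optimal: set[str] = set()
    for aa, codons in FAMILIES.items():
        xmax = max(pooled[c] for c in codons)
        for c in codons:
            w[c] = (pooled[c] + pseudocount) / (xmax + pseudocount)
        if aa in DEGENERATE_AAS:
            best = sorted(c for c in codons if pooled[c] == xmax)
            if len(best) > 1:
                logger.info("family %s: optimal-codon tie %s, chose %s", aa, best, best[0])
            optimal.add(best[0])
    return ReferenceWeights(w=w, optimal_set=frozenset(optimal))


_EXCLUDED_FROM_CAI = frozenset(
    c for c in SENSE_CODONS if AA_OF[c] not in DEGENERATE_AAS
)


def cai(counts: CodonCounts, ref: ReferenceWeights) -> float | None:
    """Codon adaptation index: geometric mean of w over eligible codons."""
    missing = [c for c in SENSE_CODONS if c not in ref.w]
    if missing:
        raise ValueError(f"reference weights missing codons: {missing[:3]}...")
    log_sum = 0.0
    n = 0
    for codon, x in counts.counts.items():
        if codon in _EXCLUDED_FROM_CAI:
            continue
        log_sum += x * math.log(ref.w[codon])
        n += x
    if n == 0:
        logger.warning("%s: CAI undefined (no eligible codons)", counts.gene_id)
        return None
    return math.exp(log_sum / n)


def fop(counts: CodonCounts, ref: ReferenceWeights) -> float | None:
    """Frequency of optimal codons over degenerate amino acids."""
    n_opt = n_tot = 0
    for codon, x in counts.counts.items():
        if AA_OF[codon] not in DEGENERATE_AAS:
            continue
        n_tot += x
        if codon in ref.optimal_set:
            n_opt += x
    if n_tot == 0:
        logger.warning("%s: FOP undefined", counts.gene_id)
        return None
    return n_opt / n_tot


def cbi(counts: CodonCounts, ref: ReferenceWeights) -> float | None:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    N_ran is the optimal-codon count expected under uniform within-family
    usage, i.e. one optimal codon per family of size k contributes n_aa / k.
    """
    n_opt = n_tot = 0.0
    n_ran = 0.0
    for aa in DEGENERATE_AAS:
        fam = counts.family_counts(aa)
        n_aa = sum(fam.values())
        if n_aa == 0:
            continue
        n_tot += n_aa
        n_ran += n_aa / DEGENERACY[aa]
        n_opt += sum(x for c, x in fam.items() if c in ref.optimal_set)
    if n_tot == 0:
        logger.warning("%s: CBI undefined", counts.gene_id)
        return None
    return (n_opt - n_ran) / (n_tot - n_ran)


def compute_stats(
    gene_id: str,
    cds: str,
    ref: ReferenceWeights | None = None,
    exon_length_mean: float | None = None,
) -> CodonUsageStats:
    """All bias indices for one CDS; reference indices are None without a ref."""
    counts = count_codons(cds, gene_id)
    s = gc3s(counts)
    return CodonUsageStats(
        gene_id=gene_id,
        gc=gc_content(cds),
        gc3s=s,
        rscu=rscu(counts),
        enc_obs=enc_observed(counts),
        enc_exp=enc_expected(s) if s is not None and 0 < s < 1 else None,
        fop=fop(counts, ref) if ref else None,
        cbi=cbi(counts, ref) if ref else None,
        cai=cai(counts, ref) if ref else None,
        length_nt=len(cds),
        exon_length_mean=exon_length_mean,
    )


def stats_table(stats: list[CodonUsageStats]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "gc": s.gc,
            "gc3s": s.gc3s,
            "enc_obs": s.enc_obs,
            "enc_exp": s.enc_exp,
            "fop": s.fop,
            "cbi": s.cbi,
            "cai": s.cai,
            "length_nt": s.length_nt,
            "exon_length_mean": s.exon_length_mean,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)


_FEATURES = ("gc", "gc3s", "length_nt", "exon_length_mean")
_INDICES = ("fop", "cbi", "cai")


def correlate_features(
    table: pd.DataFrame,
    features: tuple[str, ...] = _FEATURES,
    indices: tuple[str, ...] = _INDICES,
    alpha: float = 0.01,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of gene features against bias indices with significance flags.

    Returns a long-format frame (feature, index, r, r_rounded, p, significant);
    constant columns yield NaN r with a flag in the log.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 genes for correlation")
    corr_fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    rows = []
    for feat in features:
        for idx in indices:
            sub = table[[feat, idx]].dropna()
            x, y = sub[feat].to_numpy(float), sub[idx].to_numpy(float)
            if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlation %s~%s undefined (constant or short)", feat, idx)
                r, p = float("nan"), float("nan")
            else:
                r, p = corr_fn(x, y)
            rows.append(
                {
                    "feature": feat,
                    "index": idx,
                    "r": r,
                    "r_rounded": round(r, 1) if not math.isnan(r) else float("nan"),
                    "p": p,
                    "significant": bool(p < alpha) if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)


def enc_plot_table(stats: list[CodonUsageStats]) -> pd.DataFrame:
    """ENC-plot rows (gene, GC3s, observed and expected ENC, residual).

    Genes without a defined GC3s are excluded with a log line; rows are
    sorted by GC3s for plotting.
    """
    rows = []
    for s in stats:
        if s.gc3s is None or not 0 < s.gc3s < 1:
            logger.info("%s: excluded from ENC plot (GC3s undefined or degenerate)", s.gene_id)
            continue
        exp = enc_expected(s.gc3s)
        rows.append(
            {
                "gene_id": s.gene_id,
                "gc3s": s.gc3s,
                "enc_obs": s.enc_obs,
                "enc_exp": exp,
                "residual": s.enc_obs - exp,
            }
        )
    return pd.DataFrame(rows).sort_values("gc3s").reset_index(drop=True)
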