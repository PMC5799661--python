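"""Ka/Ks estimation for paralog pairs by the Nei–Gojobori (1986) method.

The pipeline back-translates a pairwise protein alignment onto the source
CDSs (codon-aware, gaps in whole-codon units), counts synonymous and
nonsynonymous sites and differences with equal-weight averaging over minimal
mutational pathways, applies the Jukes–Cantor correction, and classifies the
selection regime from omega = Ka/Ks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import pandas as pd

from ._codons import GENETIC_CODE, STOP_CODONS, codons_of, translate

logger = logging.getLogger(__name__)

GAP_CODON = "---"

__all__ = [
    "CodonAlignment",
    "SelectionResult",
    "backtranslate_alignment",
    "nei_gojobori",
    "classify_selection",
    "group_selection_table",
    "jukes_cantor",
]


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    codon_columns: list[tuple[str, str]]

    def ungapped(self, row: int) -> str:
        return "".join(col[row] for col in self.codon_columns if col[row] != GAP_CODON)


@dataclass
class SelectionResult:
    pair: tuple[str, str]
    ka: float | None
    ks: float | None
    omega: float | None
    n_sites: float
    s_sites: float
    n_diffs: float = 0.0
    s_diffs: float = 0.0
    regime: str = "undefined"


def backtranslate_alignment(
    aligned_a: str,
    aligned_b: str,
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Thread CDSs through a gapped protein alignment, codon by codon.

    Each protein residue column carries its source codon; each protein gap
    becomes a gap triplet. The CDSs must translate exactly to the ungapped
    protein rows (a trailing stop codon on the CDS is tolerated and dropped).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows differ in length")

    def prepare(cds: str, aligned: str, name: str) -> list[str]:
        cods = codons_of(cds.upper().replace("U", "T"))
        if cods and cods[-1] in STOP_CODONS:
            cods = cods[:-1]
        prot = aligned.replace("-", "")
        if len(cods) != len(prot):
            raise ValueError(
                f"{name}: CDS has {len(cods)} codons but protein row has {len(prot)} residues"
            )
        for i, (codon, res) in enumerate(zip(cods, prot)):
            if GENETIC_CODE.get(codon, "X") != res.upper():
                raise ValueError(
                    f"{name}: codon {codon} at position {i + 1} translates to "
                    f"{GENETIC_CODE.get(codon, '?')}, protein row has {res}"
                )
        return cods

    cods_a = prepare(cds_a, aligned_a, gene_a)
    cods_b = prepare(cds_b, aligned_b, gene_b)
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for ra, rb in zip(aligned_a, aligned_b):
        if ra == "-":
            ca = GAP_CODON
        else:
            ca = cods_a[ia]
            ia += 1
        if rb == "-":
            cb = GAP_CODON
        else:
            cb = cods_b[ib]
            ib += 1
        columns.append((ca, cb))
    return CodonAlignment(gene_a=gene_a, gene_b=gene_b, codon_columns=columns)


def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    Each position contributes one site, split by the fraction of possible
    single-nucleotide changes that are synonymous; changes creating stop
    codons are excluded from consideration.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            tot += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weight over all minimal mutational pathways; pathways
    passing through a stop codon are discarded (all pathways are kept if every
    one is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            if not ok:
                break
            cur = nxt
        (results if ok else blocked).append((sd, nd))
    pool = results or blocked
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    if not results:
        # every pathway crosses a stop; count remaining steps as nonsynonymous
        sd, nd = 0.0, float(len(diff_pos))
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; None beyond saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def nei_gojobori(caln: CodonAlignment) -> SelectionResult:
    """Nei–Gojobori Ka, Ks and omega for a codon alignment.

    Columns containing a gap or a stop codon are excluded. Site counts are
    averaged over the two sequences; proportions are Jukes–Cantor corrected.
    Omega is defined only when Ks > 0.
    """
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    n_cols = 0
    for ca, cb in caln.codon_columns:
        if GAP_CODON in (ca, cb) or ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_cols += 1
        sa, _ = _codon_sites(ca)
        sb, _ = _codon_sites(cb)
        s_sites_a += sa
        s_sites_b += sb
        d = _pathway_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    if n_cols == 0:
        raise ValueError("no comparable (ungapped, stop-free) codon columns")
    s_sites = (s_sites_a + s_sites_b) / 2
    n_sites = 3.0 * n_cols - s_sites

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps) if s_sites > 0 else None
    ka = jukes_cantor(pn) if n_sites > 0 else None
    if ks is None and s_sites > 0:
        logger.warning("%s-%s: synonymous sites saturated (pS=%.3f)", caln.gene_a, caln.gene_b, ps)
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    result = SelectionResult(
        pair=(caln.gene_a, caln.gene_b),
        ka=ka,
        ks=ks,
        omega=omega,
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=nd,
        s_diffs=sd,
    )
    result.regime = classify_selection(result)
    return result


def classify_selection(result: SelectionResult, neutral_band: float = 0.0) -> str:
    """Regime from omega: purifying (<1-band), positive (>1+band), else neutral."""
    if result.omega is None:
        return "undefined"
    if result.omega < 1 - neutral_band:
        return "purifying"
    if result.omega > 1 + neutral_band:
        return "positive"
    return "neutral"


def group_selection_table(
    groups: list[tuple[str, str, str]],
    results: dict[tuple[str, str], SelectionResult],
    pairs_per_group: int = 2,
) -> pd.DataFrame:
    """Per-group table of member-pair omega values.

    For each triplicate group (a, b, c), the first ``pairs_per_group`` member
    pairs with computed results are listed; missing pairs are flagged.
    """
    rows = []
    for gi, group in enumerate(groups, start=1):
        a, b, c = group
        listed = 0
        for pair in ((a, c), (b, c), (a, b)):
            if listed >= pairs_per_group:
                break
            key = tuple(sorted(pair))
            res = results.get(key) or results.get(pair)
            if res is None:
                continue
            listed += 1
            rows.append(
                {
                    "group": f"group_{gi}",
                    "gene_a": pair[0],
                    "gene_b": pair[1],
                    "omega": res.omega,
                    "regime": res.regime,
                    "flagged": False,
                }
            )
        if listed < pairs_per_group:
            logger.warning("group %d: only %d pair result(s) available", gi, listed)
            rows.append(
                {
                    "group": f"group_{gi}",
                    "gene_a": "",
                    "gene_b": "",
                    "omega": float("nan"),
                    "regime": "undefined",
                    "flagged": True,
                }
            )
    return pd.DataFrame(rows)
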