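# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Codon usage

Indices are computed over the 61 sense codons of the standard nuclear code;
a trailing stop codon is tracked separately and codons containing ambiguous
bases are skipped with a log line.

* **GC3s** uses only third positions of synonymously degenerate codons
  (Met, Trp and stops excluded), so genes consisting solely of ATG/TGG have
  undefined GC3s and are excluded from the ENC plot with a log line.
* **ENC** follows Wright's estimator. Codon homozygosity
  F = (nΣp̂² − 1)/(n − 1) is averaged per degeneracy class (9 two-fold,
  1 three-fold, 5 four-fold, 3 six-fold families); families with n < 2 are
  omitted from their class mean, and a wholly unobserved class is imputed
  from the mean of its neighbouring classes. If a class mean is ≤ 0 (no
  usable signal), the gene reports the no-bias ceiling of 61. Results are
  clamped to [20, 61]; genes under 30 codons are flagged low-confidence.
* **ENC expected curve**: ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²). Note
  the curve is *not* symmetric about s = 0.5 — the linear term shifts
  mirrored values by exactly (1 − 2s) — and its maximum is ≈ 60.501 at
  s ≈ 0.502, while the conventional reference value ENC_exp(0.5) = 60.5
  is exact.
* **CAI/FOP/CBI** require an explicit reference set; there is no silent
  organism default (reference-set choice changes these indices materially,
  which is why externally published CAI means cannot be reproduced without
  the original reference). Weights derived from a designated gene set use
  +0.5 pseudocounts, w = (x + ½)/(x_max + ½) within each family; the
  optimal set is the argmax codon per degenerate family, ties broken
  lexicographically and logged.
* **Correlations** are Pearson on untransformed values (Spearman by
  option), two-sided p, flagged at p < 0.01, reported rounded to one
  decimal alongside full precision.

## Homology

Pairwise global alignment uses Biopython's `PairwiseAligner` with BLOSUM62,
gap open 10, extend 0.5, and **free terminal gaps** (the EMBOSS-needle
`endweight` default). Free end gaps make a length difference read as an
unaligned tail rather than internal gaps and remove a co-optimal-alignment
ambiguity in which a terminal residue pairs across the tail.

* **Identity** defaults to matches / full alignment length. A forced
  global alignment of unrelated ~200-aa proteins then scores ≈ 0.15,
  safely below the 30% floor of the low-stringency standard; the
  gap-excluded denominator (matches / both-residue columns) is available
  via flag but inflates unrelated-pair identity to 0.25–0.31 and is not
  used for classification.
* **Coverage** is the residues of the *longer* protein spanned between the
  first and last aligned residue pair, divided by the longer protein's
  length — the conservative reading of "covering ≥ X% of the protein
  length".
* Stringency thresholds are inclusive; high (≥ 50% identity, ≥ 90%
  coverage) implies low (≥ 30%, ≥ 70%).
* **Triplicate groups** are 3-cliques of the duplicate-pair graph; larger
  cliques are reported as all their 3-subsets with a logged notice.
* **Mechanism**: tandem requires same chromosome, ≤ 5 intervening family
  genes and ≤ 200 kb separation; segmental/large-scale calls are made only
  from user-supplied collinear-block evidence — whole-genome synteny
  detection is out of scope.

## Selection (Ka/Ks)

The estimator is classic Nei–Gojobori (1986) over a codon alignment
obtained by threading each CDS through the protein alignment (gaps in
whole-codon units; columns with a gap or stop codon dropped).

* Site counts: each codon position contributes one site, split by the
  fraction of its possible single-nucleotide changes that are synonymous;
  changes that would create a stop codon are excluded from both numerator
  and denominator. Site totals are averaged over the two sequences, and
  n_sites + s_sites = 3 × (comparable columns) exactly.
* Differences: minimal mutational pathways between two codons are
  enumerated and averaged with equal weight; pathways crossing a stop are
  discarded (if all are blocked, the differences count as nonsynonymous).
* Distances: Jukes–Cantor, undefined at p ≥ 3/4 (saturation), in which
  case ω is undefined and the regime is reported as such.
* Regime: purifying if ω < 1 − band, positive if ω > 1 + band, neutral
  inside the band; the default band is 0 (strict ω < 1 ⇒ purifying).

This counting estimator is transparent and exactly testable (the pathway
averaging is verified against exhaustive enumeration); it is not a
maximum-likelihood codon model, so ω values from codeml-class software on
the same pairs will differ in detail.

## Gene structure

Phases are defined on CDS exons only (UTRs ignored); coordinates are GFF3
1-based inclusive throughout; one model per gene (longest CDS transcript).
Intron i's phase is the cumulative upstream exon length mod 3. Symmetric
exons are internal exons whose two flanking introns share a phase; terminal
exons are excluded from the symmetric/asymmetric tally by default because
they have only one flank (a flag treats gene boundaries as phase-0 flanks
instead, for comparison with conventions that count terminal exons).
Models whose CDS length is not divisible by 3 are excluded from phase
analysis with a warning.

## Promoter scanning

Promoters default to 2000 nt immediately upstream of the translation start
on the coding strand (the length fed to element-scanning services is
rarely reported; 2 kb is the common convention and is configurable).
Windows are clipped and flagged at contig edges; minus-strand promoters
are reverse-complemented so position 1 is the most distal base.

Matching is IUPAC consensus (presence/absence, PlantCARE-style), not
position-weight-matrix scoring. An N in the sequence never matches.
Overlapping hits are all reported. For both-strand motifs the reverse
complement of the consensus is matched on the forward sequence and
reported with strand '−' at its plus-coordinate; palindromic consensi
(e.g. CACGTG) record only the plus-strand hit so each physical site
appears once. The bundled motif table is representative and editable —
consensus strings for elements such as ABRE and HSE vary across database
releases, so absolute hit counts depend on the table version.

## Expression / differential expression

Intensities are assumed already RMA-normalized and positive. High
expression is a strict log₂ > 14 call. The DE statistic per gene is the
ratio of raw replicate means (not log-scale means), with a one-tailed
paired t-test (treatment > control, pairing by replicate index, df = n−1)
on the raw intensities; induction is called on fold ≥ 1.5 alone —
p-values are reported but not filtered on, matching how such fold-rule
tables are built. Printed tables round half-up to two decimals; full
precision is kept internally. Zero-variance differences yield a flagged
degenerate p (0 for a positive shift, else 1).

The packaged published cold-stress table is reproduced exactly by this
procedure for every internally consistent entry (49 of 50 means; 20 of 25
folds; 23 of 25 p-values to two decimals). The exceptions are errata in
the source table itself: four 4-h fold entries and one 8-h fold entry do
not equal the ratio of their own printed means (three of them instead
equal the *minimum* per-replicate ratio, one the median), and one 4-h
control mean is off by one unit in the last decimal. The recomputed
values are kept; the discrepant entries are enumerated in the acceptance
test.

## Phylogeny

Distances are p-distances with pairwise gap deletion (Poisson-corrected
distances by flag). NJ is Saitou–Nei with ties in the Q-matrix broken at
the lowest (row, column) index pair for reproducibility; negative branch
lengths are clamped to zero with the clamped deficit recorded. Bootstrap
support for an internal edge is the percentage of column-resampled
replicates whose NJ tree contains the same bipartition. Clade calling
takes, for each supported edge, the smaller bipartition side (both sides
for an even split) and keeps the maximal candidates, absorbing nested
ones; called clades are therefore disjoint and the remaining taxa are
orphans. The multiple alignment itself is consumed, not computed.

## Synthetic data generator

All randomness flows from one seeded NumPy generator per call; identical
spec and seed give byte-identical FASTA/GFF3/TSV output.

* **CDS**: amino acids drawn uniformly; the synonymous codon is chosen
  with weight t on G/C-ending codons and 1 − t otherwise, which makes
  realized GC3s track the target exactly for every family with an equal
  G/C vs A/T third-position split (all but Ile, whose 1-of-3 G/C split
  pulls the family mean slightly low — the realized family mean stays
  within ±0.05 of the target for n ≥ 50).
* **Divergence with controlled ω**: synonymous and nonsynonymous change
  quotas are derived from the targets through the inverse Jukes–Cantor
  map over the sequence's fractional site counts, then planted by
  accept/reject over random point mutations (stop-creating changes
  rejected; one mutation per position; the ATG start kept). Because the
  quotas are planted on the same counting scale the estimator uses,
  re-estimation recovers ω within ±0.1 at ≥ 500 codons.
* **Duplicates/triples**: copies are planted by whole-codon substitution
  to a different amino acid, so planted pairs have exactly the intended
  protein identity; triple copies mutate disjoint residue sets, giving
  copy-to-copy identity 2·identity − 1. A random tail lowers coverage
  below 1 where requested. Note the planted changes are all
  nonsynonymous by construction, so these pairs genuinely estimate
  ω > 1; the ω-controlled pairs are the purifying-regime fixtures.
* **Gene models**: introns (GT…AG, configurable length) are inserted at
  evenly spread cut points consistent with the requested phases; the
  spliced exons reproduce the CDS byte-for-byte on either strand.
* **Expression**: control replicate i is base × noise; treatment
  replicate i is control replicate i × fold × noise, with mean-one
  multiplicative log-normal noise of the requested CV — the paired
  structure the DE test assumes.
* The default family spec emulates a mid-size plant TF family study:
  94 genes (56 base + 16 duplicate copies + 9 × 2 triple copies + 4 ω
  pairs), 100–400 codons, GC3s 0.45, 2-kb promoters (about two thirds
  with a planted G-box, a third with an ABRE), paired 3-replicate
  control/treatment expression with CV 0.2 and fold 4 planted in ~20% of
  genes.

What the generator does **not** emulate: real codon-usage covariation and
amino-acid composition, microarray probe effects or normalization
artifacts, genome-scale intergenic structure, regulatory grammar beyond
planted consensi, and rate heterogeneity along sequences. Passing
round-trips therefore demonstrate the correctness of the computations
under the stated models, not robustness to every property of real data.

## Numerical choices and calibrations

* Rounding for printable tables is decimal half-up, two decimals.
* Measured size of the one-tailed paired t-test under the generator's
  null (fold 1, log-normal CV 0.2, n = 3): ≈ 3.3% at nominal 5% — the
  test is conservative because the paired differences are right-skewed;
  the calibration check uses 3000 simulations and accepts 5% ± 2 points.
* Pearson flag calibration at p < 0.01 on independent columns: ≈ 1%
  (checked over 100 × 12 pairs).
* Problem sizes in tests and the acceptance script are kept small by
  design (families of 8–20 genes for round-trips, 500-codon pairs for ω
  recovery, 100-replicate bootstraps in unit tests and 1000 in the
  analysis driver); the full suite runs in well under a minute.

## Known limitations

* Ka/Ks is counting-based; no transition/transversion weighting, no ML.
* Mechanism classification is conservative: without collinearity input,
  non-tandem pairs stay unclassified rather than guessing segmental.
* The promoter scanner is consensus-only; elements defined by matrices
  are approximated by representative strings.
* CAI/FOP/CBI depend on the reference set; cross-study comparison of
  absolute values is not meaningful without the same reference.
* The clade-calling convention (maximal supported bipartition, smaller
  side) matches "N clades + orphans" reporting but can absorb a stray
  taxon into a clade when its attachment is bootstrap-stable; that is a
  property of the data, not an error.
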