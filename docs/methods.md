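# Methods notes

This note records the models, the numerical choices, and what the synthetic
data does and does not emulate.  It is the place to look when a default
seems arbitrary or a test tolerance needs justifying.

## Coordinates and gene models

All interval arithmetic is 0-based half-open; GTF's 1-based closed
convention is converted at the I/O boundary only.  Genes are collapsed
across isoforms: the exon set is the union of transcript exons, introns are
the complement within the gene span, and the CDS span is the union span of
transcript CDS records.  On the collapsed model a base is 5'UTR, CDS or
3'UTR by its position relative to the CDS span in transcription direction;
when isoforms disagree (a base exonic in one isoform, intronic in another)
the exon label wins.  Genes without any CDS keep a plain `exon` label and
stay out of the UTR/CDS split.  Overlapping genes on opposite strands are
independent because read assignment is strand-aware; for same-strand
overlaps the exon-over-intron precedence applies across genes too, which is
a simplification worth remembering on dense annotations.

## Read assignment

A read is assigned to the category holding the majority of its aligned
bases (gaps excluded), ties broken exon-category-first (CDS, then 5'UTR,
then 3'UTR, then plain exon, then intron).  Read-level counting matches
how genic distributions are usually reported ("% of reads"); the majority
rule makes boundary reads deterministic.  Antisense reads are never
assigned to a gene.  The implementation paints base-resolution label/gene
arrays per (chromosome, strand); the test suite checks it against a
brute-force per-base scan of the partition intervals.

## Junction statistic

Alignment gaps (N operations) whose genomic interval overlaps an annotated
intron form the gap spectrum; the junction fraction is the fraction of all
reads with at least one such gap of length within [1,000, 3,000] nt
(closed bounds, configurable).  A read sampled from a spliced transcript
that straddles an exon–exon boundary aligns with a gap exactly equal to
the excised intron's length, so this window separates mature-mRNA binding
from pre-mRNA binding, whose reads are contiguous.

## Synthetic data: what it emulates

The generator defines the study conditions; its defaults are fixed and the
acceptance checks run against them.

**Toy genome.**  One chromosome, 50 genes (3–8 exons each), intergenic
gaps of 2–5 kb, random uniform base composition.  Intron lengths are
1,000 + Exp(600) truncated at 3,000 nt — a short-intron-heavy, right-skewed
draw (mean ≈ 1,520 nt) resembling the short end of mammalian intron length
distributions and keeping every junction gap inside the diagnostic window.
Per-gene exon aggregate length is pinned to 12:88 against introns, the
canonical exon:intron genomic share this analysis normalizes by.  The CDS
occupies ~55% of the spliced transcript with ~15% 5'UTR and the remainder
3'UTR.  Per-gene expression is log-normal with sd 0.4 in log10 units
(σ_e below).

**CLIP regimes.**  A library is a mixture: fraction w_pre of reads uniform
over the unspliced gene body, w_mature uniform over the spliced transcript
(emitting junction gaps), w_bg uniform over intergenic space.  For both
genic components the gene is chosen with probability proportional to
expression^α · 10^ε, ε ~ N(0, σ_ε²), so the log–log Pearson correlation
between per-gene read counts and expression is, in expectation,

    R = α σ_e / sqrt(α² σ_e² + σ_ε²).

The presets invert this closed form (α = 1):

| preset | w_pre | w_mature | w_bg | target R | σ_ε (log10) |
|---|---|---|---|---|---|
| nuclear_WT | 0.852 | 0 | 0.148 | 0.34 | 1.1064 |
| cytoplasmic_R495X | 0.3636 | 0.50 | 0.1364 | 0.61 | 0.5196 |

The mixture weights are chosen against the fixture's 88:12 intron:exon
length share so that the expected genic distribution is ~75% intronic /
~10% exonic for the nuclear binder and ~32% / ~54% for the cytoplasmic
binder.  Downstream recovery of those fractions and correlations is
therefore an emergent property of read placement plus assignment, not a
value read back from configuration.  Empirically the count-level
correlation converges to the closed form within ±0.02 at 2,000 genes and
2M reads; pseudocounts compress the low-count tail, so much shallower
libraries attenuate R.

Reads are error-free, unpaired, without quality scores or PCR duplicates,
and carry no crosslink-induced truncations or mutations; one library per
condition.  An optional 6-mer can be planted into a given fraction of read
sequences (overwriting six bases at a random offset, emulating a bound
motif) for enrichment-recovery tests.  None of the analyses here depend on
the omitted error processes, but absolute enrichment z-scales on real data
will differ.

**Count matrices.**  counts ~ NB(mean = baseline · sizefactor · 2^lfc,
dispersion), baseline log-normal (median ≈ 126), per-sample size factors
uniform in [0.5, 2], per-gene dispersion on a 0.02 + 3/μ trend with 0.15 dex
scatter unless specified.  Planted effects are per (condition, assay)
log2 fold-change vectors; truth tables are returned alongside.  Exon-level
matrices are derived by multinomially splitting gene counts over exon
weights, optionally perturbing one exon's weight per condition (an
exon-usage change that preserves the gene total).  RNA-Seq is simulated at
the matrix level, not the read level.

## The NB Wald test and its calibration

Per gene, group means of normalized counts give the log2 fold-change (with
pseudo-mean 0.5 guarding zero groups); the delta-method variance of the
log ratio under NB sampling is Var(ln m̄) ≈ (c̄/μ + α)/n per group, where
c̄ is the group mean of 1/sizefactor.  With the true dispersion this z
statistic is essentially exactly calibrated (type-I 0.051 at α = 0.05 in a
200,000-gene direct simulation), so all calibration effort goes into the
dispersion estimate:

- genewise method-of-moments estimates pooled over groups;
- a mean–dispersion trend a0 + a1/μ fitted through **bin means** (the
  genewise estimates are strongly right-skewed at 3 replicates; a
  median-based trend sits low and inflates the test to ~0.09);
- genewise values clipped to [trend/4, 4·trend] and blended 50/50 with
  the trend on the natural scale (log-scale averaging of skewed estimates
  biases the blend low).

With three replicates this lands the null type-I error at 0.050–0.067
across seeds and gives power ≈ 0.84 at a planted twofold change (baseline
mean 200, dispersion 0.05, BH FDR 0.05, balanced up/down effects on 25% of
genes).  One-sided planted effects are partially absorbed by
median-of-ratios normalization once a large minority of genes move — a
normalization property, not a test defect — so power fixtures plant
balanced effects.  Size factors are anchored to geometric mean 1, which
makes normalization exactly idempotent without changing any ratio.

BH adjustment is used wherever multiplicity arises; the tested universe
excludes features with all-zero counts.  Exon-level tests reuse gene-level
size factors so exon usage is not confounded by library composition.

## Translation-efficiency candidate selection

TE = mean normalized Ribo / mean normalized RNA per gene and condition;
genes with zero RNA mean are excluded.  The candidate filter takes the
ribosome-profiling comparisons of both conditions against the same
control: the stability window on the WT comparison is **open**
(−0.5, 0.5) and the mutant magnitude threshold **strict** (|lfc| > 0.5),
matching the printed inequalities; passers are ranked by ascending mutant
p-value (stable sort, so the result is invariant to input row order) and
the first floor(top_q · N) kept, with N the size of the tested universe —
"top 2%" is interpreted against the universe, consistent with ~280
candidates from a ~14,000-gene universe.  An optional RNA-level result
flags candidates whose expression also changed at α.

## k-mer enrichment

Foreground 6-mer counts are compared to 20 per-read dinucleotide-preserving
shuffles (Eulerian-trail construction with a rejection-sampled last-edge
arborescence; homopolymers are their own unique shuffle).  The z-score
uses the shuffle mean and sd inflated by sqrt(1 + 1/n_rounds) (the
foreground is one extra draw), and p-values use a t reference with
n_rounds − 1 degrees of freedom; shuffle-vs-shuffle z-scores are standard
normal to Kolmogorov–Smirnov precision at 4,096 k-mers.  Dinucleotide
preservation is the appropriate null for crosslink reads because it keeps
dinucleotide-driven composition biases out of the signal.

## Metaprofiles and ranked-set binding

Metaprofiles average block coverage over anchored exon windows (flank
500 bp, body 100 bp by default), strand-oriented so position 0 is the
first exon base (5' side) or first base past the exon (3' side); density
is per-region mean with no library-size scaling (single library per
condition).  Ranked-set binding splits an ordered gene list into
contiguous bins (10 by default) and reports the bound-gene fraction and
the mean ± SE exonic density per bin; the accompanying trend test is a
one-sided Mann–Whitney between top and bottom bins.

## Degenerate inputs and numerical conventions

Zero reads, empty exon sets, empty results and all-zero matrices raise
typed errors (`EmptyInputError`, `InsufficientDataError`,
`CountMatrixError`) rather than returning NaN; an empty exon matrix yields
an empty result frame.  Correlations use pseudocount 1 before log10 on
both axes and require ≥ 10 informative genes.  Fold-change bins use a
closed boundary (|FC| ≥ threshold counts as "at or above").  Reports are
rounded to 6 decimals and JSON-serialized with sorted keys, so identical
configurations produce byte-identical reports.

## Problem sizes

Defaults were chosen so a full demo runs in seconds and the acceptance
recomputation in well under a minute on one CPU: 50-gene toy genome,
200,000-read CLIP libraries, 2,000-gene count matrices with 3 replicates,
2M-read count-level binding simulations, 20 k-mer shuffle rounds.  These
sizes put the statistics comfortably past their asymptotic regimes
(standard errors of the recovered fractions ≈ 0.1 percentage points)
while staying desk-scale.

## Known limitations

- Collapsed gene models: no isoform-resolution quantification, no
  trans-splicing or fusion genes; per-transcript assignment could shift
  exact genic fractions on annotations with heavy isoform diversity.
- The exon-level test is plain per-exon differential expression with
  shared size factors, not a usage model with gene-level interaction
  terms.
- The NB test's calibration is tuned for the small-replicate regime; with
  many replicates the genewise clip window is unnecessarily tight (though
  harmless).
- Intergenic background is uniform; real CLIP backgrounds are structured
  (rRNA/tRNA and repeat elements are assumed to be removed upstream).
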