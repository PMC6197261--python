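# clipshift

Multi-omic analysis of what happens when an RNA-binding protein that
normally works in the nucleus ends up in the cytoplasm.  The motivating
biology is the ALS-associated truncation of the FUS nuclear localization
signal: the wild-type protein binds precursor mRNAs (intronic territory,
co-transcriptionally), while the mislocalized mutant binds **mature,
spliced mRNAs** in an expression-directed way and perturbs the translation
of a selectable gene set.  `clipshift` implements the complete analysis
chain needed to demonstrate and quantify such a compartment shift from
CLIP-Seq, RNA-Seq and Ribo-Seq data — together with a synthetic-data module
that generates ground-truthed toy genomes, CLIP libraries and count
matrices, so every statistic can be validated against a known answer.

It is aimed at computational biologists who want a tested, reusable and
fully simulatable version of this analysis rather than a one-off script
collection.

## What it computes

**CLIP side** (`clipshift.annotation`, `clipshift.binding`)

- Collapsed gene models from GTF and the genic partition
  (5'UTR / CDS / 3'UTR / intron), with aggregate element lengths.
- Read-to-category assignment (strand-aware, per-read majority of aligned
  bases, exon-first tie-break) and the genic read distribution.
- Length-normalized exon/intron binding densities: share_exon =
  (reads_exon / bp_exon) / (reads_exon / bp_exon + reads_intron / bp_intron).
- The exon–exon junction statistic: the fraction of reads carrying an
  alignment gap of 1,000–3,000 nt that overlaps an annotated intron (such a
  gap is the genomic footprint of an excised intron, so it diagnoses
  binding to spliced mRNA).
- Binding–expression coupling: Pearson R of log10(reads+1) vs
  log10(expression+1) per gene.
- 6-mer enrichment against per-read dinucleotide-preserving shuffles
  (Altschul–Erickson), with z-scores and BH-adjusted p-values.
- Metaprofiles of binding density around exon boundaries, and binding
  across ranked gene sets (bound fraction and mean exonic density per rank
  bin).

**Expression/translation side** (`clipshift.diffexp`, `clipshift.translation`)

- Median-of-ratios size factors and normalized counts.
- A negative-binomial Wald test per gene: NB(μ, α) with Var = μ + αμ²,
  method-of-moments dispersion shrunk 50/50 toward a fitted mean–dispersion
  trend, Wald z on the log fold-change of normalized group means, BH
  adjustment.  Calibrated so the null type-I error sits at the nominal
  level with three replicates.
- Congruence/overlap partition of two comparisons, fold-change magnitude
  bins, and per-exon differential usage with gene-level size factors.
- Translation efficiency TE = normalized Ribo / normalized RNA per gene.
- The differential-translation candidate selection: keep genes with
  −w < log2FC(WT vs control) < w (default w = 0.5), require
  |log2FC(mutant vs control)| > t (default t = 0.5), rank by p-value and
  keep the top q (default 2%) of the tested universe.

**Synthesis** (`clipshift.simulate`) — the study conditions

- Toy genome: 50 genes by default, 3–8 exons each, intron lengths
  short-skewed within [1,000, 3,000] nt, exon:intron aggregate length
  12:88.
- CLIP regimes as mixtures of pre-mRNA (uniform over the unspliced gene),
  mature (uniform over the spliced transcript, junction gaps emitted),
  and intergenic background reads.  Gene choice is proportional to
  expression^α times log-normal noise, so the log–log binding–expression
  correlation has the closed form R = ασ_e / √(α²σ_e² + σ_ε²).
- Two presets: `nuclear_WT` (w_pre = 0.852, w_bg = 0.148, R calibrated to
  0.34) and `cytoplasmic_R495X` (w_pre = 0.3636, w_mature = 0.50,
  w_bg = 0.1364, R calibrated to 0.61).
- NB count matrices (control/WT/R495X × RNA/Ribo × replicates) with drawn
  size factors and planted log2 fold-change effects, truth tables emitted.

## Worked example

The single-command demo generates the toy genome, simulates a nuclear-WT
and a cytoplasmic-mutant CLIP library (50,000 reads here), simulates count
matrices with planted effects, and runs every stage:

```sh
clipshift demo --out demo --seed 1 --n-clip-reads 50000
```

Selected lines of the printed report (also written to `demo/report.json`):

```json
"binding": {
  "WT":    {"intron_fraction": 0.75626, "exon_fraction": 0.09438,
            "junction_fraction": 0.0,     "binding_expression_r": 0.298411},
  "R495X": {"intron_fraction": 0.3176,  "exon_fraction": 0.5444,
            "junction_fraction": 0.12962, "binding_expression_r": 0.484067}
},
"diffexp":  {"overlap": {"both_up": 17, "both_down": 22, "non_congruent": 1}},
"translate": {"n_candidates": 40, "universe_size": 2000,
              "n_expression_changed": 11, "planted_dt_recall": 0.75}
```

Reading it: the nuclear binder leaves ~76% of its reads in introns and
never spans a junction; the cytoplasmic binder shifts to ~54% exonic reads
with a junction-read fraction of 13%, and its per-gene binding tracks
expression more tightly.  (The per-gene correlations printed here are
computed over the 50 toy genes; at 2,000 genes they converge to the preset
calibrations of 0.34 and 0.61.)  Differential expression recovers the
planted, sign-congruent overlap structure with a single non-congruent
gene, and the windowed top-2% selection returns 40 candidates from the
2,000-gene universe, of which few show expression changes — translation
changes are not an mRNA-abundance echo.

Each stage is also exposed separately (`clipshift simulate|bind|counts|
diffexp|translate|select|integrate`), and everything is importable from
Python; see the module docstrings.

## Layout

```
src/clipshift/
  annotation.py   gene models, genic partition, GTF/BED I/O
  reads.py        gapped-alignment container, SAM I/O
  simulate.py     toy genome, CLIP regimes, NB count matrices
  binding.py      CLIP statistics (distribution, gaps, correlation, ...)
  kmers.py        k-mer counting and dinucleotide shuffling
  diffexp.py      size factors, NB Wald test, exon usage
  translation.py  translation efficiency, candidate selection
  pipeline.py     end-to-end orchestration and cross-layer statistics
  cli.py          command-line surface
docs/methods.md   model and design notes
tests/            pytest suite with brute-force oracles
```
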