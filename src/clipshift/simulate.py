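"""Synthetic data: toy genome, CLIP read simulation, NB count matrices.

Two named CLIP regimes emulate the compartment shift of an RNA-binding
protein.  A nuclear binder samples reads uniformly along unspliced pre-mRNA
(mostly intronic territory); a cytoplasmic binder samples spliced mature
mRNA (exonic territory, junction-spanning reads whose genomic gap equals an
intron length).  In both regimes the gene a read comes from is chosen
proportionally to expression^alpha times multiplicative log-normal noise, so
the log-log Pearson correlation between per-gene read count and expression
has the closed form

    R = alpha * sigma_e / sqrt(alpha^2 sigma_e^2 + sigma_eps^2)

where sigma_e is the sd of log10 expression.  The preset noise levels are
fixed from this formula so that correlation recovery downstream is an
emergent property of the pipeline, not a read-back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    Transcript,
    write_gtf,
)
from .diffexp import CountMatrix
from .reads import AlignedReadSet, ReadRecord, revcomp

#: sd of log10 expression in the toy expression table (sigma_e above)
EXPRESSION_SDLOG10 = 0.4
EXPRESSION_MEANLOG10 = 2.0

#: target exon share of genic length in the toy annotation (12:88 exon:intron)
EXON_SHARE = 0.12

#: intron lengths: 1000 + Exp(600) truncated at 3000 (short-intron-heavy)
INTRON_MIN, INTRON_MAX, INTRON_EXP_SCALE = 1000, 3000, 600.0


def sigma_eps_for_correlation(r: float, sigma_e: float = EXPRESSION_SDLOG10) -> float:
    """Noise sd giving log-log binding-expression Pearson correlation ``r``."""
    if not 0 < r <= 1:
        raise ValueError("target correlation must be in (0, 1]")
    return sigma_e * math.sqrt(1.0 / r**2 - 1.0)


@dataclass(frozen=True)
class ClipRegime:
    """Mixture weights and expression coupling of a simulated CLIP library."""

    name: str
    w_pre: float  # fraction of reads uniform over unspliced pre-mRNA
    w_mature: float  # fraction uniform over spliced mature mRNA
    w_bg: float  # intergenic background fraction
    alpha: float = 1.0  # expression-coupling exponent for gene choice
    sigma_eps: float = 0.0  # log10-scale sd of per-gene coupling noise
    planted_kmer: str | None = None
    planted_kmer_prob: float = 0.0

    def __post_init__(self):
        if abs(self.w_pre + self.w_mature + self.w_bg - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.w_pre, self.w_mature, self.w_bg) < 0:
            raise ValueError("mixture weights must be non-negative")
        if self.alpha < 0 or self.sigma_eps < 0:
            raise ValueError("alpha and sigma_eps must be >= 0")
        if self.planted_kmer is not None and not (
            0 <= self.planted_kmer_prob <= 1
        ):
            raise ValueError("planted_kmer_prob must be in [0, 1]")


# Preset weights: the nuclear binder should place 75% of reads in introns and
# ~10% in exons given the fixture's 88:12 intron:exon genic length share
# (0.852 * 0.88 = 0.75); the cytoplasmic binder 32% in introns and 54% in
# exons (0.3636 * 0.88 = 0.32; 0.50 + 0.3636 * 0.12 = 0.544).  Coupling noise
# targets log-log correlations of 0.34 and 0.61 respectively.
NUCLEAR_WT = ClipRegime(
    name="nuclear_WT",
    w_pre=0.852,
    w_mature=0.0,
    w_bg=0.148,
    alpha=1.0,
    sigma_eps=sigma_eps_for_correlation(0.34),
)
CYTOPLASMIC_R495X = ClipRegime(
    name="cytoplasmic_R495X",
    w_pre=0.3636,
    w_mature=0.50,
    w_bg=0.1364,
    alpha=1.0,
    sigma_eps=sigma_eps_for_correlation(0.61),
)
PRESETS = {r.name: r for r in (NUCLEAR_WT, CYTOPLASMIC_R495X)}


def expected_genic_fractions(
    regime: ClipRegime, intron_share: float = 1 - EXON_SHARE
) -> dict[str, float]:
    """Expected read fractions implied by the mixture weights and length shares."""
    return {
        "intron": regime.w_pre * intron_share,
        "exon": regime.w_mature + regime.w_pre * (1 - intron_share),
        "other": regime.w_bg,
    }


@dataclass
class ToyReference:
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    expression: pd.Series  # gene_id -> expression level (arbitrary units)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.annotation.genes]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_toy_reference(
    n_genes: int = 50,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ToyReference:
    """Build the toy genome: FASTA, gene models, per-gene expression.

    Each gene has 3-8 exons; intron lengths are short-intron-skewed within
    [1000, 3000] nt so junction gaps fall in the diagnostic window; per-gene
    exon:intron aggregate length is pinned at 12:88.  Deterministic for a
    fixed seed.  When ``out_dir`` is given, writes genome.fa, genes.gtf and
    expression.tsv there.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    genes: list[GeneModel] = []
    cursor = 0
    for gi in range(n_genes):
        cursor += int(rng.integers(2000, 5001))  # intergenic gap
        n_exons = int(rng.integers(3, 9))
        introns = []
        while len(introns) < n_exons - 1:
            ln = INTRON_MIN + rng.exponential(INTRON_EXP_SCALE)
            if ln <= INTRON_MAX:
                introns.append(int(ln))
        intron_total = sum(introns)
        exon_total = max(n_exons * 60, round(intron_total * EXON_SHARE / (1 - EXON_SHARE)))
        # split the exon budget with a 50 bp floor per exon
        spare = exon_total - 50 * n_exons
        props = rng.dirichlet(np.full(n_exons, 2.0))
        exon_lens = (50 + np.floor(props * spare)).astype(int)
        exon_lens[-1] += exon_total - int(exon_lens.sum())
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += introns[i]
        strand = "+" if rng.random() < 0.5 else "-"
        spliced_len = int(exon_lens.sum())
        # CDS on spliced coordinates: ~15% 5'UTR, ~55% CDS (codon-rounded)
        five = max(24, round(0.15 * spliced_len))
        cds_len = max(60, round(0.55 * spliced_len))
        cds_len -= cds_len % 3
        if five + cds_len > spliced_len - 24:
            cds_len = spliced_len - 24 - five
            cds_len -= cds_len % 3
        if strand == "+":
            c0, c1 = five, five + cds_len
        else:  # 5' end is the genomic right
            c0, c1 = spliced_len - five - cds_len, spliced_len - five
        cds_span = (
            _spliced_to_genomic(exons, c0),
            _spliced_to_genomic(exons, c1 - 1) + 1,
        )
        gene_id = f"gene{gi + 1:03d}"
        genes.append(
            GeneModel(
                gene_id,
                chrom,
                strand,
                [Transcript(f"{gene_id}.t1", exons, cds_span)],
            )
        )
        cursor = pos
    chrom_len = cursor + int(rng.integers(2000, 5001))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, chrom_len)])
    annotation = GenomeAnnotation(genes, {chrom: chrom_len})
    expression = pd.Series(
        10 ** rng.normal(EXPRESSION_MEANLOG10, EXPRESSION_SDLOG10, n_genes),
        index=[g.gene_id for g in genes],
        name="expression",
    )
    ref = ToyReference(annotation, {chrom: seq}, expression)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(ref.sequences, out_dir / "genome.fa")
        write_gtf(annotation, out_dir / "genes.gtf")
        expression.to_frame().to_csv(
            out_dir / "expression.tsv", sep="\t", float_format="%.6f"
        )
    return ref


def _spliced_to_genomic(exons: list[tuple[int, int]], pos: int) -> int:
    """Map a spliced-transcript coordinate to its genomic base."""
    for s, e in exons:
        if pos < e - s:
            return s + pos
        pos -= e - s
    raise IndexError("spliced position beyond transcript")


def _spliced_interval_to_blocks(
    exons: list[tuple[int, int]], start: int, length: int
) -> list[tuple[int, int]]:
    """Genomic blocks covered by [start, start+length) in spliced coordinates."""
    blocks = []
    remaining = length
    pos = start
    for s, e in exons:
        exon_len = e - s
        if pos >= exon_len:
            pos -= exon_len
            continue
        take = min(remaining, exon_len - pos)
        blocks.append((s + pos, s + pos + take))
        remaining -= take
        pos = 0
        if remaining == 0:
            break
    if remaining:
        raise IndexError("spliced interval beyond transcript")
    return blocks


def gene_choice_probabilities(
    expression: np.ndarray, regime: ClipRegime, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene sampling probabilities: expression^alpha x log-normal noise."""
    logw = regime.alpha * np.log10(expression) + rng.normal(
        0.0, regime.sigma_eps, len(expression)
    )
    w = 10 ** (logw - logw.max())
    return w / w.sum()


def simulate_binding_counts(
    expression: pd.Series | np.ndarray,
    regime: ClipRegime,
    n_reads: int = 2_000_000,
    seed: int = 0,
) -> pd.Series:
    """Per-gene CLIP read counts at the count level (no read placement).

    Only the genic (pre + mature) portion of the library is allocated to
    genes; the background fraction is discarded.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    expr = np.asarray(expression, dtype=float)
    p = gene_choice_probabilities(expr, regime, rng)
    n_genic = rng.binomial(n_reads, regime.w_pre + regime.w_mature)
    counts = rng.multinomial(n_genic, p)
    index = expression.index if isinstance(expression, pd.Series) else None
    return pd.Series(counts, index=index, name="clip_reads")


def simulate_clip_reads(
    reference: ToyReference,
    regime: ClipRegime,
    n_reads: int,
    read_len: int = 50,
    seed: int = 0,
    sam_path: str | Path | None = None,
) -> AlignedReadSet:
    """Simulate gapped CLIP alignments under a binder regime.

    Pre-mRNA reads are contiguous and uniform over the unspliced gene span;
    mature reads are uniform along the spliced transcript and carry an N-gap
    exactly equal to an annotated intron length whenever they straddle a
    junction; background reads fall in intergenic space.  Every read carries
    its truth category in the XC tag (pre|mature|bg).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    rng = np.random.default_rng(seed)
    ann = reference.annotation
    genes = ann.genes
    expr = reference.expression.loc[[g.gene_id for g in genes]].to_numpy()
    p_gene = gene_choice_probabilities(expr, regime, rng)

    n_pre, n_mat, n_bg = rng.multinomial(
        n_reads, [regime.w_pre, regime.w_mature, regime.w_bg]
    )

    # intergenic intervals long enough to hold a read
    intergenic: list[tuple[str, int, int]] = []
    for chrom, size in ann.chrom_sizes.items():
        spans = sorted(g.span for g in genes if g.chrom == chrom)
        cursor = 0
        for s, e in spans:
            if s - cursor >= read_len:
                intergenic.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if size - cursor >= read_len:
            intergenic.append((chrom, cursor, size))
    ig_lens = np.array([e - s - read_len + 1 for _, s, e in intergenic], dtype=float)

    reads: list[ReadRecord] = []
    counter = 0

    def seq_for(chrom: str, blocks: list[tuple[int, int]], strand: str) -> str:
        s = "".join(reference.sequences[chrom][a:b] for a, b in blocks)
        return revcomp(s) if strand == "-" else s

    def maybe_plant(seq: str) -> str:
        if regime.planted_kmer and rng.random() < regime.planted_kmer_prob:
            k = regime.planted_kmer
            off = int(rng.integers(0, len(seq) - len(k) + 1))
            seq = seq[:off] + k + seq[off + len(k) :]
        return seq

    # --- pre-mRNA reads: contiguous, uniform over the unspliced gene span
    gidx = rng.choice(len(genes), n_pre, p=p_gene)
    for gi in gidx:
        g = genes[gi]
        s0, s1 = g.span
        start = int(s0 + rng.integers(0, max(1, (s1 - s0) - read_len + 1)))
        blocks = [(start, start + read_len)]
        counter += 1
        reads.append(
            ReadRecord(
                g.chrom,
                g.strand,
                tuple(blocks),
                name=f"r{counter:07d}",
                seq=maybe_plant(seq_for(g.chrom, blocks, g.strand)),
                category="pre",
            )
        )

    # --- mature reads: uniform along the spliced transcript
    gidx = rng.choice(len(genes), n_mat, p=p_gene)
    for gi in gidx:
        g = genes[gi]
        exons = g.collapsed_exons
        spliced_len = sum(e - s for s, e in exons)
        eff_len = min(read_len, spliced_len)
        spos = int(rng.integers(0, max(1, spliced_len - eff_len + 1)))
        blocks = _spliced_interval_to_blocks(exons, spos, eff_len)
        counter += 1
        reads.append(
            ReadRecord(
                g.chrom,
                g.strand,
                tuple(blocks),
                name=f"r{counter:07d}",
                seq=maybe_plant(seq_for(g.chrom, blocks, g.strand)),
                category="mature",
            )
        )

    # --- background reads: uniform over intergenic space, random strand
    if n_bg and not intergenic:
        raise ValueError("no intergenic space available for background reads")
    if n_bg:
        iidx = rng.choice(len(intergenic), n_bg, p=ig_lens / ig_lens.sum())
        for ii in iidx:
            chrom, s, e = intergenic[ii]
            start = int(s + rng.integers(0, e - s - read_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            blocks = [(start, start + read_len)]
            counter += 1
            reads.append(
                ReadRecord(
                    chrom,
                    strand,
                    tuple(blocks),
                    name=f"r{counter:07d}",
                    seq=maybe_plant(seq_for(chrom, blocks, strand)),
                    category="bg",
                )
            )

    read_set = AlignedReadSet(reads, dict(ann.chrom_sizes))
    if sam_path is not None:
        read_set.write_sam(sam_path)
    return read_set


# ---------------------------------------------------------------------------
# NB count matrices with planted effects


def default_dispersion(mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mean-dependent dispersion trend with mild gene-to-gene scatter."""
    trend = 0.02 + 3.0 / np.maximum(mean, 1.0)
    return trend * 10 ** rng.normal(0.0, 0.15, len(mean))


@dataclass
class CountSimulationDesign:
    """Design of a simulated count experiment.

    ``effects`` maps (condition, assay) to a length-``n_genes`` array of
    planted log2 fold-changes versus control; missing entries mean no effect.
    """

    n_genes: int = 5000
    conditions: tuple[str, ...] = ("control", "WT", "R495X")
    assays: tuple[str, ...] = ("rna", "ribo")
    n_reps: int = 3
    baseline_meanlog10: float = 2.1
    baseline_sdlog10: float = 0.45
    dispersion: float | np.ndarray | None = None  # None -> mean trend
    effects: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    size_factor_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("need >= 2 replicates per condition")
        for key, arr in self.effects.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_genes,):
                raise ValueError(f"effect array for {key} has wrong length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"effect array for {key} has non-finite values")
            self.effects[key] = arr
        if isinstance(self.dispersion, np.ndarray) and np.any(self.dispersion <= 0):
            raise ValueError("dispersions must be > 0")
        if isinstance(self.dispersion, float) and self.dispersion <= 0:
            raise ValueError("dispersions must be > 0")


def simulate_counts(
    design: CountSimulationDesign, seed: int = 0
) -> tuple[CountMatrix, dict]:
    """Draw NB counts under the design; returns the matrix and a truth table.

    counts_gs ~ NB(mean = baseline_g * sizefactor_s * 2^log2fc, dispersion_g);
    size factors are drawn uniformly from the design range.
    """
    rng = np.random.default_rng(seed)
    n = design.n_genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    baseline = 10 ** rng.normal(design.baseline_meanlog10, design.baseline_sdlog10, n)
    if design.dispersion is None:
        disp = default_dispersion(baseline, rng)
    elif np.isscalar(design.dispersion):
        disp = np.full(n, float(design.dispersion))
    else:
        disp = np.asarray(design.dispersion, dtype=float)

    samples = []
    for assay in design.assays:
        for cond in design.conditions:
            for rep in range(1, design.n_reps + 1):
                samples.append((f"{cond}_{assay}_{rep}", cond, assay, rep))
    sample_df = pd.DataFrame(
        samples, columns=["sample", "condition", "assay", "replicate"]
    ).set_index("sample")
    lo, hi = design.size_factor_range
    size_factors = pd.Series(
        rng.uniform(lo, hi, len(sample_df)), index=sample_df.index, name="size_factor"
    )

    cols = {}
    r_nb = 1.0 / disp
    for name, row in sample_df.iterrows():
        lfc = design.effects.get((row["condition"], row["assay"]), None)
        mean = baseline * size_factors[name]
        if lfc is not None:
            mean = mean * 2.0**lfc
        p_nb = r_nb / (r_nb + mean)
        cols[name] = rng.negative_binomial(r_nb, p_nb)
    counts = pd.DataFrame(cols, index=gene_ids)
    truth = {
        "baseline_mean": pd.Series(baseline, index=gene_ids),
        "dispersion": pd.Series(disp, index=gene_ids),
        "size_factors": size_factors,
        "effects": {
            k: pd.Series(v, index=gene_ids) for k, v in design.effects.items()
        },
    }
    return CountMatrix(counts, sample_df), truth


def simulate_exon_counts(
    gene_matrix: CountMatrix,
    n_exons: dict[str, int] | int = 5,
    effects: dict[tuple[str, str, int], float] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Split gene-level counts into per-exon counts.

    Each gene's count in each sample is distributed over its exons
    multinomially with fixed per-gene exon weights; ``effects`` maps
    (condition, gene_id, exon_index) to a log2 fold-change applied to that
    exon's weight in that condition (an exon-usage change).  Returns the
    exon-level matrix and an exon_id -> gene_id parent map.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    counts = gene_matrix.counts
    samples = gene_matrix.samples
    exon_rows: dict[str, list] = {}
    exon_ids: list[str] = []
    parents: list[str] = []
    base_weights: dict[str, np.ndarray] = {}
    for gene_id in counts.index:
        k = n_exons if isinstance(n_exons, int) else n_exons[gene_id]
        base_weights[gene_id] = rng.dirichlet(np.full(k, 5.0))
        for e in range(k):
            exon_ids.append(f"{gene_id}:E{e + 1:02d}")
            parents.append(gene_id)
    data = np.zeros((len(exon_ids), counts.shape[1]), dtype=int)
    row0 = 0
    for gene_id in counts.index:
        w0 = base_weights[gene_id]
        k = len(w0)
        for j, (sample, srow) in enumerate(samples.iterrows()):
            w = w0.copy()
            for e in range(k):
                lfc = effects.get((srow["condition"], gene_id, e))
                if lfc is not None:
                    w[e] *= 2.0**lfc
            w /= w.sum()
            data[row0 : row0 + k, j] = rng.multinomial(counts.loc[gene_id, sample], w)
        row0 += k
    exon_counts = pd.DataFrame(data, index=exon_ids, columns=counts.columns)
    return (
        CountMatrix(exon_counts, samples.copy()),
        pd.Series(parents, index=exon_ids, name="gene_id"),
    )


def write_regime_config(regime: ClipRegime, path: str | Path) -> None:
    """Persist a regime as a flat key=value file."""
    with open(path, "w") as fh:
        fh.write(f"name={regime.name}\n")
        fh.write(f"w_pre={regime.w_pre}\nw_mature={regime.w_mature}\n")
        fh.write(f"w_bg={regime.w_bg}\nalpha={regime.alpha}\n")
        fh.write(f"sigma_eps={regime.sigma_eps}\n")
        if regime.planted_kmer:
            fh.write(f"planted_kmer={regime.planted_kmer}\n")
            fh.write(f"planted_kmer_prob={regime.planted_kmer_prob}\n")


def read_regime_config(path: str | Path) -> ClipRegime:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                kv[k] = v
    return ClipRegime(
        name=kv["name"],
        w_pre=float(kv["w_pre"]),
        w_mature=float(kv["w_mature"]),
        w_bg=float(kv["w_bg"]),
        alpha=float(kv.get("alpha", 1.0)),
        sigma_eps=float(kv.get("sigma_eps", 0.0)),
        planted_kmer=kv.get("planted_kmer"),
        planted_kmer_prob=float(kv.get("planted_kmer_prob", 0.0)),
    )
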