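"""CLIP-side statistics.

Read-to-element assignment against the genic partition, genic read
distributions, length-normalized exon/intron densities, the junction
gap-size statistic, per-gene binding profiles, binding-expression
correlation, k-mer enrichment, exon metaprofiles and binding across ranked
gene sets.

Assignment is read-level and strand-aware: a read is labeled by the genic
category holding the majority of its aligned bases on same-strand genes,
with ties broken in favor of exon categories; reads overlapping no gene are
``other``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import EXON_LABELS, LABELS, GenicPartition, IntronCatalog
from .kmers import kmer_enrichment_table
from .reads import AlignedReadSet, ReadRecord

logger = logging.getLogger(__name__)

#: label codes for the per-base index; 0 is "no gene", order = tie precedence
_CODE = {lab: i + 1 for i, lab in enumerate(LABELS)}
_DECODE = {i + 1: lab for i, lab in enumerate(LABELS)}


class EmptyInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class _StrandIndex:
    """Per-(chrom, strand) base-resolution label and gene index."""

    def __init__(self, size: int):
        self.labels = np.zeros(size, dtype=np.uint8)
        self.genes = np.zeros(size, dtype=np.int32)  # 0 = none, else gene idx+1

    def paint(self, start: int, end: int, code: int, gene_num: int) -> None:
        region = self.labels[start:end]
        # exon categories overwrite introns of overlapping same-strand genes;
        # otherwise first writer wins (lower code = higher precedence)
        takeover = (region == 0) | (region > code)
        region[takeover] = code
        self.genes[start:end][takeover] = gene_num


class GenomeIndex:
    """Base-resolution genic index over both strands, built from a partition."""

    def __init__(self, partition: GenicPartition, chrom_sizes: dict[str, int]):
        self.partition = partition
        self.gene_ids = sorted(partition.intervals)
        self._gene_num = {g: i + 1 for i, g in enumerate(self.gene_ids)}
        self._idx: dict[tuple[str, str], _StrandIndex] = {}
        # paint introns first so exon labels take precedence across genes
        for pass_labels in (("intron",), EXON_LABELS):
            for gene_id in self.gene_ids:
                gene = partition.genes[gene_id]
                key = (gene.chrom, gene.strand)
                if key not in self._idx:
                    self._idx[key] = _StrandIndex(chrom_sizes[gene.chrom])
                si = self._idx[key]
                for s, e, lab in partition.intervals[gene_id]:
                    if lab in pass_labels:
                        si.paint(s, e, _CODE[lab], self._gene_num[gene_id])

    def lookup(self, read: ReadRecord) -> tuple[str, str | None]:
        """Majority-base label and gene for one read."""
        si = self._idx.get((read.chrom, read.strand))
        if si is None:
            return "other", None
        labs = np.concatenate([si.labels[s:e] for s, e in read.blocks])
        counts = np.bincount(labs, minlength=len(LABELS) + 1)
        if counts[1:].sum() == 0:
            return "other", None
        # majority count, ties broken by precedence (exon categories first)
        best = min(
            (c for c in range(1, len(LABELS) + 1) if counts[c] > 0),
            key=lambda c: (-counts[c], c),
        )
        gene_slice = np.concatenate([si.genes[s:e] for s, e in read.blocks])
        gnums = gene_slice[labs == best]
        gene_num = np.bincount(gnums).argmax()
        gene = self.gene_ids[gene_num - 1] if gene_num > 0 else None
        return _DECODE[best], gene


@dataclass
class ReadAssignments:
    """Per-read labels plus aggregated tallies."""

    labels: list[str]
    genes: list[str | None]
    tallies: Counter = field(default_factory=Counter)
    gene_tallies: pd.DataFrame | None = None

    @property
    def n_reads(self) -> int:
        return len(self.labels)


def assign_reads(
    reads: AlignedReadSet, partition: GenicPartition
) -> ReadAssignments:
    """Assign every read to a genic category (and gene) by base majority."""
    chrom_sizes = dict(reads.chrom_sizes)
    for gene in partition.genes.values():
        chrom_sizes.setdefault(gene.chrom, gene.span[1])
    ann_chroms = {g.chrom for g in partition.genes.values()}
    index = GenomeIndex(partition, chrom_sizes)
    labels: list[str] = []
    genes: list[str | None] = []
    tallies: Counter = Counter()
    per_gene: dict[str, Counter] = {}
    warned: set[str] = set()
    for read in reads:
        if read.chrom not in ann_chroms and read.chrom not in warned:
            logger.warning(
                "chromosome %s absent from annotation; reads counted as other",
                read.chrom,
            )
            warned.add(read.chrom)
        lab, gene = index.lookup(read)
        labels.append(lab)
        genes.append(gene)
        tallies[lab] += 1
        if gene is not None:
            per_gene.setdefault(gene, Counter())[lab] += 1
    gene_tallies = pd.DataFrame(
        {g: {lab: per_gene.get(g, Counter()).get(lab, 0) for lab in LABELS}
         for g in sorted(partition.intervals)}
    ).T
    gene_tallies.index.name = "gene_id"
    return ReadAssignments(labels, genes, tallies, gene_tallies[list(LABELS)])


@dataclass
class GenicDistribution:
    """Read fractions over genic categories; ``other`` is non-genic."""

    fractions: dict[str, float]
    n_reads: int

    @property
    def exon_fraction(self) -> float:
        """Pooled exonic fraction (5'UTR + CDS + 3'UTR + plain exon)."""
        return sum(self.fractions.get(lab, 0.0) for lab in EXON_LABELS)

    @property
    def intron_fraction(self) -> float:
        return self.fractions.get("intron", 0.0)


def genic_distribution(tallies: Counter | dict[str, int]) -> GenicDistribution:
    """Normalize category tallies to fractions (summing to 1)."""
    total = sum(tallies.values())
    if total == 0:
        raise EmptyInputError("no reads to distribute")
    return GenicDistribution(
        {lab: n / total for lab, n in sorted(tallies.items())}, total
    )


@dataclass
class NormalizedElementDensity:
    """Exon/intron read densities normalized to sum to 1."""

    exon_share: float
    intron_share: float
    exon_density: float  # reads per bp
    intron_density: float


def length_normalized_density(
    tallies: Counter | dict[str, int], partition: GenicPartition
) -> NormalizedElementDensity:
    """Per-bp exon and intron read densities, scaled so the shares sum to 1."""
    exon_bp = partition.exon_bp
    intron_bp = partition.intron_bp
    if exon_bp == 0 or intron_bp == 0:
        raise EmptyInputError(
            "zero aggregate exon or intron length; shares undefined"
        )
    exon_reads = sum(tallies.get(lab, 0) for lab in EXON_LABELS)
    intron_reads = tallies.get("intron", 0)
    de = exon_reads / exon_bp
    di = intron_reads / intron_bp
    total = de + di
    if total == 0:
        raise EmptyInputError("no genic reads; shares undefined")
    return NormalizedElementDensity(de / total, di / total, de, di)


@dataclass
class GapSpectrum:
    """Alignment-gap lengths restricted to gaps overlapping annotated introns."""

    gap_lengths: np.ndarray
    junction_fraction: float
    window: tuple[int, int]
    n_reads: int

    def histogram(self, bins: int | np.ndarray = 50) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.gap_lengths, bins=bins)


def gap_spectrum(
    reads: AlignedReadSet,
    introns: IntronCatalog,
    window: tuple[int, int] = (1000, 3000),
) -> GapSpectrum:
    """Gap-size spectrum and the junction-read fraction.

    Only gaps whose genomic interval overlaps an annotated intron enter the
    spectrum; ``junction_fraction`` is the fraction of all reads carrying at
    least one such gap with length inside ``window`` (closed bounds).
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window lower bound must be below upper bound")
    # merged intron intervals per chromosome for fast overlap queries
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, *_ in introns.introns}:
        ivs = sorted(
            (s, e) for c, s, e, _ in introns.introns if c == chrom
        )
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in out]),
            np.array([e for _, e in out]),
        )

    def overlaps_intron(chrom: str, s: int, e: int) -> bool:
        if chrom not in merged:
            return False
        starts, ends = merged[chrom]
        i = np.searchsorted(starts, e, side="left")
        return i > 0 and ends[i - 1] > s

    lengths: list[int] = []
    n_junction = 0
    for read in reads:
        hit = False
        for gs, ge in read.gaps:
            if overlaps_intron(read.chrom, gs, ge):
                glen = ge - gs
                lengths.append(glen)
                if lo <= glen <= hi:
                    hit = True
        n_junction += hit
    n_reads = len(reads)
    frac = n_junction / n_reads if n_reads else 0.0
    return GapSpectrum(np.array(lengths, dtype=int), frac, (lo, hi), n_reads)


def gene_binding_profile(
    assignments: ReadAssignments, partition: GenicPartition
) -> pd.DataFrame:
    """Per-gene exonic/intronic read counts and per-kb densities."""
    gt = assignments.gene_tallies
    exonic = gt[list(EXON_LABELS)].sum(axis=1)
    intronic = gt["intron"]
    exon_kb = pd.Series(
        {g: sum(v for lab, v in partition.gene_lengths(g).items()
                if lab in EXON_LABELS) / 1000.0 for g in gt.index}
    )
    intron_kb = pd.Series(
        {g: partition.gene_lengths(g)["intron"] / 1000.0 for g in gt.index}
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ed = np.where(exon_kb > 0, exonic / exon_kb, 0.0)
        idn = np.where(intron_kb > 0, intronic / intron_kb, 0.0)
    return pd.DataFrame(
        {
            "exonic_reads": exonic.astype(int),
            "intronic_reads": intronic.astype(int),
            "exonic_density": ed,
            "intronic_density": idn,
        },
        index=gt.index,
    )


def binding_expression_correlation(
    binding: pd.Series | pd.DataFrame, expression: pd.Series
) -> tuple[float, int]:
    """Pearson correlation of log10(binding + 1) vs log10(expression + 1).

    ``binding`` may be a per-gene read-count Series or a binding-profile
    frame (exonic + intronic reads are summed).  Returns (R, n genes used);
    requires at least 10 genes with binding > 0 and expression > 0.
    """
    if isinstance(binding, pd.DataFrame):
        binding = binding["exonic_reads"] + binding["intronic_reads"]
    common = binding.index.intersection(expression.index)
    b = binding.loc[common].astype(float)
    e = expression.loc[common].astype(float)
    usable = e > 0
    if int(((b > 0) & usable).sum()) < 10:
        raise InsufficientDataError(
            "fewer than 10 genes with positive binding and expression"
        )
    r, _ = stats.pearsonr(np.log10(b[usable] + 1), np.log10(e[usable] + 1))
    return float(r), int(usable.sum())


def kmer_enrichment(
    reads: AlignedReadSet | list[str],
    k: int = 6,
    n_shuffles: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """6-mer (by default) enrichment of read sequences vs shuffled background."""
    if isinstance(reads, AlignedReadSet):
        seqs = [r.seq for r in reads if r.seq]
    else:
        seqs = list(reads)
    if not seqs:
        raise EmptyInputError("no read sequences available")
    if all(len(s) < k for s in seqs):
        raise ValueError(f"k={k} exceeds every read length")
    return kmer_enrichment_table(seqs, k=k, n_shuffles=n_shuffles, seed=seed)


@dataclass
class MetaProfile:
    """Mean positional read density over a set of anchored exon regions.

    Position 0 is the exon 5' end (side="five") or 3' end (side="three");
    negative positions are outside the exon for the 5' side and inside for
    the 3' side.  Density is reads covering the position divided by the
    number of exons in the set.
    """

    positions: np.ndarray
    density: np.ndarray
    side: str
    n_regions: int


def exon_metaprofile(
    reads: AlignedReadSet,
    exon_sets: dict[str, list[tuple[str, int, int, str]]],
    flank_bp: int = 500,
    body_bp: int = 100,
) -> dict[tuple[str, str], MetaProfile]:
    """Binding density around exon boundaries for labeled exon sets.

    Returns a profile per (set name, side) with side in {"five", "three"};
    the window spans flank_bp outside and body_bp inside the exon, oriented
    5'->3' in transcription direction.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    for name, exons in exon_sets.items():
        if not exons:
            raise EmptyInputError(f"exon set {name!r} is empty")
    # chromosome coverage from aligned blocks
    cov: dict[str, np.ndarray] = {}
    for chrom, size in reads.chrom_sizes.items():
        cov[chrom] = np.zeros(size + 1, dtype=np.int64)
    for read in reads:
        for s, e in read.blocks:
            arr = cov.get(read.chrom)
            if arr is not None:
                arr[s] += 1
                arr[min(e, len(arr) - 1)] -= 1
    cov = {c: np.cumsum(a)[:-1] for c, a in cov.items()}

    window = flank_bp + body_bp
    out: dict[tuple[str, str], MetaProfile] = {}
    for name, exons in exon_sets.items():
        for side in ("five", "three"):
            acc = np.zeros(window, dtype=float)
            for chrom, start, end, strand in exons:
                arr = cov.get(chrom)
                if arr is None:
                    continue
                # anchor at the genomic-left edge for (+,five) and (-,three);
                # both give the window [start - flank, start + body)
                anchor_left = (side == "five") == (strand == "+")
                lo = start - flank_bp if anchor_left else end - body_bp
                seg = np.zeros(window, dtype=float)
                s0, s1 = max(lo, 0), min(lo + window, len(arr))
                if s1 > s0:
                    seg[s0 - lo : s1 - lo] = arr[s0:s1]
                if strand == "-":
                    seg = seg[::-1]
                acc += seg
            positions = np.arange(-flank_bp, body_bp) if side == "five" else np.arange(
                -body_bp, flank_bp
            )
            out[(name, side)] = MetaProfile(
                positions, acc / len(exons), side, len(exons)
            )
    return out


def binding_by_ranked_sets(
    profile: pd.DataFrame,
    ranked_genes: list[str],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Bound-gene fraction and mean exonic density over contiguous rank bins.

    ``ranked_genes`` is ordered from the strongest to the weakest signal
    (e.g. decreasing differential translation); bins split that order into
    ``n_bins`` contiguous groups.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(ranked_genes) < n_bins:
        raise ValueError("ranked list shorter than the number of bins")
    missing = set(ranked_genes) - set(profile.index)
    if missing:
        raise ValueError(f"ranked genes absent from profile: {sorted(missing)[:5]}")
    rows = []
    for b, chunk in enumerate(np.array_split(np.array(ranked_genes), n_bins)):
        sub = profile.loc[chunk]
        dens = sub["exonic_density"].to_numpy(dtype=float)
        bound = (sub["exonic_reads"] > 0).to_numpy()
        rows.append(
            {
                "bin": b + 1,
                "n_genes": len(chunk),
                "bound_fraction": bound.mean(),
                "mean_exonic_density": dens.mean(),
                "se_exonic_density": dens.std(ddof=1) / np.sqrt(len(dens))
                if len(dens) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def ranked_set_trend_test(
    profile: pd.DataFrame, ranked_genes: list[str], n_bins: int = 10
) -> float:
    """One-sided Mann-Whitney p for top-bin exonic density exceeding bottom-bin."""
    chunks = np.array_split(np.array(ranked_genes), n_bins)
    top = profile.loc[chunks[0], "exonic_density"].to_numpy(dtype=float)
    bottom = profile.loc[chunks[-1], "exonic_density"].to_numpy(dtype=float)
    return float(stats.mannwhitneyu(top, bottom, alternative="greater").pvalue)
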