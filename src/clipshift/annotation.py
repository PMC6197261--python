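"""Gene models and the genic partition.

Loads gene annotations from GTF into a collapsed per-gene model and derives
the interval partition (5'UTR / CDS / 3'UTR / intron) that every binding
statistic is computed against.  All coordinates are 0-based half-open
internally; GTF's 1-based closed convention is converted at the I/O boundary.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

Interval = tuple[int, int]

#: genic category labels, in tie-break precedence order (exon categories first)
LABELS = ("cds", "five_utr", "three_utr", "exon", "intron")
EXON_LABELS = ("cds", "five_utr", "three_utr", "exon")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def complement_within(span: Interval, intervals: list[Interval]) -> list[Interval]:
    """Intervals of ``span`` not covered by the (disjoint, sorted) intervals."""
    out = []
    cursor = span[0]
    for s, e in intervals:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]
    cds: Interval | None = None  # genomic span of the coding region

    def __post_init__(self):
        self.exons = merge_intervals(self.exons)
        if self.cds is not None and self.cds[0] >= self.cds[1]:
            raise AnnotationError(
                f"transcript {self.transcript_id}: empty CDS span {self.cds}"
            )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    collapsed_exons: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        self.collapsed_exons = merge_intervals(
            [iv for t in self.transcripts for iv in t.exons]
        )
        self.introns = complement_within(self.span, self.collapsed_exons)

    @property
    def span(self) -> Interval:
        return (self.collapsed_exons[0][0], self.collapsed_exons[-1][1])

    @property
    def cds_span(self) -> Interval | None:
        """Union span of all transcript CDS regions, or None for non-coding."""
        spans = [t.cds for t in self.transcripts if t.cds is not None]
        if not spans:
            return None
        return (min(s for s, _ in spans), max(e for _, e in spans))


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen[g.gene_id] = g.chrom
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.span[1] > size:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.span[1]} > {size})"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class GenicPartition:
    """Per-gene labeled intervals plus aggregate element lengths.

    ``intervals`` maps gene_id -> list of (start, end, label); labels within a
    gene are disjoint and tile the gene span.  ``aggregate_lengths`` sums bp
    per label over all genes; the exon aggregate is five_utr + cds + three_utr
    (+ exon for non-coding genes).
    """

    intervals: dict[str, list[tuple[int, int, str]]]
    genes: dict[str, GeneModel]

    @property
    def aggregate_lengths(self) -> dict[str, int]:
        agg = {lab: 0 for lab in LABELS}
        for ivs in self.intervals.values():
            for s, e, lab in ivs:
                agg[lab] += e - s
        return agg

    def gene_lengths(self, gene_id: str) -> dict[str, int]:
        agg = {lab: 0 for lab in LABELS}
        for s, e, lab in self.intervals[gene_id]:
            agg[lab] += e - s
        return agg

    @property
    def exon_bp(self) -> int:
        agg = self.aggregate_lengths
        return sum(agg[lab] for lab in EXON_LABELS)

    @property
    def intron_bp(self) -> int:
        return self.aggregate_lengths["intron"]


@dataclass(frozen=True)
class IntronCatalog:
    """Annotated introns as (chrom, start, end, strand) with lengths."""

    introns: frozenset[tuple[str, int, int, str]]

    @classmethod
    def from_annotation(cls, annotation: GenomeAnnotation) -> "IntronCatalog":
        items = set()
        for g in annotation.genes:
            for s, e in g.introns:
                items.add((g.chrom, s, e, g.strand))
        return cls(frozenset(items))

    @property
    def lengths(self) -> set[int]:
        return {e - s for _, s, e, _ in self.introns}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        # catalogs here are small (toy genomes); linear scan is fine
        return any(
            c == chrom and start < e and end > s for c, s, e, _ in self.introns
        )


def genic_partition(annotation: GenomeAnnotation) -> GenicPartition:
    """Label every base of every gene span by genic category.

    On the collapsed model, exonic bases 5' of the CDS span (in transcription
    direction) are five_utr, bases inside it cds, bases 3' of it three_utr;
    non-exonic gene-span bases are intron.  Genes without any CDS get the
    plain ``exon`` label and do not enter the UTR/CDS splits.
    """
    out: dict[str, list[tuple[int, int, str]]] = {}
    for g in annotation.genes:
        ivs: list[tuple[int, int, str]] = []
        cds = g.cds_span
        if cds is not None:
            exon_union = g.collapsed_exons
            covered = sum(
                max(0, min(e, cds[1]) - max(s, cds[0])) for s, e in exon_union
            )
            # the CDS span may bridge introns, but its endpoints must be exonic
            if not any(s <= cds[0] < e for s, e in exon_union) or not any(
                s < cds[1] <= e for s, e in exon_union
            ):
                raise AnnotationError(
                    f"gene {g.gene_id}: CDS span {cds} not contained in exons"
                )
            if covered == 0:
                raise AnnotationError(
                    f"gene {g.gene_id}: CDS span {cds} not contained in exons"
                )
        for s, e in g.collapsed_exons:
            if cds is None:
                ivs.append((s, e, "exon"))
                continue
            left_lab = "five_utr" if g.strand == "+" else "three_utr"
            right_lab = "three_utr" if g.strand == "+" else "five_utr"
            if e <= cds[0]:
                ivs.append((s, e, left_lab))
            elif s >= cds[1]:
                ivs.append((s, e, right_lab))
            else:
                if s < cds[0]:
                    ivs.append((s, cds[0], left_lab))
                ivs.append((max(s, cds[0]), min(e, cds[1]), "cds"))
                if e > cds[1]:
                    ivs.append((cds[1], e, right_lab))
        for s, e in g.introns:
            ivs.append((s, e, "intron"))
        out[g.gene_id] = sorted(ivs)
    return GenicPartition(out, {g.gene_id: g for g in annotation.genes})


# ---------------------------------------------------------------------------
# GTF I/O


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: bad coordinate range "
                    f"{start}-{end}"
                )


def load_annotation(
    gtf_path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> GenomeAnnotation:
    """Load a GTF into a :class:`GenomeAnnotation`.

    Exon and CDS features are grouped by transcript_id within gene_id;
    collapsed exons and introns are derived.  GTF coordinates (1-based
    closed) are converted to 0-based half-open.  ``chrom_sizes`` is optional;
    when omitted, each chromosome's size is taken as the rightmost annotated
    coordinate.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(gtf_path)
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    per_gene: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError:
                raise AnnotationError(
                    f"{ftype} feature at {feat.seqid}:{feat.start} lacks "
                    "gene_id/transcript_id attributes"
                ) from None
            entry = per_gene.setdefault(
                gene_id, {"chrom": feat.seqid, "strand": feat.strand, "tx": {}}
            )
            if entry["chrom"] != feat.seqid:
                raise AnnotationError(
                    f"duplicate gene_id {gene_id!r} on multiple chromosomes "
                    f"({entry['chrom']}, {feat.seqid})"
                )
            tx = entry["tx"].setdefault(tx_id, {"exons": [], "cds": []})
            iv = (feat.start - 1, feat.end)  # to 0-based half-open
            tx["exons" if ftype == "exon" else "cds"].append(iv)

    genes = []
    for gene_id, entry in per_gene.items():
        txs = []
        for tx_id, d in entry["tx"].items():
            cds = None
            if d["cds"]:
                cds = (min(s for s, _ in d["cds"]), max(e for _, e in d["cds"]))
            txs.append(Transcript(tx_id, d["exons"], cds))
        genes.append(GeneModel(gene_id, entry["chrom"], entry["strand"], txs))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))

    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.span[1])
    return GenomeAnnotation(genes, dict(chrom_sizes))


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene/transcript/exon/CDS features, converting to 1-based closed."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}";'
            s, e = g.span
            fh.write(
                f"{g.chrom}\tclipshift\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                ts, te = t.exons[0][0], t.exons[-1][1]
                fh.write(
                    f"{g.chrom}\tclipshift\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for es, ee in t.exons:
                    fh.write(
                        f"{g.chrom}\tclipshift\texon\t{es + 1}\t{ee}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds is not None:
                    for es, ee in t.exons:
                        cs, ce = max(es, t.cds[0]), min(ee, t.cds[1])
                        if cs < ce:
                            fh.write(
                                f"{g.chrom}\tclipshift\tCDS\t{cs + 1}\t{ce}\t.\t"
                                f"{g.strand}\t0\t{tattrs}\n"
                            )


def write_partition_bed(partition: GenicPartition, path: str | Path) -> None:
    """BED6 export of the partition (one record per labeled interval)."""
    rows = []
    for gene_id, ivs in partition.intervals.items():
        g = partition.genes[gene_id]
        for s, e, lab in ivs:
            rows.append((g.chrom, s, e, f"{gene_id}|{lab}", 0, g.strand))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")
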