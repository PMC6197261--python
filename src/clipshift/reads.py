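"""Gapped-alignment container and SAM I/O.

A read is a set of sorted, non-overlapping aligned blocks on one chromosome;
gaps between consecutive blocks are N-type alignment gaps (excised introns
for junction-spanning reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 0-based
    name: str = ""
    seq: str | None = None  # sense-strand sequence (5'->3' of the read)
    category: str | None = None  # simulation truth tag, if any

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("read must have at least one aligned block")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"blocks not sorted/non-overlapping: {self.blocks}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals of the alignment gaps between blocks."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        )

    @property
    def gap_lengths(self) -> tuple[int, ...]:
        return tuple(s2 - e1 for e1, s2 in self.gaps)

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class AlignedReadSet:
    reads: list[ReadRecord] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @classmethod
    def from_sam(cls, path: str | Path) -> "AlignedReadSet":
        """Load primary mapped alignments from SAM/BAM; N CIGAR ops become gaps."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        reads = []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            sizes = dict(zip(fh.references, fh.lengths))
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                blocks = _merge_adjacent(aln.get_blocks())
                seq = aln.query_sequence
                strand = "-" if aln.is_reverse else "+"
                if seq is not None and strand == "-":
                    seq = revcomp(seq)  # store in read-sense orientation
                tag = (
                    aln.get_tag("XC") if aln.has_tag("XC") else None
                )  # simulation truth category
                reads.append(
                    ReadRecord(
                        chrom=aln.reference_name,
                        strand=strand,
                        blocks=tuple(blocks),
                        name=aln.query_name,
                        seq=seq,
                        category=tag,
                    )
                )
        return cls(reads, sizes)

    def write_sam(self, path: str | Path) -> None:
        """Write a coordinate-sorted SAM with an @SQ header."""
        chroms = sorted(self.chrom_sizes)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": self.chrom_sizes[c]} for c in chroms],
        }
        order = sorted(
            range(len(self.reads)),
            key=lambda i: (self.reads[i].chrom, self.reads[i].start),
        )
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for i in order:
                r = self.reads[i]
                a = pysam.AlignedSegment(fh.header)
                a.query_name = r.name or f"read{i}"
                a.flag = 16 if r.strand == "-" else 0
                a.reference_id = chroms.index(r.chrom)
                a.reference_start = r.start
                a.mapping_quality = 255
                cigar = []
                prev_end = None
                for s, e in r.blocks:
                    if prev_end is not None:
                        cigar.append((3, s - prev_end))  # N
                    cigar.append((0, e - s))  # M
                    prev_end = e
                a.cigartuples = cigar
                if r.seq is not None:
                    a.query_sequence = r.seq if r.strand == "+" else revcomp(r.seq)
                if r.category is not None:
                    a.set_tag("XC", r.category)
                fh.write(a)


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge abutting blocks (pysam splits on I/D ops as well as N)."""
    out: list[list[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
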