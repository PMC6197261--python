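"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's indexed/vectorized code paths: labels
are found by scanning partition intervals base by base, and BH adjustment is
computed from its textbook definition.
"""

import numpy as np

from clipshift.annotation import LABELS, GenicPartition
from clipshift.reads import ReadRecord

_RANK = {lab: i for i, lab in enumerate(LABELS)}


def brute_force_label(read: ReadRecord, partition: GenicPartition) -> str:
    """Per-base majority label with exon-first precedence and tie-breaking."""
    genes = [
        (gene_id, g)
        for gene_id, g in partition.genes.items()
        if g.chrom == read.chrom
        and g.strand == read.strand
        and g.span[0] < read.end
        and g.span[1] > read.start
    ]
    counts: dict[str, int] = {}
    for s, e in read.blocks:
        for pos in range(s, e):
            best = None
            for gene_id, _ in genes:
                for a, b, lab in partition.intervals[gene_id]:
                    if a <= pos < b and (best is None or _RANK[lab] < _RANK[best]):
                        best = lab
            if best is not None:
                counts[best] = counts.get(best, 0) + 1
    if not counts:
        return "other"
    return min(counts, key=lambda lab: (-counts[lab], _RANK[lab]))


def brute_force_bh(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_force_partition_labels(partition: GenicPartition, gene_id: str) -> dict:
    """Per-base label map of one gene via direct interval scanning."""
    out = {}
    for s, e, lab in partition.intervals[gene_id]:
        for pos in range(s, e):
            out[pos] = lab
    return out
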