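"""k-mer counting and dinucleotide-preserving shuffle background.

Enrichment of k-mers in CLIP read sequences is scored against per-read
shuffles that preserve the dinucleotide composition (Altschul-Erickson
Eulerian-path shuffling), the standard background for crosslink read motif
analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def kmer_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = idx * 4 + _BASE_TO_INT[b]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def count_kmers(seqs: list[str], k: int) -> np.ndarray:
    """Counts over all 4^k k-mers, pooled across sequences.

    Sequences shorter than k (or with non-ACGT characters, which are
    skipped) contribute nothing.
    """
    counts = np.zeros(4**k, dtype=np.int64)
    mask = 4 ** (k - 1)
    for seq in seqs:
        code = 0
        run = 0  # valid-base run length
        for ch in seq:
            b = _BASE_TO_INT.get(ch)
            if b is None:
                run = 0
                code = 0
                continue
            code = (code % mask) * 4 + b
            run += 1
            if run >= k:
                counts[code] += 1
    return counts


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Eulerian-trail method).

    The sequence is a trail in the graph whose vertices are bases and whose
    edges are its dinucleotides; a uniform random Eulerian trail with the
    same start yields a shuffle with identical dinucleotide composition.
    """
    if len(seq) < 3:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    vertices = list(succ)
    sink = seq[-1]
    if len(vertices) == 1 and (sink not in succ or len(set(succ[vertices[0]])) <= 1):
        return seq  # homopolymer or two-letter alternation: unique trail

    # choose random "last edges" forming an arborescence toward the sink
    for _ in range(200):
        last = {}
        for v in vertices:
            if v == sink:
                continue
            last[v] = succ[v][rng.integers(0, len(succ[v]))]
        # check every vertex reaches the sink through last-edges
        ok = True
        for v in last:
            seen = {v}
            cur = v
            while cur != sink:
                cur = last.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pathological composition; give up and return the original
        return seq

    pools: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in last:
            edges.remove(last[v])
        rng.shuffle(edges)
        if v in last:
            edges.append(last[v])
        pools[v] = edges
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def kmer_zscores(
    observed: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """z and two-sided p per k-mer from a rounds x 4^k background matrix.

    The background mean is scaled so its total matches the observed total
    (dinucleotide shuffles keep per-read k-mer counts, so the scale factor
    is 1 unless sequences were dropped).  p-values use a t reference with
    n_rounds - 1 degrees of freedom to account for the estimated sd.
    """
    n_rounds = background.shape[0]
    mean = background.mean(axis=0)
    total_obs, total_bg = observed.sum(), mean.sum()
    if total_bg > 0:
        mean = mean * (total_obs / total_bg)
    sd = background.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / n_rounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mean) / sd
    z = np.where(sd > 0, z, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=n_rounds - 1)
    return z, np.minimum(p, 1.0)


def kmer_enrichment_table(
    seqs: list[str], k: int = 6, n_shuffles: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Ranked k-mer enrichment of sequences vs dinucleotide-shuffle background.

    Returns a frame sorted by descending z with columns kmer, observed,
    expected, log2_enrichment, z, pvalue, padj.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    if not any(len(s) >= k for s in seqs):
        raise ValueError(f"k={k} exceeds every read length")
    rng = np.random.default_rng(seed)
    observed = count_kmers(seqs, k)
    background = np.zeros((n_shuffles, 4**k), dtype=np.int64)
    for i in range(n_shuffles):
        background[i] = count_kmers(
            [dinucleotide_shuffle(s, rng) for s in seqs], k
        )
    z, p = kmer_zscores(observed, background)
    mean = background.mean(axis=0)
    scale = observed.sum() / mean.sum() if mean.sum() > 0 else 1.0
    expected = mean * scale
    with np.errstate(divide="ignore"):
        enr = np.log2((observed + 0.5) / (expected + 0.5))
    df = pd.DataFrame(
        {
            "kmer": [index_to_kmer(i, k) for i in range(4**k)],
            "observed": observed,
            "expected": expected,
            "log2_enrichment": enr,
            "z": z,
            "pvalue": p,
            "padj": benjamini_hochberg(p),
        }
    )
    return df.sort_values("z", ascending=False).reset_index(drop=True)
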