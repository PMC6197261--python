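"""Translation efficiency and differential-translation candidate selection.

Translation efficiency (TE) is the normalized ribosome-footprint signal
divided by the normalized mRNA signal per gene.  Candidate selection picks
genes whose translation responds specifically to the cytoplasmic mutant:
stable in the overexpression control comparison (WT vs control inside an
open log2 fold-change window), strongly shifted in the mutant comparison
(|log2FC| above a strict threshold), ranked by p-value, keeping the top
fraction of the tested gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the differential-translation candidate filter."""

    stability_window: float = 0.5  # open interval (-w, w) on the WT comparison
    magnitude_threshold: float = 0.5  # strict |log2FC| > t on the mutant
    top_q: float = 0.02  # fraction of the tested universe to keep
    alpha: float = 0.05  # significance level for the expression-change flag

    def __post_init__(self):
        if self.stability_window <= 0 or self.magnitude_threshold <= 0:
            raise ValueError("window and threshold must be positive")
        if not 0 < self.top_q < 1:
            raise ValueError("top_q must be in (0, 1)")


@dataclass
class TECandidateSet:
    """Ordered differential-translation candidates from a tested universe."""

    candidates: pd.DataFrame  # ordered by ascending mutant p-value
    universe_size: int
    n_passing_filters: int
    params: SelectionParams

    @property
    def gene_ids(self) -> list[str]:
        return list(self.candidates.index)

    @property
    def n_expression_changed(self) -> int:
        if "expression_changed" not in self.candidates:
            return 0
        return int(self.candidates["expression_changed"].sum())

    @property
    def fraction_expression_changed(self) -> float:
        n = len(self.candidates)
        return self.n_expression_changed / n if n else float("nan")


def translation_efficiency(
    rna_norm: pd.DataFrame | pd.Series, ribo_norm: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Per-gene TE = mean normalized ribo / mean normalized rna.

    Inputs are normalized count frames (samples as columns) or precomputed
    per-gene means for one condition.  Genes with zero rna mean are
    excluded.  Returns a frame with rna_mean, ribo_mean, te and log2_te.
    """
    rna_mean = rna_norm.mean(axis=1) if isinstance(rna_norm, pd.DataFrame) else rna_norm
    ribo_mean = (
        ribo_norm.mean(axis=1) if isinstance(ribo_norm, pd.DataFrame) else ribo_norm
    )
    common = rna_mean.index.intersection(ribo_mean.index)
    if len(common) == 0:
        raise ValueError("no overlapping genes between rna and ribo inputs")
    rna_mean, ribo_mean = rna_mean.loc[common], ribo_mean.loc[common]
    keep = rna_mean > 0
    te = ribo_mean[keep] / rna_mean[keep]
    with np.errstate(divide="ignore"):
        log2_te = np.log2(te)
    return pd.DataFrame(
        {
            "rna_mean": rna_mean[keep],
            "ribo_mean": ribo_mean[keep],
            "te": te,
            "log2_te": log2_te,
        }
    )


def top_te_quantile(te: pd.DataFrame, q: float = 0.2) -> pd.Index:
    """Gene ids in the top ``q`` quantile of TE (the highly translated set)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    cutoff = te["te"].quantile(1 - q)
    return te.index[te["te"] >= cutoff]


def select_translation_candidates(
    res_wt: pd.DataFrame,
    res_mut: pd.DataFrame,
    params: SelectionParams | None = None,
    expression_result: pd.DataFrame | None = None,
) -> TECandidateSet:
    """Windowed top-q% differential-translation candidate selection.

    ``res_wt`` and ``res_mut`` are differential results (vs the same
    control) of the ribosome-profiling assay on the same gene universe.
    Genes pass when the WT log2FC lies strictly inside the open stability
    window and the mutant |log2FC| strictly exceeds the magnitude
    threshold; passers are ranked by ascending mutant p-value and the first
    floor(top_q * N) kept, N being the universe size.  When an RNA-level
    ``expression_result`` is supplied, candidates significant there at
    ``params.alpha`` are flagged as expression-changed.
    """
    params = params or SelectionParams()
    if set(res_wt.index) != set(res_mut.index):
        raise ValueError("WT and mutant results are not on the same universe")
    res_wt = res_wt.sort_index()
    res_mut = res_mut.loc[res_wt.index]
    n_universe = len(res_mut)

    w, t = params.stability_window, params.magnitude_threshold
    stable = res_wt["log2_fold_change"].abs() < w  # open interval
    shifted = res_mut["log2_fold_change"].abs() > t  # strict inequality
    passing = res_mut[stable & shifted]
    if passing.empty:
        logger.warning("no genes pass the selection filters; empty candidate set")
    n_keep = int(np.floor(params.top_q * n_universe))
    ranked = passing.sort_values("pvalue", kind="mergesort")
    candidates = ranked.head(n_keep).copy()
    candidates["wt_log2_fold_change"] = res_wt.loc[
        candidates.index, "log2_fold_change"
    ]
    if expression_result is not None:
        flag = expression_result["pvalue"].reindex(candidates.index) < params.alpha
        candidates["expression_changed"] = flag.fillna(False).astype(bool)
    return TECandidateSet(candidates, n_universe, int(passing.shape[0]), params)
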