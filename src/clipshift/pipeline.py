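"""End-to-end orchestration and cross-layer statistics.

``run_pipeline`` drives a fully synthetic experiment: toy genome, CLIP
libraries under the nuclear and cytoplasmic binder regimes, NB count
matrices with planted effects, then every downstream statistic, persisting
stage TSVs and a deterministic JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import binding as bd
from . import diffexp as dx
from . import simulate as sim
from . import translation as tr
from .annotation import IntronCatalog, genic_partition, load_annotation
from .reads import AlignedReadSet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class RunConfig:
    """Parameters of an end-to-end synthetic run."""

    out_dir: str = "clipshift_run"
    seed: int = 0
    # synthetic reference + CLIP
    n_genes: int = 50
    n_clip_reads: int = 200_000
    read_len: int = 50
    # count simulation
    n_count_genes: int = 2000
    n_reps: int = 3
    n_binding_reads: int = 2_000_000
    # analysis parameters
    junction_window: tuple[int, int] = (1000, 3000)
    alpha: float = 0.05
    selection: tr.SelectionParams = field(default_factory=tr.SelectionParams)
    n_bins: int = 10
    flank_bp: int = 500
    kmer_k: int = 6
    n_shuffles: int = 20

    regimes: dict[str, str] = field(
        default_factory=lambda: {
            "WT": "nuclear_WT",
            "R495X": "cytoplasmic_R495X",
        }
    )


def binding_vs_differential(
    profile: pd.DataFrame, result: pd.DataFrame, compartment: str = "exon"
) -> dict[str, float]:
    """Pearson correlation of differential expression vs log binding density.

    ``compartment`` selects exonic or intronic binding; genes without
    binding in that compartment are excluded.  Returns R, R^2 and n.
    """
    if compartment not in ("exon", "intron"):
        raise ValueError("compartment must be 'exon' or 'intron'")
    col_reads = f"{compartment}ic_reads"
    col_dens = f"{compartment}ic_density"
    common = profile.index.intersection(result.index)
    sub = profile.loc[common]
    bound = sub[sub[col_reads] > 0]
    if len(bound) < 10:
        raise bd.InsufficientDataError(
            f"fewer than 10 genes with {compartment}ic binding"
        )
    lfc = result.loc[bound.index, "log2_fold_change"]
    r, _ = stats.pearsonr(lfc, np.log10(bound[col_dens] + 1))
    return {"r": float(r), "r_squared": float(r**2), "n": int(len(bound))}


def simulate_gene_binding_profile(
    expression: pd.Series,
    regime: sim.ClipRegime,
    n_reads: int = 2_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Count-level per-gene binding profile under a regime.

    Total per-gene reads follow the expression-coupled mixture; each gene's
    reads split between exonic and intronic compartments with the regime's
    expected exon probability; per-gene exon/intron lengths are drawn from
    the toy-genome geometry so densities are on the same scale as the
    read-level pipeline.
    """
    rng = np.random.default_rng(seed)
    counts = sim.simulate_binding_counts(expression, regime, n_reads, seed=seed)
    genic = regime.w_pre + regime.w_mature
    p_exon = (
        (regime.w_mature + regime.w_pre * sim.EXON_SHARE) / genic if genic else 0.0
    )
    n = len(counts)
    n_introns = rng.integers(2, 8, n)
    intron_kb = np.empty(n)
    for i, k in enumerate(n_introns):
        lens = []
        while len(lens) < k:
            ln = sim.INTRON_MIN + rng.exponential(sim.INTRON_EXP_SCALE)
            if ln <= sim.INTRON_MAX:
                lens.append(ln)
        intron_kb[i] = sum(lens) / 1000.0
    exon_kb = intron_kb * sim.EXON_SHARE / (1 - sim.EXON_SHARE)
    exonic = rng.binomial(counts.to_numpy(), p_exon)
    intronic = counts.to_numpy() - exonic
    return pd.DataFrame(
        {
            "exonic_reads": exonic,
            "intronic_reads": intronic,
            "exonic_density": exonic / (exon_kb * 1000) * 1000,
            "intronic_density": intronic / (intron_kb * 1000) * 1000,
        },
        index=counts.index,
    )


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {"seed": config.seed, "alpha": config.alpha}}
    rng_master = np.random.default_rng(config.seed)
    seeds = {k: int(rng_master.integers(2**31)) for k in
             ("reference", "clip_WT", "clip_R495X", "counts", "binding", "exons")}

    # --- stage: simulate -------------------------------------------------
    stage = "simulate"
    try:
        ref = sim.make_toy_reference(config.n_genes, seeds["reference"], out_dir=out)
        sam_paths = {}
        for cond, regime_name in config.regimes.items():
            regime = sim.PRESETS[regime_name]
            sam = out / f"clip_{cond}.sam"
            sim.simulate_clip_reads(
                ref, regime, config.n_clip_reads, config.read_len,
                seed=seeds[f"clip_{cond}"], sam_path=sam,
            )
            sim.write_regime_config(regime, out / f"regime_{cond}.txt")
            sam_paths[cond] = sam

        n = config.n_count_genes
        rng = np.random.default_rng(seeds["counts"])
        effects: dict[tuple[str, str], np.ndarray] = {}
        de_wt = np.zeros(n)
        de_mut = np.zeros(n)
        idx = rng.permutation(n)
        # modest expression effects (below 1.5-fold), partly shared between
        # conditions with congruent signs, plus condition-specific sets
        k = max(20, n // 20)
        n_shared = k // 3
        shared = idx[:n_shared]
        signs = rng.choice([-0.5, 0.5], n_shared)
        de_wt[shared] = signs
        de_mut[shared] = signs
        de_wt[idx[n_shared : n_shared + k]] = rng.choice([-0.5, 0.5], k)
        de_mut[idx[n_shared + k : n_shared + 2 * k]] = rng.choice([-0.5, 0.5], k)
        # translation-only effects on a set well below the top-q slot budget
        dt = np.zeros(n)
        dt_idx = idx[n_shared + 2 * k : n_shared + 2 * k + max(10, n // 100)]
        dt[dt_idx] = rng.choice([-1.0, 1.0], len(dt_idx))
        effects[("WT", "rna")] = de_wt
        effects[("WT", "ribo")] = de_wt.copy()
        effects[("R495X", "rna")] = de_mut
        effects[("R495X", "ribo")] = de_mut + dt
        design = sim.CountSimulationDesign(
            n_genes=n, n_reps=config.n_reps, effects=effects
        )
        matrix, truth = sim.simulate_counts(design, seed=seeds["counts"])
        matrix.to_tsv(out / "counts.tsv", out / "samples.tsv")
        truth["size_factors"].to_csv(out / "true_size_factors.tsv", sep="\t")
        report["simulate"] = {
            "n_genes": config.n_genes,
            "n_clip_reads": config.n_clip_reads,
            "n_count_genes": n,
            "n_planted_dt": int(len(dt_idx)),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: bind ------------------------------------------------------
    stage = "bind"
    try:
        annotation = load_annotation(out / "genes.gtf", ref.annotation.chrom_sizes)
        partition = genic_partition(annotation)
        introns = IntronCatalog.from_annotation(annotation)
        report["binding"] = {}
        for cond, sam in sam_paths.items():
            if not Path(sam).exists():
                raise FileNotFoundError(sam)
            read_set = AlignedReadSet.from_sam(sam)
            asn = bd.assign_reads(read_set, partition)
            dist = bd.genic_distribution(asn.tallies)
            dens = bd.length_normalized_density(asn.tallies, partition)
            spec = bd.gap_spectrum(read_set, introns, config.junction_window)
            profile = bd.gene_binding_profile(asn, partition)
            profile.to_csv(out / f"binding_profile_{cond}.tsv", sep="\t")
            pd.Series(dist.fractions).to_csv(
                out / f"genic_distribution_{cond}.tsv", sep="\t",
                header=["fraction"],
            )
            corr, n_used = bd.binding_expression_correlation(
                profile, ref.expression
            )
            report["binding"][cond] = {
                "intron_fraction": dist.intron_fraction,
                "exon_fraction": dist.exon_fraction,
                "exon_density_share": dens.exon_share,
                "junction_fraction": spec.junction_fraction,
                "binding_expression_r": corr,
                "n_genes_correlated": n_used,
            }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: diffexp ---------------------------------------------------
    stage = "diffexp"
    try:
        res_rna = {}
        for cond in ("WT", "R495X"):
            res_rna[cond] = dx.differential_test(matrix, "control", cond, "rna")
            res_rna[cond].to_csv(out / f"de_rna_{cond}.tsv", sep="\t")
        ov = dx.overlap_analysis(res_rna["WT"], res_rna["R495X"], config.alpha)
        bins = {
            cond: dx.foldchange_bins(res_rna[cond], alpha=config.alpha)
            for cond in res_rna
        }
        report["diffexp"] = {
            "n_significant": {
                c: int((r["pvalue"] < config.alpha).sum())
                for c, r in res_rna.items()
            },
            "overlap": ov,
            "frac_below_1p5_fold": {
                c: float(b.loc[b["threshold"] == 1.5, "frac_below"].iloc[0])
                for c, b in bins.items()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: translate -------------------------------------------------
    stage = "translate"
    try:
        res_ribo = {}
        for cond in ("WT", "R495X"):
            res_ribo[cond] = dx.differential_test(matrix, "control", cond, "ribo")
            res_ribo[cond].to_csv(out / f"dt_ribo_{cond}.tsv", sep="\t")
        rna_ctrl = dx.normalized_counts(matrix.select(condition="control", assay="rna"))
        ribo_ctrl = dx.normalized_counts(
            matrix.select(condition="control", assay="ribo")
        )
        te = tr.translation_efficiency(rna_ctrl, ribo_ctrl)
        te.to_csv(out / "translation_efficiency_control.tsv", sep="\t")
        cand = tr.select_translation_candidates(
            res_ribo["WT"], res_ribo["R495X"], config.selection,
            expression_result=res_rna["R495X"],
        )
        cand.candidates.to_csv(out / "dt_candidates.tsv", sep="\t")
        truth_dt = set(np.array(matrix.counts.index)[dt != 0])
        recall = (
            len(truth_dt & set(cand.gene_ids)) / len(truth_dt) if truth_dt else None
        )
        report["translate"] = {
            "n_candidates": len(cand.candidates),
            "universe_size": cand.universe_size,
            "n_passing_filters": cand.n_passing_filters,
            "n_expression_changed": cand.n_expression_changed,
            "fraction_expression_changed": cand.fraction_expression_changed,
            "planted_dt_recall": recall,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: integrate ---------------------------------------------------
    stage = "integrate"
    try:
        baseline = truth["baseline_mean"]
        report["integrate"] = {}
        for cond in ("WT", "R495X"):
            regime = sim.PRESETS[config.regimes[cond]]
            prof = simulate_gene_binding_profile(
                baseline, regime, config.n_binding_reads, seed=seeds["binding"]
            )
            prof.to_csv(out / f"gene_binding_{cond}.tsv", sep="\t")
            entry = {}
            for comp in ("exon", "intron"):
                entry[comp] = binding_vs_differential(prof, res_rna[cond], comp)
            if cond == "R495X":
                ranked = res_ribo[cond].sort_values("pvalue").index.tolist()
                ranked_bins = bd.binding_by_ranked_sets(prof, ranked, config.n_bins)
                ranked_bins.to_csv(out / "ranked_set_binding.tsv", sep="\t")
                entry["ranked_top_bin_density"] = float(
                    ranked_bins["mean_exonic_density"].iloc[0]
                )
                entry["ranked_bottom_bin_density"] = float(
                    ranked_bins["mean_exonic_density"].iloc[-1]
                )
            report["integrate"][cond] = entry
        report["integrate"]["junction_fractions"] = {
            cond: report["binding"][cond]["junction_fraction"]
            for cond in config.regimes
        }
        report["integrate"]["mutant_junction_higher"] = bool(
            report["binding"]["R495X"]["junction_fraction"]
            > report["binding"]["WT"]["junction_fraction"]
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
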