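import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipshift.diffexp import (
    CountMatrix,
    CountMatrixError,
    benjamini_hochberg,
    differential_exon_usage,
    differential_test,
    foldchange_bins,
    normalized_counts,
    overlap_analysis,
    size_factors,
)
from clipshift.simulate import (
    CountSimulationDesign,
    simulate_counts,
    simulate_exon_counts,
)
from oracle_utils import brute_force_bh


def make_matrix(counts: dict, conditions: dict, assay: str = "rna") -> CountMatrix:
    df = pd.DataFrame(counts)
    samples = pd.DataFrame(
        {
            "condition": pd.Series(conditions),
            "assay": assay,
            "replicate": 1,
        }
    )
    return CountMatrix(df, samples.loc[df.columns])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert size_factors(df).tolist() == [1.0, 1.0]

    def test_doubled_column_gives_double_factor(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_recovers_simulated_factors_within_five_percent(self):
        design = CountSimulationDesign(
            n_genes=2000, conditions=("control", "WT"), assays=("rna",)
        )
        matrix, truth = simulate_counts(design, seed=5)
        est = size_factors(matrix.counts)
        est = est / np.exp(np.log(est).mean())
        tru = truth["size_factors"]
        tru = tru / np.exp(np.log(tru).mean())
        assert (est / tru - 1).abs().max() < 0.05

    def test_matches_reference_implementation(self):
        """Median-of-ratios factors equal the packaged reference fit."""
        from pydeseq2.dds import DeseqDataSet

        design = CountSimulationDesign(
            n_genes=300, conditions=("control", "WT"), assays=("rna",)
        )
        matrix, _ = simulate_counts(design, seed=9)
        meta = pd.DataFrame({"condition": matrix.samples["condition"]})
        dds = DeseqDataSet(
            counts=matrix.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        theirs = np.asarray(dds.obs["size_factors"])
        theirs = theirs / np.exp(np.log(theirs).mean())  # same anchoring
        ours = size_factors(matrix.counts).to_numpy()
        assert np.allclose(ours, theirs, rtol=1e-6)

    def test_no_common_nonzero_gene_rejected(self):
        df = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        with pytest.raises(CountMatrixError, match="nonzero"):
            size_factors(df)

    def test_normalization_idempotent(self):
        design = CountSimulationDesign(
            n_genes=500, conditions=("control", "WT"), assays=("rna",)
        )
        matrix, _ = simulate_counts(design, seed=11)
        norm = matrix.counts / size_factors(matrix.counts)
        again = size_factors(norm)
        assert np.allclose(again.to_numpy(), 1.0, atol=1e-6)


class TestBenjaminiHochberg:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=100,
        )
    )
    def test_equals_brute_force(self, pvals):
        assert np.allclose(benjamini_hochberg(pvals), brute_force_bh(pvals))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        assert (benjamini_hochberg(p) >= p - 1e-12).all()


class TestCountMatrix:
    def test_mismatched_sample_sheet_rejected(self):
        df = pd.DataFrame({"a": [1], "b": [2]})
        samples = pd.DataFrame(
            {"condition": ["x"], "assay": ["rna"]}, index=["a"]
        )
        with pytest.raises(CountMatrixError, match="sample sheet"):
            CountMatrix(df, samples)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"a": [-1]})
        samples = pd.DataFrame(
            {"condition": ["x"], "assay": ["rna"]}, index=["a"]
        )
        with pytest.raises(CountMatrixError, match="negative"):
            CountMatrix(df, samples)

    def test_tsv_round_trip(self, tmp_path):
        design = CountSimulationDesign(n_genes=20)
        matrix, _ = simulate_counts(design, seed=1)
        matrix.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, matrix.counts)


class TestDifferentialTest:
    def test_flat_genes_have_zero_lfc_and_p_near_one(self):
        # identical counts in every sample: no signal, unit size factors
        levels = [100, 20, 350, 57]
        counts = {s: levels for s in ("c1", "c2", "c3", "w1", "w2", "w3")}
        conditions = {f"c{i}": "control" for i in (1, 2, 3)}
        conditions |= {f"w{i}": "WT" for i in (1, 2, 3)}
        matrix = make_matrix(counts, conditions)
        res = differential_test(matrix, "control", "WT", "rna")
        assert np.allclose(res["log2_fold_change"], 0.0, atol=1e-9)
        assert (res["pvalue"] > 0.99).all()

    def test_all_zero_genes_excluded(self):
        design = CountSimulationDesign(
            n_genes=100, conditions=("control", "WT"), assays=("rna",),
            baseline_meanlog10=0.1, baseline_sdlog10=0.8,
        )
        matrix, _ = simulate_counts(design, seed=13)
        matrix.counts.iloc[:5] = 0
        res = differential_test(matrix, "control", "WT", "rna")
        assert set(matrix.counts.index[:5]).isdisjoint(res.index)

    def test_missing_assay_rejected(self):
        design = CountSimulationDesign(
            n_genes=20, conditions=("control", "WT"), assays=("rna",)
        )
        matrix, _ = simulate_counts(design, seed=1)
        with pytest.raises(CountMatrixError, match="replicates"):
            differential_test(matrix, "control", "WT", "ribo")

    def test_single_replicate_rejected(self):
        counts = {"c1": [5], "w1": [9], "w2": [11]}
        conditions = {"c1": "control", "w1": "WT", "w2": "WT"}
        matrix = make_matrix(counts, conditions)
        with pytest.raises(CountMatrixError, match="replicates"):
            differential_test(matrix, "control", "WT", "rna")


class TestOverlap:
    @staticmethod
    def _res(lfc, p, idx=None):
        idx = idx or [f"g{i}" for i in range(len(lfc))]
        return pd.DataFrame(
            {"log2_fold_change": lfc, "pvalue": p}, index=idx
        )

    def test_identical_results_all_shared(self):
        res = self._res([1.0, -2.0, 0.1], [0.01, 0.001, 0.9])
        out = overlap_analysis(res, res)
        assert out["both_up"] == 1 and out["both_down"] == 1
        assert out["a_only_up"] == out["b_only_up"] == 0
        assert out["non_congruent"] == 0

    def test_disjoint_significant_sets(self):
        a = self._res([1.0, 0.5], [0.01, 0.5])
        b = self._res([1.0, 0.5], [0.5, 0.01])
        out = overlap_analysis(a, b)
        assert out["both_up"] == out["both_down"] == 0
        assert out["a_only_up"] == 1 and out["b_only_up"] == 1

    def test_opposite_signs_non_congruent(self):
        a = self._res([1.0], [0.01])
        b = self._res([-1.0], [0.01])
        assert overlap_analysis(a, b)["non_congruent"] == 1

    def test_universe_mismatch_rejected(self):
        a = self._res([1.0], [0.01], idx=["g1"])
        b = self._res([1.0], [0.01], idx=["g2"])
        with pytest.raises(ValueError, match="universe"):
            overlap_analysis(a, b)

    def test_planted_overlap_recovered(self):
        """Shared and condition-specific planted DE genes partition correctly."""
        n = 3000
        shared = np.arange(100)
        wt_only = np.arange(100, 150)
        eff_wt = np.zeros(n)
        eff_mut = np.zeros(n)
        eff_wt[shared] = 1.0
        eff_mut[shared] = 1.0
        eff_wt[wt_only] = 1.0
        design = CountSimulationDesign(
            n_genes=n,
            baseline_meanlog10=np.log10(300),
            baseline_sdlog10=0.3,
            dispersion=0.02,
            effects={("WT", "rna"): eff_wt, ("R495X", "rna"): eff_mut},
        )
        matrix, _ = simulate_counts(design, seed=17)
        res_wt = differential_test(matrix, "control", "WT", "rna")
        res_mut = differential_test(matrix, "control", "R495X", "rna")
        # a strict level keeps chance hits from diluting the planted structure
        out = overlap_analysis(res_wt, res_mut, alpha=0.001)
        assert out["both_up"] == pytest.approx(100, abs=15)
        assert out["a_only_up"] == pytest.approx(50, abs=15)
        assert out["non_congruent"] <= 2


class TestFoldchangeBins:
    def test_boundary_rules(self):
        res = pd.DataFrame(
            {
                "log2_fold_change": [0.5, 1.0, -1.2],
                "pvalue": [0.01, 0.01, 0.01],
            }
        )
        bins = foldchange_bins(res)
        b15 = bins[bins["threshold"] == 1.5].iloc[0]
        b20 = bins[bins["threshold"] == 2.0].iloc[0]
        assert b15["n_below"] == 1  # 2^0.5 = 1.41 < 1.5
        assert b20["n_at_or_above"] == 2  # 2.0 and 2.3, closed boundary
        assert b15["n_significant"] == 3

    def test_small_planted_effects_mostly_below_threshold(self):
        n = 3000
        eff = np.zeros(n)
        eff[:600] = np.resize([0.35, -0.35], 600)
        design = CountSimulationDesign(
            n_genes=n,
            conditions=("control", "WT"),
            assays=("rna",),
            baseline_meanlog10=np.log10(400),
            baseline_sdlog10=0.3,
            dispersion=0.01,
            effects={("WT", "rna"): eff},
        )
        matrix, _ = simulate_counts(design, seed=19)
        res = differential_test(matrix, "control", "WT", "rna")
        bins = foldchange_bins(res)
        assert bins[bins["threshold"] == 1.5].iloc[0]["frac_below"] > 0.85

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            foldchange_bins(pd.DataFrame())


class TestExonUsage:
    def test_planted_exon_shift_detected(self):
        design = CountSimulationDesign(
            n_genes=300,
            conditions=("control", "R495X"),
            assays=("rna",),
            baseline_meanlog10=np.log10(1500),
            baseline_sdlog10=0.2,
            dispersion=0.01,
        )
        matrix, _ = simulate_counts(design, seed=23)
        target = matrix.counts.index[0]
        exon_matrix, parents = simulate_exon_counts(
            matrix, n_exons=5,
            effects={("R495X", target, 0): 1.0},
            seed=23,
        )
        res = differential_exon_usage(
            exon_matrix, parents, "control", "R495X",
            gene_size_factors=size_factors(matrix.counts),
        )
        assert res.loc[f"{target}:E01", "padj"] < 0.05

    def test_proportional_exons_mostly_null(self):
        design = CountSimulationDesign(
            n_genes=400,
            conditions=("control", "R495X"),
            assays=("rna",),
            baseline_meanlog10=np.log10(800),
        )
        matrix, _ = simulate_counts(design, seed=29)
        exon_matrix, parents = simulate_exon_counts(matrix, n_exons=4, seed=29)
        res = differential_exon_usage(
            exon_matrix, parents, "control", "R495X",
            gene_size_factors=size_factors(matrix.counts),
        )
        assert (res["pvalue"] < 0.05).mean() < 0.1

    def test_orphan_exon_rejected(self):
        design = CountSimulationDesign(
            n_genes=20, conditions=("control", "WT"), assays=("rna",)
        )
        matrix, _ = simulate_counts(design, seed=1)
        exon_matrix, parents = simulate_exon_counts(matrix, n_exons=2, seed=1)
        with pytest.raises(ValueError, match="parent"):
            differential_exon_usage(
                exon_matrix, parents.iloc[:-1], "control", "WT"
            )

    def test_empty_matrix_gives_empty_result(self):
        samples = pd.DataFrame(
            {
                "condition": ["control", "control", "WT", "WT"],
                "assay": "rna",
                "replicate": [1, 2, 1, 2],
            },
            index=["c1", "c2", "w1", "w2"],
        )
        empty = CountMatrix(
            pd.DataFrame(columns=samples.index, dtype=int), samples
        )
        res = differential_exon_usage(empty, pd.Series(dtype=object), "control", "WT")
        assert res.empty


def test_normalized_counts_scale_matches_factors():
    design = CountSimulationDesign(
        n_genes=100, conditions=("control", "WT"), assays=("rna",)
    )
    matrix, _ = simulate_counts(design, seed=3)
    norm = normalized_counts(matrix)
    sf = size_factors(matrix.counts)
    pd.testing.assert_frame_equal(norm, matrix.counts / sf)
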