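import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from secretomapper import stats
from secretomapper.types import IntensityTable, ParameterSet, Sample, SampleDesign

from conftest import make_design, make_table

DATA = Path(__file__).parent / "data"


def two_group_table(a, b, group_names=("A", "B"), scale="log2"):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    design = SampleDesign(
        [Sample(f"{group_names[0]}_{i+1}", group_names[0], i + 1)
         for i in range(a.shape[1])]
        + [Sample(f"{group_names[1]}_{i+1}", group_names[1], i + 1)
           for i in range(b.shape[1])]
    )
    return make_table(np.hstack([a, b]), design, scale=scale)


class TestPearson:
    def test_diagonal_and_affine_pair(self, design_2x6):
        rng = np.random.default_rng(0)
        values = rng.normal(25, 2, size=(50, 12))
        values[:, 1] = 3.0 * values[:, 0] + 2.0  # affine transform of col 0
        table = make_table(values, design_2x6, scale="log2")
        corr = stats.pearson_matrix(table)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_matches_direct_covariance_formula(self, design_2x6):
        rng = np.random.default_rng(1)
        values = rng.normal(25, 2, size=(5, 12))
        table = make_table(values, design_2x6, scale="log2")
        corr = stats.pearson_matrix(table)
        x, y = values[:, 3], values[:, 7]
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert corr.iloc[3, 7] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_values_is_missing(self, design_2x6):
        values = np.full((5, 12), 25.0)
        values[2:, 0] = np.nan
        values[:3, 1] = np.nan  # cols 0,1 share 0 proteins
        table = make_table(values, design_2x6, scale="log2")
        corr = stats.pearson_matrix(table)
        assert np.isnan(corr.iloc[0, 1])


class TestModeratedDA:
    def test_flat_protein_scores_zero(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.5, size=(20, 6))
        a = 25.0 + noise[:, :3]
        b = np.hstack([a[:, :1], a[:, 1:]])  # identical group values
        table = two_group_table(a, a)
        result = stats.moderated_pairwise_da(table, "A", "B")
        assert np.allclose(result["log2_fold_change"], 0)
        assert np.allclose(result["t_stat"], 0)
        assert np.allclose(result["p_value"], 1)
        assert not result["significant"].any()

    def test_single_protein_falls_back_to_classical_t(self):
        a = np.array([[25.1, 24.8, 25.6]])
        b = np.array([[22.3, 23.0, 22.5]])
        table = two_group_table(a, b)
        result = stats.moderated_pairwise_da(table, "A", "B")
        t_ref, p_ref = sps.ttest_ind(a[0], b[0], equal_var=True)
        assert result["t_stat"].iloc[0] == pytest.approx(t_ref, abs=1e-9)
        assert result["p_value"].iloc[0] == pytest.approx(p_ref, abs=1e-9)
        assert result.attrs["prior_df"] == 0

    @pytest.mark.parametrize(
        "fixture,reference,n_a",
        [("limma_fixture.tsv", "limma_reference.tsv", 4),
         ("limma_fixture2.tsv", "limma_reference2.tsv", 3)],
        ids=["infinite_prior", "finite_prior"],
    )
    def test_matches_limma_reference(self, fixture, reference, n_a):
        """Frozen outputs of Bioconductor limma's eBayes on the same data."""
        df = pd.read_csv(DATA / fixture, sep="\t", index_col=0)
        a = df.iloc[:, :n_a].to_numpy()
        b = df.iloc[:, n_a:].to_numpy()
        table = two_group_table(a, b)
        table.data.index = df.index
        table.detected.index = df.index
        result = stats.moderated_pairwise_da(table, "A", "B")
        ref = pd.read_csv(DATA / reference, sep="\t", index_col=0)
        assert np.abs(result["t_stat"] - ref["t"]).max() < 1e-9
        assert np.abs(result["p_value"] - ref["p"]).max() < 1e-9

    def test_prior_df_interpolates_monotonically(self):
        # as the prior df grows, each variance moves monotonically toward
        # the prior, so |t| changes monotonically protein by protein
        rng = np.random.default_rng(3)
        a = rng.normal(25, 1, size=(40, 6)) + 1.0
        b = rng.normal(25, 1, size=(40, 6))
        table = two_group_table(a, b)
        grid = [0.0, 1.0, 10.0, 100.0, 1e6]
        results = [
            stats.moderated_pairwise_da(table, "A", "B", prior_df=d0)
            for d0 in grid
        ]
        t = np.vstack([r["t_stat"].to_numpy() for r in results])
        diffs = np.diff(t, axis=0)
        # per protein, all steps share one sign (monotone interpolation)
        sign_consistent = (diffs >= -1e-12).all(axis=0) | (diffs <= 1e-12).all(axis=0)
        assert sign_consistent.all()

    def test_significance_requires_both_p_and_fold(self):
        rng = np.random.default_rng(4)
        n = 50
        a = rng.normal(25, 0.2, size=(n, 6))
        b = rng.normal(25, 0.2, size=(n, 6))
        a[0] += 1.0   # strong p, fold below 2
        a[1] += 3.0   # strong p, fold above 2
        table = two_group_table(a, b)
        result = stats.moderated_pairwise_da(
            table, "A", "B", ParameterSet(alpha=0.05, da_log2fc_min=2.0))
        assert not result["significant"].iloc[0]
        assert result["significant"].iloc[1]
        assert (result["p_adjusted"] >= result["p_value"]).all()

    def test_degenerate_variances_abort(self):
        a = np.full((20, 6), 25.0)
        b = np.full((20, 6), 23.0)
        table = two_group_table(a, b)
        with pytest.raises(ValueError, match="degenerate"):
            stats.moderated_pairwise_da(table, "A", "B")


class TestS0Permutation:
    def test_s0_zero_reduces_to_classical_t(self):
        rng = np.random.default_rng(5)
        a = rng.normal(25, 1, size=(100, 6))
        b = rng.normal(25, 1, size=(100, 6))
        table = two_group_table(a, b)
        result = stats.s0_permutation_test(table, "A", "B", s0=0.0, seed=1)
        t_ref, _ = sps.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.abs(result["t_stat"].to_numpy() - t_ref).max() < 1e-12

    def test_exhaustive_enumeration_for_tiny_groups(self, caplog):
        rng = np.random.default_rng(6)
        a = rng.normal(25, 1, size=(30, 2))
        b = rng.normal(25, 1, size=(30, 2))
        table = two_group_table(a, b)
        with caplog.at_level("WARNING"):
            result = stats.s0_permutation_test(table, "A", "B", seed=1)
        assert "exhaustive enumeration" in caplog.text
        assert result.attrs["n_permutations"] == math.comb(4, 2)

    def test_invariant_to_protein_order(self):
        rng = np.random.default_rng(7)
        a = rng.normal(25, 1, size=(60, 6))
        a[:10] += 3.0
        b = rng.normal(25, 1, size=(60, 6))
        table = two_group_table(a, b)
        res1 = stats.s0_permutation_test(table, "A", "B", seed=3)
        perm = rng.permutation(60)
        shuffled = table.subset([table.protein_ids[i] for i in perm])
        res2 = stats.s0_permutation_test(shuffled, "A", "B", seed=3)
        assert res1.attrs["t_cutoff"] == pytest.approx(res2.attrs["t_cutoff"])
        assert (res2["significant"].reindex(res1.index) == res1["significant"]).all()

    def test_planted_effects_are_called(self):
        rng = np.random.default_rng(8)
        a = rng.normal(25, 0.5, size=(200, 6))
        b = rng.normal(25, 0.5, size=(200, 6))
        a[:20] += 3.0
        table = two_group_table(a, b)
        result = stats.s0_permutation_test(table, "A", "B", s0=0.1,
                                           alpha=0.05, seed=2)
        called = set(np.flatnonzero(result["significant"].to_numpy()))
        assert set(range(20)) <= called
        assert len(called - set(range(20))) <= 10
        curve = result.attrs["threshold_curve"]
        assert (curve["neg_log10_p"] >= 0).all()


class TestPlainT:
    def test_identical_groups_p_one(self):
        a = np.array([[25.0, 24.0, 26.0]])
        table = two_group_table(a, a)
        result = stats.plain_two_sample_t(table, "A", "B")
        assert result["p_value"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # pooled-variance t computed by hand:
        # A = (10, 11, 12), B = (8, 9, 10): diff = 2, sp2 = 1, t = 2/sqrt(2/3)
        a = np.array([[10.0, 11.0, 12.0]])
        b = np.array([[8.0, 9.0, 10.0]])
        table = two_group_table(a, b)
        result = stats.plain_two_sample_t(table, "A", "B")
        t_expected = 2.0 / math.sqrt(2.0 / 3.0)
        p_expected = 2.0 * sps.t.sf(t_expected, 4)
        assert result["t_stat"].iloc[0] == pytest.approx(t_expected, abs=1e-9)
        assert result["p_value"].iloc[0] == pytest.approx(p_expected, abs=1e-9)

    def test_exclusive_detection_lists(self, design_2x6):
        values = np.full((3, 12), np.nan)
        values[0, :6] = 100.0          # control only
        values[1, 6:] = 100.0          # treated only
        values[2, :] = 100.0           # both
        table = make_table(values, design_2x6)
        exclusive = stats.exclusive_proteins(table, "control", "treated")
        assert exclusive["control"] == ["P000"]
        assert exclusive["treated"] == ["P001"]
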