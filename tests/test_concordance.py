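import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omiclag.concordance import (
    across_gene_correlation,
    fraction_of_total,
    lag_matrix,
    matched_vs_mismatched,
    per_gene_correlations,
    rma_regression,
    top_k_share,
)
from omiclag.data_model_io import ExpressionMatrix, select_quantified_proteins
from omiclag.protein_de import ImputationParams, impute_minprob
from omiclag.synthetic_data import SimulationConfig, generate_paired_dataset
from tests.conftest import make_matrix, make_sample_table


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_spearman(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) on distinct values (no ties)."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))


def brute_force_pearson(x, y):
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


def rma_oracle(x, y):
    """Independent range-scaled major-axis slope via eigen decomposition."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    u = x / (x.max() - x.min())
    v = y / (y.max() - y.min())
    cov = np.cov(u, v, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    slope_scaled = major[1] / major[0]
    return slope_scaled * (y.max() - y.min()) / (x.max() - x.min())


class TestFractionOfTotal:
    def test_simple_column(self):
        samples = make_sample_table("transcript", [0], 1, plate=False)
        m = make_matrix([[2.0], [3.0], [5.0]], samples, "raw_count")
        out = fraction_of_total(m)
        np.testing.assert_allclose(out.values.iloc[:, 0], [0.2, 0.3, 0.5])

    def test_equal_genes_uniform(self):
        samples = make_sample_table("transcript", [0], 1, plate=False)
        m = make_matrix(np.full((10, 1), 7.0), samples, "raw_count")
        out = fraction_of_total(m)
        np.testing.assert_allclose(out.values.iloc[:, 0], 0.1)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        samples = make_sample_table("transcript", [0, 2], 3, plate=False)
        m = make_matrix(rng.integers(0, 100, size=(50, 6)).astype(float) + 1, samples, "raw_count")
        out = fraction_of_total(m)
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-12)

    def test_delog_maps_log2_back(self):
        samples = make_sample_table("protein", [0], 1)
        m = make_matrix([[1.0], [2.0]], samples)  # 2^1=2, 2^2=4 -> 1/3, 2/3
        out = fraction_of_total(m, delog=True)
        np.testing.assert_allclose(out.values.iloc[:, 0], [1 / 3, 2 / 3])

    def test_missing_values_rejected(self):
        samples = make_sample_table("protein", [0], 1)
        m = make_matrix([[np.nan]], samples)
        with pytest.raises(ValueError, match="complete"):
            fraction_of_total(m)


class TestCorrelationOracles:
    def test_spearman_worked_example(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        from scipy.stats import spearmanr

        assert spearmanr(x, y).statistic == pytest.approx(brute_force_spearman(x, y))
        assert brute_force_spearman(x, y) == pytest.approx(0.8)

    def test_pearson_worked_example(self):
        assert brute_force_pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_exhaustive_small_permutations(self):
        # all distinct-value vectors of length <= 6 against the identity
        from scipy.stats import pearsonr, spearmanr

        for n in (3, 4, 5):
            x = list(range(1, n + 1))
            for perm in itertools.permutations(range(10, 10 + n)):
                y = list(perm)
                assert spearmanr(x, y).statistic == pytest.approx(
                    brute_force_spearman(x, y), rel=1e-12, abs=1e-12
                )
                assert pearsonr(x, y).statistic == pytest.approx(
                    brute_force_pearson(x, y), rel=1e-12, abs=1e-12
                )


class TestAcrossGeneCorrelation:
    def _paired(self, rna_vals, prot_vals):
        # single replicate so the replicate mean IS the value and monotone
        # transforms stay monotone
        rna_s = make_sample_table("transcript", [0], 1)
        prot_s = make_sample_table("protein", [0], 1)
        samples = pd.concat([rna_s, prot_s], ignore_index=True)
        rna = make_matrix(rna_vals, rna_s, "fraction")
        prot = make_matrix(prot_vals, prot_s, "fraction")
        return rna, prot, samples

    def test_monotone_transform_gives_one(self):
        rng = np.random.default_rng(1)
        base = rng.random((20, 1))
        rna, prot, samples = self._paired(base, np.exp(base))
        assert across_gene_correlation(rna, prot, samples, 0.0, 0.0) == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        base = np.linspace(0.1, 1.0, 10)[:, None]
        rna, prot, samples = self._paired(base, -base)
        assert across_gene_correlation(rna, prot, samples, 0.0, 0.0) == pytest.approx(-1.0)

    def test_too_few_genes_rejected(self):
        rna, prot, samples = self._paired(np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(ValueError, match=">=3"):
            across_gene_correlation(rna, prot, samples, 0.0, 0.0)


class TestLagMatrix:
    def test_self_match_gives_zero_lag(self):
        rng = np.random.default_rng(2)
        rna_s = make_sample_table("transcript", [0, 2, 4], 2)
        prot_s = make_sample_table("protein", [0, 2, 4], 2)
        samples = pd.concat([rna_s, prot_s], ignore_index=True)
        vals = rng.random((30, 6))
        rna = make_matrix(vals, rna_s, "fraction")
        prot = make_matrix(vals, prot_s, "fraction")
        res = lag_matrix(rna, prot, samples)
        assert res.estimated_lag_h == 0.0
        np.testing.assert_allclose(np.diag(res.lag_matrix), 1.0)

    def test_diagonal_equals_per_timepoint(self):
        config = SimulationConfig(n_genes=100, seed=4)
        ds = generate_paired_dataset(config)
        direct, imputable, _ = select_quantified_proteins(ds.intensities, ds.samples)
        intens = impute_minprob(ds.intensities, direct, imputable, ImputationParams(seed=4))
        common = [g for g in ds.counts.gene_ids if g in set(intens.gene_ids)]
        rna = fraction_of_total(ds.counts.subset_genes(common))
        prot = fraction_of_total(intens.subset_genes(common), delog=True)
        res = lag_matrix(rna, prot, ds.samples)
        for t, rho in res.per_timepoint_rho.items():
            assert res.lag_matrix.loc[t, t] == rho

    def test_kinetic_lag_recovered(self):
        config = SimulationConfig(n_genes=800, seed=5, delta_range=(1 / 3, 1 / 3))
        ds = generate_paired_dataset(config)
        direct, imputable, _ = select_quantified_proteins(ds.intensities, ds.samples)
        intens = impute_minprob(ds.intensities, direct, imputable, ImputationParams(seed=5))
        common = [g for g in ds.counts.gene_ids if g in set(intens.gene_ids)]
        rna = fraction_of_total(ds.counts.subset_genes(common))
        prot = fraction_of_total(intens.subset_genes(common), delog=True)
        res = lag_matrix(rna, prot, ds.samples)
        assert 2.0 <= res.estimated_lag_h <= 4.0

    def test_single_shared_time_point_defaults_to_zero(self):
        rng = np.random.default_rng(6)
        rna_s = make_sample_table("transcript", [0], 2)
        prot_s = make_sample_table("protein", [0], 2)
        samples = pd.concat([rna_s, prot_s], ignore_index=True)
        rna = make_matrix(rng.random((10, 2)), rna_s, "fraction")
        prot = make_matrix(rng.random((10, 2)), prot_s, "fraction")
        res = lag_matrix(rna, prot, samples)
        assert res.lag_matrix.shape == (1, 1)
        assert res.estimated_lag_h == 0.0


class TestRmaRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        y = 2 * x + 1
        slope, intercept = rma_regression(x, y)
        assert slope == pytest.approx(2.0, rel=1e-10)
        assert intercept == pytest.approx(1.0, rel=1e-8)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(scale=0.5, size=100)
        s_xy, _ = rma_regression(x, y)
        s_yx, _ = rma_regression(y, x)
        assert s_xy == pytest.approx(1 / s_yx, rel=1e-10)

    def test_oracle_equivalence_gaussian_cloud(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(scale=0.8, size=200)
        slope, _ = rma_regression(x, y)
        assert slope == pytest.approx(rma_oracle(x, y), abs=1e-10)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            rma_regression(np.ones(5), np.arange(5.0))


class TestPerGeneCorrelations:
    def _dataset(self, transform):
        rna_s = make_sample_table("transcript", [0, 2], 2)
        prot_s = make_sample_table("protein", [0, 2], 2)
        samples = pd.concat([rna_s, prot_s], ignore_index=True)
        rng = np.random.default_rng(9)
        base = rng.random((5, 4))
        rna = make_matrix(base, rna_s, "fraction")
        prot = make_matrix(transform(base), prot_s, "fraction")
        return rna, prot, samples

    def test_affine_transform_gives_one(self):
        rna, prot, samples = self._dataset(lambda x: 3 * x + 1)
        r = per_gene_correlations(rna, prot, samples)
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_negation_gives_minus_one(self):
        rna, prot, samples = self._dataset(lambda x: -x)
        r = per_gene_correlations(rna, prot, samples)
        np.testing.assert_allclose(r.to_numpy(), -1.0)

    def test_constant_gene_flagged_nan(self):
        rna, prot, samples = self._dataset(lambda x: x)
        rna.values.iloc[0, :] = 0.25
        r = per_gene_correlations(rna, prot, samples)
        assert np.isnan(r.iloc[0])

    def test_direct_formula_small_case(self):
        rna_s = make_sample_table("transcript", [0, 2, 4], 1)
        prot_s = make_sample_table("protein", [0, 2, 4], 1)
        samples = pd.concat([rna_s, prot_s], ignore_index=True)
        rna = make_matrix([[1.0, 2.0, 3.0]], rna_s, "fraction")
        prot = make_matrix([[1.0, 3.0, 2.0]], prot_s, "fraction")
        r = per_gene_correlations(rna, prot, samples)
        assert r.iloc[0] == pytest.approx(0.5)


class TestMatchedVsMismatched:
    def test_plate_effect_makes_matched_higher(self):
        config = SimulationConfig(n_genes=300, seed=10, plate_effect_sd=0.4)
        ds = generate_paired_dataset(config)
        direct, imputable, _ = select_quantified_proteins(ds.intensities, ds.samples)
        intens = impute_minprob(ds.intensities, direct, imputable, ImputationParams(seed=10))
        common = [g for g in ds.counts.gene_ids if g in set(intens.gene_ids)]
        rna = fraction_of_total(ds.counts.subset_genes(common))
        prot = fraction_of_total(intens.subset_genes(common), delog=True)
        matched, mismatched, p = matched_vs_mismatched(rna, prot, ds.samples, n_perm=200, seed=1)
        assert matched > mismatched
        assert p < 0.05

    def test_no_plate_effect_indistinguishable(self):
        config = SimulationConfig(n_genes=300, seed=12, plate_effect_sd=0.0)
        ds = generate_paired_dataset(config)
        direct, imputable, _ = select_quantified_proteins(ds.intensities, ds.samples)
        intens = impute_minprob(ds.intensities, direct, imputable, ImputationParams(seed=12))
        common = [g for g in ds.counts.gene_ids if g in set(intens.gene_ids)]
        rna = fraction_of_total(ds.counts.subset_genes(common))
        prot = fraction_of_total(intens.subset_genes(common), delog=True)
        matched, mismatched, p = matched_vs_mismatched(rna, prot, ds.samples, n_perm=200, seed=1)
        assert p > 0.05

    def test_single_replicate_rejected(self):
        rna_s = make_sample_table("transcript", [0, 2], 1)
        prot_s = make_sample_table("protein", [0, 2], 1)
        samples = pd.concat([rna_s, prot_s], ignore_index=True)
        rng = np.random.default_rng(12)
        rna = make_matrix(rng.random((5, 2)), rna_s, "fraction")
        prot = make_matrix(rng.random((5, 2)), prot_s, "fraction")
        with pytest.raises(ValueError, match="permute"):
            matched_vs_mismatched(rna, prot, samples, n_perm=10, seed=0)


class TestTopKShare:
    def test_simple(self):
        samples = make_sample_table("transcript", [0], 1, plate=False)
        m = make_matrix([[0.5], [0.3], [0.2]], samples, "fraction")
        assert top_k_share(m, 2) == pytest.approx(0.8)

    def test_uniform(self):
        samples = make_sample_table("transcript", [0], 1, plate=False)
        m = make_matrix(np.full((10, 1), 0.1), samples, "fraction")
        assert top_k_share(m, 2) == pytest.approx(0.2)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=3, max_size=20), st.integers(1, 5))
    def test_matches_sort_and_sum_oracle(self, weights, k):
        w = np.asarray(weights)
        fracs = w / w.sum()
        values = pd.DataFrame({"s1": fracs}, index=[f"g{i}" for i in range(len(w))])
        expected = np.sort(fracs)[::-1][: min(k, len(w))].sum()
        assert top_k_share(values, k) == pytest.approx(expected, rel=1e-12)
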