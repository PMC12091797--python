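import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ymcflux import (
    EnrichmentMatrix,
    atac_association,
    critical_value,
    dominance_analysis,
    metabolic_dominance,
    select_correlated_genes,
    shuffle_null,
)
from ymcflux.synthetic_data import SyntheticScenario, simulate_epigenome


def matrix(rows, genes=None, assay="H3K9Ac"):
    rows = np.atleast_2d(np.asarray(rows, float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    cols = [f"t{j+1}" for j in range(rows.shape[1])]
    return EnrichmentMatrix(values=pd.DataFrame(rows, index=genes, columns=cols), assay=assay)


FLUX15 = np.sin(np.linspace(0, 2 * np.pi, 15)) + 2.0


class TestMetabolicDominance:
    def test_identical_series_correlate_perfectly(self):
        r = metabolic_dominance(matrix([FLUX15]), FLUX15)
        assert r["g0"] == pytest.approx(1.0)

    def test_negated_series_anticorrelate_perfectly(self):
        r = metabolic_dominance(matrix([-FLUX15]), FLUX15)
        assert r["g0"] == pytest.approx(-1.0)

    def test_hand_computed_triple(self):
        # r((1,2,3),(1,2,4)) = 3 / (sqrt(2) sqrt(14/3)) = 0.98198...
        r = metabolic_dominance(matrix([[1.0, 2.0, 3.0]]), np.array([1.0, 2.0, 4.0]))
        expected = 3.0 / (np.sqrt(2.0) * np.sqrt(14.0 / 3.0))
        assert r["g0"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9820, abs=5e-5)

    def test_matches_scipy_pearson_to_high_precision(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 15))
        flux = rng.normal(size=15)
        r = metabolic_dominance(matrix(X), flux)
        for i in range(20):
            assert r.iloc[i] == pytest.approx(stats.pearsonr(X[i], flux)[0], abs=1e-12)

    def test_zero_variance_gene_flagged_undefined(self):
        r = metabolic_dominance(matrix([np.ones(15), FLUX15]), FLUX15)
        assert np.isnan(r["g0"]) and r["g1"] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            metabolic_dominance(matrix([np.ones(10)]), FLUX15)


class TestShuffleNull:
    def test_same_seed_reproduces_bit_identical_null(self):
        m = matrix(np.random.default_rng(2).normal(size=(30, 15)))
        a = shuffle_null(m, FLUX15, seed=42)
        b = shuffle_null(m, FLUX15, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_null_mean_consistent_with_symmetry(self):
        rng = np.random.default_rng(3)
        m = matrix(rng.normal(size=(500, 15)))
        null = shuffle_null(m, FLUX15, reps_per_gene=20, seed=0)
        assert len(null) == 500 * 20
        assert abs(null.mean()) <= 3 * null.std() / np.sqrt(len(null))

    def test_two_point_series_correlations_are_plus_minus_one(self):
        m = matrix([[1.0, 2.0, 3.0]])
        # length-3 permutations: |r| can be below 1; but a 2-point series is
        # degenerate by construction, so assert the documented precondition
        with pytest.raises(ValueError, match="3 time points"):
            shuffle_null(matrix([[1.0, 2.0]]), np.array([1.0, 2.0]))

    def test_single_vs_double_shuffle_same_distribution(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(1, 15))
        m = matrix(X)
        both = shuffle_null(m, FLUX15, reps_per_gene=5000, seed=1)
        # one-sided shuffle: permute only the mark series
        rng2 = np.random.default_rng(2)
        one = np.array([
            stats.pearsonr(rng2.permutation(X[0]), FLUX15)[0] for _ in range(5000)
        ])
        assert stats.ks_2samp(both, one).pvalue > 1e-3


class TestCriticalValue:
    def test_observed_equal_null_never_attains(self):
        vals = np.linspace(-0.9, 0.9, 200)
        cv = critical_value(vals, vals, 0.10, "positive")
        assert not cv.attained and cv.threshold is None

    def test_planted_separation_is_detected(self):
        rng = np.random.default_rng(8)
        null = rng.uniform(-0.5, 0.5, 2000)
        observed = np.concatenate([rng.uniform(-0.5, 0.5, 2000), np.full(100, 0.95)])
        cv = critical_value(observed, null, 0.10, "positive")
        assert cv.attained and cv.threshold <= 0.95
        assert cv.null_count / cv.observed_count < 0.10
        assert cv.observed_count >= 100

    def test_threshold_is_least_extreme_qualifying_observed_value(self):
        observed = [0.05] * 50 + [0.8] * 20
        null = [0.5] * 30 + [-0.5] * 70
        # at 0.05: 30 null / 70 obs fails; at 0.8: 0 null / 20 obs qualifies
        cv = critical_value(observed, null, 0.10, "positive")
        assert cv.threshold == pytest.approx(0.8)
        assert (cv.null_count, cv.observed_count) == (0, 20)

    def test_negative_tail_mirror(self):
        observed = [-0.8] * 20 + [0.0] * 30
        null = [0.0] * 50
        cv = critical_value(observed, null, 0.10, "negative")
        assert cv.attained and cv.threshold <= -0.8

    def test_vacuous_extreme_tail_does_not_attain(self):
        # a single extreme gene with zero null beyond it is not evidence
        observed = list(np.linspace(-0.4, 0.4, 100)) + [0.99]
        null = np.linspace(-0.45, 0.45, 101)
        cv = critical_value(observed, null, 0.10, "positive")
        assert not cv.attained

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            critical_value([], [0.1], 0.10, "positive")


class TestGeneSelection:
    def test_inclusive_threshold_boundary(self):
        r = pd.Series({"a": 0.71, "b": 0.69})
        assert select_correlated_genes(r, 0.7) == ["a"]

    def test_exact_cutoff_values_are_selected(self):
        r = pd.Series({"a": 0.7, "b": 0.7, "c": 0.7})
        assert len(select_correlated_genes(r, 0.7)) == 3

    def test_empty_input_gives_empty_list(self):
        assert select_correlated_genes(pd.Series(dtype=float), 0.7) == []

    def test_sorted_by_descending_correlation(self):
        r = pd.Series({"a": 0.75, "b": 0.9, "c": 0.8})
        assert select_correlated_genes(r, 0.7) == ["b", "c", "a"]


class TestAtacAssociation:
    def test_perfect_linear_relation(self):
        dom = pd.Series(np.linspace(-0.5, 0.9, 20), index=[f"g{i}" for i in range(20)])
        atac = matrix(np.tile(dom.to_numpy()[:, None], (1, 6)), assay="ATAC",
                      genes=list(dom.index))
        out = atac_association(dom, atac)
        np.testing.assert_allclose(out["pearson_r"], 1.0)
        np.testing.assert_allclose(out["slope"], 1.0)

    def test_permuted_dominance_within_null_envelope(self):
        rng = np.random.default_rng(9)
        n = 1000
        dom = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        atac = matrix(rng.normal(10, 1, size=(n, 6)), assay="ATAC",
                      genes=list(dom.index))
        out = atac_association(dom, atac)
        envelope = stats.norm.ppf(1 - 0.0005) / np.sqrt(n - 3)  # 99.9% two-sided
        assert (out["pearson_r"].abs() < envelope * 1.5).all()

    def test_constant_atac_column_is_missing_with_warning(self):
        dom = pd.Series(np.linspace(0, 1, 10), index=[f"g{i}" for i in range(10)])
        vals = np.tile(dom.to_numpy()[:, None], (1, 2))
        vals[:, 1] = 7.0
        atac = matrix(vals, assay="ATAC", genes=list(dom.index))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = atac_association(dom, atac)
        assert np.isnan(out["pearson_r"].iloc[1])

    def test_too_few_shared_genes_rejected(self):
        dom = pd.Series({"a": 0.5, "b": 0.2})
        atac = matrix(np.ones((2, 3)) * [[1.0], [2.0]], assay="ATAC", genes=["a", "x"])
        with pytest.raises(ValueError, match="shared"):
            atac_association(dom, atac)


class TestPlantedSignalRecovery:
    def test_planted_correlation_recovered_within_sampling_band(self):
        scen = SyntheticScenario(seed=0, n_genes=1000, n_correlated=1000, rho_planted=0.8)
        mat, rho = simulate_epigenome(scen, FLUX15)
        r = metabolic_dominance(mat, FLUX15)
        # E[r] ~ rho (1 - (1-rho^2)/(2n)) for n=15; mean over 1000 genes
        expected = 0.8 * (1 - (1 - 0.64) / 30)
        assert abs(r.mean() - expected) <= 0.02

    def test_critical_value_captures_majority_of_planted_genes(self):
        scen = SyntheticScenario(seed=1, n_genes=1000, n_correlated=500, rho_planted=0.8)
        mat, rho = simulate_epigenome(scen, FLUX15)
        res = dominance_analysis(mat, FLUX15, 0.10, seed=5)
        assert res.positive.attained
        planted = res.r.iloc[:500]
        assert (planted >= res.positive.threshold).mean() > 0.5

    def test_null_only_input_attains_no_threshold(self):
        scen = SyntheticScenario(seed=2, n_genes=800, n_correlated=0, rho_planted=0.0)
        mat, _ = simulate_epigenome(scen, FLUX15)
        res = dominance_analysis(mat, FLUX15, 0.10, seed=6)
        assert not res.positive.attained
        assert not res.negative.attained

    def test_same_seed_analysis_bit_identical(self):
        scen = SyntheticScenario(seed=3, n_genes=200, n_correlated=40)
        mat, _ = simulate_epigenome(scen, FLUX15)
        a = dominance_analysis(mat, FLUX15, seed=9)
        b = dominance_analysis(mat, FLUX15, seed=9)
        np.testing.assert_array_equal(a.null, b.null)
        pd.testing.assert_series_equal(a.r, b.r)
        assert a.positive.threshold == b.positive.threshold
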