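"""Parallel analysis, factor models, fit indices, and adjudication."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from delibank.correlations import TetrachoricResult, tetrachoric_matrix
from delibank.dimensionality import (
    FactorModelFit,
    ParallelAnalysisResult,
    adjudicate_dimensions,
    assign_simple_structure,
    efa,
    eigenvalues,
    fit_bifactor,
    fit_cfa,
    fit_indices,
    permuted_parallel_analysis,
)

from .conftest import bernoulli_matrix
from .oracles import cfi_rmsea_oracle


def tet_from_corr(R, n=1000):
    k = R.shape[0]
    return TetrachoricResult(
        indicator_ids=[f"v{i}" for i in range(k)],
        matrix=R, raw=R, estimable=np.ones((k, k), bool),
        thresholds=np.zeros(k), n_pairs=np.full((k, k), n), n_persons=n,
    )


class TestEigenvalues:
    def test_identity_matrix(self):
        w = eigenvalues(tet_from_corr(np.eye(5)))
        assert np.allclose(w, 1.0)

    def test_equicorrelation_closed_form(self):
        R = np.full((5, 5), 0.5)
        np.fill_diagonal(R, 1.0)
        w = eigenvalues(tet_from_corr(R))
        assert np.allclose(w, [3.0, 0.5, 0.5, 0.5, 0.5])

    def test_one_factor_first_root(self):
        k, lam = 6, 0.8
        R = np.full((k, k), lam**2)
        np.fill_diagonal(R, 1.0)
        w = eigenvalues(tet_from_corr(R))
        # direct eigensolver cross-check
        assert np.allclose(np.sort(w), np.sort(np.linalg.eigvalsh(R)))
        assert w[0] == pytest.approx(1 + (k - 1) * lam**2)

    def test_spectrum_sums_to_dimension(self, default_cohort):
        ids = [i for i in default_cohort.indicator_ids if i.startswith("f2_obs")]
        tet = tetrachoric_matrix(default_cohort, ids)
        w = np.linalg.eigvalsh(tet.matrix)
        assert np.sum(w) == pytest.approx(len(ids), abs=1e-6)


class TestParallelAnalysis:
    def test_permutation_preserves_margins(self):
        # the engine's null: shuffled columns keep their margins exactly
        m = bernoulli_matrix(n=300, k=4, seed=1)
        y = m.values.to_numpy()
        rng = np.random.default_rng(0)
        yp = rng.permuted(y, axis=0)
        assert np.array_equal(np.sort(yp, axis=0), np.sort(y, axis=0))

    def test_null_data_no_significant_roots(self):
        m = bernoulli_matrix(n=2000, k=10, seed=2)
        pa = permuted_parallel_analysis(m, n_permutations=100, seed=3)
        assert pa.m_significant == 0

    def test_one_factor_detected(self, one_factor_cohort):
        pa = permuted_parallel_analysis(one_factor_cohort, n_permutations=100, seed=4)
        assert pa.m_significant == 1

    def test_two_factors_detected(self, two_factor_cohort):
        pa = permuted_parallel_analysis(two_factor_cohort, n_permutations=100, seed=5)
        assert pa.m_significant == 2

    def test_requires_enough_permutations(self, one_factor_cohort):
        with pytest.raises(ValueError):
            permuted_parallel_analysis(one_factor_cohort, n_permutations=10, seed=0)

    def test_deterministic_given_seed(self, two_factor_cohort):
        pa1 = permuted_parallel_analysis(two_factor_cohort, n_permutations=60, seed=9)
        pa2 = permuted_parallel_analysis(two_factor_cohort, n_permutations=60, seed=9)
        assert np.array_equal(pa1.permutation_quantiles, pa2.permutation_quantiles)


class TestEFA:
    def test_one_factor_loading_recovery(self):
        # 2PL discrimination a maps to underlying-variable loading
        # a / sqrt(1 + a^2) in the normal-ogive metric (D absorbs the
        # link); moderate difficulties keep the latent-normal
        # approximation of the logistic link accurate
        from delibank.synthetic import CohortSpec, DimensionSpec, generate_truth, simulate_responses

        spec = CohortSpec(dimensions=[
            DimensionSpec("d1", 1, "direct", 10, a_range=(0.8, 2.0),
                          b_range=(-0.5, 1.5))
        ])
        truth = generate_truth(spec, 17)
        cohort = simulate_responses(truth, 4598, 18)
        tet = tetrachoric_matrix(cohort)
        fit = efa(tet, 1)
        a = np.array(truth.dimensions[0].a)
        lam_true = a / np.sqrt(1 + a**2)
        lam_hat = np.abs(fit.loadings[:, 0])
        assert np.abs(lam_hat - lam_true).max() < 0.05

    def test_one_factor_no_rotation(self, one_factor_cohort):
        tet = tetrachoric_matrix(one_factor_cohort)
        fit = efa(tet, 1)
        assert fit.loadings.shape[1] == 1
        assert np.allclose(fit.factor_correlations, 1.0)

    def test_two_blocks_simple_structure(self, two_factor_cohort):
        tet = tetrachoric_matrix(two_factor_cohort)
        fit = efa(tet, 2)
        L = np.abs(fit.loadings)
        own = np.array([L[i].max() for i in range(12)])
        cross = np.array([L[i].min() for i in range(12)])
        assert (own >= 0.4).all()
        assert (cross < 0.2).all()

    def test_invalid_m_rejected(self, two_factor_cohort):
        tet = tetrachoric_matrix(two_factor_cohort)
        with pytest.raises(ValueError):
            efa(tet, 0)


class TestAssignSimpleStructure:
    @staticmethod
    def fit_with_loadings(L):
        L = np.asarray(L, float)
        return FactorModelFit(
            model_kind="EFA", m_factors=L.shape[1],
            indicator_ids=[f"v{i}" for i in range(L.shape[0])],
            loadings=L, pattern=None, factor_correlations=np.eye(L.shape[1]),
            chi_square=0.0, df=0, CFI=1.0, RMSEA=0.0, discrepancy=0.0, n=100,
        )

    def test_dominant_loading(self):
        fit = self.fit_with_loadings([[0.8, 0.1]])
        assert assign_simple_structure(fit) == {"v0": 0}

    def test_absolute_value_rule(self):
        fit = self.fit_with_loadings([[0.3, -0.6]])
        assert assign_simple_structure(fit) == {"v0": 1}

    def test_tie_goes_to_lower_factor(self):
        fit = self.fit_with_loadings([[0.5, 0.5]])
        assert assign_simple_structure(fit) == {"v0": 0}


class TestCFAAndBifactor:
    def test_self_fit_is_perfect(self):
        lam = np.array([0.8, 0.7, 0.6, 0.75, 0.65])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        tet = tet_from_corr(R, n=4598)
        fit = fit_cfa(tet, {f"v{i}": 0 for i in range(5)})
        assert fit.CFI == pytest.approx(1.0)
        assert fit.RMSEA == pytest.approx(0.0, abs=1e-6)
        assert fit.discrepancy < 1e-10

    def test_clean_one_factor_in_good_fit_region(self, one_factor_cohort):
        tet = tetrachoric_matrix(one_factor_cohort)
        fit = fit_cfa(tet, {i: 0 for i in tet.indicator_ids})
        assert fit.CFI > 0.94
        assert fit.RMSEA < 0.05

    def test_underfactoring_hurts_fit(self, two_factor_cohort):
        tet = tetrachoric_matrix(two_factor_cohort)
        ids = tet.indicator_ids
        one = fit_cfa(tet, {i: 0 for i in ids})
        pattern = {i: (0 if i.startswith("d1") else 1) for i in ids}
        two = fit_cfa(tet, pattern)
        assert two.CFI > one.CFI

    def test_bifactor_on_common_factor_only(self, one_factor_cohort):
        tet = tetrachoric_matrix(one_factor_cohort)
        ids = tet.indicator_ids
        pattern = {i: (0 if j < 5 else 1) for j, i in enumerate(ids)}
        bfa = fit_bifactor(tet, pattern)
        specifics = bfa.loadings[np.arange(10), 1 + (np.arange(10) >= 5)]
        assert np.median(np.abs(specifics)) < 0.15
        assert not bfa.large_secondary

    def test_bifactor_dominant_block_flagged(self, two_factor_cohort):
        tet = tetrachoric_matrix(two_factor_cohort)
        pattern = {i: (0 if i.startswith("d1") else 1) for i in tet.indicator_ids}
        bfa = fit_bifactor(tet, pattern)
        assert bfa.large_secondary

    def test_bifactor_fits_at_least_as_well_as_cfa(self, two_factor_cohort):
        tet = tetrachoric_matrix(two_factor_cohort)
        pattern = {i: (0 if i.startswith("d1") else 1) for i in tet.indicator_ids}
        cfa = fit_cfa(tet, pattern)
        bfa = fit_bifactor(tet, pattern)
        assert bfa.discrepancy <= cfa.discrepancy + 1e-8

    def test_pattern_needs_two_indicators_per_factor(self, two_factor_cohort):
        tet = tetrachoric_matrix(two_factor_cohort)
        pattern = {i: 0 for i in tet.indicator_ids}
        pattern[tet.indicator_ids[0]] = 1
        with pytest.raises(ValueError):
            fit_cfa(tet, pattern)


class TestFitIndices:
    def test_perfect_fit(self):
        cfi, rmsea = fit_indices(50.0, 50, 500.0, 55, 1000)
        assert (cfi, rmsea) == (1.0, 0.0)

    def test_closed_form_example(self):
        _, rmsea = fit_indices(100.0, 50, 1000.0, 55, 1001)
        assert rmsea == pytest.approx(np.sqrt(50 / (50 * 1000)))

    def test_zero_df_rmsea(self):
        cfi, rmsea = fit_indices(0.0, 0, 10.0, 5, 100)
        assert rmsea == 0.0

    @given(
        chi2=st.floats(0, 1e4), df=st.integers(0, 200),
        chi2_b=st.floats(0, 1e5), df_b=st.integers(0, 300),
        n=st.integers(2, 10000),
    )
    def test_matches_hand_formula(self, chi2, df, chi2_b, df_b, n):
        cfi, rmsea = fit_indices(chi2, df, chi2_b, df_b, n)
        ocfi, ormsea = cfi_rmsea_oracle(chi2, df, chi2_b, df_b, n)
        assert cfi == pytest.approx(ocfi, abs=1e-10)
        assert rmsea == pytest.approx(ormsea, abs=1e-10)


class TestAdjudication:
    @staticmethod
    def pa_with_m(m, k=8):
        return ParallelAnalysisResult(
            observed_eigenvalues=np.linspace(3, 0.2, k),
            permutation_quantiles=np.full(k, 1.2),
            n_permutations=100, m_significant=m, seed=0,
        )

    @staticmethod
    def cfa_fit(m, cfi, ids, pattern=None):
        k = len(ids)
        return FactorModelFit(
            model_kind="CFA", m_factors=m, indicator_ids=ids,
            loadings=np.zeros((k, m)), pattern=pattern,
            factor_correlations=np.eye(m), chi_square=10.0, df=5,
            CFI=cfi, RMSEA=0.03, discrepancy=0.0, n=4598,
        )

    @staticmethod
    def bfa_fit(large, ids, pattern):
        k = len(ids)
        return FactorModelFit(
            model_kind="BFA", m_factors=2, indicator_ids=ids,
            loadings=np.zeros((k, 3)), pattern=pattern,
            factor_correlations=np.eye(3), chi_square=8.0, df=4,
            CFI=0.99, RMSEA=0.02, discrepancy=0.0, n=4598,
            large_secondary=large,
        )

    def test_single_root_keeps_one_dimension(self):
        ids = [f"v{i}" for i in range(8)]
        dec = adjudicate_dimensions(self.pa_with_m(1), [self.cfa_fit(1, 0.99, ids)])
        assert dec.m_retained == 1
        assert dec.subsets == [ids]

    def test_two_roots_with_support_splits(self):
        ids = [f"v{i}" for i in range(8)]
        pattern = {i: (0 if j < 4 else 1) for j, i in enumerate(ids)}
        fits = [
            self.cfa_fit(1, 0.90, ids),
            self.cfa_fit(2, 0.99, ids, pattern),
            self.bfa_fit(True, ids, pattern),
        ]
        dec = adjudicate_dimensions(self.pa_with_m(2), fits)
        assert dec.m_retained == 2
        assert dec.modeled == [True, True]

    def test_two_roots_without_support_stays_one(self):
        # significant second eigenvalue alone is not a preponderance
        ids = [f"v{i}" for i in range(8)]
        pattern = {i: (0 if j < 4 else 1) for j, i in enumerate(ids)}
        fits = [
            self.cfa_fit(1, 0.99, ids),
            self.cfa_fit(2, 0.995, ids, pattern),
            self.bfa_fit(False, ids, pattern),
        ]
        dec = adjudicate_dimensions(self.pa_with_m(2), fits)
        assert dec.m_retained == 1

    def test_small_subset_not_modeled(self):
        ids = [f"v{i}" for i in range(7)]
        pattern = {i: (0 if j < 4 else 1) for j, i in enumerate(ids)}
        fits = [
            self.cfa_fit(1, 0.90, ids),
            self.cfa_fit(2, 0.99, ids, pattern),
            self.bfa_fit(True, ids, pattern),
        ]
        dec = adjudicate_dimensions(self.pa_with_m(2), fits)
        assert dec.modeled == [True, False]  # 3-indicator block reported only
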