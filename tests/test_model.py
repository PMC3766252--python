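import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linklcm import (
    AgreementPatternTable,
    ClassicalParams,
    InteractionTerm,
    LambdaParams,
    ModelSpec,
    bic,
    classical_to_lambda,
    expected_cell_means,
    lambda_to_classical,
    log_likelihood,
    match_score,
    n_free_params,
    pattern_probabilities,
)
from linklcm.model import deviance_from_probs, pattern_matrix

from conftest import fs_mixture_probs


def zero_lambda(K: int, n_terms: int = 0) -> LambdaParams:
    return LambdaParams(0.0, 0.0, np.zeros(K), np.zeros(K), np.zeros(n_terms), np.zeros(n_terms))


class TestSpecValidation:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec(3, (InteractionTerm(0, 1, "both_shared"), InteractionTerm(0, 1, "match_only")))

    def test_out_of_range_index(self):
        with pytest.raises(ValueError, match="out of range"):
            ModelSpec(2, (InteractionTerm(0, 2, "both_shared"),))

    def test_bad_structure(self):
        with pytest.raises(ValueError, match="structure"):
            InteractionTerm(0, 1, "sometimes")

    def test_j_ge_l_rejected(self):
        with pytest.raises(ValueError):
            InteractionTerm(2, 1, "both_shared")


class TestExpectedCellMeans:
    def test_all_zero_lambda_gives_unit_cells(self):
        cells = expected_cell_means(zero_lambda(1), ModelSpec(1))
        assert cells.shape == (2, 2)
        np.testing.assert_allclose(cells, 1.0)

    def test_both_shared_doubles_agreeing_cells(self):
        spec = ModelSpec(2, (InteractionTerm(0, 1, "both_shared"),))
        lam = LambdaParams(0.0, 0.0, np.zeros(2), np.zeros(2), np.array([math.log(2)]), np.zeros(1))
        cells = expected_cell_means(lam, spec)
        Y = pattern_matrix(2)
        both = (Y[:, 0] * Y[:, 1]).astype(bool)
        np.testing.assert_allclose(cells[both], 2.0)
        np.testing.assert_allclose(cells[~both], 1.0)

    def test_ci_class_ratio_depends_only_on_lamMk_sum(self):
        rng = np.random.default_rng(3)
        K = 3
        lam = LambdaParams(rng.normal(), rng.normal(), rng.normal(size=K), rng.normal(size=K))
        cells = expected_cell_means(lam, ModelSpec(K))
        Y = pattern_matrix(K)
        ratio = np.log(cells[:, 1] / cells[:, 0])
        np.testing.assert_allclose(ratio, lam.lamM + Y @ lam.lamM_k, rtol=1e-12)

    def test_nonfinite_lambda_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            LambdaParams(np.inf, 0.0, np.zeros(1), np.zeros(1))


class TestPatternProbabilities:
    def test_uniform_at_zero_lambda(self):
        P = pattern_probabilities(zero_lambda(2), ModelSpec(2))
        np.testing.assert_allclose(P, 0.25)

    def test_half_half_mixture(self):
        # pi=0.5 with extreme m/u: P(y=1) = 0.5*m + 0.5*u
        cp = ClassicalParams(0.5, np.array([1 - 1e-12]), np.array([1e-12]))
        lam = classical_to_lambda(cp, 1)
        P = pattern_probabilities(lam, ModelSpec(1))
        assert P[1] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("K", [1, 2, 3, 4, 5])
    def test_normalization(self, K):
        rng = np.random.default_rng(K + 10)
        lam = LambdaParams(rng.normal(), rng.normal(), rng.normal(size=K), rng.normal(size=K))
        assert pattern_probabilities(lam, ModelSpec(K)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        K = 3
        lam = LambdaParams(rng.normal(), rng.normal(), rng.normal(size=K), rng.normal(size=K))
        P1 = pattern_probabilities(lam, ModelSpec(K))
        P2 = pattern_probabilities(lam.translated(3.7), ModelSpec(K))
        np.testing.assert_allclose(P1, P2, rtol=1e-12)


class TestClassicalLambdaMaps:
    def test_all_zero_lambda_maps_to_half(self):
        cp = lambda_to_classical(zero_lambda(2), ModelSpec(2))
        assert cp.pi == pytest.approx(0.5)
        np.testing.assert_allclose(cp.m, 0.5)
        np.testing.assert_allclose(cp.u, 0.5)

    def test_logistic_identity_sex_row(self):
        # u = expit(lam_k) = 0.661, m = expit(lam_k + lamM_k) = 0.710
        from scipy.special import logit

        lam_k = logit(0.661)
        lamM_k = logit(0.710) - lam_k
        lam = LambdaParams(0.0, 0.0, np.array([lam_k]), np.array([lamM_k]))
        cp = lambda_to_classical(lam, ModelSpec(1))
        assert cp.u[0] == pytest.approx(0.661, abs=1e-12)
        assert cp.m[0] == pytest.approx(0.710, abs=1e-12)

    def test_round_trip_ci(self):
        rng = np.random.default_rng(4)
        for K in (1, 3, 4):
            cp = ClassicalParams(
                rng.uniform(0.01, 0.4), rng.uniform(0.4, 0.9, K), rng.uniform(0.05, 0.3, K)
            )
            cp2 = lambda_to_classical(classical_to_lambda(cp, K), ModelSpec(K))
            assert cp2.pi == pytest.approx(cp.pi, abs=1e-10)
            np.testing.assert_allclose(cp2.m, cp.m, atol=1e-10)
            np.testing.assert_allclose(cp2.u, cp.u, atol=1e-10)

    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    def test_induced_mixture_matches_fs_formula(self, K):
        rng = np.random.default_rng(K)
        cp = ClassicalParams(
            rng.uniform(0.01, 0.5), rng.uniform(0.3, 0.95, K), rng.uniform(0.02, 0.4, K)
        )
        P = pattern_probabilities(classical_to_lambda(cp, K), ModelSpec(K))
        np.testing.assert_allclose(P, fs_mixture_probs(cp.pi, cp.m, cp.u), rtol=1e-10)

    def test_boundary_probability_rejected(self):
        with pytest.raises(ValueError):
            ClassicalParams(0.5, np.array([1.0]), np.array([0.2]))


class TestLogLikelihood:
    def test_empty_table_zero(self):
        table = AgreementPatternTable(2, np.zeros(4, dtype=int))
        assert log_likelihood(zero_lambda(2), ModelSpec(2), table) == 0.0

    def test_single_pattern(self):
        table = AgreementPatternTable(2, np.array([0, 0, 0, 40]))
        ll = log_likelihood(zero_lambda(2), ModelSpec(2), table)
        assert ll == pytest.approx(40 * math.log(0.25), rel=1e-12)

    def test_hand_summed(self, toy_table_k2):
        cp = ClassicalParams(0.1, np.array([0.8, 0.7]), np.array([0.2, 0.3]))
        lam = classical_to_lambda(cp, 2)
        P = fs_mixture_probs(cp.pi, cp.m, cp.u)
        expected = sum(
            f * math.log(p) for f, p in zip(toy_table_k2.counts, P) if f > 0
        )
        assert log_likelihood(lam, ModelSpec(2), toy_table_k2) == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self, toy_table_k2):
        rng = np.random.default_rng(0)
        lam = LambdaParams(rng.normal(), rng.normal(), rng.normal(size=2), rng.normal(size=2))
        l1 = log_likelihood(lam, ModelSpec(2), toy_table_k2)
        l2 = log_likelihood(lam.translated(-2.5), ModelSpec(2), toy_table_k2)
        assert abs(l1 - l2) <= 1e-9

    def test_dimension_mismatch(self, toy_table_k2):
        with pytest.raises(ValueError, match="K="):
            log_likelihood(zero_lambda(3), ModelSpec(3), toy_table_k2)


class TestDeviance:
    def test_zero_at_saturated_probs(self, toy_table_k2):
        P = toy_table_k2.counts / toy_table_k2.N
        assert deviance_from_probs(P, toy_table_k2) == pytest.approx(0.0, abs=1e-12)

    def test_positive_off_saturation(self, toy_table_k2):
        P = np.full(4, 0.25)
        assert deviance_from_probs(P, toy_table_k2) > 0

    def test_empty_cells_contribute_zero(self):
        table = AgreementPatternTable(2, np.array([10, 0, 0, 10]))
        P = np.array([0.5, 1e-9, 1e-9, 0.5 - 2e-9])
        assert deviance_from_probs(P, table) == pytest.approx(0.0, abs=1e-6)


class TestBic:
    def test_lower_loglik_higher_bic(self):
        spec = ModelSpec(3)
        assert bic(-1000.0, spec, 500) > bic(-900.0, spec, 500)

    def test_nested_specs_delta(self):
        N = 1000
        ci = ModelSpec(3)
        ext = ModelSpec(3, (InteractionTerm(0, 1, "both_distinct"),))
        assert bic(-500.0, ext, N) - bic(-500.0, ci, N) == pytest.approx(2 * math.log(N))


class TestNFreeParams:
    def test_k7_ci_is_15(self):
        assert n_free_params(ModelSpec(7)) == 15

    def test_k7_one_both_distinct_is_17(self):
        spec = ModelSpec(7, (InteractionTerm(3, 4, "both_distinct"),))
        assert n_free_params(spec) == 17

    def test_k1_is_3(self):
        assert n_free_params(ModelSpec(1)) == 3

    @pytest.mark.parametrize(
        "structure,extra",
        [("match_only", 1), ("nonmatch_only", 1), ("both_shared", 1), ("both_distinct", 2)],
    )
    def test_structure_increments(self, structure, extra):
        base = n_free_params(ModelSpec(4))
        spec = ModelSpec(4, (InteractionTerm(1, 2, structure),))
        assert n_free_params(spec) == base + extra


class TestMatchScore:
    def test_zero_when_classes_identical(self):
        cp = ClassicalParams(0.3, np.array([0.4, 0.6]), np.array([0.4, 0.6]))
        lam = classical_to_lambda(cp, 2)
        for pattern in ([0, 0], [0, 1], [1, 0], [1, 1]):
            assert match_score(lam, ModelSpec(2), pattern) == pytest.approx(0.0, abs=1e-9)

    def test_k1_closed_form(self):
        cp = ClassicalParams(0.5, np.array([0.8]), np.array([0.2]))
        lam = classical_to_lambda(cp, 1)
        assert match_score(lam, ModelSpec(1), [1]) == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_ci_equals_fs_weight_sum(self, K):
        rng = np.random.default_rng(K + 20)
        cp = ClassicalParams(
            rng.uniform(0.05, 0.5), rng.uniform(0.3, 0.9, K), rng.uniform(0.05, 0.4, K)
        )
        lam = classical_to_lambda(cp, K)
        Y = pattern_matrix(K)
        for pattern in Y:
            oracle = float(
                np.sum(
                    pattern * np.log2(cp.m / cp.u)
                    + (1 - pattern) * np.log2((1 - cp.m) / (1 - cp.u))
                )
            )
            assert match_score(lam, ModelSpec(K), pattern) == pytest.approx(oracle, abs=1e-9)

    def test_wrong_pattern_length(self):
        with pytest.raises(ValueError, match="length"):
            match_score(zero_lambda(2), ModelSpec(2), [1, 0, 1])


@settings(max_examples=30, deadline=None)
@given(
    K=st.integers(1, 5),
    seed=st.integers(0, 10_000),
)
def test_property_normalization_and_translation(K, seed):
    rng = np.random.default_rng(seed)
    lam = LambdaParams(rng.normal(), rng.normal(), rng.normal(size=K), rng.normal(size=K))
    spec = ModelSpec(K)
    P = pattern_probabilities(lam, spec)
    assert P.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(P > 0)
    c = rng.normal() * 5
    np.testing.assert_allclose(P, pattern_probabilities(lam.translated(c), spec), rtol=1e-9)
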