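import math

import numpy as np
import pytest

from linklcm import (
    AgreementPatternTable,
    FitOptions,
    InteractionTerm,
    ModelSpec,
    correlation_residuals,
    expected_correlations,
    fit_ml,
    flag_candidates,
    observed_correlations,
    plot_residuals,
)
from linklcm.model import pattern_matrix
from linklcm.synthetic import SimulationScenario, sample_table

FAST = FitOptions(n_starts=1, compute_se=False)


class TestObservedCorrelations:
    def test_perfect_agreement_correlation_one(self):
        # y_1 == y_2 on every pair
        table = AgreementPatternTable(2, np.array([40, 0, 0, 60]))
        rset = observed_correlations(table)
        assert rset.observed[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_counts_zero(self):
        table = AgreementPatternTable(2, np.array([10, 10, 10, 10]))
        assert observed_correlations(table).observed[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self, toy_table_k2):
        # f(11)=30, f(10)=10, f(01)=10, f(00)=50
        # p1 = p2 = 0.4, p12 = 0.3 -> (0.3 - 0.16)/sqrt(0.24 * 0.24)
        expected = (0.3 - 0.4 * 0.4) / math.sqrt(0.4 * 0.6 * 0.4 * 0.6)
        got = observed_correlations(toy_table_k2).observed[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.58333333, rel=1e-6)

    def test_degenerate_margin_nan_not_fatal(self):
        # field 1 never agrees -> undefined correlation, reported as NaN
        table = AgreementPatternTable(2, np.array([50, 50, 0, 0]))
        rset = observed_correlations(table)
        assert np.isnan(rset.observed[0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            observed_correlations(AgreementPatternTable(2, np.zeros(4, dtype=int)))

    def test_pair_count_and_order(self):
        table = AgreementPatternTable(4, np.arange(16) + 1)
        rset = observed_correlations(table)
        assert rset.pairs == ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        table = AgreementPatternTable(3, rng.integers(1, 100, 8))
        obs = observed_correlations(table).observed
        assert np.all(obs >= -1 - 1e-12) and np.all(obs <= 1 + 1e-12)


class TestExpectedCorrelations:
    def test_single_class_limit_near_zero(self):
        # pi tiny: mixture is essentially one CI class -> correlations ~ 0
        sc = SimulationScenario(
            K=2, pi=1e-6, m=np.array([0.9, 0.9]), u=np.array([0.3, 0.4]), N=10, seed=0
        )
        fit_like = _fit_from_scenario(sc)
        exp = expected_correlations(fit_like)
        assert abs(exp[0]) < 1e-5

    def test_two_class_ci_positive_correlation(self):
        # brute-force oracle over all 4 patterns for K=2
        pi, m, u = 0.2, np.array([0.8, 0.9]), np.array([0.1, 0.2])
        sc = SimulationScenario(K=2, pi=pi, m=m, u=u, N=10, seed=0)
        fit_like = _fit_from_scenario(sc)
        exp = expected_correlations(fit_like)[0]

        Y = pattern_matrix(2)
        P = pi * np.prod(m**Y * (1 - m) ** (1 - Y), axis=1) + (1 - pi) * np.prod(
            u**Y * (1 - u) ** (1 - Y), axis=1
        )
        p1 = P[Y[:, 0] == 1].sum()
        p2 = P[Y[:, 1] == 1].sum()
        p12 = P[(Y[:, 0] == 1) & (Y[:, 1] == 1)].sum()
        oracle = (p12 - p1 * p2) / math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        assert exp == pytest.approx(oracle, rel=1e-10)
        assert exp > 0

    def test_modeled_pair_residual_vanishes(self, dep_scenario_k4):
        table = sample_table(dep_scenario_k4)
        fit = fit_ml(table, dep_scenario_k4.spec, FAST)
        rset = correlation_residuals(table, fit)
        assert abs(rset.residual_of(1, 3)) < 0.01


def _fit_from_scenario(sc):
    """Wrap scenario truth in a FitResult-shaped object for diagnostics."""
    from linklcm.model import (
        FitResult,
        natural_to_classical,
        natural_to_lambda,
    )

    nat = sc.natural
    return FitResult(
        spec=sc.spec,
        lam=natural_to_lambda(nat, sc.spec, total=sc.N),
        natural=nat,
        classical=natural_to_classical(nat, sc.spec),
        se_classical=None,
        loglik=0.0,
        deviance=0.0,
        bic=0.0,
        converged=True,
        n_iter=0,
        N=sc.N,
    )


class TestCorrelationResiduals:
    def test_residual_is_observed_minus_expected(self, ci_scenario_k4):
        table = sample_table(ci_scenario_k4)
        fit = fit_ml(table, ci_scenario_k4.spec, FAST)
        rset = correlation_residuals(table, fit)
        np.testing.assert_allclose(rset.residual, rset.observed - rset.expected)

    def test_self_consistency_small_at_large_n(self):
        sc = SimulationScenario(
            K=5,
            pi=0.05,
            m=np.array([0.7, 0.8, 0.6, 0.75, 0.65]),
            u=np.array([0.1, 0.05, 0.2, 0.15, 0.1]),
            N=1_000_000,
            seed=21,
        )
        table = sample_table(sc)
        fit = fit_ml(table, sc.spec, FAST)
        rset = correlation_residuals(table, fit)
        assert np.nanmax(np.abs(rset.residual)) < 0.01

    def test_calibration_shrinks_with_n(self):
        maxima = {}
        for N in (10_000, 1_000_000):
            sc = SimulationScenario(
                K=4,
                pi=0.1,
                m=np.array([0.8, 0.7, 0.6, 0.9]),
                u=np.array([0.1, 0.05, 0.2, 0.3]),
                N=N,
                seed=5,
            )
            table = sample_table(sc)
            fit = fit_ml(table, sc.spec, FAST)
            maxima[N] = np.nanmax(np.abs(correlation_residuals(table, fit).residual))
        assert maxima[1_000_000] < maxima[10_000]

    def test_symmetry_via_field_swap(self, ci_scenario_k4):
        table = sample_table(ci_scenario_k4)
        fit = fit_ml(table, ci_scenario_k4.spec, FAST)
        rset = correlation_residuals(table, fit)
        assert rset.residual_of(0, 2) == rset.residual_of(2, 0)


class TestFlagCandidates:
    def test_all_below_threshold_empty(self, ci_scenario_k4):
        table = sample_table(ci_scenario_k4)
        fit = fit_ml(table, ci_scenario_k4.spec, FAST)
        rset = correlation_residuals(table, fit)
        assert flag_candidates(rset, threshold=0.5) == []

    def test_dependent_pair_flagged_first(self, dep_scenario_k7):
        table = sample_table(dep_scenario_k7)
        fit = fit_ml(table, ModelSpec(7), FAST)  # misspecified CI fit
        rset = correlation_residuals(table, fit)
        flags = flag_candidates(rset, threshold=0.05)
        assert flags
        assert flags[0][0] == (3, 4)

    def test_threshold_zero_returns_all_sorted(self, ci_scenario_k4):
        table = sample_table(ci_scenario_k4)
        fit = fit_ml(table, ci_scenario_k4.spec, FAST)
        rset = correlation_residuals(table, fit)
        flags = flag_candidates(rset, threshold=0.0)
        assert len(flags) == 6
        mags = [abs(v) for _, v in flags]
        assert mags == sorted(mags, reverse=True)


class TestPlotResiduals:
    def test_writes_nonempty_file(self, tmp_path, ci_scenario_k4):
        table = sample_table(ci_scenario_k4)
        fit = fit_ml(table, ci_scenario_k4.spec, FAST)
        rset = correlation_residuals(table, fit)
        out = tmp_path / "resid.png"
        plot_residuals(rset, out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_pairs_axes_only(self, tmp_path):
        from linklcm.diagnostics import ResidualSet

        rset = ResidualSet((), np.zeros(0), np.zeros(0), ("only",))
        out = tmp_path / "empty.png"
        plot_residuals(rset, out)
        assert out.exists()

    def test_multi_panel(self, tmp_path, dep_scenario_k4):
        table = sample_table(dep_scenario_k4)
        f0 = fit_ml(table, ModelSpec(4), FAST)
        f1 = fit_ml(table, dep_scenario_k4.spec, FAST)
        sets = [correlation_residuals(table, f) for f in (f0, f1)]
        out = tmp_path / "panels.png"
        plot_residuals(sets, out, titles=["Model 0", "Model I"])
        assert out.exists() and out.stat().st_size > 0
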