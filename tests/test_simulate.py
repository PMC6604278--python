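"""Generator tests: copula markers, calibrated truth, calibrated misclassification."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import prevcombine as pc
from prevcombine._bvn import bvn_cdf, orthant_prob
from prevcombine.simulate import (
    DependenceSpec,
    FeasibilityError,
    implied_cells,
    resolve_marker_prevalences,
)


def mvn_orthant(p1, p2, rho):
    """Independent oracle for the dichotomized-normal joint cell (quadrature CDF)."""
    from scipy.stats import norm

    h, k = norm.ppf(1 - p1), norm.ppf(1 - p2)
    return multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([-h, -k])


class TestBvn:
    @pytest.mark.parametrize(
        "h,k,rho",
        [(0.5, -0.3, 0.6), (1.4, 1.6, 0.85), (-2.0, 0.0, -0.4), (0.0, 0.0, 0.3)],
    )
    def test_owens_t_route_matches_quadrature(self, h, k, rho):
        ref = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([h, k])
        assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-8)

    def test_independence_factorizes(self):
        from scipy.special import ndtr

        assert bvn_cdf(0.7, -1.1, 0.0) == pytest.approx(ndtr(0.7) * ndtr(-1.1), abs=1e-12)


class TestMarkerCorrelation:
    def test_zero_exchangeable_is_identity(self):
        assert np.array_equal(
            pc.build_marker_correlation("exchangeable", 0.0, 8), np.eye(8)
        )

    def test_exchangeable_off_diagonals(self):
        mat = pc.build_marker_correlation("exchangeable", 0.20, 3)
        off = mat[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.20)
        assert np.allclose(np.diag(mat), 1.0)

    def test_unstructured_mean_and_positive_definite(self):
        mat = pc.build_marker_correlation("unstructured", 0.50, 16, seed=7)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.linalg.eigvalsh(mat).min() > 0
        off = mat[np.triu_indices(16, 1)]
        assert 0.49 <= off.mean() <= 0.51

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pc.build_marker_correlation("exchangeable", -0.1, 8)
        with pytest.raises(ValueError):
            pc.build_marker_correlation("diagonal", 0.1, 8)


class TestGenerateMarkers:
    def test_independent_moments(self):
        panel = pc.generate_markers(100_000, [0.5, 0.5], np.eye(2), seed=1)
        means = panel.values.mean(axis=0)
        assert np.all(np.abs(means - 0.5) < 0.005)
        assert abs(np.corrcoef(panel.values.T)[0, 1]) < 0.01

    def test_phi_attenuation_matches_orthant_oracle(self):
        # dichotomization attenuates the latent correlation; the binary (phi)
        # correlation must match the bivariate-normal orthant computation
        rho, p = 0.99, 0.3
        panel = pc.generate_markers(100_000, [p, p], [[1, rho], [rho, 1]], seed=2)
        phi_emp = np.corrcoef(panel.values.T)[0, 1]
        p11 = mvn_orthant(p, p, rho)
        phi_exact = (p11 - p * p) / (p * (1 - p))
        assert 0.9 < phi_emp < 0.99
        assert phi_emp == pytest.approx(phi_exact, abs=0.01)

    def test_deterministic_under_seed(self):
        a = pc.generate_markers(10, [0.3, 0.6], np.eye(2), seed=5)
        b = pc.generate_markers(10, [0.3, 0.6], np.eye(2), seed=5)
        assert np.array_equal(a.values, b.values)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pc.generate_markers(10, [0.3, 0.6, 0.2], np.eye(2), seed=0)


class TestTruthModel:
    def test_intercept_closed_form_when_coefficients_vanish(self):
        panel = pc.generate_markers(1000, [0.5, 0.5], np.eye(2), seed=3)
        b0 = pc.calibrate_intercept(np.zeros(2), panel, 0.20, tol=1e-10)
        assert b0 == pytest.approx(np.log(0.20 / 0.80), abs=1e-6)
        b0 = pc.calibrate_intercept(np.zeros(2), panel, 0.10, tol=1e-10)
        assert b0 == pytest.approx(np.log(1 / 9), abs=1e-6)

    def test_intercept_round_trip(self):
        from scipy.special import expit

        panel = pc.generate_markers(5000, [0.5, 0.5], np.eye(2), seed=4)
        coefs = np.array([0.5, 0.5])
        b0 = pc.calibrate_intercept(coefs, panel, 0.2, tol=1e-8)
        mean = expit(b0 + panel.values @ coefs).mean()
        assert mean == pytest.approx(0.2, abs=1e-6)

    def test_truth_saturates_and_matches_target(self):
        panel = pc.generate_markers(100_000, [0.3], np.eye(1), seed=5)
        all_one = pc.generate_truth(
            panel, pc.DiseaseModel(50.0, np.zeros(1)), seed=0
        )
        assert all_one.all()
        target = pc.generate_truth(
            panel, pc.DiseaseModel(float(np.log(0.25)), np.zeros(1)), seed=0
        )
        assert 0.195 < target.mean() < 0.205

    def test_positive_coefficient_raises_risk(self):
        panel = pc.generate_markers(100_000, [0.3], np.eye(1), seed=6)
        model = pc.DiseaseModel(-2.0, np.array([1.0]))
        truth = pc.generate_truth(panel, model, seed=1)
        pos = panel.values[:, 0] == 1
        assert truth[pos].mean() > truth[~pos].mean()


class TestAccuracyCalibration:
    def test_marginal_constraint_algebra(self):
        assert pc.solve_sensitivity(0.18, 0.20, 0.95) == pytest.approx(0.70)
        assert pc.solve_sensitivity(0.10, 0.10, 1.0) == pytest.approx(1.0)
        with pytest.raises(FeasibilityError):
            pc.solve_sensitivity(0.05, 0.10, 0.90)  # false-positive floor above target

    @pytest.mark.parametrize(
        "cond",
        [
            pc.SimulationCondition(0.20, 0.18, 0.15, 0.85),
            pc.SimulationCondition(0.10, 0.08, 0.05, 0.85),
            pc.SimulationCondition(0.10, 0.05, 0.05, 0.65),
        ],
        ids=["p20-85", "p10-85", "p10-65"],
    )
    def test_exact_margins_and_correlation(self, cond):
        acc1, acc2, dep = pc.calibrate_accuracy(cond)
        cells = implied_cells(cond.true_prev, acc1, acc2, dep)
        m1 = cells[1, :].sum()
        m2 = cells[:, 1].sum()
        assert m1 == pytest.approx(cond.obs_prev_1, abs=1e-9)
        assert m2 == pytest.approx(cond.obs_prev_2, abs=1e-9)
        # tetrachoric of the implied table equals the target (quadrature oracle)
        from scipy.optimize import brentq

        tet = brentq(
            lambda r: mvn_orthant(m1, m2, r) - cells[1, 1], -0.999, 0.999, xtol=1e-8
        )
        assert tet == pytest.approx(cond.source_corr, abs=0.01)

    def test_residual_dependence_path(self):
        # a correlation target above the conditional-independence range
        cond = pc.SimulationCondition(0.10, 0.08, 0.05, 0.92)
        acc1, acc2, dep = pc.calibrate_accuracy(cond)
        assert dep.error_corr_diseased > 0
        cells = implied_cells(cond.true_prev, acc1, acc2, dep)
        from scipy.optimize import brentq

        tet = brentq(
            lambda r: mvn_orthant(cond.obs_prev_1, cond.obs_prev_2, r) - cells[1, 1],
            -0.999,
            0.999,
        )
        assert tet == pytest.approx(0.92, abs=0.01)

    def test_infeasible_correlation_names_range(self):
        # near-perfect fixed specificities force strong agreement through the
        # disease signal; a zero-correlation target is then unattainable
        with pytest.raises(FeasibilityError, match="attainable"):
            pc.calibrate_accuracy(
                pc.SimulationCondition(0.10, 0.08, 0.05, 0.0),
                specificity_override=(0.999, 0.999),
            )

    def test_specificity_override_reproduces_fixed_closure(self):
        cond = pc.SimulationCondition(0.20, 0.18, 0.15, 0.85)
        acc1, acc2, _ = pc.calibrate_accuracy(cond, specificity_override=(0.95, 0.90))
        assert acc1.sensitivity == pytest.approx(0.70)
        assert acc1.specificity == 0.95
        assert acc2.sensitivity == pytest.approx(0.35)

    def test_monte_carlo_round_trip(self):
        cond = pc.SimulationCondition(
            0.20, 0.18, 0.15, 0.85, population_size=200_000
        )
        acc1, acc2, dep = pc.calibrate_accuracy(cond)
        gen = np.random.default_rng(9)
        truth = (gen.random(200_000) < cond.true_prev).astype(np.int8)
        src = pc.apply_misclassification(truth, acc1, acc2, dep, seed=gen)
        assert abs(src.y1.mean() - 0.18) < 0.005
        assert abs(src.y2.mean() - 0.15) < 0.005
        tet = pc.tetrachoric_correlation(src.y1, src.y2)
        assert abs(tet.rho - 0.85) < 0.03


class TestMisclassification:
    def test_perfect_tests_reproduce_truth(self):
        truth = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        acc = pc.AccuracySpec(1.0, 1.0)
        src = pc.apply_misclassification(truth, acc, acc, seed=0)
        assert np.array_equal(src.y1, truth)
        assert np.array_equal(src.y2, truth)

    def test_marginal_accuracy_preserved(self):
        gen = np.random.default_rng(10)
        truth = (gen.random(200_000) < 0.2).astype(np.int8)
        acc = pc.AccuracySpec(0.72, 0.95)
        src = pc.apply_misclassification(truth, acc, acc, seed=gen)
        sn_emp = src.y1[truth == 1].mean()
        sp_emp = 1 - src.y1[truth == 0].mean()
        assert abs(sn_emp - 0.72) < 0.005
        assert abs(sp_emp - 0.95) < 0.005

    def test_conditional_independence_when_uncorrelated(self):
        gen = np.random.default_rng(11)
        truth = (gen.random(200_000) < 0.2).astype(np.int8)
        acc = pc.AccuracySpec(0.72, 0.95)
        src = pc.apply_misclassification(truth, acc, acc, DependenceSpec(0, 0), seed=gen)
        for d in (0, 1):
            mask = truth == d
            corr = np.corrcoef(src.y1[mask], src.y2[mask])[0, 1]
            assert abs(corr) < 0.01

    def test_phi_bounded_by_conditional_independence_limit(self):
        # with independent errors the binary correlation cannot exceed the
        # value implied analytically by the joint cells
        gen = np.random.default_rng(12)
        prev = 0.2
        truth = (gen.random(200_000) < prev).astype(np.int8)
        acc1, acc2 = pc.AccuracySpec(0.8, 0.97), pc.AccuracySpec(0.65, 0.98)
        src = pc.apply_misclassification(truth, acc1, acc2, seed=gen)
        cells = implied_cells(prev, acc1, acc2, DependenceSpec(0, 0))
        m1, m2, p11 = cells[1, :].sum(), cells[:, 1].sum(), cells[1, 1]
        bound = (p11 - m1 * m2) / np.sqrt(m1 * (1 - m1) * m2 * (1 - m2))
        phi_emp = np.corrcoef(src.y1, src.y2)[0, 1]
        assert phi_emp <= bound + 0.01
        assert phi_emp == pytest.approx(bound, abs=0.01)

    def test_dependent_errors_raise_agreement(self):
        gen = np.random.default_rng(13)
        truth = (gen.random(100_000) < 0.2).astype(np.int8)
        acc = pc.AccuracySpec(0.72, 0.95)
        indep = pc.apply_misclassification(truth, acc, acc, seed=1)
        dep = pc.apply_misclassification(
            truth, acc, acc, DependenceSpec(0.9, 0.9), seed=1
        )
        agree_i = (indep.y1 == indep.y2).mean()
        agree_d = (dep.y1 == dep.y2).mean()
        assert agree_d > agree_i


class TestConditionPlumbing:
    def test_replication_is_bit_identical_under_seed(self, flagship_condition):
        a = pc.simulate_condition(flagship_condition, seed=123)
        b = pc.simulate_condition(flagship_condition, seed=123)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[2].y1, b[2].y1)
        assert np.array_equal(a[2].y2, b[2].y2)

    def test_condition_seed_stable_and_distinct(self, flagship_condition):
        s1 = pc.condition_seed(flagship_condition, 5)
        s2 = pc.condition_seed(flagship_condition, 5)
        assert s1 == s2
        other = pc.SimulationCondition(0.20, 0.18, 0.15, 0.65)
        assert pc.condition_seed(other, 5) != s1

    def test_marker_prevalences_drawn_once_in_range(self, flagship_condition):
        p1 = resolve_marker_prevalences(flagship_condition)
        p2 = resolve_marker_prevalences(flagship_condition)
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0.05) & (p1 <= 0.35))

    def test_marginals_recovered_at_scale(self):
        cond = pc.SimulationCondition(
            0.10, 0.08, 0.07, 0.85, population_size=200_000
        )
        panel, truth, src = pc.simulate_condition(cond, seed=77)
        assert abs(truth.mean() - 0.10) < 0.005
        assert abs(src.y1.mean() - 0.08) < 0.005
        assert abs(src.y2.mean() - 0.07) < 0.005

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            pc.SimulationCondition(0.0, 0.1, 0.1, 0.5)
        with pytest.raises(ValueError):
            pc.SimulationCondition(0.2, 0.1, 0.1, 1.5)
        with pytest.raises(ValueError):
            pc.SimulationCondition(0.2, 0.1, 0.1, 0.5, marker_corr_pattern="banded")
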