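"""Partial credit model estimation, WLE, information, IRT curves."""

import itertools

import numpy as np
import pytest

from cutrel import (
    CohortSpec,
    EstimationSettings,
    ExamGeneratorConfig,
    expected_percent_score,
    fit_pcm,
    generate_exam_spec,
    irt_crel_curve,
    percent_to_theta,
    separation_index,
    simulate_responses,
    wle_theta,
)
from cutrel.irt import (  # noqa: F401
    PCMFit,
    ThetaEstimates,
    UnidentifiedItemError,
    marginal_log_likelihood,
)
from cutrel.irt import test_information as information_curve
from cutrel.synthetic import ExamSpec, ItemSpec

from conftest import dichotomous_items, make_matrix


def symmetric_fit(k: int = 4) -> PCMFit:
    """A converged fit object with all dichotomous steps at zero."""
    return PCMFit(
        item_ids=[f"i{j + 1}" for j in range(k)],
        item_kinds=["typeA"] * k,
        item_params=[np.array([0.0])] * k,
        latent_sd=1.0,
        log_likelihood=0.0,
        converged=True,
        n_iter=1,
        iteration_trace=np.array([0.0]),
        n_quadrature=41,
        quadrature_range=(-6.0, 6.0),
    )


class TestFitPcm:
    def test_swapped_identical_columns_get_equal_difficulty(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, size=200).astype(float)
        other = rng.integers(0, 2, size=200).astype(float)
        matrix = make_matrix(
            np.column_stack([col, other, col]), kinds=["typeA"] * 3
        )
        fit = fit_pcm(matrix)
        assert fit.item_params[0][0] == pytest.approx(fit.item_params[2][0], abs=1e-6)

    def test_em_trace_monotone(self, mixed_fit):
        _, fit, _ = mixed_fit
        assert np.all(np.diff(fit.iteration_trace) >= -1e-8)
        assert fit.converged

    def test_em_beats_exhaustive_grid_two_items(self):
        """EM optimum matches a full 0.05-step grid search (2 dichotomous
        items, latent sd fixed at 1 in both routes)."""
        exam = ExamSpec("g", dichotomous_items([-0.6, 0.9]), 50.0)
        responses = simulate_responses(exam, CohortSpec(n_examinees=150), seed=8)
        settings = EstimationSettings(estimate_latent_sd=False, tol=1e-9)
        fit = fit_pcm(responses, settings)
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.05)
        best = -np.inf
        for b1, b2 in itertools.product(grid, grid):
            ll = marginal_log_likelihood(
                responses, [[b1], [b2]], latent_sd=1.0, settings=settings
            )
            best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-4

    def test_em_beats_grid_profiles_five_items(self):
        """On 5 items x 200 examinees the EM optimum dominates 0.05-step
        scans through each parameter and a cloud of random probes."""
        exam = ExamSpec("g5", dichotomous_items([-1.5, -0.5, 0.0, 0.5, 1.5]), 50.0)
        responses = simulate_responses(exam, CohortSpec(n_examinees=200), seed=15)
        settings = EstimationSettings(estimate_latent_sd=False, tol=1e-9)
        fit = fit_pcm(responses, settings)
        at_fit = [p.copy() for p in fit.item_params]
        best = -np.inf
        for j in range(5):  # coordinate profiles through the optimum
            for offset in np.arange(-1.0, 1.0 + 1e-9, 0.05):
                params = [p.copy() for p in at_fit]
                params[j] = params[j] + offset
                ll = marginal_log_likelihood(responses, params, 1.0, settings)
                best = max(best, ll)
        rng = np.random.default_rng(99)
        for _ in range(2000):  # random probes across the box
            params = [np.array([b]) for b in rng.uniform(-3, 3, size=5)]
            best = max(best, marginal_log_likelihood(responses, params, 1.0, settings))
        assert fit.log_likelihood >= best - 1e-4

    def test_parameter_recovery_improves_with_sample_size(self):
        exam = generate_exam_spec(
            ExamGeneratorConfig(n_items=20, mtf_fraction=0.3), seed=40
        )
        true = np.concatenate([it.step_params for it in exam.items])
        rmse = {}
        for n in (250, 1000):
            responses = simulate_responses(exam, CohortSpec(n_examinees=n), seed=41)
            fit = fit_pcm(responses)
            est = np.concatenate(fit.item_params)
            rmse[n] = float(np.sqrt(np.mean((est - true) ** 2)))
        assert rmse[1000] < rmse[250]
        assert rmse[1000] < 0.15

    def test_unidentified_item_is_named(self):
        matrix = make_matrix(
            [[1, 1], [1, 0], [1, 1], [1, 0]], kinds=["typeA"] * 2
        )
        with pytest.raises(UnidentifiedItemError, match="i1"):
            fit_pcm(matrix)

    def test_non_convergence_is_flagged_not_silent(self, mixed_fit):
        responses, _, _ = mixed_fit
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_pcm(responses, EstimationSettings(max_iter=3))
        assert not fit.converged


class TestWle:
    def test_symmetric_half_score_maps_to_zero(self):
        fit = symmetric_fit(k=4)
        matrix = make_matrix(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]], kinds=["typeA"] * 4
        )
        estimates = wle_theta(fit, matrix)
        assert np.allclose(estimates.theta, 0.0, atol=1e-6)

    def test_finite_estimates_at_zero_and_perfect_scores(self):
        fit = symmetric_fit(k=6)
        matrix = make_matrix(
            [[0] * 6, [1] * 6, [1, 0, 0, 0, 0, 0]], kinds=["typeA"] * 6
        )
        estimates = wle_theta(fit, matrix)
        assert np.all(np.isfinite(estimates.theta))
        assert np.all(estimates.se_theta > 0)
        assert estimates.theta[0] < -1 and estimates.theta[1] > 1

    def test_identical_patterns_identical_estimates(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        weights = fit.point_weights
        cats = np.rint(responses.scores.to_numpy() / weights)
        totals = cats.sum(axis=1)  # category totals are sufficient for theta
        order = np.argsort(totals)
        same = np.diff(totals[order]) == 0
        th = estimates.theta[order]
        se = estimates.se_theta[order]
        assert np.allclose(np.diff(th)[same], 0.0)
        assert np.allclose(np.diff(se)[same], 0.0)

    def test_wle_finite_on_real_fit_extremes(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        assert np.all(np.isfinite(estimates.theta))
        assert np.all(estimates.se_theta > 0)


class TestInformation:
    def test_single_item_information_quarter_at_difficulty(self):
        fit = symmetric_fit(k=1)
        curve = information_curve(fit, np.array([0.0]))
        assert curve.info[0] == pytest.approx(0.25)
        assert curve.csem_theta[0] == pytest.approx(2.0)

    def test_additivity_over_items(self):
        grid = np.linspace(-3, 3, 13)
        one = symmetric_fit(k=1)
        two = symmetric_fit(k=2)
        assert np.allclose(
            information_curve(two, grid).info, 2 * information_curve(one, grid).info
        )

    def test_inverse_square_root_identity(self, mixed_fit):
        _, fit, _ = mixed_fit
        grid = np.linspace(-4, 4, 21)
        curve = information_curve(fit, grid)
        assert np.allclose(curve.csem_theta, np.sqrt(1.0 / curve.info))

    def test_empty_grid_rejected(self, mixed_fit):
        _, fit, _ = mixed_fit
        with pytest.raises(ValueError):
            information_curve(fit, np.array([]))


class TestTcc:
    def test_floor_ceiling_and_symmetry(self):
        fit = symmetric_fit(k=5)
        assert expected_percent_score(fit, -10.0) == pytest.approx(0.0, abs=0.01)
        assert expected_percent_score(fit, 10.0) == pytest.approx(100.0, abs=0.01)
        assert expected_percent_score(fit, 0.0) == pytest.approx(50.0)

    def test_strictly_increasing_and_invertible(self, mixed_fit):
        _, fit, _ = mixed_fit
        grid = np.linspace(-6, 6, 200)
        tcc = expected_percent_score(fit, grid)
        assert np.all(np.diff(tcc) > 0)
        for theta in (-2.0, -0.3, 1.7):
            pct = expected_percent_score(fit, theta)
            assert percent_to_theta(fit, pct) == pytest.approx(theta, abs=1e-6)


class TestSeparationAndCurve:
    def test_error_free_limit_and_zero_point(self):
        theta = np.array([-1.0, 0.0, 1.0, 2.0])
        tiny = ThetaEstimates(theta=theta, se_theta=np.full(4, 1e-9))
        assert separation_index(tiny) == pytest.approx(1.0)
        var = np.var(theta, ddof=1)
        matched = ThetaEstimates(theta=theta, se_theta=np.full(4, np.sqrt(var)))
        assert separation_index(matched) == pytest.approx(0.0)

    def test_separation_close_to_alpha_on_synthetic_exam(self):
        from cutrel import cronbach_alpha

        exam = generate_exam_spec(
            ExamGeneratorConfig(n_items=100, mtf_fraction=0.3), seed=50
        )
        responses = simulate_responses(exam, CohortSpec(n_examinees=260), seed=51)
        fit = fit_pcm(responses)
        estimates = wle_theta(fit, responses)
        assert separation_index(estimates) == pytest.approx(
            cronbach_alpha(responses), abs=0.05
        )

    def test_crel_standardisation_identity(self, mixed_fit):
        _, fit, estimates = mixed_fit
        curve = irt_crel_curve(fit, estimates)
        var = estimates.variance
        assert np.allclose(curve.crel, (var - curve.csem**2) / var)
        assert curve.crel.max() <= 1.0
        # where csem^2 equals the ability variance the curve crosses zero
        gap = var - curve.csem**2
        assert np.all(np.sign(curve.crel) == np.sign(gap))

    def test_doubling_items_never_lowers_crel(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        doubled = PCMFit(
            item_ids=fit.item_ids + [f"{i}b" for i in fit.item_ids],
            item_kinds=fit.item_kinds * 2,
            item_params=[p.copy() for p in fit.item_params] * 2,
            latent_sd=fit.latent_sd,
            log_likelihood=0.0,
            converged=True,
            n_iter=1,
            iteration_trace=np.array([0.0]),
            n_quadrature=fit.n_quadrature,
            quadrature_range=fit.quadrature_range,
        )
        grid = np.linspace(-4, 4, 41)
        base = irt_crel_curve(fit, estimates, grid)
        more = irt_crel_curve(doubled, estimates, grid)
        assert np.all(more.crel >= base.crel - 1e-12)
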