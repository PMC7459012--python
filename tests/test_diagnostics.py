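"""Fit diagnostics: Q3, infit/outfit, SRMR/SRMSR, misfit rates."""

import numpy as np
import pandas as pd
import pytest

from cutrel import (
    CohortSpec,
    ExamGeneratorConfig,
    fit_pcm,
    generate_exam_spec,
    simulate_responses,
    wle_theta,
)
from cutrel.diagnostics import (
    fit_report,
    implied_correlations,
    infit_outfit,
    misfit_rate,
    q3_statistic,
    residual_correlation_summaries,
    srmr_srmsr,
)
from cutrel.synthetic import ResponseMatrix

from conftest import make_matrix


class TestQ3:
    def test_duplicated_item_pair_correlates_perfectly(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        frame = responses.scores.copy()
        frame["dup"] = frame.iloc[:, 0]
        doubled = ResponseMatrix(frame, responses.item_kinds + [responses.item_kinds[0]])
        from cutrel.irt import PCMFit

        fit2 = PCMFit(
            item_ids=fit.item_ids + ["dup"],
            item_kinds=fit.item_kinds + [fit.item_kinds[0]],
            item_params=fit.item_params + [fit.item_params[0].copy()],
            latent_sd=fit.latent_sd,
            log_likelihood=0.0,
            converged=True,
            n_iter=1,
            iteration_trace=np.array([0.0]),
            n_quadrature=fit.n_quadrature,
            quadrature_range=fit.quadrature_range,
        )
        q3 = q3_statistic(fit2, doubled, estimates)
        first = fit.item_ids[0]
        assert q3.matrix.loc[first, "dup"] == pytest.approx(1.0)
        assert q3.max == pytest.approx(1.0)

    def test_mean_signed_q3_near_negative_one_over_k_minus_one(self):
        # locally independent data: signed Q3 centres near -1/(k-1)
        exam = generate_exam_spec(
            ExamGeneratorConfig(n_items=60, mtf_fraction=0.3), seed=60
        )
        responses = simulate_responses(exam, CohortSpec(n_examinees=500), seed=61)
        fit = fit_pcm(responses)
        estimates = wle_theta(fit, responses)
        q3 = q3_statistic(fit, responses, estimates)
        assert q3.mean_signed == pytest.approx(-1.0 / 59, abs=0.01)
        assert 0.02 <= q3.mean_abs <= 0.10

    def test_symmetry_and_bounds(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        q3 = q3_statistic(fit, responses, estimates)
        mat = q3.matrix.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        off = mat[np.triu_indices_from(mat, k=1)]
        assert np.all((off >= -1) & (off <= 1))


class TestInfitOutfit:
    def test_relabeling_examinees_is_invariant(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        base = infit_outfit(fit, responses, estimates).table
        perm = np.random.default_rng(3).permutation(responses.n_examinees)
        from cutrel.irt import ThetaEstimates

        shuffled = ResponseMatrix(
            responses.scores.iloc[perm], list(responses.item_kinds)
        )
        est_perm = ThetaEstimates(
            theta=estimates.theta[perm], se_theta=estimates.se_theta[perm]
        )
        other = infit_outfit(fit, shuffled, est_perm).table
        pd.testing.assert_frame_equal(base, other)

    def test_coin_flip_item_flagged_by_outfit(self):
        exam = generate_exam_spec(
            ExamGeneratorConfig(n_items=40, mtf_fraction=0.0), seed=70
        )
        responses = simulate_responses(exam, CohortSpec(n_examinees=600), seed=71)
        rng = np.random.default_rng(72)
        frame = responses.scores.copy()
        noisy = frame.columns[0]
        frame[noisy] = rng.integers(0, 2, size=len(frame)).astype(float)
        tampered = ResponseMatrix(frame, list(responses.item_kinds))
        fit = fit_pcm(tampered)
        estimates = wle_theta(fit, tampered)
        stats = infit_outfit(fit, tampered, estimates).table
        assert stats.loc[noisy, "outfit"] > 1.2

    def test_degenerate_constant_exam_reported_unavailable(self):
        # all residuals zero: mean squares are not estimable, not faked
        from cutrel.irt import PCMFit, ThetaEstimates

        k = 3
        fit = PCMFit(
            item_ids=[f"i{j + 1}" for j in range(k)],
            item_kinds=["typeA"] * k,
            item_params=[np.array([-8.0])] * k,  # everyone succeeds
            latent_sd=1.0,
            log_likelihood=0.0,
            converged=True,
            n_iter=1,
            iteration_trace=np.array([0.0]),
            n_quadrature=41,
            quadrature_range=(-6.0, 6.0),
        )
        matrix = make_matrix(np.ones((4, k)), kinds=["typeA"] * k)
        estimates = ThetaEstimates(
            theta=np.array([2.0, 2.0, 2.0, 2.0]), se_theta=np.ones(4)
        )
        result = infit_outfit(fit, matrix, estimates)
        # model variance ~e^-10 > 0, residuals ~0: mean squares collapse to ~0
        assert result.table["outfit"].max() < 0.01


class TestSrmr:
    def test_zero_when_observed_equals_implied(self):
        corr = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        srmr, srmsr = residual_correlation_summaries(corr, corr)
        assert srmr == 0.0 and srmsr == 0.0

    def test_small_under_true_model_large_n(self):
        exam = generate_exam_spec(
            ExamGeneratorConfig(n_items=25, mtf_fraction=0.3), seed=80
        )
        responses = simulate_responses(exam, CohortSpec(n_examinees=5000), seed=81)
        fit = fit_pcm(responses)
        result = srmr_srmsr(fit, responses)
        assert result.srmsr < 0.05
        assert result.srmr <= result.srmsr

    def test_srmsr_dominates_srmr(self, mixed_fit):
        responses, fit, _ = mixed_fit
        result = srmr_srmsr(fit, responses)
        assert result.srmsr >= result.srmr >= 0

    def test_implied_matrix_is_valid_correlation(self, mixed_fit):
        _, fit, _ = mixed_fit
        implied = implied_correlations(fit)
        assert np.allclose(np.diag(implied), 1.0)
        assert np.all(np.abs(implied) <= 1.0 + 1e-12)
        assert np.allclose(implied, implied.T)


class TestMisfitRate:
    def test_arithmetic(self):
        inside = np.full(57, 1.0)
        values = np.concatenate([inside, [0.5, 1.5, 2.0]])
        assert misfit_rate(values) == pytest.approx(5.0)
        assert misfit_rate(inside) == 0.0

    def test_custom_bounds_and_nan_handling(self):
        values = np.array([0.85, 1.1, np.nan])
        assert misfit_rate(values, (0.9, 1.2)) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            misfit_rate(values, (1.2, 0.8))

    def test_outfit_flags_more_than_infit_under_misfit_injection(self):
        # replace 10% of items by coin flips: outfit is the outlier-
        # sensitive statistic, so it should flag at least as many items
        exam = generate_exam_spec(
            ExamGeneratorConfig(n_items=30, mtf_fraction=0.0), seed=90
        )
        responses = simulate_responses(exam, CohortSpec(n_examinees=500), seed=91)
        rng = np.random.default_rng(92)
        frame = responses.scores.copy()
        for col in frame.columns[:3]:
            frame[col] = rng.integers(0, 2, size=len(frame)).astype(float)
        tampered = ResponseMatrix(frame, list(responses.item_kinds))
        fit = fit_pcm(tampered)
        estimates = wle_theta(fit, tampered)
        stats = infit_outfit(fit, tampered, estimates).table
        assert misfit_rate(stats["outfit"]) >= misfit_rate(stats["infit"])


class TestFitReport:
    def test_report_row_is_complete(self, mixed_fit):
        responses, fit, estimates = mixed_fit
        report = fit_report(fit, responses, estimates)
        row = report.to_row()
        assert set(row) == {
            "q3_mean", "q3_mean_signed", "q3_min", "q3_max",
            "infit_min", "infit_max", "infit_mean", "pct_misfit_infit",
            "outfit_min", "outfit_max", "outfit_mean", "pct_misfit_outfit",
            "srmr", "srmsr",
        }
        assert report.infit_mean == pytest.approx(1.0, abs=0.1)
        assert report.outfit_mean == pytest.approx(1.0, abs=0.15)
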