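"""End-to-end driver: simulate, analyse per exam, compare across exams.

Per exam: totals -> alpha -> CTT curve; PCM fit -> fit diagnostics ->
WLE abilities -> information -> IRT curve; both curves are read off at
the cut score into one :class:`CutScoreReport` row.  Across exams: the
theory ANOVA, the stacked interaction regression and the collinearity
screen.  A failing exam is logged and skipped; it never takes the study
down with it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as an
from . import ctt, diagnostics, io, irt
from .config import StudyConfig
from .curves import ConditionalReliabilityCurve
from .synthetic import ExamSpec, ResponseMatrix, StudyData, generate_study

logger = logging.getLogger("cutrel")


@dataclass
class ExamAnalysis:
    """Everything computed for one exam."""

    exam: ExamSpec
    summary: ctt.ScoreSummary
    alpha: float
    ctt_curve: ConditionalReliabilityCurve
    fit: irt.PCMFit
    estimates: irt.ThetaEstimates
    irt_curve: ConditionalReliabilityCurve
    fit_report: diagnostics.FitReport
    report: an.CutScoreReport


def analyze_exam(
    exam: ExamSpec,
    responses: ResponseMatrix,
    estimation: irt.EstimationSettings | None = None,
    misfit_bounds: tuple[float, float] = (0.8, 1.2),
    theta_grid_points: int = 121,
    drop_items: list[str] | None = None,
) -> ExamAnalysis:
    """Run both frameworks on one exam and assemble its report row.

    Mean conditional reliability is averaged over achieved scores: each
    examinee contributes the curve value at their own percent score
    (CTT) or ability estimate (IRT).  Maxima are taken over the curve
    grid.
    """
    if drop_items:
        exam = exam.drop_items(drop_items)
        responses = responses.drop_items(drop_items)
    responses.validate()
    summary = ctt.total_scores(responses)
    alpha = ctt.cronbach_alpha(responses)
    ctt_curve = ctt.ctt_crel_curve(summary)
    fit = irt.fit_pcm(responses, estimation)
    estimates = irt.wle_theta(fit, responses)
    grid = np.linspace(*fit.quadrature_range, theta_grid_points)
    irt_curve = irt.irt_crel_curve(fit, estimates, grid)
    freport = diagnostics.fit_report(fit, responses, estimates, misfit_bounds)
    crel_ctt_at_scores = np.interp(
        summary.percent_score, ctt_curve.score_grid, ctt_curve.crel
    )
    crel_irt_at_thetas = irt.crel_at_theta(fit, estimates, estimates.theta)
    report = an.CutScoreReport(
        exam_id=exam.exam_id,
        crel_cut_ctt=an.crel_at_cut(ctt_curve, exam.cut_percent),
        crel_cut_irt=an.crel_at_cut(irt_curve, exam.cut_percent),
        crel_max_ctt=float(ctt_curve.crel.max()),
        crel_max_irt=float(irt_curve.crel.max()),
        crel_mean_ctt=float(crel_ctt_at_scores.mean()),
        crel_mean_irt=float(crel_irt_at_thetas.mean()),
        alpha=alpha,
        separation=irt.separation_index(estimates),
        perf_range=an.performance_range(summary),
        cut_percent=exam.cut_percent,
        n_items=exam.n_items,
        pct_mtf=exam.pct_mtf,
        school=exam.school,
        year_of_study=exam.year_of_study,
    )
    return ExamAnalysis(
        exam=exam,
        summary=summary,
        alpha=alpha,
        ctt_curve=ctt_curve,
        fit=fit,
        estimates=estimates,
        irt_curve=irt_curve,
        fit_report=freport,
        report=report,
    )


@dataclass
class StudyResult:
    """Per-exam analyses plus the study-level comparison."""

    config: StudyConfig
    data: StudyData
    exams: list[ExamAnalysis]
    failed: list[tuple[str, str]]  # (exam_id, error message)
    reports: pd.DataFrame
    fit_reports: pd.DataFrame
    comparison: an.ComparisonResult


def analyze_study(config: StudyConfig, data: StudyData) -> StudyResult:
    analyses: list[ExamAnalysis] = []
    failed: list[tuple[str, str]] = []
    for exam, responses in data:
        try:
            logger.info("exam %s: analysing (%d examinees, %d items)",
                        exam.exam_id, responses.n_examinees, exam.n_items)
            result = analyze_exam(
                exam,
                responses,
                estimation=config.estimation,
                misfit_bounds=config.analysis.misfit_bounds,
                theta_grid_points=config.analysis.theta_grid_points,
                drop_items=config.drop_items.get(exam.exam_id),
            )
            analyses.append(result)
        except Exception as err:  # noqa: BLE001 - one exam must not kill the study
            logger.error("exam %s: failed: %s", exam.exam_id, err)
            failed.append((exam.exam_id, str(err)))
    if not analyses:
        raise RuntimeError("every exam failed; nothing to compare")
    reports = an.reports_to_frame([a.report for a in analyses])
    fit_rows = pd.DataFrame(
        [a.fit_report.to_row() for a in analyses],
        index=[a.exam.exam_id for a in analyses],
    )
    comparison = an.compare_theories(reports, alpha=config.analysis.alpha)
    return StudyResult(
        config=config,
        data=data,
        exams=analyses,
        failed=failed,
        reports=reports,
        fit_reports=fit_rows,
        comparison=comparison,
    )


def run_pipeline(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Simulate a study from the config's seed and analyse it end to end.

    With ``out_dir`` set, writes the full output tree: per-exam
    responses/metadata/curves, the manifest, the report and fit tables,
    the comparison outputs, the mean-curve figure with its backing CSV,
    and an echo of the resolved config for provenance.
    """
    data = generate_study(config.generator, config.seed)
    result = analyze_study(config, data)
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: StudyResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    exams_dir = out / "exams"
    exams_dir.mkdir(exist_ok=True)
    for (exam, responses) in result.data:
        io.write_responses(responses, exams_dir / f"{exam.exam_id}_responses.csv")
        io.write_exam_spec(exam, exams_dir / f"{exam.exam_id}_meta.json")
    for a in result.exams:
        io.write_curve_csv(a.ctt_curve, exams_dir / f"{a.exam.exam_id}_ctt_curve.csv")
        io.write_curve_csv(a.irt_curve, exams_dir / f"{a.exam.exam_id}_irt_curve.csv")
        fit_meta = {
            "exam_id": a.exam.exam_id,
            "item_params": {
                i: list(p) for i, p in zip(a.fit.item_ids, a.fit.item_params)
            },
            "latent_sd": a.fit.latent_sd,
            "log_likelihood": a.fit.log_likelihood,
            "converged": bool(a.fit.converged),
            "n_iter": a.fit.n_iter,
        }
        (exams_dir / f"{a.exam.exam_id}_fit.json").write_text(
            json.dumps(fit_meta, indent=1)
        )
    io.write_tsv(result.data.manifest.reset_index(), out / "manifest.tsv")
    io.write_tsv(result.reports, out / "reports.tsv")
    io.write_tsv(result.fit_reports.reset_index(names="exam_id"), out / "fit_reports.tsv")
    write_comparison(result.comparison, out)
    plot_crel_curves(
        {
            "ctt": [a.ctt_curve for a in result.exams],
            "irt": [a.irt_curve for a in result.exams],
        },
        out / "crel_curves.png",
    )
    result.config.to_yaml(out / "config_resolved.yaml")
    if result.failed:
        (out / "failed_exams.tsv").write_text(
            "exam_id\terror\n"
            + "\n".join(f"{e}\t{msg}" for e, msg in result.failed)
            + "\n"
        )


def write_comparison(comparison: an.ComparisonResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    anova = comparison.anova
    (out / "anova.json").write_text(
        json.dumps(
            {
                "F": anova.F,
                "df": list(anova.df),
                "p": anova.p,
                "partial_eta2": anova.partial_eta2,
                "mean_crel_cut_ctt": anova.mean_ctt,
                "mean_crel_cut_irt": anova.mean_irt,
                "regression_r_squared": comparison.r_squared,
                "regression_F": comparison.f_overall,
                "regression_df": (
                    None if comparison.f_df is None else list(comparison.f_df)
                ),
                "regression_p": comparison.f_p,
                "excluded_predictors": comparison.excluded_predictors,
                "regression_skipped_reason": comparison.regression_skipped_reason,
            },
            indent=1,
        )
    )
    if comparison.regression is not None:
        io.write_tsv(
            comparison.regression.reset_index(names="predictor"),
            out / "regression.tsv",
        )
    io.write_tsv(
        comparison.collinearity.reset_index(names="predictor"),
        out / "correlations.tsv",
    )


def mean_curves_frame(
    curves_by_framework: dict[str, list[ConditionalReliabilityCurve]],
    percent_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and SD of conditional reliability on a common percent grid.

    Curves on different grids are linearly resampled; grid points
    outside a curve's support are dropped for that curve.
    """
    if percent_grid is None:
        percent_grid = np.linspace(0.0, 100.0, 101)
    rows = []
    for framework, curves in curves_by_framework.items():
        if not curves:
            continue
        stack = np.full((len(curves), percent_grid.size), np.nan)
        for i, c in enumerate(curves):
            inside = (percent_grid >= c.score_grid[0]) & (
                percent_grid <= c.score_grid[-1]
            )
            stack[i, inside] = np.interp(
                percent_grid[inside], c.score_grid, c.crel
            )
        count = np.sum(~np.isnan(stack), axis=0)
        mean = np.full(percent_grid.size, np.nan)
        sd = np.zeros(percent_grid.size)
        mean[count > 0] = np.nanmean(stack[:, count > 0], axis=0)
        if len(curves) > 1:
            sd[count > 1] = np.nanstd(stack[:, count > 1], axis=0, ddof=1)
        rows.append(
            pd.DataFrame(
                {
                    "framework": framework,
                    "percent_score": percent_grid,
                    "crel_mean": mean,
                    "crel_sd": sd,
                    "n_curves": count,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def plot_crel_curves(
    curves_by_framework: dict[str, list[ConditionalReliabilityCurve]],
    path: str | Path,
) -> pd.DataFrame:
    """Mean +/- SD conditional reliability per framework, percent axis.

    Writes the figure and, next to it, the plotted numbers as CSV so the
    figure is auditable.  Returns the plotted table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    table = mean_curves_frame(curves_by_framework)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"ctt": "tab:blue", "irt": "tab:red"}
    for framework, part in table.groupby("framework"):
        ok = part["n_curves"] > 0
        x = part.loc[ok, "percent_score"]
        m = part.loc[ok, "crel_mean"]
        s = part.loc[ok, "crel_sd"]
        color = colors.get(framework, None)
        ax.plot(x, m, label=framework.upper(), color=color)
        ax.fill_between(x, m - s, m + s, alpha=0.2, color=color)
    ax.set_xlabel("score (% of maximum points)")
    ax.set_ylabel("conditional reliability")
    ax.set_xlim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    table.to_csv(path.with_suffix(".csv"), index=False)
    return table
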