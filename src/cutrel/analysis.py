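"""Study-level comparisons of CTT and IRT cut-score precision.

Per exam, the conditional reliability curves of both frameworks are read
off at the exam's cut score (linear interpolation on the shared percent
axis).  Across exams, the theory contrast is a one-way repeated-measures
ANOVA (theory within exam, algebraically the squared paired t), and the
influencing-factor analysis is an ordinary least squares regression on
the stacked exam-by-theory table: conditional reliability at the cut on
a theory indicator (0 = CTT, 1 = IRT), performance range, item count,
school code, MTF proportion, and the four theory interactions.  A
collinearity screen justifies dropping study year (which tracks the
performance range almost perfectly when cohorts homogenise over years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ctt import ScoreSummary
from .curves import ConditionalReliabilityCurve


@dataclass
class CutScoreReport:
    """Per-exam summary: cut-score reliability in both theories + covariates."""

    exam_id: str
    crel_cut_ctt: float
    crel_cut_irt: float
    crel_max_ctt: float
    crel_max_irt: float
    crel_mean_ctt: float
    crel_mean_irt: float
    alpha: float
    separation: float
    perf_range: float  # percent
    cut_percent: float
    n_items: int
    pct_mtf: float
    school: str
    year_of_study: int

    def to_row(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA for the theory factor."""

    F: float
    df: tuple[int, int]
    p: float
    partial_eta2: float
    mean_ctt: float
    mean_irt: float


@dataclass
class ComparisonResult:
    """ANOVA plus stacked regression plus collinearity screen.

    The regression fields are None when the report table cannot support
    the full 9-predictor model (too few exams or a degenerate design);
    ``regression_skipped_reason`` then says why.
    """

    anova: AnovaResult
    regression: pd.DataFrame | None  # index predictor; B, SE_B, beta_std, t, p
    r_squared: float | None
    f_overall: float | None
    f_df: tuple[int, int] | None
    f_p: float | None
    collinearity: pd.DataFrame
    collinearity_p: pd.DataFrame
    excluded_predictors: list[str] = field(default_factory=list)
    regression_skipped_reason: str | None = None


def reports_to_frame(reports: Iterable[CutScoreReport] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(reports, pd.DataFrame):
        return reports
    return pd.DataFrame([r.to_row() for r in reports])


# --------------------------------------------------------------------------

def crel_at_cut(curve: ConditionalReliabilityCurve, cut_percent: float) -> float:
    """Conditional reliability at the cut score by linear interpolation.

    The curves are dense (one point per achievable score, or a fine
    theta grid mapped through the TCC), so interpolation error is
    negligible; a cut coinciding with a grid point returns that value
    exactly.
    """
    grid = curve.score_grid
    if not grid[0] <= cut_percent <= grid[-1]:
        raise ValueError(
            f"cut {cut_percent} outside curve support [{grid[0]:.3f}, {grid[-1]:.3f}]"
        )
    return float(np.interp(cut_percent, grid, curve.crel))


def performance_range(summary: ScoreSummary) -> float:
    """Spread of observed performance: max minus min percent score."""
    pct = np.asarray(summary.percent_score, dtype=float)
    if pct.size < 2:
        raise ValueError("performance range needs at least 2 examinees")
    return float(pct.max() - pct.min())


def paired_theory_anova(
    reports: Iterable[CutScoreReport] | pd.DataFrame,
) -> AnovaResult:
    """One-way repeated-measures ANOVA, theory as the within-exam factor.

    With two conditions this is exactly the squared paired t test:
    F(1, n-1) = t^2.  Partial eta^2 = SS_theory / (SS_theory + SS_error).
    Identical differences across all exams (zero error SS) are reported
    as the boundary case F = inf, p = 0.
    """
    frame = reports_to_frame(reports)
    ctt = frame["crel_cut_ctt"].to_numpy(dtype=float)
    irt = frame["crel_cut_irt"].to_numpy(dtype=float)
    n = ctt.size
    if n < 2:
        raise ValueError("paired ANOVA needs at least 2 exams")
    d = irt - ctt
    ss_theory = n * np.mean(d) ** 2 / 2.0
    ss_error = float(np.sum((d - d.mean()) ** 2)) / 2.0
    df = (1, n - 1)
    if ss_error == 0.0:
        F = np.inf if ss_theory > 0 else 0.0
        p = 0.0 if ss_theory > 0 else 1.0
    else:
        F = float(ss_theory / (ss_error / (n - 1)))
        p = float(stats.f.sf(F, *df))
    eta2 = float(ss_theory / (ss_theory + ss_error)) if (ss_theory + ss_error) else 0.0
    return AnovaResult(
        F=float(F),
        df=df,
        p=p,
        partial_eta2=eta2,
        mean_ctt=float(ctt.mean()),
        mean_irt=float(irt.mean()),
    )


# --------------------------------------------------------------------------
# stacked regression

#: predictor order mirrors the influencing-factor table layout
PREDICTORS = [
    "theory",
    "perf_range",
    "n_items",
    "school",
    "pct_mtf",
    "theory_x_perf_range",
    "theory_x_n_items",
    "theory_x_school",
    "theory_x_pct_mtf",
]


def _school_codes(schools: pd.Series) -> pd.Series:
    levels = sorted(schools.unique())
    mapping = {s: i for i, s in enumerate(levels)}
    return schools.map(mapping).astype(float)


def stacked_design(reports: Iterable[CutScoreReport] | pd.DataFrame) -> pd.DataFrame:
    """Long-format design: one row per exam x theory, response + predictors.

    The school enters as a single numeric code; the MTF share enters as
    a proportion (0-1) so its coefficient is on a comparable scale to
    the other predictors.
    """
    frame = reports_to_frame(reports)
    rows = []
    school = _school_codes(frame["school"])
    for theory, col in ((0.0, "crel_cut_ctt"), (1.0, "crel_cut_irt")):
        part = pd.DataFrame(
            {
                "exam_id": frame["exam_id"],
                "crel_cut": frame[col].to_numpy(dtype=float),
                "theory": theory,
                "perf_range": frame["perf_range"].to_numpy(dtype=float),
                "n_items": frame["n_items"].to_numpy(dtype=float),
                "school": school.to_numpy(),
                "pct_mtf": frame["pct_mtf"].to_numpy(dtype=float) / 100.0,
            }
        )
        rows.append(part)
    long = pd.concat(rows, ignore_index=True)
    for var in ("perf_range", "n_items", "school", "pct_mtf"):
        long[f"theory_x_{var}"] = long["theory"] * long[var]
    return long


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = sm.add_constant(X.to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        sds = X.std(axis=0)
        constant = list(X.columns[sds == 0])
        corr = X.loc[:, sds > 0].corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        dup_pairs = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(
            "design matrix is rank deficient; constant columns: "
            f"{constant}; perfectly collinear pairs: {dup_pairs}"
        )


def stacked_regression(
    reports: Iterable[CutScoreReport] | pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, float, tuple[int, int], float]:
    """OLS of cut-score conditional reliability on theory and covariates.

    Returns (table, r_squared, F, (df1, df2), p).  The table reports the
    unstandardised coefficient B with its SE, the standardised beta
    (response and predictors z-scored, interactions standardised after
    forming the product), t and p, plus a significance flag at ``alpha``.
    """
    long = stacked_design(reports)
    y = long["crel_cut"].to_numpy(dtype=float)
    X = long[PREDICTORS]
    if long.shape[0] <= len(PREDICTORS) + 1:
        raise ValueError(
            f"need more than {len(PREDICTORS) + 1} rows for {len(PREDICTORS)} predictors"
        )
    _check_full_rank(X)
    model = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
    zX = (X - X.mean()) / X.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    zmodel = sm.OLS(zy, sm.add_constant(zX.to_numpy(dtype=float))).fit()
    table = pd.DataFrame(
        {
            "B": model.params,
            "SE_B": model.bse,
            "beta_std": zmodel.params,
            "t": model.tvalues,
            "p": model.pvalues,
        },
        index=["intercept"] + PREDICTORS,
    )
    table["significant"] = table["p"] < alpha
    df = (int(model.df_model), int(model.df_resid))
    return table, float(model.rsquared), float(model.fvalue), df, float(model.f_pvalue)


def collinearity_screen(
    reports: Iterable[CutScoreReport] | pd.DataFrame,
    predictors: Sequence[str] = ("year_of_study", "n_items", "perf_range"),
    threshold: float = 0.7,
    exclusion_priority: Sequence[str] = ("year_of_study",),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise predictor correlations and exclusion flags.

    Returns (correlations, p_values, excluded).  While any retained pair
    exceeds ``threshold`` in absolute correlation, one member is
    excluded: priority predictors first (study year, which merely proxies
    the range restriction), otherwise the predictor most correlated with
    the rest on average.
    """
    frame = reports_to_frame(reports)
    data = frame[list(predictors)].astype(float)
    k = len(predictors)
    corr = pd.DataFrame(np.eye(k), index=predictors, columns=predictors)
    pval = pd.DataFrame(np.zeros((k, k)), index=predictors, columns=predictors)
    for i, a in enumerate(predictors):
        for j, b in enumerate(predictors):
            if i < j:
                r, p = stats.pearsonr(data[a], data[b])
                corr.loc[a, b] = corr.loc[b, a] = r
                pval.loc[a, b] = pval.loc[b, a] = p
    excluded: list[str] = []
    retained = list(predictors)
    while True:
        worst = None
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                r = abs(corr.loc[a, b])
                if r > threshold and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        _, a, b = worst
        drop = next((p for p in exclusion_priority if p in (a, b)), None)
        if drop is None:
            mean_abs = {
                x: corr.loc[x, [c for c in retained if c != x]].abs().mean()
                for x in (a, b)
            }
            drop = max(mean_abs, key=mean_abs.get)
        excluded.append(drop)
        retained.remove(drop)
    return corr, pval, excluded


def compare_theories(
    reports: Iterable[CutScoreReport] | pd.DataFrame,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Full study-level comparison: ANOVA + regression + collinearity."""
    frame = reports_to_frame(reports)
    anova = paired_theory_anova(frame)
    corr, pval, excluded = collinearity_screen(frame)
    table = r2 = f = df = fp = None
    reason = None
    try:
        table, r2, f, df, fp = stacked_regression(frame, alpha=alpha)
    except ValueError as err:
        reason = str(err)
    return ComparisonResult(
        anova=anova,
        regression=table,
        r_squared=r2,
        f_overall=f,
        f_df=df,
        f_p=fp,
        collinearity=corr,
        collinearity_p=pval,
        excluded_predictors=excluded,
        regression_skipped_reason=reason,
    )
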