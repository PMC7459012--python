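"""Classical test theory engine.

Total scoring, Cronbach's alpha, and the binomial-error conditional SEM
of Lord, standardised into a conditional reliability curve:

    cSEM(X)  = sqrt( X (k - X) / (k - 1) )
    cRel(X)  = ( sigma_x^2 - cSEM(X)^2 ) / sigma_x^2

where X is a total score, k the number of items and sigma_x^2 the
between-examinee variance of totals.  The binomial model assumes
integer item scores; with MTF half-points the formula is evaluated on
the points scale with k = max_points, accepting non-integer X.  All
variances use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ConditionalReliabilityCurve, conditional_reliability
from .synthetic import MTF, ResponseMatrix


@dataclass
class ScoreSummary:
    """Per-examinee totals and their dispersion for one exam."""

    total_points: np.ndarray
    percent_score: np.ndarray
    score_variance: float  # points^2, n-1 denominator
    n_items: int
    has_half_points: bool = False

    @property
    def max_points(self) -> float:
        return float(self.n_items)


def total_scores(responses: ResponseMatrix) -> ScoreSummary:
    """Sum points per examinee and report percent scores and variance."""
    if responses.n_examinees < 2:
        raise ValueError("need at least 2 examinees for a score variance")
    values = responses.scores.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    return ScoreSummary(
        total_points=totals,
        percent_score=100.0 * totals / responses.max_points,
        score_variance=float(np.var(totals, ddof=1)),
        n_items=responses.n_items,
        has_half_points=MTF in responses.item_kinds,
    )


def cronbach_alpha(responses: ResponseMatrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    values = responses.scores.to_numpy(dtype=float)
    n, k = values.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if n < 2:
        raise ValueError("Cronbach's alpha needs at least 2 examinees")
    total_var = float(np.var(values.sum(axis=1), ddof=1))
    if total_var == 0:
        raise ValueError(
            "total-score variance is zero; Cronbach's alpha is undefined"
        )
    item_vars = np.var(values, axis=0, ddof=1)
    return k / (k - 1) * (1.0 - float(item_vars.sum()) / total_var)


def binomial_csem(X: float | np.ndarray, k: float) -> float | np.ndarray:
    """Binomial-error conditional SEM on the points scale.

    Zero at both the floor and the ceiling score and maximal at k/2.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("binomial cSEM needs k >= 2")
    if np.any((X < 0) | (X > k)):
        raise ValueError(f"score outside [0, {k}]")
    out = np.sqrt(X * (k - X) / (k - 1))
    return float(out) if out.ndim == 0 else out


def ctt_crel_curve(summary: ScoreSummary) -> ConditionalReliabilityCurve:
    """Conditional reliability over the full achievable score grid.

    The grid steps by the scoring increment (0.5 points when the exam
    contains MTF items, else 1 point) from 0 to max_points, expressed in
    percent.  Negative values are kept as computed and flagged on the
    curve: a homogeneous cohort can push cSEM^2 above the score
    variance, and truncating would hide exactly the phenomenon of
    interest.
    """
    if summary.score_variance <= 0:
        raise ValueError("score variance is zero; conditional reliability undefined")
    k = summary.max_points
    step = 0.5 if summary.has_half_points else 1.0
    grid_points = np.arange(0.0, k + step / 2, step)
    csem = binomial_csem(grid_points, k)
    crel = conditional_reliability(csem, summary.score_variance)
    percent = 100.0 * grid_points / k
    achieved = np.isin(
        np.round(grid_points / step).astype(int),
        np.round(np.asarray(summary.total_points) / step).astype(int),
    )
    return ConditionalReliabilityCurve(
        framework="ctt",
        score_grid=percent,
        csem=csem,
        crel=crel,
        variance_used=summary.score_variance,
        achieved_mask=achieved,
    )
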