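"""Model-fit assessment for the partial credit model.

Four families of checks, all residual-based:

* **Q3** (Yen): pairwise correlations of item residuals after removing
  the modelled trait — a screen for local-dependence violations.  Under
  a fitting model the signed statistic has a small negative expectation
  (about -1/(k-1)); the headline summary here is the mean absolute Q3,
  with the signed mean reported alongside.
* **Infit / outfit**: information-weighted and unweighted mean squares
  of standardised item residuals, expectation ~1 under fit.
* **SRMR / SRMSR**: summaries of the discrepancy between observed and
  model-implied inter-item correlations (mean absolute residual
  correlation, and root mean square residual correlation).
* **Misfit rate**: percent of items whose mean square leaves a band
  (default 0.8-1.2).

Residuals are evaluated at the WLE point estimates of ability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .irt import PCMFit, ThetaEstimates, item_moments, _latent_log_weights
from .synthetic import ResponseMatrix


@dataclass
class Q3Summary:
    """Pairwise residual correlations over all item pairs."""

    mean_abs: float
    mean_signed: float
    min: float
    max: float
    n_pairs: int
    n_skipped_items: int
    matrix: pd.DataFrame  # symmetric, unit diagonal (excluded from summaries)


@dataclass
class ItemFit:
    """Per-item infit/outfit mean squares."""

    table: pd.DataFrame  # index item_id, columns infit/outfit
    n_excluded_cells: int  # saturated cells (zero model variance)


@dataclass
class ResidualCorrelationSummary:
    srmr: float
    srmsr: float
    n_excluded_items: int  # constant observed columns


@dataclass
class FitReport:
    """One exam's fit row: Q3, infit/outfit summaries, SRMR/SRMSR."""

    q3_mean: float
    q3_mean_signed: float
    q3_min: float
    q3_max: float
    infit_min: float
    infit_max: float
    infit_mean: float
    pct_misfit_infit: float
    outfit_min: float
    outfit_max: float
    outfit_mean: float
    pct_misfit_outfit: float
    srmr: float
    srmsr: float

    def to_row(self) -> dict[str, float]:
        return dict(self.__dict__)


def _point_residuals(
    fit: PCMFit, responses: ResponseMatrix, estimates: ThetaEstimates
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-minus-expected points and model variances at theta-hat.

    Returns (residuals, variances), both (n_examinees, n_items) on the
    points metric.
    """
    observed = responses.scores.to_numpy(dtype=float)
    E, V, _ = item_moments(fit, estimates.theta)
    w = fit.point_weights
    return observed - E * w, V * w**2


def q3_statistic(
    fit: PCMFit, responses: ResponseMatrix, estimates: ThetaEstimates
) -> Q3Summary:
    """Yen's Q3: correlation of residuals for every item pair.

    Items whose residual column is constant are skipped (their pairs are
    undefined) and counted in ``n_skipped_items``.
    """
    resid, _ = _point_residuals(fit, responses, estimates)
    sd = resid.std(axis=0, ddof=1)
    keep = sd > 0
    n_skipped = int((~keep).sum())
    ids = [i for i, k in zip(fit.item_ids, keep) if k]
    corr = np.corrcoef(resid[:, keep], rowvar=False)
    corr = np.atleast_2d(corr)
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    if vals.size == 0:
        raise ValueError("fewer than 2 items with non-constant residuals")
    matrix = pd.DataFrame(corr, index=ids, columns=ids)
    return Q3Summary(
        mean_abs=float(np.mean(np.abs(vals))),
        mean_signed=float(np.mean(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        n_pairs=int(vals.size),
        n_skipped_items=n_skipped,
        matrix=matrix,
    )


def infit_outfit(
    fit: PCMFit, responses: ResponseMatrix, estimates: ThetaEstimates
) -> ItemFit:
    """Infit (information-weighted) and outfit mean squares per item.

    outfit_i = mean over examinees of r^2/W; infit_i = sum r^2 / sum W,
    with W the model score variance at the examinee's ability.  Cells
    with (numerically) zero variance are excluded and counted; an item
    with no usable cells gets NaN mean squares.
    """
    resid, W = _point_residuals(fit, responses, estimates)
    eps = 1e-12
    usable = W > eps
    n_excluded = int((~usable).sum())
    z2 = np.where(usable, resid**2 / np.where(usable, W, 1.0), np.nan)
    with np.errstate(invalid="ignore"):
        outfit = np.nanmean(z2, axis=0)
    sum_w = np.where(usable, W, 0.0).sum(axis=0)
    sum_r2 = np.where(usable, resid**2, 0.0).sum(axis=0)
    infit = np.where(sum_w > eps, sum_r2 / np.where(sum_w > eps, sum_w, 1.0), np.nan)
    table = pd.DataFrame({"infit": infit, "outfit": outfit}, index=fit.item_ids)
    return ItemFit(table=table, n_excluded_cells=n_excluded)


def residual_correlation_summaries(
    observed_corr: np.ndarray, implied_corr: np.ndarray
) -> tuple[float, float]:
    """SRMR and SRMSR from observed vs model-implied correlation matrices.

    SRMR is the mean absolute off-diagonal residual correlation; SRMSR
    its root-mean-square counterpart (hence SRMSR >= SRMR).
    """
    observed_corr = np.asarray(observed_corr, dtype=float)
    implied_corr = np.asarray(implied_corr, dtype=float)
    iu = np.triu_indices_from(observed_corr, k=1)
    resid = observed_corr[iu] - implied_corr[iu]
    srmr = float(np.mean(np.abs(resid)))
    srmsr = float(np.sqrt(np.mean(resid**2)))
    return srmr, srmsr


def implied_correlations(fit: PCMFit) -> np.ndarray:
    """Model-implied inter-item correlation matrix.

    Marginalises the fitted model over the estimated latent density:
    items are conditionally independent, so cross-moments are quadrature
    averages of products of conditional expectations.
    """
    nodes = np.linspace(*fit.quadrature_range, fit.n_quadrature)
    wq = np.exp(_latent_log_weights(nodes, fit.latent_sd))
    E, V, _ = item_moments(fit, nodes)  # (Q, k), category metric
    pw = fit.point_weights
    Ep = E * pw  # expected points per item given theta
    mean = wq @ Ep
    cross = (Ep * wq[:, None]).T @ Ep  # E[x_i x_j] for i != j
    second = wq @ ((V * pw**2) + Ep**2)  # E[x_i^2]
    cov = cross - np.outer(mean, mean)
    np.fill_diagonal(cov, second - mean**2)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


def srmr_srmsr(fit: PCMFit, responses: ResponseMatrix) -> ResidualCorrelationSummary:
    """SRMR/SRMSR between observed and model-implied item correlations.

    Constant observed columns have undefined correlations; those items
    are excluded from both matrices and counted.
    """
    values = responses.scores.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("SRMR needs at least 2 items")
    keep = values.std(axis=0, ddof=1) > 0
    n_excluded = int((~keep).sum())
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant items; SRMR undefined")
    observed = np.corrcoef(values[:, keep], rowvar=False)
    implied = implied_correlations(fit)[np.ix_(keep, keep)]
    srmr, srmsr = residual_correlation_summaries(observed, implied)
    return ResidualCorrelationSummary(srmr=srmr, srmsr=srmsr, n_excluded_items=n_excluded)


def misfit_rate(
    mean_squares: np.ndarray | pd.Series, bounds: tuple[float, float] = (0.8, 1.2)
) -> float:
    """Percent of items whose mean square falls outside ``bounds``.

    NaN entries (degenerate items) are ignored.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"invalid misfit bounds ({lo}, {hi})")
    ms = np.asarray(mean_squares, dtype=float)
    ms = ms[~np.isnan(ms)]
    if ms.size == 0:
        return float("nan")
    return 100.0 * float(((ms < lo) | (ms > hi)).mean())


def fit_report(
    fit: PCMFit,
    responses: ResponseMatrix,
    estimates: ThetaEstimates,
    misfit_bounds: tuple[float, float] = (0.8, 1.2),
) -> FitReport:
    """Assemble the per-exam fit row (Q3, infit/outfit, SRMR/SRMSR)."""
    q3 = q3_statistic(fit, responses, estimates)
    item_fit = infit_outfit(fit, responses, estimates)
    resid = srmr_srmsr(fit, responses)
    infit = item_fit.table["infit"]
    outfit = item_fit.table["outfit"]
    return FitReport(
        q3_mean=q3.mean_abs,
        q3_mean_signed=q3.mean_signed,
        q3_min=q3.min,
        q3_max=q3.max,
        infit_min=float(infit.min()),
        infit_max=float(infit.max()),
        infit_mean=float(infit.mean()),
        pct_misfit_infit=misfit_rate(infit, misfit_bounds),
        outfit_min=float(outfit.min()),
        outfit_max=float(outfit.max()),
        outfit_mean=float(outfit.mean()),
        pct_misfit_outfit=misfit_rate(outfit, misfit_bounds),
        srmr=resid.srmr,
        srmsr=resid.srmsr,
    )
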