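"""1-PL partial credit model: estimation, person ability, information.

Item parameters are estimated by marginal maximum likelihood with an
EM algorithm over a fixed quadrature grid, assuming a normal latent
trait with mean fixed at 0 (identification) and standard deviation
estimated.  Person abilities use Warm's weighted likelihood estimator
(WLE), which stays finite at zero and perfect raw scores.  The test
information function I_s(theta) is the sum of item category-score
variances (unit discrimination), and the IRT conditional SEM is
csem(theta) = sqrt(1 / I_s(theta)).  Conditional reliability
standardises csem^2 by the variance of the WLE ability estimates.

The EM M-step is an exact per-item Newton maximisation with
backtracking, so the marginal log-likelihood trace is non-decreasing
(a property the test suite asserts on every fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from ._pcm import grouped_probs, moments
from .curves import ConditionalReliabilityCurve, conditional_reliability
from .synthetic import POINT_WEIGHTS, ResponseMatrix


class UnidentifiedItemError(ValueError):
    """An item shows responses in fewer than 2 categories."""


@dataclass(frozen=True)
class EstimationSettings:
    """MML-EM settings: quadrature, convergence, latent density."""

    n_quadrature: int = 41
    quadrature_range: tuple[float, float] = (-6.0, 6.0)
    tol: float = 1e-5  # log-likelihood gain per EM cycle
    max_iter: int = 500
    estimate_latent_sd: bool = True
    latent_sd_bounds: tuple[float, float] = (0.1, 3.0)
    # step estimates are kept in [-bound, bound]: a category that is
    # (almost) never observed has a flat likelihood toward infinity, and
    # beyond ~8 logits the fitted probabilities are indistinguishable
    step_bound: float = 8.0


@dataclass
class PCMFit:
    """Estimated partial credit model for one exam."""

    item_ids: list[str]
    item_kinds: list[str]
    item_params: list[np.ndarray]  # step parameters per item (logits)
    latent_sd: float
    log_likelihood: float
    converged: bool
    n_iter: int
    iteration_trace: np.ndarray
    n_quadrature: int
    quadrature_range: tuple[float, float]
    settings: EstimationSettings = field(repr=False, default_factory=EstimationSettings)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def point_weights(self) -> np.ndarray:
        """Points per category step (1 for Type A, 0.5 for MTF)."""
        return np.array([POINT_WEIGHTS[k] for k in self.item_kinds])

    @property
    def max_points(self) -> float:
        return float(self.n_items)


@dataclass
class ThetaEstimates:
    """Per-examinee weighted likelihood ability estimates."""

    theta: np.ndarray
    se_theta: np.ndarray
    estimator: str = "WLE"

    @property
    def variance(self) -> float:
        """Between-examinee variance of the ability estimates (n-1)."""
        return float(np.var(self.theta, ddof=1))


@dataclass
class InformationCurve:
    """Test information and IRT conditional SEM along a theta grid."""

    theta_grid: np.ndarray
    info: np.ndarray
    csem_theta: np.ndarray


# --------------------------------------------------------------------------
# internal data layout

def _categories(responses: ResponseMatrix) -> np.ndarray:
    """Integer category matrix (points / per-item step weight)."""
    values = responses.scores.to_numpy(dtype=float)
    weights = np.array([POINT_WEIGHTS[k] for k in responses.item_kinds])
    cats = np.rint(values / weights).astype(np.int64)
    return cats


@dataclass
class _Group:
    """Items sharing a category count, for vectorised EM updates."""

    idx: np.ndarray  # positions in the exam's item order
    steps: np.ndarray  # (I, S)
    X: np.ndarray  # (N, I) observed categories
    onehot: np.ndarray  # (N, I, C)

    @property
    def onehot_flat(self) -> np.ndarray:  # (N, I*C), item-major
        return self.onehot.reshape(self.onehot.shape[0], -1)


def _build_groups(cats: np.ndarray, kinds: list[str], init: list[np.ndarray] | None = None):
    n_steps = np.array([1 if k == "typeA" else 2 for k in kinds])
    groups = []
    for s in np.unique(n_steps):
        idx = np.flatnonzero(n_steps == s)
        X = cats[:, idx]
        C = s + 1
        onehot = np.eye(C, dtype=float)[X]  # (N, I, C)
        if init is None:
            steps = np.zeros((idx.size, s))
        else:
            steps = np.vstack([np.asarray(init[j], dtype=float) for j in idx])
        groups.append(_Group(idx=idx, steps=steps, X=X, onehot=onehot))
    return groups


def _check_identified(cats: np.ndarray, item_ids: list[str]) -> None:
    bad = [
        item_ids[j]
        for j in range(cats.shape[1])
        if np.unique(cats[:, j]).size < 2
    ]
    if bad:
        raise UnidentifiedItemError(
            "items with responses in fewer than 2 categories "
            f"cannot be estimated: {bad}"
        )


def _latent_log_weights(nodes: np.ndarray, sd: float) -> np.ndarray:
    logw = -0.5 * (nodes / sd) ** 2  # normal density up to the common constant
    return logw - logsumexp(logw)


def _data_loglik(groups: list[_Group], nodes: np.ndarray) -> np.ndarray:
    """(N, Q) log-likelihood of each response vector at each node."""
    n = groups[0].X.shape[0]
    L = np.zeros((n, nodes.size))
    for g in groups:
        logp = np.log(grouped_probs(g.steps, nodes))  # (I, Q, C)
        L += g.onehot_flat @ logp.transpose(0, 2, 1).reshape(-1, nodes.size)
    return L


def _group_objective(steps: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Expected complete-data log-likelihood per item, given counts r (I,Q,C)."""
    probs = grouped_probs(steps, nodes)
    return np.einsum("iqc,iqc->i", r, np.log(probs))


def _mstep_group(
    steps: np.ndarray,
    r: np.ndarray,
    nodes: np.ndarray,
    bound: float = 8.0,
    grad_tol: float = 1e-8,
) -> np.ndarray:
    """Per-item Newton maximisation of the expected log-likelihood.

    The objective is concave in the step parameters (exponential
    family); backtracking guards the few cases where a full Newton step
    overshoots, so the objective never decreases.  Iterates are clipped
    to [-bound, bound]; along a flat direction (unobserved category) the
    objective is monotone, so clipping keeps the ascent property.
    """
    steps = steps.copy()
    I, S = steps.shape
    n_iq = r.sum(axis=2)  # (I, Q)
    # observed counts of "category >= j" per item/node, j = 1..S
    R = np.stack([r[:, :, j:].sum(axis=2) for j in range(1, S + 1)], axis=2)  # (I,Q,S)
    g_old = _group_objective(steps, r, nodes)
    for _ in range(100):
        probs = grouped_probs(steps, nodes)  # (I, Q, C)
        # P(X >= j) for j = 1..S
        Pge = np.stack([probs[:, :, j:].sum(axis=2) for j in range(1, S + 1)], axis=2)
        grad = np.einsum("iq,iqs->is", n_iq, Pge) - R.sum(axis=1)  # d/d delta_j
        if np.abs(grad).max() < grad_tol:
            break
        # Hessian: -sum_q n_q Cov(s_j, s_l); E[s_j s_l] = P(X >= max(j,l))
        Pmax = np.minimum(Pge[:, :, :, None], Pge[:, :, None, :])
        cov = Pmax - Pge[:, :, :, None] * Pge[:, :, None, :]
        H = -np.einsum("iq,iqsl->isl", n_iq, cov)  # (I, S, S)
        H[:, np.arange(S), np.arange(S)] -= 1e-12  # keep solvable at saturation
        # ascent step: delta - H^-1 grad (H negative definite)
        direction = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        candidate = np.clip(steps - direction, -bound, bound)
        scale = np.ones(I)
        for _half in range(40):
            g_new = _group_objective(candidate, r, nodes)
            worse = g_new < g_old - 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
            candidate[worse] = np.clip(
                steps[worse] - scale[worse, None] * direction[worse], -bound, bound
            )
        if np.abs(candidate - steps).max() < 1e-10:  # pinned at the bound
            steps = candidate
            break
        steps, g_old = candidate, np.maximum(g_old, _group_objective(candidate, r, nodes))
    return steps


def fit_pcm(
    responses: ResponseMatrix, settings: EstimationSettings | None = None
) -> PCMFit:
    """Fit the 1-PL partial credit model by marginal maximum likelihood.

    Raises :class:`UnidentifiedItemError` when an item shows fewer than
    two observed categories.  Non-convergence within ``max_iter`` EM
    cycles is flagged on the result (``converged=False``) and warned
    about, never silent.
    """
    settings = settings or EstimationSettings()
    cats = _categories(responses)
    _check_identified(cats, responses.item_ids)
    groups = _build_groups(cats, responses.item_kinds)
    lo, hi = settings.quadrature_range
    nodes = np.linspace(lo, hi, settings.n_quadrature)
    sd = 1.0
    trace: list[float] = []
    converged = False
    ll = -np.inf
    for _iter in range(settings.max_iter):
        L = _data_loglik(groups, nodes)
        joint = L + _latent_log_weights(nodes, sd)
        ll_new = float(logsumexp(joint, axis=1).sum())
        trace.append(ll_new)
        if _iter > 0 and ll_new - ll < settings.tol:
            converged = True
            break
        ll = ll_new
        post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))  # (N, Q)
        for g in groups:
            C = g.onehot.shape[2]
            r = (post.T @ g.onehot_flat).reshape(nodes.size, -1, C).transpose(1, 0, 2)
            g.steps = _mstep_group(g.steps, r, nodes, bound=settings.step_bound)
        if settings.estimate_latent_sd:
            nbar = post.sum(axis=0)

            def neg_h(s: float) -> float:
                return -float(nbar @ _latent_log_weights(nodes, s))

            res = optimize.minimize_scalar(
                neg_h, bounds=settings.latent_sd_bounds, method="bounded"
            )
            if -res.fun >= -neg_h(sd):  # generalised EM: only accept improvements
                sd = float(res.x)
    if not converged:
        warnings.warn(
            f"EM did not converge in {settings.max_iter} iterations "
            f"(last gain {trace[-1] - trace[-2]:.2e})",
            RuntimeWarning,
        )
    item_params: list[np.ndarray] = [None] * cats.shape[1]  # type: ignore[list-item]
    for g in groups:
        for pos, j in enumerate(g.idx):
            item_params[j] = g.steps[pos].copy()
    return PCMFit(
        item_ids=list(responses.item_ids),
        item_kinds=list(responses.item_kinds),
        item_params=item_params,
        latent_sd=sd,
        log_likelihood=trace[-1],
        converged=converged,
        n_iter=len(trace),
        iteration_trace=np.asarray(trace),
        n_quadrature=settings.n_quadrature,
        quadrature_range=settings.quadrature_range,
        settings=settings,
    )


def marginal_log_likelihood(
    responses: ResponseMatrix,
    item_params: list[np.ndarray] | list[tuple[float, ...]],
    latent_sd: float = 1.0,
    settings: EstimationSettings | None = None,
) -> float:
    """Quadrature marginal log-likelihood at given parameters.

    Evaluates the same objective the EM fit maximises; used by tests to
    compare the fit against brute-force parameter grids.
    """
    settings = settings or EstimationSettings()
    cats = _categories(responses)
    groups = _build_groups(
        cats, responses.item_kinds, init=[np.asarray(p, float) for p in item_params]
    )
    lo, hi = settings.quadrature_range
    nodes = np.linspace(lo, hi, settings.n_quadrature)
    joint = _data_loglik(groups, nodes) + _latent_log_weights(nodes, latent_sd)
    return float(logsumexp(joint, axis=1).sum())


# --------------------------------------------------------------------------
# moments, information, TCC

def item_moments(fit: PCMFit, theta: np.ndarray):
    """Per-item category-score mean/variance/3rd central moment at theta.

    Returns arrays of shape (len(theta), n_items); items are processed
    in groups sharing a category count so the evaluation stays
    vectorised for mixed-format exams.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    k = fit.n_items
    E = np.empty((theta.size, k))
    V = np.empty((theta.size, k))
    M3 = np.empty((theta.size, k))
    n_steps = np.array([np.asarray(p).size for p in fit.item_params])
    for s in np.unique(n_steps):
        idx = np.flatnonzero(n_steps == s)
        steps = np.vstack([fit.item_params[j] for j in idx])
        probs = grouped_probs(steps, theta)  # (I, Q, C)
        m, v, m3 = moments(probs)  # (I, Q)
        E[:, idx] = m.T
        V[:, idx] = v.T
        M3[:, idx] = m3.T
    return E, V, M3


def test_information(fit: PCMFit, theta_grid: np.ndarray) -> InformationCurve:
    """Test information I_s(theta) and conditional SEM 1/sqrt(I_s).

    Information is on the theta metric: the Fisher information of the
    ability, which for the unit-discrimination PCM equals the summed
    category-score variances.  The conditional reliability built from it
    is scale-free, so the 0.5-point MTF weight cancels.
    """
    theta_grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if theta_grid.size == 0:
        raise ValueError("theta grid is empty")
    _, V, _ = item_moments(fit, theta_grid)
    info = V.sum(axis=1)
    return InformationCurve(
        theta_grid=theta_grid, info=info, csem_theta=1.0 / np.sqrt(info)
    )


def expected_percent_score(fit: PCMFit, theta: float | np.ndarray) -> float | np.ndarray:
    """Test characteristic curve: expected percent score at theta.

    Strictly increasing in theta; the model links every ability level to
    exactly one expected test score.
    """
    arr = np.atleast_1d(np.asarray(theta, dtype=float))
    E, _, _ = item_moments(fit, arr)
    pct = 100.0 * (E * fit.point_weights).sum(axis=1) / fit.max_points
    return float(pct[0]) if np.isscalar(theta) or np.ndim(theta) == 0 else pct


def percent_to_theta(fit: PCMFit, percent: float, bracket: float = 12.0) -> float:
    """Invert the test characteristic curve by monotone root-finding."""
    lo_val = expected_percent_score(fit, -bracket)
    hi_val = expected_percent_score(fit, bracket)
    if not lo_val < percent < hi_val:
        raise ValueError(
            f"percent {percent} outside the attainable TCC range "
            f"({lo_val:.3f}, {hi_val:.3f}) on [-{bracket}, {bracket}]"
        )
    return float(
        optimize.brentq(
            lambda t: expected_percent_score(fit, t) - percent, -bracket, bracket,
            xtol=1e-10,
        )
    )


# --------------------------------------------------------------------------
# person estimation

def _wle_objective(fit: PCMFit, totals: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Warm's weighted likelihood equation, vectorised over examinees.

    f(theta) = T - sum_i E_i(theta) + I'(theta) / (2 I(theta)), where T
    is the total category score and I' = sum of third central moments.
    """
    E, V, M3 = item_moments(fit, theta)
    info = V.sum(axis=1)
    return totals - E.sum(axis=1) + M3.sum(axis=1) / (2.0 * info)


def wle_theta(fit: PCMFit, responses: ResponseMatrix) -> ThetaEstimates:
    """Warm's weighted likelihood ability estimates with standard errors.

    For the Rasch family the total integer-category score is sufficient
    for ability, so the WLE equation is solved once per distinct total,
    for all totals at once, by safeguarded bisection (the equation is
    decreasing in theta); the bracket is widened if +/-8 logits does not
    contain the root.  The bias-correction term I'(theta)/(2 I(theta))
    keeps estimates finite at zero and perfect scores; SE = 1/sqrt(I)
    at the estimate.
    """
    if not fit.converged:
        raise ValueError("cannot compute WLE from a non-converged fit")
    cats = _categories(responses)
    if list(responses.item_ids) != fit.item_ids:
        raise ValueError("response matrix items do not match the fit")
    totals = cats.sum(axis=1)
    uniq, inverse = np.unique(totals, return_inverse=True)
    t = uniq.astype(float)
    lo = np.full(t.size, -8.0)
    hi = np.full(t.size, 8.0)
    flo = _wle_objective(fit, t, lo)
    fhi = _wle_objective(fit, t, hi)
    for half_width in (12.0, 20.0):
        unbracketed = flo * fhi > 0
        if not unbracketed.any():
            break
        lo[unbracketed], hi[unbracketed] = -half_width, half_width
        flo[unbracketed] = _wle_objective(fit, t[unbracketed], lo[unbracketed])
        fhi[unbracketed] = _wle_objective(fit, t[unbracketed], hi[unbracketed])
    if (flo * fhi > 0).any():
        bad = uniq[flo * fhi > 0]
        raise RuntimeError(f"WLE root not bracketed in [-20, 20] for totals {bad}")
    for _ in range(60):  # bisection to ~1e-17 bracket width
        mid = 0.5 * (lo + hi)
        fm = _wle_objective(fit, t, mid)
        take_low = np.sign(fm) == np.sign(flo)
        lo = np.where(take_low, mid, lo)
        flo = np.where(take_low, fm, flo)
        hi = np.where(take_low, hi, mid)
    theta_u = 0.5 * (lo + hi)
    _, V, _ = item_moments(fit, theta_u)
    se_u = 1.0 / np.sqrt(V.sum(axis=1))
    return ThetaEstimates(theta=theta_u[inverse], se_theta=se_u[inverse])


def separation_index(estimates: ThetaEstimates) -> float:
    """Person-separation reliability: (var(theta) - mean SE^2) / var(theta)."""
    if estimates.theta.size < 2:
        raise ValueError("separation index needs at least 2 examinees")
    var = estimates.variance
    if var == 0:
        raise ValueError("zero ability variance; separation index undefined")
    return (var - float(np.mean(estimates.se_theta**2))) / var


# --------------------------------------------------------------------------
# conditional reliability on the latent metric

def irt_crel_curve(
    fit: PCMFit,
    estimates: ThetaEstimates,
    theta_grid: np.ndarray | None = None,
) -> ConditionalReliabilityCurve:
    """IRT conditional reliability along a theta grid.

    crel(theta) = (var(theta_hat) - csem(theta)^2) / var(theta_hat),
    with csem = 1/sqrt(I_s).  Each grid point is annotated with its
    expected percent score via the test characteristic curve, so CTT and
    IRT curves share the percent axis.
    """
    if theta_grid is None:
        theta_grid = np.linspace(*fit.quadrature_range, 121)
    theta_grid = np.asarray(theta_grid, dtype=float)
    var = estimates.variance
    if var <= 0:
        raise ValueError("zero variance of ability estimates")
    curve = test_information(fit, theta_grid)
    crel = conditional_reliability(curve.csem_theta, var)
    percent = np.asarray(expected_percent_score(fit, theta_grid))
    return ConditionalReliabilityCurve(
        framework="irt",
        score_grid=percent,
        csem=curve.csem_theta,
        crel=crel,
        variance_used=var,
        theta_grid=theta_grid,
    )


def crel_at_theta(
    fit: PCMFit, estimates: ThetaEstimates, theta: np.ndarray
) -> np.ndarray:
    """Conditional reliability evaluated at specific ability values."""
    info = test_information(fit, np.atleast_1d(theta))
    return conditional_reliability(info.csem_theta, estimates.variance)
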