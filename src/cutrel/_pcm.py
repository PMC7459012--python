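"""Low-level partial credit model (PCM) probabilities and moments.

The PCM is the 1-PL (Rasch-family) model for ordered integer categories
0..C-1.  For an item with step parameters ``delta_1..delta_{C-1}`` the
probability of category c at ability theta is

    P(X = c | theta) = exp(c*theta - sum_{j<=c} delta_j) / D(theta)

with the c = 0 numerator equal to 1 and D the normalising sum.  A
dichotomous (single-best-answer) item is the special case C = 2, where
``delta_1`` is the usual Rasch difficulty.

All functions are vectorised over a grid of abilities and, where useful,
over groups of items sharing a category count.
"""

from __future__ import annotations

import numpy as np


def category_probs(steps: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities for one item.

    Parameters
    ----------
    steps : (S,) step parameters (logits).
    theta : (Q,) abilities.

    Returns
    -------
    (Q, S+1) probabilities, rows summing to 1.
    """
    steps = np.asarray(steps, dtype=float)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    cats = np.arange(steps.size + 1)
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    logits = np.outer(theta, cats) - cum  # (Q, C)
    logits -= logits.max(axis=1, keepdims=True)
    num = np.exp(logits)
    return num / num.sum(axis=1, keepdims=True)


def grouped_probs(steps: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities for items sharing a category count.

    Parameters
    ----------
    steps : (I, S) step parameters for I items with S steps each.
    theta : (Q,) abilities.

    Returns
    -------
    (I, Q, S+1) probabilities.
    """
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    cats = np.arange(steps.shape[1] + 1)
    cum = np.concatenate(
        (np.zeros((steps.shape[0], 1)), np.cumsum(steps, axis=1)), axis=1
    )  # (I, C)
    logits = cats[None, None, :] * theta[None, :, None] - cum[:, None, :]
    logits -= logits.max(axis=2, keepdims=True)
    num = np.exp(logits)
    return num / num.sum(axis=2, keepdims=True)


def moments(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, variance and third central moment of the category score.

    ``probs`` has categories on the last axis; moments are returned with
    that axis reduced.  The variance is the item's Fisher information
    contribution on the integer-category metric (unit discrimination),
    and the third central moment is the derivative of that information
    with respect to theta.
    """
    cats = np.arange(probs.shape[-1], dtype=float)
    mean = probs @ cats
    dev = cats - mean[..., None]
    var = np.einsum("...c,...c->...", probs, dev**2)
    mu3 = np.einsum("...c,...c->...", probs, dev**3)
    return mean, var, mu3
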