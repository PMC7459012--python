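"""Conditional reliability curves shared by the CTT and IRT engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConditionalReliabilityCurve:
    """Conditional SEM and conditional reliability along a score grid.

    ``score_grid`` is on the percent-correct scale (0-100) for both
    frameworks; the IRT curve additionally carries the theta grid it was
    evaluated on.  ``csem`` stays on the framework's own metric (points
    for CTT, logits for IRT); ``crel`` is the dimensionless Raju
    standardisation (variance - csem^2) / variance, which may be
    negative where the conditional error exceeds the score variance.
    """

    framework: str  # "ctt" | "irt"
    score_grid: np.ndarray  # percent of maximum points, increasing
    csem: np.ndarray
    crel: np.ndarray
    variance_used: float
    theta_grid: np.ndarray | None = None
    achieved_mask: np.ndarray | None = None  # grid points attained by examinees
    has_negative_crel: bool = field(init=False)

    def __post_init__(self) -> None:
        self.score_grid = np.asarray(self.score_grid, dtype=float)
        self.csem = np.asarray(self.csem, dtype=float)
        self.crel = np.asarray(self.crel, dtype=float)
        if not (self.score_grid.shape == self.csem.shape == self.crel.shape):
            raise ValueError("score_grid, csem and crel must have equal length")
        if np.any(np.diff(self.score_grid) < 0):
            raise ValueError("score_grid must be non-decreasing")
        self.has_negative_crel = bool(np.any(self.crel < 0))

    def to_frame(self) -> pd.DataFrame:
        """Tabular form used by the CSV exports."""
        data = {
            "framework": self.framework,
            "percent_score": self.score_grid,
            "csem": self.csem,
            "crel": self.crel,
        }
        if self.theta_grid is not None:
            data["theta"] = self.theta_grid
        if self.achieved_mask is not None:
            data["achieved"] = self.achieved_mask.astype(int)
        return pd.DataFrame(data)


def conditional_reliability(csem: np.ndarray, variance: float) -> np.ndarray:
    """Raju standardisation of the conditional SEM: (var - csem^2) / var."""
    if variance <= 0:
        raise ValueError("score variance must be positive")
    return (variance - np.asarray(csem, dtype=float) ** 2) / variance
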