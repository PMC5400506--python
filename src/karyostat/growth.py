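"""Tumor growth: doubling time by semi-log regression.

Volumes are assumed to grow exponentially; ordinary least squares of
ln(volume) on time gives a slope beta (1/day) and doubling time
T_d = ln(2) / beta (days). A non-positive slope means the tumor is not
growing and the doubling time is reported as undefined rather than negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class VolumeSeries:
    """Tumor volume observations over time (days, mm^3)."""

    tumor_id: str
    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.times) != len(self.volumes):
            raise ValueError("times and volumes must have equal length")
        if len(self.times) < 2:
            raise ValueError("need >= 2 observations")
        if (self.volumes <= 0).any():
            raise ValueError("volumes must be positive")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")


@dataclass
class DoublingEstimate:
    tumor_id: str
    slope: float  # beta, 1/day (natural log scale)
    doubling_time: float | None  # days; None when slope <= 0
    r_squared: float
    n_obs: int

    def summary(self) -> str:
        td = "undefined (non-positive slope)" if self.doubling_time is None else f"{self.doubling_time:.2f} days"
        return (
            f"Tumor {self.tumor_id}: semi-log growth fit over {self.n_obs} observations\n"
            f"  slope beta = {self.slope:.5f} /day, R^2 = {self.r_squared:.4f}\n"
            f"  doubling time T_d = ln(2)/beta = {td}"
        )


def fit_doubling_time(series: VolumeSeries) -> DoublingEstimate:
    """OLS of ln(volume) on time; T_d = ln(2)/slope."""
    res = stats.linregress(series.times, np.log(series.volumes))
    beta = float(res.slope)
    td = float(np.log(2) / beta) if beta > 0 else None
    r2 = float(res.rvalue**2)
    return DoublingEstimate(series.tumor_id, beta, td, r2, len(series.times))
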