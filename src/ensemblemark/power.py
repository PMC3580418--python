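"""Schoenfeld power for two-group survival comparisons.

For a two-sided level-``alpha`` test of a hazard ratio HR with NE observed
events and equal allocation between risk groups,

    z_power = sqrt(NE) * |ln HR| / 2 - z_{1 - alpha/2}
    power   = Phi(z_power)

The formula conditions on the number of events, not the number of patients.
At HR = 1 it returns Phi(-z_{1-alpha/2}) = alpha/2 (the one tail that still
rejects under the null); it is symmetric in HR <-> 1/HR, so protective
markers (HR < 1) are handled identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    """Events, hazard ratio and two-sided significance level (equal allocation)."""

    ne: int
    hr: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if self.hr <= 0:
            raise ValueError("hr must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def power(self) -> float:
        return schoenfeld_power(self.ne, self.hr, self.alpha)


def schoenfeld_power(ne: int, hr: float, alpha: float = 0.05) -> float:
    """Power of detecting hazard ratio ``hr`` with ``ne`` events at level ``alpha``."""
    PowerQuery(ne=ne, hr=hr, alpha=alpha)  # validation
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = np.sqrt(ne) * abs(np.log(hr)) / 2.0 - z_crit
    return float(stats.norm.cdf(z_power))


DEFAULT_HR_GRID = np.round(np.linspace(1.0, 2.5, 151), 2)

# event counts of the published four-site validation cohort, usable as an
# example configuration: overall plus per-stage subgroups
DEFAULT_STAGE_EVENTS = {"all": 236, "IA": 38, "IB": 73, "II": 64, "III": 60}


@dataclass
class PowerCurve:
    """Power as a function of HR for one cohort's event count."""

    label: str
    ne: int
    hr: np.ndarray
    power: np.ndarray
    threshold: float = 0.8
    hr_at_threshold: float | None = field(default=None)

    def __post_init__(self):
        self.hr = np.asarray(self.hr, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.hr) <= 0):
            raise ValueError("hr grid must be strictly increasing")


def power_curves(cohort_events: dict[str, int], hr_grid=None, alpha: float = 0.05,
                 power_threshold: float = 0.8) -> list[PowerCurve]:
    """One power curve per cohort over the HR grid (default 1.00-2.50 by 0.01).

    Each curve also reports the smallest grid HR achieving power >= the
    threshold (None if no grid point reaches it).
    """
    grid = DEFAULT_HR_GRID if hr_grid is None else np.asarray(hr_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("hr grid must be non-empty")
    curves = []
    for label, ne in cohort_events.items():
        p = np.array([schoenfeld_power(ne, h, alpha) for h in grid])
        above = np.flatnonzero(p >= power_threshold)
        hr_at = float(grid[above[0]]) if above.size else None
        curves.append(PowerCurve(label=label, ne=ne, hr=grid, power=p,
                                 threshold=power_threshold, hr_at_threshold=hr_at))
    return curves


def monte_carlo_logrank_power(ne: int, hr: float, alpha: float = 0.05,
                              n_replicates: int = 2000, seed: int = 0,
                              cohort_multiple: int = 8) -> float:
    """Empirical log-rank rejection rate under exponential survival.

    Each replicate follows a cohort of ``cohort_multiple * ne`` patients,
    split equally between groups (the second group's hazard multiplied by
    ``hr``), until the ``ne``-th event; later patients are administratively
    censored at that time, so exactly ``ne`` events are observed while the
    risk sets stay close to the equal-allocation regime the Schoenfeld
    formula assumes.  Returns the fraction of replicates where the two-sided
    log-rank test rejects at level ``alpha``; serves as an independent
    cross-check of :func:`schoenfeld_power`.
    """
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(seed)
    n = cohort_multiple * ne
    n1 = n // 2
    group = np.concatenate([np.zeros(n1), np.ones(n - n1)])
    rejections = 0
    for _ in range(n_replicates):
        t = np.concatenate([rng.exponential(1.0, n1),
                            rng.exponential(1.0 / hr, n - n1)])
        cutoff = np.sort(t)[ne - 1]
        e = t <= cutoff
        tt = np.minimum(t, cutoff)
        res = logrank_test(tt[group == 0], tt[group == 1],
                           event_observed_A=e[group == 0],
                           event_observed_B=e[group == 1])
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_replicates
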