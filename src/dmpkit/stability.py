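"""Metabolic-stability half-life from substrate-depletion time courses.

A microsomal depletion experiment samples the fraction of parent compound
remaining at a handful of times; under first-order loss
``ln(% remaining)`` is linear in time and T1/2 = ln2 / (-slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, NoDepletionError

LN2 = np.log(2.0)


@dataclass(frozen=True)
class DepletionSeries:
    """Percent of parent remaining over time, normalized to 100 at t=0."""

    enzyme_source: str
    reaction_system: str  # "cyp" or "ugt"
    times: np.ndarray
    percent_remaining: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.percent_remaining, dtype=float)
        if t.ndim != 1 or p.ndim != 1 or t.size != p.size:
            raise DegenerateDataError("times and percentages must be 1-D of equal length")
        if t.size == 0 or t[0] != 0:
            raise DegenerateDataError("time grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise DegenerateDataError("times must be strictly increasing")
        if np.any(p <= 0):
            raise DegenerateDataError("percent remaining must be strictly positive (log transform)")
        if not np.isclose(p[0], 100.0, rtol=1e-9):
            raise DegenerateDataError("first percentage must be 100 (normalize first)")
        if self.reaction_system not in ("cyp", "ugt"):
            raise DegenerateDataError(f"unknown reaction system {self.reaction_system!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "percent_remaining", p)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StabilityResult:
    """Log-linear regression summary: slope (1/min), r², and T1/2 = ln2/(-slope)."""

    slope: float
    t_half: float
    r2: float
    n_points: int
    status: str = "ok"  # "ok" or "no_depletion"


def percent_remaining(
    times,
    raw_amounts,
    enzyme_source: str = "",
    reaction_system: str = "cyp",
) -> DepletionSeries:
    """Normalize raw parent amounts to percent of the t=0 value.

    The first element becomes exactly 100, so a series rescaled by any
    positive constant yields the same half-life downstream.
    """
    raw = np.asarray(raw_amounts, dtype=float)
    if raw.size == 0 or raw[0] <= 0:
        raise DegenerateDataError("t=0 amount must be strictly positive")
    if np.any(raw <= 0):
        raise DegenerateDataError("raw amounts must be strictly positive for the log transform")
    pct = raw / raw[0] * 100.0
    pct[0] = 100.0
    return DepletionSeries(
        enzyme_source=enzyme_source,
        reaction_system=reaction_system,
        times=np.asarray(times, dtype=float),
        percent_remaining=pct,
    )


def depletion_halflife(series: DepletionSeries) -> StabilityResult:
    """OLS regression of ln(% remaining) on time, including the t=0 point.

    Raises :class:`NoDepletionError` (carrying the partial result) when the
    slope is non-negative — flat or rising series have no finite half-life.
    """
    if series.n_points < 3:
        raise InsufficientDataError("half-life regression needs at least 3 time points")
    res = stats.linregress(series.times, np.log(series.percent_remaining))
    slope = float(res.slope)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    if slope >= 0:
        partial = StabilityResult(
            slope=slope, t_half=np.inf, r2=r2, n_points=series.n_points, status="no_depletion"
        )
        raise NoDepletionError("non-negative depletion slope; half-life undefined", result=partial)
    return StabilityResult(
        slope=slope,
        t_half=float(LN2 / -slope),
        r2=r2,
        n_points=series.n_points,
    )
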