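"""Noncompartmental analysis of plasma concentration–time profiles.

Model-free PK summary: Cmax/Tmax read off the observations, AUC0–t by the
linear trapezoidal rule over the observed span, and the terminal
elimination constant λz by log-linear regression on an automatically
selected terminal stretch (best adjusted r² over suffixes, minimum three
points, excluding Tmax) — mirroring common NCA software behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidArgumentError,
    NoEliminationError,
)

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Plasma concentrations (µg/mL) over time (h) after an IV bolus dose."""

    times: np.ndarray
    concentrations: np.ndarray
    dose: float | None = None  # mg/kg, metadata only
    route: str = "iv_bolus"
    subject_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise InvalidArgumentError("times and concentrations must be 1-D of equal length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise InvalidArgumentError("times must be non-negative and strictly increasing")
        if np.any(c < 0):
            raise InvalidArgumentError("concentrations must be non-negative")
        if self.route != "iv_bolus":
            raise InvalidArgumentError(f"unsupported route {self.route!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc_0_t: float
    lambda_z: float | None
    t_half: float | None
    lambda_z_points: tuple[int, ...]
    lambda_z_r2: float | None
    issues: dict = field(default_factory=dict)


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Peak concentration and its time; ties go to the earliest time."""
    if profile.n_points == 0:
        raise InvalidArgumentError("empty concentration-time profile")
    idx = int(np.argmax(profile.concentrations))  # argmax returns first maximum
    return float(profile.concentrations[idx]), float(profile.times[idx])


def auc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """Linear trapezoidal AUC over the observed span (µg·h/mL)."""
    if profile.n_points < 2:
        raise InsufficientDataError("AUC needs at least 2 points")
    return float(np.trapezoid(profile.concentrations, profile.times))


def terminal_slope(
    profile: ConcentrationTimeProfile,
    min_points: int = 3,
    loq: float | None = None,
) -> tuple[float, float, float, tuple[int, ...]]:
    """Estimate λz by log-linear regression on the terminal stretch.

    Candidate point sets are suffixes of the profile strictly after Tmax
    with at least `min_points` points; the suffix with the best adjusted r²
    wins, longer suffixes winning exact ties. Concentrations below `loq`
    are dropped first with a logged warning.

    Returns (lambda_z [1/h], t_half [h], r2, indices used).
    """
    if min_points < 3:
        raise InvalidArgumentError("terminal regression needs at least 3 points")
    _, tmax = cmax_tmax(profile)
    t, c = profile.times, profile.concentrations
    idx = np.arange(profile.n_points)
    after = idx[t > tmax]
    if loq is not None:
        n_drop = int(np.sum(c[after] < loq))
        if n_drop:
            log.warning("dropping %d terminal points below LOQ=%g", n_drop, loq)
        after = after[c[after] >= loq]
    if after.size < min_points:
        if t[-1] <= tmax:
            raise NoEliminationError(
                "profile peaks at the last sample; no elimination phase observed"
            )
        raise InsufficientDataError(
            f"need at least {min_points} post-Tmax points, have {after.size}"
        )
    if np.any(c[after] <= 0):
        raise DegenerateDataError("non-positive concentrations in terminal region")

    best = None  # (adj_r2, n_used, lambda_z, r2, indices)
    for start in range(0, after.size - min_points + 1):
        sel = after[start:]
        res = stats.linregress(t[sel], np.log(c[sel]))
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
        n = sel.size
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = (adj, n, -float(res.slope), r2, tuple(int(i) for i in sel))
        # prefer higher adjusted r2; on exact ties, more points
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    _, _, lam, r2, sel = best
    if lam <= 0:
        raise NoEliminationError("terminal slope is non-negative; no elimination phase")
    return lam, float(LN2 / lam), r2, sel


def nca_summary(profile: ConcentrationTimeProfile, loq: float | None = None) -> NCAResult:
    """Bundle Cmax/Tmax, AUC0–t and the terminal slope into one result.

    Component failures that leave a usable partial result (too few terminal
    points, no elimination phase) are recorded under ``issues`` with a
    stage label instead of aborting the whole summary.
    """
    if profile.n_points == 0:
        raise InvalidArgumentError("empty concentration-time profile")
    if np.all(profile.concentrations == 0):
        raise DegenerateDataError("all concentrations are zero")
    cmax, tmax = cmax_tmax(profile)
    issues: dict[str, str] = {}
    try:
        auc = auc_trapezoid(profile)
    except InsufficientDataError as exc:
        auc = np.nan
        issues["auc"] = str(exc)
    try:
        lam, t_half, r2, sel = terminal_slope(profile, loq=loq)
    except (InsufficientDataError, DegenerateDataError, NoEliminationError) as exc:
        lam = t_half = r2 = None
        sel = ()
        issues["terminal_slope"] = str(exc)
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=float(auc),
        lambda_z=lam,
        t_half=t_half,
        lambda_z_points=tuple(sel),
        lambda_z_r2=r2,
        issues=issues,
    )
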