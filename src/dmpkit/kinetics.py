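"""Enzyme-kinetic laws, nonlinear fitting, model selection and intrinsic clearance.

Three saturation laws are supported, the ones routinely compared in
microsomal metabolism work:

* Michaelis–Menten        v = Vmax*S / (Km + S)
* biphasic (two-site)     v = Vmax1*S/(Ks1+S) + Vmax2*S/(Ks2+S)
* substrate inhibition    v = Vmax*S / (Ks + S + S^2/Ksi)

Velocities are in pmol/min/mg microsomal protein (or pmol/min/nmol CYP for
recombinant isoforms) and substrate concentrations in µM, so Vmax/Km comes
out directly in µL/min/mg (resp. µL/min/nmol) — the intrinsic clearance.

Fitting is plain (optionally 1/v-weighted) nonlinear least squares with a
deterministic multi-start strategy seeded from the Eadie–Hofstee linear
regression; model comparison uses the small-sample corrected Akaike
criterion (AICc) with ties broken toward the simpler model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateDataError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidParameterError,
)

MODELS = ("michaelis_menten", "biphasic", "substrate_inhibition")

PARAM_NAMES = {
    "michaelis_menten": ("Vmax", "Km"),
    "biphasic": ("Vmax1", "Ks1", "Vmax2", "Ks2"),
    "substrate_inhibition": ("Vmax", "Ks", "Ksi"),
}

#: lower bound keeping every parameter strictly positive during optimisation
_LOWER_BOUND = 1e-9


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if not np.isfinite(value) or value <= 0:
            raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")


def _check_s(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise InvalidParameterError("substrate concentration S must be >= 0")
    return S


def mm_velocity(S, Vmax: float, Km: float):
    """Michaelis–Menten velocity Vmax*S/(Km+S); saturating, bounded by Vmax."""
    S = _check_s(S)
    _check_positive(Vmax=Vmax, Km=Km)
    return Vmax * S / (Km + S)


def biphasic_velocity(S, Vmax1: float, Ks1: float, Vmax2: float, Ks2: float):
    """Two-site velocity: sum of two saturable phases with distinct affinities.

    ``Vmax2 = 0`` is admitted (the second phase vanishes and the law reduces
    to Michaelis–Menten), which keeps the model hierarchy testable.
    """
    S = _check_s(S)
    _check_positive(Vmax1=Vmax1, Ks1=Ks1, Ks2=Ks2)
    if not np.isfinite(Vmax2) or Vmax2 < 0:
        raise InvalidParameterError(f"Vmax2 must be non-negative, got {Vmax2!r}")
    return Vmax1 * S / (Ks1 + S) + Vmax2 * S / (Ks2 + S)


def substrate_inhibition_velocity(S, Vmax: float, Ks: float, Ksi: float):
    """Substrate-inhibition velocity Vmax*S/(Ks + S + S^2/Ksi).

    Unimodal in S with the maximum at S = sqrt(Ks*Ksi); at large Ksi the
    inhibitory term vanishes and the law reduces to Michaelis–Menten.
    """
    S = _check_s(S)
    _check_positive(Vmax=Vmax, Ks=Ks, Ksi=Ksi)
    return Vmax * S / (Ks + S + S**2 / Ksi)


_MODEL_FUNCS = {
    "michaelis_menten": mm_velocity,
    "biphasic": biphasic_velocity,
    "substrate_inhibition": substrate_inhibition_velocity,
}


def model_velocity(model: str, S, params: Sequence[float]):
    """Evaluate a named kinetic law at S with positional parameters."""
    if model not in _MODEL_FUNCS:
        raise InvalidArgumentError(f"unknown kinetic model {model!r}")
    return _MODEL_FUNCS[model](S, *params)


@dataclass(frozen=True)
class KineticDataset:
    """One substrate-concentration/velocity series for one enzyme source.

    ``protein_basis`` is ``per_mg_protein`` for microsomes and
    ``per_nmol_cyp`` for recombinant isoforms; it only affects units,
    never the arithmetic.
    """

    enzyme_source: str
    metabolite_id: str
    concentrations: np.ndarray
    velocities: np.ndarray
    protein_basis: str = "per_mg_protein"

    def __post_init__(self):
        S = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if S.ndim != 1 or v.ndim != 1 or S.size != v.size:
            raise InvalidArgumentError("concentrations and velocities must be 1-D of equal length")
        order = np.argsort(S)
        S, v = S[order], v[order]
        if np.any(S <= 0):
            raise InvalidParameterError("substrate concentrations must be strictly positive")
        if np.any(np.diff(S) <= 0):
            raise InvalidParameterError("substrate concentrations must be distinct")
        if np.any(v < 0):
            raise InvalidParameterError("velocities must be non-negative")
        if self.protein_basis not in ("per_mg_protein", "per_nmol_cyp"):
            raise InvalidArgumentError(f"unknown protein basis {self.protein_basis!r}")
        object.__setattr__(self, "concentrations", S)
        object.__setattr__(self, "velocities", v)

    @property
    def n_points(self) -> int:
        return int(self.concentrations.size)


@dataclass(frozen=True)
class EadieHofsteePoints:
    """v versus v/S coordinates plus the r² of their linear regression.

    Exact Michaelis–Menten data are exactly collinear here (slope −Km,
    intercept Vmax); curvature flags atypical kinetics.
    """

    v: np.ndarray
    v_over_s: np.ndarray
    linearity_r2: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class FitOptions:
    """Fitting controls.

    ``weighting``: 'none' (unweighted, the default), 'inverse_v' (1/v
    weights on squared residuals) or 'inverse_v2' (1/v² weights, i.e.
    relative least squares — the matched objective when measurement error
    is proportional to signal). ``n_refine`` caps how many multi-start
    grid points are carried into full optimization after the cheap
    objective screen of the whole grid.
    """

    weighting: str = "none"
    max_nfev: int = 300
    n_refine: int = 10
    tol: float = 1e-12

    def __post_init__(self):
        if self.weighting not in ("none", "inverse_v", "inverse_v2"):
            raise InvalidArgumentError(f"unknown weighting {self.weighting!r}")
        if self.n_refine < 1:
            raise InvalidArgumentError("n_refine must be >= 1")


@dataclass(frozen=True)
class KineticModelFit:
    """A fitted kinetic law with uncertainties, diagnostics and CLint."""

    model: str
    params: dict
    param_se: dict
    clint: float
    rss: float
    aicc: float
    n_points: int
    enzyme_source: str = ""
    metabolite_id: str = ""
    protein_basis: str = "per_mg_protein"

    @property
    def n_model_params(self) -> int:
        return len(PARAM_NAMES[self.model])

    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in PARAM_NAMES[self.model]])


def eadie_hofstee_transform(dataset: KineticDataset) -> EadieHofsteePoints:
    """Transform a dataset to Eadie–Hofstee coordinates and rate the linearity.

    Regresses v on v/S; returns the points, the regression line and its r².
    """
    if dataset.n_points < 3:
        raise InsufficientDataError("Eadie–Hofstee diagnostic needs at least 3 points")
    v = dataset.velocities
    x = v / dataset.concentrations
    if np.allclose(x, x[0]):
        # vertical/degenerate cloud: no regression possible; report r2=0
        return EadieHofsteePoints(v=v, v_over_s=x, linearity_r2=0.0, slope=np.nan, intercept=np.nan)
    res = stats.linregress(x, v)
    return EadieHofsteePoints(
        v=v,
        v_over_s=x,
        linearity_r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def aicc(n: int, n_params: int, rss: float) -> float:
    """Small-sample corrected AIC for a least-squares fit.

    k counts the model parameters plus the residual variance. When the
    correction denominator n-k-1 is non-positive the criterion is +inf —
    the model simply has too many parameters for the design.
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        return math.inf
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def _mm_start(dataset: KineticDataset) -> tuple[float, float]:
    """Initial (Vmax, Km) from the Eadie–Hofstee regression, with fallback."""
    try:
        eh = eadie_hofstee_transform(dataset)
        vmax0, km0 = eh.intercept, -eh.slope
    except InsufficientDataError:
        vmax0, km0 = np.nan, np.nan
    if not (np.isfinite(vmax0) and vmax0 > 0 and np.isfinite(km0) and km0 > 0):
        vmax0 = 1.2 * float(np.max(dataset.velocities))
        km0 = float(np.median(dataset.concentrations))
    return vmax0, km0


#: log-spaced multipliers spanning [0.1x, 10x] around the Michaelis–Menten start
_GRID5 = tuple(np.geomspace(0.1, 10.0, 5))
_SPLIT5 = (0.1, 0.3, 0.5, 0.7, 0.9)


def _starts(model: str, dataset: KineticDataset) -> list[np.ndarray]:
    """Deterministic multi-start list, enumerated in fixed order."""
    vmax0, km0 = _mm_start(dataset)
    if model == "michaelis_menten":
        return [
            np.array([vmax0, km0]),
            np.array([float(np.max(dataset.velocities)) or 1.0, float(np.median(dataset.concentrations))]),
        ]
    if model == "substrate_inhibition":
        return [
            np.array([vmax0, km0 * f1, km0 * f2])
            for f1, f2 in itertools.product(_GRID5, _GRID5)
        ]
    if model == "biphasic":
        return [
            np.array([vmax0 * s, km0 * f1, max(vmax0 * (1 - s), _LOWER_BOUND), km0 * f2])
            for f1, f2, s in itertools.product(_GRID5, _GRID5, _SPLIT5)
        ]
    raise InvalidArgumentError(f"unknown kinetic model {model!r}")


def _min_points(model: str) -> int:
    return max(5, len(PARAM_NAMES[model]) + 1)


def fit_kinetic_model(
    dataset: KineticDataset,
    model: str,
    options: FitOptions | None = None,
) -> KineticModelFit:
    """Fit one kinetic law by (optionally weighted) nonlinear least squares.

    Uses a fixed multi-start enumeration so repeated calls are bit-identical;
    standard errors come from the Gauss–Newton covariance at the optimum.
    """
    if model not in MODELS:
        raise InvalidArgumentError(f"unknown kinetic model {model!r}")
    options = options or FitOptions()
    n = dataset.n_points
    names = PARAM_NAMES[model]
    k = len(names)
    if n < _min_points(model):
        raise InsufficientDataError(
            f"{model} needs at least {_min_points(model)} points, dataset has {n}"
        )
    S, v = dataset.concentrations, dataset.velocities
    if np.all(v == 0):
        raise DegenerateDataError("all velocities are zero; nothing to fit")

    vfloor = np.maximum(v, 1e-12 * np.max(v))
    if options.weighting == "inverse_v":
        w = 1.0 / vfloor
    elif options.weighting == "inverse_v2":
        w = 1.0 / vfloor**2
    else:
        w = np.ones_like(v)
    sw = np.sqrt(w)

    func = _MODEL_FUNCS[model]

    def residuals(p):
        return sw * (func(S, *p) - v)

    # screen the whole start grid by objective value, refine only the best
    starts = [np.maximum(x0, _LOWER_BOUND) for x0 in _starts(model, dataset)]
    screened = sorted(
        range(len(starts)), key=lambda i: (float(np.sum(residuals(starts[i]) ** 2)), i)
    )[: options.n_refine]

    best = None
    for i in screened:
        try:
            sol = optimize.least_squares(
                residuals,
                starts[i],
                bounds=(_LOWER_BOUND, np.inf),
                method="trf",
                xtol=options.tol,
                ftol=options.tol,
                gtol=options.tol,
                max_nfev=options.max_nfev,
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost * (1 - 1e-12):
            best = sol
    if best is None:
        raise FitFailureError(f"no start converged for model {model}")

    rss = float(2 * best.cost)
    # Gauss–Newton covariance: sigma^2 * (J'J)^-1, pseudo-inverse for safety
    dof = n - k
    if dof > 0 and rss > 0:
        try:
            jtj_inv = np.linalg.pinv(best.jac.T @ best.jac)
            se = np.sqrt(np.maximum(np.diag(jtj_inv) * rss / dof, 0.0))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
    else:
        se = np.full(k, np.nan)

    x = np.asarray(best.x, dtype=float)
    if model == "biphasic" and x[1] > x[3]:
        # phases are exchangeable; canonical order is high-affinity first
        x = x[[2, 3, 0, 1]]
        se = se[[2, 3, 0, 1]]
    params = dict(zip(names, (float(v_) for v_ in x)))
    fit = KineticModelFit(
        model=model,
        params=params,
        param_se=dict(zip(names, (float(s) for s in se))),
        clint=clint_from_params(model, params),
        rss=rss,
        aicc=aicc(n, k, rss),
        n_points=n,
        enzyme_source=dataset.enzyme_source,
        metabolite_id=dataset.metabolite_id,
        protein_basis=dataset.protein_basis,
    )
    return fit


def clint_from_params(model: str, params: dict) -> float:
    """Intrinsic clearance from fitted parameters, in µL/min per basis unit.

    Michaelis–Menten: Vmax/Km.  Substrate inhibition: Vmax/Ks.  Biphasic:
    the low-substrate limit Vmax1/Ks1 + Vmax2/Ks2 (the slope of v(S) at the
    origin, where therapeutic exposures usually sit).
    """
    if model == "michaelis_menten":
        _check_positive(Vmax=params["Vmax"], Km=params["Km"])
        return params["Vmax"] / params["Km"]
    if model == "substrate_inhibition":
        _check_positive(Vmax=params["Vmax"], Ks=params["Ks"], Ksi=params["Ksi"])
        return params["Vmax"] / params["Ks"]
    if model == "biphasic":
        _check_positive(Vmax1=params["Vmax1"], Ks1=params["Ks1"], Ks2=params["Ks2"])
        if params["Vmax2"] < 0:
            raise InvalidParameterError("Vmax2 must be non-negative")
        return params["Vmax1"] / params["Ks1"] + params["Vmax2"] / params["Ks2"]
    raise InvalidArgumentError(f"unknown kinetic model {model!r}")


def intrinsic_clearance(fit: KineticModelFit) -> float:
    """CLint of a fitted model (µL/min/mg protein or µL/min/nmol CYP)."""
    return clint_from_params(fit.model, fit.params)


def select_kinetic_model(
    dataset: KineticDataset,
    candidates: Sequence[str] = MODELS,
    options: FitOptions | None = None,
) -> list[KineticModelFit]:
    """Fit every candidate law and rank them by AICc (ascending).

    Within a ΔAICc of 2 the ranking prefers the model with fewer
    parameters — two-site or inhibition kinetics must earn their extra
    parameters, mirroring how curvature on an Eadie–Hofstee plot is only
    trusted when it is decisive.
    """
    candidates = list(candidates)
    if not candidates:
        raise InvalidArgumentError("candidate model list is empty")
    for m in candidates:
        if m not in MODELS:
            raise InvalidArgumentError(f"unknown kinetic model {m!r}")
    fits: list[KineticModelFit] = []
    errors: list[Exception] = []
    for m in candidates:
        try:
            fits.append(fit_kinetic_model(dataset, m, options))
        except (FitFailureError, InsufficientDataError) as exc:
            errors.append(exc)
    if not fits:
        raise FitFailureError(f"no candidate model converged: {errors}")

    import functools

    def compare(a: KineticModelFit, b: KineticModelFit) -> int:
        if a.aicc < b.aicc - 2:
            return -1
        if b.aicc < a.aicc - 2:
            return 1
        if a.n_model_params != b.n_model_params:
            return -1 if a.n_model_params < b.n_model_params else 1
        return -1 if a.aicc <= b.aicc else 1

    return sorted(fits, key=functools.cmp_to_key(compare))


def round_table(value: float, ndigits: int = 2) -> float:
    """Round-half-to-even at `ndigits` decimals, the report-table convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def eadie_hofstee_plot(dataset: KineticDataset, ax=None):
    """Optional diagnostic plot (v vs v/S with the regression line)."""
    import matplotlib.pyplot as plt

    eh = eadie_hofstee_transform(dataset)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(eh.v_over_s, eh.v, "o", label=dataset.enzyme_source or "data")
    if np.isfinite(eh.slope):
        xs = np.linspace(eh.v_over_s.min(), eh.v_over_s.max(), 50)
        ax.plot(xs, eh.intercept + eh.slope * xs, "-", lw=1,
                label=f"r²={eh.linearity_r2:.3f}")
    ax.set_xlabel("v / S")
    ax.set_ylabel("v")
    ax.legend()
    return ax
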