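"""Independent oracles used to cross-check the fitting code.

The grid oracle estimates kinetic parameters by exhaustive search over a
log-spaced grid of the *nonlinear* parameters with the maximal-velocity
parameters solved linearly at each grid point (velocity is linear in Vmax
for every law), followed by Nelder–Mead refinement. It shares no code
path with the package's multi-start trust-region fitter.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def _mm_basis(S, Km):
    return S / (Km + S)


def _si_basis(S, Ks, Ksi):
    return S / (Ks + S + S**2 / Ksi)


def _rss_one_column(x, v):
    """Best rss with a single linear coefficient (clipped non-negative)."""
    sxx = np.sum(x * x)
    sxv = np.sum(x * v)
    coef = max(sxv / sxx, 0.0) if sxx > 0 else 0.0
    return float(np.sum((coef * x - v) ** 2)), coef


def grid_fit(model: str, S, v, n_grid: int = 200):
    """Exhaustive grid search + local refinement; returns (params, rss).

    Parameter order matches the package convention: (Vmax, Km),
    (Vmax1, Ks1, Vmax2, Ks2) with Ks1 < Ks2, or (Vmax, Ks, Ksi).
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    kgrid = np.geomspace(S.min() / 10.0, S.max() * 10.0, n_grid)

    if model == "michaelis_menten":
        best = (np.inf, None)
        for Km in kgrid:
            rss, Vmax = _rss_one_column(_mm_basis(S, Km), v)
            if rss < best[0] and Vmax > 0:
                best = (rss, [Vmax, Km])
        params = best[1]
    elif model == "substrate_inhibition":
        best = (np.inf, None)
        for Ks in kgrid:
            for Ksi in kgrid:
                rss, Vmax = _rss_one_column(_si_basis(S, Ks, Ksi), v)
                if rss < best[0] and Vmax > 0:
                    best = (rss, [Vmax, Ks, Ksi])
        params = best[1]
    elif model == "biphasic":
        best = (np.inf, None)
        for i, Ks1 in enumerate(kgrid):
            for Ks2 in kgrid[i + 1:]:
                x1 = _mm_basis(S, Ks1)
                x2 = _mm_basis(S, Ks2)
                a11, a12 = np.sum(x1 * x1), np.sum(x1 * x2)
                a22 = np.sum(x2 * x2)
                b1, b2 = np.sum(x1 * v), np.sum(x2 * v)
                det = a11 * a22 - a12 * a12
                if det > 1e-12 * a11 * a22:
                    v1 = (a22 * b1 - a12 * b2) / det
                    v2 = (a11 * b2 - a12 * b1) / det
                else:
                    v1, v2 = -1.0, -1.0  # force single-phase fallback
                if v1 > 0 and v2 >= 0:
                    rss = float(np.sum((v1 * x1 + v2 * x2 - v) ** 2))
                    cand = [v1, Ks1, v2, Ks2]
                else:
                    rss, v1 = _rss_one_column(x1, v)
                    cand = [v1, Ks1, 1e-9, Ks2]
                if rss < best[0] and cand[0] > 0:
                    best = (rss, cand)
        params = best[1]
    else:
        raise ValueError(model)

    def velocity(p):
        if model == "michaelis_menten":
            return p[0] * S / (p[1] + S)
        if model == "substrate_inhibition":
            return p[0] * S / (p[1] + S + S**2 / p[2])
        return p[0] * S / (p[1] + S) + p[2] * S / (p[3] + S)

    def objective(logp):
        return float(np.sum((velocity(np.exp(logp)) - v) ** 2))

    res = optimize.minimize(
        objective,
        np.log(np.maximum(params, 1e-9)),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
    )
    refined = np.exp(res.x)
    if model == "biphasic" and refined[1] > refined[3]:
        refined = refined[[2, 3, 0, 1]]
    return refined, float(res.fun)


def analytic_iv_auc(c0: float, lam: float, t_end: float) -> float:
    """Closed-form integral of c0·exp(−lam·t) over [0, t_end]."""
    return c0 / lam * (1.0 - np.exp(-lam * t_end))
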