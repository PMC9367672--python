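"""Seeded synthetic-data generators matching each analysis stage's inputs.

Every generator is a pure function of its arguments and a seed: repeated
calls are bit-identical. Measurement error is proportional (CV-scaled),
the error structure of integrated chromatographic peak areas, whose
scatter scales with signal. Default designs copy the laboratory layouts
the package targets — 8 substrate concentrations log-spaced over 1–200 µM,
depletion sampling at 0/30/60/90 min, and the 9-point IV plasma schedule —
so recovery studies probe the identifiability those designs actually have.

A single global seed expands into independent per-generator streams via
``numpy.random.SeedSequence(seed, spawn_key)`` with a fixed stream id per
generator; adding a new generator therefore never perturbs existing
streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kinetics import KineticDataset, model_velocity
from .nca import ConcentrationTimeProfile
from .screening import PeakAreaMatrix
from .stability import LN2, DepletionSeries

log = logging.getLogger(__name__)

#: fixed stream ids; never renumber, only append
_STREAMS = {"velocity": 1, "depletion": 2, "iv_profile": 3, "peak_areas": 4}

DEFAULT_S_GRID = tuple(np.geomspace(1.0, 200.0, 8))
DEFAULT_DEPLETION_TIMES = (0.0, 30.0, 60.0, 90.0)
DEFAULT_PK_TIMES = (0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 6.0, 8.0)
DEFAULT_NOISE_CV = 0.05


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream derived from the global seed."""
    if stream not in _STREAMS:
        raise InvalidParameterError(f"unknown stream {stream!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of seed, noise level, design grids and true parameters."""

    seed: int = 0
    noise_cv: float = DEFAULT_NOISE_CV
    design: dict = field(default_factory=dict)
    true_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")


def simulate_velocities(
    model: str,
    true_params,
    s_grid,
    noise_cv: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Noisy velocities v_model·(1+ε), ε ~ N(0, cv²), truncated at zero.

    With ``size`` set, draws that many replicate vectors (size × |S|).
    Truncation events are logged: they bias low-signal points upward.
    """
    v_true = np.asarray(model_velocity(model, s_grid, list(true_params)))
    shape = v_true.shape if size is None else (size,) + v_true.shape
    eps = rng.normal(0.0, noise_cv, size=shape) if noise_cv > 0 else np.zeros(shape)
    v = v_true * (1.0 + eps)
    n_trunc = int(np.sum(v < 0))
    if n_trunc:
        log.warning("truncated %d negative velocity draws to 0", n_trunc)
        v = np.maximum(v, 0.0)
    return v


def simulate_velocity_dataset(
    model: str,
    true_params,
    s_grid=DEFAULT_S_GRID,
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = 1,
    seed: int = 0,
    enzyme_source: str = "synthetic",
    metabolite_id: str = "P1",
    protein_basis: str = "per_mg_protein",
):
    """One (or a list of) synthetic concentration–velocity dataset(s)."""
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= 0):
        raise InvalidParameterError("substrate grid must be strictly positive")
    rng = stream_rng(seed, "velocity")
    datasets = []
    for r in range(replicates):
        v = simulate_velocities(model, true_params, s_grid, noise_cv, rng)
        datasets.append(
            KineticDataset(
                enzyme_source=enzyme_source,
                metabolite_id=metabolite_id,
                concentrations=s_grid.copy(),
                velocities=v,
                protein_basis=protein_basis,
            )
        )
    return datasets[0] if replicates == 1 else datasets


def simulate_depletion(
    t_half_true: float,
    times=DEFAULT_DEPLETION_TIMES,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
    enzyme_source: str = "synthetic",
    reaction_system: str = "cyp",
) -> DepletionSeries:
    """Exponential parent depletion with proportional noise; t=0 pinned at 100.

    Draws that would go non-positive (possible only at extreme noise) are
    floored at a tiny positive value with a logged warning, keeping the log
    transform defined.
    """
    if t_half_true <= 0 or not np.isfinite(t_half_true):
        raise InvalidParameterError("t_half_true must be strictly positive and finite")
    times = np.asarray(times, dtype=float)
    rng = stream_rng(seed, "depletion")
    pct = 100.0 * np.exp(-LN2 * times / t_half_true)
    if noise_cv > 0:
        pct = pct * (1.0 + rng.normal(0.0, noise_cv, size=times.size))
    pct[0] = 100.0
    n_floor = int(np.sum(pct <= 0))
    if n_floor:
        log.warning("floored %d non-positive depletion draws", n_floor)
        pct = np.maximum(pct, 1e-9)
    return DepletionSeries(
        enzyme_source=enzyme_source,
        reaction_system=reaction_system,
        times=times,
        percent_remaining=pct,
    )


def simulate_iv_profile(
    dose: float,
    clearance: float,
    volume: float,
    times=DEFAULT_PK_TIMES,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
    subject_id: str = "synthetic",
) -> ConcentrationTimeProfile:
    """One-compartment IV-bolus profile C(t) = (dose/V)·exp(−(CL/V)·t).

    Noise is multiplicative lognormal with unit mean (σ chosen so the
    coefficient of variation equals ``noise_cv``), keeping concentrations
    positive as a bioanalytical assay would report them.
    """
    if dose <= 0 or clearance <= 0 or volume <= 0:
        raise InvalidParameterError("dose, clearance and volume must be strictly positive")
    times = np.asarray(times, dtype=float)
    c = (dose / volume) * np.exp(-(clearance / volume) * times)
    if noise_cv > 0:
        rng = stream_rng(seed, "iv_profile")
        sigma = np.sqrt(np.log1p(noise_cv**2))
        c = c * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=times.size)
    return ConcentrationTimeProfile(
        times=times, concentrations=c, dose=dose, route="iv_bolus", subject_id=subject_id
    )


def simulate_peak_area_matrix(
    n_species: int,
    n_metabolites: int,
    dominance_pattern=None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PeakAreaMatrix:
    """Peak-area matrix with one designated dominant species per metabolite.

    ``dominance_pattern`` gives the dominant species index per metabolite
    (default: drawn at random); ``missing_rate`` is the probability that a
    non-dominant cell is not detected (NaN).
    """
    if n_species < 1 or n_metabolites < 1:
        raise InvalidParameterError("dimensions must be >= 1")
    if not 0 <= missing_rate < 1:
        raise InvalidParameterError("missing_rate must be in [0, 1)")
    rng = stream_rng(seed, "peak_areas")
    if dominance_pattern is None:
        dominance_pattern = rng.integers(0, n_species, size=n_metabolites)
    dominance_pattern = np.asarray(dominance_pattern, dtype=int)
    if dominance_pattern.size != n_metabolites or np.any(
        (dominance_pattern < 0) | (dominance_pattern >= n_species)
    ):
        raise InvalidParameterError("dominance_pattern must index a species per metabolite")

    areas = rng.lognormal(mean=np.log(1e4), sigma=0.8, size=(n_species, n_metabolites))
    for j, dom in enumerate(dominance_pattern):
        col_max = areas[:, j].max()
        areas[dom, j] = col_max * rng.uniform(1.2, 2.0)
    if missing_rate > 0:
        mask = rng.random((n_species, n_metabolites)) < missing_rate
        mask[dominance_pattern, np.arange(n_metabolites)] = False
        areas = np.where(mask, np.nan, areas)
    df = pd.DataFrame(
        areas,
        index=[f"S{i+1}" for i in range(n_species)],
        columns=[f"P{j+1}" for j in range(n_metabolites)],
    )
    return PeakAreaMatrix(areas=df)
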