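"""Screening normalizations: metabolite profiling, phenotyping, inhibition.

Three small, exact operations used around the kinetic work:

* peak-area matrices (species × metabolite) normalized per metabolite to
  the largest producer = 100%, with not-detected cells kept distinct from
  small values;
* percent inhibition of metabolite formation relative to an uninhibited
  control;
* ranking of recombinant CYP isoforms by their share of total formation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidParameterError

log = logging.getLogger(__name__)

#: marker used in CSV output for a metabolite peak absent from a chromatogram
ND = "N.D."


@dataclass(frozen=True)
class PeakAreaMatrix:
    """Raw peak areas, species in rows, metabolites in columns.

    Not-detected cells are NaN — explicitly distinct from a zero or small
    measured area.
    """

    areas: pd.DataFrame

    def __post_init__(self):
        df = self.areas.astype(float)
        if (df.to_numpy() < 0).any():
            raise InvalidParameterError("peak areas must be non-negative")
        object.__setattr__(self, "areas", df)

    @property
    def species(self) -> list[str]:
        return list(self.areas.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def detected(self) -> pd.DataFrame:
        return self.areas.notna()


@dataclass(frozen=True)
class InhibitionRecord:
    inhibitor: str
    target_isoform: str
    metabolite_id: str
    activity_control: float
    activity_inhibited: float

    def __post_init__(self):
        if self.activity_control <= 0:
            raise InvalidParameterError("control activity must be strictly positive")
        if self.activity_inhibited < 0:
            raise InvalidParameterError("inhibited activity must be non-negative")


def normalize_peak_areas(matrix: PeakAreaMatrix) -> pd.DataFrame:
    """Express each metabolite column as percent of its largest producer.

    The species with the largest peak is set to exactly 100; undetected
    cells stay NaN. Idempotent: normalizing a normalized matrix returns it
    unchanged.
    """
    df = matrix.areas
    out = {}
    for col in df.columns:
        vals = df[col]
        top = vals.max(skipna=True)
        if not np.isfinite(top) or top <= 0:
            raise DegenerateDataError(f"metabolite column {col!r} has no positive detected area")
        out[col] = vals / top * 100.0
    return pd.DataFrame(out, index=df.index)


def format_percent_table(percentages: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Report-table view: percentages to `ndigits` decimals, NaN as N.D."""
    rounded = percentages.round(ndigits)
    return rounded.astype(object).where(percentages.notna(), ND)


def inhibition_percent(record: InhibitionRecord, clip_activation: bool = False) -> float:
    """Percent inhibition: 100·(1 − inhibited/control).

    Activation (inhibited > control) produces a negative value, kept and
    logged by default so the information is not destroyed; pass
    ``clip_activation=True`` to floor it at 0.
    """
    pct = 100.0 * (1.0 - record.activity_inhibited / record.activity_control)
    if pct < 0:
        log.warning(
            "activation observed for %s on %s (%.1f%% above control)",
            record.inhibitor, record.target_isoform, -pct,
        )
        if clip_activation:
            return 0.0
    return pct


def phenotype_ranking(activities: Mapping[str, float]) -> list[tuple[str, float, float]]:
    """Rank isoforms by metabolite formation, descending, with % shares.

    Returns (isoform, activity, share_pct) tuples; shares sum to 100.
    Ties are broken alphabetically for determinism.
    """
    if not activities:
        raise DegenerateDataError("no isoform activities provided")
    for name, a in activities.items():
        if a < 0:
            raise InvalidParameterError(f"activity of {name} must be non-negative")
    total = float(sum(activities.values()))
    if total <= 0:
        raise DegenerateDataError("all isoform activities are zero")
    ranked = sorted(activities.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(a), 100.0 * a / total) for name, a in ranked]
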