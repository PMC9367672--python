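"""In vitro–in vivo extrapolation of hepatic clearance (well-stirred model).

The chain is:

1. CLint,in vitro = Σ_i Vmax(M_i)/Km(M_i)            [µL/min/mg protein]
2. SF             = mg microsomal protein/g liver × g liver/kg body weight
3. CLint,in vivo  = CLint,in vitro × SF / 1000        [mL/(min·kg)]
4. CLH            = QH·fu·CLint,in vivo / (QH + fu·CLint,in vivo)

The well-stirred model treats the liver as one well-mixed compartment, so
CLH is bounded above by hepatic blood flow QH; the extraction ratio
100·CLH/QH classifies the compound (<30% low, >70% high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, InvalidParameterError, UnitMismatchError
from .kinetics import KineticModelFit


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Per-species scaling constants for IVIVE."""

    species: str
    liver_weight: float  # g liver per kg body weight
    microsomal_protein: float  # mg microsomal protein per g liver
    qh: float  # hepatic blood flow, mL/(min·kg body weight)

    def __post_init__(self):
        for name in ("liver_weight", "microsomal_protein", "qh"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")


#: Literature scaling constants for the three species with IV reference data.
BUILTIN_PHYSIOLOGY = {
    "dog": SpeciesPhysiology("dog", liver_weight=32.0, microsomal_protein=77.9, qh=30.9),
    "rat": SpeciesPhysiology("rat", liver_weight=40.0, microsomal_protein=44.8, qh=55.2),
    "human": SpeciesPhysiology("human", liver_weight=25.7, microsomal_protein=48.8, qh=20.7),
}


@dataclass(frozen=True)
class HepaticClearanceResult:
    species: str
    clint_invitro: float  # µL/min/mg, summed over metabolites
    sf: float  # mg microsomal protein per kg body weight
    clint_invivo: float  # mL/(min·kg)
    fu: float
    clh: float  # mL/(min·kg)
    extraction_pct: float
    category: str  # low / intermediate / high


def aggregate_clint(fits: Sequence[KineticModelFit]) -> float:
    """Sum per-metabolite intrinsic clearances for one enzyme source.

    All fits must share the enzyme source and the protein basis; mixing
    per-mg with per-nmol clearances would be dimensionally meaningless.
    """
    fits = list(fits)
    if not fits:
        raise InvalidArgumentError("need at least one kinetic fit to aggregate")
    bases = {f.protein_basis for f in fits}
    sources = {f.enzyme_source for f in fits}
    if len(bases) > 1:
        raise UnitMismatchError(f"mixed protein bases: {sorted(bases)}")
    if len(sources) > 1:
        raise UnitMismatchError(f"mixed enzyme sources: {sorted(sources)}")
    return float(sum(f.clint for f in fits))


def scaling_factor(phys: SpeciesPhysiology) -> float:
    """mg microsomal protein per kg body weight: protein content × liver weight."""
    return phys.microsomal_protein * phys.liver_weight


def scale_clint(clint_invitro: float, sf: float) -> float:
    """Scale µL/min/mg CLint to whole-body mL/(min·kg).

    The single µL→mL conversion of the pipeline happens here (×1e-3).
    """
    if clint_invitro < 0 or sf < 0:
        raise InvalidParameterError("clint and scaling factor must be non-negative")
    return clint_invitro * sf * 1e-3


def well_stirred_clh(clint_invivo: float, qh: float, fu: float = 1.0) -> float:
    """Hepatic clearance from the well-stirred liver model.

    Monotone increasing in CLint with the flow-limited ceiling QH; fu is
    the unbound fraction in blood (default 1 when binding data are absent).
    """
    if not 0 < fu <= 1:
        raise InvalidParameterError(f"fu must be in (0, 1], got {fu!r}")
    if qh <= 0:
        raise InvalidParameterError("hepatic blood flow must be strictly positive")
    if clint_invivo < 0:
        raise InvalidParameterError("clint_invivo must be non-negative")
    return qh * fu * clint_invivo / (qh + fu * clint_invivo)


def invert_well_stirred(clh: float, qh: float, fu: float = 1.0) -> float:
    """Algebraic inverse of the well-stirred model: CLint = QH·CLH/(fu·(QH−CLH))."""
    if not 0 < fu <= 1:
        raise InvalidParameterError(f"fu must be in (0, 1], got {fu!r}")
    if not 0 <= clh < qh:
        raise InvalidParameterError("CLH must satisfy 0 <= CLH < QH")
    return qh * clh / (fu * (qh - clh))


def extraction_ratio(clh: float, qh: float) -> tuple[float, str]:
    """Hepatic extraction as a percent of blood flow, plus the clearance class.

    <30% of QH is low clearance, >70% high, otherwise intermediate; the
    boundaries themselves fall in the intermediate class.
    """
    if qh <= 0:
        raise InvalidParameterError("hepatic blood flow must be strictly positive")
    if not 0 <= clh < qh:
        raise InvalidParameterError("CLH must satisfy 0 <= CLH < QH (well-stirred bound)")
    pct = 100.0 * clh / qh
    if pct < 30.0:
        category = "low"
    elif pct > 70.0:
        category = "high"
    else:
        category = "intermediate"
    return pct, category


def predict_hepatic_clearance(
    clint_invitro: float,
    phys: SpeciesPhysiology,
    fu: float = 1.0,
) -> HepaticClearanceResult:
    """Run the full IVIVE chain for one species from an aggregated CLint."""
    sf = scaling_factor(phys)
    clint_invivo = scale_clint(clint_invitro, sf)
    clh = well_stirred_clh(clint_invivo, phys.qh, fu)
    pct, category = extraction_ratio(clh, phys.qh)
    return HepaticClearanceResult(
        species=phys.species,
        clint_invitro=float(clint_invitro),
        sf=float(sf),
        clint_invivo=float(clint_invivo),
        fu=float(fu),
        clh=float(clh),
        extraction_pct=float(pct),
        category=category,
    )
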