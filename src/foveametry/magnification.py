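"""Areal/volume magnification model of arrested foveal development.

Normal centrifugal displacement magnifies the lateral area available to
structures originating at the foveal centre: mass that would occupy a disc
of radius E − R is spread over a disc of radius E.  A retardation R at
control eccentricity E therefore reduces the preterm/control ratio of
available area to

    A(E, R) = ((E − R) / E)²,                0 ≤ R ≤ E,

and, combining with the layer thickness ratio T = t_PG/t_C, the ratio of
available volume to

    V = T · A.

At fixed cell density a constant cell count implies structure diameter
scales with the square root of available area, giving the minified
cone-pedicle diameter d = d₀·√A (d₀ = 6.3 µm at 25 000 pedicles/mm²); a
volume-like ratio maps to a sphere-equivalent diameter fraction via its
cube root.

Reporting conventions: ratios to 2 decimals, µm to 1 decimal, percentages
to integers (half-up); raw doubles are always retained in machine output.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, EccentricityRangeError
from .types import (
    Group,
    Layer,
    MagnificationRecord,
    NormalDisplacementCurve,
    PedicleModel,
)

__all__ = [
    "round_half_up",
    "area_ratio",
    "volume_ratio",
    "pedicle_diameter",
    "sphere_equivalent_diameter_ratio",
    "residual_displacement_pct",
    "build_records",
    "volume_extremes_at",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, the convention of printed clinical tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def area_ratio(eccentricity_um: float, retardation_um: float) -> float:
    """Preterm/control available-area ratio ((E − R)/E)² at eccentricity E."""
    E, R = float(eccentricity_um), float(retardation_um)
    if E <= 0:
        raise ConfigurationError("eccentricity must be positive")
    if R < 0 or R > E:
        raise ConfigurationError(
            f"retardation {R} µm outside [0, {E}] µm: total blockage beyond "
            "the foveal centre is not representable"
        )
    return ((E - R) / E) ** 2


def volume_ratio(thickness_ratio: float, area_ratio: float) -> float:
    """Preterm/control available-volume ratio T·A (raw; print to 2 dp)."""
    if thickness_ratio < 0 or area_ratio < 0:
        raise ConfigurationError("ratios must be >= 0")
    return thickness_ratio * area_ratio


def pedicle_diameter(area_ratio: float, model: PedicleModel = PedicleModel()) -> float:
    """Minified structure diameter d₀·√A under a constant cell count, µm."""
    if area_ratio < 0:
        raise ConfigurationError("area ratio must be >= 0")
    return model.reference_diameter_um * float(np.sqrt(area_ratio))


def sphere_equivalent_diameter_ratio(volume_like_ratio: float) -> float:
    """Diameter fraction of a sphere whose volume shrank by the given ratio.

    The ratio to cube is an explicit argument: published figures use the
    areal ratio of the OPL here, not the tabulated volume ratio, and the
    two differ — callers must choose deliberately.
    """
    if volume_like_ratio < 0:
        raise ConfigurationError("ratio must be >= 0")
    return float(np.cbrt(volume_like_ratio))


def residual_displacement_pct(
    retardation_um: float,
    normal_curve: NormalDisplacementCurve,
    eccentricity_um: float,
) -> float:
    """Retardation as a percent of normative displacement at E.

    Values above 100% are permitted (they flag retardation exceeding the
    supplied normative curve) but are worth inspecting.
    """
    normal = normal_curve(eccentricity_um)
    if normal <= 0:
        raise EccentricityRangeError(
            f"normative displacement at {eccentricity_um} µm is not positive"
        )
    return 100.0 * float(retardation_um) / normal


def build_records(
    cells: Iterable[tuple[Group, Layer, float, float, float]],
) -> list[MagnificationRecord]:
    """Assemble magnification records from (group, layer, E, R, T) cells."""
    out = []
    for group, layer, E, R, T in cells:
        A = area_ratio(E, R)
        out.append(
            MagnificationRecord(
                layer=Layer(layer), group=Group(group), eccentricity_um=float(E),
                retardation_um=float(R), thickness_ratio=float(T),
                area_ratio=A, volume_ratio=volume_ratio(T, A),
            )
        )
    return out


def volume_extremes_at(
    records: Sequence[MagnificationRecord], eccentricity_um: float
) -> tuple[int, int]:
    """(min, max) of 100·V over the layers at one eccentricity, integer %."""
    vals = [r.volume_ratio for r in records
            if r.eccentricity_um == float(eccentricity_um)]
    if not vals:
        raise EccentricityRangeError(
            f"no magnification records at {eccentricity_um} µm"
        )
    return (
        int(round_half_up(100.0 * min(vals))),
        int(round_half_up(100.0 * max(vals))),
    )
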