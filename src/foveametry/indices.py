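"""Morphometric indices at the foveal centre and lateral scaling.

The foveal-developmental-arrest (FDA) index relates the outer layers that
normally dominate the foveal centre (HFL+ONL) to the inner layers that are
normally extruded from it (IRL = GCL+IPL+INL, plus OPL):

    FDA = (HFL+ONL thickness) / (IRL thickness + OPL thickness)   at FC.

Mature foveae have a large FDA (thick HFL+ONL over a few µm of residual
IRL); arrested development leaves IRL and OPL at the centre and drives the
index down.  Group means of ≤ 5 coincide with clinical signs of immaturity,
so 5 is the default classification threshold (inclusive).

Lateral scaling converts instrument eccentricities to retinal µm using the
Bennett-type reduced-eye relation: retinal scale ∝ (axial length − 1.82 mm).
"""

from __future__ import annotations

import enum
from dataclasses import replace

from .errors import ConfigurationError, UndefinedIndexError
from .types import FovealCentreMetrics, LayerProfile

__all__ = [
    "fda_index",
    "thickness_ratio",
    "Maturity",
    "classify_immaturity",
    "lateral_scaling",
    "scale_profile",
    "annotate_fc_metrics",
    "FDA_THRESHOLD",
]

FDA_THRESHOLD = 5.0


def fda_index(hfl_onl_t_um: float, irl_t_um: float, opl_t_um: float) -> float:
    """Foveal-developmental-arrest index (HFL+ONL)/(IRL + OPL) at FC."""
    denom = irl_t_um + opl_t_um
    if denom <= 0:
        raise UndefinedIndexError("FDA undefined: IRL + OPL thickness is zero")
    return hfl_onl_t_um / denom


def thickness_ratio(pg_thickness_um: float, c_thickness_um: float) -> float:
    """Preterm/control thickness ratio at one eccentricity (dimensionless).

    Reported to two decimals in tables; this returns the raw value.
    """
    if c_thickness_um <= 0:
        raise UndefinedIndexError("thickness ratio undefined: control thickness is zero")
    return pg_thickness_um / c_thickness_um


class Maturity(str, enum.Enum):
    IMMATURE = "immature"
    MATURE = "mature"


def classify_immaturity(fda: float, threshold: float = FDA_THRESHOLD) -> Maturity:
    """Classify a foveal centre as immature iff FDA <= threshold."""
    if fda < 0:
        raise UndefinedIndexError("FDA must be >= 0")
    return Maturity.IMMATURE if fda <= threshold else Maturity.MATURE


def lateral_scaling(axial_length_mm: float, reference_axial_length_mm: float) -> float:
    """Multiplicative eccentricity scale factor between two eyes.

    Bennett reduced-eye relation: retinal distance per degree scales with
    (axial length − 1.82 mm), so eccentricities measured in an eye of one
    axial length map to a reference eye by the ratio of those terms.
    """
    for name, al in (("axial", axial_length_mm), ("reference", reference_axial_length_mm)):
        if al <= 2.0:
            raise ConfigurationError(f"{name} axial length {al} mm is non-physical")
    return (axial_length_mm - 1.82) / (reference_axial_length_mm - 1.82)


def scale_profile(profile: LayerProfile, factor: float) -> LayerProfile:
    """Apply a lateral scale factor to a profile's eccentricities."""
    if factor <= 0:
        raise ConfigurationError("scale factor must be positive")
    return replace(profile, eccentricity_um=profile.eccentricity_um * factor)


def annotate_fc_metrics(metrics: FovealCentreMetrics) -> FovealCentreMetrics:
    """Fill in the FDA field of a foveal-centre thickness stack."""
    fda = fda_index(metrics.hfl_onlt_um, metrics.irlt_um, metrics.oplt_um)
    return replace(metrics, fda=fda)
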