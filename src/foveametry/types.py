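"""Core domain containers.

Lateral and axial distances are in micrometres throughout; eccentricity 0 is
the foveal centre (FC) and profiles run along the temporal meridian.  Layers
follow the segmentation granularity of adult foveal OCT morphometry: the
combined ganglion-cell + inner-plexiform layer (GCL+IPL), the inner nuclear
layer (INL), the outer plexiform layer (OPL) and the combined Henle-fibre +
outer-nuclear layer (HFL+ONL).  GCL+IPL and INL together form the inner
retinal layers (IRL) that are normally extruded from FC during development.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SchemaError


class Layer(str, enum.Enum):
    GCL_IPL = "GCL_IPL"
    INL = "INL"
    OPL = "OPL"
    HFL_ONL = "HFL_ONL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Group(str, enum.Enum):
    C = "C"
    PG1 = "PG1"
    PG2 = "PG2"
    PG3 = "PG3"
    SYNTH = "SYNTH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Layers whose central depletion marks a mature fovea (sigmoid-shaped
#: thickness profiles rising from FC to the rim).
IRL_TYPE_LAYERS = (Layer.GCL_IPL, Layer.INL, Layer.OPL)


@dataclass(frozen=True)
class LayerProfile:
    """Thickness vs temporal eccentricity for one layer of one subject/group.

    Parameters
    ----------
    layer
        Retinal layer the profile belongs to.
    eccentricity_um
        Strictly increasing eccentricities (µm, >= 0), at least 4 samples.
    thickness_um
        Non-negative thickness at each eccentricity (µm).
    subject_id, group
        Provenance labels; ``group`` is one of C / PG1 / PG2 / PG3 / SYNTH.
    """

    layer: Layer
    eccentricity_um: np.ndarray
    thickness_um: np.ndarray
    subject_id: str = "synthetic"
    group: Group = Group.SYNTH
    side: str = "temporal"

    def __post_init__(self) -> None:
        e = np.asarray(self.eccentricity_um, dtype=float)
        t = np.asarray(self.thickness_um, dtype=float)
        object.__setattr__(self, "eccentricity_um", e)
        object.__setattr__(self, "thickness_um", t)
        object.__setattr__(self, "layer", Layer(self.layer))
        object.__setattr__(self, "group", Group(self.group))
        if e.ndim != 1 or t.shape != e.shape:
            raise SchemaError("eccentricity and thickness must be 1-D and equal length")
        if e.size < 4:
            raise SchemaError(
                f"profile needs >= 4 samples for spline fitting, got {e.size}"
            )
        if np.any(np.diff(e) <= 0):
            raise SchemaError("eccentricities must be strictly increasing")
        if e[0] < 0:
            raise SchemaError("eccentricities must be >= 0")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise SchemaError("thickness values must be finite and >= 0")
        if self.side != "temporal":
            raise SchemaError("only temporal-side profiles are supported")

    @property
    def n_samples(self) -> int:
        return int(self.eccentricity_um.size)


@dataclass(frozen=True)
class ReflectivityProfile:
    """A-scan reflectivity vs depth, normalised to [0, 1].

    ``true_bands`` optionally records ground-truth band boundaries for
    synthetic profiles as ``(label, inner_um, outer_um)`` triples.
    """

    depth_um: np.ndarray
    reflectivity: np.ndarray
    true_bands: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_um, dtype=float)
        r = np.asarray(self.reflectivity, dtype=float)
        object.__setattr__(self, "depth_um", d)
        object.__setattr__(self, "reflectivity", r)
        if d.ndim != 1 or r.shape != d.shape or d.size < 2:
            raise SchemaError("depth and reflectivity must be 1-D, equal length, >= 2")
        steps = np.diff(d)
        if np.any(steps <= 0):
            raise SchemaError("depths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise SchemaError("axial sampling must be uniform")
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise SchemaError("reflectivity must lie within [0, 1]")

    @property
    def step_um(self) -> float:
        return float(self.depth_um[1] - self.depth_um[0])


@dataclass(frozen=True)
class BandLocation:
    """Peak and flanking troughs of a hyperreflective band in an A-scan."""

    peak_depth_um: float
    peak_reflectivity: float
    inner_trough_um: float
    inner_trough_reflectivity: float
    outer_trough_um: float
    outer_trough_reflectivity: float

    def __post_init__(self) -> None:
        if not (self.inner_trough_um < self.peak_depth_um < self.outer_trough_um):
            raise SchemaError("troughs must flank the peak in depth")
        if (
            self.inner_trough_reflectivity >= self.peak_reflectivity
            or self.outer_trough_reflectivity >= self.peak_reflectivity
        ):
            raise SchemaError("trough reflectivity must be below peak reflectivity")


@dataclass(frozen=True)
class RetardationEstimate:
    """Horizontal displacement between control and preterm cumulative curves.

    ``residual_um`` is the residual centrifugal displacement E − retardation,
    i.e. the preterm eccentricity holding the same cumulative layer mass that
    controls hold at eccentricity E.  ``error`` is set (and ``retardation_um``
    is NaN) when the estimate failed at this eccentricity.
    """

    layer: Layer
    group: Group
    eccentricity_um: float
    retardation_um: float
    residual_um: float
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None and np.isfinite(self.retardation_um)


@dataclass(frozen=True)
class GroupSummary:
    """Mean / min / max retardation over layer x eccentricity cells."""

    group: Group
    window_um: tuple[float, float]
    mean_um: float
    min_um: float
    max_um: float
    n_cells: int

    @property
    def mean_um_rounded(self) -> int:
        """Mean rounded to integer µm, the reporting convention."""
        from .magnification import round_half_up

        return int(round_half_up(self.mean_um, 0))


@dataclass(frozen=True)
class MagnificationRecord:
    """Per-cell output of the areal/volume magnification model.

    ``area_ratio`` = ((E − R)/E)² is the preterm/control ratio of available
    lateral area implied by retardation R at control eccentricity E;
    ``volume_ratio`` = thickness_ratio × area_ratio.
    """

    layer: Layer
    group: Group
    eccentricity_um: float
    retardation_um: float
    thickness_ratio: float
    area_ratio: float
    volume_ratio: float


@dataclass(frozen=True)
class PedicleModel:
    """Cone-pedicle geometry used for minification estimates.

    Defaults: normative pedicle density 25 000 cells/mm² and mean pedicle
    diameter 6.3 µm on the adult foveal slope.
    """

    density_per_mm2: float = 25_000.0
    reference_diameter_um: float = 6.3

    def __post_init__(self) -> None:
        if self.density_per_mm2 <= 0 or self.reference_diameter_um <= 0:
            raise SchemaError("pedicle density and diameter must be positive")


@dataclass(frozen=True)
class NormalDisplacementCurve:
    """User-supplied normative centrifugal displacement vs eccentricity.

    Typically digitised from published histology-based ganglion-cell or
    pedicle displacement data; it is consumed, never derived, here.
    """

    eccentricity_um: np.ndarray
    displacement_um: np.ndarray
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        e = np.asarray(self.eccentricity_um, dtype=float)
        d = np.asarray(self.displacement_um, dtype=float)
        object.__setattr__(self, "eccentricity_um", e)
        object.__setattr__(self, "displacement_um", d)
        if e.ndim != 1 or d.shape != e.shape or e.size < 2:
            raise SchemaError("curve needs >= 2 (eccentricity, displacement) samples")
        if np.any(np.diff(e) <= 0):
            raise SchemaError("eccentricities must be strictly increasing")
        if np.any(d < 0):
            raise SchemaError("displacement must be >= 0")

    def __call__(self, eccentricity_um: float) -> float:
        from .errors import EccentricityRangeError

        e = float(eccentricity_um)
        if e < self.eccentricity_um[0] or e > self.eccentricity_um[-1]:
            raise EccentricityRangeError(
                f"eccentricity {e} µm outside curve range "
                f"[{self.eccentricity_um[0]}, {self.eccentricity_um[-1]}] µm"
            )
        return float(np.interp(e, self.eccentricity_um, self.displacement_um))


@dataclass(frozen=True)
class FovealCentreMetrics:
    """Thickness stack at the foveal centre with the derived arrest index."""

    subject_id: str
    group: Group
    rt_um: float
    fd_um: float
    irlt_um: float
    oplt_um: float
    hfl_onlt_um: float
    fda: float = field(default=float("nan"))
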