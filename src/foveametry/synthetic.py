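"""Synthetic foveal cohort and A-scan generator.

The generator emulates the two morphological regimes seen in adult foveal
OCT: controls, in which the inner retinal layers (GCL+IPL, INL) and the OPL
are depleted at the foveal centre and rise sigmoidally toward the rim, and
preterms with arrested development, in which those layers persist centrally.
Preterm profiles are derived from control profiles by a mass-preserving
eccentricity warp with analytically known ground truth, so the downstream
retardation estimator can be validated by parameter recovery: if the warp is
ψ and the control thickness is t_C, the preterm thickness is

    t_PG(e) = t_C(ψ(e)) · ψ'(e),

which makes the cumulative thickness satisfy Cum_PG(e) = Cum_C(ψ(e)) exactly,
i.e. the mass that controls hold inside eccentricity ψ(e) is compressed into
[0, e] in the preterm — the phenomenological signature of retarded
centrifugal displacement.  The true retardation at a control eccentricity E
is then r(E) = E − ψ⁻¹(E).

The warp is a stand-in for the unknown displacement mechanism (traction vs
migration); it reproduces the geometry of arrested displacement, nothing
more.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf, expit

from .errors import ConfigurationError, InvalidWarpError
from .types import IRL_TYPE_LAYERS, Group, Layer, LayerProfile, ReflectivityProfile

__all__ = [
    "WarpForm",
    "WarpSpec",
    "ShapeParams",
    "GroupSpec",
    "CohortConfig",
    "Cohort",
    "WarpedProfile",
    "control_shape",
    "make_control_profile",
    "apply_retardation_warp",
    "synthesize_ascan",
    "generate_cohort",
    "DEFAULT_CONTROL_SHAPES",
]


class WarpForm(str, enum.Enum):
    SATURATING_EXPONENTIAL = "saturating_exponential"
    LINEAR_CAPPED = "linear_capped"


@dataclass(frozen=True)
class WarpSpec:
    """Eccentricity warp ψ encoding retarded centrifugal displacement.

    ``saturating_exponential`` (default): ψ(e) = e + r_max·(1 − exp(−e/λ)),
    large fractional blockage centrally, saturating at r_max peripherally.
    ``linear_capped``: ψ(e) = e + r_max·min(e/λ, 1).

    Both satisfy ψ(0) = 0, ψ(e) ≥ e and ψ strictly increasing, so the
    induced preterm profile is a valid rearrangement of control mass.
    """

    r_max_um: float
    lambda_um: float
    form: WarpForm = WarpForm.SATURATING_EXPONENTIAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", WarpForm(self.form))
        if self.r_max_um < 0:
            raise InvalidWarpError("r_max must be >= 0")
        if self.lambda_um <= 0:
            raise InvalidWarpError("lambda must be > 0")

    def psi(self, e):
        e = np.asarray(e, dtype=float)
        if self.form is WarpForm.SATURATING_EXPONENTIAL:
            out = e + self.r_max_um * (1.0 - np.exp(-e / self.lambda_um))
        else:
            out = e + self.r_max_um * np.minimum(e / self.lambda_um, 1.0)
        return out if out.ndim else float(out)

    def dpsi(self, e):
        e = np.asarray(e, dtype=float)
        if self.form is WarpForm.SATURATING_EXPONENTIAL:
            out = 1.0 + (self.r_max_um / self.lambda_um) * np.exp(-e / self.lambda_um)
        else:
            out = np.where(e < self.lambda_um, 1.0 + self.r_max_um / self.lambda_um, 1.0)
        return out if out.ndim else float(out)

    def psi_inv(self, E: float) -> float:
        """Inverse warp; closed form where available, else bracketed root."""
        E = float(E)
        if E < 0:
            raise InvalidWarpError("psi_inv defined for E >= 0 only")
        if E == 0.0 or self.r_max_um == 0.0:
            return E
        if self.form is WarpForm.LINEAR_CAPPED:
            alpha = self.r_max_um / self.lambda_um
            if E <= self.lambda_um + self.r_max_um:
                return E / (1.0 + alpha)
            return E - self.r_max_um
        # saturating exponential: psi is strictly increasing, psi(E - r_max) <= E <= psi(E)
        lo = max(E - self.r_max_um, 0.0)
        return float(brentq(lambda x: self.psi(x) - E, lo, E, xtol=1e-12, rtol=1e-15))

    def true_retardation(self, E: float) -> float:
        """Ground-truth retardation r(E) = E − ψ⁻¹(E) at control eccentricity E."""
        return float(E) - self.psi_inv(E)


@dataclass(frozen=True)
class ShapeParams:
    """Noise-free control thickness shape for one layer.

    IRL-type layers (GCL+IPL, INL, OPL) use a renormalised logistic rising
    from ``central_um`` exactly at FC to ``rim_um`` asymptotically, with
    transition centre/width in µm.  HFL+ONL uses a Gaussian hump peaking at
    ``central_um`` at FC and decaying to ``rim_um`` outward over ``width_um``.
    """

    rim_um: float
    centre_um: float
    width_um: float
    central_um: float = 0.0

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ConfigurationError("transition width must be > 0")
        if self.rim_um < 0 or self.central_um < 0:
            raise ConfigurationError("thickness parameters must be >= 0")


#: Default control shapes.  Calibrated so the FC stack matches adult control
#: anatomy: central GCL+IPL 5 + INL 3 = 8 µm of residual IRL, OPL 7 µm and
#: HFL+ONL 170 µm, summing to 185 µm total retinal thickness at FC.
DEFAULT_CONTROL_SHAPES: dict[Layer, ShapeParams] = {
    Layer.GCL_IPL: ShapeParams(rim_um=85.0, centre_um=550.0, width_um=160.0, central_um=5.0),
    Layer.INL: ShapeParams(rim_um=38.0, centre_um=500.0, width_um=150.0, central_um=3.0),
    Layer.OPL: ShapeParams(rim_um=28.0, centre_um=450.0, width_um=140.0, central_um=7.0),
    Layer.HFL_ONL: ShapeParams(rim_um=95.0, centre_um=0.0, width_um=500.0, central_um=170.0),
}


def control_shape(layer: Layer, params: ShapeParams) -> Callable[[np.ndarray], np.ndarray]:
    """Return the noise-free thickness function t_C(e) for a control layer."""
    layer = Layer(layer)
    if layer in IRL_TYPE_LAYERS:
        # logistic renormalised so t(0) == central exactly and t(inf) -> rim
        s0 = expit(-params.centre_um / params.width_um)

        def fn(e):
            s = expit((np.asarray(e, dtype=float) - params.centre_um) / params.width_um)
            return params.central_um + (params.rim_um - params.central_um) * (s - s0) / (1.0 - s0)

    else:

        def fn(e):
            e = np.asarray(e, dtype=float)
            hump = np.exp(-0.5 * (e / params.width_um) ** 2)
            return params.rim_um + (params.central_um - params.rim_um) * hump

    return fn


DEFAULT_GRID = np.arange(0.0, 1200.0 + 1e-9, 25.0)


def make_control_profile(
    layer: Layer,
    params: Optional[ShapeParams] = None,
    *,
    grid_um: Optional[np.ndarray] = None,
    noise_sd_um: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    subject_id: str = "C-mean",
    group: Group = Group.C,
) -> LayerProfile:
    """Sample a control thickness profile on a grid, optionally with noise.

    Noise is additive Gaussian on thickness, truncated at zero (segmentation
    jitter model).  ``seed`` (or an explicit ``rng``) fully determines the
    output.
    """
    layer = Layer(layer)
    params = params if params is not None else DEFAULT_CONTROL_SHAPES[layer]
    grid = np.asarray(DEFAULT_GRID if grid_um is None else grid_um, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("eccentricity grid must not be empty")
    t = control_shape(layer, params)(grid)
    if noise_sd_um > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        t = t + rng.normal(0.0, noise_sd_um, size=grid.shape)
    t = np.maximum(t, 0.0)
    return LayerProfile(layer=layer, eccentricity_um=grid, thickness_um=t,
                        subject_id=subject_id, group=group)


@dataclass(frozen=True)
class WarpedProfile:
    """Result of warping a control profile into a preterm profile.

    ``profile`` is the sampled preterm profile; ``thickness_fn`` the exact
    continuous preterm thickness (for quadrature-level checks);
    ``true_retardation`` maps a control eccentricity E to E − ψ⁻¹(E).
    """

    profile: LayerProfile
    thickness_fn: Callable[[np.ndarray], np.ndarray]
    true_retardation: Callable[[float], float]
    warp: WarpSpec


def apply_retardation_warp(
    control: LayerProfile,
    warp: WarpSpec,
    *,
    control_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    noise_sd_um: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "PG-synth",
    group: Group = Group.SYNTH,
) -> WarpedProfile:
    """Warp a control profile into a preterm-like profile with known truth.

    The continuous control thickness is taken from ``control_fn`` when given
    (exact, for generated cohorts) and otherwise from a cubic interpolating
    spline through the control samples, extended by its edge values.  The
    preterm thickness t_C(ψ(e))·ψ'(e) is sampled on the control grid;
    eccentricities mapping beyond the control domain use the constant edge
    extension, consistent with the saturated profile shape there.
    """
    if control_fn is None:
        from scipy.interpolate import InterpolatedUnivariateSpline

        spl = InterpolatedUnivariateSpline(
            control.eccentricity_um, control.thickness_um, k=3, ext="const"
        )
        control_fn = spl

    grid = control.eccentricity_um
    t_pg = np.asarray(control_fn(warp.psi(grid)), dtype=float) * warp.dpsi(grid)
    if noise_sd_um > 0:
        if rng is None:
            rng = np.random.default_rng()
        t_pg = t_pg + rng.normal(0.0, noise_sd_um, size=grid.shape)
    t_pg = np.maximum(t_pg, 0.0)

    profile = LayerProfile(layer=control.layer, eccentricity_um=grid,
                           thickness_um=t_pg, subject_id=subject_id, group=group)

    def thickness_fn(e):
        return np.asarray(control_fn(warp.psi(e)), dtype=float) * warp.dpsi(e)

    return WarpedProfile(profile=profile, thickness_fn=thickness_fn,
                         true_retardation=warp.true_retardation, warp=warp)


def synthesize_ascan(
    bands: Sequence[tuple[str, float, float, float]],
    *,
    step_um: float = 1.0,
    depth_range_um: tuple[float, float] = (0.0, 300.0),
    edge_softness_um: float = 0.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> ReflectivityProfile:
    """Build a banded A-scan reflectivity profile with known boundaries.

    ``bands`` is an ordered sequence of ``(label, inner_um, outer_um, level)``
    hyperreflective bands on a hyporeflective baseline.  With zero softness
    each band is a boxcar; with softness σ > 0 the boxcar edges are smoothed
    with a Gaussian kernel of that σ (error-function edges), which places the
    half-height points of a well-separated band exactly at the stored
    boundaries.  Gaussian noise (sd ``noise_sd``) is added and the profile is
    clipped to [0, 1].
    """
    if edge_softness_um < 0:
        raise ConfigurationError("edge softness must be >= 0")
    prev_outer = -np.inf
    for label, inner, outer, level in bands:
        if outer <= inner:
            raise ConfigurationError(f"band {label!r}: outer must exceed inner depth")
        if inner < prev_outer:
            raise ConfigurationError(f"band {label!r} overlaps the previous band")
        prev_outer = outer

    d0, d1 = depth_range_um
    depth = np.arange(d0, d1 + 0.5 * step_um, step_um)
    r = np.full(depth.shape, float(baseline))
    for label, inner, outer, level in bands:
        amp = level - baseline
        if edge_softness_um == 0.0:
            bump = ((depth >= inner) & (depth <= outer)).astype(float)
        else:
            s = edge_softness_um * np.sqrt(2.0)
            bump = 0.5 * (erf((depth - inner) / s) - erf((depth - outer) / s))
        r = r + amp * bump
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=depth.shape)
    r = np.clip(r, 0.0, 1.0)
    return ReflectivityProfile(
        depth_um=depth,
        reflectivity=r,
        true_bands=tuple((label, float(inner), float(outer)) for label, inner, outer, _ in bands),
    )


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic cohort group: label, warp (None for controls), noise.

    ``warp_layers`` selects which layers the retardation warp displaces;
    by default the centrifugally displaced IRL-type layers (GCL+IPL, INL,
    OPL).  HFL+ONL is filled in by the independent centripetal photoreceptor
    process and is left control-shaped unless explicitly included.
    """

    label: Group
    warp: Optional[WarpSpec] = None
    noise_sd_um: float = 0.0
    n_subjects: int = 1
    warp_layers: tuple[Layer, ...] = IRL_TYPE_LAYERS

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", Group(self.label))
        object.__setattr__(self, "warp_layers",
                           tuple(Layer(ly) for ly in self.warp_layers))
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.noise_sd_um < 0:
            raise ConfigurationError("noise sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    The grid must cover at least [0, 900] µm (the analysis window plus the
    margin the default 0–1200 µm grid provides against spline edge effects);
    ``seed`` fully determines every sampled value.
    """

    groups: tuple[GroupSpec, ...]
    control_shapes: dict[Layer, ShapeParams] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_SHAPES)
    )
    grid_um: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    control_noise_sd_um: float = 0.0
    n_control_subjects: int = 1
    eval_eccentricities_um: tuple[float, ...] = (300.0, 500.0, 700.0, 900.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        grid = np.asarray(self.grid_um, dtype=float)
        object.__setattr__(self, "grid_um", grid)
        if grid.size == 0 or grid[0] > 0.0 or grid[-1] < 900.0:
            raise ConfigurationError("eccentricity grid must cover [0, 900] µm")
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("duplicate group labels in cohort config")


@dataclass(frozen=True)
class Cohort:
    """Generated cohort: per-subject profiles, exact shapes, ground truth.

    ``control_fns`` holds the noise-free control thickness functions per
    layer; ``ground_truth`` has one row per (group, layer, eccentricity) with
    the closed-form true retardation.
    """

    config: CohortConfig
    profiles: tuple[LayerProfile, ...]
    control_fns: dict[Layer, Callable[[np.ndarray], np.ndarray]]
    warped: dict[Group, dict[Layer, WarpedProfile]]
    ground_truth: pd.DataFrame

    def group_profiles(self, group: Group, layer: Layer) -> list[LayerProfile]:
        group, layer = Group(group), Layer(layer)
        return [p for p in self.profiles if p.group is group and p.layer is layer]

    def group_mean_profile(self, group: Group, layer: Layer) -> LayerProfile:
        """Average the subject profiles of one group/layer sample-wise."""
        profs = self.group_profiles(group, layer)
        if not profs:
            raise ConfigurationError(f"no profiles for group {group}, layer {layer}")
        t = np.mean([p.thickness_um for p in profs], axis=0)
        return LayerProfile(layer=layer, eccentricity_um=profs[0].eccentricity_um,
                            thickness_um=t, subject_id=f"{group.value}-mean", group=group)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort from a validated config.

    Controls are sampled from the configured shapes; each non-control group
    is produced by warping the noise-free control shapes with its WarpSpec,
    then adding per-subject truncated Gaussian noise.  Noise draws depend on
    the seed only; the ground-truth table is noise-free by construction.
    """
    rng = np.random.default_rng(config.seed)
    layers = list(config.control_shapes)
    fns = {ly: control_shape(ly, config.control_shapes[ly]) for ly in layers}

    profiles: list[LayerProfile] = []
    for s in range(config.n_control_subjects):
        for ly in layers:
            profiles.append(
                make_control_profile(
                    ly, config.control_shapes[ly], grid_um=config.grid_um,
                    noise_sd_um=config.control_noise_sd_um, rng=rng,
                    subject_id=f"C-{s:02d}", group=Group.C,
                )
            )

    warped: dict[Group, dict[Layer, WarpedProfile]] = {}
    rows = []
    for gspec in config.groups:
        if gspec.label is Group.C:
            # extra control subjects configured as an explicit group
            for s in range(gspec.n_subjects):
                for ly in layers:
                    profiles.append(
                        make_control_profile(
                            ly, config.control_shapes[ly], grid_um=config.grid_um,
                            noise_sd_um=gspec.noise_sd_um, rng=rng,
                            subject_id=f"C-x{s:02d}", group=Group.C,
                        )
                    )
            continue
        if gspec.warp is None:
            raise ConfigurationError(f"group {gspec.label} needs a WarpSpec")
        warped[gspec.label] = {}
        for ly in layers:
            if ly in gspec.warp_layers:
                ctrl = make_control_profile(ly, config.control_shapes[ly],
                                            grid_um=config.grid_um)
                wp = apply_retardation_warp(
                    ctrl, gspec.warp, control_fn=fns[ly],
                    subject_id=f"{gspec.label.value}-exact", group=gspec.label,
                )
                warped[gspec.label][ly] = wp
                group_fn = wp.thickness_fn
                for E in config.eval_eccentricities_um:
                    rows.append(
                        {
                            "group": gspec.label.value,
                            "layer": ly.value,
                            "eccentricity_um": float(E),
                            "true_retardation_um": gspec.warp.true_retardation(E),
                        }
                    )
            else:
                group_fn = fns[ly]
            for s in range(gspec.n_subjects):
                t = np.asarray(group_fn(config.grid_um), dtype=float)
                if gspec.noise_sd_um > 0:
                    t = t + rng.normal(0.0, gspec.noise_sd_um, size=config.grid_um.shape)
                profiles.append(
                    LayerProfile(
                        layer=ly, eccentricity_um=config.grid_um,
                        thickness_um=np.maximum(t, 0.0),
                        subject_id=f"{gspec.label.value}-{s:02d}", group=gspec.label,
                    )
                )

    truth = pd.DataFrame(rows, columns=["group", "layer", "eccentricity_um",
                                        "true_retardation_um"])
    return Cohort(config=config, profiles=tuple(profiles), control_fns=fns,
                  warped=warped, ground_truth=truth)
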