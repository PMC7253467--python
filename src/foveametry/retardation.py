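"""Cumulative-curve retardation estimation.

The estimator quantifies arrested centrifugal layer displacement by
comparing cumulative thickness curves.  For a layer with thickness t(e) at
temporal eccentricity e, the cumulative curve

    Cum(e) = ∫₀ᵉ max(t, 0) de'          (µm², area under the thickness curve)

is non-decreasing by construction.  If development merely *displaces* layer
mass laterally, the preterm curve is a horizontally stretched copy of the
control curve, and the retardation at a control eccentricity E is the
horizontal distance between the two curves at the ordinate Cum_C(E):

    retardation(E) = E − e*,   e* = min{ e : Cum_PG(e) = Cum_C(E) }.

Plateaus of the (weakly) monotone preterm curve are resolved to their
smallest eccentricity, which makes the horizontal distance well defined.

Thickness profiles are fitted with cubic splines before integration; the
cumulative is integrated exactly from the piecewise polynomial, with
negative spline excursions clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import (
    InterpolatedUnivariateSpline,
    PPoly,
    UnivariateSpline,
    make_smoothing_spline,
)

from .errors import (
    EccentricityRangeError,
    FitError,
    UnreachableValueError,
)
from .types import Group, GroupSummary, Layer, LayerProfile, RetardationEstimate

__all__ = [
    "fit_thickness_spline",
    "cumulative_curve",
    "CumulativeCurve",
    "retardation_at",
    "retardation_profile",
    "group_summary",
]

Smoothing = Union[float, str]


def fit_thickness_spline(profile: LayerProfile, smoothing: Smoothing = 0.0) -> PPoly:
    """Fit a C¹ cubic spline to a thickness profile.

    ``smoothing=0`` interpolates the samples exactly; a positive float is the
    residual-sum bound of a classical smoothing spline; ``"gcv"`` selects the
    roughness penalty by generalised cross-validation, appropriate for noisy
    group-mean profiles.  The returned piecewise polynomial is defined on
    [min e, max e]; negative excursions are clipped later, at integration.
    """
    if profile.n_samples < 4:
        raise FitError("spline fit needs at least 4 samples")
    x, y = profile.eccentricity_um, profile.thickness_um
    if smoothing == "gcv":
        bspl = make_smoothing_spline(x, y)
        return PPoly.from_spline((bspl.t, bspl.c, bspl.k), extrapolate=False)
    s = float(smoothing)
    if s < 0:
        raise FitError("smoothing must be >= 0 or 'gcv'")
    if s == 0.0:
        spl = InterpolatedUnivariateSpline(x, y, k=3)
    else:
        spl = UnivariateSpline(x, y, k=3, s=s)
    tck = spl._eval_args
    return PPoly.from_spline(tck, extrapolate=False)


def _extend_to_zero(pp: PPoly) -> PPoly:
    """Prepend a constant segment so the domain starts at eccentricity 0."""
    if pp.x[0] <= 0.0:
        return pp
    k = pp.c.shape[0]
    const = np.zeros((k, 1))
    const[-1, 0] = float(pp(pp.x[0]))
    x = np.concatenate([[0.0], pp.x])
    c = np.concatenate([const, pp.c], axis=1)
    return PPoly(c, x, extrapolate=False)


@dataclass(frozen=True)
class CumulativeCurve:
    """Exact cumulative integral of the positive part of a fitted spline.

    ``knots_um`` are the merged breakpoints (spline knots plus sign-change
    roots); ``cum_at_knots_um2`` the cumulative values there.  The curve is
    defined on [0, e_max_um], starts at 0 and is non-decreasing.
    """

    layer: Layer
    group: Group
    ppoly: PPoly
    knots_um: np.ndarray
    cum_at_knots_um2: np.ndarray
    e_max_um: float

    def __call__(self, e):
        e_arr = np.asarray(e, dtype=float)
        scalar = e_arr.ndim == 0
        e_arr = np.atleast_1d(e_arr)
        if np.any(e_arr < -1e-9) or np.any(e_arr > self.e_max_um + 1e-9):
            raise EccentricityRangeError(
                f"evaluation outside [0, {self.e_max_um}] µm"
            )
        e_arr = np.clip(e_arr, 0.0, self.e_max_um)
        idx = np.searchsorted(self.knots_um, e_arr, side="right") - 1
        idx = np.clip(idx, 0, self.knots_um.size - 2)
        out = np.empty_like(e_arr)
        for j, (i, ei) in enumerate(zip(idx, e_arr)):
            a = self.knots_um[i]
            # inside one piece the sign is constant, so the positive-part
            # integral is either the exact polynomial integral or zero
            if self._piece_positive(i):
                inc = self.ppoly.integrate(a, ei)
            else:
                inc = 0.0
            out[j] = self.cum_at_knots_um2[i] + inc
        return float(out[0]) if scalar else out

    def _piece_positive(self, i: int) -> bool:
        a, b = self.knots_um[i], self.knots_um[i + 1]
        return bool(self.ppoly(0.5 * (a + b)) > 0.0)

    @property
    def total_um2(self) -> float:
        return float(self.cum_at_knots_um2[-1])


def cumulative_curve(
    profile: LayerProfile,
    e_max_um: Optional[float] = None,
    *,
    smoothing: Smoothing = 0.0,
) -> CumulativeCurve:
    """Build the cumulative curve of a thickness profile up to ``e_max_um``.

    The fitted spline is extended to eccentricity 0 by constant-value
    extrapolation of the innermost sample when the data start above 0; the
    upper integration limit must lie inside the fitted domain.
    """
    pp = _extend_to_zero(fit_thickness_spline(profile, smoothing))
    domain_max = float(pp.x[-1])
    e_max = domain_max if e_max_um is None else float(e_max_um)
    if e_max <= 0 or e_max > domain_max + 1e-9:
        raise EccentricityRangeError(
            f"e_max {e_max} µm outside fitted domain (0, {domain_max}] µm"
        )
    e_max = min(e_max, domain_max)

    roots = pp.solve(0.0, extrapolate=False)
    knots = np.unique(np.concatenate([pp.x[(pp.x >= 0) & (pp.x <= e_max)],
                                      roots[(roots > 0) & (roots < e_max)],
                                      [0.0, e_max]]))
    cum = np.zeros(knots.size)
    for i in range(knots.size - 1):
        a, b = knots[i], knots[i + 1]
        mid_val = pp(0.5 * (a + b))
        inc = pp.integrate(a, b) if mid_val > 0.0 else 0.0
        cum[i + 1] = cum[i] + max(inc, 0.0)
    return CumulativeCurve(layer=profile.layer, group=profile.group, ppoly=pp,
                           knots_um=knots, cum_at_knots_um2=cum, e_max_um=e_max)


def _smallest_preimage(curve: CumulativeCurve, target: float) -> float:
    """Smallest e with curve(e) >= target, by bisection on the monotone curve.

    Because the curve is continuous and non-decreasing, this is exactly the
    smallest solution of curve(e) = target when one exists; plateaus resolve
    to their left edge.
    """
    lo, hi = 0.0, curve.e_max_um
    if curve(lo) >= target:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if curve(mid) >= target:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-12 * max(hi, 1.0):
            break
    return hi


def retardation_at(
    cum_control: CumulativeCurve, cum_pg: CumulativeCurve, eccentricity_um: float
) -> RetardationEstimate:
    """Horizontal displacement between the two cumulative curves at E.

    Moves vertically from E to the control curve and horizontally to the
    preterm curve; the retardation is E minus the matched preterm
    eccentricity.  Raises UnreachableValueError when the control ordinate
    exceeds the preterm curve's range (never silently clipped).
    """
    if cum_control.layer is not cum_pg.layer:
        raise EccentricityRangeError(
            f"layer mismatch: {cum_control.layer} vs {cum_pg.layer}"
        )
    E = float(eccentricity_um)
    target = cum_control(E)
    tol = 1e-9 * max(cum_pg.total_um2, 1.0)
    if target > cum_pg.total_um2 + tol:
        raise UnreachableValueError(
            f"control cumulative at {E} µm ({target:.3f} µm²) exceeds the "
            f"preterm curve range ({cum_pg.total_um2:.3f} µm²)"
        )
    e_star = _smallest_preimage(cum_pg, min(target, cum_pg.total_um2))
    r = E - e_star
    # snap numerical dust (below the bisection resolution, far below any
    # physical displacement) to an exact zero so the identity case is clean
    if abs(r) < 1e-6:
        r, e_star = 0.0, E
    return RetardationEstimate(
        layer=cum_pg.layer, group=cum_pg.group, eccentricity_um=E,
        retardation_um=r, residual_um=e_star,
    )


def retardation_profile(
    cum_control: CumulativeCurve,
    cum_pg: CumulativeCurve,
    eccentricities_um: Sequence[float],
) -> list[RetardationEstimate]:
    """Retardation at each eccentricity; per-point failures are recorded
    in the estimate's ``error`` field rather than aborting the profile."""
    out: list[RetardationEstimate] = []
    for E in eccentricities_um:
        try:
            out.append(retardation_at(cum_control, cum_pg, E))
        except (UnreachableValueError, EccentricityRangeError) as exc:
            out.append(
                RetardationEstimate(
                    layer=cum_pg.layer, group=cum_pg.group,
                    eccentricity_um=float(E), retardation_um=float("nan"),
                    residual_um=float("nan"), error=str(exc),
                )
            )
    return out


def group_summary(
    estimates: Sequence[RetardationEstimate],
    window_um: tuple[float, float] = (300.0, 900.0),
) -> GroupSummary:
    """Mean / min / max retardation over all layer x eccentricity cells in a
    window (inclusive).  Failed estimates are excluded; an empty window is
    an error."""
    lo, hi = float(window_um[0]), float(window_um[1])
    vals = [e for e in estimates if e.ok and lo <= e.eccentricity_um <= hi]
    if not vals:
        raise EccentricityRangeError("no usable estimates within window")
    groups = {e.group for e in vals}
    if len(groups) > 1:
        raise EccentricityRangeError(f"estimates span multiple groups: {groups}")
    r = np.array([e.retardation_um for e in vals])
    return GroupSummary(
        group=vals[0].group, window_um=(lo, hi),
        mean_um=float(r.mean()), min_um=float(r.min()), max_um=float(r.max()),
        n_cells=int(r.size),
    )
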