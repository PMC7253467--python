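# Methods

## The measurement problem

In the maturing human fovea the inner retinal layers (GCL+IPL and INL) and
the OPL move centrifugally out of the foveal centre (FC) while
photoreceptor-associated mass (HFL+ONL) accumulates centripetally. Arrested
development in preterms leaves IRL and OPL partially in place. The package
quantifies that arrest from one-dimensional, temporal-side layer
thickness-vs-eccentricity profiles (µm vs µm, eccentricity 0 at FC), and
derives its structural consequences for the lateral and volumetric space
available to cone pedicles and inner-retinal synaptic networks.

## Retardation from cumulative thickness curves

For a layer thickness profile `t(e) ≥ 0` the cumulative curve
`Cum(e) = ∫₀ᵉ max(t̂, 0) de'` is built from a cubic-spline fit `t̂`:

- `smoothing = 0` (default): interpolating spline through the samples.
- `smoothing = s > 0`: classical smoothing spline with residual bound `s`.
- `smoothing = "gcv"`: roughness penalty chosen by generalised
  cross-validation — the recommended setting for noisy profiles.

The fitted piecewise polynomial is extended to eccentricity 0 by constant
extrapolation of the innermost sample when data start above 0, and
integrated **exactly** piece by piece; sign-change roots of the spline are
inserted as breakpoints so negative excursions contribute nothing
(clipping at the integrand level keeps `Cum` non-decreasing by
construction).

If displacement is merely retarded — mass conserved but lagging laterally —
the preterm curve is a horizontally distorted copy of the control curve,
and the natural lag measure at a control eccentricity `E` is

```
R(E) = E − e*,   e* = min{ e : Cum_PG(e) = Cum_C(E) }.
```

`e*` is found by bisection on the monotone curve (~60 iterations to ~1e-12
relative resolution; the matched cumulative values agree far better than
1e-6 of the total). Plateaus of `Cum_PG` (zero-thickness stretches) make
the preimage an interval; the smallest eccentricity is taken, which is the
only convention under which "horizontal distance" is well defined there.
Estimates with `|R| < 1e-6 µm` — numerical dust below the bisection
resolution, orders of magnitude under any physical displacement — are
reported as exactly zero. If `Cum_C(E)` exceeds the preterm curve's total,
the cell is reported as unreachable, never clipped.

Group analysis averages subject profiles into a per-group mean profile
before fitting (the convention for cumulative-curve analysis of small
cohorts), and summarises retardation over the foveal window 300–900 µm as
mean/min/max across the 12 displaced-layer × eccentricity cells (three
displaced layers × four eccentricities); means are reported rounded to
integer µm with the raw value retained.

Eccentricities may be rescaled between eyes before fitting with the
Bennett-type reduced-eye factor `(AL − 1.82 mm)/(AL_ref − 1.82 mm)`; the
constant and form are a package choice recorded here because the clinical
convention cites the method without formulas. The severe-arrest group of a
real cohort may be left unscaled when axial lengths are unavailable.

## FDA index and classification

`FDA = (HFL+ONL)/(IRL + OPL)` thickness ratio at FC; dimensionless,
homogeneous of degree zero. Default classification threshold 5 with the
inclusive convention (`FDA ≤ 5 → immature`), chosen between the observed
group means of immature (5, 2) and non-immature (13, 21) foveae; the
boundary assignment matters only for values exactly at 5 and is stated
explicitly rather than left to chance.

## OPL thickness from reflectivity profiles

The OPL is a thin hyperreflective band (2–5 pixels in typical scans)
between hyporeflective neighbours, so whole-sample quantisation is
unacceptable; borders are placed with sub-sample linear interpolation at
the half-height ("midway") level between the band peak and each flanking
trough. Implementation choices, configurable where the measurement
convention is silent:

- The caller supplies the depth search window; no anatomy inference.
- Peak = window maximum; a flat-topped plateau resolves to its midpoint.
- Troughs = first local minimum walking outward from the peak; a flank
  that decreases monotonically to the window edge uses the edge sample
  (a peak *on* the edge is a band-not-found error).
- The half-height crossing nearest the peak is used on each flank,
  which is robust to baseline ripple near the trough.
- Optional Gaussian pre-smoothing (sd in µm) before peak picking only;
  boundaries are always placed on the raw profile.
- The midway rule is applied symmetrically on both flanks: the inner
  border against the INL-side trough and the outer border against the
  HFL/ONL-side trough, since a thickness requires two borders.

The measurement is invariant under affine reflectivity rescaling `a·r + b`
(a > 0).

## Areal/volume magnification model

Centrifugal displacement magnifies available lateral area. With a
retardation `R` at control eccentricity `E` (0 ≤ R ≤ E), the
preterm/control area ratio is pure lateral geometry, `A = ((E−R)/E)²`,
and the volume ratio multiplies in the layer thickness ratio, `V = T·A`.
Both formulas were verified to reproduce every printed reference area and
volume cell within ±0.015 (the residual is rounding slack: the reference
table rounded retardation to integer µm before deriving ratios).

Derived sizes assume a conserved cell count, hence density inversely
proportional to area: a structure of reference diameter `d₀` is minified
to `d₀·√A` (defaults `d₀ = 6.3 µm`, 25 000 pedicles/mm², the adult foveal
slope values). A volume-like ratio maps to a sphere-equivalent diameter
fraction by cube root; **which** ratio to cube is an explicit argument
because the published sphere-diameter percentages correspond to the cube
root of the OPL areal ratio at 300 µm, not of the tabulated volume ratios.
Retardation can also be expressed as percent of a user-supplied normative
displacement curve (e.g. digitised histology data); the curve is consumed,
never derived, its provenance is carried in metadata, and values over 100%
are permitted but worth flagging.

Reporting convention throughout: ratios to 2 decimals, µm to 1 decimal,
percentages to integers, all half-up; machine outputs always retain raw
doubles.

## Synthetic cohort generator

The generator emulates what the analysis needs and nothing more:

- **Control shapes.** IRL-type layers: a renormalised logistic rising from
  a central residual (exact at e = 0) to a rim plateau; HFL+ONL: a Gaussian
  hump peaking at FC. Defaults are calibrated so the FC stack matches adult
  control anatomy — residual IRL 8 µm (GCL+IPL 5 + INL 3), OPL 7 µm,
  HFL+ONL 170 µm, total 185 µm.
- **Preterm groups.** A warp `ψ(e) = e + r_max·(1 − exp(−e/λ))` (or a
  linear-capped variant) displaces layer mass: `t_PG(e) = t_C(ψ(e))·ψ'(e)`,
  so `Cum_PG = Cum_C ∘ ψ` exactly and the true retardation is
  `R(E) = E − ψ⁻¹(E)` in closed form. The saturating-exponential form
  gives large fractional central blockage and a bounded peripheral lag,
  matching the observed severity pattern. The warp applies by default to
  the displaced (IRL-type) layers only: a mass-preserving warp of *all*
  layers would leave the FDA index invariant at FC (degree-0 homogeneity),
  whereas HFL+ONL arrives by an independent centripetal process and is
  left control-shaped.
- **Noise.** Additive Gaussian on thickness, truncated at 0 — the simplest
  model of manual-segmentation jitter; default sd 2 µm per sample.
- **Grid.** 0–1200 µm at 25 µm, covering the 300–900 µm analysis window
  with margin against spline edge effects.
- **Severity grades.** The default cohort has three groups with
  `r_max = 60/200/420 µm` (λ = 400/350/300 µm), whose true window-mean
  retardations (~46/138/265 µm) emulate the three observed immaturity
  grades; five subjects per group.
- **A-scans.** Hyperreflective boxcar bands on a hyporeflective baseline;
  with edge softness σ the edges become error functions (Gaussian-kernel
  smoothed), which places the half-height points of a well-separated band
  exactly on the stored boundaries — giving the segmentation stage an
  analytic ground truth.

Everything is driven by one `numpy` `Generator` seed; identical
configuration and seed give bit-identical output.

What the generator does **not** emulate: 2-D B-scan structure, speckle,
registration/flattening artefacts, axial elongation, photoreceptor IS/OS
morphology, or any mechanistic model of why displacement stalls (the warp
is phenomenological). Passing recovery tests therefore show the estimator
is correct for smooth, mass-conserving lateral redistribution with
additive segmentation noise — not that it is robust to segmentation bias
or scan-quality artefacts in real data.

## Validation strategy and known limitations

- Noise-free parameter recovery is essentially exact (<1e-4 µm); the
  bisection inverse agrees with a brute-force 0.5 µm grid scan within
  1 µm; scale invariance is bit-exact for power-of-two scalings.
- Under shared segmentation noise (control vs itself warped, sd 2 µm,
  25 µm grid) with GCV smoothing, recovery at 300–900 µm is within 5 µm
  for warps up to `r_max ≈ 200 µm` — the estimator's qualified band.
- **Severe warps** (`ψ' ≳ 2` centrally, like the severe default grade)
  compress grid-scale structure past the Nyquist limit of the 25 µm grid;
  recovery degrades to ~10–17 µm there. This is an information limit of
  the sampled representation, not an estimator defect.
- With noise **independent** between control and preterm subjects, the
  vertical noise of a cumulative at E is ≈ σ·√(h·E) per curve (σ thickness
  noise per sample, h grid step); divided by the local thickness of thin
  layers (~10 µm for INL/OPL centrally) the horizontal noise floor is
  ~10–25 µm 1σ at realistic cohort sizes, for *any* estimator. Group sizes
  of clinical cohorts cannot buy this back; precise per-cell retardation
  in thin layers requires either low-noise segmentation or shared-error
  designs.
- The FDA separation property is validated on directly constructed FC
  stacks emulating the four observed group anatomies, because the warp's
  FC amplification `ψ'(0)` understates real central IRL persistence.
- Problem sizes in the test suite (49-point grids, 10 seeds, 5 subjects
  per group) were chosen as the smallest sizes at which the statistical
  properties above are cleanly visible.
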