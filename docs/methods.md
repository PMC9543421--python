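# Methods

This note documents the models, numerical choices and limitations behind
`corneatilt`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and what passing tests do and do not
demonstrate.

## Coordinate frame and the meaning of tilt

The instrument axis is +z with light propagating toward +z; x is nasal,
y superior; surface heights are sagitta in mm from the anterior apex
plane. Because fixation aligns the eye with the instrument during a scan,
the instrument axis is taken as the visual axis. Corneal tilt is then a
rigid rotation of the cornea relative to +z, parameterised by two angles
(about x, then y) pivoting at the anterior apex; torsion about z does not
change an axis direction and is omitted. Angle alpha is the 3D angle
between the corneal optical axis and +z, computed as
`arccos` of a clamped dot product.

## Optical-axis estimation

The optical axis is the light path that traverses both corneal surfaces
without net refraction. The estimator:

1. fits each elevation grid with a bivariate polynomial of total degree 8
   over the central 8 mm aperture (see *Surface fitting* below);
2. builds a two-surface eye model with refractive indices
   n_air = 1.0, n_stroma = 1.376, n_aqueous = 1.336 (Gullstrand values);
3. rotates the model by candidate angles (αx, αy) and traces the central
   ray — the ray entering along the instrument axis through (0, 0) — via
   two vector-form Snell refractions;
4. minimises the transverse components of (exit direction − ẑ) with
   Levenberg–Marquardt (SciPy `least_squares`, method `lm`, start (0, 0),
   finite-difference step ≈ 1e−4 rad, up to 200 iterations).

A ray exiting parallel to the axis has infinite focal length, so
"maximise the central ray's focal length" and "null its direction
deviation" share the same optimum; the deviation form is bounded and
smooth, which suits least squares. With two parameters against two
residual components the optimum is generically an exact zero even on
noisy grids, so convergence is declared when the residual norm falls
below 1e−8; non-convergence is reported as a flag, never an exception.
The recovered optical axis is the inverse fitted rotation applied to ẑ.
Physiologic tilts are below ~12°, far inside the region where the
objective is monotone (verified by a grid scan in the tests), so no
bounds are imposed on the two angles.

Exactness argument: a cornea generated by rotating a rotationally
symmetric model R_true about the anterior apex is nulled exactly by any
fitted rotation R_fit with R_fit R_true ẑ = ẑ, giving
R_fitᵀ ẑ = R_true ẑ — the estimator recovers the true axis irrespective
of the non-commutativity of the two-angle parameterisation.

## Surface fitting

The fitting basis is the set of bivariate monomials of total degree ≤ 8
in coordinates scaled to the fit aperture (default 4 mm radius). This
spans exactly the same function space as disc (Zernike-style) polynomials
through radial order 8 — the conventional corneal-topography choice — and
makes heights and gradients cheap closed forms; the SVD-based
least-squares solve absorbs the basis conditioning. On noise-free
conicoid grids the fit residual is below 0.1 µm and fitted normals agree
with analytic normals to < 0.01° over the central 8 mm; extrapolation
beyond the fitted aperture raises an error rather than returning
polynomial garbage.

Rotated surfaces are evaluated implicitly: p lies on the rotated surface
iff Rᵀ(p − pivot) + pivot lies on the base surface. Heights come from a
Newton iteration on z (converged to 1e−13 mm), gradients from the
implicit function theorem, normals by rotating base normals. Ray–surface
intersections use Newton on the ray parameter to |Δz| < 1e−12 mm.

## Regional densitometry

GSU volumes live on a cylindrical (radius, azimuth, depth-fraction) grid
with the corneal thickness as metadata. Aggregation weights are physical
cell volumes — annular area × depth extent — and cells straddling a zone
or layer boundary contribute their exact geometric overlap, so
piecewise-constant volumes are summarised exactly and the overall mean is
exactly the area-weighted mean of the zone means. The device's own
aggregation weighting is proprietary and published zone means are *not*
mutually consistent with a single area-weighted overall value (the
overall mean printed alongside them is lower than the area-weighted
combination of the zones); this package therefore documents its weighting
and claims no equality with device output. Layer boundaries sit 120 µm
from the anterior surface and 60 µm from the posterior surface, so
thicknesses ≤ 180 µm are rejected.

## Synthetic corneas

A synthetic eye is two conicoid surfaces (defaults: anterior R = 7.8 mm,
posterior R = 6.5 mm, both Q = −0.25, central thickness 0.55 mm — typical
healthy-eye biometry), rotated by the true tilt about the anterior apex
and sampled on a 0.2 mm grid over a 4.5 mm half-aperture, with optional
independent Gaussian elevation noise (2 µm in the noisy test conditions,
a realistic elevation repeatability figure). Generation is deterministic
per seed and grids round-trip bit-identically through the CSV dialect.

## Cohort generator and its calibration

Cohorts follow a linear-Gaussian structural chain, in standardised form:

```
tilt_z = r_at · age_z + e_t
dens_z = β_age · age_z + β_tilt · tilt_z + e_d
```

with β solving the two-predictor normal equations for the target
correlation matrix, so the implied population correlations equal the
targets exactly (for the default targets: β_age = 0.9133,
β_tilt = −0.0067). The ordering age → tilt → densitometry mirrors the
mediation case of primary interest; any trivariate Gaussian with the same
correlation matrix is equivalent for correlation-level results.

Ages are truncated Gaussian. The published summary (mean 42.8, SD 20.0,
observed range 18–79 years) cannot be realised as a normal truncated to
the observed range: on [18, 79] a truncated normal's SD is bounded by the
uniform limit (79 − 18)/√12 ≈ 17.6 < 20. The printed range is an
86-subject sample extremum, not a population support, so the generator
instead truncates at wide plausibility bounds [0, 100] years and solves
the latent (pre-truncation) mean and SD numerically so the truncated
distribution has exactly the target moments (latent ≈ N(41.6, 21.9)).
Requesting bounds too tight for the target SD raises an error that states
the uniform bound.

Tilt draws below 0° and GSU draws outside [0, 100] are redrawn (never
clamped) by resampling only the offending innovation; redraw counts are
logged in `frame.attrs["redraws"]`. At the default calibration the
redraw rates are ≲ 1% per variable, perturbing moments and correlations
well under the 1% / 0.01 verification tolerances.

Per-zone and per-layer GSU values are affine transforms of the overall
z-score with loading 0.9 plus independent noise scaled to the per-region
SDs. Cross-region correlations are not published, so the shared-component
loading is this package's choice; 0.9 keeps regions strongly coherent
within a subject (as device maps are) while leaving region-specific
variation.

What the generator does *not* emulate: Scheimpflug image formation, the
physical mechanism linking tilt to backscatter, fellow-eye correlation
(one record per subject, right-eye-only logic), demographic structure
beyond age, and any non-Gaussian features of real densitometry. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline*, not properties of real eyes.

## Mediation analysis

All regressions include intercepts and run on raw scales unless
standardisation is requested. The in-sample OLS identity c = c′ + a·b
holds to 1e−10 on every dataset, and percent direct/mediated are defined
as 100·c′/c and 100·a·b/c, which sum to 100 whenever c ≠ 0 (and are
reported as undefined when c = 0). Inference for the indirect effect uses
the percentile bootstrap (default 5000 joint row resamples, seeded,
vectorised over resamples); the mediated effect "exists" iff the CI
excludes zero. The Sobel z is reported as a diagnostic only — the
product-of-coefficients distribution is skewed at modest n and the
bootstrap is the accepted practice. Degenerate resamples (zero variance)
are dropped from the bootstrap distribution; their probability is
negligible for continuous data.

Note on decomposing *published rounded* correlations: applying the
standardised closed forms to (r_xm, r_xy, r_my) = (0.50, 0.45, 0.91)
yields a direct share of −1.5% for tilt → densitometry (and ≈ 100.4%
direct for age → densitometry), while decompositions computed from
unrounded raw data can land a few percent away (e.g. small positive
direct shares). The package reports both the sample decomposition and the
correlation-matrix counterpart and does not force them to agree.

The Shapiro–Wilk normality check delegates to SciPy; its internals are
out of scope here.

## Problem sizes and verification design

The standard verification run uses: 20 noise-free + 100 noisy corneas
spanning 2–10° of tilt, 10 zero-tilt null corneas, 1000 random
refractions, 100 random mediation datasets, 1000 simulated cohorts of
n = 86 with 1000 bootstrap resamples each for CI coverage, and a single
n = 100 000 cohort for generator calibration. These sizes put Monte-Carlo
error comfortably below the tolerances being checked (e.g. coverage SE
≈ 0.7 percentage points against a 93–97% acceptance band) while keeping
the whole run in tens of seconds.

## Known limitations

- The estimator assumes both elevation maps share one instrument frame
  and that the cornea is rigid; cyclotorsion and fixation drift between
  captures are not modelled.
- Only the central ray feeds the optimisation objective; peripheral rays
  are used for validation (paraxial focus) but not for axis estimation.
- The densitometry aggregation is volume-weighted by construction and
  intentionally does not reproduce the proprietary device weighting.
- The cohort model is linear-Gaussian; it reproduces first and second
  moments, not higher-order structure of real cohorts.
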