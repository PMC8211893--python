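# Methods

`ccshape` implements deformation-based shape analysis of the 2D mid-sagittal
corpus callosum (CC): labeled mask slices are turned into ordered boundary
curves, every subject's curve is matched to a cohort template by rigid
alignment followed by LDDMM curve registration, the Jacobian determinant of
the resulting diffeomorphism provides a pointwise "deformation marker", and
group differences in the markers are tested with covariate-adjusted
permutation statistics under family-wise error control.  This note records
the model, the numerical choices, and what the synthetic validation does and
does not establish.

## Shape objects and conventions

A slice is an integer label grid (0 background, 1 genu, 2 body, 3 splenium)
on a square raster, 1 mm isotropic by default.  Points are `(x, y)` in mm
with `x` = column and `y` = row *increasing upward*; boundary curves are
closed polygons through boundary *pixel centres*, traversed clockwise from
the lower-left boundary pixel (minimum y, then minimum x).  Under this
convention the shoelace signed area of a stored curve is negative; areas are
reported as absolute values.

Two area dialects coexist deliberately.  Region areas are pixel counts
(exact integers at 1 mm), used for all reported area statistics and for
template selection.  The polygon (shoelace) area of the pixel-centre curve
is systematically smaller — about half a pixel per boundary pixel (a 10x10
block: 100 px² vs 81 mm² polygon) — and is used only internally.  Likewise
the pixel-centre polygon of a raster boundary carries a staircase perimeter
inflation of roughly 3% that equal-arc-length resampling removes; tests
account for both offsets explicitly.

The boundary is traced by Moore-neighbour following with 8-connectivity and
Jacob's stopping criterion (terminate when the start pixel is re-entered
such that the walk would repeat).  On simply connected masks the traced
pixel set equals the brute-force definition "foreground pixel with at least
one background 4-neighbour", which the tests enforce against random blob
masks.  Sub-region labels along the curve are cleaned with a cyclic
majority vote (window 5) so that label runs are contiguous; note that the
*body* necessarily occupies two arcs of a closed band boundary (one per
wall), while genu and splenium wrap around their end caps into single arcs.

Mean thickness is estimated as twice the Euclidean distance transform
sampled on the morphological skeleton, overall and per sub-region.  The
estimator is exact for long rectangles up to end effects (tested at 15%).

## Template selection

The template is the cohort member whose CC pixel area is closest to the
cohort mean area, ties broken by smallest subject id.  It is resampled to
K equally arc-length spaced points (K = 200 by default; the desk-scale
studies below use K = 50–100) starting from the lower-left start point;
each resampled point inherits the sub-region label of the nearest original
vertex.  Arc-length gaps along the source polygon are exactly uniform by
construction.  Resampling a polygon is not a projection (chords re-cut
corners), so a same-K input with near-uniform chords is returned unchanged;
this documented fast path is what makes repeated resampling idempotent.

## Registration and the deformation marker

Each target curve is resampled to K points and rigidly aligned to the
template by ICP (symmetric nearest-point correspondences, Kabsch update
restricted to rotation + translation, initialization from centroids and
principal axes with both polarities tried).  No scaling is removed: size
differences must remain in the deformation so the marker keeps its areal
meaning, which the area-consistency check below requires.

The diffeomorphic match minimizes

    E(alpha) = sum_t dt sum_ij alpha_i(t)·alpha_j(t) K_V(x_i(t), x_j(t))
               + lambda ||[phi_1(template)] - [target]||^2_W

over momenta `alpha` supported on the K template points, with Gaussian
velocity kernel K_V of width sigma_V, explicit Euler flow over n_timesteps
(default 10), and a currents data term: curves are represented by segment
midpoints and tangents and compared through a Gaussian kernel of width
sigma_W, so no point correspondence is assumed.  The gradient is computed
by an exact reverse sweep through the Euler steps (discrete adjoint);
descent uses the kernel-preconditioned direction — both gradient terms
carry an explicit left Gram factor, so the RKHS-metric direction
`dt (2 alpha_t + xbar_{t+1})` is available without any solve — with Armijo
backtracking.  This preconditioning removes the severe ill-conditioning of
the Gaussian Gram spectrum (plain gradient descent needs an order of
magnitude more iterations for the same energy).  Accepted steps never
increase the energy; the run stops when five consecutive accepted steps
drop the energy by less than `rel_tol` (default 1e-7) relative, or at
`max_iters`.

The marker at template point k is `J_k = det D_k`, the ambient 2x2 Jacobian
of the transformation integrated along the flow with the same Euler scheme,
`D <- (I + dt grad v) D`, with `grad v` analytic from the kernel.  `J > 1`
is local outward deformation (expansion), `J < 1` inward deformation.
Markers agree within 2% with a finite-difference oracle that flows a tiny
square at each point and measures its area ratio.

### Kernel widths and the marker's areal calibration

The defaults are `sigma_V` = (template point-set diameter)/4 — about 14 mm
for the CC, roughly twice its thickness — `sigma_W = sigma_V/2`, and an
automatic `lambda` that normalizes the initial data term to 2000 (a level at
which matching dominates the expected kinetic energy of mm-scale
deformations by about an order of magnitude; "balancing the two terms at
iteration zero" is not literally implementable because the kinetic term is
exactly zero at the zero-momenta start).  The point-set diameter is used
rather than a bounding box because it is rotation-invariant, which makes
registrations exactly equivariant under common rigid motions of template
and target.

The choice of `sigma_V` is the load-bearing one.  For a velocity field
supported on the moving curve, the field's normal profile peaks *at* the
curve, so for a thin kernel the Jacobian at curve points degenerates to the
tangential stretch: registering a x1.1 uniformly scaled target then yields
mean J near 1.1, not the area ratio 1.21, and J loses its meaning as
"relative area change of an infinitesimal region".  When the kernel couples
the two boundary walls of the CC band (sigma_V of the order of twice the
thickness) the inter-wall region deforms coherently and the mean marker for
the scaled target moves to ~1.16, within 5% of the area ratio; in the
near-affine limit (sigma_V much larger than the shape) it converges to 1.21
exactly.  The default sits at the smallest width that preserves this areal
calibration while remaining far below the CC arc length (~100 mm), so
dent-sized effects still localize.  A practical consequence of the coupled
walls: an inward dent on the outer genu edge produces its strongest
contraction (J < 1) on the *facing inner wall* — spatially within sigma_V
of the dent, but half a perimeter away in arc distance.  Localization
statements therefore use the genu label or spatial/arc proximity to the
injected support, not arc distance alone.

## Statistics

At each template point the model is
`J_k(s) = beta_k0 + beta_k1 gamma(s) + sum_cov a_cov X_cov(s) + eps_k(s)`
with `gamma = 1` for patients; the full cohort covaries age, gender and
TIV, single-gender scopes age and TIV only.  The reported effect is
`-beta_k1`, so positive values mean inward deformation in the patient
group.

Inference is by randomization: the Freedman–Lane scheme fits the reduced
(nuisance-only) model, permutes its residual rows, reconstitutes responses
and refits the full model, which respects the covariates.  The
implementation uses the Frisch–Waugh shortcut (the permuted t statistics
need only the residualized group column and an orthonormal basis of the
full design), so ten thousand permutations over hundreds of points cost
seconds.  p-values use the add-one estimator `(1 + b)/(1 + m)`, so no p is
ever zero.  When the design is nuisance-free and the distinct group
assignments can be enumerated, the test switches to exhaustive enumeration
(logged); Monte-Carlo p-values agree with the exhaustive ones within
Monte-Carlo error on toy problems.

Family-wise error over the K points is controlled by the single-step
Westfall–Young max-|t| statistic; the omnibus shape p — a single p-value
for the overall shape difference — is the exceedance probability of the
maximal |t|, and equals the minimum FWER-corrected pointwise p by
construction (asserted in tests).  The gender x group interaction is tested
the same way on the product column with main effects and covariates as
nuisance; the pipeline always computes the per-gender comparisons and
records whether the interaction gate (p <= alpha) passed, so post-hoc
results can be labeled confirmatory or exploratory.  Per-structure area
comparisons (CC, gCC, bCC, sCC) use the identical machinery, one model per
structure with no correction across the four structures, reporting the
covariate-adjusted FES−HC difference, the permutation p, and Cohen's d.
Cohen's d is the pooled-SD standardized mean difference on the *raw*
(unadjusted) markers or areas; whether to adjust d for covariates is a
genuine choice and the raw convention is flagged here.  Subjects are
processed in canonical (sorted id) order so results are invariant to input
ordering.

## The synthetic cohort

The generator emulates the data such a study consumes.  The base shape is a
parametric arched band (a C opening downward) between two smooth radial
profiles with Gaussian-thickened anterior and posterior ends (mid radius
24 mm, half-thickness 2.9 mm in the body, 5.5/5.2 mm at the ends), giving a
CC-like area near 790 mm² and mean thickness near 7.3 mm.  Sub-region
labels split the band by angular thirds — a documented stand-in for
atlas-defined boundaries, configurable via `region_fractions`.

Per subject, in order: (1) global scaling by `(TIV / reference)^(1/3)`
(cube root: TIV is a volume, the slice is a 2D section); (2) a random
stationary velocity field (200 Gaussian bumps of width 6 mm, amplitudes
normalized so `warp_amplitude_mm` — default 0.5 mm — is the RMS field
magnitude along the outline), integrated by scaling and squaring on a
subgrid with a finite-difference fold check, so every subject warp is a
diffeomorphism; (3) for patients, an inward displacement along the outline
normal over the arc-fraction window `effect_support` (default
(0.10, 0.18), the superior genu) with a tapered-cosine (Tukey, taper 0.5)
profile whose integral is 0.75 x amplitude x support length — females at
full `effect_amplitude_mm` (default 0.8 mm), males scaled by
`effect_gender_ratio` (default 0, female-only, matching the gender-specific
pattern such studies report); (4) a small rigid jitter (SD 2 deg, 1 mm).
Ages are uniform on 12–43 y; TIV is Gaussian per gender (means 1.45/1.38
x 10^6 mm³ for F/M, SD 8 x 10^4) with a mild negative age slope so the
covariates correlate with global scale.  The generator encodes overall size
through TIV alone, and the defaults give females the larger CC areas — the
direction the motivating literature reports — which (deliberately, and
contrary to raw physiology) requires the larger female mean TIV.  Every
subject draws from an RNG stream keyed by (seed, subject id, purpose), so
cohorts are byte-reproducible and order-independent.

What the generator does not emulate: MRI intensities, scanner artifacts,
segmentation errors, 3D geometry, asymmetric or multimodal shape
variation, and real atlas sub-region boundaries.  Passing the validation
below therefore shows the *pipeline machinery* is correct and calibrated
under known conditions; it does not certify performance on real
segmentations.

## Validation studies and their problem sizes

The test suite runs desk-scale versions of the studies; sizes were chosen
as the smallest at which each question is statistically meaningful.

- Calibration oracles: template self-registration (markers within 2% of 1
  at K = 200), x1.1 scaling (mean marker within 5% of 1.21), closed-form
  linear-field Jacobian (1e-4 at 50 steps), finite-difference marker
  oracle (2%).
- Area consistency, the method's internal check: over a 40-subject cohort,
  corr(template area x mean marker, curve area) >= 0.95.
- FWER calibration: 200 replicate null cohorts (effect 0, 20 subjects,
  K = 50, 500 permutations, registration capped at 40 iterations — under
  the null the permutation distribution is valid regardless of registration
  convergence); empirical FWER at alpha = 0.05 must lie in the exact
  binomial 95% band [0.021, 0.088].
- Effect recovery: 20 replicate cohorts at the default conditions (0.8-mm
  female-only genu effect, 25 per cell, K = 50, 500 permutations); the
  female scope must flag FWER-significant points with the male scope clean
  in >= 80% of replicates, and >= 80% of flagged points must localize to
  the injected support (genu label or within sigma_V arc distance).

## Known limitations

- The marker's areal calibration is kernel-dependent by construction; with
  a much smaller sigma_V the Jacobian reads as tangential stretch only.
- Pixel-centre curves carry quantization: polygon areas and perimeters
  differ from pixel counts by documented offsets, and sub-pixel boundary
  localization is out of scope.
- The rigid start point (lower-left pixel) can flip between the anterior
  and posterior ends for near-symmetric shapes; all localization logic is
  therefore spatial, never index-based, and template-relative statistics
  are unaffected within a cohort.
- Freedman–Lane is approximate for finite samples with covariates; the
  FWER calibration study is the empirical guard.
- Registration uses fixed per-timestep momenta (not geodesic shooting);
  energies are not geodesic distances and are used only for optimization.
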