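# Methods

This note records the models, estimators, numerical choices and known
limitations behind each `epimech` module, in the order the pipeline runs
them.

## Contact mechanics of AFM nanoindentation

**Model.** A rigid sphere of radius *R* indenting an adhesive,
incompressible elastic half-space is described by classical JKR theory,
parametrised by the contact radius *a*:

    F(a)     = 4 E* a^3 / (3R) − sqrt(8 π w E* a^3)
    delta(a) = a^2 / R − sqrt(2 π w a / E*)

with reduced modulus E\* = E/(1 − ν²), ν = 0.5 by default for live
cells, and work of adhesion w (J/m²). Setting w = 0 recovers Hertz
contact, F = (4/3) E\* √R δ^{3/2}. The measured force adds two terms:

* a **membrane spring** K_m·δ (N/m), active for δ > 0 — a first-order
  description of the stretched cell membrane resisting indentation; and
* a **linear instrumental baseline** (offset + slope·z, in nN and
  nN/µm) representing optical interference and drift.

The dimensionless membrane-to-bulk ratio is defined as
**β = K_m/(E·R)**; the probe radius is the only natural length scale
available to non-dimensionalise a spring constant against a modulus.
The surface-tension-dominated (elastocapillary) refinement of adhesive
contact on very soft matter is not implemented; for the moduli and probe
size targeted here the classical branch is used throughout and this is a
declared limitation, not an approximation that is checked at run time.

**Numerics.** The rising (stable loading) branch of δ(a) is inverted
per depth with a clamped Newton iteration exploiting convexity of δ(a),
polished to machine precision, with a bracketed-root fallback near the
branch minimum; w = 0 inverts in closed form. The branch minimum
δ_min < 0 is the deepest point the adhesive neck reaches; retract
segments are rendered down to δ_min, approach segments begin at the
contact point (jump-to-contact is a discontinuity of the model, as it is
of the instrument).

**Contact-point estimation** (`estimate_contact_point`) grid-searches
candidate contact points z₀ over the approach samples; each candidate is
scored by the SSE of a least-squares fit that is linear in coefficients:
a straight baseline over the whole curve plus Hertz-shaped (δ^{3/2}) and
spring-shaped (δ) columns active beyond the candidate. If no candidate
beats the all-baseline fit by at least 5% relative SSE the curve is
declared contact-free. A ratio-of-local-variance detector is available
as a config alternative (`contact_method="rov"`). The estimate is
translation-equivariant by construction.

**Fitting** (`ContactModel.fit`) is bounded nonlinear least squares
(trust-region reflective) on the approach segment over
(log₁₀E, w, K_m, z₀, baseline offset, slope), with bounds
E ∈ [0.1, 10⁶] Pa, w ∈ [0, 0.1] J/m², K_m ∈ [0, 1] N/m
(config-overridable) and z₀ co-fitted within ±0.2 µm of the grid
estimate. The modulus is fitted in log space because its plausible range
spans seven decades. A deterministic list of ≥3 starts (Hertz-scale
estimate of E and ±1 decade, with and without adhesion/membrane seeds)
makes the fit reproducible; non-convergence of every start is flagged on
the result, never silent. Approach data determine E and K_m; the retract
determines adhesion. Tolerances ftol = xtol = 1e-14 cost little here and
let noise-free round trips recover parameters to machine precision.

**Adhesion energetics** are reported two ways, side by side, because
"adhesion energy" is ambiguous: (i) *w_pulloff* converts the deepest
retract excursion below the baseline via the JKR pull-off identity
|F_pull| = (3/2)πwR; (ii) *hysteresis_energy* integrates
(F_approach − F_retract) dz over the overlapping piezo range
(trapezoidal, 512-point common grid). The retract baseline is the median
force over the 20% of samples farthest from the surface — so the curve
must include a genuinely non-contact tail; for very soft, sticky
surfaces the adhesive neck can extend microns below the contact point
and the piezo range must be chosen accordingly.

An optional tip–sample separation correction (δ = z − z₀ − F/k) and an
indentation cap at 40% of a supplied cell height (warning, not error)
are config flags; both default off/unset.

## Fiber-mat morphometry

**Segmentation**: local-mean adaptive threshold (block 51 px) floored at
half the global Otsu threshold — the floor stops large empty background
patches from being promoted by a purely local criterion — then
small-object removal, closing, small-hole filling. A polarity flag
handles dark-fiber imagery.

**Diameters**: the mask is skeletonised; at each skeleton pixel the
Euclidean distance transform (EDT) gives the local radius and the sample
is 2·(EDT − 0.25) px. The quarter-pixel offset corrects the EDT's
distance-to-background-pixel-center bias, which is 0 for even and ~0.5 px
for odd discrete widths. Skeleton pixels within 1.5 local radii (+1 px)
of a skeleton branch point are excluded: where fibers cross or run
together the merged foreground inflates the EDT over a zone wider than
one radius around the topological branch point. Both constants were
calibrated on generated mats with known per-fiber truth (including the
study-scale density of ~200 full-span fibers on a 2048² image at
50 nm/px) and on exact ribbon fixtures; with them the sample mean tracks
the generating mean within ~2%. The distribution is reported over
skeleton-pixel samples, not per-fiber means — the sampling unit the EDT
naturally provides and the one the generator's truth can check.

**Pores** are 4-connected background components not touching the image
border, each reported as an equivalent diameter 2√(A/π). These are 2D
projected voids; the 3D tortuosity of a real membrane is out of scope.

**Orientation**: Hann-windowed 2D FFT; power integrated over an annulus
(defaults: 3 px from DC to 90% of the half-size, config-exposed since no
canonical radii exist) into 180 angular bins, spectral angles rotated
90° to real-space fiber orientation. The anisotropy index
S = |Σ P e^{2iθ}|/ΣP is the resultant length of the power-weighted
doubled-angle vector: 0 isotropic, 1 perfectly aligned. Windowing makes
translation invariance approximate (borders are down-weighted).

**Roughness** R_q is the RMS of residual heights after least-squares
plane removal. Note the plane is not orthogonal to a sinusoid over few
periods (∫x·sin x ≠ 0), so the analytic A/√2 value is reached only in
the many-period limit, as 1/m².

## Cell morphometrics

Nuclei: Gaussian smoothing (σ = 2 px), Otsu threshold, hole filling,
distance-transform watershed with peak markers (min separation 10 px) to
split touching nuclei, minimum-area filter (40 px). Cells: seeded
watershed on the inverted smoothed cytoskeletal channel, constrained to
its Otsu foreground, one cell per nucleus seed; seeds outside the
foreground are dropped and logged. Every parameter lives in
`CellSegConfig`.

Shape features follow the conventions: eccentricity of the second-moment
ellipse (0 = circle), compactness as circularity 4πA/P² (1 = circle;
chosen so that "more compact" = "more circular"), plus the raw axis
ratio so either convention can be read off. The perimeter is the length
of the 0.5 iso-contour of the Gaussian-smoothed (σ = 1 px) object mask:
chain-code perimeters are biased high for smooth shapes and Crofton
perimeters are biased low for axis-aligned polygons, while the smoothed
contour is accurate for both (disc compactness 0.99, square 0.80 at
r = 50 / s = 100 px). Nuclei are matched to cells by containment of the
nucleus centroid. Cell height from a topography map is the 99th
percentile of cell-region heights minus the histogram mode of substrate
heights (Otsu split when no background mask is given); a z-stack variant
multiplies occupied-slice span by slice spacing. Intensity fold change
is the ratio of group means of per-cell mean grey values with a seeded
bootstrap percentile CI (2000 replicates).

## Wound kinetics

The wound is the low-texture region of a brightfield frame: local
variance (9-px window) is thresholded by Otsu on the SD map when the
frame contains both textures (class-mean variance ratio ≥ 4); otherwise
the frame is classed all-wound or all-confluent by an absolute
homogeneity cutoff on the median variance (2.5e-3 on unit-scaled grey,
matched to the generator's default texture contrast and config-exposed
for real imagery). The candidate component must span ≥ 50% of the
scratch axis. Replicate frames per timepoint are segmented independently
and their areas averaged.

Fractions are area(t)/area(0) (the first is 1 by definition); closure is
the first timepoint at or below a 1% fraction. The migration velocity is
**per-front**: width W = area / wound extent along the scratch axis, and
v = mean over intervals of [W(tᵢ) − W(tᵢ₊₁)]/[2Δt], using only intervals
whose endpoints are both open — an interval in which closure occurs
underestimates the front speed. The total gap-closure rate (2v) is also
reported, since published "migration velocity" can mean either.

## Statistics

`compare_groups` implements the paired t-test (t = mean(d)/(SD(d)/√n),
df = n − 1) and, because between-substrate designs are arguably
unpaired, a Welch alternative with Satterthwaite df; paired is the
default to mirror the study design it supports. Zero-variance inputs are
returned with a degeneracy flag (t = 0, p = 1 for identical samples;
p below machine precision for a constant nonzero difference) rather than
NaN. No multiple-testing correction is applied by default; a Holm
step-down helper is provided.

## Synthetic generators

All randomness flows from one explicit integer seed per call
(`numpy.random.default_rng`); identical (parameters, seed) reproduce any
artifact bit-for-bit, and every artifact carries a `GroundTruth` sidecar
with the generating parameters and per-object truths.

* **Force curves**: the composite forward model plus i.i.d. Gaussian
  force noise and linear drift; the retract follows the adhesive branch
  to its minimum depth, then the baseline. Defaults (probe R = 2.6 µm,
  500 points, ~1 µm pre-contact, 0.4 µm maximum indentation) mirror the
  colloidal-probe protocol the package targets; the instrument noise
  level is not published, so it is an explicit argument everywhere and
  the default is zero.
* **Fiber mats**: full-span straight ribbons with normally distributed
  widths (default 622 ± 31 nm at 50 nm/px), axial von Mises orientations
  (κ = 0 ⇒ isotropic), analytic anti-aliased coverage, opaque (max)
  compositing. Real electrospun fibers are curved; straightness keeps
  per-fiber truth exact and curvature is deliberately not emulated.
* **Monolayers**: non-overlapping ellipses (rejection sampling on center
  distance; failure raises a capacity error naming the limiting
  parameter) with concentric elliptical nuclei; per-cell body intensity
  lognormal around its group mean (CV 10% by default). Ellipses give
  closed-form area/eccentricity truths; real cell outlines are
  polygonal and textured, so segmentation difficulty is *not* emulated.
* **Height maps**: tilted plane (zero intrinsic roughness), axial
  sinusoid, or Gaussian-filtered white noise rescaled to an exact sample
  SD.
* **Wound series**: a central low-variance band narrowing at
  2·v·t between two high-variance cell-texture flanks.

Passing tests on these inputs demonstrates correct estimator logic and
calibrated geometry recovery; it does not demonstrate robustness to
uneven illumination, debris, curved fibers, ragged wound edges or
instrument artefacts, which the generators intentionally do not model.

## Problem sizes used in tests and the acceptance script

Unit and integration tests run on reduced geometries chosen to keep the
relevant statistics stable: 1024² mats at the study's areal fiber
density, 12–30-cell monolayers, 100-curve noise ensembles, 10⁴-replicate
null calibrations. The acceptance script uses the full 2048² / 200-fiber
mat and 30-cell-per-group intensity comparison. These sizes are the
package's test design; all estimators accept arbitrarily larger inputs.

## Known limitations

* Classical JKR only; no elastocapillary regime, no viscoelasticity, no
  Oliver–Pharr analysis, no thermal-drift correction.
* β = K_m/(E·R) is this package's convention for the membrane-to-bulk
  ratio; other normalisations exist.
* 2D projected pore sizes; no 3D porosity.
* Wound segmentation assumes texture contrast between lawn and denuded
  surface; phase-contrast halos are not modelled.
* The paired default in `compare_groups` mirrors common practice in the
  supported study design even where pairing is debatable; the Welch
  route exists for that reason.
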