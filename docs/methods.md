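# Methods

## The measurement problem

Microleakage of a cemented provisional crown is assessed by immersing the
specimen in methylene-blue dye, sectioning it, and measuring how far the dye
travelled along the die–cement interface from the margin.  The interface in a
cross-section image is a curved path, so a straight-line (chord) distance
understates the true penetration.  `microleak` quantifies penetration as the
*arc length* of a polynomial model of the dye path, converted to millimetres
with a microscope-graticule calibration.

## Measurement chain

1. **Dye segmentation.**  A pixel is dye-positive iff its colour lies in a
   rectangular RGB box: `R <= r_max`, `G <= g_max`, `b_min <= B <= b_max`
   (defaults 110, 160, 150, 200 on the 8-bit scale; 16-bit input is rescaled
   to 8-bit first).  The three conditions are combined with AND — the only
   reading consistent with a per-channel threshold triple.  The threshold is
   applied to raw pixels; no image enhancement is performed.

2. **Marker extraction.**  A least-squares principal axis is put through the
   dye pixels; pixels are binned by their projection onto that axis
   (`bin_width`, default 5 px — wide enough to suppress sub-pixel jitter,
   narrow enough to preserve curvature) and each occupied bin contributes the
   centroid of its pixels, rounded to the nearest pixel (exact halves round
   toward the smaller index, for determinism).  Markers are ordered starting
   from the end nearest the margin anchor, which is user-supplied metadata —
   automatic margin detection is out of scope.  The extractor also records
   the dye pixels' projection *span*, used below.

3. **Curve fit.**  The markers are fitted with a 4th-order polynomial
   `y = a x^4 + b x^3 + c x^2 + d x + e` by least squares.  The fit is done
   in a rotation-stabilised local frame: the markers' principal axis is the
   abscissa.  A near-vertical interface in image coordinates is not a
   function `y = f(x)` there, but always is in its principal-axis frame; arc
   length is invariant under this rigid change of frame, so the measured
   value is unchanged for any interface that is also single-valued in image
   coordinates.  `fit_interface_curve(..., frame="image")` fits in raw image
   coordinates when coefficient values themselves are of interest.  With
   fewer than five markers the degree is reduced to `n - 1` and reported in
   `degree_used`; fewer than two markers is unfittable and maps to the
   `no_dye` status.

4. **Arc length and calibration.**  Penetration in pixels is
   `s = ∫ sqrt(1 + (dy/dx)^2) dx`, evaluated by adaptive quadrature
   (relative tolerance 1e-8; the integrand is a smooth function of a quartic,
   so cost is negligible).  The integration bounds are the marker extent,
   symmetrically widened to the recorded dye-pixel projection span: bin
   centroids sit half a bin inside the dye front at each end, and without the
   widening the measurement is biased low by about one `bin_width`
   (about 1% at a 500 px extent).  Millimetres are pixels times
   `mm_per_pixel` (default 0.0013028).

5. **Complete-penetration cap.**  If the trace reaches or passes the
   die-centre landmark (its far end projects at or beyond the landmark on the
   fit abscissa), or if the converted length reaches `cap_mm` (default
   7.18 mm, the margin-to-centre distance), the specimen is reported as
   `complete_penetration` with exactly `cap_mm`.  The metric fallback is this
   package's choice; it keeps the cap meaningful when no landmark is given.

6. **Cement thickness.**  Given die-side and restoration-side fitted curves,
   stations are placed at evenly spaced *arc-length* fractions along the die
   curve (endpoints inclusive; fractions 0, 1/2, 1 for the default three
   stations), matching how penetration itself is measured.  Thickness at a
   station is the distance along the die curve's local normal to the
   restoration curve, in micrometres.  Even spacing in arc length and the
   die-normal direction are both package choices — the physically meaningful
   gap — where the procedure is otherwise underdetermined.  A normal ray that
   misses the restoration curve within its (slightly extended) fitted extent
   flags the station missing, excludes it from the mean/sd, and warns.

7. **Statistics.**  The a-priori sample size for a one-way fixed-effects
   k-group comparison is the smallest balanced total N whose noncentral-F
   power (noncentrality `f^2 N`, df `(k-1, N-k)`) reaches the target; with
   Cohen's f = 0.5, alpha = 0.05, power 0.8 and k = 3 this gives N = 42.
   Shapiro–Wilk per group gates the analysis onto the nonparametric path if
   any group rejects normality (a zero-variance group — e.g. every specimen
   at the cap — is treated as non-normal with a warning rather than an
   error, because capped microleakage data make this case realistic).  The
   omnibus test is Kruskal–Wallis on midranks with tie correction; pairwise
   comparisons are Dunn z-tests with the same tie correction, two-sided
   p-values multiplied by all `k(k-1)/2` pairs (Bonferroni) and clipped at 1.
   Delaminated specimens are never measured; whether they are excluded from
   the statistics (default) or assigned the cap is a configuration policy.

## Synthetic scenes and what a green test establishes

The generator renders a die region, a cement band (constant or linearly
wedged thickness, in µm), a restoration region and a dye band painted along
the die–cement interface from the margin up to an exactly known arc length,
computed with a composite Gauss–Legendre oracle that is independent of the
measurement path's adaptive quadrature.  Default colours put the dye inside
the threshold box (60, 60, 175) and every other region outside it; sensor
noise is independent Gaussian per channel, clipped to [0, 255].  The
"stepped" texture adds a square wave (period 12 px, amplitude 2 px) to the
restoration boundary and the dye band edge, emulating the staircase
morphology of additively manufactured fitting surfaces.

These scenes validate the geometry and calibration of the pipeline — that a
known arc length is recovered within 0.5% noiseless and 2% under noise, that
the cap triggers, that thickness stations read a known gap.  They do not
emulate real specimen photographs: no uneven illumination, no dye diffusion
gradient, no cracks or varnish regions, no colour overlap between dye and
cement.  A green suite therefore establishes correctness of the computation,
not robustness to arbitrary photographic conditions.

Group-level draws (`generate_group_study`) are capped normals, clipped to
[0, cap], with independent Bernoulli delamination — the simplest model that
reproduces the tie-heavy, non-normal samples the statistics path must handle.

## Pipeline-level choices

* The study manifest carries no restoration-interface input, so pipeline
  thickness is computed only when a second RGB box (`resto_threshold`) is
  configured to segment the restoration region; its cement-facing boundary is
  traced with the same binned-centroid extractor.  Stations then span the
  dye-traced portion of the die interface.  Without a box, thickness is
  skipped with a log line.
* `simulate` writes studies at a scaled calibration (default 0.02 mm/px) so
  the 7.18 mm cap distance (359 px there) fits inside small fixture images.
* Everything is deterministic given config and inputs; all randomness flows
  through explicit seeds.

## Known limitations

* Marker centroids sit half a dye-band above the true interface, so fitted
  curves are offset by that constant; arc length, being offset-invariant for
  near-parallel curves, is unaffected to first order.
* The dye threshold box is a hard gate: dyes or cements whose colours
  overlap the box need a recalibrated threshold.
* The geometric cap test projects the landmark onto the fit abscissa; a
  landmark far off the interface axis could trigger it spuriously.
* Thickness from images requires a colour-separable restoration region.
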