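# Methods

## The measurement model

Each analysis case compares two angular positions measured about the same
reference point in an axial slice through a stented aortic aneurysm:

1. **Endoleak angle** `θ_el`: the angle of the segmented endoleak's
   representative point (its centroid by default) about a stent-graft (SG)
   centroid.
2. **Wall-stress-peak angle** `θ_ws`: the angle at which the circumferential
   wall-stress profile for the same axial level attains its (relevant) peak.

Their concordance is the matching index
`100 · Δ(θ_el, θ_ws) / θ_ws`, with `Δ` the minimal circular difference
(shorter arc, in `[0, 180]`).  Two deliberate choices:

* **Numerator = absolute, wrap-aware difference.**  A signed or plain
  difference fails whenever the two angles straddle the 0°/360° seam (8.5°
  vs 336.9° are 31.6° apart, not 328.4°) or when the endoleak trails the
  peak.  The package therefore always uses the minimal circular difference,
  and every report also carries `numerator_deg` so the raw angular
  disagreement is available independent of the percentage.
* **Denominator = the raw wall-stress angle.**  This makes the index
  dimensionless and comparable across cases, but *not* invariant to the
  choice of angular reference axis, and unboundedly sensitive as
  `θ_ws → 0°` (the statistic is undefined at exactly 0° and the package
  raises there).  This sensitivity is inherent to the statistic, not an
  implementation artifact; when screening arbitrary scenes, read
  `numerator_deg` alongside the percentage.

Reported indices are rounded to one decimal, half away from zero; internal
values are never rounded.

### Angle convention

Origin at the image's top-left, rows increasing downward.  Angles are
measured from the +x axis (increasing column), counterclockwise, with the
row axis negated — a point *above* the centroid is at 90°.  The convention
is arbitrary but fixed package-wide; any pair of angles entering the index
must share it (enforced via the `reference` tag on `AngularPosition`).
Reproducing a published table from its printed angle pairs is
convention-free, because both angles are given; absolute angles measured on
new images are not.

### Which centroid, which endoleak point

`centroid_mode="branch"` (default) measures angles about the centroid of
the SG daughter branch nearest the endoleak; `"whole_sg"` uses the
area-weighted centroid of all segmented SG regions.  The endoleak's
representative point is its centroid, except for endoleaks spreading across
both daughter branches, where no single leak site is visible: there the
**midpoint-of-contact rule** walks the endoleak's ordered boundary, marks
points within `contact_tol` (default 3 px) of either branch boundary, and
takes the middle point of the contact arc (preferring a contiguous arc that
touches both branches; otherwise the midpoint of the shortest boundary arc
between the two contacts).  Contact with fewer than two branches is an
error directing the caller back to the centroid rule.

## Segmentation chain

`crop → mean denoise → binarize → Canny → close → fill holes → regions`,
with every parameter in `SegmentationConfig` (`--dump-config` prints all
defaults):

* **Mean filter**: square window, default 3×3 (the smallest useful window),
  arithmetic mean, edge replication at borders.
* **Binarization**: Otsu by default — reproducible without per-image
  tuning — with a fixed-threshold override.  Otsu on a constant image is
  undefined and raises.
* **Canny**: σ = 1.0 px; hysteresis thresholds 0.1/0.2 *of the maximum
  gradient magnitude* (scaled internally, since the underlying routine
  takes absolute thresholds).
* **Closing**: disc element, radius 3 px — enough to seal gaps in the edge
  rings without bridging structures more than ~6 px apart.  Closing alone
  leaves ring interiors empty, so an explicit hole-fill step follows; the
  centroid of a ring and of its filled disc differ, and the filled version
  is the meaningful one.
* **Regions**: 8-connected components, area ≥ `min_region_area`
  (default 20 px, a noise-speck floor), centroid = mean of member pixel
  coordinates (sub-pixel), sorted by descending area.

**Role assignment** is the one genuinely invented step: clinically the
endoleak is pointed out by a radiologist.  Default rule: the largest region
is an SG branch; the second-largest is also a branch when its area is at
least `branch_area_ratio` (default 0.5) of the largest; the endoleak is the
largest remaining region, or the region nearest `endoleak_seed` when a seed
point is supplied (emulating the radiologist).  A slice with no qualifying
region yields a structured `NoEndoleakCandidate` outcome, not an exception —
screening negative slices is an intended use.

## Stress-peak identification

Published stress-peak positions were read from solver colour maps by eye;
this package substitutes an explicit rule so the choice is reproducible:

1. circular moving average over a `smooth_window_deg` window (default 10°),
   wrapping across the seam;
2. circular local maxima, discarding any that rise less than
   `min_height_frac` (default 0.2) of the smoothed range above its minimum —
   without this floor, baseline noise ripple produces spurious "peaks" that
   can hijack nearest-peak selection;
3. greedy acceptance by descending stress with `min_separation_deg`
   (default 30°) between accepted peaks;
4. parabolic sub-sample refinement of each accepted peak: a quadratic is
   least-squares fit to the smoothed profile within ±min(3 × smoothing
   window, separation) of the argmax sample, and the vertex (clipped to
   that window) is the reported angle.  For a symmetric bump this is
   unbiased and averages noise over the whole window, instead of trusting a
   single argmax sample whose position jitters on a flat peak top.

When several peaks survive, `peak_nearest` selects the one with minimal
circular difference to the verified endoleak angle (ties: higher stress,
then lower angle) — matching how an index is computed when a slice shows a
secondary stress peak with no endoleak near it.

## Synthetic data

`synthetic_ct` emulates just the geometry the pipeline measures:

* 256×256 8-bit scenes, background 30; SG branches as bright (200) filled
  discs of radius 40 px or annuli with a darker lumen; one endoleak as a
  filled disc (intensity 180, radius 12 px) placed at an exact angle and
  radial offset (default 60 px) from its anchor branch centre; Gaussian
  blur σ = 1 px; additive Gaussian noise (default SD 5 grey levels, ≈3% of
  the 150-level object contrast) clipped to the dynamic range.  The default
  radial offset leaves an 8 px gap between blob and branch so that closing
  (diameter 6 px) cannot merge them; endoleaks overlapping a branch lumen
  or leaving the frame are rejected at spec validation.
* stress profiles as baseline + wrapped-Gaussian bumps sampled at uniform
  angles (default 360 samples): baseline 0.2 MPa, primary amplitude
  0.6 MPa — placing stresses in the sub-MPa range reported for stent-graft
  walls — width (Gaussian σ) 25°, optional secondary bumps strictly smaller
  than the primary (otherwise the ground-truth peak would be ambiguous),
  additive noise clipped at zero.

Ground truth (branch and blob mask centroids, requested angle, noiseless
peak angle) is recorded before noise; a single integer seed makes every
output bit-reproducible.  Pixels are isotropic and unitless — angles do not
depend on pixel spacing under isotropy.

What the generator does **not** emulate: thrombus, calcification, beam
hardening, non-Gaussian CT noise texture, 3-D context, or any real lumen
anatomy.  Passing synthetic tests therefore demonstrates that the chain
measures placed geometry correctly at controlled noise, not that it
segments clinical CT robustly.

## Test problem sizes and tolerances

The synthetic validation batches run 100 seeded scenes for centroid/angle
recovery (tolerances 2 px and 2° at noise 5% of contrast), 200 seeded
profiles for peak recovery (≥95% within 2° at noise 5% of amplitude), and
50 scene/profile pairs end to end (numerator within 3° of the known
circular difference) — sizes chosen to bound the Monte-Carlo estimates
tightly while keeping the whole suite under a minute.  Operator-level
checks (mean filter vs an explicit loop, centroids vs raw pixel
enumeration, circular difference vs a two-direction scan, closing
idempotence) are exact.

## Known limitations

* Single-slice, 2-D only; no DICOM series handling or 3-D reconstruction.
* Stress profiles are inputs; no flow or structural simulation is
  performed, and how a 3-D stress field is collapsed to one slice-level
  profile is outside this package's scope.
* The index's dependence on the reference axis and its blow-up near
  `θ_ws = 0°` are properties of the statistic itself; comparisons across
  datasets measured under different conventions are not meaningful.
* Automatic endoleak/branch role assignment is heuristic; for clinical
  images use the seed-point override.
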