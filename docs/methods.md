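# Methods

`tubewidth` measures the local diameter of a single elongated biological
tube (a fallopian tube, a blood vessel, any vessel-like structure) from one
2D image, at every point along its length.  This note records the model
behind each stage, the free parameters and their defaults, what the
synthetic phantoms do and do not emulate, and the design choices made where
the method was genuinely open.

## Pipeline model

The method assumes a single tube with exactly two continuous bounding
edges, imaged roughly in-plane (no substantial bending towards or away from
the camera) against a contrasting background.  Stages:

1. **Greyscale** — channel mean `(R+G+B)/3`, with optional per-channel
   weights for vessels over-represented in one channel.
2. **Contrast enhancement** — histogram equalisation
   `B(n) = round(255·cdf(n))` by default; plain linear stretching
   `255·(g−min)/(max−min)` as the alternative route
   (`use_equalization=False`).  Stretching widens the dynamic range but
   leaves the distribution's shape (and therefore edge contrast in
   low-variance images) unchanged, which is why equalisation is the
   default.  Enhancement runs **before** smoothing: both remaps are
   monotone, so they never move an edge, whereas enhancing a
   smoothed image redistributes the transition-ramp levels of a strongly
   bimodal histogram and displaces the gradient maximum away from the
   physical boundary — on maximal-contrast phantoms the bias reaches the
   smoothing radius and corrupts every diameter by ~10 px.
3. **Gaussian smoothing** — normalised kernel, `sigma = 2` px,
   radius `ceil(3·sigma)`, mirror (reflect-101) borders so the frame edge
   produces no false gradient.
4. **Gradients** — a 2/3/2-weighted Sobel pair (the classical 1/2/1 variant
   is selectable with `sobel_variant="classic"`); magnitude
   `sqrt(Ix²+Iy²)`; orientation as a bearing from the positive row axis,
   clockwise, in [0, 360).
5. **Non-maximum suppression** — bearings quantised to {0, 45, 90, 135}
   degrees (boundary angles to the higher bucket); a pixel survives if its
   magnitude is `>=` both neighbours along the quantised direction.  The
   `>=` comparison keeps ridge plateaus: digitised edges produce exact ties
   and a strict `>` erases whole edge segments.
6. **Hysteresis binarisation** — thresholds are fractions of the maximum
   suppressed magnitude, `z2 = 0.20·max`, `z1 = 0.08·max` (scale-invariant
   across the 8-bit pipeline; no absolute values are meaningful after
   equalisation).  A weak pixel (in `[z1, z2]`) is kept iff a chain of
   non-zero pixels 8-connects it to a pixel above `z2`; the chain scan is a
   deterministic BFS — connectivity does not depend on visit order.
7. **Component filter** — 8-connected components are grouped into walls
   (components within ~6 px of each other are one wall, so a ridge that
   suppression severed over a few pixels — typically where it grazes the
   image border — still counts as one edge) and the two walls with the
   most pixels are kept; a manual override accepts explicit component
   indices.
8. **Silhouette fill** — see below.
9. **Thinning** — Zhang–Suen to a skeleton, then a secondary pass to a
   strict ≤2-neighbour line, then endpoint-to-endpoint ordering into an
   indexed coordinate list.
10. **Width profile** — at every index the tangent slope is the central
    finite difference over ±4 indices; two Bresenham rays are cast along
    the negative-reciprocal (normal) direction until the next path pixel is
    background; the diameter is the Euclidean distance between the two ray
    termini.  Optional `pixels_per_mm` calibration divides into
    millimetres.

## Silhouette filling

Each of two orthogonal passes (down columns, then down rows) reduces every
scan line to a pair of wall tracks `y1/y2` and fills between them; the
final silhouette is the intersection of the passes (union is available for
replication).  The fill's robustness rules, developed for detection gaps
and oblique/curved walls:

* **Wall identity** comes from the edge components, with gaps up to ~6 px
  bridged by dilation before labelling so a punched wall does not read as
  several walls.  Walls closer than that to each other are outside the
  method's assumptions.
* A line seeing **both walls** is bounded on both sides directly.
* A line seeing **one wall once, transversally** is a one-sided
  constraint.  Which side it bounds is decided by continuity against the
  carried opposite track; continuity is first-order (the track position is
  linearly extrapolated from its recent observations), because a wall
  oblique to the scan lines drifts several pixels per line.
* A line seeing **one wall tangentially** (several crossings, or one long
  grazing run) abstains: a single interval cannot express interior on both
  sides of a wavy wall.  The orthogonal pass bounds such lines.
* Missing track stretches up to 10 lines are bridged with one Bresenham
  segment per track (linear interpolation; its error stays within ±1.5 px
  for gaps of median length 1 px).  Across a longer unobserved stretch the
  question is whether the wall still exists there: if the *other* wall was
  observed across the stretch, this wall was merely undetected and the
  flanks are interpolated (a flank hugging an image border escapes to it —
  the wall left the scope); if neither wall was seen, those lines carry no
  wall information and the track opens to the image border on its side
  rather than fabricating a wall from a stale value.
* The scan direction is arbitrary, so each pass runs bidirectionally and
  trusts, near the span's start, the reverse scan, whose track state is
  mature there (a single scan's first lines rest on an unconfirmed seed).

## Centreline

Zhang–Suen thinning is connectivity-preserving and nearly
orientation-unbiased, but its skeleton is occasionally too thick to index:
staircase corners carry a redundant diagonal pixel, and the tube's cut ends
sprout short spurs where thinning initiates.  The secondary pass deletes
any >2-neighbour pixel whose punctured 3×3 neighbourhood stays connected
(most-connected pixels first — these are the redundant corner fillers —
row-major on ties), and if genuine junctions remain, reduces the skeleton
to its longest geodesic path by double breadth-first search before a final
clean-up.  The result is walked from the endpoint with the smaller
row-major coordinate (closed loops start at the smallest row-major pixel).

Two behaviours of textbook Zhang–Suen are worth knowing:

* **End erosion** — open tube ends erode by up to about half the tube
  width, so a quarter-arc centreline of analytic length 707 px indexes
  ~590–620 points.  The eroded region coincides with the end-noise zone
  that the valid domain trims anyway.
* **Mirror asymmetry** — the two sub-iterations scan in fixed directions,
  so mirrored inputs yield skeletons whose eroded ends differ pixel-wise.
  The measured diameters are mirror-stable within 1 px; pixel-exact
  skeleton equivariance does not hold and is not claimed.

A diagnostic `concentricity_check` reports, per index, half the difference
of the two opposite ray lengths (0 = perfectly centred).  It does not feed
back into the pipeline.

## Width measurement parameters

* `gradient_offset = 4` — the finite-difference half-width.  Smaller
  offsets alias badly on digitised lines (a ±1 offset on a 10-degree line
  yields slopes of only 0 or 1); larger offsets blur genuine curvature.
  Near the line ends the offset shrinks symmetrically to ≥1.
* Vertical tangents are an explicit flag, never an infinite float; the
  normal is then exactly horizontal.
* `end_trim = 75` — indices excluded at each end of the centreline, where
  thinning initiation makes diameters oscillate.  The default suits a
  ~500 px rendering; resolution-sweep evaluations scale it proportionally
  with the frame (the end-noise zone scales with tube width).  Summary
  statistics are reported both trimmed and untrimmed.
* No sub-pixel refinement is attempted anywhere: edges, centreline and ray
  termini are whole pixels, and the accuracy analysis is in whole pixels.

## Synthetic phantoms

`synthetic_fixtures` renders maximal-contrast (255/0, no anti-aliasing)
phantoms with analytic ground truth:

* **A/B** — straight band of perpendicular width 100 px crossing a 500×500
  frame at a 10-degree incline, positive and negative polarity.
* **C/D** — quarter annulus of outer radius 500 px and radial width 100 px
  centred on the frame's top-left corner (the only placement where it fits
  the frame), positive and negative polarity.
* **varying** — horizontal tube with an arbitrary per-arclength width
  function, e.g. `100 + 10·sin(s/50)`, for parameter recovery.
* `rescale_fixture` re-renders with all lengths scaled (never resamples
  pixels), for resolution sweeps.
* `degrade` punches seeded gaps into binary edge maps (counts and
  geometric length distribution of median 1 px configurable) and adds
  Gaussian noise / background ramps to greyscale images.

These phantoms exercise geometry, rasterisation and the full pipeline
logic, but they are noise-free, maximally contrasted, and contain exactly
one tube with no adherent tissue — passing them demonstrates geometric
correctness, not robustness to real tissue imagery, where background
texture, uneven lighting and attached ligaments degrade the global
thresholds.

On these phantoms the pipeline attains: per-index error ≤ 1 px on the
straight tube over the trimmed domain; arc mean diameters within ~0.15 px
of the true 100 px with mean absolute error ~0.4 px; total percentage
error well under 3% at a 1500 px rendering; sinusoid width recovery with
RMSE ~1 px.  All of these are recomputed, not quoted, by the test suite
and `scripts/acceptance.py`.

## Degenerate inputs and numerical conventions

* Coordinates are 0-based `(row, col)`, row axis increasing downward, in
  every serialised output.
* Intensity remaps round half-up, once per stage.
* A constant image cannot be contrast-stretched; it is returned unchanged
  with a warning.  Fewer than two edge components raises an error that
  names the remedy (lower the thresholds, or use the manual override).
* Multiple skeleton components (noise) keep the largest; the rest are
  logged and dropped.
* The default path contains no randomness: identical input and
  configuration reproduce byte-identical outputs.

## Known limitations

* Global thresholds make the detector sensitive to large background
  intensity gradients; heavy vignetting or shadows need masking first.
* Tubes whose two walls approach within ~8 px merge under the wall-identity
  bridging and are not measurable.
* The two-pass interval fill cannot represent tubes that fold back on
  themselves (a scan line crossing the tube more than once).
* Out-of-plane bending is ignored; pixel size must be approximately
  uniform across the field for millimetre calibration to be meaningful.
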