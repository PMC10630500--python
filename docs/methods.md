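# Methods

## The score

The package quantifies scoliosis globally as the normalized area enclosed
between the extracted spine curve and its head-to-tail chord. With the spine
curve written as `col = f(row)` on `[r_first, r_last]` and the chord
`ref(row)` through its endpoints, the score is

```
area = (raw_sum / n) / (max f − min f),
raw_sum = Σ_{k=0}^{n−1} |f(r_k) − ref(r_k)|,     r_k = r_first + k·H/n,
```

with `H = r_last − r_first` and `n = 100` sampling rows by default. The
sampling grid is left-closed (`k/n` spacing, right endpoint excluded), so
`raw_sum / n` is the Riemann-sum estimate of the mean absolute horizontal
deviation: for a half-sine deviation it converges to `2/π ≈ 0.6366` (the
`n = 100` value is within 6·10⁻⁵ of it), and for a triangular deviation to
exactly 0.5. An endpoint-inclusive grid of `n` rows with the same `/n`
normalization would carry a systematic `(n−1)/n` bias (0.630 instead of
0.637 for the half-sine), which is why the half-open grid was chosen.

Two variants are exposed: `mean` (default, the formula above, the scale on
which the severity bands 0.2/0.4 and the regression coefficients live) and
`literal` (`raw_sum` not divided by `n`; exactly `n` times the mean variant,
kept because the raw length sum is the quantity the area construction
produces before averaging). The denominator `max f − min f` is evaluated on
a dense per-row sampling of the fitted curve, not just the `n` sampling
rows. A curve with horizontal extent below 10⁻⁶ px is a straight spine by
construction and scores exactly 0 rather than dividing by zero.

Properties relied on by the tests: invariance under horizontal mirroring
and under rescaling of the deviation amplitude (numerator and denominator
scale together); monotone convergence in `n`; `literal = n × mean` exactly.

## The measurement chain and its assumptions

1. **Region and equalization.** The spine region box is the min/max
   envelope of 4 annotation clicks; coordinates are 0-based `(row, col)`
   with row 0 at the top, clicks being `(x, y) = (col, row)`. Equalization
   maps each pixel to the empirical CDF of its intensity over a fixed
   256-bin quantization of `[0, 1]`. Fixed bins (rather than bins over the
   observed range) pin down two contract properties: monotonicity in the
   input intensity, and idempotence to within one bin width (1/256).
   Constant images pass through unchanged; min–max normalization maps a
   constant image to all zeros instead of dividing by zero. Equalization
   follows cropping, so the contrast stretch adapts to the spine region.
2. **Flip overlay.** `G = X + X∘σ` with `X` the half-intensity image and
   `σ` the point reflection `i ↦ 2⌊M/2⌋−i` per axis (exact reversal for odd
   dimensions; for even dimensions the reflection overshoots by one and the
   out-of-range contribution is zero). Centrally symmetric structure
   satisfies `G = image`; asymmetric structure contributes only half its
   intensity at each of two mirror sites. The 0.5 threshold is non-strict
   (`≥`) by default: a maximal asymmetric pixel over dark background lands
   exactly at 0.5 and must survive, since retaining asymmetric structure is
   the point of the operation. Values are provably within `[0, 1]`; the
   implementation asserts this to catch double-halving bugs.
3. **Anchors.** Per row of the equalized region, the global maximum
   (leftmost on ties; rows with no dynamic range emit nothing) intersected
   with strict local maxima within a ±`local_radius` column neighborhood
   (radius 3 by default, 3–5 supported; plateaus excluded by strictness).
   Both searches are gated by the overlay mask by default (pixels outside
   it treated as 0); ungated mode is a config switch. Each point map is
   cleaned by removing connected components smaller than 3 px (8-connected
   by default) before intersecting.
4. **Erosion.** Square-element binary erosion (side 2 by default) is part
   of the cleanup, applied by default to the *overlay mask*, with
   `points`/`both` modes available. Applying it to the per-row point maps
   is self-destructive: a 1-px-wide anchor chain never contains a full 2×2
   block, so erosion empties it — the empty-result guard then restores the
   input — but under noise a handful of accidental 2×2 clusters survive,
   the guard sees a non-empty result, and the genuine chain is silently
   destroyed. Eroding the mask instead shaves its boundary without touching
   the anchor geometry.
5. **Sieve.** Scanning down from the topmost candidate (always kept), a
   candidate is accepted iff the segment to the current anchor is vertical
   or makes less than `max_angle` (45° default) with the vertical axis;
   rejected rows are skipped without advancing the reference anchor. The
   anatomical rationale: adjacent vertebral levels cannot displace almost
   horizontally, so shallow jumps are noise. The comparison is implemented
   on angles (`atan2(|Δcol|, |Δrow|) < max_angle`) rather than slopes
   because `tan(45°)` in floating point is fractionally below 1 and would
   wrongly accept the exact slope-1 boundary, which must be rejected.
6. **Curve.** Natural cubic spline (zero second derivative at the ends)
   through the fine anchors for ≥ 4 points, an interpolating quadratic for
   3, a straight line for 2; fewer than 2 anchors is a reported measurement
   failure, not an exception. Interpolation at the anchors is exact to
   1e-9 px.
7. **Grading.** `area ≤ 0.2` mild, `≥ 0.4` severe, the open interval
   moderate (boundaries follow the published inequalities); estimated Cobb
   angle `13.36 + 70.54 × area` degrees. There is no "normal" band on the
   area scale; screening for normal must go through the estimated Cobb.

All stages are deterministic; every report embeds a fingerprint of the
resolved configuration so batch provenance survives parameter changes.

## Evaluation statistics

Spearman correlation uses averaged ranks with the t-approximation p-value
(n − 2 degrees of freedom). ROC analysis enumerates cutoffs at the observed
score values with the rule "positive iff score ≥ cutoff"; AUC is the
trapezoidal integral of the empirical ROC, identical to pairwise
concordance with ties counted ½ (the test suite verifies this equivalence
exhaustively on small instances, cross-checked against an independent AUC
implementation). Among cutoffs maximizing the Youden index
`J = sensitivity + specificity − 1`, the moderate-scoliosis task breaks
ties toward the highest sensitivity and the severe task toward the highest
specificity, mirroring the screening intent (miss no moderate case;
overcall no severe case). The moderate task is defined as
moderate-or-severe versus mild. Regression of Cobb on area is ordinary
least squares.

## Phantoms: what they emulate and what they do not

A phantom is `clip(background + band + noise)`: a radial background
gradient (exactly point-symmetric), decoy Gaussian blobs added in
point-symmetric pairs (they reproduce themselves under the flip overlay and
so exercise its suppression contract), and a bright vertebral band
`band_peak · exp(−(c − g(r))²/(2σ²))` along an analytic centerline
`g`. Defaults: 401×201 px (odd, so the overlay reflection is exact),
`band_peak = 0.7`, background ≤ 0.3, decoys 0.2, `band_sigma = 3` px. The
intensity ordering — band always brighter than background + decoy — gives
the row-maxima stage a well-defined truth; equalization preserves it
(monotone). Noise is additive Gaussian (σ = 0.05 in the noisy test
conditions), clipped to `[0, 1]`; identical seeds give bit-identical
images.

Centerline families: straight, half-sine, double-sine (one full period,
a double-curve spine), and a smooth S-shaped polynomial
`t²(1−t)²(t−0.4)` scaled to the requested amplitude. All families keep the
lateral drift below 1 px/row at the tested amplitudes (10–60 px over 400
rows), matching the sieve's 45° assumption — a centerline steeper than
that is outside the method's stated operating domain and is deliberately
not used as a test condition. The `oracle_area` routine computes the true
score by dense quadrature (10⁵ samples) directly from `g`, independently of
the spline pipeline.

Synthetic cohorts draw a severity grade (default mix 40/50/10%), a target
area uniform in that grade's band (0.06–0.56), and realize it with a
*tilted* half-sine: a pure half-sine scores 2/π regardless of amplitude, so
the chord tilt — solved by bisection against the quadrature oracle — is
what spans the area range. The amplitude shrinks with the target area so
the tilted centerline's extent fits the 301-px cohort image width. Manual
Cobb angles are assigned through the published affine relation plus
Gaussian jitter (sd 3°, an assumed inter-observer noise of manual
measurement).

What passing phantom tests shows: the geometry of every stage is correct,
the score matches its analytic value through the full pixel chain, and the
evaluation harness recovers a known affine link under observer noise. What
it does not show: performance on real radiographs, whose vertebral texture,
ribs, pelvis and exposure variation are far richer than a Gaussian band
over symmetric decoys; dataset-dependent statistics reported for patient
cohorts are out of reach without data and are not claimed.

## Problem sizes in the shipped checks

The default test and reproduction runs use 401×201 phantom images (401×301
for cohorts), 20 noise seeds per family, and 50-case cohorts over 5 seeds —
sizes at which the statistics above are stable while a full run of the
suite plus the reproduction script stays in the tens of seconds on one
core.

## Known limitations

- The sieve discards genuinely steep (> 45°) spine segments, biasing severe
  curves downward — an inherent property of the method, visible in the
  phantom tests only because the generator deliberately stays inside the
  45° domain.
- Anchor columns are integer pixels; at small deviation amplitudes
  (extent ≈ 10 px) rounding and noise jitter are a large relative error, so
  noisy-condition accuracy is validated at amplitude 30.
- The flip overlay suppresses only *centrally* symmetric structure about
  the region-box center; bright asymmetric non-spine structure survives and
  must be dimmer than the spine for the row maxima to stay on the band.
- DICOM support covers single-frame grayscale images with the usual
  rescale/photometric attributes; multi-frame and color are rejected.
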