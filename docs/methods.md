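# Methods

## Scope and model of the problem

The package treats seagrass mapping as a two-dataset comparison problem. One
dataset is a per-pixel classification of an 8-band visible/NIR scene into four
general classes — seagrass, no seagrass, land, and no data — produced by an
ROI-trained supervised classifier (or supplied pre-classified). The other is
reference data from a monitoring program, in one of four dialects: presence
polygons, presence points, continuous percent-cover points, or ordinal
density-class polygons. Neither dataset is error-free; the statistics quantify
*agreement*, not accuracy against truth.

Two semantic rules shape everything downstream:

* **No data is not absence.** Pixels whose substrate is obscured (turbidity,
  depth, clouds) are excluded from every comparison and tallied, never counted
  as seagrass absence. The no-data flag is sticky: once masked, a pixel cannot
  re-acquire a substrate class through collapse or comparison.
* **Land is no seagrass.** A reference bed that the map classifies as land is
  disagreement, not an exclusion.

## Radiometry

Digital numbers are scaled to top-of-atmosphere reflectance by the
conventional linear calibration `ρ = π d² (g·DN + o) / (E_sun cosθ_s)`. The
atmospheric stage is deliberately minimal: the path signal in a near-infrared
reference band is estimated as a low order statistic of the water pixels (the
`dark_percentile`, default 1%, taken with no interpolation so a genuinely dark
pixel yields a genuinely zero path), extrapolated to shorter wavelengths by
the Rayleigh power law `(λ_ref/λ)^γ` with γ = 4.75 by default and γ = 4 in
haze mode, subtracted, and divided by π to give remote sensing reflectance
Rrs (sr⁻¹). The π-normalization convention is a documented choice; measured
downwelling irradiance is not modeled. Negative corrected values are clipped
to zero and the clipped fraction recorded in metadata, because the classifier
requires finite non-negative features. The whole stage is optional — the
pipeline accepts pre-corrected Rrs or pre-classified maps.

Not modeled, by design: aerosols, sun glint, water-column radiative transfer,
bathymetric optics beyond one multiplicative attenuation grid, tides.

## Classification

The classifier contract — not any particular architecture — is what matters:
trained from user-drawn ROIs, window-based, exactly one scene class per pixel,
scene classes collapsed by a lookup table onto the four general classes with
pixel counts conserved. The default backend is a class-weighted multinomial
logistic regression on the flattened `window_size²·n_bands` feature vector
(standardized), with `window_size = 1` as the purely spectral fast path and
reflection padding at scene edges so the output grid never shrinks. Class
scores are deterministic given the seed; argmax ties break by catalog order.
Training reports per-class accuracy on a seeded stratified 20% ROI holdout,
then refits on all ROI pixels. A minimum of 50 labeled pixels per class is
required (the error names the offending class).

## Synthetic data: what it emulates, what it does not

Real inputs (commercial scenes, agency shapefiles) cannot be redistributed, so
the generator emulates each actor in the chain:

* **Truth field.** Gaussian-smoothed white noise rank-mapped through the
  quantile function of Beta(tκ, (1−t)κ), t = target cover, κ = 0.15. The
  marginal has mean exactly t, so realized mean cover is within ±0.05 of
  target by construction, and is U-shaped: cells are mostly nearly vegetated
  or nearly bare, which is how percent cover actually arises (areal fraction
  of vegetated bottom). Because the quantile function is pointwise
  non-decreasing in t, raising target cover at a fixed seed never lowers any
  cell's cover. `patch_scale` (m) sets the autocorrelation length — small for
  sparse, discontinuous beds, large for continuous meadows. An optional
  two-scale variant (`trend_scale`, weight 0.7) superimposes a bed-scale
  gradient on within-bed patchiness, emulating the depth/energy gradients
  along which real meadows thin from continuous to sparse; it is what lets a
  density-polygon tiling populate all four ordinal classes in one scene.
* **Scene rendering.** Each water pixel's expected spectrum is the
  cover-weighted linear mixture of seagrass and bare-substrate endmembers
  (plausible shallow-water Rrs values for WorldView-like band centers), plus
  iid Gaussian band noise; land uses a bright vegetation spectrum. Training
  ROIs are ≥ 3 disjoint 3×3-cell rectangles per class drawn where cover ≥ 0.9
  (seagrass), ≤ 0.1 (bare), or on land.
* **Classifier error.** `degrade_to_classmap` bypasses rendering entirely: a
  pixel is seagrass-dominated when cover ≥ `dominance_threshold` (default
  0.5, encoding that sub-dominant seagrass is spectrally outweighed by the
  rest of the pixel), misses and false alarms are Bernoulli draws, and a
  spatially correlated mask converts a target fraction of water pixels to no
  data. This isolates the agreement stages from the classifier.
* **Reference delineation.** Presence polygons are connected components of
  thresholded cover after morphological closing with `amalgamation_radius` —
  closing emulates programs that amalgamate seagrass and interstitial bare
  sand into one bed outline, and is exactly the behavior that drives
  sensitivity below specificity over patchy beds. Point dialects sample
  random water locations; density polygons tile the water area into
  `polygon_size`-cell squares labeled by the scheme class containing the
  tile's mean water-cell cover, with tiles below the scheme's lowest bound
  not delineated. The over-delineation radius is a free parameter, not an
  estimate of any real program.

Not emulated: species composition, algae (indistinguishable from seagrass in
multispectral data and absent from the reference programs' delineations),
real water-column optics, registration error between datasets, temporal
mismatch. Passing tests on synthetic scenes therefore demonstrate the
*statistical machinery* and the pipeline contracts, not field performance of
any sensor or classifier.

## Statistical choices

* Mann-Whitney U from rank sums with average-rank ties; `U_A + U_B = n1·n2`
  holds identically. Exact p by enumeration of all `C(N, n1)` rank
  assignments when `n1·n2 ≤ 20` (ties handled naturally, feasible by
  construction at these sizes); otherwise normal approximation with tie
  correction and a 0.5 continuity correction.
* Kruskal-Wallis H with the standard tie-correction divisor; p from χ²(k−1).
  If every pooled value is identical the statistic is defined as 0 with p = 1.
* Effect sizes come from the statistics directly — `|r_rb| = |1 − 2U/(n1·n2)|`
  and `ε² = H/(N−1)` (clipped to [0, 1]) — and are the headline quantities;
  p-values are secondary. Magnitude labels use half-open intervals on the
  Cohen (0.1/0.3/0.5) and modified (0.01/0.08/0.26) scales; below the small
  threshold is "negligible".
* Direction conventions: the two-class polygon comparison and the cover-point
  comparison are one-sided (upper density class / satellite-seagrass pixels
  greater); post hoc pairwise tests are two-tailed. U is reported for the
  lower-ordinal group of each pair, so strong positive association gives a
  small printed U and |r_rb| near 1.
* The four-class gate checks the per-group rule (≥ 5) before the total rule
  (≥ 24); failure yields a descriptive report (per-class medians, no
  statistic), mirroring how an analyst would fall back to qualitative
  comparison.
* Post hoc tests attach when ε² reaches the small threshold (0.01) — the
  trigger for "substantive variation" is otherwise unspecified, and this is
  the most permissive defensible choice; it is recorded in the report.
* No multiple-comparison adjustment by default; an optional Holm step-down
  flag (`holm_adjust`) records adjusted post hoc p-values for users who want
  one. Medians use linear interpolation on even counts; rounding to two
  decimals happens only at report formatting.

## QC rules and their denominators

The no-data-fraction rule (> 90% → discard) uses **all** pixels in the
polygon footprint as denominator, land included; the valid-pixel rule (< 10 →
discard) counts only seagrass + no-seagrass pixels. The rules apply in that
order; a polygon containing no cell centers is flagged (too-few-valid) rather
than erroring. Every polygon appears in the output table and in the JSON-lines
run log with its tallies and QC status, so discards are auditable.

## Geometry conventions

Grid origin at the north-west corner, row-major, square cells; cell centers at
half-integer offsets. Every polygon-to-pixel assignment — rasterization,
zonal clipping, point matching — uses cell-center containment, which is
deterministic, area-unbiased, and matches the point-in-polygon oracles used
in the tests. Polygons overlapping the scene edge are effectively clipped by
the containment rule and the QC rules then decide their fate. The analysis
extent for inferring absence from presence polygons defaults to the full
scene water area and is an explicit, logged argument otherwise.

## Problem sizes and determinism

Default test and demo scenes are 96–256 cells on a side at 2 m — large enough
that binomial checks on error-rate recovery have power (3-standard-error
bands on ≥ 10⁴ eligible pixels) while the full pipeline completes in seconds.
Every generator and the pipeline as a whole are pure functions of
(parameters, seed): rerunning a config reproduces every artifact
byte-for-byte, which the manifest's checksums make checkable.

## Known limitations

* The rank tests assume exchangeable observations; spatially autocorrelated
  polygons violate independence and no correction is applied (matching
  standard practice in the agreement literature, but p-values should be read
  accordingly).
* The atmospheric stage is a dark-object power law, not a radiative-transfer
  correction; it is adequate for the synthetic forward model it inverts and
  for testing the pipeline contract, not for production atmospheric
  correction.
* The default classifier is linear in window features; scenes whose classes
  are not linearly separable in that space need a different backend via
  `model_config`.
* Density-scheme boundary values (e.g. exactly 75%) are assigned to the upper
  class; schemes with gaps between bins (e.g. 10% vs 11%) leave gap values in
  the lower bin's upper neighborhood unassigned exactly as the program
  definitions do — tiles whose mean falls in a gap are not delineated.
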