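# Methods

This note documents the models, conventions and numerical choices behind
`hypoquant`, what the synthetic-data generators do and do not emulate, and
the known limitations of each estimator.

## Ratiometric pH quantification

The apoplastic pH readout is the per-pixel ratio of a pH-responsive sense
channel (GFP) to a pH-insensitive reference channel (RFP), both expressed
at the cell wall.  The package standardizes on **sense/reference
(GFP/RFP), so lower = more acidic**; renderers accept an invert flag for
display.  Absolute pH is *not* recoverable without a sensor calibration,
which these assays do not provide: all quantitative outputs are in ratio
units, and pH appears only as the generator's latent variable.

Wall pixels are selected on the reference channel with a user-chosen
threshold using a strict `>` comparison (an arbitrary but fixed
convention; `≥` would differ only on exactly-equal pixels).  The threshold
is deliberately manual — it is set to isolate the bright wall lattice, and
the provenance report records it together with the per-frame mask sizes.
An empty mask is a warning, not an error; the frame reports n = 0.

The area kymograph packs each frame's ratios into a `rect_width ×
rows_per_block` rectangle, filled row-major in raster order of the mask
coordinates.  Values beyond the rectangle's capacity are dropped from the
tail and the count recorded, so that `placed + dropped = n_pixels` holds
exactly per frame (a tested invariant).  Raster order with tail-drop is a
declared convention, chosen for determinism and auditability — the
ordering inside the rectangle carries no spatial meaning.  Unfilled cells
hold NaN, which the 16-bit TIFF renderer maps to 0 while data occupy
1..65535 over the recorded LUT range.

Per-frame summaries report the five-number statistics with **Hazen
quantiles** (linear interpolation between order statistics at positions
p·n + ½, the convention MATLAB's boxplot uses; the quartiles of
{0.2, 0.4, 0.6, 0.8} are 0.3 and 0.7) plus two mean variants: the mean of
per-pixel ratios, and the manual protocol's ratio of channel means.  The
two agree exactly when the reference is uniform over the mask, a tested
identity.  No background subtraction is applied by default; a constant
offset can be handled upstream if an acquisition requires it.  When
several segments are pooled, their mask pixels are concatenated per
timepoint before summarizing.

Flank asymmetry (gravitropism) computes the ratio-of-means inside
wall-mask ∩ ROI for an upper and a lower flank polygon per z-section and
reports paired differences (lower − upper); sections where the mask
misses either ROI are skipped and counted.  SUM projection is a plain
per-pixel, per-channel sum over slices.

## Drift stabilization

Translation-only registration on the reference channel: the per-frame
shift is the integer-pixel cross-correlation maximum
(`skimage.registration.phase_cross_correlation`, no normalization),
estimated frame-to-frame and accumulated (or directly against frame 0).
Integer shifts mean retained pixels are exact copies — no interpolation
enters the ratio statistics.  Vacated margins are flagged invalid and
excluded from downstream wall masks.  A 1/20-px sub-pixel refinement
exists behind a flag but is off by default, precisely because fractional
shifts would interpolate intensities.  The estimator is exact for integer
circular shifts of any non-degenerate frame (tested against injected
random-walk drift).

## Elongation measurement

Segment silhouettes come from thresholding (Otsu's criterion by default,
since the original interactive protocol states no rule) and keeping one
connected component — seeded by a click-like selection point, else the
largest.  Length is the **Feret diameter** (maximum caliper) with pixels
modelled as unit squares: the diameter is the maximum pairwise distance
between convex-hull vertices of the corner points of boundary pixels.
This makes a single pixel measure exactly √2 and an axis-aligned 3×4
rectangle exactly 5, and matches a brute-force all-pairs oracle on every
tested mask.  Growth traces normalize to the first frame (= 100 exactly),
making them independent of scanner calibration; `px_per_mm` is optional
metadata for absolute lengths.

## Onset (lag-phase) detection

The onset of growth, acidification or reporter rise is operationalized as
the breakpoint of a continuous two-segment piecewise-linear least-squares
fit, `y(t) = b0 + b1·t + b2·(t − t*)₊`, with `t*` searched exhaustively
over the trace's own sample times (each arm must keep at least
`min_points_per_arm` points).  The direction constraint keeps only
candidates with `b2 > 0` (increase) or `b2 < 0` (decrease); SSE ties break
toward the earliest breakpoint (the conservative lag).  The pre-onset
slope is left free rather than pinned at zero.  No sub-sample
interpolation is attempted: the 5–10 min sampling of these assays
dominates precision.  A trace that never satisfies the constraint returns
a no-onset diagnostic, not an exception.  An optional residual bootstrap
(seeded, 200 replicates by default) attaches a breakpoint spread.

**Domain of validity.**  The two-segment model assumes the response is
roughly linear after onset within the analyzed window.  Growth traces
satisfy this (post-lag elongation is linear over the assay), and recovery
there is unbiased to the sampling grid.  Saturating responses — the
exponential pH approach and luminescence rise — violate it when the
window extends far past the time constant: the fit then absorbs the
curvature into the global slope and drifts early, or, for a near-step
response observed long into its plateau, finds no direction-consistent
breakpoint at all.  At the default conditions (τ = 30 min for pH, 60 min
for luminescence, 1-h window) the estimator lands within one to two
sampling steps of the truth but carries a systematic early bias of ~3–5
min on the pH path; the closed-loop tests bound this at 1.5× the sampling
interval.  Traces with a pronounced three-phase shape should be cropped
to the lag and initial response before fitting; multi-segment fitting is
out of scope.

## Tip angle

The organ mask is skeletonized; the free (apical) end is the skeleton
endpoint farthest from a given base point, or, absent one, the topmost
endpoint (gravistimulated organs bend upward), with ties broken so a
perfectly horizontal axis reads 0°.  The angle is the principal axis
(SVD) of the skeleton points within a tip window — 20 % of skeleton arc
length by default — oriented from base to tip and mapped to 0° =
horizontal, +90° = vertical-up (image y runs downward).  On digital lines
shorter than ~20 px the staircase pattern can bias the axis by several
degrees; recovery within 2° holds for skeletons of realistic length
(≥ ~100 px, tested over ±80°).  Closed-curve skeletons (no endpoint) are
rejected.

## Synthetic data: what it does and does not emulate

The generators produce the study conditions the pipelines are verified
under, with ground truth returned alongside and never read by analysis
code:

* **pH series** — a rectangular lattice of bright wall lines (spacing
  16 px, irregular per-line jitter: real cell files are not periodic, and
  a periodic lattice would make translation registration ambiguous up to
  its period).  The reference channel is pH-independent; the sense
  channel is scaled by the single-site protonation sigmoid
  `B(pH) = 1/(1 + 10^(pKa − pH))` (pKa 6.0, typical of GFP-derived
  sensors).  pH is uniform per frame: `ph_initial` (6.4) until onset,
  then an exponential approach to `ph_final` (5.4) with τ = 30 min over a
  13-frame, 5-min series.  Noise is additive Gaussian (σ = 10 vs wall
  intensity 200), clipped at zero.
* **Elongation series** — a capsule-shaped silhouette (semicircular caps,
  so the maximum caliper equals tip-to-tip length regardless of width);
  length constant through the lag, then linear growth (default 30 %/h
  from 200 px, onset 20 min, 25 frames at 5 min); per-frame length jitter
  1 px and pose wobble 1°, emulating scanner repositioning.
* **Luminescence** — baseline then a saturating exponential rise
  (τ = 60 min), continuous at onset.
* **Bending** — a rod pivoting about its base at a constant angular rate,
  saturating at the final angle.

Not emulated: photon statistics, optical sectioning and z-blur, wall
topology and cell geometry, tissue bending during elongation,
multi-seedling scenes, illumination gradients.  Passing the closed-loop
tests therefore demonstrates correctness of the measurement chain under
controlled geometry and noise — not robustness to every artifact of real
microscopy, where threshold choice and segmentation quality remain the
user's responsibility.

The transit-time helper is closed-form bookkeeping: with bilateral entry
into a decapitated segment, the farthest tissue is the midpoint, reached
after (L/2)/v; unilateral entry traverses the full length.

## Recovery studies (acceptance script)

`scripts/acceptance.py` runs two 12-replicate recovery studies at 5-min
sampling — growth onsets drawn from N(19.75, 2.9²) min and acidification
onsets from N(20.11, 5²) min, each replicate processed by its full
pipeline — and reports the mean estimated onset, plus the bilateral
transit time for a 1.2 mm segment at 8 mm/h.  Twelve replicates mirror
the assay design these conditions represent; image sizes (128² two-channel
pH frames, 384² scanner frames) keep a full run to a few seconds without
changing the estimators' behavior.  All randomness derives from the
`--seed` argument.
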