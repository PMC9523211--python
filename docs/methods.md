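# Methods

## Problem and model

Endometrial peristalsis presents in cine TVUS as a slow transverse
deformation travelling along the endometrial long axis, superimposed on
speckle noise and occasional rigid probe motion. `epflow` quantifies it by
tracking a sparse grid of feature points and reducing their motion to a
one-dimensional, per-row curvature signal:

- A **row** is the set of grid points sharing an initial transverse
  coordinate, ordered along the long axis (for a horizontal endometrium a
  grid row proper; for a vertical one a grid column). Rows start straight;
  a passing wave bends them, and a rigid translation of the whole field
  does not — this is what separates peristalsis from probe slip.
- The row feature is **τ**, the signed second derivative (twice the
  quadratic coefficient) of a least-squares degree-2 fit of transverse
  position against axial position. τ is a proportional stand-in for
  geometric curvature; only relative magnitude and sign matter downstream.
- The motion signal is the **lagged variation** Δτ(f) = τ(f) − τ(f − L)
  with L = 5 frames (frames earlier than L use frame 0 as reference, and
  Δτ(0) = 0). Differencing removes static anatomical curvature; static
  scenes score zero.

Salience is clip-relative: y₀ min–max normalises |Δτ| over all valid
entries of the clip, y₁ = y₀ − α with a strict mask y₀ > α, and
y₂ = logistic(β·y₁) drives the overlay rendering. Rows are counted into
the per-frame motion graph (n₊, n₋) by travel direction, and maximal
active runs of the graph become wave events.

## Direction: why an advection sign, and not sign(Δτ)

The sign of Δτ tells whether the row's bend is growing or relaxing. For a
symmetric deformation bump crossing a symmetrically weighted quadratic
fit, that time course is identical for both travel directions — every
scalar row functional rises and falls the same way whether the wave runs
left or right — so the subtraction sign cannot separate cervix-ward from
fundus-ward motion. The sign/magnitude split of Δτ is therefore kept (it
is what the salience magnitude needs), but the direction channel consumed
by the motion graph is the **lagged axial advection sign** of the row's
transverse-deformation profile d(axial):

    S = Σᵢ −(d(f) − d(f−L))ᵢ · (∂d/∂axial)ᵢ

the one-dimensional Lucas–Kanade correlation, positive when the pattern
translates toward increasing axial coordinate. S is mapped onto the image
convention (forward = image-left for horizontal, image-down for vertical)
and thresholded to {+1, −1, 0}. Time-reversing a clip flips S exactly;
mirroring the frames while swapping the declared cervix side leaves the
reported directions unchanged. Both properties are exercised in the tests.

A forward-travelling event with the cervix declared on the forward image
side is labelled **CF**; an event where both n₊ and n₋ rise above the
noise floor within one span (alternating or simultaneous peaks) is one
**CF+FC** event, not two — deliberately reproducing the automated
counting convention in which a mixed episode is a single wave.

## Event segmentation

A frame is wave-active when max(n₊, n₋) ≥ `min_count` (default 3 rows).
Because Δτ is a lagged difference, a single wave's salience necessarily
dips through zero mid-transit (the bend stops growing and starts
relaxing), splitting one transit into two active lobes 2–3 s apart at the
phantom's time scale. Active runs separated by gaps shorter than
`merge_gap_s` are therefore merged **first** (default 3 s, sized to bridge
that dip while staying below the spacing of distinct waves), and runs
shorter than `min_duration_s` (default 2 s) are discarded afterwards.

Relative normalisation has a failure mode on clips with no real motion:
min–max would stretch the noise floor to [0, 1]. An absolute guard
`min_magnitude` (default 2×10⁻⁴ /px ≈ a quarter-pixel bow over a 100 px
row, below tracking resolution) zeroes the salience of clips whose largest
|Δτ| never exceeds it. Measured on the phantom, wave clips reach
≥ 1.4×10⁻³ while static and rigidly drifting controls stay ≤ 2×10⁻⁵, so
the guard sits an order of magnitude from both.

## Measurements per event

- **Intensity**: range = (max simultaneously salient rows / total rows) ×
  `range_scale`; amplitude = (peak of (n₊+n₋) / total rows) × `amp_scale`.
  Both scales default to 2, putting a wave that involves half the rows at
  the class boundary 1: weak (both < 1), strong (both > 1), else moderate.
  The boundary units are a free convention — the intensity axes carry no
  canonical units — so both scales are exposed as parameters.
- **Velocity**: per frame in the span, the axial centroid of
  |transverse displacement| over the salient rows' valid points; the
  least-squares slope of centroid against time (path length over time,
  robust to per-frame jitter) times the pixel spacing gives mm/s.
- **Shape ratio**: amplitude / range, the peak-over-wavelength velocity
  surrogate, reported alongside the metric velocity.

## Tracking

Dense iterative-warping Lucas–Kanade flow (scikit-image, window 21 px,
3 warp iterations) is computed per adjacent frame pair inside a fixed band
around the grid and sampled at the current subpixel point positions.
Points seeded where the structure tensor's smaller eigenvalue is below
10⁻³ (texture-free patches, on intensities scaled to [0, 1]) are
untrackable, and any point leaving the frame is lost; lost points stay
invalid forever rather than being re-seeded, keeping row fits consistent.
Smoothing is a masked boxcar — temporal then spatial — whose window
shrinks at borders instead of padding, so no motion is fabricated at
sequence or grid edges; positions are rebuilt from smoothed displacements
to preserve the cumulative-sum invariant.

## Synthetic phantom

The generator emulates what a steady probe records: a static speckle
texture (low-pass-filtered seeded Gaussian noise, grain ≈ 2.5 px, rescaled
to [30, 220]) warped by travelling transverse-displacement packets
(raised-cosine bumps; default amplitude 4–5.5 px, axial footprint 80 px,
speed 20 px/s) confined to a horizontal band of flat displacement with a
cosine taper, plus additive Gaussian intensity noise (σ = 2) from a seeded
generator — fixed seed, bit-identical clip. "Both"-direction episodes are
a forward packet followed 4 s later by a backward one, the sequential form
a mixed CF+FC episode takes. A `rigid_drift_px` option translates the
whole frame sinusoidally instead, as a probe-slip control.

Deliberate simplifications, and what they imply about the tests: the
phantom's time axis is compressed (default clips are 60 s at 4 fps with
waves near 2 mm/s, versus tens-of-seconds transits near 0.15 mm/s
clinically) to keep the validation sweeps at desk scale; speckle is static
and additive rather than decorrelating; there is no out-of-plane motion,
shadowing, or anatomical curvature. Passing the recovery suite therefore
shows the pipeline recovers count, direction and speed under realistic
texture and noise — not that it is robust to every clinical artefact.
Amplitudes within a clip are drawn from a narrow range (4–5.5 px) because
detection is clip-relative: with α = 0.6, a wave weaker than 0.6× the
clip's strongest is invisible by construction. That is a property of the
method itself (worth knowing clinically), not of the phantom.

## Agreement statistics

`percent_agreement` is the exact match fraction. `icc_agreement` uses
pingouin's two-way ANOVA decomposition and reports ICC(A,1) — two-way
random effects, absolute agreement, single measure, the standard choice
for method comparison — with the model exposed (`ICC1`…`ICC3k`) since
other conventions exist; interpretation bands are poor ≤ 0.20, fair
≤ 0.40, moderate ≤ 0.60, good ≤ 0.80, excellent above. Identical-rater
tables short-circuit to 1.0 (the ANOVA ratio is 0/0 there).
`compare_counts` reports mean ± SD, Shapiro–Wilk on paired differences,
and the Wilcoxon signed-rank test (zeros dropped, average ranks on ties),
flagging the all-zero-difference case as degenerate. Reported fractions
round half-up to 2 decimals; a truncation mode is kept in the tests
because reported agreement tables mix both conventions (e.g. 88/134 = 0.6567
appearing as 0.65).

## Numerical conventions and degenerate inputs

- Coordinates are 0-based, x right / y down; ROIs are half-open
  [x0, x0+w) × [y0, y0+h); the grid needs w, h ≥ 2·spacing.
- Rows with fewer than 3 valid points (or < 3 distinct axial stations)
  have no defined τ — flagged invalid, never an exception; invalid entries
  get y₀ = 0.
- All-equal magnitudes normalise to y₀ ≡ 0; the threshold comparison is
  strict (y₀ = α is not salient).
- Axial positions are centred before the quadratic fit for conditioning.
- The analysis contains no randomness: reports are bit-reproducible for
  fixed inputs and parameters.

## Parameter summary

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| grid_spacing | 15 | px | feature-point interval |
| lag | 5 | frames | curvature-variation lag |
| alpha | 0.6 | — | salience threshold on y₀ |
| beta | 10 | — | logistic slope for rendering |
| min_magnitude | 2e-4 | 1/px | absolute |Δτ| noise floor |
| temporal_window | 5 | frames | boxcar over time |
| spatial_window | 3 | cells | boxcar over the grid |
| flow_window | 21 | px | Lucas–Kanade window |
| min_count | 3 | rows | activity threshold of the motion graph |
| min_duration_s | 2 | s | minimum event length |
| merge_gap_s | 3 | s | gap bridged within one event |
| range_scale / amp_scale | 2 | — | intensity-axis scaling |

## Known limitations

- Clip-relative salience hides waves much weaker than the clip's
  strongest; `min_magnitude` only guards the no-motion case.
- Waves closer together than `merge_gap_s` merge into one event;
  CF+FC episodes are one event by design.
- The ROI is user-drawn and assumed to stay on the endometrium for the
  whole clip (no probe-motion compensation, per the acquisition protocol's
  steady-probe assumption).
- Direction classification needs the cervix side declared per clip; the
  video alone cannot supply the anatomy.
- MP4 input requires an imageio video backend; the native path is
  uncompressed AVI.
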