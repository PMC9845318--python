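# Methods

## Coordinate and label conventions

Frames are grids of region codes {0 background, 1 left fold, 2 right fold,
3 glottis} in a continuous coordinate system with the origin at the lower
left: pixel (col i, row-from-bottom j) spans the unit square
[i, i+1) × [j, j+1), and a continuous point belongs to the pixel cell whose
square contains it (floor of its coordinates). Internally label arrays are
stored bottom-row-first; the PNG reader/writer flips vertically, since
raster formats store the top row first. Any frame size ≥ 8 × 8 is accepted;
256 × 256 is the simulator default, matching the commercial HSV systems
these masks come from.

"Rear" (posterior) defaults to the top of the image — with a 90° rigid
transoral endoscope the posterior commissure appears at the top — and can
be flipped with `rear="bottom"` (CLI `--rear`).

## The measurement procedure

**Areas.** Region areas are exact label counts per frame; the relative
glottal area is glottis / (glottis + left + right), a dimensionless
fraction that factors out zoom.

**Reference frame.** The frame with the maximal glottal area. Ties break
to the lowest index for determinism.

**Contact points.** For every 8-adjacent pair of (left-fold, right-fold)
pixels, the midpoint of the two cell centers, deduplicated. These trace
the contact line between the folds. When fewer than 3 such pairs exist
(the folds separated along their whole visible length, e.g. a wide-open
frame), the per-row centroids of the glottis region are used instead and
the fit is flagged (`source="glottis_midpoints"`).

**Midline.** Least squares with x regressed on y:
b = Σ(x−x̄)(y−ȳ) / Σ(y−ȳ)², line x = x̄ + b·(y−ȳ). Minimizing *horizontal*
residuals keeps the fit stable for the near-vertical orientation a glottal
axis usually has; b = 0 yields an exactly vertical line, which a y-on-x
regression cannot represent. If all points share one row (Σ(y−ȳ)² = 0) the
horizontal line through ȳ is returned with `fit_mode="fallback_horizontal"`.

**Collision points.** The midline is traced through the grid by exact
cell-boundary traversal: the parameter values where the line crosses any
integer x or y line are computed in closed form, and each inter-crossing
interval is classified by the label of the cell containing its midpoint.
The fold collisions are the entry into and exit from the fold∪glottis
union (marching rear → front), the glottis collisions the entry/exit of
the glottis region; first-entry/last-exit spanning means re-entrant
(hourglass-shaped) glottides span their full extent. Exact traversal was
chosen over fixed-step sampling because any finite step can skip a
corner-clipped cell (a chord shorter than the step), and because it makes
integer translations of the mask exactly neutral. A fully closed glottis
simply has no glottis collisions; a midline that never meets fold or
glottis raises an error.

**Anchor ratio.** At the reference frame, for each requested fraction f,
the point P = glottis_upper + f·(glottis_lower − glottis_upper) is
re-expressed as stored_ratio = |P − fold_lower| / |fold_upper − fold_lower|
and frozen per subject. The ratio is defined on the *fold* collision
segment, not the glottis segment: the glottis segment vanishes on closure,
while the fold segment persists, so the frozen ratio can relocate the
anchor in every frame. Because it is a ratio of collinear distances it is
invariant to translation, rotation and zoom of the larynx.

**Gap distance.** Per frame the midline is re-fitted, collisions re-found,
the anchor relocated from the stored ratio, and the perpendicular through
the anchor traced across the frame (same exact traversal). The distance is
the Euclidean length from first entry into to last exit from the glottis,
in pixels; 0 when the perpendicular meets no glottis cell. Frames where no
midline can be fitted are kept in the output with a missing distance and
`flagged=True` — never dropped silently.

## Group statistics

Distances from the ~100 frames of one recording are strongly dependent, so
groups are compared with a linear mixed-effects model estimated by REML:
distance ~ group, with a random intercept per subject. Least-squares group
means and the gap−normal difference come from the fixed effects; the 95%
interval and two-sided p use a t reference with N−2 denominator degrees of
freedom, N the total number of subjects (the containment choice for a
between-subject contrast in a two-level design). On a balanced design this
reproduces, exactly, the two-sample analysis of subject means — that closed
form is implemented independently in the test suite as the oracle.

Estimation is delegated to `statsmodels.MixedLM`. When REML drives the
between-subject variance to its zero boundary the Hessian can degenerate
(non-finite or negative-variance fixed-effect covariances); the fit then
falls back to the subject-means analysis, which coincides with the GLS
solution on balanced data for every value of the variance ratio. Flagged
observations are excluded listwise and logged. A table with zero variance
everywhere is reported as `degenerate` (diff 0, p 1) rather than crashed.

Waveform summaries collapse the per-frame relative glottal area (repeated
across fraction rows) to per-subject maxima/minima and their cohort means
and extremes.

One caution the null simulations exposed: consecutive HSV frames sample a
nearly deterministic oscillation, not independent noise, so the
within-subject variance overstates the sampling variance of a subject mean.
When true between-subject heterogeneity is small, REML pins the
between-subject variance at zero and the test becomes conservative
(rejection below nominal). With realistic between-subject spread the
calibration is close to nominal (measured 3.5% at α = 0.05 over 200 null
cohorts).

## The synthetic phonation simulator

The simulator renders what the method consumes — label masks with the
geometric and temporal structure of segmented phonation — and provides
ground truth. It is not a biomechanical model.

* The glottal axis (half-length L, default 60 px in a 256 × 256 frame)
  splits into a **membranous zone** (anterior 80%) and a **posterior zone**
  (rear 20%), mirroring the membranous vs cartilaginous glottis.
* The membranous opening is an elliptic lens whose half-width follows a
  half-rectified sinusoid A·max(0, sin(2π·f0·t/fps + φ)), A = 12 px by
  default: the simplest periodic waveform with a distinct closed phase.
  Defaults f0 = 200 Hz and fps = 4000 give 20 frames per cycle, so the
  default 100-frame recording holds exactly five cycles.
* The posterior zone opens as a brief, small **vestige** around peak
  opening (half-width 1.2 px when the cycle waveform exceeds 0.95),
  emulating the slight parting of the arytenoids at maximal opening. The
  vestige matters structurally: it guarantees that at the reference frame
  the glottis spans the full axis in *both* groups, so the 10% anchor
  lands in the posterior zone for normal subjects too. Its scale is the
  smallest that reliably rasterizes at the reference frame.
* Gap subjects additionally carry a **persistent posterior slot** of
  constant half-width through the whole cycle. The 10% line always crosses
  it; the 50% line never does — the designed contrast between a localized
  posterior measurement and a mid-membranous control line.
* Rigid rotation, translation and zoom of the whole larynx, plus smooth
  per-frame boundary jitter (Gaussian edge noise interpolated over 4-px
  knots), exercise the invariance properties.

`generate_cohort` draws per-subject parameters reproducibly from one seed:
rear-gap half-width max(0, N(gap_px/2, sd)) for the gap group with
sd = 0.75 px by default — chosen so the between-subject spread of gap
widths (~1.5 px) matches the between-subject standard errors clinical
cohorts of this size report; rotation U(−15°, 15°); translation ±8 px;
f0 U(190, 225) Hz (female speaking range); random phase; and lognormal
anatomical scaling of the opening amplitude (CV 0.25 — speakers differ
substantially in maximal opening) and vestige size (CV 0.15).

### What the simulator does and does not emulate

It reproduces the features the algorithm's correctness depends on: label
topology, oscillation with closed phases, a persistent posterior gap,
rigid motion, zoom, and boundary noise. It does not emulate CNN-specific
segmentation artifacts (label speckle, temporal flicker, systematically
biased boundaries), mucosal-wave asymmetries, hourglass or spindle closure
patterns, or intensity images at all. Passing tests therefore demonstrate
the geometry and statistics are correct on well-formed masks; they do not
certify behavior under pathological segmentations.

## Numerical choices and degenerate inputs

* Collision endpoints are exact to floating point; the independent test
  oracle marches at 0.01 px and must agree within 0.25 px.
* Gap distances inherit only rasterization error: an analytic ellipse
  chord is recovered within 1 px at generic sub-pixel placement. A mask
  aligned so that both edge cells sit exactly on the inclusion threshold
  can reach ~2 px error — a property of center-sampling rasterization, not
  of the traversal.
* Points exactly on a cell boundary belong to the cell to their upper
  right (floor convention), deterministically.
* Gamma correction v → round(255·(v/255)^γ) is monotone for any γ > 0.
  Composing two corrections matches the product exponent only up to
  quantization; the intermediate rounding is amplified by the second
  exponent (±1 level at γ = 2∘2, worse for γ₂ < 1), so repeated correction
  of stored 8-bit images should be avoided in favor of a single pass.
* Degenerate statistical inputs (constant tables, < 2 subjects per group,
  all-flagged fractions) are reported or raised explicitly, as described
  above.

## Problem sizes in tests and the acceptance script

Monte Carlo checks run on geometrically scaled-down masks (96 × 96 px,
axis half-length 22 px) so the suites stay within a desktop budget: the
oracle suite uses 100 random frames; the null calibration uses 200 cohorts
of 8 + 8 subjects × 40 frames (two full cycles, so cycle-truncation
effects average out). The cohort-recovery check runs at full scale:
20 + 30 subjects × 100 frames of 256 × 256 px, the acquisition regime the
defaults encode.

## Known limitations

* Distances are chords of the *rasterized* glottis: sub-pixel boundary
  estimation from intensities is out of scope, so single-pixel quantization
  (±0.5–1 px) is irreducible at 256 × 256; area-behind-the-line measures
  would be a natural extension.
* The anchor ratio assumes the fold collision segment is anatomically
  stable across frames; severe per-frame segmentation failures at the fold
  ends would move the anchor.
* A reference frame whose glottis does not reach the posterior commissure
  silently shifts the anchor anteriorly — in simulation this appears when
  the posterior vestige fails to rasterize; on real data a clinician should
  inspect the rendered overlay of the reference frame.
* The mixed model assumes independent within-subject residuals; with
  near-deterministic periodic data this makes the test conservative, not
  anti-conservative (see above).
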