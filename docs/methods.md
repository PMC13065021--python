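# Methods

`wormgrowth` analyses single-animal fluorescence time-lapse movies of
*C. elegans* larvae growing in agarose microchambers. This note describes
the models and algorithms the package implements, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not establish about real data.

## Growth and fluorescence model

Larval growth is modelled as piecewise-exponential in time: within each of
the four larval stages the volume-specific growth rate
g = dV/dt/V = dlog V/dt is constant (`stage_growth_rates`, h⁻¹), and each
stage ends in a lethargus plateau of zero growth (`plateau_duration`,
default 1.5 h) before cuticular ecdysis. The molt time τ is defined as the
end of the plateau — the moment growth resumes. After the final molt the
animal continues at the last larval rate, so the L4→adult transition
carries the same slope-resumption signature as earlier molts.

Per-pixel fluorescence concentration follows a single-exponential
relaxation from its hatch value toward a plateau,

    C(t) = C_inf − (C_inf − C0) · exp(−k t),

the simplest monotone curve consistent with the observed recovery of
maternally depleted animals during L1. With `coupling` enabled, the L1
growth rate tracks the instantaneous concentration,
g(t) = g_L1 · C(t)/C_inf, and the log-volume gain is integrated in closed
form. Coupling deliberately affects the growth *rate* only: stage
durations are simulator inputs, so molt *timing* does not respond to the
perturbation. The developmental delay reported for real maternally
restricted progeny is therefore not emulated; the pipeline measures and
reports it, but the generator makes no claim about it.

Default parameters describe a well-fed animal at standard conditions:
30,000 µm³ at hatch, rates 0.10/0.12/0.14/0.16 h⁻¹ and durations
12/8/8/10 h for L1–L4 (≈60-fold volume gain over ~38 h), frames every
10 min, k = 0.25 h⁻¹ (a −11% concentration deficit shrinks below 1% of
the plateau by M1). Measurement noise is multiplicative lognormal on
volume (`noise_sd_logV`, default 0.02 — scale-free, as volumetry errors
are) and additive Gaussian on concentration. Cohorts draw per-animal
lognormal jitter (CV 5%) on rates, durations, hatch volume and C0; the
jitter streams are keyed by animal index and shared between groups, so
with zero offsets the groups are exchangeable by construction, and a
relative offset on the treated group shifts the group median exactly by
that offset. The inter-individual CVs are placeholders, not estimates of
real cohort variance.

## Movie rendering

Each frame draws the worm as a tube around a smooth random midline whose
heading is a sum of two low-frequency sinusoids with bounded amplitude
(re-drawn with shrinking amplitude until the body fits the frame with
margin). The radius profile is constant along the body with a cosine
taper over 10% of the length at each tip, and is scaled so that the
rotational-symmetry volume of the drawn shape, Σ π r(s)² Δs · px³, equals
the simulated volume **exactly** — the render is therefore an analytic
oracle for the volumetry code, independent of pose. Length and radius
follow V through a fixed aspect ratio (length/diameter = 10).

Interior intensity is flat: background + C inside the tube, then Gaussian
blur (σ = 1 px) and additive Gaussian camera noise. A flat profile was
chosen over chord-length ("thickness") shading for two reasons: the
blurred step edge puts the gradient ridge exactly on the true boundary
(chord shading has a singular edge whose ridge lands ~1 px outside,
which no edge-based segmentation can recover to Jaccard ≥ 0.95), and it
makes the drawn per-pixel concentration equal C exactly. Real worms are
not perfectly flat; consequences for real data are limited to a small
multiplicative factor on measured concentration, which cancels in every
between-condition ratio the pipeline reports. Pre-hatch frames show an
ellipsoidal egg (~50 × 30 µm), which is small and compact enough to fail
the minimum-area and elongation gates, as an unhatched animal should.

QC training data corrupt rendered masks in four ways: border truncation
(the body is cut flat at a frame edge, so the straightened width profile
ends at full body width), a blob merged onto the body, a mid-body bulge
(as produced by a self-overlapping coil), and fragmentation. Severity of
the truncation class is controllable, which the tests use to check that
the classifier's faulty-score responds monotonically.

## Segmentation

Sobel gradient magnitude is thresholded with Otsu's method over the
nonzero gradients (times a configurable multiplier, default 1). All
thresholds downstream (half-max refinement, background medians) are
quantile-type statistics of the image itself, so the whole chain is
exactly equivariant under uniform intensity scaling — dimming a frame by
50% reproduces the identical mask, which is the package's analogue of the
published dimming-robustness control.

Edges are thinned to the gradient ridge; endpoints (pixels with exactly
one 8-neighbour) are bridged nearest-pair-first with straight pixel
lines up to `max_gap_px` (default 10), iterating until closed. Contours
are filled, objects below 200 px² removed, the largest component kept and
holes filled. Pixels on the 1-px contour ring itself straddle the true
boundary; including them all would dilate the mask by ~½ px, so each ring
pixel is kept only where its intensity exceeds the local half-max level
(midway between the interior median and the background median). On
noiseless renders this yields Jaccard ≥ 0.99 against the true mask.

Frame QC is an ensemble of 20 bagged decision trees
(`sklearn.BaggingClassifier`) over a fixed 9-component shape-feature
vector of the straightened animal (length; mean, CV and max/min ratio of
the central width profile; solidity; total midline curvature; boundary
roughness P²/4πA; mask-vs-straightened area ratio; border-contact
fraction). The score is the fraction of trees voting faulty; a frame
fails on a majority. Frames whose straightening fails outright are given
a sentinel feature vector and fail unconditionally. Excluded frames stay
as gaps — they are never interpolated. The synthetic training labels
stand in for the manual annotation a real deployment would use;
retraining on real annotated frames is the user's responsibility.

## Straightening and volumetry

The midline is the longest geodesic path between endpoints of the mask
skeleton, with three refinements: end segments that hook toward mask
corners (the classic rectangle-skeleton Y-branch, >30° direction change
over half a body width) are trimmed; both ends are extended to the mask
boundary along the local tangent; and after spline smoothing
(s = 0.5·n) one chord-recentering pass pulls the path back onto the body
axis where the spline cut corners of strongly bent postures. Masks
without a dominant elongated axis — path shorter than twice the body
width, as for coiled worms or blobs — raise a straightening failure that
routes the frame to QC-fail, mirroring the exclusion (rather than
repair) of faulty postures.

Straightening samples intensity and mask along the normal at each 1-px
arc-length row. The body width per row is measured as the integral of
the bilinearly interpolated mask along the normal at 0.25-px steps
rather than a hard sample count: a count is ±1 px quantized, and since
volume squares the width, that alone would contribute up to ~20% error
at a 5-px radius. Volume assumes rotational symmetry:
V = Σ π (wᵢ/2)² Δs · px³.

Accuracy against the render oracle: a straight r = 5 px, L = 100 px
cylinder is recovered to 0.1%, curved poses of a 1.2×10⁵ µm³ animal at
2.5 µm/px (radius ≈ 4.7 px) to within 3% with pose-rotation CV ≈ 1%.
The dominant residual error is not the estimator but binary mask
rasterization itself: below ~4 px body radius the pixelated mask's area
fluctuates by ±2% across poses, which squares into ±4–6% volume
deviations. Accuracy statements are therefore made at radius ≥ ~4.5 px;
at 10× magnification real hatchlings are well above this.

Background is the median intensity outside the mask dilated by 10 px;
total fluorescence is the background-subtracted sum over the mask and
concentration its per-area mean, F/A. ROI quantification (for manually
drawn organ outlines with manually marked exclusions such as nuclei) is
the same statistic restricted to roi∖exclusion.

## Trajectory analytics

Volume series are median-filtered (window 3; windows shrink to odd,
centred spans at the edges so end points are preserved) and smoothed with
a 15-point robust lowess before differentiation. The rlowess smoother is
implemented in-package: tricube weights over the 15 nearest points on the
index axis, local linear fits, five bisquare reweighting iterations with
residual scale 6·MAD. When the MAD collapses to zero (exact data), only
exact-fit points keep weight — this makes the smoother reproduce exact
lines to machine precision while rejecting isolated gross outliers
entirely, a regime in which the statsmodels implementation degenerates.
NaN gaps from QC-excluded frames split every filter; no smoothing ever
bridges a gap.

The Whittaker–Eilers smoother minimizes Σ(y−z)² + λΣ(Δ²z)² with
divided-difference penalties on the hour-valued time grid (so λ = 0.75
means the same thing on uneven grids), solved exactly via banded
Cholesky; λ = 0 reproduces the data and λ→∞ the OLS line, and the banded
solution matches a dense solve to 1e−10.

**Molt detection.** Candidate molts are local maxima of the second time
derivative (central differences) of the smoothed log volume — growth
resuming after lethargus is the strongest curvature event in the series.
Candidates must lie at least 5 h apart and after hatch, and must be
preceded within 3 h by a near-flat interval (|dlog V/dt| below 50% of the
trajectory's median positive slope; after 15-point smoothing a 1.5 h
plateau never appears flatter than ~35%, so the published idea of a
plateau precondition is kept but the threshold accounts for the
smoothing). Because the curvature peak localizes an event only to within
the smoothing span, each candidate is refined by a two-break
piecewise-linear fit of lightly filtered log V — growth, an exactly flat
plateau of scanned length (0.9–2.6 h), then growth — scanning the ecdysis
break on a quarter-frame grid; candidates refining into the same
lethargus are merged (best fit wins) and clusters are ranked by the
fitted slope jump, which is near zero for smoothing artefacts and ≈ the
resumed growth rate for genuine molts. On 50 simulated animals with
σ(log V) = 0.02 at 10-min sampling, 98–99.5% of the 200 molts land within
±2 frames of truth across seed sets. Manual curation is supported as an
override mapping ("M1"…"M4" → hours), replacing the interactive
correction step of GUI-based pipelines.

Hatch is the first run of ≥3 consecutive QC-accepted frames with an
elongated mask (length/width > 3); movies starting post-hatch are flagged
left-censored, and an override always wins. Boundary volumes are OLS fits
of V on t over the 10 retained points before a molt (or after hatch),
evaluated at the event time; fewer than 10 points flag the fit, fewer
than 3 yield a missing value.

The early-development summary follows the published convention: a robust
(Tukey bisquare) regression of ln V on t inside a 3.7 h window centred
4.3 h post-hatch gives the growth rate, and the window mean of the
median-3-filtered concentration gives C; values more than 3 SD from their
group mean are excluded in a single, non-iterated pass (SD = 0 drops
nothing). Stage rescaling interpolates each completed stage onto 100
evenly spaced progression points, with a 20-point extension into the
following stage after the last completed one (grid 100–120%); the time
axis is rescaled, values are untouched unless
`scale_values_by_duration=True` multiplies each stage's values by its
duration (the alternative reading of normalizing rates to stage length).

## Cohort statistics

Single-group mean curves carry mean ± 1.96·SEM bands (bootstrap is
reserved for between-group contrasts). Differences and treated/control
ratios between groups resample animals with replacement within each group
(1,000 repeats by default) and report 2.5/97.5 percentile bands;
percentile rather than BCa intervals are the plainest reading of the
procedure. Passing the identical animal matrix as both groups
short-circuits to a zero difference with a zero-width band. On simulated
cohorts with a known constant difference the nominal 95% band covers
truth in ≥90% of repeats at B = 300 (coverage improves toward nominal
with larger B and group size).

The Wilcoxon rank-sum test uses mid-ranks; for combined n ≤ 20 the null
is evaluated exactly by enumerating all assignments of the pooled ranks
to one group (a permutation test, so ties need no special casing), with
the two-sided p defined as P(|W−EW| ≥ |w−EW|) — identical groups give
p = 1. Larger samples use the normal approximation with tie and
continuity corrections.

## End-to-end benchmark

The pipeline (simulate → segment → measure → events → cohort) is
exercised on a two-group cohort of 12 animals per group with the
maternal-effect defaults (−13% hatch volume, −11% initial concentration,
coupling on), rendered at 2.5 µm/px in 160² frames over hatch → M1 + 4 h
— sizes chosen so a full run completes in a few minutes on one core.
Hatch volume is the 10-point boundary regression at the detected hatch;
initial concentration is an OLS back-extrapolation of the measured
concentration to the hatch time over the first 1.5 h (a plain window
mean would sit mid-recovery and understate the deficit). Across seeds the
recovered median offsets fall within ±3 percentage points of the
simulated truth and the treated/control concentration ratio exceeds 0.97
by M1. One global seed drives simulation, bagging and bootstrap through
spawned seed sequences; stages are skipped on rerun when a content hash
of their configuration and inputs is unchanged.

## What the synthetic benchmark does not show

The generator's worms are smooth tubes with flat interiors on a clean
background: real movies add bacterial lawn texture, neighbouring debris,
optical vignetting, focus drift and genuinely coiled postures at higher
rates than the renderer produces. Passing the benchmark demonstrates the
correctness of the geometry, statistics and plumbing — not that the
Sobel/Otsu chain or the synthetic-trained QC classifier will match a
neural segmenter on difficult real frames. The QC classifier in
particular should be retrained on manually annotated real frames before
use in production; its synthetic labels exist to validate the training
and exclusion machinery. Inter-individual variance parameters are
placeholders, and the developmental (molt-timing) response to maternal
perturbation is deliberately outside the generator's contract.
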