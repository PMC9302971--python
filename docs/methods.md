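# Methods

This note documents the measurement definitions, the synthetic-data models
used to validate them, the numerical conventions, and the known limitations
of the `mitoquant` pipeline.

## Coordinate and calibration conventions

Pixel indices are 0-based and a pixel's *centre* sits at integer
coordinates (x = column, y = row); all ROI geometry is continuous in that
frame. Every image carries a physical pixel size in μm/px; an explicit
calibration argument overrides TIFF metadata, and the absence of both is an
error — there is never a silent 1 μm/px default. Every distance in μm is
exactly the pixel distance times the pixel size.

Circular-ROI and annulus membership use the pixel-centre rule (a pixel
belongs if its centre is inside), with no sub-pixel area weighting. This
makes the vectorised implementations exactly equal to their per-pixel
brute-force oracles, which the tests exploit.

## Polar ejection force readout

The radial profile bins pixels by centre-to-pole distance into annuli
[k·w, (k+1)·w) with w defaulting to one pixel in μm, averaging intensity
per annulus inside a 12.5 μm maximum radius. Empty annuli are dropped, not
reported as zero. The readout is the bin centre of the global profile
maximum; ties break toward the smaller radius — the conservative choice,
since it reports the lower force. No smoothing is applied before
max-finding by default (a moving-average option exists for noisy data).
The profile is invariant under affine intensity transforms, and on
noiseless ring fixtures the estimate is within one bin width of truth.

Whether the DNA image should be background-subtracted before profiling is
left to the caller; the default is no correction, with the blur-subtraction
primitive available upstream.

## Anaphase profile analysis

Line profiles are sampled between the two pole coordinates with bilinear
interpolation at (as close as endpoint inclusion allows) 1-px spacing; the
even spacing makes the reversed segment's profile exactly the reversed
profile, so all derived distances are invariant under pole relabelling.
The profile is split at the *geometric* midpoint between the poles (not an
intensity centroid), and each half's chromosome mass is located at its
global intensity maximum, ties breaking toward the midpoint. Anaphase
onset is a caller-supplied frame annotation, not auto-detected.

The decomposition identity
`left_mass_to_pole + mass_separation + right_mass_to_pole = pole_separation`
holds exactly by construction and is asserted in tests.

The Gaussian width fit minimises least squares for
A·exp(−(x−μ)²/2σ²) + c, initialised with μ at the argmax, σ from the
second moment of baseline-subtracted intensity, A at peak-minus-baseline
and c at the minimum; σ is bounded positive. The offset c is included
because half-profiles sit on a nonzero cytoplasmic baseline; fits are
flagged not-OK when σ exceeds the half-profile span or the optimiser fails.
FWHM is reported as 2√(2 ln 2)·σ.

The "duplicate, blur, subtract" background correction treats a Gaussian
blur (default σ = 30 px) of the frame as the smooth background estimate.
At that σ, punctate pole/centromere markers lose <1 % of their peak while
illumination gradients are flattened >10×. Negative differences are
clipped to zero so the result remains a valid intensity image for peak
finding. The blur scale is configurable; 30 px is the default because it
is large against diffraction-limited spots at typical (~0.1 μm/px)
sampling.

## Nuclear solidity and classification

Solidity is the mask pixel count divided by the pixel count of the convex
hull of the mask's pixel centres, rasterised with the same pixel-centre
rule. Computing the hull on centres (rather than pixel corners) makes a
convex rasterised shape score exactly 1, which anchors the scale: a
perfectly oval nucleus has solidity 1, and lobed or fragmented nuclei fall
below it. Degenerate (collinear) masks are their own hull and score 1.

Segmentation is deliberately plain — Otsu threshold, hole filling,
connected components, an area filter in μm², and exclusion of
border-touching objects (their shape is truncated; a flag re-includes
them).

The abnormality threshold is the 5th percentile of the control
population's solidity, computed with linear interpolation between order
statistics (the numpy/spreadsheet default). The convention is documented
because thresholds are quoted to three decimals and alternative percentile
definitions change them. A nucleus is abnormal iff its solidity is
*strictly* below the threshold; ties are normal. At least 20 control
nuclei are required for the percentile to be meaningful, and the threshold
is never transferable between datasets — every summary carries its value
and control count. By construction, classifying a control population
against its own threshold yields ~5 % abnormal calls (within one count,
ties permitting).

## FRAP normalization

normalized(t) = (bleached(t) − background(t)) / (bleached(0) − background(0)),
where frame 0 is the first frame imaged. The first sample is exactly 1,
and the statistic is invariant under common gain and offset changes of the
bleached and background channels. A pre-bleach-mean reference is available
as an option but off by default. Recovery percentages are read at the
acquired sample nearest the requested time (no interpolation), because
reported values correspond to acquired frames. No diffusion model is
fitted; the summaries are the immediately post-bleach percentage and the
recovery percentage at 220 s.

## Proliferation modelling

Counts are normalized to t = 0; only wells with first-frame counts in
[10 000, 20 000] (bounds inclusive) are analysed, controlling for density
effects. Doubling time is estimated by ordinary least squares of
log₂(normalized count) on time over 0–48 h — growth plateaus later — with
τ = 1/slope; the estimator is exactly unbiased on noiseless exponential
data, and an endpoint-ratio alternative is provided. Non-positive slopes
are flagged non-growing rather than raised. Whether a pooled fit or a mean
of per-well fits is preferred is left to the caller; the CLI reports
per-well fits.

The division-failure model: if a fraction f of cells fails to divide in
each cycle, the per-cycle multiplication factor is b = 2 − f and the
normalized count at time T is b^(T/τ). The model applies f persistently
every cycle, which is what the closed form encodes. With τ = 20.72 h this
gives 48-h predictions of 4.98 (f = 0), 3.42 (f = 0.3) and 2.18
(f = 0.6).

## Synthetic-data models

All generators are deterministic given their seed, and every ground-truth
value is an exact function of the generating parameters, independent of
rasterisation.

* **Monopolar spindle**: radial Gaussian ring
  I(r) = peak·exp(−(r − R)²/2w²) plus additive Gaussian noise, clipped at
  zero. Defaults: 0.1 μm/px (typical high-NA effective pixel size),
  ring radius 3.7 μm with width 0.8 μm (the normal-force regime), peak
  1000 a.u. The force-loss regime is emulated at radius 1.6 μm.
* **Anaphase movie**: two isotropic Gaussian chromosome masses at
  ±d(t)/2 about the spindle midpoint, pole and centromere markers as
  narrow (0.2 μm) spots, 1-min frames for 10 min, 0.1 μm/px, pole
  separation 20 μm. Two stock trajectories: monotone
  d(t) = min(rate·t, plateau) for normal segregation, and a rise–dip–rise
  for recongression. Real chromosome masses are irregular, but the
  measured quantity — peak position — is insensitive to shape detail.
  Fixture masses used for recovery tests at small separations have
  σ = 0.5 μm because a sum of two Gaussians is unimodal when their
  separation is below 2σ: the split-at-midpoint peak method presupposes
  optically resolvable masses at the smallest separation measured (2 μm in
  the recongression regime), and the fixture must respect that same
  applicability condition. The wide-mass default (σ = 1.5 μm) is retained
  for broadness (FWHM) work at large separations.
* **Lobed nucleus**: boundary r(θ) = R_ellipse(θ)·(1 − depth·max(0,
  cos(n·θ + φ))) on a 7 × 5 μm semi-axis ellipse. The cosine-modulated
  radius was chosen because its continuous solidity has a cheap
  high-accuracy oracle: shoelace area over convex-hull area of dense
  boundary samples. Rasterised solidity converges to this truth as pixel
  size shrinks; at the 0.1 μm/px default the error is below 0.02.
* **FRAP trace**: single-exponential mobile/immobile model — post-bleach
  signal B + P·[d + m(1 − d)(1 − e^(−t/τ))] — sampled at 5-s intervals
  over the 25 s before the bleach and 20-s intervals for 10 min after,
  with the first post-bleach frame at t = 0 so the immediate post-bleach
  fraction equals d exactly. This is the minimal model able to reproduce
  a fully recovering (interphase-like), a largely immobile
  (metaphase-like ~18 % → ~25 %), and an intermediate (anaphase-like
  ~17 %) regime.
* **Growth curve**: N(t) = N₀·b^(t/τ)·(1 + ε) with multiplicative
  mean-zero Gaussian ε (CV default 0, typically 5 % in noisy fixtures),
  sampled every 4 h for 96 h from 15 000 cells. Noise is multiplicative
  because count errors scale with the count.

Noise models are additive Gaussian for images and traces and
multiplicative for counts; none of the generators model photophysics
(acquisition bleaching, shot noise), 3-D point-spread functions, or cell
crowding/plateau effects. Passing recovery tests therefore demonstrate the
correctness of the measurement chain on data satisfying each assay's
stated assumptions — resolvable masses, exponential growth over the fit
window, mono-exponential recovery — not robustness to every artefact of
real microscopy.

## Problem sizes

Validation uses sizes chosen to exercise the estimators well past their
asymptotic behaviour while staying desk-scale: 280²-px monopolar images
(50 fixtures per noise level), 11-frame anaphase movies at 260 × 80 px,
populations of 400–1000 synthetic nuclei, 100-replicate FRAP and growth
noise studies, and 8 noisy wells for the doubling-time summary.

## Known limitations

* Pole, centromere and bleach-ROI coordinates are inputs; there is no
  automatic pole tracking, onset detection, or monopolar/bipolar
  classification.
* The half-spindle maximum is a raw argmax; heavily overlapping masses
  (separation below twice the mass width) are reported as near-zero
  separation, which is the method's intrinsic resolution limit rather
  than an implementation artefact.
* Percentile thresholds assume the control sample is representative;
  with heavy ties the abnormal fraction can deviate from the nominal
  percentile.
* The growth model ignores confluence; fits outside the 0–48 h window
  are the caller's responsibility.
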