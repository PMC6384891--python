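# Methods

This note records the models, numerical choices, and design decisions behind
`mshts`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## The readout: per-pixel SD of a centered ROI

The aggregation readout is the population standard deviation (divisor *N*)
of pixel brightness in a centered square region of 432 × 432 pixels
(800 × 800 µm at 4× magnification, 1.852 µm/pixel). Aggregates imaged with a
co-assembling QD nanoprobe appear as bright filamentous texture on a
uniform probe background, so brightness variance tracks aggregate amount —
provided the aggregates stay within the depth of focus and the frame is
neither saturated nor underexposed.

The per-well pipeline is: **normalize → crop → QC → SD**.

1. *Normalization.* Every frame is rescaled so its mean intensity equals
   50% of the camera full scale (rounded, clipped), emulating the
   acquisition macro of the original instrument. This makes the SD
   insensitive to exposure-time and camera-gain differences; the validation
   suite checks < 1% SD drift under clip-free pre-scaling by 0.5–2×. The
   fraction of pixels clipped at full scale during normalization is recorded
   and fails QC above 0.5%.
2. *ROI.* A centered square crop; odd margins drop the extra pixel from the
   high-index side (floor offsets). On simulated frames, ROI sides of 216,
   324, and 432 px give SDs within 10% of each other (texture is spatially
   homogeneous), so the ROI size is not a sensitive parameter.
3. *QC.* Exposure metrics — mean fraction, saturated fraction, dark
   fraction — are measured on the **raw** frame, because normalization by
   construction hides over/under-exposure (it rescales the saturated value
   away from full scale). Histogram normality is enforced on the
   **normalized ROI** actually analysed, as moment bounds: |skewness| ≤ 1
   and |excess kurtosis| ≤ 2. Moment bounds were chosen over a formal
   normality test because at ~186k pixels any test statistic rejects
   trivially small deviations, while moment bounds are transparent,
   threshold-configurable, and sample-size stable. Verdict precedence:
   `fail_bright` (saturation > 1% or mean > 85%), then `fail_dark`
   (mean < 5%), then `fail_nonnormal`.
4. *SD.* Computed on the normalized, cropped raster, as float64. Population
   (divisor *N*) rather than sample SD: at 186,624 pixels the difference is
   negligible but the convention is fixed. QC failures never null the SD —
   the value is reported with the verdict attached, and dose-response
   fitting excludes flagged wells by default.

Color-CCD frames are reduced to a single channel by channel averaging
(configurable to a single channel) before analysis.

## Plate and mixing model

Concentration arithmetic is exact bookkeeping: a serial dilution places
`stock / factor^i` at step *i*, and 1:1 mixing with the amyloid/probe
working solution halves it (c · v_s / (v_s + v_r) in general). Defaults
follow the assay protocol: 2.5 µl + 2.5 µl of 50 µM amyloid-β / 50 nM QD
probe, giving 25 µM and 25 nM in-well; the dilution factor defaults to 5
with 8 steps (consistent with the 600 → 300/60/12 µM reference-inhibitor
points after mixing) and is configurable, since published screens vary it.
Layouts are built deterministically in row-major order, controls first;
every plate carrying test series must carry at least one no-inhibitor
control. The pipetting count is carried as metadata only: vigorous mixing
(≥ 10 pipettings) promotes aggregation by agitation and can mask inhibition,
which is a liquid-handling concern outside the scope of image analytics.

## The forward simulator

The simulator's purpose is to generate micrographs with *known* ground
truth so the entire analysis chain is testable. A single scalar "load"
∈ [0, ~1.2] represents aggregate amount (1 = uncontested aggregation at the
assay's operating concentration).

- **Geometry.** `round(load × filament_scale)` filaments are drawn as
  persistent random-walk polylines (step 4 px, 60 steps, angular diffusion
  0.35 rad) on a uniform background at 30% of full scale. Walks reflect at
  the image borders (clipping them instead piles mass on the edge rows and
  badly distorts large-kernel convolutions). PSF and defocus convolutions
  use wrap boundary mode, which conserves total intensity.
- **Brightness calibration.** Per-filament amplitude grows with total load
  as √((load + 0.7)/1.7). Physically, aggregates thicken as well as
  multiply; numerically, this law is calibrated so the *pipeline SD* is
  approximately affine in load on [0, 1] (within ~4% of span). Without it,
  variance scales with filament count alone, SD grows like √load, and the
  apparent EC50 of a simulated inhibitor is biased ~2–3× high — the affine
  readout is precisely the assay's premise ("SD tracks aggregate amount"),
  so the generator is built to satisfy it.
- **Depth of focus.** The assay operates at the amyloid concentration where
  SD peaks, so the default threshold is load = 1.0: the no-inhibitor control
  sits at the contrast peak. For loads above the threshold, only a
  `threshold/load` fraction of each filament's mass stays in sharp focus;
  the excess is convolved with a large defocus kernel
  (σ = psf + 30 × (load − threshold) px) and becomes near-uniform haze.
  Light is conserved but contrast collapses, reproducing the rise-then-fall
  of SD versus amyloid concentration. Setting the threshold below 1 (as the
  validation profile does, at 0.8) demonstrates the fall within the
  simulated load range.
- **Noise.** Zero-mean Gaussian read noise at 1.5% of full scale by
  default; a Poisson option exists for shot-noise-limited regimes, and
  camera gain is modelled as multiplicative scaling plus gain-proportional
  noise. QD blinking is not modelled: at 4× magnification the fluorescence
  of very many probes is averaged per pixel and blinking is invisible.
- **Normality by construction.** Filament density and amplitude defaults
  (220 filaments at load 1, amplitude 0.16, PSF σ 2.0 px) were chosen so
  that optimum-condition frames have near-normal brightness histograms at
  every load — the regime the real instrument is tuned to. Sparser/brighter
  textures produce skewness > 1 and would flag healthy wells.
- **Determinism.** Every well's seed is mixed from (master seed, row,
  column, timepoint) via `numpy.random.SeedSequence`, so a single well can
  be re-rendered in isolation and full plates are bit-reproducible.
- **Kinetics.** Aggregate load over time is zero through a lag phase, then
  rises as a saturating exponential toward a plateau
  (plateau · (1 − e^(−rate·(t − lag)))). This shape is continuous, monotone,
  flat through the lag, and has positive slope immediately after it — the
  features that distinguish tau-like (lag ≈ 0) from amyloid-β-like
  (lag ≈ hours) traces. A symmetric logistic was rejected because it cannot
  be exactly zero throughout the lag phase.

**What the simulator does not capture.** Real micrographs have optical
vignetting, focus drift, well-edge artefacts, chlorophyll-type inner-filter
absorption in crude extracts, and aggregate morphologies beyond thin
filaments; none are modelled. Passing validation therefore demonstrates the
*analysis chain* is correct and well-calibrated on images with the assumed
statistics, not that the assay itself would achieve the same accuracy on
any given sample class.

## Dose-response estimation

SD series are first converted to percent inhibition against the plate's own
controls: PI = 100 (SD⁺ − SD)/(SD⁺ − SD⁻), with SD⁺ the mean no-inhibitor
24 h control and SD⁻ the mean 0 h background of the same wells. Values are
deliberately not clipped to [0, 100]; noise outside the range is
informative to the fit. Fitting on PI rather than raw SD makes plates with
different absolute intensity scales comparable, and the whole fit is
invariant to uniform rescaling of all SDs.

The default estimator is a four-parameter logistic in log₁₀ concentration
with asymptotes fixed at 0 and 100 (free asymptotes optional), solved by
bounded least squares (`scipy.optimize.least_squares`, TRF), initialised at
the interpolated 50% crossing with Hill slope 1. If the optimiser fails,
the estimator falls back to monotone log-linear interpolation of the 50%
crossing, with the method recorded in the result. QC-flagged wells are
excluded before fitting (configurable); fewer than three usable points is
an error, not a silent fit.

Status semantics: `not_active` when observed inhibition never reaches 50%
within the tested range; `below_range`/`above_range` when the fitted
crossing falls outside the tested concentrations (the EC50 is then not
reported — an extrapolated EC50 from a fixed-asymptote fit is not
trustworthy); `determinable` otherwise, and only then is the EC50 defined.
The validation suite cross-checks the least-squares fit against an
independent dense grid search minimising the same residual (agreement
within 1% on noisy curves).

Activity tiers are closed on the more-active side: extracts with EC50
≤ 0.018 mg/ml are `high_red` (more active than the most active reference
spice), (0.018, 0.05] `active_yellow`, (0.05, 0.1] `listed`, otherwise
`inactive`; compounds use a single ≤ 200 µM cut. Ranking is ascending by
EC50 with non-determinable samples last and lexicographic sample-id
tie-breaks, so it is invariant to input order. Replicate summaries report
the arithmetic mean and sample SD (ddof = 1). No multiple-testing machinery
is involved: the screen reports point estimates, not hypothesis tests.

Two readings of the historical EC50 procedure exist (fit on percent
inhibition vs direct SD interpolation); both are implemented (`fourPL`,
`interpolation`) and agree within 10% on clean Hill-1 curves.

## Synthetic screening libraries

The per-sample EC50 tables of the published screens live in supplementary
material not redistributed here; only their band structure is public
(504 extracts: 139 ≤ 0.1, 55 ≤ 0.05, 20 ≤ 0.018 mg/ml, 19 of the top 20
eudicots; 98 compounds: 13 active with 7 tropolones; 36 tropolone
derivatives: 25 active). `mshts.synthetic_library` generates deterministic
**synthetic** stand-in tables with EC50s drawn log-uniformly within each
band. They exercise and validate the tiering/ranking/counting logic against
the published totals; the individual values and group assignments are
invented and carry no biological information.

## Validation experiment sizes

The experiments in `mshts.validation` (run by `scripts/acceptance.py` and
the test suite) use: 1,000 random rasters for the SD oracle; 100 image-level
dilution series (8 points, five-fold, full 432² frames, default noise) plus
100 noiseless SD-level series for EC50 recovery; 20 seeds per load for the
contrast profile; a 96-well all-control plate for 0 h/24 h separation
(a scale-down of the full 1536-well validation run); and 61 SD-level
replicates at the 26.9 µM reference activity with 10% proportional noise.
These sizes give stable medians and fractions at interactive runtimes on a
single CPU.

## Known limitations

- Absolute SD values are simulator-specific; only ordinal and calibrated
  affine properties are meaningful. No photon-budget calibration is
  attempted.
- The 4PL fit reports no confidence intervals; a bootstrap would be the
  natural extension.
- Autofocus, flat-field correction, multi-field stitching, and 3D confocal
  stacks are out of scope; frames are assumed in focus and flat.
- The depth-of-focus model is an effective 2D approximation (in-focus
  fraction + haze), not a physical 3D PSF.
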