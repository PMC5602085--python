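# Methods

This note documents what the package computes, the assumptions behind the
synthetic cohort, and the choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimulus model

Each of the 103 hexagons flickers according to a circular shift of one
maximal-length sequence of order 13 (period 8191), generated by a Fibonacci
LFSR with shipped primitive taps for orders 2–16; generation verifies the
full state-cycle period explicitly, so non-primitive taps fail loudly.
Shifts are spaced `ceil(8191/103) = 80` steps apart — far more than the
2-step epoch span, which is what makes the first-order kernels separable.

The per-step frame pattern is `M, dark, GF, dark, GF, dark` at 75 Hz
(6 frames = 80 ms per step). This is the smallest pattern consistent with
two global flashes per step, a flash-to-flash interval of two frames
(26.7 ms), and a total run of 8191 × 80 ms = 10 min 55 s. The frame rate is
not a measured quantity here and remains configurable; the luminances
(100 / <1 / 200 cd/m²) are carried as schedule metadata only.

## Signal chain

Recording segments (16 near-equal runs of the step sequence) pass through:

1. **Artifact rejection, two passes.** A segment is flagged when the
   z-score of its peak amplitude against the remaining segments
   (leave-one-out) exceeds 3, and is replaced by the mean of its nearest
   surviving neighbours. The second pass catches borderline artifacts whose
   z-score was masked by a gross outlier in pass one. The commercial
   algorithm is proprietary; this is a parameterized, documented stand-in
   with the same two-pass structure.
2. **Zero-phase band-pass, 1–200 Hz.** 2nd-order Butterworth applied
   forward–backward (`sosfiltfilt`), so epoch windows are not shifted by
   filter delay. Steady-state gain is within 5% at mid-band and below 0.04
   one octave above the upper edge.
3. **Kernel extraction.** The first-order kernel of hexagon *h* is the
   circular cross-correlation of the ±1-recoded, *h*-shifted sequence with
   the trace, sampled on the 0–105 ms post-step grid and scaled by
   `2/(L+1)` so a noise-free injected response is recovered with unit gain
   (the 0/1 stimulus equals the ±1 code shifted and halved). Residual
   cross-talk between hexagons is of order `1/L`.
4. **Epoch RMS.** Root-mean-square over DC 15–45 ms, IC1 45–75 ms, IC2
   75–105 ms (half-open windows), without local baseline subtraction — the
   windows abut and the 1 Hz high-pass already removes offset. Per-hexagon
   RMS values are arithmetically averaged over the central 7 and central 19
   hexagons. Epoch time zero is the onset of the step's M frame.

An independent oracle (direct averaging of epochs after a hexagon's
on-steps minus its off-steps) backs the extraction tests; on noise-free
single-hexagon input the two agree to correlation > 0.999 and the pipeline
RMS matches the injected template's RMS to 1e-6 relative error.

## Geometry and correspondence

Retina-to-field conversion uses 3.3 °/mm, under which the GCIPL annulus
diameters (4.0 mm vertical, 4.8 mm horizontal) map to 13.2° and 15.8°. The
ganglion-cell displacement is represented piecewise-linearly through the
two anchors (1 mm, 0.62 mm) and (4 mm, 0.12 mm), constant outside [1, 4] mm
— the minimal curve reproducing both anchor values without inventing an
analytic form. Perimetry points enter the central-10° set when their
displacement-corrected eccentricity is within 10°; the central-15° set adds
exactly four configured points (default: one per quadrant from the ~12°
ring), user-overridable since the exact identity of such added points is a
protocol choice, not a derivable fact. Coordinates are visual-field
degrees, fovea at origin, right-eye orientation.

The shipped perimetry grid is a synthetic G2-style pattern (56 points on
seven rings out to 26°, denser centrally); it is a stand-in with the same
central emphasis, not a copy of any proprietary grid.

## Synthetic cohort

The generator's defaults are the study conditions: 16 control, 6
preperimetric (PPG) and 20 perimetric (POAG) glaucoma eyes, ages
49.2 ± 7.0 / 63 ± 15.9 / 60.6 ± 12.4 years, male fractions 2/16, 5/6, 0.80,
GCIPL 80.7 ± 4.7 / 68.2 ± 10.2 / 65.4 ± 9.3 µm, macular thickness
308.4 ± 12.7 / 302.6 ± 15.8 / 296.5 ± 18.7 µm.

Per eye, GCIPL and macular thickness are drawn from the group normals with
a shared latent factor (ρ = 0.5). Disease severity is anchored to the
GCIPL draw: `s = clip((80.7 − GCIPL)/40 µm, 0, 1)`, and a spatially smooth
ganglion-integrity field `g(x, y) = clip(1 − s(1 + 0.3 φ(x, y)), 0, 1)`
(random low-frequency cosine pattern φ) modulates everything functional:

- **mfERG**: per-hexagon response = `gain · (outer(t) + g_hex · inner(t))`,
  where `outer` is a biphasic outer-retinal wave inside the DC window and
  `inner` carries the adaptive DC term and both induced components — only
  the inner-retinal terms scale with integrity. A full-field global-flash
  response is added at every step and cancels in first-order extraction.
  `gain` is a per-eye lognormal (σ = 0.12) with a mild age slope.
- **SAP**: linear sensitivity follows `min(1, g/0.5)^2.5` — a functional
  reserve: loss is invisible until integrity drops below 0.5. POAG eyes
  additionally receive a focal Gaussian scotoma (depth scaled by severity,
  σ = 3°, centre drawn at 6–20° eccentricity, so it may or may not invade
  the central 15°). Point noise is a shared per-eye offset (0.8 dB) plus
  independent 0.6 dB; the shared component keeps the family-wise
  false-positive rate of the 0.5% point criterion realistic. The reserve
  and the focal component are what let preperimetric eyes combine
  structural thinning and reduced mfERG with a normal field — the
  phenomenon the analysis is about; a pure shared-severity coupling cannot
  produce it.
- **OCT sectors**: GCIPL wedge sectors around the eye's draw with
  severity-weighted spatial modulation (zero-mean across sectors) plus 2 µm
  noise; ETDRS sectors around the macular-thickness draw (3 µm noise,
  thinner outer ring). The explicit loss knob (`severity_shift`) lowers the
  functional outputs and the GCIPL base coherently.

Age and gender effects are centred at each group's mean age, so the group
means above are preserved exactly in expectation while within-group
covariate structure exists for the adjusted models to use.

**Trace mode vs fast mode.** Trace mode synthesizes the full 786k-sample
recording (superposed per-hexagon responses, 50/50 white + 1/f noise of
8 µV total) and runs the complete signal chain. Fast mode generates the
kernels directly with Gaussian noise matched to the extraction-noise scale
(`2σ·b/√L`, with b ≈ 0.6 for the post-filter band fraction); it is used for
Monte-Carlo calibration suites (specificity at n = 1000, 50-seed
direction-of-effect checks) where trace synthesis would dominate runtime.
Problem sizes used in the shipped tests — 42-eye cohorts, 120–500-eye
normative samples, 50–100 seeds — were chosen as the smallest giving
stable Monte-Carlo assertions.

What the generator does **not** emulate: biophysically realistic ERG
waveshapes, fixation losses, media opacity, OCT segmentation failure,
test–retest learning effects, or the selection process of a real clinic
(groups are defined by parameter distributions, not by inclusion criteria
applied to a population). Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under the assumed
generative model, not clinical performance.

## Statistics

- ANOVA: classical F (scipy), pairwise two-sample t-tests multiplied by the
  number of pairs (Bonferroni), capped at 1.
- Structure–function: `function ~ structure + age + gender` with a subject
  random intercept (statsmodels MixedLM, REML); when every subject
  contributes a single eye the intercept is unidentifiable and the model
  collapses to OLS. Per-group slopes are available through a group ×
  predictor interaction helper; the pooled model is the headline. All
  regression p-values of one run form a single BH-FDR family.
- Adjusted ROC: logistic regression `disease ~ age + gender + marker`
  (sklearn, no penalty); the ROC is computed on the predicted
  probabilities with the Mann–Whitney statistic (ties half-weighted) and
  the DeLong variance estimator. With constant covariates the logistic
  score is monotone in the marker, so the adjusted AUC equals the raw
  marker AUC. Under perfect separation the fit may not converge; the score
  ordering is still valid and a warning is logged. The DeLong paired test
  compares correlated AUCs computed on the same eyes; the implementation is
  cross-checked against R's pROC to 1e-9.

## Classification

"Outside the 95% quantile of controls" for the mfERG criterion is read
one-sided (below the control 5th percentile) because glaucomatous damage
reduces amplitude; a two-sided option exists. The criterion is evaluated on
the 15° averages by default (configurable region), per epoch. OCT sector
flags are boundary-inclusive (value ≤ percentile), matching device
conventions. Normative quantiles are empirical (linear interpolation) from
a control-only sample whose size and seed are recorded in the database;
with ~100 controls the extreme point-wise quantiles (0.5%) are necessarily
coarse — a real normative database would be far larger.

`example_crosstab_flags()` ships a worked 26-eye agreement table (six
preperimetric, twenty perimetric eyes) with fixed flag combinations, used
by tests and the acceptance script to exercise the cross-tab arithmetic on
a known answer.

## Numerical and degenerate-input choices

- Epoch windows are half-open `[t0, t1)`; sample indices round from ms.
- Empty region masks warn rather than fail (a selection can come up empty);
  statistics raise typed errors on degenerate input (single class, constant
  predictor, all segments flagged, < 10 complete cases).
- All randomness flows through `numpy.random.Generator`; a fixed seed makes
  cohort simulation and the whole pipeline bit-identical, which the test
  suite asserts on output digests.
- Segment boundaries of unequal length (±1 step) are conformed by
  crop/edge-pad when an artifact replacement averages neighbours.

## Known limitations

- The per-hexagon response templates are Gaussian-lobe sketches with the
  right polarity, latency bands and integrity scaling, not fitted ERG
  waveforms; absolute RMS values (µV) are therefore only scale-plausible.
- Fast mode approximates extraction noise as white, ignoring the spectral
  shaping of the band-pass within epochs.
- The mm↔degree conversion uses a single global factor; real displacement
  and magnification vary with axial length and eccentricity.
- The mixed model supports one random intercept per subject; more complex
  covariance structures (e.g. inter-eye correlation differing by group) are
  out of scope.
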