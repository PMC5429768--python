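# Methods

## The measurement problem

The Golgi apparatus of adherent mammalian cells is normally a compact
perinuclear ribbon. Mitosis, apoptosis, trafficking blocks (Brefeldin A),
microtubule poisons (nocodazole) and oncogenic transformation fragment it
— first into discrete perinuclear stacks (*partial* fragmentation), then
into vesicles dispersed through the cytosol (*full* fragmentation, the
"mitotic haze"). The classical readout is manual classification of a few
hundred immunofluorescence images, which is slow and user-biased.
Imaging flow cytometry (IFC) records a multichannel image of every cell
in flow, so the same classification can be made automatically on tens of
thousands of cells. `golgiq` implements that analysis as an open,
scriptable pipeline: per-cell masks and features, hierarchical gating,
Fisher-discriminant feature ranking, and pulse-shape analysis (PulSA) as
the flow-cytometry baseline, validated end to end on a built-in
synthetic image generator.

## Masks and features

Features are scalar statistics of a (channel, mask) pair per cell.

* **Object mask** — global Otsu threshold, holes filled, 8-connected
  components. For the bright-field (BF) cell body only the largest
  component is kept; for Golgi and DNA staining *all* components are
  kept, because fragmented staining is exactly the signal of interest
  (a largest-component rule would reduce a fully fragmented Golgi to a
  single vesicle and invert the area readout).
* **Threshold mask** — the p% highest-intensity pixels of a parent mask.
  "p%" is read as a fraction of the parent *pixel count* (the literal
  reading of "the 60% highest intensity pixels"); an intensity-fraction
  variant is selectable via `masks.threshold_mode`. Ties at the cutoff
  are resolved in row-major scan order, making masks bit-reproducible.
  The pipeline's central masks are Threshold-60 of the Golgi staining
  and Threshold-50 of the DNA staining.
* **Area** — mask pixel count × pixel_size², μm².
* **Minor-axis intensity** — with in-mask intensities as weights, the
  eigen-decomposition of the 2×2 weighted second-central-moment matrix
  gives the best-fit (equal-moment) ellipse; the minor axis is reported
  as 4·√λ₂·pixel_size (the ±2σ diameter). The constant is a frozen
  convention — any fixed positive constant only rescales the gate axis.
* **Aspect ratio** — the same construction with unit weights,
  minor/major; 1 for a point-like mask by convention.
* **Gradient RMS** — RMS of the 3×3 Sobel gradient magnitude over the
  mask; an absolute sharpness (focus) metric.
* **BF contrast** — gradient RMS divided by mean in-mask intensity; a
  brightness-invariant texture metric. Keeping the focus metric
  absolute and the texture metric normalized matches their distinct
  uses (focus gate vs apoptosis gate). Both are documented stand-ins
  with the qualitative behavior of the instrument software's features,
  whose exact formulas are proprietary.
* **Bright-detail intensity** — Σ max(channel − grayscale opening by a
  radius-3 disk, 0) over the mask: the summed intensity of features
  smaller than the structuring element after local-background removal.
  High for speckled/condensed chromatin.
* **PulSA triplet** — the in-mask Golgi intensity projected onto the
  x axis emulates a cytometer pulse: height = profile maximum, area =
  profile sum, width = full width at half maximum (FWHM; the pulse-width
  convention is config-overridable in principle — FWHM is the most
  robust single-threshold choice).

No per-cell background subtraction is applied before moments: the
generator's constant camera offset is second-order once the
Threshold-60 mask confines the moments to bright pixels. This is a
documented limitation for strongly non-uniform backgrounds.

## Gating hierarchy

1. **Singlets**: BF object area within [86, 256] μm² and aspect ratio
   ≥ 0.79 (doublets sit near twice the singlet area and ~0.55 aspect).
2. **Focused**: BF gradient RMS ≥ 319 au. Defocus washes out cell
   texture but not the shot-noise gradient floor, so the threshold sits
   just above that floor (~0.72× the in-focus median).
3. **DNA content**: the G1 (2N) reference is the highest peak of a
   smoothed DNA total-intensity histogram; G1 = [0.75, 1.25]×mode,
   G2/M = [1.7, 2.3]×mode (conventional flow-cytometry windows,
   config-overridable), between = S/indeterminate, outside = excluded.
   *Limitation:* in heavily mitotic-arrested or heavily apoptotic
   populations the modal peak is not the 2N peak; set
   `dna_content.g1_reference` explicitly for such samples.
4. **Mitotic sub-phases** (within G2/M): bright-detail intensity below
   threshold → interphase G2; two separated nuclear masses → anaphase
   (centroid separation > 5.75 μm) or telophase; one condensed mass
   with Threshold-50 DNA area below threshold → metaphase; remainder →
   prophase. Prometaphase (the nocodazole arrest state) is folded into
   metaphase; separating it requires visual nuclear morphology that is
   out of scope here.
5. **Apoptosis**: BF contrast ≥ 2.0 and Threshold-50 DNA area ≤ 22 μm²
   — high-contrast bright-field texture plus condensed DNA.
6. **Golgi morphology**: on the plane x = Threshold-60 minor-axis
   intensity (μm), y = Threshold-60 area (μm²), *intact* is the closed
   lower-left rectangle (x ≤ 1.9 ∧ y ≤ 5.9 with default gates), *full*
   the open upper-right region (x > 8.8 ∧ y > 16.1), *partial* the
   complement — a partition of the quadrant by construction. Boundaries
   are closed-below/open-above, so a point exactly on a threshold
   belongs to the lower class; polygon gates are accepted via config
   for users replicating hand-drawn regions (containment with
   deterministic nearest-region fallback preserves the partition).

All numeric defaults above were calibrated once on the synthetic
exemplar population and frozen; `calibrate_gate_config` re-derives every
threshold from any labeled exemplar sample. Two-class boundaries sit at
the variance-weighted midpoint t = (μ₁σ₂ + μ₂σ₁)/(σ₁ + σ₂), which
equalizes the z-distance to both classes and reduces to the arithmetic
midpoint for equal spreads. Gates are calibrated rather than hard-coded
because published gate coordinates for this assay are drawn by hand
around reference treatments and are not recoverable.

## Feature selection

`rank_features` scores each feature by Fisher's discriminant ratio
RD = (μ_b − μ_a)/(σ_a + σ_b) (sample SDs, sign kept, ranked by |RD|,
ties broken by name). On the synthetic exemplars the Threshold-60 area
and minor-axis intensity rank at the top for intact-vs-full separation
— the same selection that motivates the gate plane.

## Population statistics

Golgi-class percentages use eligible (singlet ∧ focused) cells with an
assigned label as denominator, so intact + partial + full = 100%;
apoptotic and cycle percentages use eligible cells; mitotic-phase
percentages use G2/M cells. Replicate comparisons report mean ± SEM
(sd/√n) and a two-tailed t-test against a reference condition. Welch's
unequal-variance test is the default — with n = 3 replicates it is the
safer choice — and the pooled-variance Student's variant is selectable.
No multiple-testing correction is applied.

## The synthetic generator

64×64 px tiles at 0.5 μm/px (cell radius 7.5 μm, nucleus 4.5 μm —
chosen so a ~15-μm cell fits the canvas with margin; the source
instrument's magnification is not published). Channels:

* **Golgi**: *intact* = 2–4 overlapping Gaussian blobs (σ 0.85–1.1 px)
  along a perinuclear arc spanning ~30–45°; *partial* = 4–8 discrete
  puncta at stratified angles within 0.65–0.85× the nucleus radius
  (fragment size shrinks as count grows, conserving stained material);
  *full* = 25–60 small vesicles (σ 0.7–0.95 px) dispersed over
  0.85–0.98× the cell radius. Total Golgi intensity ~18,000 au with
  15% lognormal cell-to-cell scatter, so class differences are
  geometric, not photometric.
* **DNA**: interphase = smooth disk; prophase = disk + bright granules
  (0.65/0.35 mass split keeps the Threshold-50 area near interphase
  while raising bright-detail); metaphase = thin rotated bar (low
  Threshold-50 area); anaphase/telophase = two granular masses 7.0 /
  4.5 μm apart; apoptotic = 2–4 very bright condensed blobs. 2N states
  integrate to ~40,000 au, 4N to ~80,000 (8% lognormal scatter);
  apoptotic nuclei to ~28,000 (sub-G1).
* **BF**: soft disk (300 au) with smooth internal texture; apoptotic
  cells get sharper, stronger speckle (blebbing), which drives the
  contrast metric.
* **Artifacts**: out-of-focus cells get 2.5–4 px extra Gaussian blur;
  doublets render a second cell at 0.8–1.2× size ~1.5 radii away.
* **Noise**: signal = Poisson(clean × gain)/gain + N(0, σ_read) +
  offset, with gain 0.25, σ_read 2 au, offset 5 au, quantized to
  uint16.

Population presets encode the studied treatment conditions as
(Golgi × nucleus)-class mixtures. The Golgi marginals — untreated
0.80/0.17/0.03, noc_4h 0.25/0.60/0.15, noc_16h 0.10/0.25/0.65,
bfa_60min 0.20/0.75/0.05, tnf_chx_6h 0.35/0.60/0.05 (with 75%
apoptotic nuclei), wi38 0.82/0.15/0.03 — are set to satisfy the
reported population-level claims for those conditions (untreated
cultures >70% intact and <5% fully fragmented; untreated apoptosis <3%
vs >70% after 6 h TNFα/CHX; untransformed fibroblasts <20% partially
fragmented); exact per-condition bar heights are not published as
numbers. The `thymidine_release_9h` preset couples Golgi state to
cell-cycle phase (fragmenting through prophase–anaphase, reassembling
at telophase). `exemplars` is the balanced 1/3-1/3-1/3 calibration
sample with enough mitotic and apoptotic nuclei to calibrate every
gate.

**What the generator does not emulate:** real GM130/Giantin texture
statistics, optics (PSF shape, spectral bleed-through), cell-shape
heterogeneity, debris, or the intensity correlations of real staining.
Passing tests therefore demonstrate that the *pipeline* is correct and
self-consistent — masks, features, calibration and gating recover known
ground truth under realistic noise — not that the gates would transfer
unchanged to a particular instrument; on real data the gates should be
re-fitted from that instrument's reference treatments via
`calibrate_gate_config` / `golgiq fit-gates`.

## Numerical choices and degenerate inputs

* 8-connectivity everywhere (components, hole filling).
* Threshold-mask ties broken in row-major order; exactly
  ceil(p/100·|parent|) pixels kept.
* Empty masks and zero in-mask intensity yield flagged NaN features,
  never exceptions, so one degenerate cell cannot abort a batch; an
  empty Otsu parent makes the derived threshold mask empty (area 0).
* Gate boundaries closed-below/open-above; stable under ±1 ulp.
* RD of two point masses: 0 when means agree, ±inf (flagged) otherwise.
* Welch's test on two zero-variance equal samples returns t = 0, p = 1.
* Problem sizes: calibration uses 300 exemplars (~100 per class, the
  scale of a manually classified reference set); population-scale runs
  use 5,000 cells per condition, at which multinomial sampling error on
  a percentage is ≲1.5 points.

## Known limitations

* The DNA-content G1 reference assumes the 2N peak is modal (see above).
* Feature formulas named after instrument-software features (gradient
  RMS, contrast, bright detail) are qualitative reimplementations; their
  absolute values are not comparable to vendor-software exports.
* Rectangular default gates cannot represent curved class boundaries;
  polygon configs can.
* No spectral compensation, no proprietary (.rif/.cif/.daf) readers:
  input is per-cell multi-page TIFF (BF, GOLGI, DNA) plus a CSV
  manifest.
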