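# Methods

This note documents the models, algorithms and numerical choices behind
`synquant`, and what the synthetic validation does and does not establish.

## Segmentation of synaptic puncta

Excitatory synapses appear as PSD-95-immunopositive puncta.  The mask stage
blurs the raw channel with a Gaussian of σ = 2 px (kernel truncated at 4σ,
half-sample-symmetric borders), thresholds it with Otsu's method on a
256-bin histogram spanning [min, max], and splits merged neighbours with a
prominence-based maxima detector.  Masks take pixels strictly above the
threshold.  Intensity statistics are always measured on background-
subtracted raw images; the mask stage runs on the blurred raw channel.

**Find Maxima.**  The detector is a topological-persistence sweep: pixels
are visited in decreasing intensity order (ties broken row-major) while a
union-find structure tracks connected components.  A component is born at
its peak and dies when it merges into a component with a higher peak (equal
peaks: the earlier-born survives); a maximum is reported iff its
persistence — peak minus death level — strictly exceeds the noise
tolerance (`prominence`).  Persistence is computed on the full image; a
`floor` (the Otsu threshold in the pipeline) restricts only which maxima
are *reported* and which pixels are flooded.  The globally surviving peak
must additionally clear `peak − floor > prominence`, so a featureless
thresholded field reports nothing.  Equal-valued plateaus form a single
maximum reported at the plateau centroid (rounded; if the rounded centroid
leaves the plateau — a concave plateau — its first-visited pixel is used);
plateaus touching the image border are discarded.  Segmented-particles mode
floods the above-floor support from the accepted maxima by watershed
(8-connectivity), so each final label contains exactly one accepted
maximum.  The core loop is JIT-compiled; an independent level-descent
oracle (connected-component labelling per intensity level) verifies it in
the test suite.

Defaults for the noise tolerance (never a published quantity; it is an
instrument-scale parameter): 5 AU for confocal channels and 50 AU for STED
Munc13-1 — roughly 3× the blurred shot-noise amplitude of the respective
default intensity scales, and in the middle of the plateau over which
recovered counts are insensitive to the exact value (nanocluster counts
change by < 3% across tolerances 20–100).

## Morphometry

Areas are pixel counts × (pixel size)².  The aspect ratio AR is the
major/minor axis ratio of the ellipse matching the region's second central
moments (axis length = 4·√eigenvalue, so a solid ellipse reproduces its own
axes); AR ≥ 2.7 classifies a synapse as side-view, AR < 2.7 as en-face.
Nearest-neighbour distances (NND) are computed within each field from mask
centroids via a k-d tree and verified against the O(n²) oracle.  The mean
NND drops points that lie nearer to the field border than to their nearest
neighbour (their true neighbour may be outside the field); with this
correction the mean NND of a uniform point process matches the complete-
spatial-randomness expectation 1/(2√λ) within sampling error.  Labels
touching the field border are flagged and excluded from area/NND summaries
(truncated objects) but still count toward densities.

## Intensity measurements

The background of each channel is a rolling-ball estimate (radius 7 px),
implemented as grayscale opening with a spherical-cap structuring element
of height √(r² − d²).  On shot-noise-limited images the bare opening tracks
noise minima, so the pipeline pre-smooths with a 3×3 mean filter before
rolling and clips the result back below the raw image (background ≤ image
everywhere; constants are reproduced exactly).  Per-synapse means and
integrals are taken over (channel − background) clipped at zero — negative
fluorescence is unphysical; the clipping introduces a small positive bias
of roughly 0.4·σ_noise per pixel, which is why the generator's default
backgrounds are low and why ratio-based measures are preferred.

Normalized mean intensity divides a synapse's paired-protein mean by the
population mean of PSD-95 means *within the same reaction*, cancelling
labeling-efficiency differences between reactions; it is invariant to a
gain applied jointly to both channels of a reaction.

## STED nanocluster counting

Munc13-1 forms sub-diffraction clusters in the presynaptic active zone; in
side-view synapses the active zone lies laterally offset from the PSD-95
bar, so synaptic masks are dilated by 3 px (Euclidean disc) before
counting.  Maxima of the raw Munc13-1 channel (shared tolerance across all
subjects of an experiment) are assigned to the synapse whose *non-dilated*
mask boundary is nearest (via the exact Euclidean distance transform),
resolving overlaps between dilated masks; peaks farther than the dilation
radius from every mask are ignored.

## PV-dendrite receptor densities

Synapses on PV+ dendrites carry weak PSD-95, so their masks are built from
the summed PSD-95 + AMPAR + GluN1 fluorescence (identical procedure), then
filtered to > 10 AU integrated background-subtracted PSD-95.  A synapse is
"on" a PV dendrite when its label shares ≥ 1 px with a (non-myelinated-
axon) dendrite mask; dendrites come from annotation CSVs (polylines in µm,
rasterized as tubes of configurable width, 1.2 µm default) — the scriptable
replacement for manual outlining.  Receptor density is the
receptor/PSD-95 integral ratio per synapse; PV-synapse densities are
normalized by the mean per-synapse ratio of all non-PV synapses in the
same subject's fields (mean-of-ratios; ratio-of-means is available).  The
per-subject scope absorbs inter-subject staining differences.  Dendrite
synapse counts per µm use the polyline arc length.

## Somatic PV analysis

Cell bodies are segmented from the blurred PV channel by the triangle
threshold; the raw mask is refined deterministically (hole filling + 2 px
erosion, trimming the blurred rim that would bias somatic means downward)
and filtered to ≥ 50 µm².  An `exclusions` list of label ids replays
manual revisions.  The neuropil background mask is the complement of the
mean-threshold PV-positive mask on the unfiltered image; its scalar mean is
subtracted from each soma's raw mean.

## Statistics

All group tests operate on per-subject means.  Two-sample tests are
classical pooled-variance t tests (df = n₁+n₂−2; Welch optional) — the
pooled form reproduces the package's own worked summary-statistic checks —
with two-tailed p values from the t distribution.  Families of comparisons
reported together (e.g., the three PV receptor densities) are adjusted with
the Holm–Bonferroni step-down (monotone-enforced, capped at 1); family
membership is declared in configuration.  Spearman correlation is Pearson
on mid-ranks with the large-sample t approximation.  Normality screening
uses Shapiro–Wilk for small samples and, for large ones, the Kolmogorov–
Smirnov test against the fitted normal with the Lilliefors correction —
without the correction the estimated-parameter KS is so conservative that
the null calibration property (≈5% rejections) cannot hold.  Covariate
effects (condition, age, gender as a binary indicator, postmortem
interval) are ordinary least squares with t-based coefficient p values;
rank-deficient designs fail loudly, naming the collinear columns.
Degenerate inputs (zero pooled variance) are flagged rather than producing
NaNs.

## Synthetic cohorts

The generator renders what the analysis assumes, with exhaustive ground
truth.  Key choices, with the reasoning:

* **Templates.**  Objects are rotated anisotropic Gaussians whose sigmas
  already include the modality's point-spread function; the planted "area"
  is the above-half-max footprint (area = 2π·ln2·σ_maj·σ_min).  Rendering
  normalizes each patch to its exact target integral.
* **Synapse sizes.**  Lognormal, σ_log = 0.5, mean 0.11 µm² (the
  superresolution-measured scale — measured confocal mask areas are
  blur-inflated well beyond the true footprint), truncated below
  0.04 µm² (a minimal postsynaptic density).  En-face synapses draw
  AR ∈ [1, 2], side-view AR ∈ [3.5, 6], leaving a margin around the 2.7
  classification boundary; the en-face fraction is 0.74.
* **Placement.**  Homogeneous Poisson counts with a hard-core minimum
  separation of 0.5 µm — the distance below which two puncta are a single
  punctum for this measurement (blurred template σ ≈ 0.26 µm), and below
  which no measured NND can occur in real data either.  Placement failure
  beyond a 2% tolerance raises (density too high for non-overlapping
  objects).
* **Intensities.**  PSD-95 integral ∝ area × lognormal noise
  (σ_log = 0.3 confocal) × per-reaction gain (lognormal, σ = 0.25) ×
  per-subject random effect (lognormal, σ = 0.15).  Backgrounds are low
  (10 AU confocal Layer 2, 3 AU STED, 0.5 AU deep-layer sequential
  reactions — resin-section postembedding imaging has very little
  autofluorescence), keeping the faintest synapses at signal-to-background
  ≥ 5, the regime in which the mask stage is reliable.  Noise is Poisson
  shot noise on signal + background plus Gaussian read noise, over a
  smooth multiplicative background modulation.
* **Nanoclusters.**  count = max(1, round(32·area) + Poisson(1) − 1),
  calibrated so the planted population mean is 3.4 clusters/synapse;
  clusters keep ≥ 60 nm spacing inside the half-max ellipse (side views:
  along the active-zone line, offset 40 nm presynaptically) and are
  rendered at σ = 20 nm, i.e. the ~40 nm FWHM resolution of the modality —
  wider clusters would make the 60 nm spacing unresolvable by construction.
* **PV model.**  Somatic intensities per subject ~ Normal(1362, 151)
  control / Normal(955, 265) case; PV-dendrite synapses at 0.87 µm⁻¹ along
  random polylines with PSD-95 scaled by 122/192, and per-subject receptor
  multipliers ~ Normal with means 1.72/1.60/1.72 (control) vs
  1.54/1.30/1.43 (case) and the corresponding subject SDs for
  AMPAR/GluN1/GluN2B.  Non-PV synapses are excluded from a one-synapse-
  radius padding around dendrite tubes — the dendrite occupies that
  space — which keeps the PV synapse set pure under the ≥ 1 px overlap
  rule.
* **Covariates.**  Age uniform on 55–85 years, gender Bernoulli(½),
  postmortem interval ~ Normal(3.3, 0.7) h.
* **Side-view fixture.**  A deterministic, noiseless multi-channel synapse
  at 20 nm/px with channel bars offset 0 (GluA2), 40 (Munc13-1), 100
  (Bassoon) and 220 nm (VGLUT1) from PSD-95; regenerating it is
  byte-identical, so it ships as code, not as an image file.
* **Fast statistical path.**  `simulate_subject_summaries` draws subject
  means directly from the cohort model (no rendering) for calibration and
  power suites: 500-replicate type-I-error checks and the
  GluN1-effect/AMPAR-null power analysis run in milliseconds.

**What the synthetic validation shows — and does not.**  Recovery tests
demonstrate that the pipeline's measurements are faithful to a known
object model under realistic noise: detection F1 ≥ 0.9 (200 nm gate),
mean detected density within 10% of the planted 0.15 µm⁻² (the residual
~9% deficit is the physically expected loss of sub-resolution pairs and
sub-threshold faint puncta), nanocluster means within ±0.3, and PV
receptor-density ratios recovered within a few percent.  The generator
does not emulate tissue artefacts (fractures, vessels, uneven section
thickness), antibody penetration gradients, 3-D sectioning effects, or
non-Gaussian punctum shapes (perforated synapses), so passing tests bound
algorithmic, not histological, error.

## Problem sizes and runtime choices

The default test suite and acceptance script size their simulations to the
scale at which the estimates stabilize: 20 Layer-2 fields (≈ 40,000
synapses) for density recovery, ~200 STED synapses for nanocluster means,
7 × 2 deep-layer fields for the PV-dendrite cohort, and 500/200
subject-level replicates for the calibration and power suites.

## Known limitations

* Strictly 2-D; no section-thickness or stereological correction.
* Translation-only channel registration (sufficient for the generator's
  aligned rounds; real multi-round data may need non-rigid alignment
  upstream).
* The Otsu mask area is threshold-relative, not a half-max area: absolute
  measured areas depend on the field's intensity histogram and exceed true
  footprints by design of the method; cross-group comparisons are
  unaffected because acquisition settings are shared.
* Background-subtraction clipping biases integrals of very dim channels
  upward; ratio normalization largely cancels it, but absolute integrals
  of near-background signals should be interpreted cautiously.
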