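# Methods

`scarmorph` quantifies the remodelling state of scar tissue from
multi-channel section images and a four-timepoint expression matrix. The
read-outs mirror how a dermatopathology imaging study would score a scar
biopsy before and after an intervention: epidermal architecture, the
epidermal–dermal junction (EDJ), dermal cellularity and vascularity, the
architecture of the collagen type I network seen by second-harmonic
generation (SHG), and the transcriptomic time course. Everything is
validated by parameter recovery on synthetic sections whose ground truth is
recorded at generation time.

## Coordinate and angle conventions

Images use the origin at the top-left corner, x rightward (parallel to the
epidermis) and y downward (depth). A pixel at array position `(row, col)`
has its centre at `((col + 0.5)·px, (row + 0.5)·px)` µm. Orientation angles
are undirected and live in [0°, 180°), with 0° parallel to the epidermis;
the direction vector of an angle θ is `(cos θ, sin θ)` in (x, y-down)
coordinates, so the generator and the structure-tensor estimator share one
chart.

## Synthetic sections

`SectionSpec` describes a layered section: a flat top boundary of the
viable epidermis (at a fixed 20 µm margin), a sinusoidal EDJ
(amplitude/period), a basement-membrane band with a Gaussian cross-profile
centred on the EDJ, nuclei drawn as non-overlapping 3 µm disks placed by
Poisson-disk dart throwing, a chosen fraction of epidermal nuclei marked
Ki67-positive, vessel cross-sections drawn as annuli in the dermis, and a
dermal fibre field of constant-width strokes. A sinusoidal EDJ keeps the
true arc-chord ratio computable by dense polyline summation; free-form
boundaries are accepted everywhere else through `BoundaryCurve`.

Default parameters emulate a mature occipital-scalp scar biopsy ROI:
600 × 450 µm at 0.5 µm/px (the pixel size is a package default recorded in
the image metadata), ~50 µm viable epidermis, 4% Ki67-positive epidermal
nuclei, 6% vessel area, a thin/thick fibre width mix of 6 and 14 µm with
roughly equal area shares, and SHG fibre/background intensities of 150/50.
Channels are noiseless by default so analytic examples stay exact; Gaussian
noise of stated SD is opt-in (`noise_sd`).

Ground-truth bookkeeping is what makes the generator testable: the exact
nucleus centres and Ki67 labels, the per-fibre width/angle/pixel-area
table, the painted vessel pixel count, and the arc-chord ratio of the
generated EDJ are all stored and serialized losslessly to JSON.

Two rendering rules keep truth and measurement consistent:

- The basement-membrane band is rendered from exact subpixel distances to
  the densely sampled EDJ curve (KD-tree query), not from a rasterized
  curve, so the profile FWHM read back from the image is within ~1% of
  2.355 σ.
- Fibre strokes never touch the canvas border. Local thickness treats the
  image edge as background, so a border-clipped stroke would render
  thinner than its nominal width and the class bookkeeping would disagree
  with any faithful measurement.

The fibre packer treats the mixture weights as *area* weights: each width
class grows until its share of painted area reaches its weight, and the
last stroke of a class is trimmed so the class does not overshoot its
target. Packing is rejection-based with a 2-pixel clearance between
strokes; a request whose realized area fraction falls below 90% of the ask
raises an explicit infeasible-packing error.

The expression generator plants four disjoint gene sets on top of
per-gene N(7, 1) log2 baselines: `unique2`/`unique4`/`unique6` genes are
shifted at exactly one post-baseline timepoint, `core` genes at all three.
Effects have a stated log2 magnitude and random sign; noise is i.i.d.
Gaussian per sample. An effect smaller than ~2 standard errors at the
requested design logs a warning rather than failing.

### What the synthetic data does not emulate

No 3-D structure, no point-spread function or shot noise, no illumination
gradients, no touching nuclei (overlap is a separate stress flag), no
fibre curvature or branching, no probe-level microarray artefacts, and no
correlation structure between genes. Passing recovery tests therefore
demonstrates correctness of the measurement chain under controlled
conditions, not robustness to every artefact of real histology.

## Segmentation

**Fibre classes.** The three-class segmentation (background / thin fibre /
thick fibre) is deterministic: intensity threshold (Otsu by default, fixed
value as an option) → per-pixel local thickness → skeletonize → split the
skeleton at junction pixels (8-neighbour degree > 2) → per-segment width =
mean local thickness over the segment's skeleton pixels ("average width
along its length") → thin iff width ≤ 10 µm (inclusive), thick otherwise.
Foreground pixels are then assigned to the nearest skeleton segment *of
their own connected component*, so fibres separated by a gap never trade
pixels. The thin/thick/background areas partition the ROI exactly.

**Local thickness.** The thickness at a foreground pixel is the diameter
of the largest inscribed disk containing it. The implementation covers the
foreground with maximal disks (every pixel carries a disk of radius equal
to its Euclidean distance transform), processing radii in descending order;
the image border counts as background via padding. Agreement with an
exhaustive per-pixel search is within one pixel-diameter quantum; disk
membership is closed (≤ with a 1e-9 slack) so exact-boundary ties resolve
consistently on both paths.

**Nuclei.** Laplacian-of-Gaussian multiscale blob detection over a stated
diameter range (default 4–9 µm), followed by greedy suppression so no two
centres are closer than half the minimum diameter. Marker positivity is
*not* decided here.

**Vessels.** An intensity threshold (Otsu within the supplied dermis
region by default) on the COLIV channel; the method and threshold are
recorded in the output provenance. Only the percentage area is used
downstream.

## Epidermis and EDJ morphometry

- **Thickness**: vertical-ray distances from the top boundary to the EDJ
  at `n_probes` locations `spacing_um` apart (defaults 10 × 150 µm,
  requiring a 1350 µm span; the pipeline scales the spacing to its section
  width). EDJ-normal probing exists but is off by default.
- **Ki67 fraction**: a nucleus is positive when its mean Ki67 intensity
  over a 2.5 µm disk exceeds the threshold (Otsu over the per-nucleus
  means by default; fixed override). Reported per 250 µm window along x and
  pooled; zero nuclei yield a missing value, never 0.
- **Arc-chord ratio**: the boundary is split into consecutive sections of
  equal arc length; each section's ratio is arc length over end-to-end
  distance and the mean over sections is reported (the whole-boundary
  ratio is also emitted, since either convention is defensible). The
  trailing remainder shorter than one section is discarded. The section
  length is not dictated by any single convention; the default is 100 µm —
  shorter than an ROI, long against pixel noise — and configurable. A
  sensitivity sweep on the synthetic default (A = 10 µm, L = 100 µm
  sinusoid) gives 1.046/1.092/1.092/1.092 at section lengths of
  50/100/200/400 µm: sections shorter than the undulation period
  straighten the curve and depress the ratio, while anything from one
  period upward is stable (the sweep is exercised in the test suite).
- **COLIV profiles**: trajectories normal to the local EDJ tangent,
  centred on the EDJ, 25 µm long, sampled at pixel resolution by bilinear
  interpolation; trajectories leaving the image are skipped and logged.
  Profile width/peak use a concrete reading of "width and peak": baseline
  = mean of the outer 20% of samples at each end, peak = max − baseline,
  width = full width at half maximum with linear interpolation between
  samples. A non-positive peak makes the width missing.

## Dermis morphometry

Cell density is centre counting in an ROI divided by its area in mm²;
vessel density is the masked-area percentage. Collagen summaries come from
the fibre-class mask: total collagen fraction (fibre / ROI area),
thick-fibre proportion (thick / fibre area, missing when there are no
fibre pixels) and area-weighted mean fibre width.

**Orientation** is estimated from the local structure tensor at a stated
smoothing scale (default 4 µm); the fibre direction is the eigenvector of
the smaller eigenvalue, and coherence (λ₁−λ₂)/(λ₁+λ₂) measures local
anisotropy. **Alignment** is the circular-statistics mean resultant length
of doubled angles, R = |Σ w·e^{2iθ}| / Σ w ∈ [0, 1]: doubling removes the
180° ambiguity of undirected fibres, R = 1 means perfect alignment and
values near 0 an isotropic field. For pixel fields the votes are weighted
by coherence by default: fibre-interior pixels have near-zero gradient, so
their tensor orientation is noise and uniform voting biases R low (the
test suite checks on rendered fields that coherence-weighted recovery of
the generator's per-fibre truth is tighter than uniform voting, and within
0.05 absolute). `weights="uniform"` restores one-vote-per-pixel. For the von
Mises concentration used by the generator, E[R] = I₁(κ)/I₀(κ), which the
estimator reproduces within 0.02 at n = 10⁴.

Normalized SHG intensity is the mean over fibre pixels divided by the mean
over a background region (default: non-fibre pixels of the ROI); a zero
background mean is an error, not an infinity.

## Transcriptomics

The pipeline consumes a normalized genes × samples log2 matrix (plain TSV/
CSV or the table block of a GEO series-matrix file); array preprocessing
(e.g. RMA) is established upstream machinery and out of scope. Stages:

1. **Baseline transform**: subtract each gene's median across all samples
   (idempotent).
2. **DE filter**: per-gene one-way ANOVA across the four timepoints;
   Benjamini–Hochberg FDR over all genes; fold change = largest-magnitude
   linear fold change of any post-baseline timepoint mean versus the
   0-month mean, signed positive for up-regulation, FC = ±2^|Δlog2|. The
   gate is |FC| > 1.5 AND p < 0.01 AND FDR < 0.01. Zero within-group
   variance falls back to the degenerate rule (p = 0 if the means differ,
   1 otherwise) and is logged.
3. **Pairwise comparisons** (0 vs 2, 0 vs 4, 0 vs 6 months): Welch's
   two-sample t on log2 values with the same gates. The FDR gate is
   configurable (`use_fdr=False` keeps only |FC| and p) because the two
   gate conventions give different set sizes and both are defensible; the
   stricter gate is the default.
4. **Venn partition**: unique sets (in exactly one comparison) and the
   core signature (in all three). Direction consistency across timepoints
   is not required of core genes by default.
5. **Hierarchical clustering** of samples on the passing genes: distance
   1 − Pearson correlation, average linkage, recorded in provenance;
   columns are sorted internally so input order cannot change the tree.
   The dendrogram is exported as Newick.
6. **qPCR relative quantification**: RQ = 2^(−ΔΔCt) against a reference
   gene and a baseline condition (baseline RQ = 1 by construction);
   samples missing the reference Ct are excluded and logged.

At zero noise the filter has sensitivity and specificity 1.0 for planted
|FC| > 1.5 genes; under a global null, BH keeps the any-discovery
probability at the gate level. With few true positives the BH adjustment
is the binding constraint on power: at 4% prevalence the effective p
threshold is ≈ 0.01 × prevalence⁻¹ smaller, which is why the recovery
tests use 8 samples per timepoint.

## Statistical decision procedure

For each metric, per-timepoint groups go through a fixed tree: normality
per group (D'Agostino–Pearson at α = 0.05; groups of n < 8, where that
test's skewness component is undefined, use Shapiro–Wilk and the trace
records which ran) → variance equality (F test for two groups, Bartlett
for more) → Student's t / one-way ANOVA + Tukey / two-way ANOVA + Tukey on
the parametric branch, Mann–Whitney U / Kruskal–Wallis + Dunn (Bonferroni-
adjusted, mid-rank tie correction) otherwise. The two-way model is
`value ~ timepoint + subject`, matching a design of few subjects sampled
at every timepoint with ROI replicates. The full decision trace is
returned, making the procedure a pure function of its inputs. Calibration:
over 1000 null replicates of four N(0,1) groups the selected pipeline
rejects at 5% within [0.03, 0.07].

Grubbs' outlier screen (α = 0.05) uses G = max|x−x̄|/s against the
two-sided critical value from the Student t quantile, flags at most one
point per call, and is applied once per (metric, timepoint) group.

## Pipeline and problem sizes

`run_pipeline` executes simulate → segment → morphometry → stats →
transcriptomics → report from one YAML-configurable dictionary, with all
randomness flowing from a single seed through spawned generators. Timepoint
effects are multiplicative factors on section parameters; defaults emulate
the remodelling course of a transplanted scar (epidermis ×1.6/1.4/2.0,
cell density ×1.8/1.5/2.0, vessels 6→10/9/10%, thick-fibre share
52→46/39/35%, falling orientation concentration and SHG intensity). A
log-normal section-to-section coefficient of variation (default 5%) stands
in for biological and sampling variability so that group statistics are
non-degenerate. Default pipeline sections are 400 × 300 µm at 1 µm/px with
3 subjects × 4 timepoints, sizes chosen so a full run completes in seconds
while every metric keeps ≥ 3 values per timepoint group; the recovery test
fixtures use 250–300 µm canvases for the same reason. Outputs are tidy
CSVs (byte-identical on re-run with the same seed), per-metric decision
results, scatter-with-grand-mean figures, and a provenance JSON with
package versions, seed, and the full configuration.

## Known limitations

- The structure-tensor orientation is biased near stroke end caps; the
  coherence weighting suppresses but does not eliminate this (residual
  alignment error ≤ ~0.03 on rendered fields).
- Blob detection assumes roughly circular nuclei of the stated diameter
  range; elongated or clumped nuclei would need a different detector.
- The thin/thick rule is a hard threshold on mean width; fibres whose
  width straddles 10 µm along their length are classed by the mean only.
- Pairwise DE uses Welch's t, not a moderated (shrinkage) statistic; at
  n ≤ 4 per group its power is limited and the FDR gate dominates.
- The two-way ANOVA assumes no subject × timepoint interaction (no
  replicates of that cell would remain in the default design).
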