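# Methods

## Scope and data model

The package analyzes 2D multi-channel rasters of transverse muscle
sections.  A `LabeledSection` bundles equally shaped named channels
(laminin boundary, MHC-I, MHC-IIa, ORO, SDH, COX, Sirius-red-like ECM,
CD31) with the physical pixel scale (default 0.5 µm/px, typical of 20×
microscopy).  All measurement modules operate on a fiber label map derived
from the boundary channel, so serial stains acquired on one geometry join
exactly; for truly serial sections a mutual-nearest-centroid matcher with
an IoU ≥ 0.5 acceptance check provides the correspondence.

## Synthetic sections

The generator exists so that every estimator can be validated by parameter
recovery rather than by eye.  Construction:

1. **Mosaic.** Per-fiber target areas are drawn log-normally per
   contractile type (defaults: type-I 5 000 µm², IIA 6 000 µm², IIX
   6 500 µm², hybrids in between; CV 0.25).  Seeds are placed by
   Poisson-disc dart throwing, tessellated as a power (Laguerre) diagram,
   relaxed with two Lloyd iterations (removes slivers), and the cell
   weights are then balanced for three iterations toward the target areas.
   If the realized mean CSA deviates from the target mean by more than 5%
   the domain is rescaled and rebuilt (at most three attempts).
2. **ECM.** Cell–cell and cell–background interfaces are dilated to the
   endomysial width (default 2 µm).  A perimysial band (default 12 µm) is
   painted by thickening the interfaces inside a corridor around a random
   chord — perimysium follows fascicle boundaries rather than cutting
   through fibers.
3. **Channels.** 8-bit, dark background (0) with bright signal (200) for
   immunofluorescence-like channels; SDH/COX are brightfield-like with
   background 230 and fiber intensity 230·10^(−OD), OD drawn log-normally
   per type (type-I SDH 0.70, IIA 0.50; CV 0.15).  IIA-IIX hybrids carry an
   intermediate MHC-IIa level (70) between the positivity threshold and
   half the strong-positive level.  All channels receive additive Gaussian
   noise (σ = 5 gray levels) and are clipped to [0, 255].
4. **Droplets.** Per-fiber Poisson counts (type-I mean 20, IIA 6 —
   chosen so the lipid content index is 3–4× higher in type-I than IIA
   fibers, as in trained muscle), areas log-normal (mean 3 µm², CV 0.5),
   placed as non-overlapping disks strictly inside the fiber.
5. **Capillaries.** Anchored on shared cell edges (preferring edge ends,
   i.e. junctions), drawn as an edge arc of log-normal target contact
   length (mean 12 µm) dilated to a 3–6 µm caliber, with a random
   perpendicular offset that controls how many fibers each capillary ends
   up contacting (~1.5 capillaries/fiber by default).
6. **Coupling.** An optional per-fiber latent score z ~ N(0,1) jointly
   modulates droplet rate, SDH OD and capillary placement/contact length
   (mean-preserving log-normal modulation).  `coupling = 0` gives
   independent indices; the correlation-structure experiment uses 0.8 for
   the coordinated condition, which plants pairwise r ≈ 0.4–0.55 among
   LC, ∑LD and Int-SDH in pooled type-I fibers — the "clearly
   inter-related" regime — and 0 for the decorrelated condition.

Ground truth records realized (painted) values — pixel-count areas,
contact lengths measured on the noise-free masks with the same geometric
definition as the pipeline — not the pre-discretization draws, so recovery
errors isolate measurement behavior from rasterization.

**What the generator does not emulate:** staining heterogeneity and
batch effects, uneven illumination, out-of-focus blur, fiber splitting and
freezing artifacts, true serial-section deformation (all channels share
one geometry unless the matcher is exercised explicitly), and photoreal
histology.  Passing recovery tests therefore demonstrates correctness of
the estimators under controlled noise, not robustness to every real-world
artifact.

## Estimator choices

- **Segmentation.** Fiber interiors are 4-connected components of
  boundary-negative pixels (boundary effectively 8-connected), preventing
  diagonal leakage between fibers.  Border-touching regions are excluded
  from all per-fiber statistics (truncated CSA/PF are biased), as are
  regions below 500 µm² (segmentation slivers).
- **Perimeter.** Sub-pixel marching-squares contour of the lightly
  Gaussian-smoothed (σ = 1 px) region mask.  Naive boundary-pixel counts
  are ~20% high; a 4-direction Crofton estimate is accurate on smooth
  profiles but ~5% low on polygonal ones (−10% on the squared shape
  factor).  The smoothed-contour length is within ~1% on both a rasterized
  disk (r = 50 px) and square (s = 100 px).
- **Typing.** A fiber is stain-positive when its median interior intensity
  is ≥ the positivity threshold (default 50).  MHC-I⁺ only → I; both → 
  I-IIA; strong MHC-IIa (≥ half the section's 95th-percentile positive
  level) → IIA; positive-but-intermediate MHC-IIa → IIA-IIX; neither →
  IIX.  Hybrids are scarce and dropped from cohort statistics downstream.
- **Thresholding of sparse objects.** Droplet and capillary channels are
  thresholded by Otsu's method for reproducibility, floored at 40% of the
  channel maximum: with foreground at ~1% of pixels plain Otsu collapses
  onto the background mode.  Channels whose maximum is below 60 gray
  levels (noise only) yield no detections.  Explicit thresholds override.
- **Densitometry.** OD = mean over fiber pixels of −log₁₀(I/I_bg), I
  floored at 1 gray level, I_bg the modal intensity of the region outside
  the tissue's convex hull; per-fiber means are clipped at 0.  An opt-in
  `section-median` normalization exists for cross-section comparisons but
  is off by default — batch effects are real but unmodeled.
- **ECM.** White top-hat (disk radius 20 px = 10 µm: wider than any
  endomysial band, narrower than a fiber) then Otsu with a manual
  override.  The network is split at a local width of 6 µm (typical
  endomysium ≤ 3 µm, perimysium ≥ 10 µm); local width is twice the
  distance value of the nearest medial-axis point, so the endo/peri masks
  exactly partition the ECM mask.  Mean endomysial thickness is 2× the
  mean medial-axis distance value; on straight bands of 1–10 µm it is
  within 10% of truth (network junctions genuinely widen the estimate
  slightly).
- **Capillary contacts.** A fiber-boundary pixel is "in contact" when
  within 1.5 µm (basal-lamina apposition at light-microscopy scale) of its
  nearest capillary.  Per-pair contact arcs are measured as polyline
  length after angular ordering around the capillary centroid; the
  per-fiber total LC uses the union of contacted boundary pixels (arcs
  from different capillaries merged), so LC/PF cannot double-count and
  stays within [0, 100].  Each boundary pixel is attributed to its nearest
  capillary; tortuosity is not computed (out of scope).
- **Statistics.** Fibers are pseudo-replicates: values are averaged to one
  number per subject × time × fiber type before cohort tests.  The mixed
  ANOVA (pingouin) needs no sphericity correction with a 2-level within
  factor.  Fisher LSD post hocs are deliberately unadjusted and use the
  paired error for within-group PRE/POST pairs and the pooled two-sample
  error otherwise — with one between and one within factor no single
  error term serves all comparisons.  Trends (p < 0.1) are reported as a
  flag, never as significance.
- **Proteomics.** Only proteins quantified in every sample are tested.
  The default multiple-testing correction is Benjamini–Hochberg FDR 0.05
  (the label-free standard), selectable to BY or Bonferroni.  FCS ranks
  proteins by the unsigned t statistic, compares in-set vs out-of-set
  ranks with a two-sided two-sample KS test, applies BY across sets and
  flags adjusted p < 0.01; sets mapping to < 3 proteins are skipped.
  Direction is read from the set's mean rank relative to the mid-rank.

## Problem sizes and numerical notes

Recovery tests run on 12–16-fiber sections (~700² px); the depletion
experiment uses 25-fiber all-type-I sections, 6 + 6 (retention 0.11) and
5 + 5 (retention 0.63) PRE/POST sections, five replicate cohorts — the
depletion statistic is a ratio of mean detected counts, so detection
efficiency cancels and the measured value tracks the planted retention.
ANOVA calibration uses 1 000 null simulations of the 6 + 5-subject design;
FDR calibration 400 null 400-protein tables; FCS recovery 20 replicate
tables with a 25-protein set shifted by 0.6 log2 units.  Degenerate inputs
(blank channels, empty masks, constant cohorts, zero-variance proteins)
either warn and return empty results or raise with a diagnostic, as listed
per function.  Seeded generators make every synthetic experiment
bit-reproducible; cohort seeds are derived from a base seed and kept below
2³¹.

## Known limitations

Hybrid-fiber typing depends on a section-internal reference level and
degrades if no strongly IIA-positive fiber is present.  The thickness
estimator inherits a small upward bias at ECM junctions.  Capillary
contact length is attributed to the nearest capillary, which slightly
truncates arcs where two capillaries nearly touch.  Correlation analyses
pool fibers across subjects within a cell (a `--per-subject` style
aggregation is available via the stats module); pooled fibers are not
independent across subjects, so the p-values are descriptive, as in the
source workflow.
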