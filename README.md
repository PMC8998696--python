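# myoquant

Fiber-type-specific histomorphometry of skeletal-muscle cross-sections.

Exercise-physiology and muscle-aging studies quantify serial biopsy
cross-sections stained for fiber boundaries (laminin), myosin heavy chains
(MHC-I / MHC-IIa), neutral lipids (Oil red O), mitochondrial enzymes
(SDH, COX), collagens (Sirius red) and capillaries (CD31).  `myoquant`
turns those multi-channel images into per-fiber measurements and
cohort-level statistics, and ships a synthetic-section generator with full
ground truth so that every estimator can be validated by parameter
recovery.

## What it measures

Per fiber, from the segmented boundary network:

- **CSA** (µm²), perimeter **PF** (µm), and the shape factor
  **PF² / (4π·CSA)** — 1.0 for a circle, larger for elongated profiles;
- contractile type (I, I-IIA, IIA, IIA-IIX, IIX) from MHC channel
  intensities;
- lipid droplet count, summed droplet area **∑LD** (µm²) and lipid content
  index **LI = 100·∑LD/CSA** (%);
- SDH and COX optical densities (−log₁₀ I/I_bg) and the spatially
  integrated SDH activity **Int-SDH = OD_SDH × CSA** (OD·µm²);
- the capillary-to-fiber interface family: **CAF** (capillaries around a
  fiber), **C/Fi** (each capillary credited 1/sharing-factor to every fiber
  it contacts), **CFPE** (C/Fi per mm of perimeter), **LC** (total contact
  length, µm) and **LC/PF** (% of the perimeter in contact);
- ECM endomysium/perimysium masks and mean endomysial thickness (µm), and
  capillary density **CD** (capillaries/mm²) at the section level.

Serial-section measurements are joined per fiber (LC, ∑LD, Int-SDH) and
their coordination is quantified with pairwise Pearson correlations per
group × time × fiber-type cell.  Cohort comparisons use a mixed-design
repeated-measures ANOVA (group between, time within) with Fisher LSD post
hocs.  Protein tables are analyzed with per-protein t-tests (FDR-adjusted)
and Kolmogorov–Smirnov functional class scoring of protein sets with
Benjamini–Yekutieli correction.

## Worked example

Generate a synthetic 25-fiber section (known ground truth) and run the
measurement pipeline on it:

```sh
$ myoquant synth section --seed 3 --out demo/sec
wrote section with 25 fibers to demo/sec
$ myoquant fibers --in demo/sec/section.tif --out demo/fib
25 fibers analyzed
$ myoquant lipids --in demo/sec/section.tif --out demo/lip
295 droplets detected
$ myoquant capillaries --in demo/sec/section.tif --out demo/cap
28 capillaries; CD = 216 /mm²
$ myoquant ecm --in demo/sec/section.tif --out demo/ecm
endomysium mean thickness: 1.93 µm
```

All 25 planted fibers are recovered; the 28 detected capillaries match the
generator's count, the endomysial thickness estimate sits within 4% of the
planted 2 µm band width, and `demo/fib/fibers.tsv` holds one row per fiber
with CSA, PF, shape factor and contractile type.  The same pipeline is
available as library calls (`myoquant.morphometry.analyze_section`,
`myoquant.lipids.detect_droplets`, …) returning pandas DataFrames.

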