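# Methods

## The phantom model

The simulated experiment reproduces an *activity painting* measurement: a
²²Na point source (1.1 MBq, 0.25 mm diameter) is stepped through a raster of
positions inside a 5×5×5 cm³ painting volume submerged in a ~15 L water tank
containing ¹⁸F solution. The source dwells at grid position *i* for
`base_dwell × v_i / max(v)` seconds, where `v_i` is the target pattern
value, so the time-integrated activity seen by the scanner is proportional
to the pattern. Travel between positions is capped at 2 mm/s (the physical
constraint that avoids surface waves in the tank).

Model assumptions, in decreasing order of consequence:

* **The source is a point.** Its 0.25 mm diameter is far below every voxel
  size and every PSF width in play, so it is rendered as a delta deposit in
  the fine-grid cell containing each waypoint.
* **Travel deposits nothing.** Dwell times dominate travel times and
  ignoring travel makes the painted total exactly conserved:
  `Σ painted = source_activity × Σ dwell`, which the test suite asserts to
  machine precision. The physical measurement does accumulate a faint trace
  along the trajectory; this surrogate does not.
* **²²Na decay is neglected** over a ≤3 h measurement (half-life 2.6 y) —
  the same argument that motivates using ²²Na in the first place.
* **Background decay is exact ¹⁸F decay** (half-life 6586.2 s). Each
  acquisition uses the time-averaged decayed concentration over its window.
  Session start times are anchored to the logged per-session start
  activities, which already encode the between-scan gaps: propagating the
  last session's activity through its acquisition gives an end-of-measurement
  background of ≈49 % of the initial value, consistent with the reported
  ~50 % decline. Lesion-to-background contrast consequently differs across
  the three sequential sessions (longer acquisitions spread the same painted
  activity over more time while the background SUV stays near 1).

## Lesion generation

The three canonical templates are lumpy Gaussian-blob mixtures on a 2.5 mm
painting grid (21³ positions; the grid pitch is a configurable default
chosen to be comparable to the reconstruction voxel sizes). A mixture field
is thresholded to the target volume by keeping the densest cells:
`L1` = 8.66 mL from 2 broad blobs (compact, mildly heterogeneous),
`L2` = 11.55 mL from 5 blobs, `L3` = 15.44 mL from 9 narrow blobs with
wide amplitude spread (most complex). Volumes are exact up to grid
quantization (±half a cell, <0.5 %). Generation is deterministic per seed;
the three presets use fixed seed offsets so one experiment seed yields three
distinct lesions.

## The scanner surrogate

Iterative reconstruction algorithms are deliberately not emulated. Each of
the eight settings `A`–`H` is characterised by what it does to the image:

| code | voxel size (mm) | post-filter FWHM | effective PSF FWHM* | noise scale |
|------|-----------------|------------------|---------------------|-------------|
| A | 2.67 iso | 5.0 | 5.5 | 0.30 |
| B | 4×4×3 | 5.0 | 6.0 | 0.30 |
| C | 3.0 iso | — | 6.0 | 0.28 |
| D | 2.73 iso | 6.4 | 6.3 | 0.25 |
| E | 3.64 iso | 4.4 | 6.5 | 0.27 |
| F | 4.0 iso | — | 5.2 | 0.30 |
| G | 2.73 iso | — | 4.0 | 0.20 |
| H | 2.73 iso | 3.2 | 4.4 | 0.22 |

\* the effective PSF values are **assumptions**, not measurements: a 4–7 mm
band with the digital scanner (G/H) sharpest, configurable per setting.

Rendering pipeline: Gaussian blur at the PSF FWHM on the 1 mm fine grid →
trilinear sampling onto the setting's voxel grid (point sampling is adequate
because the field is already smooth at ≥4 mm scale) → additive Gaussian
noise with variance proportional to local intensity (a post-reconstruction
Poisson surrogate), scaled by `noise_scale × sqrt(reference_exposure /
(activity × acquisition_time))` so later, longer sessions at lower activity
are noisier per unit signal → Gaussian post-filter → SUV conversion.

SUV normalisation uses the tank water mass as "body weight"
(`SUV = concentration / (injected activity / mass)`, 1 g/mL), so a uniform
tank at session start reads SUV 1. Image grids are centred on the painting
cube; with even voxel counts a voxel boundary (not a centre) falls on the
cube centre.

## VOI, resampling, discretization

Manual contouring is replaced by ground-truth masks: the template support is
transferred to each image grid with a ≥50 % occupancy rule (each voxel
probed on a 4³ subgrid; the voxel joins the VOI when at least half the
probes land inside the support). This removes contouring variability by
design — which is why volume-driven indices (Volume, TLG) are much more
stable here than in a manually contoured study. A threshold mode is kept for
sensitivity experiments.

Spatial resampling (trilinear for intensities, nearest-neighbour for masks)
precedes discretization, matching the common radiomics processing chain;
the order is a documented assumption. Both discretizations use the
floor-plus-one convention with a top-edge clamp; the printed equations of
the FBS/FBN schemes omit the rounding operator, and this choice reproduces
the `I = I_max → level D` branch exactly. FBS defaults to B = 0.3125 SUV,
FBN to D = 64.

## Feature definitions

The 46-index catalogue is frozen in `petpaint/registry.py`. The
definitions follow the LIFEx-style conventions widespread in PET radiomics;
none of the formulas are exotic:

* **Conventional**: population SD for SUVstd; TLG = SUVmean × volume (mL);
  SUVpeak = mean over a 1 mL sphere (radius 6.204 mm, voxel-centre
  inclusion) centred on the hottest voxel and intersected with the VOI
  (with a warning when the sphere is clipped). MATV ≡ SHAPE_Volume_mL —
  the catalogue counts volume once.
* **Shape**: surface area from a marching-cubes mesh of the binary mask.
  Sphericity = π^⅓(6V)^⅔/A; Compacity = V/(√π A^{3/2}). The binary-mesh
  convention overestimates the area of a digitized ball by a few percent
  (staircase facets), so a radius-10-voxel ball scores ≈0.91 rather than
  1.0; smoothing the mask before meshing would push sphericity above 1 and
  was rejected to preserve the (0,1] range.
* **Histogram**: population skewness, plain (non-excess) kurtosis, entropy
  in both log bases over the occupied-level histogram, energy = Σp².
* **GLCM**: symmetric co-occurrences at distance 1, counts merged over the
  13 unique 3-D directions, then normalised. Correlation of a degenerate
  (single-level) matrix is reported as 0 with a warning; entropy 0.
* **GLRLM**: maximal equal-level runs per direction, counts merged over the
  13 directions; run percentage divides by voxels × directions (so a
  single-direction matrix reproduces the textbook `RP = runs/voxels`).
* **NGLDM**: 26-neighbourhood mean-difference statistics (coarseness,
  contrast, busyness); neighbourhoods are restricted to in-VOI voxels, and
  a perfectly uniform VOI has its infinite coarseness capped at 10⁶.
* **GLZLM**: zones are 26-connected equal-level components; same index
  algebra as GLRLM with zone size in place of run length.

Every matrix builder is verified against independent brute-force oracles
(pair enumeration, per-line run-length encoding, BFS flood fill, per-voxel
neighbour loops) on >100 random volumes at 10⁻¹⁰ tolerance.

## Robustness statistics

* **Relative difference**: `(X_i − X_D)/X_D × 100` against the (arbitrary)
  reference setting D; undefined at zero reference, reported missing.
* **CV**: sample (n−1) standard deviation over mean × 100 across the eight
  settings — the estimator is configurable since the convention is not
  universal. 46 × 3 lesions × 2 discretizations = 276 values per run.
* **ICC**: two-way ANOVA mean squares with lesions as targets (n = 3) and
  settings as raters (k = 8) plugged into the absolute-agreement
  single-measurement form. Negative estimates are reported as-is.
  Cross-checked against an independent implementation (pingouin ICC(A,1))
  at 10⁻¹⁰.
* **Wilcoxon rank-sum** between lesion pairs uses the eight per-setting
  values per group; p-values are exact (full enumeration of rank-sum
  assignments with mid-rank ties) for groups ≤10, normal approximation
  beyond. The paired signed-rank variant is available but not the primary
  test. BH-FDR is applied jointly to all index × lesion-pair tests within
  one discretization — the family boundary is a documented assumption.

## Problem sizes and numerical choices

Default runs paint on a 1 mm fine grid over an 80 mm box (margin 15 mm
around the cube), which keeps a full 3 × 8 × 2 study under ~20 s on one
core while the fine grid stays ≳2.7× finer than every voxel size. Blur
kernels use `mode="nearest"` boundaries; resampling to the identical grid
is idempotent to 10⁻⁶; ties in lesion thresholding are broken by flat index
so generation is bit-reproducible; all noise flows through
`numpy.random.default_rng` seeded per (lesion, setting) from the experiment
seed.

## What the synthetic data does and does not show

The generator emulates: heterogeneous lesions of the documented volumes,
session-to-session background decay, voxel-size/PSF/filter differences
between settings, and exposure-dependent noise. It does **not** emulate:
scatter and attenuation physics, reconstruction-algorithm artefacts
(OSEM/RAMLA/penalised-likelihood behaviour), manual contouring variability,
repositioning effects, or water motion. Passing tests therefore demonstrate
the internal consistency of the analysis chain and the direction of
setting-driven effects (blur lowers SUVmax and GLCM contrast, zone-length
indices are the most setting-sensitive family, absolute discretization is
more repeatable), not the numerical CV/ICC values of any physical scanner
fleet. In particular, volume-linked indices are markedly more stable here
than in the physical study because ground-truth masks remove contouring
variability, which narrows the CV gap between SUVmean and SUVpeak.

## Known limitations

* Effective per-setting resolution is assumed, not fitted to published NEMA
  data; absolute CV levels shift with those assumptions (orderings are
  robust across seeds and were the design target).
* The exact Wilcoxon enumeration is O(C(16,8)) per test — fine at the
  study's sample sizes, unsuitable for large groups (the normal
  approximation takes over automatically).
* The painted map ignores source travel and water displacement; contrast is
  controlled by `base_dwell`, not calibrated to an absolute count-rate
  model.
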