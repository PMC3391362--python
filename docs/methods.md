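# Methods

This note documents the models and procedures implemented in `cenarea`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## The measurement procedure

A cell is measured on the 2D maximum-intensity projection of its CENH3
channel. Maximum projection (rather than sum or mean) is the standard
choice for punctate signals: it preserves each focus's peak over the
diffuse background regardless of its z position.

The threshold is **one grey level above the brightest non-centromeric
pixel in the cell**: `T = max(projection[background]) + 1`, and the mask is
`projection >= T`, i.e. exactly the pixels strictly brighter than every
background pixel. "One grey level" means one unit of the stored integer
image, whatever its bit depth; the threshold is chosen per cell, never per
slide or batch. Components are 8-connected by default (conventional for
projected spot counting; configurable), and the headline statistic is
thresholded **area** in projected pixels. Integrated intensity is
deliberately not used: area is robust to exposure differences — rescaling
all intensities by a positive integer and re-deriving the threshold from
the same background region reproduces the identical mask — whereas
intensity is not. No physical pixel calibration is applied; areas are
comparable only within a study.

What counts as "non-centromeric" is the procedure's one judgment call. The
package accepts three sources, in priority order:

1. **ground truth** (synthetic mode): the complement of the rendered truth
   mask;
2. **annotation**: a user-supplied boolean mask, standing in for the
   operator's manual judgment;
3. **auto**: candidate foci by Otsu thresholding, dilated by 3 px
   (configurable), background = complement. This is a reproducible stand-in
   for a manual step, and every measurement records which source produced
   its threshold.

Species are summarized by the mean and sample SD (ddof = 1) of per-cell
total areas. The design minimum is 20 cells per species; fewer cells
produce a warning, not an error. All-pairs species comparisons use Welch's
two-sample *t* test (the robust default when variances differ) at
alpha = 0.01, two-sided; a species is "distinct" when it differs from every
other species. Raw p-values are used by default, mirroring the convention
of reporting uncorrected p < 0.01 in this literature; this is a known
multiplicity caveat, and a Holm step-down adjustment is available behind a
flag.

### Addition-line colocalization

In a host cell carrying alien centromeres, the FISH channel is projected
and thresholded (threshold supplied by the caller, since FISH background
behaves differently from immunostaining), and a CENH3 component is labeled
*alien* when the fraction of its pixels inside the FISH mask strictly
exceeds `min_overlap_fraction` (default 0: any overlapping pixel
suffices). Alien areas are compared against per-cell *mean* host areas —
one number per cell, so a cell with 41 host centromeres contributes a
single host observation — by Welch's *t* test, reported with the ratio of
means.

## The synthetic imaging model

`render_cell` produces stacks with exact ground truth. The model is
deliberately minimal:

- **Foci** are hard spheres of constant intensity (radius and peak drawn
  uniformly per focus), placed with centres laterally inside a nuclear
  ellipse (semi-axes 0.4× the image width/height) and rejected until the
  projected footprints are disjoint — sphere surfaces keep a lateral
  clearance of `2 + 4·blur_sigma` pixels so blur cannot merge neighbouring
  footprints. Placement failure after 500 tries per focus is an error
  (the image is too crowded), never a silent overlap.
- **Optics** are a single isotropic Gaussian blur applied to the focus
  layer. No point-spread-function model, no deconvolution.
- **Background** is a smoothed Gaussian random field rescaled so its
  maximum is *exactly* `background_max`. The CENH3 channel is the voxelwise
  maximum of background and (blurred) foci, so on a noiseless render the
  correct threshold is exactly `background_max + 1` — the threshold rule is
  testable to the grey level.
- **Noise** is Poisson per voxel (shot noise), applied last.
- **Ground truth** is taken from the pre-noise stack: the truth mask is the
  set of projected pixels whose noiseless projected intensity exceeds
  `background_max`. With `blur_sigma = 0` and no noise, measurement must
  reproduce the truth area *exactly* (and does, enforced by test); with the
  default 1-voxel blur and Poisson noise, the mean relative area error over
  20 default cells is ~3%, bounded at 10% by test.

Defaults: 16×128×128 voxels, 20 foci of radius 2–4 px, peaks 1500–3000,
background max 300, 12-bit depth (typical scientific CCD), blur sigma 1,
Poisson noise. The DAPI channel is a filled nuclear ellipsoid, rendered for
realism only; no statistic consumes it.

What the synthetic data does **not** emulate: real point-spread functions
and deconvolution artifacts, chromatic shifts between channels,
non-centromeric bright debris, antibody-affinity differences between
species, or metaphase morphology. Passing the ground-truth tests therefore
establishes that the *measurement rule* is implemented correctly and is
robust to blur and shot noise — not that the rule is unbiased on any
particular real microscope.

`render_addition_line_cell` adds a FISH channel containing only the alien
foci (zero elsewhere before noise) and labels every focus host/alien in the
ground truth. The default geometry — 41 host + 1 alien focus — emulates one
cell of an oat line (2n = 42) carrying a single added maize chromosome,
with host and alien sizes equal by default (the regime in which the two
classes should be statistically indistinguishable).

## The species-panel simulator

`simulate_species_panel` generates the study conditions for the statistics
layer: genome sizes log-uniform over 400–16,000 Mb (grass genome sizes span
more than 30-fold; the bounds bracket rice and hexaploid wheat), haploid
chromosome numbers uniform integers over 7–21 (the span of the ten grass
study species), drawn *independently* of genome size, and

    total_centromere_area = intercept + slope·G + Normal(0, noise_sd)

with defaults slope = 0.1 area-units/Mb, intercept = 100 (a nonzero
minimum centromere size; the intercept is exposed as a free parameter, not
pinned to zero, because whether the relation passes through the origin is
itself a question of interest), noise_sd = 50. These defaults put simulated
panels in the empirically reported regime — genome-size R² ≈ 0.985 with
chromosome number uninformative — so the qualitative ordering
R²(G) > R²(n) is a property of the generating process, not of a tuned test.

`partition_centromere_budget` splits a total area into equal
per-centromere shares (the limiting-component idealization), with an
optional mean-preserving Gaussian dispersion; the sum is conserved exactly
by construction.

## Phylogenetically independent contrasts

The contrasts recursion is implemented from scratch (tree I/O is delegated
to dendropy). Conventions:

- **Standardization**: contrast `(x1 − x2)/√(v1 + v2)` with `v` the
  branch lengths adjusted by the pruning rule `v_parent += v1·v2/(v1+v2)`;
  ancestral values are the variance-weighted averages, computed in the
  form `(x1·v2 + x2·v1)/(v1 + v2)`, which stays finite when one sister
  branch has zero length. Two zero-length sisters (zero combined variance)
  are an error.
- **Regression**: least squares through the origin on standardized
  contrasts, each pair positivized so the x-contrast is non-negative (sign
  flips applied jointly to x and y) — the standard convention, since
  contrast signs are arbitrary. R² is computed about zero and the slope
  test uses n_contrasts − 1 degrees of freedom.
- **Node identity**: each contrast is keyed by the sorted tuple of its
  descendant tip names, so contrast sets computed on the same tree align
  without reference to node order.
- **Polytomies** are resolved arbitrarily into zero-length bifurcations
  with a warning. The packaged grass tree is strictly bifurcating, so this
  path is defensive only.
- **Branch lengths** are used exactly as given; no rate smoothing,
  ultrametricization, or transformation.

Correctness is established two independent ways: closed-form two-tip
cases, and the identity between the contrasts regression slope and the
generalized-least-squares slope under the Brownian covariance matrix
(V[i,j] = shared root-to-tip path length), which holds to machine
precision on random trees; the root ancestral value likewise equals the
GLS minimum-variance root estimate. The Brownian simulator (per-branch
Normal(0, σ²·length) increments, optionally bivariate with correlated
increments via a Cholesky factor) provides calibration checks: the slope
test's type-I error is nominal, and under correlated evolution with true
slope ρ·σy/σx the mean fitted slope over 500 replicates recovers the truth
within 2%.

### The printed grass tree

The ten-taxon grass phylogeny ships in two text forms: the verbatim
printed text and a normalized standard Newick file. The printed dialect
attaches branch lengths as `name, length` (comma, not colon), separates
sister taxa with semicolons, and juxtaposes a clade after its sister's
branch length with no separator. `normalize_printed_newick` rewrites it —
semicolons to sibling commas, `", length"` to `":length"`, a comma
inserted between a branch length and a following `(` — and the result
parses to a strictly bifurcating 10-tip tree (sorghum, maize,
Z. luxurians, foxtail millet, pearl millet, oat, barley, rye, wheat,
rice), yielding exactly 9 contrasts. This normalization is this package's
reading of a nonstandard notation; both fixture forms are packaged so the
reading is auditable, and parsing either form produces the identical tree.

## Regression machinery

`fit_ols` wraps a standard OLS fit (statsmodels) behind a single result
container used by every analysis. With an intercept: R² about the mean,
p-value from the F test of the slope on (1, n−2) df. Through the origin:
uncentred R², (1, n−1) df. Degenerate designs (zero predictor variance, or
an identically-zero predictor in the no-intercept case) are errors, not
NaNs. Species enter regressions with equal weight and untransformed
predictors. The positive-intercept question ("is there a minimum
centromere size?") is a one-sided t test of the intercept on n−2 df. A
leave-one-out R² diagnostic is provided because small cross-species panels
are leverage-prone: in the packaged ten-species microtubule table,
removing the one giant-genome plant (Haemanthus) moves R² from 0.92 to
0.82 — the relationship is real but its tightness leans on the extreme
point.

Displayed average chromosome sizes round to one decimal with ties going
*away from zero* (165/4 = 41.25 → 41.3), matching how printed karyotype
tables round; raw quotients are used in all computation.

## The pipeline

`run_pipeline` chains simulate → render → quantify → summarize → compare →
regress → contrasts. One global seed is expanded into named per-stage
substreams (numpy `SeedSequence.spawn`), so any stage is reproducible in
isolation and the whole JSON report is byte-identical for a fixed
configuration. When the panel uses the grass species names, the contrasts
stage runs on the packaged tree; otherwise it is skipped and says so. Each
species' cells are rendered with 2n foci whose radius is chosen so the
expected *measured* footprint matches the species' configured area budget
(the above-threshold footprint of a blurred sphere is wider than the
sphere, by roughly 0.7·sigma of radius, and the mapping saturates for
areas demanding radii outside ~1–5 px — a documented fidelity limit of the
demo, not of the measurement).

## Problem sizes

The test suite and the acceptance script use: 200 simulated panels for the
predictor-ordering rate; 500 Brownian replicates for slope recovery and
2000 for type-I error on the grass tree; 50 random trees (≤ 8 tips) for
the PIC–GLS identity; 20 default-render cells for measurement error and
100 random images for the monotonicity/exposure invariants; 8 rendered
addition-line cells (42 foci each) for label recovery and 500 simulated
replicates for the equal-size false-positive rate. These sizes give Monte
Carlo standard errors comfortably inside the asserted tolerances while
keeping a full run to seconds.

## Known limitations

- The area unit is the projected pixel; cross-study comparison requires a
  shared optical configuration, which the package does not model.
- The automatic background mode is a stand-in for operator judgment; on
  images whose foci Otsu cannot separate it will misplace the threshold.
  Its provenance string is attached to every measurement for audit.
- The pairwise species comparison runs uncorrected by default (by
  convention for this analysis); with ten species that is 45 tests at
  alpha = 0.01.
- Contrasts assume Brownian evolution on a correct, fully resolved tree
  with meaningful branch lengths; none of these assumptions is tested by
  the package.
- The demo pipeline's configured-to-measured area mapping compresses at
  the extremes of focus size (radius clipped to what the stack geometry
  holds), so panels spanning a narrow area range reproduce the configured
  relation less faithfully than panels spanning the full realistic range.
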