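# Methods

`plaquekit` reimplements, as a tested pipeline, the quantitative procedures of a
two-timepoint amyloid-plaque imaging and transcriptomics study in APP/PS1 mice
carrying human APOE isoforms with or without Trem2: 3D plaque growth and
microglial-barrier morphometry, 2D plaque-compaction / radial-glia / FISH
quantification, a weighted co-expression module–trait workflow, and the study's
comparison statistics. Every component is exercisable on synthetic data with
known ground truth; this note records the models, the parameters that matter,
and the design choices made where the procedure was genuinely open.

## 3D volumetry model

A stack is a set of named intensity channels (X04, TR, IBA1) on a common
`(z, y, x)` grid with per-axis voxel sizes in µm (default z step 1.5 µm,
lateral 0.5 µm). The analysis voxelizes the original surface-based procedure:

1. **Background removal** — voxels below a fixed intensity floor (default 500
   on a 12-bit scale) are zeroed in every channel.
2. **Segmentation** — connected components (26-connectivity by default, the
   closest voxel analogue of surfaces that merge diagonal contacts) of the
   thresholded channel; components under `min_object_voxels` (default 10) are
   dropped. The object threshold defaults to the background floor; Otsu is
   available as a method tag.
3. **Surface area** — the sum of exposed voxel faces, each weighted by its
   physical area (`dy·dx` for a face perpendicular to z, etc.), so anisotropic
   voxels are handled exactly. Faces on the image border count as exposed.
4. **Shell** — the one-voxel 26-neighborhood dilation of the object minus the
   object, clipped at image bounds ("1 voxel" is a voxel-space notion, so the
   structuring element is defined in voxel space, not µm).
5. **Percent surface contact** — contacted shell voxels over total shell
   voxels × 100. The source procedure divides a voxel count by a surface
   *area*, which mixes units; the shell-voxel fraction is the dimensionless
   quantity in [0, 100] that the downstream "exposed area" formula needs.
   **Exposed surface area** = face-based surface area × (1 − contact/100).
6. **Matching** — each TR object is paired to the X04 object of maximal voxel
   overlap (greedy one-to-one, ties by overlap fraction then lower id). TR
   objects without X04 overlap are reported as new deposits: growth equals
   their full TR volume and fold change is missing; they are excluded from the
   control regression.
7. **Growth** = TR volume − X04 volume, **fold change** = TR/X04. The study
   text states the subtraction in both directions in different places; the
   supplementary definition ("growth (TR−X04)", "fold change (TR/X04)") fixes
   the sign used here.
8. **Inclusion filters** — plaques at least 50 µm from the tissue edge and
   50 µm from other plaques. Edge distance is measured to the lateral (y, x)
   borders only: the z extent of a confocal stack of a 30 µm section cannot
   honor a 50 µm margin, and the rule concerns the tissue edge. Neighbor
   distance is boundary-to-boundary via KD-trees on boundary voxels
   (deterministic and stricter than centroid distance). Filters only flag;
   kept + rejected always partitions the input, one primary reason each.
9. **Control calibration** — on a zero-growth cohort, OLS of TR volume on X04
   volume; R² is the squared Pearson correlation, alongside mean growth and
   mean fold change.

## Synthetic stacks

The generator plants spherical X04 cores (radius 3–8 µm by default) whose TR
object is the same sphere enlarged by a growth thickness (0–2 µm by default;
exactly 0 for the 48-h control condition). Truth volumes are **counted on the
discretized noise-free masks** (voxels whose center falls inside the sphere),
not from 4πr³/3, so discretization never enters the recovery error budget.

The IBA1 barrier is an exact angular cap: the true TR shell is ranked by polar
angle about a random axis and the first `round(f·N)` voxels define the covered
fraction, which is therefore exact by construction. The painted IBA1 signal
fills the whole angular sector of a radial band from 0.5 µm inside to 2.5 µm
outside the TR surface; the radial thickness absorbs the ~half-voxel dilation
that thresholding a blurred edge produces, while the angular boundary — the
quantity the coverage fraction measures — stays put. This keeps planted
coverage recoverable to ~1–3 percentage points under the default blur/noise.

Rendering: intensities on a 12-bit scale (plaque 2000, background 100) so the
conventional floor of 500 is meaningful; Gaussian blur of σ = 0.3 µm (a
compromise between the ~0.1 µm lateral and ~0.6 µm axial PSF widths of a high-NA
confocal) applied before additive Gaussian noise (SD 50, truncated at 0), then
integer quantization. Blur is computed on the bounding box of the painted
signal plus a 4σ margin, which is exactly equivalent to a full-stack blur of a
field that is zero elsewhere. Identical spec + seed is bit-identical; cohorts
derive per-plaque seeds by `SeedSequence` spawning. Plaque placement is seeded
rejection sampling with bounded retries; an infeasible spacing constraint
raises a placement error naming the constraint.

Default stack geometry (24 × 264 × 264 voxels at 1.5 × 0.5 × 0.5 µm) holds one
plaque at least 50 µm from the lateral borders — the study's selection margin —
within a section-like z extent. Cohorts are sequences of single-plaque stacks;
multi-plaque stacks with a minimum center separation are supported for the
matching and inclusion-filter paths.

The coupled cohort draws the growth thickness as an affine function of the
standardized uncovered shell fraction plus independent noise, giving a latent
growth–exposure correlation of 0.9 by default; clipping at zero growth is the
only departure from exact correlation.

What the generator does **not** emulate: realistic microglial morphology,
optical sectioning physics, bleed-through, autofluorescence, non-spherical
plaques. Passing recovery tests therefore demonstrates the correctness of the
measurement code under the stated imaging model, not robustness to real-tissue
artifacts.

## 2D histology and FISH

Slides are named 2D channels with a µm pixel size. Operations:

* **Thresholded area** in an ROI: positive pixels × pixel area, and percent of
  the ROI.
* **Compaction**: OC/X34 area ratio; an OC connected component is core-bound
  iff it shares ≥1 pixel with X34 (no extra distance parameter), and the
  non-core-bound OC percent is the OC area in coreless components over total
  OC. Conventions: no OC → ratio 0, noncore 0; OC without any X34 → ratio
  missing, noncore 100.
* **Radial cell counts**: cells are counted by centroid; the distance of a
  centroid to the plaque is the distance to the nearest plaque-positive pixel
  center (KD-tree; exactly the brute-force definition). "10/20/40/60 µm from
  the edge" is read as cumulative distance bands from the plaque edge — a
  literal reading as diameters is incompatible with "from the edge" — and a
  per-annulus table is emitted alongside. Cells inside the plaque mask are
  excluded.
* **Plaque-associated marker area**: marker-positive pixels within the plaque
  mask dilated by a Euclidean association radius (default 0 = overlap only).
* **FISH near/far**: near coverage is the puncta-positive fraction of the
  50 µm disc about the plaque center; far is the mean over 4 seeded random
  discs of identical area placed fully in-image and entirely outside every
  plaque ROI (center > 2 × radius from every plaque center, so the background
  area lies wholly beyond 50 µm of any plaque). Background discs may overlap
  each other; placement failure after bounded retries is an error.
* **Apoe per microglia**: summed Apoe intensity over Tmem119-positive cell
  regions inside the ROI divided by the number of such cells (a cell belongs
  to the ROI if any pixel intersects it); zero cells yields a missing value,
  not zero. Whether intensity should be summed over whole cells instead is
  configurable by passing an ROI covering the full image.

The slide generator plants disc cores and halos, a marker channel positive on
an exact pixel fraction of each halo, nuclei at analytically known distances
from the nearest core edge, and homogeneous Poisson puncta at separate
densities inside/outside the 50 µm near region (defaults 0.010/0.005 per µm²,
2-pixel-scale puncta). All truth quantities are recorded exactly or by
construction.

## Co-expression workflow

Input is a genes × samples matrix of normalized log-scale values with sample
annotations (APOE, Trem2, APP, sex, batch). Steps, with the study's stated
parameters as defaults:

1. **Covariate removal**: per-gene least squares on retained + unwanted
   covariates jointly; only the fitted unwanted contribution (default: batch)
   is subtracted. The original pipeline used an empirical-Bayes-moderated
   regression whose moderation details are unspecified; plain least squares is
   used here (the subtraction step is identical in expectation), and a
   collinear design raises an error naming the aliased columns.
2. **Adjacency**: unsigned `a_ij = |r_ij|^β`, β = 10. Signed networks were not
   specified; unsigned is the referenced tool's default.
3. **TOM**: `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.
4. **Modules**: average-linkage clustering of 1 − TOM, flat cut at height
   0.995 by default, minimum module size 44, then iterative merging of modules
   whose eigengene dissimilarity 1 − r falls below 0.25. The original
   "automatic" dynamic tree cut is unspecified; a fixed high static cut is
   deterministic and testable. On the synthetic design the choice is
   uncritical: genuine modules complete near dissimilarity 0.89 while
   unclustered background pairs sit at ≈ 1.0 and coalesce only in the last
   merges. (A scan that maximizes the count of min-size clusters was
   considered and rejected: near the dendrogram root the noise background
   coalesces into large clusters and the scan lands there.)
5. **Eigengene**: first principal component of the gene-standardized module
   submatrix, unit norm, sign-aligned to correlate positively with the module
   mean profile.
6. **Module–trait correlation**: Pearson r with the t-transform two-sided p
   (n − 2 df), significance at p < 0.05; constant traits give missing values.
7. **GS / MM**: absolute gene–trait and gene–eigengene correlations.
8. **Hubs**: genes with GS > 0.2 and MM > 0.8, ranked by MM (ties by
   intramodular connectivity then id), top 5; the hub edge list exports all
   adjacency entries from hubs into the module at or above a threshold.
9. **Eigengene–phenotype correlation** per genotype group (e.g. amyloid
   coverage within each APP group); groups under 3 samples give missing
   values with a warning.

The expression generator reproduces the study's eight genotype groups and
sample sizes (total n = 88). Each planted module follows
`x_g = loading_g · s · L + batch + noise` with effect size s = 2 (expected
within-module correlation s²/(s²+1) = 0.8), latent–trait correlation 0.7,
loadings ~ N(1, 0.3); the first five genes of each module carry a fixed high
loading (2.0, with non-hub loadings clipped below it) so planted hubs are
unambiguous. Per-sample amyloid coverage is generated for APP samples, coupled
within-group to the first module's latent at r = 0.8 except in the designated
uncoupled group (APP/E3/Trem2-knockout), mirroring the study's contrast of a
present versus absent eigengene–pathology correlation.

## Statistics and behavior

Two-way between-subject ANOVA uses Type III sums of squares with sum-to-zero
coding (the convention of the GraphPad-style analysis of unbalanced designs;
identical to the classical decomposition when balanced), followed by
Sidak-adjusted pairwise comparisons (`p_adj = 1 − (1 − p)^m`) with the pooled
residual variance. The default family compares the levels of each factor
within each level of the other (each direction one family, m logged per
comparison); an all-cell-pairs family is available, since the original family
definition is unstated. One-way ANOVA is followed by Tukey's HSD via the
studentized-range distribution with the Tukey–Kramer standard error. Degenerate
conventions: zero between-group SS → F = 0, p = 1 (even when the residual is
also zero); zero residual with a real effect → F = ∞, p = 0. Group summaries
report mean ± SEM (sd/√n).

Behavioral scores: NOR percent exploration = 100 × novel/(novel + familiar),
excluded when total exploration < 10 s; percent freezing = 100 ×
freezing/duration, excluded only when *contextual* freezing < 30 s. Exclusion
rules set flags and never mutate or drop records.

## Reproducibility and problem sizes

One global seed drives everything: the pipeline derives per-stage seeds by
hashing the stage name, generators derive per-item seeds by `SeedSequence`
spawning, and CSV output is written at full double precision so reruns are
checksum-identical. The test suite and the acceptance script use cohorts of
100 zero-growth plaques, 20 plaques per planted coverage fraction, 10 × 20
plaques for the growth–exposure coupling, 100 random ≤12³ voxel grids for the
brute-force oracles, 50–100 seeded slides for the FISH properties, and 5–20
replicates of the 2 000-gene / 88-sample expression design — sizes chosen so
each property is measured with comfortable statistical margin on a single CPU.

## Known limitations

* The voxel-face surface area overestimates the area of smooth surfaces (a
  digitized sphere's face area converges to 1.5 × the true area); all
  surface-derived quantities are therefore internally consistent voxel-space
  measures, as in the original voxel-counting contact procedure, not
  mesh-accurate areas.
* Volumes of blurred objects are recovered with a small positive bias (the
  threshold sits below the half-maximum of the edge response); growth and fold
  change, being differences/ratios of identically biased X04 and TR measures
  under zero growth, are unbiased, which is exactly what the control
  calibration checks.
* The dynamic tree cut, signed-network, and moderated-regression variants of
  the original transcriptomic pipeline are approximated by deterministic
  counterparts (fixed static cut, unsigned network, plain least squares); the
  published module list from the real data is out of scope.
* 3D microglia are modeled only as a shell-coverage pattern; no cell-level
  morphology or counting in 3D is attempted.
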