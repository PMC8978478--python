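# Methods

## The pothole/molehill model

The pipeline quantifies *spatially independent* white-matter anomalies in a
cohort of aligned fractional-anisotropy (FA) volumes.  FA is a scalar in
[0, 1] from the diffusion tensor; organized white matter has high FA.  With
volumes `F_i`, i = 1..n, on one grid, the cohort reference is the voxel-wise
mean `m(v)` and sample SD `s(v)` (n−1 denominator; every subject contributes
to its own reference).  Analysis is restricted to the white-matter mask

    M = { v : m(v) > 0.2  and  s(v) > 0 },

with a strict inequality at the FA threshold, and each subject gets a z-map
`z_i(v) = (F_i(v) − m(v)) / s(v)` on M (NaN off-mask).

A **pothole** is a maximal connected component of `{v : z_i(v) < −2}`; a
**molehill** the mirror component of `{v : z_i(v) > +2}` (both strict).
Clusters are filtered by physical volume — voxel count × voxel volume from
the image header, never assumed isotropic — at the minimum-size ladder
25, 50, 100, 200 mm³, again with strict ">".  The per-subject counts by
polarity and size are the imaging phenotype.  Clusters are localized by
assigning each to the atlas tract owning the plurality of its voxels (ties
to the lowest label id; zero overlap goes to an "unassigned" bucket), which
makes the tract table an exact decomposition of the global counts; an
any-overlap rule is available when double-counting spanning clusters is
preferred.

The genetic exposure is a thresholded additive polygenic risk score:
`PRS_i = Σ_j d_ij β_j` over variants with discovery GWAS p-value strictly
below P_T = 0.01, with optional exclusion of listed variant ids and of
half-open genomic regions (MHC default chr6:25–35 Mb, a conventional
boundary).  Scores are standardized over the analyzed subjects, so
regression coefficients are "scaled" betas: count units per SD of genetic
risk.

Associations are ordinary least-squares regressions of counts (counts are
left in natural units; a Poisson-family option exists for sensitivity but is
not part of the primary surface).  Effect size is ΔR², the R² increment of
the full over the exposure-dropped model on identical rows (listwise
deletion).  Multiple testing is controlled per family with
Benjamini–Hochberg FDR: 16 tests for the descriptive sex/age suite (sex and
age mutually adjusted), 8 for the PRS suite (adjusted for age, sex, and 10
genetic principal components), and 17 for the post hoc tract suite, where
handedness enters as a covariate only for lateralized tracts.

## Numerical and design choices

- **Connectivity** defaults to 26 (faces + edges + corners), the common
  convention for cluster thresholding in neuroimaging; 6 and 18 are
  selectable and recorded in the run manifest.
- **Strict thresholds** everywhere the method states an inequality (mask
  FA > 0.2, |z| > 2, volume > 25 mm³, GWAS p < P_T); each is configurable,
  and the cluster thresholds can be relaxed to "≥" for sensitivity checks.
- **Deterministic ordering**: clusters are emitted by descending volume,
  ties by lexicographically smallest voxel coordinate, so output tables are
  byte-stable across reruns.
- **sd = 0 voxels** are excluded from the mask rather than producing
  infinite z.
- **Degenerate outcomes**: if a count outcome is constant across subjects
  (common for large volume thresholds in small cohorts), the regression
  reports beta 0, p 1, ΔR² 0 instead of NaN, keeping suite-level FDR
  well-defined.
- **Counts under stricter z thresholds** are not guaranteed monotone
  cluster-wise (a cluster can split); the guaranteed and tested invariants
  are monotonicity along the volume ladder and shrinkage of the
  suprathreshold voxel set.
- **Sex is coded female = 1 / male = 0**, so sex betas are female-vs-male
  differences; handedness right = 1; maternal education ordinal 0/1/2.
- **ΔR² convention**: the outcome is not standardized; "scaled" refers to
  the standardized score only.  A fully standardized variant can be obtained
  by z-scoring the counts before calling the suite.

## The synthetic cohort

Real cohort data are not redistributable, so the generator produces cohorts
with planted truth:

- **Template**: a 17-region toy geometry (one midline corpus-callosum-like
  slab, 8 left/right tract pairs) with FA 0.55 in tracts over 0.08
  background, Gaussian-smoothed (σ = 1 voxel).  Default grid 32³ at 2 mm
  isotropic — big enough to host hundreds of plantable voxels per tract
  while keeping a 100-subject cohort ~130 MB in memory.
- **Subjects**: template + i.i.d. Gaussian voxel noise (default
  noise_sd = 0.02 FA units, the order of within-tract FA variability),
  clipped to [0, 1].
- **Plants**: contiguous voxel sets grown by randomized 6-neighbor
  accretion inside the region with template FA > 0.25 (the 0.2 mask
  threshold plus a 0.05 margin so sampling noise cannot push planted voxels
  off-mask), shifted by ±magnitude·noise_sd.  Magnitude is specified in
  noise-SD units so the expected planted z is ≈ ±magnitude; plants slightly
  inflate the reference SD (by a factor ≈ √(1 + magnitude²/(n−1)), ~8% at
  magnitude 6, n = 100), which is why detection tests use magnitude 6, far
  from the ±2 threshold.
- **Genetics**: dosages Binomial(2, maf) with maf uniform on [0.05, 0.5];
  weights N(0, 0.1) with log-uniform p-values over 10⁻⁸–1 (the shape of a
  pruned GWAS hit list).  The first variant is named rs3135388, placed in
  the MHC with the largest effect and smallest p, so the exclusion
  sensitivity analyses have a real target.
- **Score-count link**: molehill counts per subject are
  Poisson(λ₀ + b·score) with λ₀ = 26 (the reported median molehill count at
  the 25 mm³ size) and b derived from a target ΔR² via
  b = √(ΔR²/(1−ΔR²)·λ₀); the default target 0.0085 matches the magnitude of
  the reported strongest score–molehill association, giving b ≈ 0.47.  The
  link is linear-rate (not log-link) to mirror the linear-regression
  analysis; negative rates clamp at 0 by default.
- **Covariates**: age uniform 9–12 y, sex Bernoulli(0.5), 10 standard-normal
  PCs, handedness Bernoulli(0.9), maternal education categorical.

### What the generator does not emulate

Voxel noise is spatially independent, whereas real FA noise is smooth;
spurious-cluster rates here are therefore optimistic, and passing detection
tests bound performance on this noise model only.  At the default planting
rate (λ₀ = 26) plants occupy a noticeable fraction of the toy white matter,
so adjacent plants can merge into one detected cluster: detected counts are
an attenuated (but still monotone) image of planted counts — visible in the
demo run, where a planted median of 26 molehills yields a detected median of
16.  Registration error, scanner effects, age trends in FA, LD structure in
the genotypes, and population stratification are all outside the generator.

## Problem sizes used in the automated checks

Cluster-partition checks run against an independent flood fill on 100 random
grids up to 16³; standardization and conservation checks use 50-subject
cohorts; planted-anomaly recovery uses 100 subjects at 32³ with plants of
4/7/13/26 voxels at magnitude 6; the family-wise null study uses 500
replicates of the 8-test suite at n = 500; effect recovery uses 100
replicates at n = 1000 with the default ΔR² ≈ 0.0085 link, where the
analytic power of the two-sided test is ≈ 0.83 — the 80% recovery criterion
is intentionally close to that value.  End-to-end determinism is checked on
a 30-subject 24³ run.
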