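# potholes

Voxel-wise z-score cluster analysis of white-matter microstructure —
"potholes" and "molehills" — for cohorts of spatially aligned
fractional-anisotropy (FA) volumes, with a polygenic-risk-score association
suite and a fully synthetic cohort generator.

Diffuse disease processes can leave small, *spatially non-overlapping*
patches of abnormal white matter that voxel-wise group maps average away.
This package implements the cluster-counting approach to that problem: each
subject's FA volume is z-scored against the cohort voxel-wise mean and SD
inside a white-matter mask (mean FA > 0.2), and the phenotype is the number
of contiguous clusters in which **every** voxel is extreme —

- **pothole**: a maximal connected component of `z < −2` (low FA),
- **molehill**: a maximal connected component of `z > +2` (high FA),

counted at minimum cluster volumes of 25, 50, 100, and 200 mm³ and localized
within labeled tracts (any integer-labeled atlas on the cohort grid; a
17-tract toy atlas ships with the package).  Counts are then regressed on
sex, age, and a P_T-thresholded polygenic risk score (with rs3135388 and
MHC-region exclusion sensitivity variants), with Benjamini–Hochberg FDR
applied per test family (16 descriptive / 8 genetic / 17 tract tests).
It is aimed at imaging-genetics researchers who want the whole chain —
simulation, z-maps, cluster detection, tract mapping, scoring, regression —
as tested, scriptable pieces.

Because the original cohort data are not public, the package includes a
first-class synthetic module: tract-shaped FA templates, planted contiguous
anomalies of known size/polarity/magnitude, genotypes with a GWAS-style
weight table, and a Poisson link from the genetic score to per-subject
molehill counts.  See `docs/methods.md` for the model and all conventions.

## Worked example

```bash
potholes all demo_run --n-subjects 30 --seed 7
```

runs simulation → reference → z-maps → clusters → tracts → PRS →
associations and prints the result locations; the same stages can be run
one at a time (`potholes simulate|reference|zmap|clusters|prs|associate`).
Programmatically:

```python
from potholes import CohortSpec, generate_fa_cohort, zmap_cohort, count_profile

spec = CohortSpec(n_subjects=50, grid_shape=(32, 32, 32), seed=202)
cohort, truth = generate_fa_cohort(spec)          # no plants: pure noise
reference, mask, zmaps = zmap_cohort(cohort)
profile = count_profile(zmaps[0])
print(profile.thresholds, profile.counts)
```

prints

```
(25.0, 50.0, 100.0, 200.0) {'pothole': [1, 0, 0, 0], 'molehill': [3, 0, 0, 0]}
```

— in a plant-free cohort this subject carries one spurious pothole and three
spurious molehills bigger than 25 mm³ and nothing at the larger rungs.  The numbered scripts under
`analysis/` (run from the repository root, e.g.
`python analysis/01_simulate_cohort.py`) walk
the full study on a 100-subject cohort with a planted score–molehill link:
`01_simulate_cohort.py` reports the planted counts (median 26 molehills per
subject), `02_map_anomalies.py` the detected count ladder and busiest
tracts, `03_polygenic_score.py` the score and its exclusion variants, and
`04_associations.py` the three FDR-corrected suites.

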