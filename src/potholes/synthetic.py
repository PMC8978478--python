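"""Synthetic FA cohorts with known ground truth.

The study data this pipeline targets (aligned child FA volumes, imputed
genotypes, covariates) are not public, so every downstream stage is exercised
on simulated cohorts with planted truth:

* a smooth FA *template* — low-FA background with tract-shaped high-FA
  regions laid out to match the 17-label toy atlas (one midline corpus
  callosum plus 8 left/right pairs);
* per-subject volumes = template + independent Gaussian voxel noise, clipped
  to [0, 1];
* optional *planted anomalies*: contiguous voxel sets inside the
  white-matter region shifted by ``magnitude_sd`` noise-SD units, negative
  for potholes and positive for molehills, so the expected planted z-score is
  about -/+ magnitude;
* genotype dosages (binomial per variant), GWAS-style weight tables, and a
  covariate table (age, sex, 10 genetic PCs, handedness, maternal education);
* a score-linked planting mode where each subject's molehill count is drawn
  Poisson(lambda0 + b * score), mirroring a positive polygenic association
  with molehill counts, with the per-subject truth recorded.

Noise is independent across voxels — real FA noise is spatially correlated,
so spurious-cluster rates here are optimistic; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import TractAtlas, toy_atlas_names
from .geometry import Geometry
from .zmap import FAVolumeSet

#: Margin above the 0.2 analysis-mask threshold required of planting sites,
#: so sampling noise in the cohort mean cannot push a planted voxel off-mask.
PLANT_MARGIN = 0.05

_SIX_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


# ---------------------------------------------------------------------------
# Template and toy atlas
# ---------------------------------------------------------------------------

def toy_template(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    background_fa: float = 0.08,
    tract_fa: float = 0.55,
    smooth_sigma_vox: float = 1.0,
) -> tuple[np.ndarray, TractAtlas]:
    """Smooth FA template plus the aligned 17-label toy atlas.

    Tracts are axis-aligned boxes in normalized coordinates: a midline
    sagittal slab (label 1, "corpus callosum") and 8 bilateral pairs (labels
    2-17), mutually disjoint.  The FA field is ``tract_fa`` inside any tract
    and ``background_fa`` outside, Gaussian-smoothed so tract cores stay well
    above the 0.2 analysis threshold while edges fall off smoothly.
    """
    geometry = Geometry(shape=grid_shape, voxel_size_mm=voxel_size_mm)
    nx, ny, nz = grid_shape
    ix, iy, iz = np.meshgrid(
        (np.arange(nx) + 0.5) / nx,
        (np.arange(ny) + 0.5) / ny,
        (np.arange(nz) + 0.5) / nz,
        indexing="ij",
    )

    def box(xc, yc, zc, hx, hy, hz):
        return (
            (np.abs(ix - xc) < hx) & (np.abs(iy - yc) < hy) & (np.abs(iz - zc) < hz)
        )

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[box(0.5, 0.5, 0.575, 0.08, 0.30, 0.125)] = 1  # midline slab
    label = 2
    for k in range(8):
        yc = 0.2 + 0.2 * (k % 4)
        zc = 0.3 if k < 4 else 0.65
        for xc in (0.25, 0.75):  # left then right
            region = box(xc, yc, zc, 0.10, 0.08, 0.10) & (labels == 0)
            labels[region] = label
            label += 1

    fa = np.where(labels > 0, tract_fa, background_fa).astype(float)
    if smooth_sigma_vox > 0:
        fa = ndimage.gaussian_filter(fa, sigma=smooth_sigma_vox)
    atlas = TractAtlas(labels=labels, names=toy_atlas_names(), geometry=geometry)
    return fa, atlas


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Conditions for one simulated cohort."""

    n_subjects: int = 100
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 0.02  # subject-level voxel noise, FA units
    seed: int = 0
    template: np.ndarray | None = None  # defaults to toy_template on the grid
    atlas: TractAtlas | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.template is None:
            self.template, self.atlas = toy_template(
                self.grid_shape, self.voxel_size_mm
            )
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != tuple(self.grid_shape):
            raise ValueError("template shape does not match grid_shape")
        if self.template.min() < 0 or self.template.max() > 1:
            raise ValueError("template FA values must lie in [0, 1]")

    @property
    def geometry(self) -> Geometry:
        return Geometry(shape=self.grid_shape, voxel_size_mm=self.voxel_size_mm)

    def eligible_mask(self, margin: float = PLANT_MARGIN) -> np.ndarray:
        """Voxels safe to plant in: template FA above threshold + margin."""
        return self.template > (0.2 + margin)


@dataclass
class PlantedAnomaly:
    """Ground-truth contiguous anomaly for one subject."""

    subject_index: int
    polarity: str  # "pothole" | "molehill"
    voxel_set: np.ndarray  # (k, 3) int coordinates, contiguous
    magnitude_sd: float  # shift in units of noise_sd

    def __post_init__(self) -> None:
        if self.polarity not in ("pothole", "molehill"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if self.magnitude_sd <= 0:
            raise ValueError("magnitude_sd must be positive")
        self.voxel_set = np.asarray(self.voxel_set, dtype=int)
        if self.voxel_set.ndim != 2 or self.voxel_set.shape[1] != 3:
            raise ValueError("voxel_set must be (k, 3)")


def effect_for_delta_r2(delta_r2: float, lambda0: float) -> float:
    """Rate slope b giving the score an expected dR2 share of count variance.

    For counts Poisson(lambda0 + b*score) with a standardized score,
    Var(count) = lambda0 + b^2, the score explains b^2 of it, so
    b = sqrt(dR2 / (1 - dR2) * lambda0).
    """
    if not 0 < delta_r2 < 1:
        raise ValueError("delta_r2 must be in (0, 1)")
    return float(np.sqrt(delta_r2 / (1.0 - delta_r2) * lambda0))


@dataclass
class GeneticSpec:
    """Conditions for genotypes, weights, and the score-count link.

    The default rate intercept (26 molehills) and the slope derived from a
    target dR2 of 0.0085 reproduce the magnitude of the strongest reported
    polygenic association with molehill counts.
    """

    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.1  # weights drawn N(0, effect_sd)
    log10_p_range: tuple[float, float] = (-8.0, 0.0)  # p ~ 10^U(range)
    base_rate_lambda0: float = 26.0
    prs_effect_b: float = field(default=None)  # type: ignore[assignment]
    target_delta_r2: float = 0.0085
    size_choices: tuple[int, ...] = (4, 7, 13, 26)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be at least 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.base_rate_lambda0 < 0:
            raise ValueError("base_rate_lambda0 must be non-negative")
        if self.prs_effect_b is None:
            self.prs_effect_b = effect_for_delta_r2(
                self.target_delta_r2, self.base_rate_lambda0
            )


# ---------------------------------------------------------------------------
# FA cohort generation
# ---------------------------------------------------------------------------

def _check_contiguous(voxels: np.ndarray, shape: tuple[int, int, int]) -> bool:
    grid = np.zeros(shape, dtype=bool)
    grid[tuple(voxels.T)] = True
    _, n = ndimage.label(grid, structure=ndimage.generate_binary_structure(3, 3))
    return n == 1


def _validate_plants(spec: CohortSpec, plants: list[PlantedAnomaly]) -> None:
    inside = spec.template > 0.2
    per_subject: dict[int, set] = {}
    for idx, plant in enumerate(plants):
        if not 0 <= plant.subject_index < spec.n_subjects:
            raise ValueError(f"plant {idx}: subject index {plant.subject_index} "
                             f"outside cohort of {spec.n_subjects}")
        coords = plant.voxel_set
        if np.any(coords < 0) or np.any(coords >= np.array(spec.grid_shape)):
            raise ValueError(f"plant {idx}: voxels outside the grid")
        if not np.all(inside[tuple(coords.T)]):
            raise ValueError(
                f"plant {idx}: voxels fall outside the template FA>0.2 region"
            )
        if not _check_contiguous(coords, spec.grid_shape):
            raise ValueError(f"plant {idx}: voxel_set is not contiguous")
        seen = per_subject.setdefault(plant.subject_index, set())
        as_tuples = {tuple(v) for v in coords.tolist()}
        clash = seen & as_tuples
        if clash:
            raise ValueError(
                f"plant {idx} overlaps an earlier plant of subject "
                f"{plant.subject_index} at voxels {sorted(clash)[:3]}"
            )
        seen |= as_tuples


def generate_fa_cohort(
    spec: CohortSpec, plants: list[PlantedAnomaly] | None = None
) -> tuple[FAVolumeSet, pd.DataFrame]:
    """Simulate the cohort and return it with the ground-truth plant table.

    Each subject volume is template + N(0, noise_sd) per voxel; planted
    voxels are additionally shifted by +/- magnitude_sd * noise_sd (sign by
    polarity); everything is clipped to [0, 1].  The truth table lists one
    row per plant: subject, polarity, voxel count, and physical volume
    (count x voxel volume).  Identical (spec, seed) gives identical output.
    """
    plants = plants or []
    if not np.any(spec.template > 0.2):
        raise ValueError("template has no voxels above FA 0.2; nothing to analyze")
    _validate_plants(spec, plants)
    rng = np.random.default_rng(spec.seed)
    data = spec.template[None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_subjects, *spec.grid_shape)
    )
    voxvol = spec.geometry.voxel_volume_mm3
    truth_rows = []
    for plant in plants:
        shift = plant.magnitude_sd * spec.noise_sd
        if plant.polarity == "pothole":
            shift = -shift
        data[(plant.subject_index, *tuple(plant.voxel_set.T))] += shift
        truth_rows.append(
            {
                "subject": f"s{plant.subject_index:04d}",
                "subject_index": plant.subject_index,
                "polarity": plant.polarity,
                "n_voxels": plant.voxel_set.shape[0],
                "volume_mm3": plant.voxel_set.shape[0] * voxvol,
                "magnitude_sd": plant.magnitude_sd,
            }
        )
    np.clip(data, 0.0, 1.0, out=data)
    cohort = FAVolumeSet(data=data, geometry=spec.geometry)
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject", "subject_index", "polarity", "n_voxels", "volume_mm3",
                 "magnitude_sd"],
    )
    return cohort, truth


def grow_plant_region(
    spec: CohortSpec,
    size: int,
    rng: np.random.Generator,
    forbidden: set | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Random contiguous voxel set of ``size`` inside the plantable region.

    Growth is a randomized breadth-first accretion over 6-neighbors, so the
    result is contiguous under every supported connectivity.  ``forbidden``
    voxels (earlier plants of the same subject) are never used.
    """
    eligible = spec.eligible_mask()
    coords = np.argwhere(eligible)
    if coords.shape[0] < size:
        raise ValueError(f"plantable region ({coords.shape[0]} voxels) smaller "
                         f"than requested plant size {size}")
    forbidden = forbidden or set()
    shape = np.array(spec.grid_shape)
    for _ in range(max_tries):
        seed_vox = tuple(coords[rng.integers(coords.shape[0])])
        if seed_vox in forbidden:
            continue
        region = [seed_vox]
        member = {seed_vox}
        frontier: list[tuple[int, int, int]] = []

        def extend_frontier(vox):
            for d in _SIX_NEIGHBORS:
                nb = tuple(int(v) for v in (np.array(vox) + d))
                if (
                    all(0 <= nb[i] < shape[i] for i in range(3))
                    and eligible[nb]
                    and nb not in member
                    and nb not in forbidden
                ):
                    frontier.append(nb)

        extend_frontier(seed_vox)
        while len(region) < size and frontier:
            pick = frontier.pop(rng.integers(len(frontier)))
            if pick in member:
                continue
            region.append(pick)
            member.add(pick)
            extend_frontier(pick)
        if len(region) == size:
            return np.array(region, dtype=int)
    raise RuntimeError(f"could not grow a {size}-voxel plant in {max_tries} tries")


# ---------------------------------------------------------------------------
# Genetics and covariates
# ---------------------------------------------------------------------------

def generate_genotypes(
    n_subjects: int, gspec: GeneticSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage matrix (subjects x variants, values 0/1/2) and weight table.

    Dosages are Binomial(2, maf) per variant, maf uniform over
    ``maf_range``.  The weight table carries ID/CHR/BP/BETA/P with effects
    N(0, effect_sd) and p-values log-uniform over ``log10_p_range`` — the
    shape of a pre-pruned GWAS hit list.  The first variant is named
    rs3135388 and placed inside the MHC region on chromosome 6 with a strong
    effect and a tiny p-value, emulating the HLA-DRB1*15:01 tag SNP so the
    exclusion sensitivity analyses have a meaningful target.
    """
    rng = np.random.default_rng(gspec.seed)
    m = gspec.n_variants
    mafs = rng.uniform(*gspec.maf_range, size=m)
    ids = [f"rs{1_000_000 + i}" for i in range(m)]
    chrom = rng.integers(1, 23, size=m).astype(str)
    bp = rng.integers(1, 200_000_000, size=m)
    betas = rng.normal(0.0, gspec.effect_sd, size=m)
    pvals = 10.0 ** rng.uniform(*gspec.log10_p_range, size=m)
    # tag-SNP stand-in: largest-effect variant, inside the MHC, smallest p
    ids[0] = "rs3135388"
    chrom[0], bp[0] = "6", 32_400_000
    betas[0] = abs(betas).max() * 1.5 + gspec.effect_sd
    pvals[0] = min(pvals.min(), 1e-9)
    weights = pd.DataFrame(
        {"ID": ids, "CHR": chrom, "BP": bp, "BETA": betas, "P": pvals}
    )
    dosages = pd.DataFrame(
        rng.binomial(2, mafs, size=(n_subjects, m)).astype(float),
        index=[f"s{i:04d}" for i in range(n_subjects)],
        columns=ids,
    )
    return dosages, weights


def generate_covariates(
    n_subjects: int, seed: int = 0, age_range: tuple[float, float] = (9.0, 12.0)
) -> pd.DataFrame:
    """Covariate table: age (years), sex (female=1/male=0), pc1..pc10,
    handedness (right=1), maternal_education (ordinal 0/1/2)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=[f"s{i:04d}" for i in range(n_subjects)])
    out["age"] = rng.uniform(*age_range, size=n_subjects)
    out["sex"] = rng.binomial(1, 0.5, size=n_subjects)
    for i in range(1, 11):
        out[f"pc{i}"] = rng.normal(size=n_subjects)
    out["handedness"] = rng.binomial(1, 0.9, size=n_subjects)
    out["maternal_education"] = rng.choice(3, size=n_subjects, p=[0.1, 0.4, 0.5])
    return out


def linked_molehill_counts(
    scores: np.ndarray,
    gspec: GeneticSpec,
    rng: np.random.Generator,
    truncate: bool = True,
) -> np.ndarray:
    """Per-subject molehill counts Poisson(lambda0 + b * score).

    The rate is linear in the standardized score (matching the linear
    regression downstream); with ``truncate`` negative rates clamp to 0,
    otherwise any negative rate raises.
    """
    rates = gspec.base_rate_lambda0 + gspec.prs_effect_b * np.asarray(scores, float)
    if np.any(rates < 0):
        if not truncate:
            bad = int(np.argmin(rates))
            raise ValueError(
                f"negative molehill rate {rates[bad]:.3f} for subject {bad} "
                "(enable truncation or reduce prs_effect_b)"
            )
        rates = np.maximum(rates, 0.0)
    return rng.poisson(rates)


def plant_prs_linked_anomalies(
    scores: pd.Series,
    gspec: GeneticSpec,
    spec: CohortSpec,
    magnitude_sd: float = 6.0,
    truncate: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[list[PlantedAnomaly], pd.DataFrame]:
    """Molehill plants whose per-subject count follows the genetic score.

    Counts are Poisson(lambda0 + b * score); with ``truncate`` negative rates
    clamp to 0, otherwise any negative rate is an error.  Plant locations are
    random contiguous regions in the plantable mask, sizes drawn uniformly
    from ``gspec.size_choices``, non-overlapping within a subject.  Returns
    the plants plus a per-subject truth table of planted counts.

    ``scores`` must be standardized (mean 0, SD 1 over subjects).
    """
    s = scores.to_numpy(dtype=float)
    if abs(s.mean()) > 1e-6 or abs(s.std(ddof=1) - 1) > 1e-6:
        raise ValueError("scores must be standardized (mean 0, SD 1)")
    if len(s) != spec.n_subjects:
        raise ValueError("scores length must equal spec.n_subjects")
    rng = rng if rng is not None else np.random.default_rng(gspec.seed + 1)
    counts = linked_molehill_counts(s, gspec, rng, truncate=truncate)
    plants: list[PlantedAnomaly] = []
    for i in range(spec.n_subjects):
        occupied: set = set()
        for _ in range(int(counts[i])):
            size = int(rng.choice(gspec.size_choices))
            region = grow_plant_region(spec, size, rng, forbidden=occupied)
            occupied |= {tuple(v) for v in region.tolist()}
            plants.append(
                PlantedAnomaly(
                    subject_index=i,
                    polarity="molehill",
                    voxel_set=region,
                    magnitude_sd=magnitude_sd,
                )
            )
    truth = pd.DataFrame(
        {
            "subject": [f"s{i:04d}" for i in range(spec.n_subjects)],
            "score": s,
            "planted_molehills": counts,
        }
    )
    return plants, truth
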