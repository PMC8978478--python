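"""End-to-end driver: simulate -> reference -> z-maps -> clusters -> tracts
-> polygenic score -> association suites.

Every stage reads and writes files in one run directory with a fixed layout,
so a run is resumable from its on-disk intermediates and each stage can also
be invoked alone from the CLI.  All parameters and a digest of every input
artifact are echoed into ``manifest.yaml``; identical configuration and seed
reproduce byte-identical results tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .clusters import (
    DEFAULT_VOLUME_THRESHOLDS,
    detect_clusters,
    filter_by_min_volume,
)
from .atlas import tract_count_table
from .prs import PRSConfig, compute_prs, select_variants
from .stats import run_global_suite, run_tract_suite
from .synthetic import (
    CohortSpec,
    GeneticSpec,
    generate_covariates,
    generate_fa_cohort,
    generate_genotypes,
    plant_prs_linked_anomalies,
)
from .zmap import compute_reference, compute_wm_mask, z_transform

LAYOUT = {
    "cohort": "inputs/cohort.nii.gz",
    "atlas": "inputs/atlas.nii.gz",
    "atlas_labels": "inputs/atlas_labels.tsv",
    "dosages": "inputs/dosages.tsv",
    "weights": "inputs/weights.tsv",
    "covariates": "inputs/covariates.tsv",
    "truth_plants": "inputs/truth_plants.tsv",
    "truth_counts": "inputs/truth_counts.tsv",
    "mean": "reference/mean.nii.gz",
    "sd": "reference/sd.nii.gz",
    "mask": "reference/mask.nii.gz",
    "zmaps": "zmaps/zmaps.nii.gz",
    "clusters": "clusters/clusters.tsv",
    "counts": "clusters/counts.tsv",
    "tract_counts": "clusters/tract_counts.tsv",
    "scores": "prs/scores.tsv",
    "assoc_descriptive": "associations/descriptive_global.tsv",
    "assoc_prs": "associations/prs_global.tsv",
    "assoc_tract": "associations/prs_tract.tsv",
    "manifest": "manifest.yaml",
}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, echoed verbatim into the run manifest."""

    out_dir: str = "run"
    seed: int = 0
    # cohort
    n_subjects: int = 100
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 0.02
    # genetics / planting
    n_variants: int = 100
    base_rate_lambda0: float = 26.0
    target_delta_r2: float = 0.0085
    plant_magnitude_sd: float = 6.0
    # z-map / clustering
    fa_threshold: float = 0.2
    z_threshold: float = 2.0
    connectivity: int = 26
    volume_thresholds: tuple[float, ...] = DEFAULT_VOLUME_THRESHOLDS
    assignment_rule: str = "plurality"
    # PRS
    p_threshold: float = 0.01
    exclude_ids: tuple[str, ...] = ()
    exclude_regions: tuple[tuple[str, int, int], ...] = ()
    # associations
    tract_suite: bool = True
    tract_polarity: str = "molehill"
    tract_threshold: float = 25.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.normalize()
        return cfg

    def normalize(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.volume_thresholds = tuple(float(v) for v in self.volume_thresholds)
        self.exclude_ids = tuple(self.exclude_ids)
        self.exclude_regions = tuple(
            (str(c), int(s), int(e)) for c, s, e in self.exclude_regions
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_regions"] = [list(r) for r in self.exclude_regions]
        return d

    def prs_config(self) -> PRSConfig:
        return PRSConfig(
            p_threshold=self.p_threshold,
            exclude_ids=self.exclude_ids,
            exclude_regions=self.exclude_regions,
        )


def _path(run_dir: Path, key: str) -> Path:
    return run_dir / LAYOUT[key]


def _need(run_dir: Path, key: str) -> Path:
    p = _path(run_dir, key)
    if not p.exists():
        raise FileNotFoundError(
            f"required artifact {LAYOUT[key]} not found under {run_dir}; "
            "run the producing stage first"
        )
    return p


def _scores_from_files(run_dir: Path, config: RunConfig) -> pd.Series:
    weights = io.read_table(_need(run_dir, "weights"))
    dosages = io.read_table(_need(run_dir, "dosages"), index_col=0)
    selected = select_variants(weights, config.prs_config())
    return compute_prs(dosages, selected, config.prs_config()).standardized


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    """Generate and write all synthetic inputs (cohort, atlas, genetics)."""
    spec = CohortSpec(
        n_subjects=config.n_subjects,
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    gspec = GeneticSpec(
        n_variants=config.n_variants,
        base_rate_lambda0=config.base_rate_lambda0,
        target_delta_r2=config.target_delta_r2,
        seed=config.seed + 1,
    )
    dosages, weights = generate_genotypes(config.n_subjects, gspec)
    covariates = generate_covariates(config.n_subjects, seed=config.seed + 2)
    selected = select_variants(weights, config.prs_config())
    scores = compute_prs(dosages, selected, config.prs_config()).standardized
    plants, truth_counts = plant_prs_linked_anomalies(
        scores, gspec, spec, magnitude_sd=config.plant_magnitude_sd,
        rng=np.random.default_rng(config.seed + 3),
    )
    cohort, truth_plants = generate_fa_cohort(spec, plants)

    io.save_cohort(cohort, _path(run_dir, "cohort"))
    io.save_atlas(
        spec.atlas, _path(run_dir, "atlas"), _path(run_dir, "atlas_labels")
    )
    io.write_table(dosages, _path(run_dir, "dosages"), index=True)
    io.write_table(weights, _path(run_dir, "weights"))
    io.write_table(covariates, _path(run_dir, "covariates"), index=True)
    io.write_table(truth_plants, _path(run_dir, "truth_plants"))
    io.write_table(truth_counts, _path(run_dir, "truth_counts"))


def stage_reference(config: RunConfig, run_dir: Path) -> None:
    cohort = io.load_cohort(_need(run_dir, "cohort"))
    reference = compute_reference(cohort)
    mask = compute_wm_mask(reference, fa_threshold=config.fa_threshold)
    io.save_volume(reference.mean, cohort.geometry, _path(run_dir, "mean"))
    io.save_volume(reference.sd, cohort.geometry, _path(run_dir, "sd"))
    io.save_volume(mask.astype(np.uint8), cohort.geometry, _path(run_dir, "mask"))


def stage_zmap(config: RunConfig, run_dir: Path) -> None:
    cohort = io.load_cohort(_need(run_dir, "cohort"))
    mean, _ = io.load_volume(_need(run_dir, "mean"))
    sd, _ = io.load_volume(_need(run_dir, "sd"))
    mask_arr, _ = io.load_volume(_need(run_dir, "mask"))
    from .zmap import ReferenceImages

    reference = ReferenceImages(
        mean=mean, sd=sd, n_reference=cohort.n_subjects, geometry=cohort.geometry
    )
    mask = mask_arr > 0
    zstack = np.stack(
        [
            z_transform(cohort.data[i], reference, mask).z
            for i in range(cohort.n_subjects)
        ]
    )
    io.save_volume(np.nan_to_num(zstack), cohort.geometry, _path(run_dir, "zmaps"))


def stage_clusters(config: RunConfig, run_dir: Path) -> None:
    """Detect clusters per subject; write the cluster table, the global count
    profile, and (if an atlas is present) the per-tract counts."""
    from .zmap import ZVolume

    zstack, geometry = io.load_volume(_need(run_dir, "zmaps"))
    mask_arr, _ = io.load_volume(_need(run_dir, "mask"))
    mask = mask_arr > 0
    atlas = None
    if config.tract_suite:
        atlas = io.load_atlas(
            _need(run_dir, "atlas"), _need(run_dir, "atlas_labels")
        )
    cluster_rows, count_rows, tract_frames = [], [], []
    for i in range(zstack.shape[0]):
        sid = f"s{i:04d}"
        zvol = ZVolume(z=zstack[i], mask=mask, geometry=geometry, subject_id=sid)
        clusters = detect_clusters(
            zvol, z_threshold=config.z_threshold, connectivity=config.connectivity
        )
        for c in clusters:
            cluster_rows.append(
                {
                    "subject": sid,
                    "polarity": c.polarity,
                    "n_voxels": c.n_voxels,
                    "volume_mm3": c.volume_mm3,
                    "peak_abs_z": c.peak_abs_z,
                    "centroid_x": c.centroid[0],
                    "centroid_y": c.centroid[1],
                    "centroid_z": c.centroid[2],
                }
            )
        for polarity in ("pothole", "molehill"):
            of_pol = [c for c in clusters if c.polarity == polarity]
            for t in config.volume_thresholds:
                count_rows.append(
                    {
                        "subject": sid,
                        "polarity": polarity,
                        "min_volume_mm3": t,
                        "count": len(filter_by_min_volume(of_pol, t)),
                    }
                )
        if atlas is not None:
            tc = tract_count_table(
                clusters, atlas, config.volume_thresholds, rule=config.assignment_rule
            )
            tc.insert(0, "subject", sid)
            tract_frames.append(tc)
    io.write_table(pd.DataFrame(cluster_rows), _path(run_dir, "clusters"))
    io.write_table(pd.DataFrame(count_rows), _path(run_dir, "counts"))
    if tract_frames:
        io.write_table(pd.concat(tract_frames), _path(run_dir, "tract_counts"))


def stage_prs(config: RunConfig, run_dir: Path) -> None:
    weights = io.read_table(_need(run_dir, "weights"))
    dosages = io.read_table(_need(run_dir, "dosages"), index_col=0)
    prs_cfg = config.prs_config()
    selected = select_variants(weights, prs_cfg)
    score_set = compute_prs(dosages, selected, prs_cfg)
    out = score_set.scores.copy()
    out["n_variants_used"] = score_set.n_variants_used
    io.write_table(out, _path(run_dir, "scores"), index=True)


def stage_associate(config: RunConfig, run_dir: Path) -> None:
    counts = io.read_table(_need(run_dir, "counts"))
    covariates = io.read_table(_need(run_dir, "covariates"), index_col=0)
    scores = io.read_table(_need(run_dir, "scores"), index_col=0)["standardized"]
    io.write_table(
        run_global_suite(counts, covariates, suite="descriptive",
                         thresholds=config.volume_thresholds),
        _path(run_dir, "assoc_descriptive"),
    )
    io.write_table(
        run_global_suite(counts, covariates, scores=scores, suite="prs",
                         thresholds=config.volume_thresholds),
        _path(run_dir, "assoc_prs"),
    )
    if config.tract_suite:
        atlas = io.load_atlas(
            _need(run_dir, "atlas"), _need(run_dir, "atlas_labels")
        )
        tract_counts = io.read_table(_need(run_dir, "tract_counts"))
        io.write_table(
            run_tract_suite(
                tract_counts, covariates, scores, atlas,
                polarity=config.tract_polarity, threshold=config.tract_threshold,
            ),
            _path(run_dir, "assoc_tract"),
        )


STAGES = [
    ("simulate", stage_simulate, ["cohort"]),
    ("reference", stage_reference, ["mean", "sd", "mask"]),
    ("zmap", stage_zmap, ["zmaps"]),
    ("clusters", stage_clusters, ["clusters", "counts"]),
    ("prs", stage_prs, ["scores"]),
    ("associate", stage_associate, ["assoc_prs"]),
]


def write_manifest(config: RunConfig, run_dir: Path) -> None:
    digests = {
        key: io.sha256_of(_path(run_dir, key))
        for key in LAYOUT
        if key != "manifest" and _path(run_dir, key).exists()
    }
    manifest = {"config": config.to_dict(), "artifact_sha256": digests}
    with open(_path(run_dir, "manifest"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Run all stages in dependency order and write the manifest.

    With ``resume``, stages whose outputs already exist are skipped, so a
    failed run continues from its last good intermediate.
    """
    config.normalize()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for name, fn, outputs in STAGES:
        if resume and all(_path(run_dir, key).exists() for key in outputs):
            continue
        fn(config, run_dir)
    write_manifest(config, run_dir)
    return run_dir
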