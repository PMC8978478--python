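"""Cohort reference images, white-matter mask, and per-subject z-maps.

Given a cohort of spatially aligned fractional-anisotropy (FA) volumes, this
module derives the voxel-wise cohort mean and standard deviation, restricts
analysis to a white-matter mask (cohort mean FA strictly above a threshold,
default 0.2, and non-zero SD), and converts each subject's FA volume into a
z-map: z = (FA - mean) / SD per voxel.  Off-mask voxels carry NaN.

Because each subject contributes to the reference it is compared against, the
cross-subject distribution of z at any masked voxel has mean exactly 0 and
sample SD exactly 1; downstream cluster counts are therefore relative to the
cohort, not to an external norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry

DEFAULT_FA_THRESHOLD = 0.2


@dataclass
class FAVolumeSet:
    """Cohort of aligned FA volumes stacked subject-first: ``data[(i, x, y, z)]``."""

    data: np.ndarray  # (n_subjects, *geometry.shape), FA in [0, 1]
    geometry: Geometry
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (subjects, x, y, z)")
        if self.data.shape[1:] != self.geometry.shape:
            raise ValueError(
                f"volume shape {self.data.shape[1:]} does not match geometry "
                f"{self.geometry.shape}"
            )
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i:04d}" for i in range(self.n_subjects)]
        elif len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length does not match number of volumes")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass
class ReferenceImages:
    """Voxel-wise cohort mean and sample SD (n-1 denominator by default)."""

    mean: np.ndarray
    sd: np.ndarray
    n_reference: int
    geometry: Geometry


@dataclass
class ZVolume:
    """Per-subject z-map; NaN marks voxels outside the analysis mask."""

    z: np.ndarray
    mask: np.ndarray  # boolean, True where z is defined
    geometry: Geometry
    subject_id: str = ""


def compute_reference(cohort: FAVolumeSet, ddof: int = 1) -> ReferenceImages:
    """Voxel-wise mean and sample SD over all subjects in the cohort.

    Every subject is included in its own reference (the default convention for
    this method); see :func:`zmap_cohort` for a leave-one-out variant.
    ``ddof=1`` gives the n-1 sample SD; set ``ddof=0`` for the population SD.
    """
    n = cohort.n_subjects
    if n <= ddof:
        raise ValueError(f"need more than {ddof} subjects for SD with ddof={ddof}")
    mean = cohort.data.mean(axis=0)
    sd = cohort.data.std(axis=0, ddof=ddof)
    return ReferenceImages(mean=mean, sd=sd, n_reference=n, geometry=cohort.geometry)


def compute_wm_mask(
    reference: ReferenceImages, fa_threshold: float = DEFAULT_FA_THRESHOLD
) -> np.ndarray:
    """Boolean analysis mask: cohort mean FA strictly above ``fa_threshold``
    and SD strictly positive (zero-SD voxels would give infinite z)."""
    return (reference.mean > fa_threshold) & (reference.sd > 0)


def z_transform(
    subject_fa: np.ndarray,
    reference: ReferenceImages,
    mask: np.ndarray,
    subject_id: str = "",
) -> ZVolume:
    """z = (FA - mean) / SD on the mask; NaN elsewhere."""
    subject_fa = np.asarray(subject_fa, dtype=float)
    if subject_fa.shape != reference.geometry.shape:
        raise ValueError(
            f"subject volume shape {subject_fa.shape} does not match reference "
            f"geometry {reference.geometry.shape}"
        )
    z = np.full(reference.geometry.shape, np.nan)
    z[mask] = (subject_fa[mask] - reference.mean[mask]) / reference.sd[mask]
    return ZVolume(z=z, mask=mask, geometry=reference.geometry, subject_id=subject_id)


def zmap_cohort(
    cohort: FAVolumeSet,
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    ddof: int = 1,
    leave_one_out: bool = False,
) -> tuple[ReferenceImages, np.ndarray, list[ZVolume]]:
    """Reference, mask, and one z-map per subject.

    With ``leave_one_out`` each subject is z-scored against the mean/SD of the
    remaining n-1 subjects (the mask still comes from the full-cohort
    reference so all subjects share one analysis domain).
    """
    reference = compute_reference(cohort, ddof=ddof)
    mask = compute_wm_mask(reference, fa_threshold=fa_threshold)
    zvols: list[ZVolume] = []
    for i in range(cohort.n_subjects):
        if leave_one_out:
            others = np.delete(cohort.data, i, axis=0)
            ref_i = ReferenceImages(
                mean=others.mean(axis=0),
                sd=others.std(axis=0, ddof=ddof),
                n_reference=cohort.n_subjects - 1,
                geometry=cohort.geometry,
            )
            mask_i = mask & (ref_i.sd > 0)
            zvols.append(
                z_transform(cohort.data[i], ref_i, mask_i, cohort.subject_ids[i])
            )
        else:
            zvols.append(
                z_transform(cohort.data[i], reference, mask, cohort.subject_ids[i])
            )
    return reference, mask, zvols
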