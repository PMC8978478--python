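"""Pothole/molehill detection: contiguous suprathreshold clusters of a z-map.

A *pothole* is a maximal connected component of voxels with z strictly below
-z_threshold (default 2.0); a *molehill* is its mirror with z strictly above
+z_threshold.  Contiguity is configurable as 6- (faces), 18- (faces+edges) or
26-connectivity (faces+edges+corners); 26 is the default, the common choice
for cluster thresholding in neuroimaging.  Clusters are then filtered by
physical volume (count x voxel volume from the header, never assumed
isotropic) at a ladder of minimum sizes, default 25/50/100/200 mm^3, with a
strict ">" comparison, yielding a per-subject count profile by polarity and
size threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .zmap import ZVolume

DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_VOLUME_THRESHOLDS = (25.0, 50.0, 100.0, 200.0)
POLARITIES = ("pothole", "molehill")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class Cluster:
    polarity: str  # "pothole" | "molehill"
    voxels: np.ndarray  # (k, 3) int voxel coordinates
    volume_mm3: float
    peak_abs_z: float
    centroid: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(c) for c in v) for v in self.voxels}


@dataclass
class CountProfile:
    """Cluster counts per (polarity, minimum-volume threshold)."""

    thresholds: tuple[float, ...]
    counts: dict[str, list[int]] = field(default_factory=dict)

    def count(self, polarity: str, threshold: float) -> int:
        return self.counts[polarity][self.thresholds.index(threshold)]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, "
            f"got {connectivity}"
        )
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def _components(exceed: np.ndarray, connectivity: int) -> list[np.ndarray]:
    labels, n = ndimage.label(exceed, structure=_structure(connectivity))
    if n == 0:
        return []
    coords = np.argwhere(labels > 0)
    lab = labels[tuple(coords.T)]
    order = np.argsort(lab, kind="stable")
    coords, lab = coords[order], lab[order]
    bounds = np.searchsorted(lab, np.arange(1, n + 2))
    return [coords[bounds[i] : bounds[i + 1]] for i in range(n)]


def detect_clusters(
    z: ZVolume,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    connectivity: int = 26,
    strict: bool = True,
) -> list[Cluster]:
    """All potholes and molehills of a z-map, each suprathreshold voxel in
    exactly one cluster.

    ``strict`` keeps the "z < -t" / "z > +t" comparisons strict; set False for
    a >=-style sensitivity analysis.  Output order is deterministic:
    descending volume, ties broken by the lexicographically smallest voxel.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    zdata = np.where(z.mask, z.z, 0.0)  # NaN off-mask -> never suprathreshold
    voxvol = z.geometry.voxel_volume_mm3
    out: list[Cluster] = []
    for polarity in POLARITIES:
        if polarity == "pothole":
            exceed = (zdata < -z_threshold) if strict else (zdata <= -z_threshold)
        else:
            exceed = (zdata > z_threshold) if strict else (zdata >= z_threshold)
        exceed &= z.mask
        for coords in _components(exceed, connectivity):
            vals = zdata[tuple(coords.T)]
            out.append(
                Cluster(
                    polarity=polarity,
                    voxels=coords,
                    volume_mm3=coords.shape[0] * voxvol,
                    peak_abs_z=float(np.max(np.abs(vals))),
                    centroid=tuple(float(c) for c in coords.mean(axis=0)),
                )
            )
    out.sort(key=lambda c: (-c.volume_mm3, min(map(tuple, c.voxels.tolist()))))
    return out


def filter_by_min_volume(
    clusters: list[Cluster], min_volume_mm3: float, strict: bool = True
) -> list[Cluster]:
    """Clusters larger than ``min_volume_mm3`` (strict ">"), order preserved."""
    if min_volume_mm3 < 0:
        raise ValueError("min_volume_mm3 must be non-negative")
    if strict:
        return [c for c in clusters if c.volume_mm3 > min_volume_mm3]
    return [c for c in clusters if c.volume_mm3 >= min_volume_mm3]


def count_profile(
    z: ZVolume,
    thresholds: tuple[float, ...] = DEFAULT_VOLUME_THRESHOLDS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    connectivity: int = 26,
) -> CountProfile:
    """Counts of potholes/molehills surviving each minimum-volume threshold."""
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("volume thresholds must be strictly increasing")
    clusters = detect_clusters(z, z_threshold=z_threshold, connectivity=connectivity)
    profile = CountProfile(thresholds=thresholds)
    for polarity in POLARITIES:
        of_pol = [c for c in clusters if c.polarity == polarity]
        profile.counts[polarity] = [
            len(filter_by_min_volume(of_pol, t)) for t in thresholds
        ]
    return profile
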