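"""Shared grid geometry for aligned scalar volumes.

Every stage of the pipeline assumes its inputs live on one voxel grid; this
module holds that contract in a single small value object so mismatches are
caught once, with a useful message, instead of surfacing as shape errors deep
inside numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Geometry:
    """Grid shape plus physical voxel dimensions of an aligned volume set.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes.
    voxel_size_mm
        Edge lengths of one voxel in millimetres.  Never assumed isotropic;
        voxel volume is always computed from these values.
    affine
        Voxel-to-world affine (4x4).  Defaults to a scaling affine built from
        ``voxel_size_mm`` so synthetic volumes round-trip through NIfTI.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(
                f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        if self.affine is None:
            aff = np.diag(list(self.voxel_size_mm) + [1.0])
            object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def matches(self, other: "Geometry") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    @classmethod
    def from_nifti(cls, img) -> "Geometry":
        """Build from a ``nibabel`` image, taking voxel size from the header."""
        zooms = img.header.get_zooms()[:3]
        return cls(
            shape=tuple(img.shape[:3]),
            voxel_size_mm=tuple(float(z) for z in zooms),
            affine=np.asarray(img.affine, dtype=float),
        )


def check_same_geometry(geom: Geometry, other: Geometry, what: str = "volume") -> None:
    """Raise ``ValueError`` naming ``what`` if the two geometries differ."""
    if not geom.matches(other):
        raise ValueError(
            f"geometry mismatch for {what}: expected shape {geom.shape} / "
            f"voxels {geom.voxel_size_mm} mm, got {other.shape} / "
            f"{other.voxel_size_mm} mm"
        )
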