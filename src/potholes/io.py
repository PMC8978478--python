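"""NIfTI and TSV input/output for pipeline artifacts."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import TractAtlas
from .geometry import Geometry
from .zmap import FAVolumeSet


def save_volume(array: np.ndarray, geometry: Geometry, path: str | Path) -> Path:
    """Write one 3-D (or subject-stacked 4-D) volume; 4-D input is stored with
    subjects on the last NIfTI axis."""
    array = np.asarray(array)
    if array.ndim == 4:  # (subjects, x, y, z) -> (x, y, z, subjects)
        array = np.moveaxis(array, 0, -1)
    img = nib.Nifti1Image(array.astype(np.float32), affine=geometry.affine)
    img.header.set_zooms(geometry.voxel_size_mm + ((1.0,) if array.ndim == 4 else ()))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, Geometry]:
    img = nib.load(str(path))
    geometry = Geometry.from_nifti(img)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return data, geometry


def save_cohort(cohort: FAVolumeSet, path: str | Path) -> Path:
    return save_volume(cohort.data, cohort.geometry, path)


def load_cohort(path: str | Path) -> FAVolumeSet:
    data, geometry = load_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4-D cohort volume")
    return FAVolumeSet(data=data, geometry=geometry)


def save_atlas(atlas: TractAtlas, volume_path: str | Path, table_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), affine=atlas.geometry.affine)
    img.header.set_zooms(atlas.geometry.voxel_size_mm)
    Path(volume_path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(volume_path))
    write_table(atlas.names, table_path)


def load_atlas(volume_path: str | Path, table_path: str | Path) -> TractAtlas:
    img = nib.load(str(volume_path))
    labels = np.asarray(img.dataobj).astype(int)
    names = read_table(table_path)
    return TractAtlas(labels=labels, names=names, geometry=Geometry.from_nifti(img))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
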