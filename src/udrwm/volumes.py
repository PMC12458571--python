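"""3D volume containers and grid plumbing.

Every downstream statistic in this package assumes voxel correspondence
across subjects: inputs are expected to be pre-registered to a common grid
(e.g. MNI152 for real FA maps).  This module provides the three carriers --
scalar volumes, binary brain masks, and integer label atlases -- together
with NIfTI I/O and the single fixed masked-vector scan order that the
permutation machinery relies on.

Scan order: masked vectors are extracted in C order of the stored array,
i.e. the last axis varies fastest (``data[mask == 1]`` with both arrays in
C order).  This order is deterministic and documented so that permutation
tests and tie-breaking are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "BrainMask",
    "LabelAtlas",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_atlas",
    "validate_grid",
    "apply_mask",
    "scatter_into_mask",
]

AFFINE_ATOL = 1e-5


class GridMismatchError(ValueError):
    """Raised when volumes supposed to share a voxel grid do not."""


@dataclass
class Volume3D:
    """A single 3D scalar image on a fixed grid with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume3D requires a 3D array, got {self.data.ndim}D "
                f"(shape {self.data.shape}); 4D inputs must be split upstream"
            )
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BrainMask:
    """Binary inclusion mask; 1 = inside brain."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.data.sum() == 0:
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelAtlas:
    """Integer-labeled partition of the grid into named regions (0 = background)."""

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("atlas voxels must be integers")
            arr = rounded
        if (arr < 0).any():
            raise ValueError("atlas labels must be non-negative")
        self.data = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("atlas must be 3D")
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.labels:
            self.labels = {r: f"region_{r}" for r in sorted(present)}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"labels table missing ids {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def region_ids(self) -> list[int]:
        return sorted(set(int(v) for v in np.unique(self.data)) - {0})

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_labeled(self) -> int:
        return int((self.data > 0).sum())

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.data == region_id


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path} is {data.ndim}D (shape {data.shape}); expected a single 3D volume"
        )
    return np.asarray(data), np.asarray(img.affine)


def read_volume(path: str | Path) -> Volume3D:
    """Read one 3D scalar NIfTI volume (.nii or .nii.gz)."""
    data, affine = _load_nifti(path)
    return Volume3D(data=data, affine=affine, name=Path(path).name)


def write_volume(vol: Volume3D, path: str | Path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1; data stored at ``dtype`` precision."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BrainMask:
    data, affine = _load_nifti(path)
    return BrainMask(data=np.rint(data).astype(np.uint8), affine=affine)


def read_atlas(path: str | Path, labels_tsv: str | Path | None = None) -> LabelAtlas:
    """Read a label atlas; optional 2-column TSV (label_id, region_name)."""
    data, affine = _load_nifti(path)
    labels: dict[int, str] = {}
    if labels_tsv is not None:
        tab = pd.read_csv(labels_tsv, sep="\t", header=None, names=["label_id", "region_name"])
        labels = {int(r.label_id): str(r.region_name) for r in tab.itertuples()}
    return LabelAtlas(data=data, affine=affine, labels=labels)


def write_atlas_labels(atlas: LabelAtlas, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"label_id": list(atlas.labels), "region_name": list(atlas.labels.values())}
    ).to_csv(path, sep="\t", header=False, index=False)
    return path


def validate_grid(volumes, atol: float = AFFINE_ATOL) -> None:
    """Check that all items share one shape and one affine (within ``atol``).

    Raises :class:`GridMismatchError` naming the first offending item.
    """
    vols = list(volumes)
    if not vols:
        raise ValueError("validate_grid needs at least one volume")
    ref = vols[0]
    for i, v in enumerate(vols[1:], start=1):
        if tuple(v.shape) != tuple(ref.shape):
            raise GridMismatchError(
                f"shape mismatch: item 0 has {tuple(ref.shape)}, item {i} has {tuple(v.shape)}"
            )
        if not np.allclose(v.affine, ref.affine, atol=atol, rtol=0.0):
            delta = float(np.abs(v.affine - ref.affine).max())
            raise GridMismatchError(
                f"affine mismatch: item {i} differs from item 0 by up to {delta:.3g}"
            )


def apply_mask(vol: Volume3D, mask: BrainMask) -> np.ndarray:
    """Extract masked voxel values in the fixed C scan order (last axis fastest)."""
    validate_grid([vol, mask])
    sel = mask.data.astype(bool)
    vals = vol.data[sel]
    if np.isnan(vals).any():
        raise ValueError("NaN voxels inside the mask")
    return vals


def scatter_into_mask(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`apply_mask`: place a masked vector back on the grid."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels,):
        raise ValueError(f"expected {mask.n_voxels} values, got {values.shape}")
    out = np.full(mask.shape, fill, dtype=np.float64)
    out[mask.data.astype(bool)] = values
    return out
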