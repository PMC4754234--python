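"""Volumes, binary masks, NIfTI/Analyze I/O and mid-plane reflection.

A :class:`Volume` is the unit every pipeline stage consumes and produces:
a 3-D scalar grid together with its voxel spacing (mm) and voxel-to-world
affine.  All in-memory computation is floating point regardless of the
on-disk integer type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from cada.errors import DimensionalityError, FormatError

__all__ = [
    "Volume",
    "Mask",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "reflect_midplane",
    "lr_axis",
]


@dataclass
class Volume:
    """A 3-D scalar image with spacing and world affine.

    Parameters
    ----------
    data : ndarray
        3-D array of counts or normalized intensities.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    affine : ndarray
        4x4 voxel-to-world transform.
    id : str
        Subject identifier.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.data.ndim}-D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray, id: str | None = None) -> "Volume":
        """New Volume sharing this volume's grid geometry."""
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       id=self.id if id is None else id)


@dataclass
class Mask:
    """A binary mask congruent with a parent :class:`Volume`.

    ``side`` records which hemisphere the mask belongs to
    (``"left"``, ``"right"`` or ``"none"``).
    """

    data: np.ndarray
    side: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError("mask must be 3-D")
        if self.side not in ("left", "right", "none"):
            raise ValueError(f"side must be left/right/none, got {self.side!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 or Analyze 7.5 volume.

    Raises :class:`FormatError` on unreadable files and
    :class:`DimensionalityError` on non-3-D images.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} is {data.ndim}-D; expected a 3-D volume"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        affine=np.asarray(img.affine, dtype=np.float64),
        id=path.name.split(".")[0],
    )


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32 on disk)."""
    path = Path(path)
    img = nib.Nifti1Image(v.data.astype(np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def write_mask(m: Mask, affine: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI."""
    img = nib.Nifti1Image(m.data.astype(np.uint8), np.asarray(affine))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_mask(path: str | Path, side: str = "none") -> Mask:
    v = read_volume(path)
    return Mask(data=v.data > 0.5, side=side)


def lr_axis(affine: np.ndarray) -> int:
    """Array axis most aligned with the world left-right (x) direction.

    Falls back to axis 0 when the direction cosines are degenerate.
    """
    direction = np.asarray(affine, dtype=float)[:3, :3]
    norms = np.linalg.norm(direction, axis=0)
    if np.any(norms == 0):
        return 0
    # |x-component| of each voxel axis direction cosine
    xcomp = np.abs(direction[0, :]) / norms
    return int(np.argmax(xcomp))


def reflect_midplane(v: Volume) -> Volume:
    """Flip a volume across the mid-sagittal plane.

    A pure array flip along the left-right axis (index k -> N-1-k), so the
    operation is an exact involution and preserves the voxel sum.
    """
    axis = lr_axis(v.affine)
    return v.copy_with(np.flip(v.data, axis=axis))
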