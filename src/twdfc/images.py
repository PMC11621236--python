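"""Lightweight gridded-volume containers.

``Image3D`` and ``Image4D`` wrap a numpy array plus the NIfTI affine mapping
voxel indices to world (RAS, mm) coordinates.  ``Image4D`` additionally
carries the repetition time so windowed analyses can translate seconds to
timepoints.  Conversion to and from :class:`nibabel.Nifti1Image` is lossless
to float32 precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Image3D", "Image4D"]


@dataclass
class Image3D:
    """A 3D volume with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Image3D requires 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Image3D":
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))

    def like(self, data: np.ndarray) -> "Image3D":
        """New image with the same geometry and the given data."""
        return Image3D(data, self.affine.copy())


@dataclass
class Image4D:
    """A 4D (x, y, z, t) volume with affine and repetition time in seconds."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D requires 4D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def frame(self, t: int) -> Image3D:
        return Image3D(self.data[..., t], self.affine.copy())

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        zooms = list(img.header.get_zooms())
        zooms = zooms[:3] + [float(self.tr_s)]
        img.header.set_zooms(tuple(zooms))
        img.header.set_xyzt_units("mm", "sec")
        return img

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Image4D":
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine), tr_s=tr)

    def like(self, data: np.ndarray) -> "Image4D":
        return Image4D(data, self.affine.copy(), tr_s=self.tr_s)
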