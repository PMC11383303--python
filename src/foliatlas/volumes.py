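"""Regular isotropic voxel grids: occupancy, contrast, and label volumes.

All three share the same grid geometry: ``origin`` is the mm position of the
center of voxel (0, 0, 0), ``spacing`` is the isotropic voxel edge in mm,
and the affine maps voxel indices to mm.  Voxel cells are half-open per axis,
``(center - spacing/2, center + spacing/2]``: a point exactly on the plane
between two voxels belongs to the lower-index voxel.  This convention is
shared bit-exactly by the volume→surface and surface→volume transfers.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


class GridMismatchError(ValueError):
    """Two volumes do not share grid geometry (shape, origin, spacing)."""


@dataclass
class _Gridded:
    data: np.ndarray
    origin: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = float(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map mm points to integer voxel indices under the half-open cell rule.

        A coordinate exactly on a cell boundary maps to the lower index.
        Out-of-grid points yield indices outside [0, shape).
        """
        u = (np.atleast_2d(points_mm) - self.origin) / self.spacing
        return np.ceil(u - 0.5).astype(np.int64)

    def in_grid(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)

    def same_grid(self, other: "_Gridded") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "_Gridded") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.origin}/{self.spacing} vs "
                f"{other.shape}@{other.origin}/{other.spacing}"
            )


class OccupancyGrid(_Gridded):
    """Per-apex normalized solid angle snapped to {0, 0.5, 1}."""


class ContrastVolume(_Gridded):
    """Virtual contrast 0–54: twice the 27-apex occupancy sum, stored uint8.

    54 means the voxel's full 3×3×3 apex neighborhood is interior; 0 means
    entirely exterior; intermediate values encode partial occupancy.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.uint8)
        if self.data.max(initial=0) > 54:
            raise ValueError("contrast values must lie in [0, 54]")


class LabelVolume(_Gridded):
    """Integer region labels on the voxel grid, 0 = background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int64)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.origin.copy(), self.spacing)


def write_nifti(volume: _Gridded, path: str, dtype=None) -> None:
    """Write a volume as NIfTI-1.

    Contrast volumes are stored uint8 (max value 54).  Label volumes default
    to uint8 when the maximum id fits, else uint16; requesting uint8 for
    labels above 255 is an explicit error.
    """
    data = volume.data
    if dtype is None:
        if isinstance(volume, LabelVolume) and data.max(initial=0) > 255:
            dtype = np.uint16
        elif isinstance(volume, OccupancyGrid):
            dtype = np.float32
        else:
            dtype = np.uint8
    info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
    if info is not None and data.max(initial=0) > info.max:
        raise ValueError(
            f"label id {int(data.max())} overflows {np.dtype(dtype).name}; use uint16"
        )
    img = nib.Nifti1Image(data.astype(dtype), volume.affine)
    nib.save(img, path)


def read_nifti(path: str, cls=None) -> _Gridded:
    """Read a NIfTI-1 volume written by :func:`write_nifti`.

    ``cls`` selects the returned type (ContrastVolume, LabelVolume,
    OccupancyGrid); default LabelVolume for integer data.
    """
    img = nib.load(path)
    aff = img.affine
    spacing = float(aff[0, 0])
    if not np.allclose(np.diag(aff)[:3], spacing):
        raise ValueError("expected an isotropic diagonal affine")
    data = np.asarray(img.dataobj)
    if cls is None:
        cls = LabelVolume if np.issubdtype(data.dtype, np.integer) else OccupancyGrid
    return cls(data, aff[:3, 3], spacing)
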