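"""Virtual contrast volume from a watertight mesh via solid angles.

The inside/outside test is the summed signed solid angle of the oriented
surface at an observation point (apex): 4π steradians inside, 2π on a
locally planar surface point, 0 outside.  Apexes form a regular isotropic
grid that doubles as the voxel centers; each voxel's contrast is twice the
sum of the normalized solid angles over its 3×3×3 apex neighborhood, an
integer 0–54 that is roughly proportional to the portion of the voxel lying
inside the surface and fits an unsigned 8-bit store.

Per-triangle solid angles use the Van Oosterom–Strackee arctangent formula,
vectorized over apex × face blocks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .mesh import TriangleMesh
from .volumes import ContrastVolume, OccupancyGrid

FOUR_PI = 4.0 * np.pi

#: Default apex spacing in mm (the working resolution of the source atlas).
DEFAULT_SPACING_MM = 0.4

#: Default snap tolerance as a fraction of 4π.
DEFAULT_TOLERANCE = 0.05


class NonWatertightSurfaceError(ValueError):
    """Normalized solid angle near none of {0, 0.5, 1}: open or self-intersecting surface."""


#: Fixed oblique perturbation direction for degenerate apexes (never
#: parallel to a coordinate axis or the main diagonal).
_PERTURB_DIR = np.array([1.0, np.e, np.pi]) / np.linalg.norm([1.0, np.e, np.pi])


def _solid_angle_block(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Summed principal-value solid angle at each point; ``tri`` is (F, 3, 3)."""
    r = tri[None, :, :, :] - points[:, None, None, :]  # (N, F, 3, 3)
    r1, r2, r3 = r[..., 0, :], r[..., 1, :], r[..., 2, :]
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    n3 = np.linalg.norm(r3, axis=-1)
    det = np.einsum("...i,...i->...", r1, np.cross(r2, r3))
    denom = (
        n1 * n2 * n3
        + np.einsum("...i,...i->...", r1, r2) * n3
        + np.einsum("...i,...i->...", r2, r3) * n1
        + np.einsum("...i,...i->...", r3, r1) * n2
    )
    term = 2.0 * np.arctan2(det, denom)
    # a triangle seen edge-on (apex in its plane) subtends zero solid angle;
    # the principal value must be taken explicitly because atan2(±0, -x)
    # would yield ±2π for an apex inside the coplanar triangle
    term[np.abs(det) <= 1e-12 * n1 * n2 * n3] = 0.0
    return np.sum(term, axis=-1)


def _ambiguous(omega: np.ndarray) -> np.ndarray:
    """True where omega is not near a winding multiple {0, 2π, 4π}.

    Happens only for apexes on a surface edge or vertex (wedge or cone
    angles), which must be perturbed off the degeneracy.
    """
    snapped = np.clip(np.round(omega / (2 * np.pi)), 0, 2) * 2 * np.pi
    return np.abs(omega - snapped) > 0.02 * FOUR_PI


def solid_angles(
    points_mm: np.ndarray,
    mesh: TriangleMesh,
    perturb_step: float = 1e-6,
    validate: bool = True,
) -> np.ndarray:
    """Summed signed solid angle (steradians) of the surface at each point.

    Points lying on a surface edge or vertex subtend a genuine wedge/cone
    angle that snaps to none of {0, 2π, 4π}; such points are perturbed by
    ``perturb_step`` mm along a fixed oblique direction, deterministically,
    and re-evaluated.  Points on the interior of a planar facet need no
    perturbation: the principal-value sum is exactly 2π there.
    """
    if validate:
        mesh.validate()
    points = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    n_faces = len(tri)
    chunk = max(1, int(1_000_000 // max(n_faces, 1)))
    omega = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        pts = points[lo:lo + chunk]
        om = _solid_angle_block(pts, tri)
        bad = _ambiguous(om)
        if np.any(bad):
            shifted = pts[bad].copy()
            for _ in range(5):
                shifted += perturb_step * _PERTURB_DIR
                om_b = _solid_angle_block(shifted, tri)
                if not np.any(_ambiguous(om_b)):
                    break
            om[bad] = om_b
        omega[lo:lo + chunk] = om
    return omega


def solid_angle_sum(apex_mm, mesh: TriangleMesh, perturb_step: float = 1e-6) -> float:
    """Solid angle (steradians) subtended by the surface at one apex.

    4π for an interior point, 2π on a locally planar boundary point, 0
    outside, up to floating-point error.
    """
    return float(solid_angles(np.asarray(apex_mm, float).reshape(1, 3), mesh, perturb_step)[0])


def classify_apex(omega, tolerance: float = DEFAULT_TOLERANCE):
    """Snap ``omega``/4π (scalar or array) to the nearest of {0, 0.5, 1}.

    A value farther than ``tolerance`` (fraction of 4π) from all snap points
    signals a defective surface and raises
    :class:`NonWatertightSurfaceError`.
    """
    if not 0.0 < tolerance < 0.25:
        raise ValueError("tolerance must lie in (0, 0.25)")
    w = np.asarray(omega, dtype=np.float64) / FOUR_PI
    snapped = np.clip(np.round(w * 2.0) / 2.0, 0.0, 1.0)
    off = np.abs(w - snapped)
    if np.any(off > tolerance):
        worst = np.max(off)
        raise NonWatertightSurfaceError(
            f"normalized solid angle {worst:.4f} away from nearest of {{0, 0.5, 1}}: "
            "surface appears open or self-intersecting"
        )
    return float(snapped) if np.isscalar(omega) else snapped


def build_contrast_volume(
    mesh: TriangleMesh,
    spacing_mm: float = DEFAULT_SPACING_MM,
    padding_voxels: int = 2,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[OccupancyGrid, ContrastVolume]:
    """Voxelize a watertight mesh into occupancy and 0–54 contrast volumes.

    The apex grid coincides with the voxel centers and covers the mesh
    bounding box plus ``padding_voxels`` on every side (padding ≥ 1 gives
    every mesh-adjacent voxel a full 27-apex neighborhood).  Grid-boundary
    voxels sum only existing apexes.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if padding_voxels < 0:
        raise ValueError("padding must be non-negative")
    mesh.validate()
    vmin = mesh.vertices.min(axis=0)
    vmax = mesh.vertices.max(axis=0)
    dims = np.ceil((vmax - vmin) / spacing_mm).astype(int) + 1 + 2 * padding_voxels
    origin = vmin - padding_voxels * spacing_mm
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    apexes = origin + spacing_mm * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    omega = solid_angles(apexes, mesh, perturb_step=1e-6 * spacing_mm, validate=False)
    occ = classify_apex(omega, tolerance=tolerance).reshape(tuple(dims))
    if not np.any(occ == 1.0):
        warnings.warn(
            "no apex lies strictly inside the surface; the grid spacing is "
            "likely too coarse for this mesh",
            stacklevel=2,
        )
    occ2 = np.rint(occ * 2.0).astype(np.int64)  # exact: values {0, 1, 2}
    contrast = ndimage.convolve(occ2, np.ones((3, 3, 3), dtype=np.int64), mode="constant", cval=0)
    return (
        OccupancyGrid(occ, origin, spacing_mm),
        ContrastVolume(contrast.astype(np.uint8), origin, spacing_mm),
    )
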