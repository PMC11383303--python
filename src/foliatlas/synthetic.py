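"""Synthetic labeled test surfaces with analytically known spherical maps.

The generator emulates the geometry of a folded cortical sheet: an icosphere
radially perturbed by a smooth angular modulation ("foliation"), with region
labels assigned as contiguous latitude/longitude sectors.  Because the
perturbed surface is star-shaped around the origin, radial projection onto
the unit sphere is an exact, bijective spherical representation.

Default dimensions emulate the human cerebellar cortex: a total surface area
of roughly 1,520 cm² (the scale implied by ~800 patches of ~1.9 cm² mean
area) split into 8 regions.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .mesh import SphericalMap, SurfaceLabeling, TriangleMesh

#: Region display colors (cycled) for generated labelings.
_PALETTE = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
]


def make_icosphere(radius_mm: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere with 10·4^n + 2 vertices, vertices exactly on the sphere."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(m.vertices, dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return TriangleMesh(v * radius_mm, np.asarray(m.faces, dtype=np.int64))


def make_cube(extent_mm: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned cube of 12 triangles, consistently outward oriented."""
    m = trimesh.creation.box(extents=[extent_mm] * 3)
    return TriangleMesh(
        np.asarray(m.vertices, dtype=np.float64) + np.asarray(center, dtype=np.float64),
        np.asarray(m.faces, dtype=np.int64),
    )


def _sector_labels(unit: np.ndarray, n_regions: int) -> np.ndarray:
    """Assign 1-based region labels by latitude band × longitude slice.

    The sector grid is n_lat × n_lon with n_lat·n_lon = n_regions and n_lat
    the largest divisor of n_regions not exceeding sqrt(n_regions).  Points
    exactly on a sector boundary go to the lower region id.
    """
    n_lat = int(np.floor(np.sqrt(n_regions)))
    while n_regions % n_lat:
        n_lat -= 1
    n_lon = n_regions // n_lat
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # polar angle [0, pi]
    phi = np.arctan2(unit[:, 1], unit[:, 0])  # azimuth [-pi, pi]
    lat_edges = np.linspace(0.0, np.pi, n_lat + 1)[1:-1]
    lon_edges = np.linspace(-np.pi, np.pi, n_lon + 1)[1:-1]
    # side='left': a value equal to an edge is inserted before it -> lower bin
    lat = np.searchsorted(lat_edges, theta, side="left")
    lon = np.searchsorted(lon_edges, phi, side="left")
    return (lat * n_lon + lon + 1).astype(np.int64)


def make_labeled_sphere(
    radius_mm: float = 100.0,
    subdivisions: int = 6,
    n_regions: int = 8,
    fold_amplitude: float | None = None,
    fold_frequency: float = 6.0,
    seed: int = 0,
) -> tuple[TriangleMesh, SurfaceLabeling, SphericalMap]:
    """Foliated labeled sphere with an exact radial spherical map.

    The radius is modulated as
    ``r(theta, phi) = radius * (1 + (fold_amplitude/radius) *
    sin(fold_frequency*theta) * sin(fold_frequency*phi))``, which keeps the
    surface star-shaped for ``fold_amplitude < radius`` and adds surface area
    relative to the unperturbed sphere, mimicking cortical folding.  Regions
    are contiguous latitude/longitude sectors.  The construction is fully
    deterministic; ``seed`` is recorded for parity with downstream stages
    that do consume randomness.

    Returns
    -------
    (TriangleMesh, SurfaceLabeling, SphericalMap)
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if fold_amplitude is None:
        # default relief: 11.6% of the radius, sized so the default sphere
        # (radius 100 mm) carries ~1,520 cm² of folded surface
        fold_amplitude = 0.116 * radius_mm
    if fold_amplitude >= radius_mm:
        raise ValueError(
            "fold_amplitude must be smaller than the radius "
            "(larger folds risk a self-intersecting, non-star-shaped surface)"
        )
    del seed  # construction is deterministic
    base = make_icosphere(radius_mm=1.0, subdivisions=subdivisions)
    unit = base.vertices  # already unit vectors
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    r = radius_mm * (
        1.0
        + (fold_amplitude / radius_mm)
        * np.sin(fold_frequency * theta)
        * np.sin(fold_frequency * phi)
    )
    mesh = TriangleMesh(unit * r[:, None], base.faces)
    labels = _sector_labels(unit, n_regions)
    regions = {
        k: (f"region_{k:02d}", _PALETTE[(k - 1) % len(_PALETTE)])
        for k in range(1, n_regions + 1)
    }
    labeling = SurfaceLabeling(labels, regions)
    sphere = SphericalMap(unit.copy())
    return mesh, labeling, sphere


def radial_spherical_map(mesh: TriangleMesh) -> SphericalMap:
    """Radial projection of vertices to the unit sphere.

    Exact (bijective) only for surfaces star-shaped around the origin, which
    holds for all meshes produced by :func:`make_labeled_sphere`.
    """
    norms = np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("vertex at the origin cannot be projected radially")
    return SphericalMap(mesh.vertices / norms)
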