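"""Core surface types: triangulated meshes, spherical maps, labelings, parcellations.

Coordinates are millimetres throughout; vertex indices are 0-based.  The mesh
is the substrate of the atlas: a watertight, consistently oriented triangular
tessellation of a cortical surface.  A spherical map carries one unit-sphere
point per vertex and is used to approximate geodesic distances by Euclidean
ones; a surface labeling carries one integer region label per vertex (0 =
unlabeled) plus a region table; a parcellation subdivides labeled regions
into patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class MeshValidationError(ValueError):
    """Raised when a surface violates the watertight/oriented invariants."""


@dataclass
class TriangleMesh:
    """Watertight oriented triangle mesh in mm coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Triangles as ordered vertex-index triples.  Consistent orientation
        means each undirected edge is traversed in opposite directions by
        its two incident faces.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self, check_degenerate: bool = True) -> None:
        """Check watertightness, orientation, and non-degeneracy.

        Raises
        ------
        MeshValidationError
            Naming the offending edges (at most 20 listed) or faces.
        """
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise MeshValidationError("face indices out of vertex range")
        directed = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        # consistent orientation <=> every directed edge occurs exactly once
        # and its reverse also occurs exactly once
        keys = directed[:, 0] * self.n_vertices + directed[:, 1]
        uniq, counts = np.unique(keys, return_counts=True)
        if np.any(counts > 1):
            bad = uniq[counts > 1][:20]
            edges = [(int(k // self.n_vertices), int(k % self.n_vertices)) for k in bad]
            raise MeshValidationError(
                f"inconsistently oriented or non-manifold edges: {edges}"
            )
        rev = directed[:, 1] * self.n_vertices + directed[:, 0]
        missing = np.setdiff1d(keys, rev)
        if missing.size:
            edges = [(int(k // self.n_vertices), int(k % self.n_vertices)) for k in missing[:20]]
            raise MeshValidationError(f"boundary (non-watertight) edges: {edges}")
        if check_degenerate:
            areas = face_areas(self, validate=False)
            if np.any(areas <= 0.0):
                raise MeshValidationError(
                    f"degenerate (zero-area) faces: {np.flatnonzero(areas <= 0.0)[:20].tolist()}"
                )


def vertex_adjacency(mesh: TriangleMesh, validate: bool = True) -> list[np.ndarray]:
    """Per-vertex neighbor lists (sorted ascending) from the mesh edge graph.

    The adjacency is symmetric by construction.  Raises
    :class:`MeshValidationError` on a non-watertight mesh when ``validate``.
    """
    if validate:
        mesh.validate(check_degenerate=False)
    rows, cols = _edge_arrays(mesh)
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    starts = np.searchsorted(rows, np.arange(mesh.n_vertices + 1))
    return [cols[starts[i]:starts[i + 1]] for i in range(mesh.n_vertices)]


def _edge_arrays(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric (row, col) arrays of unique undirected edges, both directions."""
    e = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return rows, cols


def adjacency_matrix(mesh: TriangleMesh) -> sp.csr_matrix:
    """Sparse symmetric 0/1 vertex adjacency matrix."""
    rows, cols = _edge_arrays(mesh)
    n = mesh.n_vertices
    return sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )


def face_areas(mesh: TriangleMesh, validate: bool = True) -> np.ndarray:
    """Per-face area in mm² (half the cross-product magnitude)."""
    if validate:
        mesh.validate(check_degenerate=False)
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def total_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm²."""
    return float(face_areas(mesh, validate=False).sum())


@dataclass
class SphericalMap:
    """Per-vertex unit-sphere coordinates, one entry per mesh vertex."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)

    def validate(self, mesh: TriangleMesh | None = None, rtol: float = 1e-9) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, rtol=rtol, atol=rtol):
            raise ValueError("spherical map points must have unit norm")
        if mesh is not None and len(self.coords) != mesh.n_vertices:
            raise ValueError(
                f"spherical map has {len(self.coords)} points for a mesh "
                f"with {mesh.n_vertices} vertices"
            )


@dataclass
class SurfaceLabeling:
    """Per-vertex integer region labels (0 = unlabeled) plus a region table.

    ``regions`` maps label id -> (name, (R, G, B)).  Label 0 never appears
    in the table.
    """

    labels: np.ndarray
    regions: dict[int, tuple[str, tuple[int, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    def validate(self, mesh: TriangleMesh | None = None) -> None:
        if 0 in self.regions:
            raise ValueError("label 0 (unlabeled) must not appear in the region table")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.regions)
        if missing:
            raise ValueError(f"labels on vertices missing from region table: {sorted(missing)}")
        if mesh is not None and len(self.labels) != mesh.n_vertices:
            raise ValueError("label count does not match vertex count")

    def copy(self) -> "SurfaceLabeling":
        return SurfaceLabeling(self.labels.copy(), dict(self.regions))


@dataclass
class Parcellation:
    """Per-vertex patch ids (1-based, 0 = no patch) with a patch table.

    ``patches`` maps patch id -> (parent region id, area in cm²).
    """

    patch_ids: np.ndarray
    patches: dict[int, tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patch_ids = np.asarray(self.patch_ids, dtype=np.int64).ravel()

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def areas_cm2(self) -> np.ndarray:
        """Patch areas in ascending patch-id order."""
        return np.array([self.patches[p][1] for p in sorted(self.patches)])

    def validate(self, mesh: TriangleMesh, labeling: SurfaceLabeling) -> None:
        """Check vertex conservation, purity and edge-connectivity of patches."""
        labeled = labeling.labels != 0
        if np.any(self.patch_ids[labeled] == 0):
            raise ValueError("labeled vertices without a patch id")
        for pid, (region, _area) in self.patches.items():
            verts = np.flatnonzero(self.patch_ids == pid)
            if verts.size == 0:
                raise ValueError(f"empty patch {pid}")
            if np.any(labeling.labels[verts] != region):
                raise ValueError(f"patch {pid} crosses region boundaries")
        adj = adjacency_matrix(mesh)
        for pid in self.patches:
            verts = np.flatnonzero(self.patch_ids == pid)
            sub = adj[verts][:, verts]
            n_comp = sp.csgraph.connected_components(sub, directed=False)[0]
            if n_comp != 1:
                raise ValueError(f"patch {pid} is not edge-connected ({n_comp} components)")
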