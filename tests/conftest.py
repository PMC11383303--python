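"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use different algorithms from the package:
ray-casting parity (Möller–Trumbore) for inside/outside, naive triple-loop
neighborhood modes for the volume filter, and networkx BFS neighborhoods
for the surface filter.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import foliatlas as ft


@pytest.fixture
def unit_cube() -> ft.TriangleMesh:
    return ft.make_cube(1.0)


@pytest.fixture
def tetrahedron() -> ft.TriangleMesh:
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return ft.TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def small_labeled_sphere():
    """642-vertex foliated sphere with 4 regions (radius 20 mm)."""
    return ft.make_labeled_sphere(
        radius_mm=20.0, subdivisions=3, n_regions=4,
        fold_amplitude=2.0, fold_frequency=6.0, seed=0,
    )


def ray_parity_inside(
    points: np.ndarray,
    mesh: ft.TriangleMesh,
    direction=(0.57735027, 0.51449576, 0.63960215),
) -> np.ndarray:
    """Inside test by ray-casting parity (Möller–Trumbore), independent of
    the solid-angle implementation.  The fixed irrational-ish direction
    avoids axis-aligned edge grazing."""
    d = np.asarray(direction, dtype=np.float64)
    d /= np.linalg.norm(d)
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    pvec = np.cross(d, e2)
    det = np.einsum("fi,fi->f", e1, pvec)
    ok = np.abs(det) > 1e-12
    v0, e1, e2, pvec, det = v0[ok], e1[ok], e2[ok], pvec[ok], det[ok]
    inside = np.zeros(len(points), dtype=bool)
    chunk = max(1, 2_000_000 // max(len(v0), 1))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        tvec = p[:, None, :] - v0[None, :, :]
        u = np.einsum("pfi,fi->pf", tvec, pvec) / det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("pfi,i->pf", qvec, d) / det
        t = np.einsum("pfi,fi->pf", qvec, e2) / det
        hit = (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        inside[lo:lo + chunk] = (hit.sum(axis=1) % 2) == 1
    return inside


def naive_mode_smooth_volume(
    data: np.ndarray, in_surface: np.ndarray, iterations: int, include_center: bool
) -> np.ndarray:
    """Triple-loop 26/27-neighborhood mode filter with the package's
    tie-break (keep current if modal, else smallest id)."""
    data = data.copy()
    shape = data.shape
    offsets = [
        o for o in itertools.product((-1, 0, 1), repeat=3)
        if include_center or o != (0, 0, 0)
    ]
    for _ in range(iterations):
        new = data.copy()
        for i, j, k in np.ndindex(shape):
            if not in_surface[i, j, k]:
                continue
            votes: dict[int, int] = {}
            for di, dj, dk in offsets:
                a, b, c = i + di, j + dj, k + dk
                if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                    lab = data[a, b, c]
                    if lab != 0:
                        votes[lab] = votes.get(lab, 0) + 1
            if not votes:
                continue
            m = max(votes.values())
            modal = sorted(lab for lab, cnt in votes.items() if cnt == m)
            cur = int(data[i, j, k])
            new[i, j, k] = cur if cur in modal else modal[0]
        data = new
    return data


def naive_mode_smooth_surface(
    labels: np.ndarray, mesh: ft.TriangleMesh, hops: int, iterations: int
) -> np.ndarray:
    """Per-vertex BFS to depth ``hops`` (networkx), then mode with the
    package's tie-break."""
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    edges = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    g.add_edges_from(map(tuple, edges))
    hoods = [
        sorted(nx.single_source_shortest_path_length(g, v, cutoff=hops))
        for v in range(mesh.n_vertices)
    ]
    labels = labels.copy()
    for _ in range(iterations):
        new = labels.copy()
        for v, hood in enumerate(hoods):
            if labels[v] == 0:
                continue
            votes: dict[int, int] = {}
            for u in hood:
                if labels[u] != 0:
                    votes[labels[u]] = votes.get(labels[u], 0) + 1
            m = max(votes.values())
            modal = sorted(lab for lab, cnt in votes.items() if cnt == m)
            new[v] = labels[v] if labels[v] in modal else modal[0]
        labels = new
    return labels
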