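"""Transfer volumetric labels to the surface and keep the two consistent.

A surface atlas is created by assigning to each vertex the label of the
voxel containing it.  Vertices falling in background (contrast = 0) or
out-of-grid voxels are repaired by copying the label of the closest labeled
vertex; the labeling is then smoothed on the mesh graph by a mode filter
over the ≤ ``hops``-edge neighborhood; finally, consistency is enforced in
the opposite direction by setting every vertex-containing voxel to the mode
of the labels of its contained vertices.

Voxel membership uses the shared half-open cell convention of
:mod:`foliatlas.volumes`: a point exactly on the boundary plane between two
voxels belongs to the lower-index voxel.  Mode ties keep the current label
when modal, else take the smallest label id, as in the volume filters.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .mesh import SurfaceLabeling, TriangleMesh, adjacency_matrix
from .volumes import LabelVolume


def transfer_to_surface(
    mesh: TriangleMesh,
    labels: LabelVolume,
    regions: dict[int, tuple[str, tuple[int, int, int]]] | None = None,
) -> SurfaceLabeling:
    """Per-vertex label = label of the voxel containing the vertex.

    Vertices in background or out-of-grid voxels get label 0; the number of
    out-of-grid vertices is reported as a warning.
    """
    idx = labels.voxel_index(mesh.vertices)
    inside = labels.in_grid(idx)
    out = np.zeros(mesh.n_vertices, dtype=np.int64)
    ii = idx[inside]
    out[inside] = labels.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} vertices fall outside the volume grid", stacklevel=2)
    if regions is None:
        regions = {
            int(k): (f"region_{int(k):02d}", (128, 128, 128))
            for k in np.unique(out)
            if k != 0
        }
    else:
        regions = {k: v for k, v in regions.items() if k != 0}
    return SurfaceLabeling(out, regions)


def nearest_vertex_fill(
    labeling: SurfaceLabeling, mesh: TriangleMesh
) -> SurfaceLabeling:
    """Give every unlabeled vertex the label of the closest labeled vertex.

    Distance is Euclidean in mm; exact distance ties go to the labeled
    vertex with the smaller index.
    """
    out = labeling.copy()
    unlabeled = np.flatnonzero(out.labels == 0)
    if unlabeled.size == 0:
        return out
    labeled = np.flatnonzero(out.labels != 0)
    if labeled.size == 0:
        raise ValueError("no labeled vertices to fill from")
    tree = cKDTree(mesh.vertices[labeled])
    k = min(8, labeled.size)
    dist, nn = tree.query(mesh.vertices[unlabeled], k=k)
    dist = np.atleast_2d(dist.T).T
    nn = np.atleast_2d(nn.T).T
    # among the k nearest, keep every candidate tied with the minimum
    # distance (within fp tolerance) and take the smallest vertex index
    tied = dist <= dist[:, :1] * (1 + 1e-12) + 1e-12
    cand = np.where(tied, labeled[nn], np.iinfo(np.int64).max)
    best = cand.min(axis=1)
    out.labels[unlabeled] = out.labels[best]
    return out


def hop_neighborhood_matrix(
    adj: sp.csr_matrix, hops: int = 3
) -> sp.csr_matrix:
    """Boolean reachability matrix for graph distance ≤ hops, self included."""
    n = adj.shape[0]
    a1 = (adj.astype(bool) + sp.identity(n, dtype=bool, format="csr")).tocsr()
    reach = a1
    for _ in range(hops - 1):
        reach = (reach @ a1).astype(bool).tocsr()
    return reach


def _mode_sweep_ids(ids: np.ndarray, reach: sp.csr_matrix) -> np.ndarray:
    """One synchronous mode sweep of integer ids over a reachability matrix.

    Zero ids neither change nor contribute.  Ties keep the current id when
    it is modal, else take the smallest modal id.
    """
    labs = np.unique(ids)
    labs = labs[labs != 0]
    if labs.size <= 1:
        return ids.copy()
    col = np.searchsorted(labs, ids)
    labeled = ids != 0
    onehot = np.zeros((len(ids), len(labs)), dtype=np.int64)
    onehot[np.flatnonzero(labeled), col[labeled]] = 1
    counts = reach.astype(np.int64) @ onehot
    maxc = counts.max(axis=1)
    smallest_modal = labs[np.argmax(counts, axis=1)]
    cur = np.where(labeled, counts[np.arange(len(ids)), np.clip(col, 0, len(labs) - 1)], -1)
    new = ids.copy()
    upd = labeled & (maxc > 0) & (cur != maxc)
    new[upd] = smallest_modal[upd]
    return new


def mode_smooth_surface(
    labeling: SurfaceLabeling,
    mesh: TriangleMesh,
    hops: int = 3,
    iterations: int = 3,
) -> SurfaceLabeling:
    """Mode-filter vertex labels over the ≤ ``hops``-edge neighborhood.

    Per iteration every vertex simultaneously takes the mode over all
    vertices within graph distance ≤ ``hops`` of it (itself included);
    exactly ``iterations`` synchronous sweeps are applied.
    """
    out = labeling.copy()
    if iterations <= 0:
        return out
    reach = hop_neighborhood_matrix(adjacency_matrix(mesh), hops=hops)
    ids = out.labels
    for _ in range(iterations):
        ids = _mode_sweep_ids(ids, reach)
    out.labels = ids
    return out


def enforce_voxel_vertex_consistency(
    labels: LabelVolume, mesh: TriangleMesh, labeling: SurfaceLabeling
) -> LabelVolume:
    """Set every vertex-containing voxel to the mode of its vertices' labels.

    Voxels containing no vertices are unchanged; the half-open cell rule
    matches :func:`transfer_to_surface`.  Ties keep the voxel's current
    label when modal, else the smallest vertex label.
    """
    out = labels.copy()
    idx = labels.voxel_index(mesh.vertices)
    inside = labels.in_grid(idx)
    idx = idx[inside]
    vlabs = labeling.labels[inside]
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), labels.shape)
    kmax = int(vlabs.max(initial=0)) + 1
    pair = flat * kmax + vlabs
    pairs, counts = np.unique(pair, return_counts=True)
    vox = pairs // kmax
    lab = pairs % kmax
    starts = np.flatnonzero(np.r_[True, np.diff(vox) != 0])
    group_max = np.maximum.reduceat(counts, starts)
    sizes = np.diff(np.r_[starts, len(pairs)])
    is_max = counts == np.repeat(group_max, sizes)
    sentinel = len(pairs)
    first_max = np.minimum.reduceat(
        np.where(is_max, np.arange(len(pairs)), sentinel), starts
    )
    vox_ids = vox[starts]
    winner = lab[first_max]
    # keep the voxel's current label when it is among the modal labels
    cur = out.data.ravel()[vox_ids]
    cur_pair = vox_ids * kmax + cur
    pos = np.searchsorted(pairs, cur_pair)
    pos_ok = (pos < len(pairs)) & (pairs[np.clip(pos, 0, len(pairs) - 1)] == cur_pair)
    cur_count = np.where(pos_ok, counts[np.clip(pos, 0, len(pairs) - 1)], -1)
    winner = np.where(cur_count == group_max, cur, winner)
    flat_out = out.data.ravel()
    flat_out[vox_ids] = winner
    out.data = flat_out.reshape(labels.shape)
    return out
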