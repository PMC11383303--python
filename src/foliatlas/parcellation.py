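"""Subdivide labeled surface regions into approximately equal-area patches.

The procedure is semi-stochastic region growing with area regularization:

1. Each region receives a patch budget proportional to its share of the
   total surface area (largest-remainder rounding of
   ``target_total × area_region / area_total``; 800 by default).
2. That many pointer vertices are drawn uniformly at random in each region.
3. Pointers repel each other for a fixed number of iterations: a pointer
   moves to the adjacent same-region vertex that maximizes its distance to
   the nearest other pointer, with geodesic distance approximated by
   Euclidean distance in the spherical surface representation.
4. Patches grow from the pointers by synchronized breadth-first expansion
   within their region, then patch ids are mode-smoothed on the mesh graph
   (3 hops, 3 iterations) without ever crossing region boundaries.
5. Patches larger than ``split_threshold_cm2`` (3.1) are bisected at the
   median along their first principal axis; patches smaller than
   ``merge_threshold_cm2`` (0.83) are merged into the same-region neighbor
   sharing the longest border.  This repeats for a bounded number of rounds
   and, if bounds are still violated, ends with exactly one final
   split-all-large pass followed by one merge-all-small pass.

Areas are accounted per face: a face belongs to the patch holding the
majority of its three vertices (ties to the smallest patch id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .mesh import (
    Parcellation,
    SphericalMap,
    SurfaceLabeling,
    TriangleMesh,
    adjacency_matrix,
    face_areas,
    vertex_adjacency,
)
from .surface_labeling import _mode_sweep_ids, hop_neighborhood_matrix

MM2_PER_CM2 = 100.0


@dataclass
class ParcellationParams:
    """Tunable parameters of the parcellation pipeline.

    Defaults reproduce the published procedure: 800 initial patches, 100
    pointer-spreading iterations, 3-hop/3-iteration smoothing, split above
    3.1 cm², merge below 0.83 cm², and a bounded split/merge loop followed
    by one forced final split-then-merge pass.
    """

    target_total: int = 800
    spread_iterations: int = 100
    smooth_hops: int = 3
    smooth_iterations: int = 3
    split_threshold_cm2: float = 3.1
    merge_threshold_cm2: float = 0.83
    max_split_merge_rounds: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.merge_threshold_cm2 >= self.split_threshold_cm2:
            raise ValueError("merge threshold must be below split threshold")


def majority_face_owner(ids: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Owner id per face: vertex majority, ties to the smallest id (0 = none)."""
    trip = np.sort(ids[faces], axis=1)
    has_majority = (trip[:, 1] == trip[:, 0]) | (trip[:, 1] == trip[:, 2])
    return np.where(has_majority, trip[:, 1], trip[:, 0])


def region_areas_cm2(mesh: TriangleMesh, labeling: SurfaceLabeling) -> dict[int, float]:
    """Per-region surface area in cm² by face-majority accounting."""
    owner = majority_face_owner(labeling.labels, mesh.faces)
    fa = face_areas(mesh, validate=False)
    out: dict[int, float] = {}
    for lab in sorted(labeling.regions):
        out[lab] = float(fa[owner == lab].sum()) / MM2_PER_CM2
    return out


def patch_areas_cm2(patch_ids: np.ndarray, mesh: TriangleMesh, fa: np.ndarray | None = None) -> dict[int, float]:
    """Per-patch area in cm² by face-majority accounting (0 excluded)."""
    if fa is None:
        fa = face_areas(mesh, validate=False)
    owner = majority_face_owner(patch_ids, mesh.faces)
    sums = np.bincount(owner, weights=fa)
    present = np.unique(patch_ids)
    return {
        int(p): float(sums[p]) / MM2_PER_CM2 if p < len(sums) else 0.0
        for p in present
        if p != 0
    }


def initial_patch_counts(
    region_areas: dict[int, float], target_total: int = 800
) -> dict[int, int]:
    """Area-proportional patch budget per region, largest-remainder rounding.

    Counts sum exactly to ``target_total`` and every region receives at
    least one patch.
    """
    regions = sorted(region_areas)
    if len(regions) > target_total:
        raise ValueError(
            f"{len(regions)} regions exceed the patch budget {target_total}"
        )
    areas = np.array([region_areas[r] for r in regions], dtype=np.float64)
    if np.any(areas <= 0):
        raise ValueError("all region areas must be positive")
    quota = target_total * areas / areas.sum()
    counts = np.floor(quota).astype(np.int64)
    remainder = quota - counts
    short = target_total - counts.sum()
    # distribute leftovers to the largest remainders (ties: lower region id)
    order = np.lexsort((np.arange(len(regions)), -remainder))
    counts[order[:short]] += 1
    # floor of one patch per region, funded by the largest counts
    while np.any(counts == 0):
        counts[np.argmax(counts)] -= 1
        counts[int(np.flatnonzero(counts == 0)[0])] += 1
    return {r: int(c) for r, c in zip(regions, counts)}


def seed_pointers(
    labeling: SurfaceLabeling, counts: dict[int, int], rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pointer vertices uniformly without replacement in each region.

    Returns ``(pointer_vertices, pointer_regions)`` with pointers ordered by
    ascending region id; deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    vertices: list[np.ndarray] = []
    regions: list[np.ndarray] = []
    for region in sorted(counts):
        members = np.flatnonzero(labeling.labels == region)
        k = counts[region]
        if k > members.size:
            raise ValueError(
                f"region {region} has {members.size} vertices, cannot seed {k} pointers"
            )
        chosen = rng.choice(members, size=k, replace=False)
        vertices.append(chosen)
        regions.append(np.full(k, region, dtype=np.int64))
    return np.concatenate(vertices), np.concatenate(regions)


def spread_pointers(
    pointers: np.ndarray,
    sphere: SphericalMap,
    labeling: SurfaceLabeling,
    adjacency: list[np.ndarray],
    iterations: int = 100,
) -> np.ndarray:
    """Repel pointers across the surface for a fixed number of iterations.

    Each pointer, visited in ascending pointer-id order, moves to the
    adjacent vertex of its own region that maximizes the minimum Euclidean
    distance on the spherical representation to all other current pointers;
    it stays put when no neighbor strictly improves that objective, and a
    move onto a vertex already holding a pointer is blocked.
    """
    pos = np.asarray(pointers, dtype=np.int64).copy()
    regions = labeling.labels[pos]
    coords = sphere.coords
    occupied = set(pos.tolist())
    if len(occupied) != len(pos):
        raise ValueError("two pointers occupy one vertex")
    n = len(pos)
    if n == 1:
        return pos
    for _ in range(iterations):
        for i in range(n):
            v = pos[i]
            nbrs = adjacency[v]
            cand = nbrs[labeling.labels[nbrs] == regions[i]]
            cand = np.array([c for c in cand if c not in occupied], dtype=np.int64)
            if cand.size == 0:
                continue
            others = np.delete(pos, i)
            oc = coords[others]
            d_stay = np.min(np.linalg.norm(coords[v] - oc, axis=1))
            dc = np.linalg.norm(coords[cand][:, None, :] - oc[None, :, :], axis=2)
            d_cand = dc.min(axis=1)
            j = int(np.argmax(d_cand))  # candidates ascend by vertex index
            if d_cand[j] > d_stay:
                occupied.discard(int(v))
                pos[i] = cand[j]
                occupied.add(int(cand[j]))
    return pos


def _nearest_assigned(targets: np.ndarray, sources: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Index into ``sources`` of the nearest source per target, ties to the
    source with the smallest vertex index."""
    tree = cKDTree(coords[sources])
    k = min(8, sources.size)
    dist, nn = tree.query(coords[targets], k=k)
    dist = np.atleast_2d(dist.T).T
    nn = np.atleast_2d(nn.T).T
    tied = dist <= dist[:, :1] * (1 + 1e-12) + 1e-12
    cand = np.where(tied, sources[nn], np.iinfo(np.int64).max)
    return cand.min(axis=1)


def _patch_components(
    patch_ids: np.ndarray, adj: sp.csr_matrix, pid: int
) -> list[np.ndarray]:
    """Connected components of one patch, largest first (ties: smallest
    minimum vertex index)."""
    verts = np.flatnonzero(patch_ids == pid)
    sub = adj[verts][:, verts]
    n_comp, comp = csgraph.connected_components(sub, directed=False)
    comps = [verts[comp == c] for c in range(n_comp)]
    comps.sort(key=lambda c: (-len(c), int(c.min())))
    return comps


def _repair_connectivity(
    patch_ids: np.ndarray,
    patch_region: dict[int, int],
    adj: sp.csr_matrix,
    pids: list[int] | None = None,
    max_passes: int = 10,
) -> np.ndarray:
    """Reattach stranded patch fragments to an adjacent same-region patch.

    For every patch that is not edge-connected, all but its largest
    component are reassigned to the neighboring same-region patch sharing
    the most boundary edges with the fragment (ties: smallest patch id).
    Repeats until stable.
    """
    ids = patch_ids.copy()
    for _ in range(max_passes):
        changed = False
        check = pids if pids is not None else sorted(patch_region)
        for pid in check:
            if not np.any(ids == pid):
                continue
            comps = _patch_components(ids, adj, pid)
            for frag in comps[1:]:
                nbr_rows = adj[frag]
                nbr_ids = ids[nbr_rows.indices]
                ok = np.array(
                    [
                        q != pid and q != 0 and patch_region.get(int(q)) == patch_region[pid]
                        for q in nbr_ids
                    ]
                )
                if not ok.any():
                    continue
                counts = np.bincount(nbr_ids[ok])
                target = int(np.argmax(counts))  # argmax -> smallest id on tie
                ids[frag] = target
                changed = True
        if not changed:
            return ids
    return ids


def grow_patches(
    mesh: TriangleMesh,
    pointers: np.ndarray,
    labeling: SurfaceLabeling,
    pointer_regions: np.ndarray | None = None,
    smooth_hops: int = 3,
    smooth_iterations: int = 3,
) -> Parcellation:
    """Grow patches from pointers by synchronized BFS, then smooth ids.

    All patches expand one edge ring per round inside their own region; a
    vertex reached by several patches in the same round goes to the
    smallest patch id.  Labeled region components that no pointer can reach
    are assigned to the nearest same-region patch by Euclidean distance
    (with a warning).  Patch ids are finally mode-smoothed (``smooth_hops``,
    ``smooth_iterations``) on per-region subgraphs so region boundaries are
    never crossed, and any fragment created by smoothing is reattached.
    """
    pointers = np.asarray(pointers, dtype=np.int64)
    if pointer_regions is None:
        pointer_regions = labeling.labels[pointers]
    labels = labeling.labels
    n = mesh.n_vertices
    patch = np.zeros(n, dtype=np.int64)
    patch_region = {
        i + 1: int(r) for i, r in enumerate(pointer_regions)
    }
    if np.any(labels[pointers] != pointer_regions):
        raise ValueError("pointer region does not match the vertex label")
    patch[pointers] = np.arange(1, len(pointers) + 1)
    region_of_patch = np.r_[0, pointer_regions]
    adj = adjacency_matrix(mesh)
    frontier = pointers.copy()
    while frontier.size:
        rows = adj[frontier]
        src = np.repeat(frontier, np.diff(rows.indptr))
        dst = rows.indices.astype(np.int64)
        claim_patch = patch[src]
        ok = (patch[dst] == 0) & (labels[dst] == region_of_patch[claim_patch]) & (labels[dst] != 0)
        dst, claim_patch = dst[ok], claim_patch[ok]
        if dst.size == 0:
            break
        order = np.lexsort((claim_patch, dst))
        dst, claim_patch = dst[order], claim_patch[order]
        first = np.flatnonzero(np.r_[True, np.diff(dst) != 0])
        dst, claim_patch = dst[first], claim_patch[first]
        patch[dst] = claim_patch
        frontier = dst
    orphan = np.flatnonzero((labels != 0) & (patch == 0))
    if orphan.size:
        warnings.warn(
            f"{orphan.size} labeled vertices unreachable from any pointer; "
            "assigned to the nearest same-region patch",
            stacklevel=2,
        )
        for region in np.unique(labels[orphan]):
            targets = orphan[labels[orphan] == region]
            sources = np.flatnonzero((labels == region) & (patch != 0))
            if sources.size == 0:
                raise ValueError(f"region {int(region)} has no pointer at all")
            nearest = _nearest_assigned(targets, sources, mesh.vertices)
            patch[targets] = patch[nearest]
    if smooth_iterations > 0:
        patch = _smooth_patches_within_regions(
            patch, labels, adj, smooth_hops, smooth_iterations
        )
    patch = _repair_connectivity(patch, patch_region, adj)
    areas = patch_areas_cm2(patch, mesh)
    patches = {
        pid: (patch_region[pid], areas.get(pid, 0.0))
        for pid in sorted(patch_region)
        if np.any(patch == pid)
    }
    return Parcellation(patch, patches)


def _smooth_patches_within_regions(
    patch: np.ndarray,
    labels: np.ndarray,
    adj: sp.csr_matrix,
    hops: int,
    iterations: int,
) -> np.ndarray:
    """Mode-smooth patch ids on each region's subgraph independently."""
    out = patch.copy()
    for region in np.unique(labels[labels != 0]):
        verts = np.flatnonzero(labels == region)
        sub = adj[verts][:, verts].tocsr()
        reach = hop_neighborhood_matrix(sub, hops=hops)
        ids = out[verts]
        for _ in range(iterations):
            ids = _mode_sweep_ids(ids, reach)
        out[verts] = ids
    return out


def _split_patch(
    patch_ids: np.ndarray,
    verts: np.ndarray,
    new_id: int,
    old_id: int,
    coords: np.ndarray,
    adj: sp.csr_matrix,
) -> bool:
    """Bisect one patch at the median of its first principal axis.

    The lower-projection half keeps ``old_id``; the upper half becomes
    ``new_id``.  Fragments disconnected from their half's main component
    are flipped to the other half; if a connected two-way split cannot be
    reached the split is abandoned (returns False).
    """
    if verts.size < 2:
        return False
    x = coords[verts]
    xc = x - x.mean(axis=0)
    _w, vec = np.linalg.eigh(xc.T @ xc)
    axis = vec[:, -1]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    t = xc @ axis
    order = np.lexsort((verts, t))
    half = verts.size // 2
    side = np.zeros(verts.size, dtype=bool)  # False = lower/old, True = upper/new
    side[order[half:]] = True
    sub = adj[verts][:, verts].tocsr()
    assign = np.where(side, new_id, old_id)
    for _ in range(10):
        moved = False
        for flag in (False, True):
            members = np.flatnonzero(side == flag)
            if members.size == 0:
                return False
            ssub = sub[members][:, members]
            n_comp, comp = csgraph.connected_components(ssub, directed=False)
            if n_comp <= 1:
                continue
            sizes = np.bincount(comp)
            main = min(
                range(n_comp),
                key=lambda c: (-sizes[c], int(verts[members[comp == c]].min())),
            )
            for c in range(n_comp):
                if c != main:
                    side[members[comp == c]] = not flag
                    moved = True
        if not moved:
            break
    else:
        return False
    if not side.any() or side.all():
        return False
    # verify both halves connected
    for flag in (False, True):
        members = np.flatnonzero(side == flag)
        ssub = sub[members][:, members]
        if csgraph.connected_components(ssub, directed=False)[0] != 1:
            return False
    patch_ids[verts[side]] = new_id
    patch_ids[verts[~side]] = old_id
    return True


def _boundary_neighbor(
    patch_ids: np.ndarray,
    pid: int,
    patch_region: dict[int, int],
    edges: np.ndarray,
    edge_len: np.ndarray,
) -> int | None:
    """Same-region neighbor patch sharing the longest summed border with
    ``pid`` (ties: smallest patch id), or None."""
    a = patch_ids[edges[:, 0]]
    b = patch_ids[edges[:, 1]]
    m1 = a == pid
    m2 = b == pid
    nbr = np.concatenate([b[m1], a[m2]])
    lens = np.concatenate([edge_len[m1], edge_len[m2]])
    region = patch_region[pid]
    ok = np.array(
        [q != pid and q != 0 and patch_region.get(int(q)) == region for q in nbr]
    )
    if not ok.any():
        return None
    sums = np.bincount(nbr[ok], weights=lens[ok])
    return int(np.argmax(sums))  # first max -> smallest patch id


def enforce_area_bounds(
    parc: Parcellation,
    mesh: TriangleMesh,
    params: ParcellationParams | None = None,
) -> Parcellation:
    """Split oversized and merge undersized patches until within bounds.

    Up to ``max_split_merge_rounds`` rounds of (split all patches above the
    split threshold, then merge all patches below the merge threshold); if
    bounds are still violated afterwards, exactly one final split-all-large
    pass followed by one merge-all-small pass is performed and iteration
    stops regardless of the outcome.  Patch ids are compacted to 1..N.
    """
    params = params or ParcellationParams()
    ids = parc.patch_ids.copy()
    patch_region = {pid: reg for pid, (reg, _a) in parc.patches.items()}
    fa = face_areas(mesh, validate=False)
    adj = adjacency_matrix(mesh)
    edges_rows, edges_cols = adj.nonzero()
    keep = edges_rows < edges_cols
    edges = np.stack([edges_rows[keep], edges_cols[keep]], axis=1)
    edge_len = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )

    def split_pass(ids: np.ndarray) -> bool:
        areas = patch_areas_cm2(ids, mesh, fa)
        big = sorted(p for p, a in areas.items() if a > params.split_threshold_cm2)
        did = False
        for pid in big:
            verts = np.flatnonzero(ids == pid)
            new_id = max(patch_region) + 1
            if _split_patch(ids, verts, new_id, pid, mesh.vertices, adj):
                patch_region[new_id] = patch_region[pid]
                did = True
        return did

    def merge_pass(ids: np.ndarray) -> bool:
        areas = patch_areas_cm2(ids, mesh, fa)
        small = sorted(p for p, a in areas.items() if a < params.merge_threshold_cm2)
        did = False
        for pid in small:
            if not np.any(ids == pid) or areas.get(pid, 0.0) >= params.merge_threshold_cm2:
                continue
            target = _boundary_neighbor(ids, pid, patch_region, edges, edge_len)
            if target is None:
                warnings.warn(
                    f"patch {pid} below the merge threshold has no same-region "
                    "neighbor; left in place",
                    stacklevel=3,
                )
                continue
            ids[ids == pid] = target
            areas[target] = areas.get(target, 0.0) + areas.pop(pid, 0.0)
            patch_region.pop(pid)
            did = True
        return did

    def within_bounds(ids: np.ndarray) -> bool:
        areas = patch_areas_cm2(ids, mesh, fa)
        return all(
            params.merge_threshold_cm2 <= a <= params.split_threshold_cm2
            for a in areas.values()
        )

    for _ in range(params.max_split_merge_rounds):
        if within_bounds(ids):
            break
        s = split_pass(ids)
        m = merge_pass(ids)
        if not (s or m):
            break
    if not within_bounds(ids):
        split_pass(ids)
        merge_pass(ids)
    # compact ids to 1..N in ascending old-id order
    present = np.unique(ids)
    present = present[present != 0]
    remap = np.zeros(int(present.max(initial=0)) + 1, dtype=np.int64)
    remap[present] = np.arange(1, len(present) + 1)
    ids = np.where(ids > 0, remap[ids], 0)
    areas = patch_areas_cm2(ids, mesh, fa)
    patches = {
        int(remap[old]): (patch_region[int(old)], areas.get(int(remap[old]), 0.0))
        for old in present
    }
    return Parcellation(ids, patches)


def patch_statistics(parc: Parcellation) -> dict[str, float]:
    """Count and mean/std/min/max patch area (cm²)."""
    a = parc.areas_cm2()
    return {
        "n_patches": int(len(a)),
        "mean_cm2": float(a.mean()),
        "std_cm2": float(a.std()),
        "min_cm2": float(a.min()),
        "max_cm2": float(a.max()),
    }


def parcellate(
    mesh: TriangleMesh,
    labeling: SurfaceLabeling,
    sphere: SphericalMap,
    params: ParcellationParams | None = None,
) -> tuple[Parcellation, dict]:
    """Full parcellation pipeline; returns the parcellation and a report.

    The report records the seed and parameters plus count and mean/std/min/
    max patch area in cm², enough to reproduce the run bit-exactly.
    """
    params = params or ParcellationParams()
    labeling.validate(mesh)
    sphere.validate(mesh)
    areas = region_areas_cm2(mesh, labeling)
    counts = initial_patch_counts(areas, params.target_total)
    pointers, pregions = seed_pointers(labeling, counts, params.rng_seed)
    adj_lists = vertex_adjacency(mesh, validate=False)
    pointers = spread_pointers(
        pointers, sphere, labeling, adj_lists, iterations=params.spread_iterations
    )
    parc = grow_patches(
        mesh,
        pointers,
        labeling,
        pointer_regions=pregions,
        smooth_hops=params.smooth_hops,
        smooth_iterations=params.smooth_iterations,
    )
    parc = enforce_area_bounds(parc, mesh, params)
    report = {"params": asdict(params), **patch_statistics(parc)}
    return parc, report
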