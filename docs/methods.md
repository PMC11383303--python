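# Methods

## The model

The toolkit treats a cortical sheet as a watertight, consistently oriented
triangle mesh in millimetre coordinates. All downstream structure — the
contrast volume, the label volumes, the surface atlas, and the parcellation
— is derived from that mesh and is deterministic given the inputs and one
integer seed.

### Solid-angle voxelization

The inside/outside/on-surface decision at an observation point (apex) uses
the summed signed solid angle of the oriented surface,

    Ω(p) = Σ_faces 2·atan2( r₁·(r₂×r₃), |r₁||r₂||r₃| + (r₁·r₂)|r₃| + (r₂·r₃)|r₁| + (r₃·r₁)|r₂| )

(the Van Oosterom–Strackee arctangent form), which is 4π for an interior
point, 2π on a locally planar surface point, and 0 outside. Ω/4π is
snapped to {1, ½, 0}; a value farther than a tolerance (default 0.05,
fraction of 4π) from every snap point is diagnosed as an open or
self-intersecting surface rather than silently rounded.

Two numerical points matter:

- **Coplanar triangles.** For an apex lying in the plane of a triangle the
  arctangent term must be taken at its principal value 0 (a triangle seen
  edge-on subtends no solid angle). `atan2(±0, −x)` would otherwise
  return ±π and double-count apexes on planar facets. With this rule an
  apex on the interior of a planar facet evaluates to exactly 2π with no
  perturbation, including apexes on the shared diagonal of two coplanar
  triangles.
- **Edge and vertex apexes.** An apex on a non-planar edge or vertex
  subtends a genuine wedge/cone angle that is near none of {0, 2π, 4π}.
  Such apexes (detected by that very criterion, at 2% of 4π) are moved by
  1e-6 grid spacings along a fixed oblique direction (unit vector
  ∝ (1, e, π)) and re-evaluated, deterministically. An axis-aligned
  perturbation would fail for edges parallel to it, which is why an
  oblique direction is used. These are measure-zero events; the snap
  value an on-edge apex receives after perturbation (inside or outside)
  is arbitrary but reproducible.

The apex grid coincides with the voxel centers, covers the mesh bounding
box plus a padding (default 2 voxels, ensuring mesh-adjacent voxels have
complete 27-apex neighborhoods), and the voxel contrast is
`2 × Σ occupancy` over the 3×3×3 neighborhood — an integer in [0, 54]
stored as uint8, roughly proportional to the voxel's interior fraction.
Grid-boundary voxels simply sum fewer apexes (no mirroring). The default
apex spacing is 0.4 mm, the working resolution of the source atlas; all
tests and examples pass coarser spacings explicitly to match their mesh
scale.

### Label-volume cleaning

Labels are painted manually on the contrast volume in practice; the
automated stages assume only a label volume sharing the contrast grid.
Neighborhoods are 26-connected, matching the 27-apex contrast
construction. Sweeps are synchronous (Jacobi-style, computed from the
previous state), so results do not depend on voxel visiting order. Mode
ties keep the element's current label when it is among the modal set and
otherwise take the smallest label id — deterministic and minimally
churning. The fill stage errors out, naming the components, if some
26-connected in-surface component contains no label at all (detected as a
sweep that makes no progress; progress is otherwise strictly monotone, so
termination is bounded by the in-surface voxel count).

### Volume ↔ surface transfer

Voxel membership of a point uses half-open cells, `(c − s/2, c + s/2]` per
axis: a point exactly on the plane between two voxels belongs to the
lower-index voxel. The same convention is used bit-exactly in both
directions (vertex ← voxel lookup and voxel ← mode of contained vertices),
which is what makes the consistency pass a fixed point at voxels whose
contained vertices are unanimous. "Closest labeled vertex" for gap repair
is Euclidean in mm — gaps are local (a vertex inside a contrast-0 voxel
sits within one voxel of labeled cortex), so geodesic distance would add
cost without changing results in practice; exact distance ties go to the
smaller vertex index. Surface smoothing takes the mode over all vertices
within 3 edges (self included), three iterations, synchronous.

### Parcellation

Regions are subdivided into approximately equal-area patches:

1. **Budget.** `target_total` (default 800) patches are apportioned to
   regions in proportion to region area with largest-remainder rounding
   (exact total, ties to the lower region id) and a floor of one patch per
   region funded from the largest allocations.
2. **Seeding.** Pointer vertices are drawn uniformly without replacement
   within each region from one `numpy` Generator seeded by `rng_seed`.
3. **Spreading.** For 100 iterations, each pointer in ascending id order
   moves to the adjacent same-region vertex that maximizes its distance to
   the *nearest* other pointer (farthest-point reading of "moved away from
   one another"); distance is Euclidean between the vertices' images in
   the spherical surface representation, a standard geodesic proxy. A
   pointer stays put when no neighbor strictly improves the objective or
   when the best vertex is already occupied.
4. **Growth.** All patches expand one edge ring per round (synchronized
   BFS) inside their own region; same-round collisions go to the smallest
   patch id. Region components unreachable from any pointer are assigned
   to the nearest same-region patch by Euclidean distance, with a warning.
   Patch ids are then mode-smoothed (3 hops, 3 iterations) on per-region
   subgraphs, so region boundaries are never crossed; any fragment the
   smoothing strands is reattached to the adjacent same-region patch
   sharing the most boundary edges. Smoothing can absorb a very small
   patch entirely; growth itself conserves the patch count exactly.
5. **Area bounds.** Patch areas use face-majority accounting: a face
   belongs to the patch holding ≥ 2 of its vertices (ties to the smallest
   id). Up to `max_split_merge_rounds` (default 10) rounds, every patch
   above 3.1 cm² is bisected at the median of its first principal axis
   (the lower-projection half keeps the id; disconnected fragments are
   flipped to the other half, and a split that cannot produce two
   connected halves is abandoned), then every patch below 0.83 cm² is
   merged into the same-region neighbor sharing the longest summed
   boundary-edge length. The loop does not converge for all
   configurations, so if bounds are still violated a single final
   split-all-large pass followed by one merge-all-small pass is performed
   and iteration stops. Patch ids are compacted to 1..N.

Every stage is a pure function of (mesh, labeling, spherical map,
parameters); the report records the seed and all parameters.

## Synthetic data

`make_labeled_sphere` emulates a folded cortical sheet: an icosphere whose
radius is modulated by `r(θ, φ) = R·(1 + (A/R)·sin(fθ)·sin(fφ))`. The
surface is star-shaped for A < R, so radial projection onto the unit
sphere is an exact, bijective spherical representation — the synthetic
analogue of the spherical surface produced by surface-inflation pipelines.
Regions are contiguous latitude/longitude sectors (boundary ties to the
lower region id).

Defaults are sized to the human cerebellar cortex as the pipeline's target
substrate: radius 100 mm with relief A = 0.116·R and f = 6 gives a total
area of ≈ 1,520 cm² (the scale implied by ~800 patches of ~1.9 cm² mean
area) split into 8 regions, at subdivision 6 (40,962 vertices — a reduced
working resolution chosen so end-to-end runs remain interactive; the
procedure itself is resolution-independent).

What the generator does **not** emulate: the sharp, deep, nearly touching
folial walls of real cerebellar cortex (where opposing banks can fall in
one voxel), topological noise from imperfect reconstructions, and
anatomically meaningful region boundaries (sectors are geometric). Passing
tests therefore demonstrate the correctness and determinism of the
operations, not robustness to reconstruction artifacts — the snap
tolerance diagnostics exist precisely because real surfaces can violate
the watertightness assumption.

## Numerical and design choices

- 0-based vertex indices; mm coordinates consistent with the NIfTI affine
  (`diag(spacing)` + origin); contrast stored uint8, labels uint8 when the
  maximum id fits and uint16 otherwise.
- The inside/outside test is cross-checked in the test suite against an
  independently implemented ray-casting parity oracle (Möller–Trumbore),
  and the mode filters against naive brute-force re-implementations.
- The per-patch split axis is the leading eigenvector of the patch's
  vertex covariance with a deterministic sign convention; median split
  with rank tie-break by vertex index.
- "Longest border" between patches is the greatest *summed length* of
  shared boundary edges, not the edge count, making the choice invariant
  under uniform remeshing.
- Region count is data-driven throughout; nothing assumes a particular
  atlas size.

## Known limitations

- Voxelization is O(apexes × faces); at 0.4 mm spacing on million-vertex
  meshes it is compute-heavy and intended for batch use.
- Pointer spreading optimizes a local objective; it spreads pointers well
  but does not guarantee a centroidal (Lloyd-like) configuration.
- The split/merge loop can leave a patch slightly above the split
  threshold after the final pass (by design: the final pass runs exactly
  once), and a sub-threshold patch with no same-region neighbor is left
  in place with a warning.
- FreeSurfer binary surfaces are read, not written; spherical maps for
  externally supplied meshes must be provided (only star-shaped synthetic
  surfaces get an exact radial map).
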