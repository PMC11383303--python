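"""Clean, fill, and smooth a label volume against the contrast volume.

Manual voxel annotation leaves two kinds of defect: labels painted outside
the surface (where contrast = 0), and in-surface voxels (contrast > 0) that
were never painted.  The former are discarded; the latter are filled by
iteratively assigning each unlabeled in-surface voxel the mode of its
neighbors' labels until the in-surface set is completely labeled.  A mode
smoothing filter is then applied for a fixed number of iterations to remove
isolated mislabeled voxels and smooth region borders.

Neighborhoods are 26-connected, matching the 27-apex contrast construction.
Sweeps are synchronous (computed from the previous state), so results are
independent of voxel visiting order.  Mode ties keep the voxel's current
label when it is among the modal set, otherwise take the smallest label id.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes import ContrastVolume, LabelVolume

_KERNEL27 = np.ones((3, 3, 3), dtype=np.int64)
_KERNEL26 = _KERNEL27.copy()
_KERNEL26[1, 1, 1] = 0


class UnreachableComponentError(ValueError):
    """An in-surface connected component contains no labels to propagate."""


def discard_outside_labels(
    labels: LabelVolume, contrast: ContrastVolume
) -> tuple[LabelVolume, int]:
    """Zero every label at a voxel whose virtual contrast is 0.

    Returns the cleaned volume and the number of discarded voxels.
    """
    labels.require_same_grid(contrast)
    out = labels.copy()
    outside = (contrast.data == 0) & (out.data != 0)
    out.data[outside] = 0
    return out, int(outside.sum())


def _label_counts(data: np.ndarray, labs: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Stacked neighbor counts per candidate label, shape (len(labs), *grid)."""
    counts = np.empty((len(labs),) + data.shape, dtype=np.int64)
    for i, lab in enumerate(labs):
        counts[i] = ndimage.convolve(
            (data == lab).astype(np.int64), kernel, mode="constant", cval=0
        )
    return counts


def _mode_update(
    data: np.ndarray, active: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    """One synchronous mode sweep over ``active`` voxels.

    Returns the new label array.  Only nonzero labels contribute counts; a
    voxel keeps its label when it is among the modal set, otherwise takes
    the smallest modal label.  Active voxels with no labeled neighbors are
    left unchanged.
    """
    labs = np.unique(data)
    labs = labs[labs != 0]
    if labs.size == 0:
        return data.copy()
    counts = _label_counts(data, labs, kernel)
    maxc = counts.max(axis=0)
    smallest_modal = labs[np.argmax(counts, axis=0)]  # first max -> smallest id
    cur_idx = np.searchsorted(labs, data.clip(min=labs[0]))
    cur_idx = np.clip(cur_idx, 0, len(labs) - 1)
    cur_count = np.where(
        np.take(labs, cur_idx) == data,
        np.take_along_axis(counts, cur_idx[None], axis=0)[0],
        -1,
    )
    new = data.copy()
    upd = active & (maxc > 0)
    keep = upd & (cur_count == maxc) & (data != 0)
    change = upd & ~keep
    new[change] = smallest_modal[change]
    return new


def fill_unlabeled(labels: LabelVolume, contrast: ContrastVolume) -> LabelVolume:
    """Flood labels into unlabeled in-surface voxels by iterated neighbor mode.

    Each synchronous sweep assigns to every still-unlabeled contrast>0 voxel
    the mode of the nonzero labels among its 26 neighbors (from the previous
    sweep's state); repeats until no unlabeled in-surface voxel remains.

    Raises
    ------
    UnreachableComponentError
        If some 26-connected in-surface component contains no label at all
        (detected as a sweep that makes no progress).
    """
    labels.require_same_grid(contrast)
    data = labels.data.copy()
    in_surface = contrast.data > 0
    while True:
        todo = in_surface & (data == 0)
        if not np.any(todo):
            return LabelVolume(data, labels.origin, labels.spacing)
        new = _mode_update(data, todo, _KERNEL26)
        if np.array_equal(new, data):
            comp, _ = ndimage.label(in_surface, structure=_KERNEL27)
            empty = sorted(
                set(np.unique(comp[in_surface]).tolist())
                - set(np.unique(comp[in_surface & (data != 0)]).tolist())
            )
            raise UnreachableComponentError(
                f"in-surface component(s) {empty} contain no labels; "
                "cannot fill by neighbor mode"
            )
        data = new


def mode_smooth_volume(
    labels: LabelVolume, contrast: ContrastVolume, iterations: int = 3
) -> LabelVolume:
    """Mode-filter the label volume for a fixed number of iterations.

    Per iteration every in-surface voxel simultaneously takes the mode of
    the nonzero labels over its 27-voxel neighborhood (itself included).
    Background (contrast = 0) voxels never change and, being label 0, never
    contribute.
    """
    labels.require_same_grid(contrast)
    data = labels.data.copy()
    in_surface = contrast.data > 0
    for _ in range(iterations):
        data = _mode_update(data, in_surface, _KERNEL27)
    return LabelVolume(data, labels.origin, labels.spacing)
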