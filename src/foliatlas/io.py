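"""Surface and label table I/O.

Meshes: PLY and OBJ (via trimesh, with vertex order preserved) and read
support for FreeSurfer binary surfaces (magic 0xFFFFFE, via nibabel).
Labels travel in sidecar files: a two-column TSV (vertex_id, label) and a
FreeSurfer-style color LUT text file (id, name, R, G, B, A).
"""

from __future__ import annotations

import os

import nibabel.freesurfer.io as fsio
import numpy as np
import pandas as pd
import trimesh

from .mesh import SurfaceLabeling, TriangleMesh


class SurfaceFormatError(ValueError):
    """Raised for unknown extensions or unparseable surface files."""


_MESH_EXTS = {".ply", ".obj"}


def write_surface(mesh: TriangleMesh, path: str, labeling: SurfaceLabeling | None = None) -> None:
    """Write a mesh as PLY or OBJ; labels (if given) as ``<path>.labels.tsv``.

    PLY is written in binary; coordinates survive a round trip at float32
    precision, labels exactly.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext not in _MESH_EXTS:
        raise SurfaceFormatError(f"unsupported surface extension {ext!r} (use .ply or .obj)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)
    if labeling is not None:
        write_label_table(labeling, _label_sidecar(path))


def read_surface(path: str) -> tuple[TriangleMesh, SurfaceLabeling | None]:
    """Read PLY/OBJ or a FreeSurfer binary surface; load sidecar labels if present."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in _MESH_EXTS:
        try:
            tm = trimesh.load(path, process=False, force="mesh")
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise SurfaceFormatError(f"could not parse {path}: {exc}") from exc
        if not hasattr(tm, "faces") or len(getattr(tm, "faces", ())) == 0:
            raise SurfaceFormatError(f"{path} contains no triangle faces")
        mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))
    else:
        mesh = read_freesurfer_surface(path)
    labeling = None
    sidecar = _label_sidecar(path)
    if os.path.exists(sidecar):
        labeling = read_label_table(sidecar, n_vertices=mesh.n_vertices)
    return mesh, labeling


def read_freesurfer_surface(path: str) -> TriangleMesh:
    """Read a FreeSurfer binary triangle surface (magic 0xFFFFFE)."""
    try:
        coords, faces = fsio.read_geometry(path)
    except Exception as exc:  # noqa: BLE001
        raise SurfaceFormatError(f"not a readable FreeSurfer surface: {path}: {exc}") from exc
    return TriangleMesh(np.asarray(coords, float), np.asarray(faces))


def _label_sidecar(mesh_path: str) -> str:
    return os.path.splitext(mesh_path)[0] + ".labels.tsv"


def write_label_table(labeling: SurfaceLabeling, path: str) -> None:
    """Write per-vertex labels as TSV (vertex_id, label)."""
    pd.DataFrame(
        {"vertex_id": np.arange(len(labeling.labels)), "label": labeling.labels}
    ).to_csv(path, sep="\t", index=False)


def read_label_table(path: str, n_vertices: int | None = None) -> SurfaceLabeling:
    """Read per-vertex labels from TSV; region table filled with defaults."""
    df = pd.read_csv(path, sep="\t")
    labels = np.zeros(
        n_vertices if n_vertices is not None else int(df["vertex_id"].max()) + 1,
        dtype=np.int64,
    )
    labels[df["vertex_id"].to_numpy()] = df["label"].to_numpy()
    regions = {
        int(k): (f"region_{int(k):02d}", (128, 128, 128))
        for k in np.unique(labels)
        if k != 0
    }
    return SurfaceLabeling(labels, regions)


def write_color_lut(labeling: SurfaceLabeling, path: str) -> None:
    """Write a FreeSurfer-style color LUT: id, name, R, G, B, A."""
    with open(path, "w") as fh:
        fh.write("# id name R G B A\n")
        fh.write("0 unlabeled 0 0 0 0\n")
        for lab in sorted(labeling.regions):
            name, (r, g, b) = labeling.regions[lab]
            fh.write(f"{lab} {name} {r} {g} {b} 255\n")


def read_color_lut(path: str) -> dict[int, tuple[str, tuple[int, int, int]]]:
    """Read a color LUT back into a region table (label 0 skipped)."""
    regions: dict[int, tuple[str, tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            lab = int(parts[0])
            if lab == 0:
                continue
            regions[lab] = (parts[1], (int(parts[2]), int(parts[3]), int(parts[4])))
    return regions
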