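"""Readers and writers for FreeSurfer surface / morph-data files and an
array-container exchange format.

FreeSurfer stores surfaces and per-vertex scalars ("curv" / morph data) in
big-endian binary layouts (surface magic 0xFFFFFE, new-format curv magic
0xFFFFFF).  Parsing and serialization are delegated to :mod:`nibabel`, wrapped
here with the vertex-count checks and error contract the rest of the package
relies on.  The exchange format is a NumPy ``.npz`` container with named arrays
(``vertices``, ``faces``, ``features``, ``medial_wall``) for callers that do
not use FreeSurfer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import nibabel.freesurfer.io as fsio

from .atlas import Mesh

__all__ = [
    "FormatError",
    "read_freesurfer_geometry",
    "write_freesurfer_geometry",
    "read_freesurfer_morph",
    "write_freesurfer_morph",
    "save_surface_npz",
    "load_surface_npz",
]


class FormatError(ValueError):
    """Raised for malformed FreeSurfer files or count mismatches."""


def read_freesurfer_geometry(path: str | Path, hemisphere: str = "left") -> Mesh:
    """Read a FreeSurfer binary surface file into a :class:`Mesh`."""
    try:
        vertices, faces = fsio.read_geometry(str(path))
    except Exception as exc:  # nibabel raises bare ValueError on bad magic
        raise FormatError(f"{path}: not a FreeSurfer surface file ({exc})") from exc
    return Mesh(vertices=np.asarray(vertices, float), faces=np.asarray(faces, int),
                hemisphere=hemisphere)


def write_freesurfer_geometry(path: str | Path, mesh: Mesh) -> None:
    fsio.write_geometry(str(path), mesh.vertices, mesh.faces)


def read_freesurfer_morph(path: str | Path, expected_vertices: int | None = None) -> np.ndarray:
    """Read per-vertex scalars from a FreeSurfer curv / morph-data file.

    If ``expected_vertices`` is given, the array length is checked against it
    and a :class:`FormatError` is raised on mismatch.
    """
    try:
        data = fsio.read_morph_data(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a FreeSurfer morph-data file ({exc})") from exc
    data = np.asarray(data, dtype=np.float64)
    if expected_vertices is not None and len(data) != expected_vertices:
        raise FormatError(
            f"{path}: morph data has {len(data)} values at offset 15 onward, "
            f"expected {expected_vertices} (vertex count of the bound mesh)"
        )
    return data


def write_freesurfer_morph(path: str | Path, values: np.ndarray) -> None:
    fsio.write_morph_data(str(path), np.asarray(values, dtype=np.float32))


def save_surface_npz(
    path: str | Path,
    mesh: Mesh,
    features: np.ndarray | None = None,
    medial_wall: np.ndarray | None = None,
    **extra: np.ndarray,
) -> None:
    """Save a mesh (and optional per-vertex arrays) to the npz exchange container."""
    arrays: dict[str, np.ndarray] = {
        "vertices": mesh.vertices,
        "faces": mesh.faces,
        "hemisphere": np.array(mesh.hemisphere),
        "n_left": np.array(-1 if mesh.n_left is None else mesh.n_left),
    }
    if features is not None:
        arrays["features"] = np.asarray(features)
    if medial_wall is not None:
        arrays["medial_wall"] = np.asarray(medial_wall, dtype=bool)
    arrays.update(extra)
    np.savez(str(path), **arrays)


def load_surface_npz(path: str | Path) -> dict[str, np.ndarray | Mesh]:
    """Load the npz exchange container; returns a dict with a ``mesh`` entry."""
    with np.load(str(path), allow_pickle=False) as npz:
        data = {k: npz[k] for k in npz.files}
    n_left = int(data.pop("n_left", -1))
    mesh = Mesh(
        vertices=data.pop("vertices"),
        faces=data.pop("faces"),
        hemisphere=str(data.pop("hemisphere", "left")),
        n_left=None if n_left < 0 else n_left,
    )
    out: dict[str, np.ndarray | Mesh] = {"mesh": mesh}
    out.update(data)
    return out
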