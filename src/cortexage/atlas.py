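"""Nested spherical atlas meshes for cortical surface analysis.

Cortical morphometry resampled to fsaverage-style icosahedral atlases lives on a
pair of spherical meshes, one per hemisphere, available at several nested
subdivision levels (an ico-n sphere has ``10 * 4**n + 2`` vertices).  This module
builds those meshes from scratch (midpoint subdivision of a regular icosahedron
with a deterministic, parents-first vertex ordering), joins the two hemispheres
into a single disconnected graph, and derives the adjacency structures and
medial-wall masks that the rest of the package consumes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Mesh",
    "AtlasHierarchy",
    "build_icosphere",
    "concatenate_hemispheres",
    "adjacency",
    "adjacency_matrix",
    "khop_neighbors",
    "medial_wall_mask",
    "build_hierarchy",
]

#: Angular radius (radians) of the synthetic medial-wall cap on each hemisphere.
MEDIAL_WALL_RADIUS = 0.25

#: Spatial offset applied to each hemisphere in a joint mesh (cosmetic only;
#: learning never reads absolute coordinates).
HEMI_OFFSET = 2.0


@dataclass
class Mesh:
    """A triangular surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates.  Atlas meshes are unit spheres per hemisphere.
    faces : (T, 3) int array
        Triangles as vertex-index triples.
    hemisphere : {"left", "right", "joint"}
        Which hemisphere the mesh represents; "joint" for a two-hemisphere mesh.
    n_left : int or None
        For joint meshes, the number of left-hemisphere vertices (right
        hemisphere indices start here).
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    n_left: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be triangles, shape (T, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def hemisphere_slices(self) -> list[slice]:
        """Vertex-index slices, one per hemisphere contained in this mesh."""
        if self.hemisphere == "joint":
            if self.n_left is None:
                raise ValueError("joint mesh without n_left")
            return [slice(0, self.n_left), slice(self.n_left, self.n_vertices)]
        return [slice(0, self.n_vertices)]


# regular icosahedron: 12 vertices from three orthogonal golden rectangles
def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One midpoint subdivision with parents-first, fixed-edge-order children.

    New vertices are appended after the parents, one per unique undirected edge,
    in lexicographic edge order, so subdivision levels share a vertex prefix.
    """
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    edges = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    midpoints = vertices[uniq[:, 0]] + vertices[uniq[:, 1]]
    midpoints /= np.linalg.norm(midpoints, axis=1, keepdims=True)
    new_vertices = np.concatenate([vertices, midpoints], axis=0)

    n = len(vertices)
    m01 = n + inverse[: len(faces)]
    m12 = n + inverse[len(faces) : 2 * len(faces)]
    m20 = n + inverse[2 * len(faces) :]
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([b, m12, m01], axis=1),
            np.stack([c, m20, m12], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ],
        axis=0,
    )
    return new_vertices, new_faces


def build_icosphere(level: int, hemisphere: str = "left") -> Mesh:
    """Unit icosphere after ``level`` midpoint subdivisions (10*4**n + 2 vertices).

    Vertex ordering is deterministic and parents-first: the first
    ``10 * 4**k + 2`` vertices of any level ``k + 1`` sphere coincide exactly
    with the level-``k`` sphere.
    """
    if level < 0:
        raise ValueError(f"subdivision level must be >= 0, got {level}")
    vertices, faces = _icosahedron()
    for _ in range(level):
        vertices, faces = _subdivide(vertices, faces)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    return Mesh(vertices=vertices, faces=faces, hemisphere=hemisphere)


def concatenate_hemispheres(left: Mesh, right: Mesh) -> Mesh:
    """Join two hemisphere meshes into one disconnected joint mesh.

    Right-hemisphere vertex indices are offset by the left vertex count; no
    edges cross hemispheres.  Hemispheres are translated apart along x
    (left at -HEMI_OFFSET, right at +HEMI_OFFSET) purely so renderings do not
    overlap; the translation carries no meaning for learning.
    """
    lv = left.vertices.copy()
    rv = right.vertices.copy()
    lv[:, 0] -= HEMI_OFFSET
    rv[:, 0] += HEMI_OFFSET
    vertices = np.concatenate([lv, rv], axis=0)
    faces = np.concatenate([left.faces, right.faces + left.n_vertices], axis=0)
    return Mesh(vertices=vertices, faces=faces, hemisphere="joint", n_left=left.n_vertices)


def adjacency(mesh: Mesh) -> list[np.ndarray]:
    """Symmetric, deduplicated 1-hop neighbor lists from face edges (no self-loops)."""
    A = adjacency_matrix(mesh)
    indptr, indices = A.indptr, A.indices
    return [indices[indptr[v] : indptr[v + 1]] for v in range(mesh.n_vertices)]


def adjacency_matrix(mesh: Mesh) -> sparse.csr_matrix:
    """Binary symmetric adjacency as CSR, derived from face edges."""
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(len(rows), dtype=np.float64)
    A = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    A.data[:] = 1.0  # dedupe parallel entries
    A.setdiag(0)
    A.eliminate_zeros()
    return A


def khop_neighbors(mesh: Mesh, v: int, k: int) -> set[int]:
    """Vertices within graph distance <= k of ``v``, excluding ``v`` itself.

    Hemispheres are disconnected in a joint mesh, so the result never crosses
    hemispheres.
    """
    if not 0 <= v < mesh.n_vertices:
        raise ValueError(f"vertex index {v} out of range [0, {mesh.n_vertices})")
    if k < 1:
        raise ValueError("k must be >= 1")
    A = adjacency_matrix(mesh)
    seen = {v}
    frontier = deque([(v, 0)])
    out: set[int] = set()
    while frontier:
        u, d = frontier.popleft()
        if d == k:
            continue
        for w in A.indices[A.indptr[u] : A.indptr[u + 1]]:
            if w not in seen:
                seen.add(int(w))
                out.add(int(w))
                frontier.append((int(w), d + 1))
    return out


def khop_matrix(A: sparse.csr_matrix, k: int, include_self: bool = True) -> sparse.csr_matrix:
    """Binary reachability within <= k hops (optionally including the diagonal)."""
    n = A.shape[0]
    reach = sparse.identity(n, format="csr")
    power = sparse.identity(n, format="csr")
    for _ in range(k):
        power = power @ A
        reach = reach + power
    reach = reach.tocsr()
    reach.data[:] = 1.0
    if not include_self:
        reach.setdiag(0)
        reach.eliminate_zeros()
    return reach


def medial_wall_mask(mesh: Mesh, radius: float = MEDIAL_WALL_RADIUS) -> np.ndarray:
    """Synthetic medial-wall mask: a geodesic cap per hemisphere.

    Each hemisphere's "medial pole" is the point on its unit sphere facing the
    other hemisphere (+x for left, -x for right); vertices within ``radius``
    radians of the pole are flagged.  Real data should instead use the atlas
    annotation's medial-wall label.
    """
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    slices = mesh.hemisphere_slices()
    poles = {"left": np.array([1.0, 0.0, 0.0]), "right": np.array([-1.0, 0.0, 0.0])}
    if mesh.hemisphere == "joint":
        hemi_names = ["left", "right"]
    else:
        hemi_names = [mesh.hemisphere]
    for sl, name in zip(slices, hemi_names):
        v = mesh.vertices[sl].copy()
        # undo the cosmetic joint-mesh translation before measuring angles
        center = v.mean(axis=0)
        v = v - center
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ang = np.arccos(np.clip(v @ poles[name], -1.0, 1.0))
        mask[sl] = ang <= radius
    return mask


@dataclass
class AtlasHierarchy:
    """Nested two-hemisphere atlas meshes, coarsest to finest.

    ``levels[i]`` is the joint mesh at subdivision level ``subdivisions[i]``;
    vertex counts strictly increase, and each joint graph has exactly two
    connected components (one per hemisphere).
    """

    levels: list[Mesh]
    subdivisions: list[int]
    medial_wall: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = self.vertex_counts
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("levels must strictly increase in vertex count")
        for mesh in self.levels:
            n, _ = connected_components(adjacency_matrix(mesh), directed=False)
            if n != 2:
                raise ValueError(f"joint mesh has {n} components, expected 2")
        if not self.medial_wall:
            self.medial_wall = [medial_wall_mask(m) for m in self.levels]

    @property
    def vertex_counts(self) -> list[int]:
        return [m.n_vertices for m in self.levels]

    @property
    def finest(self) -> Mesh:
        return self.levels[-1]

    @property
    def coarsest(self) -> Mesh:
        return self.levels[0]


def build_hierarchy(subdivisions: tuple[int, ...] = (4, 5, 6)) -> AtlasHierarchy:
    """Build a joint two-hemisphere hierarchy at the given subdivision levels.

    The default (4, 5, 6) reproduces the production configuration with joint
    vertex counts 5124, 20484 and 81924; tests use (0, 1, 2).
    """
    subs = sorted(subdivisions)
    meshes = []
    for s in subs:
        left = build_icosphere(s, "left")
        right = build_icosphere(s, "right")
        meshes.append(concatenate_hemispheres(left, right))
    return AtlasHierarchy(levels=meshes, subdivisions=list(subs))
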