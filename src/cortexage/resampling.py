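"""Cross-resolution receptive fields and averaging pool operators.

Information moves between atlas resolutions through *receptive fields* built
bottom-up: each coarse vertex is matched to its nearest fine vertex (Euclidean
distance on the per-hemisphere unit-sphere embedding, ties broken by lowest
index), and its receptive field R(v) is that matched vertex together with the
matched vertex's 1-hop neighbors in the fine mesh.  The inverse field
R⁻¹(u) of a fine vertex is the set of coarse vertices whose field contains it.
Downsampling averages features over R(v); upsampling averages over R⁻¹(u).

Both operators are materialized as sparse row-stochastic matrices so that they
are cheap to apply, exactly linear, and trivially differentiable (the adjoint
is the transpose), which the graph U-Net's backward pass exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .atlas import Mesh, adjacency_matrix

__all__ = ["ReceptiveFieldMap", "build_receptive_fields", "pool_down", "pool_up"]


@dataclass
class ReceptiveFieldMap:
    """Receptive fields between one coarse/fine resolution pair.

    Attributes
    ----------
    match : (Vc,) int array
        Nearest fine vertex for each coarse vertex (same hemisphere).
    fields : list of int arrays
        R(v) for each coarse vertex: match plus its fine 1-hop neighbors.
    inverse : list of int arrays
        R⁻¹(u) for each fine vertex, the exact set dual of ``fields``.
    down, up : sparse CSR matrices
        Row-stochastic averaging operators, (Vc, Vf) and (Vf, Vc).  ``up``
        includes deterministic neighbor-mean imputation for fine vertices
        with empty inverse fields.
    n_imputed : int
        Number of fine vertices whose upsampled value had to be imputed.
    """

    n_coarse: int
    n_fine: int
    match: np.ndarray
    fields: list[np.ndarray]
    inverse: list[np.ndarray]
    down: sparse.csr_matrix
    up: sparse.csr_matrix
    n_imputed: int

    @property
    def coverage(self) -> float:
        """Fraction of fine vertices with a non-empty inverse field."""
        return 1.0 - self.n_imputed / self.n_fine

    def save(self, path: str | Path) -> None:
        """Serialize to an npz container (ragged sets as index+offset arrays)."""
        f_idx = np.concatenate(self.fields) if self.fields else np.empty(0, int)
        f_off = np.cumsum([0] + [len(f) for f in self.fields])
        np.savez(
            str(path),
            n_coarse=self.n_coarse,
            n_fine=self.n_fine,
            match=self.match,
            fields_idx=f_idx,
            fields_off=f_off,
            up_data=self.up.data, up_indices=self.up.indices, up_indptr=self.up.indptr,
            n_imputed=self.n_imputed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReceptiveFieldMap":
        with np.load(str(path)) as z:
            n_coarse, n_fine = int(z["n_coarse"]), int(z["n_fine"])
            off = z["fields_off"]
            fields = [z["fields_idx"][off[i]:off[i + 1]] for i in range(n_coarse)]
            inverse = _invert(fields, n_fine)
            up = sparse.csr_matrix(
                (z["up_data"], z["up_indices"], z["up_indptr"]), shape=(n_fine, n_coarse)
            )
            return cls(
                n_coarse=n_coarse, n_fine=n_fine, match=z["match"], fields=fields,
                inverse=inverse, down=_mean_matrix(fields, n_coarse, n_fine),
                up=up, n_imputed=int(z["n_imputed"]),
            )


def _invert(fields: list[np.ndarray], n_fine: int) -> list[np.ndarray]:
    inv: list[list[int]] = [[] for _ in range(n_fine)]
    for vc, fld in enumerate(fields):
        for vf in fld:
            inv[vf].append(vc)
    return [np.array(sorted(s), dtype=np.int64) for s in inv]


def _mean_matrix(sets: list[np.ndarray], n_rows: int, n_cols: int) -> sparse.csr_matrix:
    rows, cols, data = [], [], []
    for r, s in enumerate(sets):
        if len(s) == 0:
            continue
        rows.extend([r] * len(s))
        cols.extend(s.tolist())
        data.extend([1.0 / len(s)] * len(s))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_rows, n_cols))


def _nearest_within(coarse_xyz: np.ndarray, fine_xyz: np.ndarray) -> np.ndarray:
    """Brute-force nearest neighbor, lowest index on ties, chunked for memory."""
    out = np.empty(len(coarse_xyz), dtype=np.int64)
    chunk = max(1, 2**22 // max(1, len(fine_xyz)))
    for start in range(0, len(coarse_xyz), chunk):
        block = coarse_xyz[start : start + chunk]
        d2 = ((block[:, None, :] - fine_xyz[None, :, :]) ** 2).sum(axis=2)
        out[start : start + chunk] = np.argmin(d2, axis=1)  # argmin takes lowest index
    return out


def build_receptive_fields(coarse: Mesh, fine: Mesh) -> ReceptiveFieldMap:
    """Build the receptive-field map between a coarse and a fine atlas mesh.

    Hemispheres are matched independently so fields never cross hemispheres.
    Fine vertices left with an empty inverse field are imputed in the ``up``
    operator as the mean of their already-covered fine 1-hop neighbors,
    iterated in deterministic BFS order until every vertex is covered.
    """
    if coarse.n_vertices == 0 or fine.n_vertices == 0:
        raise ValueError("meshes must be non-empty")
    if coarse.n_vertices > fine.n_vertices:
        raise ValueError("coarse mesh must not have more vertices than fine mesh")

    c_slices = coarse.hemisphere_slices()
    f_slices = fine.hemisphere_slices()
    if len(c_slices) != len(f_slices):
        raise ValueError("hemisphere structure differs between levels")

    match = np.empty(coarse.n_vertices, dtype=np.int64)
    for cs, fs in zip(c_slices, f_slices):
        c_xyz = _unit_per_hemi(coarse.vertices[cs])
        f_xyz = _unit_per_hemi(fine.vertices[fs])
        match[cs] = _nearest_within(c_xyz, f_xyz) + fs.start

    A_fine = adjacency_matrix(fine)
    fields = []
    for vc in range(coarse.n_vertices):
        vf = match[vc]
        nbrs = A_fine.indices[A_fine.indptr[vf] : A_fine.indptr[vf + 1]]
        fields.append(np.unique(np.concatenate([[vf], nbrs])))
    inverse = _invert(fields, fine.n_vertices)

    down = _mean_matrix(fields, coarse.n_vertices, fine.n_vertices)
    up_base = _mean_matrix(inverse, fine.n_vertices, coarse.n_vertices)
    up, n_imputed = _impute_uncovered(up_base, inverse, A_fine)
    return ReceptiveFieldMap(
        n_coarse=coarse.n_vertices, n_fine=fine.n_vertices, match=match,
        fields=fields, inverse=inverse, down=down, up=up, n_imputed=n_imputed,
    )


def _unit_per_hemi(xyz: np.ndarray) -> np.ndarray:
    """Undo the joint-mesh translation and renormalize to the unit sphere."""
    centered = xyz - xyz.mean(axis=0)
    return centered / np.linalg.norm(centered, axis=1, keepdims=True)


def _impute_uncovered(
    up: sparse.csr_matrix, inverse: list[np.ndarray], A_fine: sparse.csr_matrix
) -> tuple[sparse.csr_matrix, int]:
    """Fill rows for fine vertices with empty R⁻¹ by neighbor-mean composition.

    Each uncovered row becomes the mean of its covered 1-hop neighbors' rows;
    vertices are processed in BFS order from the covered set, so the result is
    deterministic and the operator stays linear in the coarse features.
    """
    uncovered = [v for v, s in enumerate(inverse) if len(s) == 0]
    if not uncovered:
        return up, 0
    covered = np.array([len(s) > 0 for s in inverse])
    rows = {v: up.getrow(v) for v in range(up.shape[0]) if covered[v]}
    pending = set(uncovered)
    while pending:
        progressed = []
        for v in sorted(pending):
            nbrs = A_fine.indices[A_fine.indptr[v] : A_fine.indptr[v + 1]]
            done = [u for u in nbrs if u in rows]
            if done:
                acc = rows[done[0]].copy()
                for u in done[1:]:
                    acc = acc + rows[u]
                rows[v] = acc / len(done)
                progressed.append(v)
        if not progressed:
            raise ValueError("fine mesh has vertices unreachable from any covered vertex")
        pending.difference_update(progressed)
    out = sparse.vstack([rows[v] for v in range(up.shape[0])]).tocsr()
    return out, len(uncovered)


def pool_down(features: np.ndarray, rf: ReceptiveFieldMap) -> np.ndarray:
    """Average fine per-vertex features over each coarse vertex's receptive field."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != rf.n_fine:
        raise ValueError(
            f"features have {features.shape[0]} rows, expected fine count {rf.n_fine}"
        )
    return rf.down @ features


def pool_up(features: np.ndarray, rf: ReceptiveFieldMap) -> np.ndarray:
    """Average coarse per-vertex features over each fine vertex's inverse field."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != rf.n_coarse:
        raise ValueError(
            f"features have {features.shape[0]} rows, expected coarse count {rf.n_coarse}"
        )
    return rf.up @ features
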