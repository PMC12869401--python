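"""Post-processing of local brain-age maps.

After prediction, three steps run in order: (1) the medial wall — a non-cortical
band on each hemisphere's medial face — is removed from consideration; (2) the
remaining predictions are smoothed by synchronous neighborhood averaging
(each vertex replaced by the mean of itself and its neighbors up to ``hops``
steps away, repeated ``iterations`` times); (3) a *semi-global* bias correction
removes the well-known regression-to-the-mean bias of brain-age models: at
each vertex the local brain-age gap (LBAG = LBA - CA) is regressed on CA by
ordinary least squares, the per-vertex slopes m_v and intercepts b_v are
averaged across vertices into a single (m_mu, b_mu), and the adjustment term
m_mu * CA_s + b_mu is subtracted from every vertex of subject s.  Coefficients
fitted on a reference (e.g. cognitively normal) cohort can be reused to
correct a disease cohort so disease-specific bias is not removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .atlas import Mesh, adjacency_matrix, khop_matrix
from .model import LbaMap

__all__ = [
    "BiasModel",
    "remove_medial_wall",
    "scatter_to_full",
    "smoothing_matrix",
    "smooth",
    "fit_bias",
    "apply_bias",
    "global_bag",
]


@dataclass
class BiasModel:
    """Per-vertex and vertex-averaged bias-correction coefficients."""

    slopes: np.ndarray  # m_v, unitless (years per year)
    intercepts: np.ndarray  # b_v, years
    m_mu: float
    b_mu: float
    fitted_on: str = ""

    def save(self, path: str | Path) -> None:
        payload = {
            "m_mu": self.m_mu,
            "b_mu": self.b_mu,
            "fitted_on": self.fitted_on,
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BiasModel":
        d = json.loads(Path(path).read_text())
        return cls(
            slopes=np.asarray(d["slopes"], float),
            intercepts=np.asarray(d["intercepts"], float),
            m_mu=float(d["m_mu"]),
            b_mu=float(d["b_mu"]),
            fitted_on=d.get("fitted_on", ""),
        )


def remove_medial_wall(lba_map: LbaMap, mask: np.ndarray) -> LbaMap:
    """Restrict a full-mesh map to non-wall vertices, keeping the index map back.

    ``mask`` is True at medial-wall vertices.  Runs before smoothing; wall
    vertices are excluded from all later neighborhoods.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(lba_map.lba):
        raise ValueError(
            f"mask length {len(mask)} does not match map length {len(lba_map.lba)}"
        )
    keep = np.nonzero(~mask)[0]
    return LbaMap(
        lba=lba_map.lba[keep], scan_id=lba_map.scan_id, stage=lba_map.stage,
        vertex_index=keep,
    )


def scatter_to_full(lba_map: LbaMap, n_vertices: int, fill: float = np.nan) -> np.ndarray:
    """Scatter a wall-removed map back onto the full mesh (wall gets ``fill``)."""
    out = np.full(n_vertices, fill)
    idx = lba_map.vertex_index
    if idx is None:
        idx = np.arange(len(lba_map.lba))
    out[idx] = lba_map.lba
    return out


def smoothing_matrix(
    mesh: Mesh, hops: int = 2, keep: np.ndarray | None = None
) -> sparse.csr_matrix:
    """Row-stochastic operator averaging each vertex with its <=hops neighbors.

    ``keep`` optionally restricts to a working vertex subset (e.g. after wall
    removal); neighborhoods are then computed in the induced subgraph, so paths
    through removed vertices do not count.
    """
    A = adjacency_matrix(mesh)
    if keep is not None:
        keep = np.asarray(keep)
        A = A[keep][:, keep]
    S = khop_matrix(A, hops, include_self=True)
    inv_deg = 1.0 / np.asarray(S.sum(axis=1)).ravel()
    return sparse.diags(inv_deg) @ S


def smooth(
    lba_map: LbaMap,
    mesh: Mesh,
    hops: int = 2,
    iterations: int = 4,
    S: sparse.csr_matrix | None = None,
) -> LbaMap:
    """Synchronous (Jacobi-style) neighborhood-mean smoothing of an LBA map.

    Each iteration replaces every value with the unweighted mean of itself and
    its <=hops-step neighbors within the working vertex set, all vertices
    updating from the previous iterate.  Defaults (hops=2, iterations=4) match
    the production pipeline.
    """
    if S is None:
        S = smoothing_matrix(mesh, hops=hops, keep=lba_map.vertex_index)
    vals = lba_map.lba
    for _ in range(iterations):
        vals = S @ vals
    return LbaMap(lba=vals, scan_id=lba_map.scan_id, stage="smoothed",
                  vertex_index=lba_map.vertex_index)


def fit_bias(
    maps: list[LbaMap], cas: np.ndarray | list[float], fitted_on: str = ""
) -> BiasModel:
    """Fit the semi-global bias model: per-vertex OLS of LBAG on CA, averaged.

    For every vertex v, LBAG_vs = m_v * CA_s + b_v is fitted across scans s by
    ordinary least squares; m_mu and b_mu are the vertex-wise means of the
    coefficients.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 scans to fit the bias model")
    cas = np.asarray(cas, dtype=np.float64)
    ca_var = cas.var()
    if ca_var <= 1e-12:
        raise ValueError("chronological age has zero variance; bias fit undefined")
    lbag = np.stack([m.lba for m in maps]) - cas[:, None]  # (S, V)
    ca_c = cas - cas.mean()
    slopes = (ca_c @ lbag) / (ca_c @ ca_c)
    intercepts = lbag.mean(axis=0) - slopes * cas.mean()
    return BiasModel(
        slopes=slopes, intercepts=intercepts,
        m_mu=float(slopes.mean()), b_mu=float(intercepts.mean()),
        fitted_on=fitted_on,
    )


def apply_bias(lba_map: LbaMap, ca: float, model: BiasModel) -> LbaMap:
    """Subtract the semi-global adjustment term (m_mu * CA + b_mu) everywhere.

    Cross-cohort use is intentional: correcting a disease cohort with
    coefficients fitted on the reference cohort preserves disease-specific
    deviation.
    """
    if model.slopes is None or model.intercepts is None:
        raise RuntimeError("bias model is not fitted")
    adjustment = model.m_mu * ca + model.b_mu
    return LbaMap(
        lba=lba_map.lba - adjustment, scan_id=lba_map.scan_id,
        stage="bias_corrected", vertex_index=lba_map.vertex_index,
    )


def global_bag(lba_map: LbaMap, ca: float) -> float:
    """Global brain-age gap: the vertex-averaged gap for one scan."""
    return float(np.mean(lba_map.lba - ca))
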