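"""Graph U-Net for vertex-level brain age ("local brain age", LBA) estimation.

The network operates on a nested atlas hierarchy of two-hemisphere spherical
meshes.  Encoding applies, at each resolution from finest to coarsest, a graph
convolution (GCN) followed by batch normalization and ReLU, then averages
features into the next-coarser mesh through fixed receptive-field pooling.
Decoding mirrors this: receptive-field upsampling, concatenation with the
skip tensor saved from the encoder at the same resolution, then GCN + BN +
ReLU.  The final block applies a GCN only, producing one output channel per
vertex — the predicted age at that cortical location.

Training minimizes vertex-wise mean absolute error against chronological age
broadcast to every vertex, with Adam.  Inputs are z-scored per morphometric
feature using training-set statistics; the age target is likewise z-scored
internally (predictions are mapped back to years), which makes the optimizer's
step sizes scale-free and convergence rapid at any cohort size.  Both sets of
standardization constants are stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasHierarchy, adjacency_matrix
from .nn import Adam, BatchNorm, GCNConv, ReLU, SparseOp, gcn_layer, normalized_adjacency
from .resampling import ReceptiveFieldMap, build_receptive_fields

__all__ = [
    "ModelConfig",
    "SurfaceSample",
    "LbaMap",
    "GraphUNet",
    "train",
    "predict",
    "evaluate_mae",
    "gcn_layer",
]

FEATURE_NAMES = ("thickness", "sulcal_depth", "curvature", "area", "gwr")


@dataclass
class ModelConfig:
    """Hyperparameters of the graph U-Net.

    ``feature_widths[0]`` is the input feature count (5 morphometric features);
    subsequent entries are the encoder output widths per resolution.  Defaults
    follow the production recipe: widths (5, 8, 16), 50 epochs, batch 128,
    Adam at learning rate 0.01, vertex-wise MAE loss.
    """

    feature_widths: tuple[int, ...] = (5, 8, 16)
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 0.01
    seed: int = 0
    mask_medial_wall_loss: bool = False

    def __post_init__(self) -> None:
        if len(self.feature_widths) < 2:
            raise ValueError("need at least two feature widths (input + one level)")


@dataclass
class SurfaceSample:
    """One scan: per-vertex features at the finest resolution plus metadata."""

    features: np.ndarray  # (V_finest, F0)
    ca: float  # chronological age, years
    sex: int = 0  # 0 = female, 1 = male
    education_years: float = 0.0
    cohort: str = ""
    subject_id: str = ""
    scan_id: str = ""
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be (V, F)")
        if not self.ca > 0:
            raise ValueError("chronological age must be positive")


@dataclass
class LbaMap:
    """Per-vertex predicted age for one scan.

    ``vertex_index`` maps rows back to full-mesh vertex indices once the
    medial wall has been removed (None while the map covers the full mesh).
    """

    lba: np.ndarray
    scan_id: str = ""
    stage: str = "raw"  # raw | smoothed | bias_corrected
    vertex_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lba = np.asarray(self.lba, dtype=np.float64).ravel()

    def lbag(self, ca: float) -> np.ndarray:
        """Local brain-age gap: predicted age minus chronological age."""
        return self.lba - ca


class GraphUNet:
    """Three-resolution (or deeper) graph U-Net bound to an atlas hierarchy."""

    def __init__(
        self,
        hierarchy: AtlasHierarchy,
        config: ModelConfig | None = None,
        rf_maps: list[ReceptiveFieldMap] | None = None,
    ):
        self.hierarchy = hierarchy
        self.config = config or ModelConfig()
        L = len(hierarchy.levels)
        if len(self.config.feature_widths) != L:
            raise ValueError(
                f"feature_widths has {len(self.config.feature_widths)} entries "
                f"for a {L}-level hierarchy"
            )
        if rf_maps is None:
            rf_maps = [
                build_receptive_fields(hierarchy.levels[i], hierarchy.levels[i + 1])
                for i in range(L - 1)
            ]
        self.rf_maps = rf_maps
        self._build(np.random.default_rng(self.config.seed))
        # standardization constants, set by fit()
        self.feat_mean = np.zeros(self.config.feature_widths[0])
        self.feat_std = np.ones(self.config.feature_widths[0])
        self.age_mean = 0.0
        self.age_std = 1.0
        self.fitted = False

    # ------------------------------------------------------------------ build
    def _build(self, rng: np.random.Generator) -> None:
        H, w = self.hierarchy, self.config.feature_widths
        L = len(H.levels)
        A_hat = [normalized_adjacency(adjacency_matrix(m)) for m in H.levels]
        down = [SparseOp(rf.down) for rf in self.rf_maps]
        up = [SparseOp(rf.up) for rf in self.rf_maps]

        self.enc: dict[int, tuple[GCNConv, BatchNorm, ReLU]] = {}
        for h in range(L - 1, 0, -1):  # finest -> next-to-coarsest
            j = L - 1 - h
            self.enc[h] = (
                GCNConv(A_hat[h], w[j], w[j + 1], rng), BatchNorm(w[j + 1]), ReLU()
            )
        self.bottleneck = (
            GCNConv(A_hat[0], w[L - 1], w[L - 1], rng), BatchNorm(w[L - 1]), ReLU()
        )
        self.dec: dict[int, tuple[GCNConv, BatchNorm, ReLU]] = {}
        for h in range(1, L - 1):
            wu = w[L - h]
            self.dec[h] = (GCNConv(A_hat[h], 2 * wu, w[L - 1 - h], rng),
                           BatchNorm(w[L - 1 - h]), ReLU())
        self.final = GCNConv(A_hat[L - 1], 2 * w[1], 1, rng)
        self.down, self.up = down, up
        self._L = L

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for h in sorted(self.enc, reverse=True):
            g, bn, _ = self.enc[h]
            out += g.params + bn.params
        g, bn, _ = self.bottleneck
        out += g.params + bn.params
        for h in sorted(self.dec):
            g, bn, _ = self.dec[h]
            out += g.params + bn.params
        out += self.final.params
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for h in sorted(self.enc, reverse=True):
            g, bn, _ = self.enc[h]
            out += g.grads + bn.grads
        g, bn, _ = self.bottleneck
        out += g.grads + bn.grads
        for h in sorted(self.dec):
            g, bn, _ = self.dec[h]
            out += g.grads + bn.grads
        out += self.final.grads
        return out

    # ---------------------------------------------------------- forward/back
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the U-Net on a (B, V_finest, F0) batch of standardized features.

        Returns standardized per-vertex age predictions of shape (B, V_finest).
        """
        L = self._L
        skips: dict[int, np.ndarray] = {}
        for h in range(L - 1, 0, -1):
            g, bn, relu = self.enc[h]
            X = relu.forward(bn.forward(g.forward(X), training))
            skips[h] = X
            X = self.down[h - 1].forward(X)
        g, bn, relu = self.bottleneck
        X = relu.forward(bn.forward(g.forward(X), training))
        for h in range(1, L):
            X = self.up[h - 1].forward(X)
            X = np.concatenate([X, skips[h]], axis=2)
            if h < L - 1:
                g, bn, relu = self.dec[h]
                X = relu.forward(bn.forward(g.forward(X), training))
            else:
                X = self.final.forward(X)
        return X[..., 0]

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        """Backpropagate (B, V_finest) output gradients; returns input gradients."""
        L = self._L
        dX = dOut[..., None]
        dskips: dict[int, np.ndarray] = {}
        for h in range(L - 1, 0, -1):
            if h < L - 1:
                g, bn, relu = self.dec[h]
                dX = g.backward(bn.backward(relu.backward(dX)))
            else:
                dX = self.final.backward(dX)
            wu = dX.shape[2] // 2
            dskips[h] = dX[..., wu:]
            dX = self.up[h - 1].backward(dX[..., :wu])
        g, bn, relu = self.bottleneck
        dX = g.backward(bn.backward(relu.backward(dX)))
        for h in range(1, L):
            dX = self.down[h - 1].backward(dX)
            dX = dX + dskips[h]
            g, bn, relu = self.enc[h]
            dX = g.backward(bn.backward(relu.backward(dX)))
        return dX

    # ------------------------------------------------------------- interface
    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feat_mean) / self.feat_std

    def fit(self, cohort: list[SurfaceSample]) -> list[float]:
        """Train on a cohort; returns the per-epoch mean training loss.

        The loss is vertex-wise MAE on the z-scored age scale (CA broadcast
        to every vertex, medial wall included unless configured otherwise).
        """
        if not cohort:
            raise ValueError("cohort must be non-empty")
        cfg = self.config
        V = self.hierarchy.finest.n_vertices
        for s in cohort:
            if s.features.shape[0] != V:
                raise ValueError("sample feature rows do not match finest vertex count")
        stack = np.stack([s.features for s in cohort])  # (N, V, F0)
        self.feat_mean = stack.reshape(-1, stack.shape[2]).mean(axis=0)
        std = stack.reshape(-1, stack.shape[2]).std(axis=0)
        self.feat_std = np.where(std > 1e-12, std, 1.0)
        cas = np.array([s.ca for s in cohort])
        self.age_mean = float(cas.mean())
        self.age_std = float(cas.std()) if cas.std() > 1e-12 else 1.0

        X_all = (stack - self.feat_mean) / self.feat_std
        y_all = (cas - self.age_mean) / self.age_std
        loss_weights = np.ones(V)
        if cfg.mask_medial_wall_loss:
            loss_weights = (~self.hierarchy.medial_wall[-1]).astype(float)
        wsum = loss_weights.sum()

        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.params, lr=cfg.learning_rate)
        history: list[float] = []
        n = len(cohort)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                X = X_all[idx]
                y = y_all[idx]
                pred = self.forward(X, training=True)
                resid = pred - y[:, None]
                loss = float((np.abs(resid) * loss_weights).sum() / (len(idx) * wsum))
                dOut = np.sign(resid) * loss_weights / (len(idx) * wsum)
                self.backward(dOut)
                opt.step(self.grads)
                epoch_loss += loss * len(idx)
                seen += len(idx)
            history.append(epoch_loss / seen)
        self.fitted = True
        return history

    def predict_sample(self, sample: SurfaceSample) -> LbaMap:
        if not self.fitted:
            raise RuntimeError("model must be trained (or have constants set) first")
        xz = self.standardize(sample.features)[None]
        pred_z = self.forward(xz, training=False)[0]
        return LbaMap(lba=pred_z * self.age_std + self.age_mean,
                      scan_id=sample.scan_id, stage="raw")

    def scalar_output(self, xz: np.ndarray, vertex_weights: np.ndarray) -> float:
        """Weighted sum over vertices of the predicted age in years, for one
        standardized feature matrix xz of shape (V, F0)."""
        pred_z = self.forward(xz[None], training=False)[0]
        pred = pred_z * self.age_std + self.age_mean
        return float(pred @ vertex_weights)

    def input_gradient(self, xz: np.ndarray, vertex_weights: np.ndarray) -> np.ndarray:
        """Gradient of :meth:`scalar_output` with respect to xz, shape (V, F0)."""
        self.forward(xz[None], training=False)
        dOut = (vertex_weights * self.age_std)[None, :]
        return self.backward(dOut)[0]


def train(
    cohort: list[SurfaceSample],
    config: ModelConfig,
    hierarchy: AtlasHierarchy,
    rf_maps: list[ReceptiveFieldMap] | None = None,
) -> tuple[GraphUNet, list[float]]:
    """Train a graph U-Net on a cohort; returns (model, loss history)."""
    model = GraphUNet(hierarchy, config, rf_maps)
    history = model.fit(cohort)
    return model, history


def predict(cohort: list[SurfaceSample], model: GraphUNet) -> list[LbaMap]:
    """Deterministic per-scan LBA maps (batch norm in inference mode)."""
    return [model.predict_sample(s) for s in cohort]


def evaluate_mae(
    maps: list[LbaMap], cohort: list[SurfaceSample], mask: np.ndarray | None = None
) -> float:
    """Mean over scans of the per-scan mean |LBA - CA| in years.

    ``mask`` (optional) flags vertices to exclude (e.g. the medial wall).
    Computed on raw predictions, before any bias correction.
    """
    per_scan = []
    for m, s in zip(maps, cohort):
        vals = m.lba
        if mask is not None and m.vertex_index is None:
            vals = vals[~mask]
        per_scan.append(np.mean(np.abs(vals - s.ca)))
    return float(np.mean(per_scan))
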