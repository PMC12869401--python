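"""Minimal NumPy neural-network primitives for mesh-structured data.

The graph U-Net needs only a handful of operations — spectral graph
convolution with symmetric degree normalization, batch normalization, ReLU,
fixed sparse pooling, feature concatenation, a mean-absolute-error loss and
the Adam optimizer.  Each layer here implements an explicit ``forward`` (with
cached intermediates) and ``backward`` (vector-Jacobian product), which keeps
training, inference and input-gradient computation (for integrated gradients)
on one well-tested code path.

Batched inputs have shape (B, V, F): B graphs sharing one adjacency, V
vertices, F feature channels.  Sparse vertex-space operators are applied with
:func:`spmm`, which folds the batch into the column dimension.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "spmm",
    "normalized_adjacency",
    "gcn_layer",
    "GCNConv",
    "BatchNorm",
    "ReLU",
    "SparseOp",
    "Adam",
]


def spmm(A: sparse.spmatrix, X: np.ndarray) -> np.ndarray:
    """Apply a (M, V) sparse operator to every graph of a (B, V, F) batch."""
    B, V, F = X.shape
    flat = np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(V, B * F)
    out = A @ flat
    return out.reshape(A.shape[0], B, F).transpose(1, 0, 2)


def normalized_adjacency(A: sparse.spmatrix) -> sparse.csr_matrix:
    """Â = D̃^{-1/2} (A + I) D̃^{-1/2}, the GCN propagation operator."""
    A = sparse.csr_matrix(A, dtype=np.float64)
    A_tilde = A + sparse.identity(A.shape[0], format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sparse.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


def gcn_layer(
    features: np.ndarray, A: sparse.spmatrix, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """One graph convolution: Â X W + b on a single (V, F) feature matrix.

    ``A`` is the raw binary adjacency; self-loops and symmetric normalization
    are applied here.  Output at a vertex depends only on its closed 1-hop
    neighborhood and the layer weights.
    """
    features = np.asarray(features, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != weights.shape[0]:
        raise ValueError(
            f"feature width {features.shape} incompatible with weights {weights.shape}"
        )
    if features.shape[0] != A.shape[0]:
        raise ValueError("feature rows must match adjacency size")
    A_hat = normalized_adjacency(A)
    return A_hat @ features @ weights + np.asarray(bias, dtype=np.float64)


class GCNConv:
    """Graph convolution layer with a pre-normalized propagation operator."""

    def __init__(self, A_hat: sparse.csr_matrix, in_dim: int, out_dim: int,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_dim + out_dim))  # Glorot-uniform
        self.W = rng.uniform(-limit, limit, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.A_hat = A_hat
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._H: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._H = spmm(self.A_hat, X)
        return self._H @ self.W + self.b

    def backward(self, dY: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bvf,bvg->fg", self._H, dY)
        self.db = dY.sum(axis=(0, 1))
        # Â is symmetric, so the adjoint of X ↦ ÂX is Â itself
        return spmm(self.A_hat, dY @ self.W.T)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class BatchNorm:
    """Per-channel batch normalization over all vertices of all graphs in a batch."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self._cache = None

    def forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        B, V, F = X.shape
        flat = X.reshape(B * V, F)
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (flat - mean) * inv_std
        self._cache = (x_hat, inv_std, X.shape, training)
        return (x_hat * self.gamma + self.beta).reshape(B, V, F)

    def backward(self, dY: np.ndarray) -> np.ndarray:
        x_hat, inv_std, shape, training = self._cache
        B, V, F = shape
        dy = dY.reshape(B * V, F)
        self.dgamma = (dy * x_hat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        if not training:
            return (dy * self.gamma * inv_std).reshape(shape)
        n = B * V
        dxhat = dy * self.gamma
        dx = (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - x_hat * (dxhat * x_hat).sum(axis=0)
        )
        return dx.reshape(shape)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._mask = X > 0
        return X * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY * self._mask

    params: list = []
    grads: list = []


class SparseOp:
    """A fixed (parameter-free) sparse linear map, e.g. a pooling operator."""

    def __init__(self, M: sparse.csr_matrix):
        self.M = sparse.csr_matrix(M)
        self.MT = self.M.T.tocsr()

    def forward(self, X: np.ndarray) -> np.ndarray:
        return spmm(self.M, X)

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return spmm(self.MT, dY)

    params: list = []
    grads: list = []


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
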