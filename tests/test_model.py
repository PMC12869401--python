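"""Graph U-Net: GCN layer contract, forward oracle, training and evaluation."""

import numpy as np
import pytest
from scipy import sparse

from cortexage import (
    GraphUNet,
    LbaMap,
    ModelConfig,
    SurfaceSample,
    build_hierarchy,
    evaluate_mae,
    gcn_layer,
    predict,
    train,
)
from cortexage.nn import normalized_adjacency


def dense_gcn_oracle(X, A, W, b):
    """Brute-force D̃^{-1/2} Ã D̃^{-1/2} X W + b with dense matrices."""
    A = np.asarray(A, float)
    A_tilde = A + np.eye(len(A))
    d = A_tilde.sum(axis=1)
    D = np.diag(1.0 / np.sqrt(d))
    return D @ A_tilde @ D @ X @ W + b


def make_cohort(hierarchy, cas, rng, signal_col=0, scale=0.1, center=65.0):
    """Cohort whose features encode (CA - center) * scale in one column."""
    V = hierarchy.finest.n_vertices
    samples = []
    for i, ca in enumerate(cas):
        feats = np.zeros((V, 5))
        feats[:, signal_col] = (ca - center) * scale
        samples.append(SurfaceSample(features=feats, ca=float(ca), scan_id=f"s{i}"))
    return samples


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gcn_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    n, fin, fout = 9, 4, 3
    A = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
    A = A + A.T
    X = rng.standard_normal((n, fin))
    W = rng.standard_normal((fin, fout))
    b = rng.standard_normal(fout)
    got = gcn_layer(X, sparse.csr_matrix(A), W, b)
    assert np.allclose(got, dense_gcn_oracle(X, A, W, b), atol=1e-6)


def test_gcn_isolated_vertex_identity():
    # degree-1 normalization: a lone vertex with only its self-loop passes through
    A = sparse.csr_matrix((1, 1))
    X = np.array([[2.0, -3.0]])
    W = np.eye(2)
    b = np.array([0.5, 0.5])
    assert np.allclose(gcn_layer(X, A, W, b), X + b)


def test_gcn_respects_graph_automorphism():
    # two connected vertices with identical features stay identical
    A = sparse.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    X = np.array([[1.0, 2.0], [1.0, 2.0]])
    rng = np.random.default_rng(3)
    W, b = rng.standard_normal((2, 2)), rng.standard_normal(2)
    out = gcn_layer(X, A, W, b)
    assert np.allclose(out[0], out[1])


def test_gcn_shape_errors():
    A = sparse.csr_matrix(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        gcn_layer(np.zeros((2, 3)), A, np.zeros((4, 2)), np.zeros(2))
    with pytest.raises(ValueError):
        gcn_layer(np.zeros((3, 4)), A, np.zeros((4, 2)), np.zeros(2))


def test_forward_zero_weights_zero_output(hierarchy_012, rng):
    net = GraphUNet(hierarchy_012, ModelConfig(seed=0))
    for p in net.params:
        p[:] = 0.0
    X = rng.standard_normal((2, hierarchy_012.finest.n_vertices, 5))
    assert np.allclose(net.forward(X, training=False), 0.0)


def test_hemisphere_swap_equivariance(hierarchy_012, rng):
    """Swapping the two hemispheres' feature blocks swaps the output blocks."""
    net = GraphUNet(hierarchy_012, ModelConfig(seed=4))
    V = hierarchy_012.finest.n_vertices
    half = V // 2
    X = rng.standard_normal((1, V, 5))
    X_swapped = np.concatenate([X[:, half:], X[:, :half]], axis=1)
    out = net.forward(X, training=False)
    out_swapped = net.forward(X_swapped, training=False)
    assert np.allclose(out_swapped[:, :half], out[:, half:], atol=1e-10)
    assert np.allclose(out_swapped[:, half:], out[:, :half], atol=1e-10)


def test_forward_matches_straightline_reference(hierarchy_012, rng):
    """Independent dense re-implementation of the exact block sequence."""
    net = GraphUNet(hierarchy_012, ModelConfig(seed=5))
    H = hierarchy_012
    from cortexage import adjacency_matrix

    A_hat = [np.asarray(normalized_adjacency(adjacency_matrix(m)).todense())
             for m in H.levels]
    down = [np.asarray(rf.down.todense()) for rf in net.rf_maps]
    up = [np.asarray(rf.up.todense()) for rf in net.rf_maps]

    def bn_eval(x, bn):
        return (x - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) * bn.gamma + bn.beta

    x = rng.standard_normal((H.finest.n_vertices, 5))

    def block(x, h, layers, A):
        g, bn, _ = layers
        y = A @ x @ g.W + g.b
        return np.maximum(bn_eval(y, bn), 0.0)

    skips = {}
    y = x
    L = len(H.levels)
    for h in range(L - 1, 0, -1):
        y = block(y, h, net.enc[h], A_hat[h])
        skips[h] = y
        y = down[h - 1] @ y
    y = block(y, 0, net.bottleneck, A_hat[0])
    for h in range(1, L):
        y = up[h - 1] @ y
        y = np.concatenate([y, skips[h]], axis=1)
        if h < L - 1:
            y = block(y, h, net.dec[h], A_hat[h])
        else:
            y = A_hat[h] @ y @ net.final.W + net.final.b
    expected = y[:, 0]
    got = net.forward(x[None], training=False)[0]
    assert np.allclose(got, expected, atol=1e-10)


def test_locality_no_cross_hemisphere_influence(hierarchy_012, rng):
    """Perturbing a left-hemisphere vertex never changes right-hemisphere output."""
    net = GraphUNet(hierarchy_012, ModelConfig(seed=6))
    V = hierarchy_012.finest.n_vertices
    half = V // 2
    X = rng.standard_normal((1, V, 5))
    base = net.forward(X, training=False)
    X2 = X.copy()
    X2[0, 3, :] += 10.0
    pert = net.forward(X2, training=False)
    assert np.allclose(pert[0, half:], base[0, half:], atol=1e-12)
    assert not np.allclose(pert[0, :half], base[0, :half])


def test_training_memorizes_single_sample(hierarchy_012, rng):
    V = hierarchy_012.finest.n_vertices
    sample = SurfaceSample(features=rng.standard_normal((V, 5)), ca=70.0)
    cfg = ModelConfig(epochs=50, seed=7)
    _, history = train([sample], cfg, hierarchy_012)
    assert history[-1] < history[0]


def test_training_recovers_linear_age_signal(hierarchy_012):
    """Features carrying (CA-65)/10 in one column are decoded to < 2 y MAE."""
    rng = np.random.default_rng(8)
    cas = rng.uniform(45, 90, size=200)
    cohort = make_cohort(hierarchy_012, cas, rng)
    model, history = train(cohort, ModelConfig(seed=8), hierarchy_012)
    maps = predict(cohort, model)
    mae = evaluate_mae(maps, cohort)
    naive = np.abs(cas - np.median(cas)).mean()  # best constant predictor
    assert mae < 2.0
    assert naive > 8.0  # sanity: the age spread makes the bar meaningful


def test_training_is_deterministic(hierarchy_012):
    rng = np.random.default_rng(9)
    cas = rng.uniform(50, 80, size=24)
    cohort = make_cohort(hierarchy_012, cas, rng)
    cfg = ModelConfig(epochs=3, batch_size=8, seed=11)
    _, h1 = train(cohort, cfg, hierarchy_012)
    _, h2 = train(cohort, cfg, hierarchy_012)
    assert h1 == h2  # bitwise identical loss history


def test_empty_cohort_rejected(hierarchy_012):
    with pytest.raises(ValueError):
        train([], ModelConfig(), hierarchy_012)


def test_evaluate_mae_definition():
    cohort = [
        SurfaceSample(features=np.zeros((4, 5)), ca=70.0),
        SurfaceSample(features=np.zeros((4, 5)), ca=60.0),
    ]
    perfect = [LbaMap(lba=np.full(4, 70.0)), LbaMap(lba=np.full(4, 60.0))]
    assert evaluate_mae(perfect, cohort) == 0.0
    shifted = [LbaMap(lba=np.full(4, 73.0))]
    assert evaluate_mae(shifted, cohort[:1]) == pytest.approx(3.0)
    # unweighted mean of per-scan MAEs: 2 and 4 -> 3
    mixed = [LbaMap(lba=np.full(4, 72.0)), LbaMap(lba=np.full(4, 64.0))]
    assert evaluate_mae(mixed, cohort) == pytest.approx(3.0)


def test_constant_predictor_loss_is_mean_absolute_deviation():
    cas = [60.0, 70.0, 80.0]
    cohort = [SurfaceSample(features=np.zeros((3, 5)), ca=c) for c in cas]
    c_hat = 68.0
    maps = [LbaMap(lba=np.full(3, c_hat)) for _ in cas]
    assert evaluate_mae(maps, cohort) == pytest.approx(np.mean(np.abs(c_hat - np.array(cas))))


def test_config_validation(hierarchy_012):
    with pytest.raises(ValueError):
        ModelConfig(feature_widths=(5,))
    with pytest.raises(ValueError):
        GraphUNet(hierarchy_012, ModelConfig(feature_widths=(5, 8)))
    with pytest.raises(ValueError):
        SurfaceSample(features=np.zeros((4, 5)), ca=-1.0)
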