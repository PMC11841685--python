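"""Feature encoders: pooling, adjacency normalisation, GCN, providers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from icusurv import (
    ConceptGraph,
    FileBackedEmbeddingProvider,
    GCNParams,
    SyntheticEmbeddingProvider,
    default_concept_graph,
    encode_saps_factors,
    encode_text,
    gcn_forward,
    init_node_features,
    normalize_adjacency,
    pool_token_embeddings,
    save_cohort,
)


# ---------------------------------------------------------------------------
# pooling


def test_pooling_basics(rng):
    row = rng.normal(size=5)
    np.testing.assert_allclose(pool_token_embeddings(row[None, :]), row)
    np.testing.assert_allclose(pool_token_embeddings(np.tile(row, (4, 1))), row)
    X = rng.normal(size=(7, 5))
    manual = np.array([sum(X[i, j] for i in range(7)) / 7 for j in range(5)])
    np.testing.assert_allclose(pool_token_embeddings(X), manual, rtol=1e-12)
    with pytest.raises(ValueError):
        pool_token_embeddings(np.empty((0, 5)))


@settings(deadline=None, max_examples=30)
@given(
    X=arrays(np.float64, (4, 3), elements=st.floats(-50, 50)),
    alpha=st.floats(-5, 5),
)
def test_pooling_linearity(X, alpha):
    np.testing.assert_allclose(
        pool_token_embeddings(alpha * X),
        alpha * pool_token_embeddings(X),
        atol=1e-9,
    )


# ---------------------------------------------------------------------------
# concept graph / adjacency


def test_default_graph_is_valid():
    g = default_concept_graph()
    assert g.n_nodes == 14
    assert g.node_names[-1] == "no_finding"


def test_graph_validation():
    with pytest.raises(ValueError, match="symmetric"):
        ConceptGraph(adjacency=np.array([[0, 1], [0, 0]]), node_names=["a", "b"])
    with pytest.raises(ValueError, match="binary"):
        ConceptGraph(adjacency=np.array([[0, 2.0], [2.0, 0]]), node_names=["a", "b"])


def test_normalized_adjacency_edgeless_is_identity():
    g = ConceptGraph(adjacency=np.zeros((5, 5)), node_names=list("abcde"))
    np.testing.assert_allclose(normalize_adjacency(g), np.eye(5))


def test_normalized_adjacency_two_node_edge():
    g = ConceptGraph(adjacency=np.array([[0.0, 1.0], [1.0, 0.0]]), node_names=["a", "b"])
    np.testing.assert_allclose(normalize_adjacency(g), np.full((2, 2), 0.5))


def test_normalized_adjacency_spectrum_and_purity(rng):
    for _ in range(10):
        n = int(rng.integers(3, 12))
        A = (rng.uniform(size=(n, n)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        g = ConceptGraph(adjacency=A, node_names=[str(i) for i in range(n)])
        before = g.adjacency.copy()
        ahat = normalize_adjacency(g)
        np.testing.assert_array_equal(g.adjacency, before)  # input never mutated
        np.testing.assert_allclose(ahat, ahat.T)
        np.testing.assert_allclose(ahat, normalize_adjacency(g))  # recompute identical
        eig = np.linalg.eigvalsh(ahat)
        assert eig.min() >= -1 - 1e-10 and eig.max() <= 1 + 1e-10


def test_graph_json_round_trip(tmp_path):
    g = default_concept_graph()
    g.to_json(tmp_path / "g.json")
    back = ConceptGraph.from_json(tmp_path / "g.json")
    np.testing.assert_array_equal(back.adjacency, g.adjacency)
    assert back.node_names == g.node_names


# ---------------------------------------------------------------------------
# node-feature convolution


def _params(n_nodes=3, d=4, hidden=5, out=2, k=2, seed=0):
    return GCNParams.initialize(
        n_nodes=n_nodes, embed_dim=d, hidden_dim=hidden, output_dim=out,
        kernel_size=k, seed=seed,
    )


def test_conv_identity_kernel_single_token(rng):
    p = _params(n_nodes=3, d=6, k=1)
    p.conv_weights = np.array([[1.0], [2.0], [0.5]])
    tok = rng.normal(size=(1, 6))
    h0 = init_node_features(tok, p)
    np.testing.assert_allclose(h0, np.outer([1.0, 2.0, 0.5], tok[0]))


def test_conv_matches_sliding_window_loop(rng):
    for _ in range(50):
        m = int(rng.integers(2, 15))
        d = int(rng.integers(1, 8))
        k = int(rng.integers(1, m + 1))
        n = int(rng.integers(1, 5))
        p = _params(n_nodes=n, d=d, k=k)
        tok = rng.normal(size=(m, d))
        h0 = init_node_features(tok, p)
        expected = np.zeros((n, d))
        for c in range(n):
            for pos in range(m - k + 1):
                for kk in range(k):
                    expected[c] += p.conv_weights[c, kk] * tok[pos + kk]
        expected /= m - k + 1
        np.testing.assert_allclose(h0, expected, atol=1e-8)


def test_conv_short_report_error():
    p = _params(k=3)
    with pytest.raises(ValueError, match="pad"):
        init_node_features(np.zeros((2, 4)), p)


# ---------------------------------------------------------------------------
# GCN propagation


def test_gcn_two_node_toy_matches_hand_matrices():
    ahat = np.full((2, 2), 0.5)
    p = GCNParams(
        conv_weights=np.ones((2, 1)),
        W0=np.array([[1.5]]),
        b0=np.array([0.25]),
        W1=np.array([[2.0, -1.0]]),
        b1=np.array([0.1, -0.2]),
    )
    h0 = np.array([[1.0], [-3.0]])
    z = gcn_forward(h0, ahat, p)
    h1 = np.maximum(ahat @ h0 @ p.W0 + p.b0, 0.0)
    pre = ahat @ h1 @ p.W1 + p.b1
    hand = np.exp(pre) / np.exp(pre).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(z, hand, atol=1e-10)
    np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-12)


def test_gcn_identity_layer_under_relu(rng):
    # A_hat = I, W0 = I, b0 = 0: the hidden layer reproduces nonnegative H0
    d = 4
    p = GCNParams(
        conv_weights=np.ones((3, 1)),
        W0=np.eye(d),
        b0=np.zeros(d),
        W1=rng.normal(size=(d, 2)),
        b1=np.zeros(2),
    )
    h0 = np.abs(rng.normal(size=(3, d)))
    z = gcn_forward(h0, np.eye(3), p)
    pre = h0 @ p.W1  # H1 == H0 exactly
    hand = np.exp(pre - pre.max(axis=1, keepdims=True))
    hand /= hand.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(z, hand, atol=1e-12)


def test_gcn_shape_errors():
    p = _params()
    with pytest.raises(ValueError, match="W0"):
        gcn_forward(np.zeros((3, 7)), np.eye(3), p)  # feature dim mismatch
    with pytest.raises(ValueError, match="nodes"):
        gcn_forward(np.zeros((2, 4)), np.eye(3), p)


def test_gcn_permutation_equivariance(rng):
    n, d = 5, 6
    A = (rng.uniform(size=(n, n)) < 0.4).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    g = ConceptGraph(adjacency=A, node_names=[str(i) for i in range(n)])
    p = _params(n_nodes=n, d=d, k=2, seed=3)
    tok = rng.normal(size=(9, d))
    z = gcn_forward(init_node_features(tok, p), normalize_adjacency(g), p)
    perm = rng.permutation(n)
    g2 = ConceptGraph(adjacency=A[np.ix_(perm, perm)], node_names=[str(i) for i in perm])
    p2 = GCNParams(
        conv_weights=p.conv_weights[perm], W0=p.W0, b0=p.b0, W1=p.W1, b1=p.b1
    )
    z2 = gcn_forward(init_node_features(tok, p2), normalize_adjacency(g2), p2)
    np.testing.assert_allclose(z2, z[perm], atol=1e-10)


# ---------------------------------------------------------------------------
# per-record encoding & providers


def test_encode_text_modes(emb_cohort):
    rec = emb_cohort[0]
    np.testing.assert_array_equal(encode_text(rec, "labels"), rec.labels.astype(float))
    assert encode_text(rec, "transformer").shape == (768,)
    p = GCNParams.initialize(seed=0)
    ahat = normalize_adjacency(default_concept_graph())
    assert encode_text(rec, "gcn", gcn_params=p, a_hat=ahat).shape == (28,)
    with pytest.raises(ValueError, match="unknown text mode"):
        encode_text(rec, "bert")


def test_encode_text_requires_embeddings(small_cohort):
    with pytest.raises(ValueError, match="token embeddings"):
        encode_text(small_cohort[0], "transformer")


def test_encode_saps_factors_scales(emb_cohort):
    v = encode_saps_factors(emb_cohort[0])
    assert v.shape == (15,)
    assert np.all(np.isfinite(v))


def test_synthetic_provider_deterministic(emb_cohort):
    prov = SyntheticEmbeddingProvider(emb_cohort.config)
    t1, i1 = prov.get(emb_cohort[5])
    t2, i2 = prov.get(emb_cohort[5])
    np.testing.assert_array_equal(t1, t2)
    np.testing.assert_array_equal(i1, i2)


def test_file_backed_provider(tmp_path, emb_cohort):
    save_cohort(emb_cohort, tmp_path / "c")
    prov = FileBackedEmbeddingProvider(tmp_path / "c" / "embeddings.npz")
    tok, img = prov.get(emb_cohort[3])
    np.testing.assert_array_equal(tok, emb_cohort[3].token_embeddings)
    np.testing.assert_array_equal(img, emb_cohort[3].image_embedding)
    rec = emb_cohort[0]
    rec2 = type(rec)(**{**rec.__dict__, "subject_id": "missing"})
    with pytest.raises(KeyError, match="missing"):
        prov.get(rec2)
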