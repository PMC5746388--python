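import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import equicorrelated
from netsurv.network import (
    CoexpressionNetwork,
    ScaleFreeFitCurve,
    WeightedCoexpressionNetwork,
    detect_modules,
    export_links,
    pick_soft_threshold,
    scale_free_curve,
    scale_free_fit_index,
    similarity_matrix,
    topological_overlap,
)


# ---------------------------------------------------------------- similarity
def test_similarity_diagonal_and_sign_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    X = np.column_stack([x, -x, rng.normal(size=20)])
    s = similarity_matrix(X)
    assert s[0, 0] == 1.0
    assert s[0, 1] == pytest.approx(1.0)  # unsigned network
    assert np.allclose(s, s.T)


def test_similarity_matches_brute_force_correlation():
    X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5],
                  [3.0, 5.0, 2.5], [4.0, 3.0, 4.0]])
    s = similarity_matrix(X)
    for i in range(3):
        for j in range(3):
            xi, xj = X[:, i], X[:, j]
            num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
            den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
            assert s[i, j] == pytest.approx(abs(num / den), abs=1e-12)


def test_zero_variance_gene_marked_unconnected():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 4))
    X[:, 2] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        s = similarity_matrix(X)
    assert s[2, 2] == 1.0
    assert np.all(s[2, [0, 1, 3]] == 0)


# ---------------------------------------------------------------- scale-free
def test_planted_power_law_scores_high():
    """Degree sequence with p(k) exactly proportional to k^-1.5 on log-spaced
    atoms: the log-log regression is exact."""
    ks = 2.0 ** np.arange(1, 11)
    freq = (ks ** -1.5 * 1e4).astype(int)
    k = np.repeat(ks, freq)
    assert scale_free_fit_index(k) >= 0.99


def test_increasing_degree_law_scores_zero():
    ks = 2.0 ** np.arange(1, 11)
    freq = (ks ** 1.5).astype(int)
    k = np.repeat(ks, freq)
    assert scale_free_fit_index(k) == 0.0


def test_degenerate_connectivity_scores_zero():
    assert scale_free_fit_index(np.full(50, 3.0)) == 0.0


def test_mean_connectivity_non_increasing_in_power():
    rng = np.random.default_rng(2)
    for _ in range(5):
        s = rng.uniform(size=(30, 30))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        curve = scale_free_curve(s, powers=range(1, 11))
        assert (np.diff(curve.mean_connectivity) <= 1e-12).all()


def test_pick_soft_threshold_first_crossing():
    curve = ScaleFreeFitCurve(powers=np.array([1, 2, 3, 4]),
                              fit_index=np.array([0.2, 0.5, 0.91, 0.93]),
                              mean_connectivity=np.array([9.0, 5, 3, 2]))
    assert pick_soft_threshold(curve, r2_target=0.90) == 3


def test_pick_soft_threshold_argmax_fallback():
    curve = ScaleFreeFitCurve(powers=np.array([1, 2, 3, 4]),
                              fit_index=np.array([0.2, 0.45, 0.62, 0.5]),
                              mean_connectivity=np.array([9.0, 5, 3, 2]))
    with pytest.warns(UserWarning, match="argmax"):
        assert pick_soft_threshold(curve, r2_target=0.90) == 3


def test_pick_soft_threshold_uninformative_curve_uses_conventional_power():
    curve = ScaleFreeFitCurve(powers=np.arange(1, 21),
                              fit_index=np.zeros(20),
                              mean_connectivity=np.linspace(20, 1, 20))
    with pytest.warns(UserWarning, match="conventional"):
        assert pick_soft_threshold(curve) == 6


# ----------------------------------------------------------------------- TOM
def test_tom_of_disconnected_graph_is_identity():
    a = np.zeros((4, 4))
    np.testing.assert_allclose(topological_overlap(a), np.eye(4))


def test_tom_three_node_hand_value():
    """All off-diagonal adjacency 0.5: TOM_ij = (0.25+0.5)/(1+1-0.5) = 0.5."""
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 0.0)
    tom = topological_overlap(a)
    expected = (0.5 * 0.5 + 0.5) / (1.0 + 1.0 - 0.5)
    off = ~np.eye(3, dtype=bool)
    np.testing.assert_allclose(tom[off], expected, atol=1e-12)
    np.testing.assert_allclose(np.diag(tom), 1.0)


def test_tom_bounded_and_symmetric_on_random_adjacency():
    rng = np.random.default_rng(3)
    for _ in range(5):
        s = rng.uniform(size=(25, 25))
        a = ((s + s.T) / 2) ** 3
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.allclose(tom, tom.T, atol=1e-10)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


def test_power_strictly_shrinks_adjacency():
    rng = np.random.default_rng(4)
    s = rng.uniform(0.05, 0.95, size=(10, 10))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    off = ~np.eye(10, dtype=bool)
    assert ((s ** 3)[off] < (s ** 2)[off]).all()


# -------------------------------------------------------------------- modules
def _two_block_expression(seed, n=100, block=50, rho=0.7):
    rng = np.random.default_rng(seed)
    return np.hstack([equicorrelated(rng, n, block, rho),
                      equicorrelated(rng, n, block, rho)])


@pytest.mark.parametrize("seed", range(5))
def test_two_planted_blocks_recovered(seed):
    """Without background genes every top merge is a within-module merge, so
    the static cut sits close to the top of the dendrogram."""
    X = _two_block_expression(seed)
    s = similarity_matrix(X)
    tom = topological_overlap(s ** 6)
    labels = detect_modules(tom, cut_quantile=0.97)
    planted = np.repeat([1, 2], 50)
    assert len(set(labels) - {0}) == 2
    assert adjusted_rand_score(planted, labels) >= 0.9


def test_identical_genes_form_single_module():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    X = np.tile(x[:, None], (1, 35)) + 1e-12 * rng.normal(size=(40, 35))
    s = similarity_matrix(X)
    labels = detect_modules(topological_overlap(s ** 6), min_module_size=10)
    assert len(set(labels)) == 1 and labels[0] != 0


def test_gene_permutation_permutes_labels():
    X = _two_block_expression(7)
    rng = np.random.default_rng(8)
    perm = rng.permutation(X.shape[1])
    tom = topological_overlap(similarity_matrix(X) ** 6)
    lab = detect_modules(tom)
    lab_p = detect_modules(topological_overlap(similarity_matrix(X[:, perm]) ** 6))
    assert adjusted_rand_score(lab[perm], lab_p) == pytest.approx(1.0)


def test_too_few_genes_all_noise():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(20, 10))
    with pytest.warns(UserWarning, match="noise"):
        labels = detect_modules(topological_overlap(similarity_matrix(X) ** 6),
                                min_module_size=30)
    assert (labels == 0).all()


# --------------------------------------------------------------------- links
def _toy_network():
    a = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.7], [0.2, 0.7, 1.0]])
    return CoexpressionNetwork(gene_ids=["x", "y", "z"], similarity=a, beta=1,
                               adjacency=a, tom=a, module_of_gene={})


def test_export_links_strict_threshold():
    net = _toy_network()
    assert export_links(net, threshold=1.0).empty
    assert len(export_links(net, threshold=0.0)) == 3
    edges = export_links(net, threshold=0.5)
    assert set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy())) == {
        ("x", "y"), ("y", "z")}


def test_export_links_counts_match_brute_force():
    rng = np.random.default_rng(10)
    s = rng.uniform(size=(15, 15))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    net = CoexpressionNetwork(gene_ids=[f"g{i}" for i in range(15)],
                              similarity=s, beta=1, adjacency=s, tom=s,
                              module_of_gene={})
    thr = 0.6
    brute = int((np.triu(s, 1) > thr).sum())
    assert len(export_links(net, threshold=thr)) == brute


# ------------------------------------------------------------------ estimator
def test_estimator_assembles_consistent_network():
    X = pd.DataFrame(_two_block_expression(11),
                     columns=[f"g{i}" for i in range(100)])
    est = WeightedCoexpressionNetwork(beta=6)
    labels = est.fit_predict(X)
    assert est.beta_ == 6
    np.testing.assert_allclose(est.adjacency_, est.similarity_ ** 6)
    assert np.allclose(est.tom_, est.tom_.T)
    assert list(est.network_.module_of_gene) == list(X.columns)
    assert (labels == est.labels_).all()
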