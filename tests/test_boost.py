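import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from conftest import equicorrelated
from netsurv.boost import (
    ComponentwiseBoostingRegressor,
    NetworkSparseBoostSelector,
    componentwise_boost,
    joint_step,
    module_step,
)


def _orthonormal_design(rng, n, p):
    A = rng.normal(size=(n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q * np.sqrt(n)  # mean zero, X'X/n = I


# ------------------------------------------------------------ core boosting
def test_single_predictor_single_full_step_is_ols():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    y = 2.0 * x + 0.1 * rng.normal(size=50)
    fit = componentwise_boost(x[:, None], y, np.ones(50), max_iter=1,
                              step_size=1.0, selection_criterion="fixed_iter")
    xs = (x - x.mean()) / x.std()
    slope = np.sum(xs * (y - y.mean())) / np.sum(xs**2)
    assert fit.final_coefs[0] == pytest.approx(slope, abs=1e-12)


def test_orthonormal_full_steps_reach_ols():
    rng = np.random.default_rng(1)
    n, p = 64, 8
    X = _orthonormal_design(rng, n, p)
    y = X[:, :3] @ [1.0, -0.5, 0.25] + 0.1 * rng.normal(size=n)
    fit = componentwise_boost(X, y, np.ones(n), max_iter=30, step_size=1.0,
                              selection_criterion="fixed_iter")
    ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
    np.testing.assert_allclose(fit.coef_path[-1], ols[1:], atol=1e-8)


def test_orthonormal_bic_support_not_larger_than_ols():
    rng = np.random.default_rng(2)
    n, p = 64, 8
    X = _orthonormal_design(rng, n, p)
    y = X[:, :3] @ [1.0, -0.5, 0.25] + 0.1 * rng.normal(size=n)
    fit = componentwise_boost(X, y, np.ones(n), max_iter=30, step_size=1.0)
    assert len(fit.support) <= p


@pytest.mark.parametrize("seed", range(5))
def test_null_design_selects_almost_nothing(seed):
    rng = np.random.default_rng(100 + seed)
    X = rng.normal(size=(200, 50))
    y = rng.normal(size=200)
    fit = componentwise_boost(X, y, np.ones(200))
    assert len(fit.support) <= 2


def test_weighted_rss_non_increasing_along_path():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(80, 10))
    y = X[:, 0] - X[:, 3] + rng.normal(size=80)
    w = rng.uniform(0.0, 1.0, size=80)
    w[rng.random(80) < 0.3] = 0.0
    w[0] = 1.0
    fit = componentwise_boost(X, y, w, max_iter=100)
    wn = w / w.sum()
    Xs = (X - fit.predictor_means) / fit.predictor_sds
    yc = y - fit.response_mean
    rss = [wn @ (yc - Xs @ b) ** 2 for b in fit.coef_path]
    assert (np.diff(rss) <= 1e-10).all()


def test_support_size_bounded_by_iteration():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 20))
    y = X[:, 2] + rng.normal(size=60)
    fit = componentwise_boost(X, y, np.ones(60), max_iter=5,
                              selection_criterion="fixed_iter")
    assert len(fit.support) <= 5
    for m, row in enumerate(fit.coef_path):
        assert (row != 0).sum() <= m


def test_zero_variance_predictor_excluded():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 3))
    X[:, 1] = 4.0
    y = X[:, 0] + 0.1 * rng.normal(size=50)
    with pytest.warns(UserWarning, match="zero-variance"):
        fit = componentwise_boost(X, y, np.ones(50))
    assert fit.final_coefs[1] == 0.0


def test_all_zero_weights_error():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError, match="zero"):
        componentwise_boost(rng.normal(size=(10, 2)), rng.normal(size=10),
                            np.zeros(10))


def test_tie_breaks_to_lowest_index():
    x = np.array([1.0, -1.0, 1.0, -1.0])
    X = np.column_stack([x, x])  # identical predictors: exact tie
    y = x.copy()
    fit = componentwise_boost(X, y, np.ones(4), max_iter=1,
                              step_size=1.0, selection_criterion="fixed_iter")
    assert fit.final_coefs[0] != 0.0 and fit.final_coefs[1] == 0.0


# ------------------------------------------------------------- module step
def test_super_marker_values_reproducible(small_cohort):
    rng = np.random.default_rng(7)
    Z = equicorrelated(rng, 120, 8, 0.5)
    y = 0.7 * Z[:, 0] + 0.5 * rng.normal(size=120)
    t = np.exp(6.0 + y)
    mk = module_step(pd.DataFrame(Z, columns=[f"g{i}" for i in range(8)]),
                     t, np.ones(120, dtype=int), module_index=4)
    assert mk.module_index == 4
    assert mk.active
    wn = np.full(120, 1 / 120)
    cols = [int(g[1]) for g in mk.member_genes]
    Xs = (Z - wn @ Z) / np.sqrt(wn @ (Z - wn @ Z) ** 2)
    np.testing.assert_allclose(mk.values, Xs[:, cols] @ mk.gene_weights, atol=1e-12)


def test_null_single_gene_module_usually_inactive():
    inactive = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        Z = rng.normal(size=(150, 1))
        t = np.exp(6.0 + rng.normal(size=150))
        mk = module_step(pd.DataFrame(Z), t, np.ones(150, dtype=int))
        inactive += not mk.active
    assert inactive >= 18


def test_signal_genes_recovered_within_module():
    """5 planted signal genes (effect 0.5) among 45 correlated nulls,
    n=300: at least 3 of 5 land in the boosting support on average
    (10 seeds)."""
    hits = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        Z = equicorrelated(rng, 300, 50, 0.6)
        y = 0.5 * Z[:, :5].sum(axis=1) + rng.normal(size=300)
        t = np.exp(6.5 + y)
        mk = module_step(pd.DataFrame(Z), t, np.ones(300, dtype=int))
        hits.append(len(set(mk.member_genes) & set(range(5))))
    assert np.mean(hits) >= 3.0


# -------------------------------------------------------------- joint step
def test_single_active_marker_selected_when_predictive():
    rng = np.random.default_rng(8)
    Z = equicorrelated(rng, 200, 6, 0.5)
    y = 0.8 * Z[:, 0] + 0.5 * rng.normal(size=200)
    t = np.exp(6.0 + y)
    ev = np.ones(200, dtype=int)
    mk = module_step(pd.DataFrame(Z), t, ev, module_index=1)
    res = joint_step([mk], t, ev)
    assert res.selected_modules == {1}
    assert res.final_genes == set(mk.member_genes)


def test_pure_noise_marker_not_selected():
    rng = np.random.default_rng(9)
    from netsurv.boost import SuperMarker

    noise = SuperMarker(module_index=2, member_genes=["a"],
                        gene_weights=np.array([1.0]),
                        values=rng.normal(size=200))
    t = np.exp(6.0 + rng.normal(size=200))
    res = joint_step([noise], t, np.ones(200, dtype=int))
    assert res.selected_modules == set()
    assert res.final_genes == set()


def test_clean_three_signal_modules_selected():
    """3 signal modules (5 effects of 0.5 in 10 genes) among 7 noise
    modules: the joint step keeps the signal modules and almost never a
    noise module."""
    recovered, extras = [], []
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        n = 300
        y = np.zeros(n)
        blocks = []
        for m in range(10):
            Z = equicorrelated(rng, n, 10, 0.6)
            blocks.append(Z)
            if m < 3:
                y += 0.5 * Z[:, :5].sum(axis=1)
        y += rng.normal(size=n)
        t = np.exp(6.5 + y)
        ev = np.ones(n, dtype=int)
        markers = [module_step(pd.DataFrame(Z), t, ev, module_index=i + 1)
                   for i, Z in enumerate(blocks)]
        res = joint_step(markers, t, ev)
        recovered.append(len(res.selected_modules & {1, 2, 3}))
        extras.append(len(res.selected_modules - {1, 2, 3}))
    assert sum(r == 3 for r in recovered) >= 8
    assert np.mean(extras) <= 1.0


def test_module_order_invariance():
    rng = np.random.default_rng(10)
    n = 200
    blocks = [equicorrelated(rng, n, 8, 0.5) for _ in range(4)]
    y = 0.6 * blocks[1][:, 0] + 0.6 * blocks[3][:, 1] + 0.5 * rng.normal(size=n)
    t = np.exp(6.0 + y)
    ev = np.ones(n, dtype=int)

    def run(order):
        markers = [module_step(
            pd.DataFrame(blocks[i], columns=[f"m{i}g{j}" for j in range(8)]),
            t, ev, module_index=i) for i in order]
        return joint_step(markers, t, ev)

    assert run([0, 1, 2, 3]).final_genes == run([3, 1, 0, 2]).final_genes


def test_empty_marker_list_warns_and_returns_empty():
    rng = np.random.default_rng(11)
    t = np.exp(6.0 + rng.normal(size=50))
    with pytest.warns(UserWarning, match="no active"):
        res = joint_step([], t, np.ones(50, dtype=int))
    assert res.final_genes == set()


# -------------------------------------------------------------- estimators
def test_regressor_predict_consistency():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(100, 5))
    y = X[:, 0] - 0.5 * X[:, 2] + 0.3 * rng.normal(size=100)
    est = ComponentwiseBoostingRegressor(max_iter=200).fit(X, y)
    pred = est.predict(X)
    assert np.corrcoef(pred, y)[0, 1] > 0.8
    clone(est)  # sklearn params round-trip


def test_selector_end_to_end_on_labels():
    rng = np.random.default_rng(13)
    n = 200
    Z1 = equicorrelated(rng, n, 6, 0.5)
    Z2 = equicorrelated(rng, n, 6, 0.5)
    X = pd.DataFrame(np.hstack([Z1, Z2]),
                     columns=[f"g{i}" for i in range(12)])
    y = 0.8 * Z1[:, 0] + 0.5 * rng.normal(size=n)
    t = np.exp(6.0 + y)
    surv = pd.DataFrame({"time": t, "event": 1})
    sel = NetworkSparseBoostSelector().fit(X, surv, module_labels=[1] * 6 + [2] * 6)
    assert 1 in sel.selected_modules_
    assert all(g in sel.module_estimates_ for g in sel.final_genes_)
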