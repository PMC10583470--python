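"""LHS sampling, MI estimators, alpha scoring, gap threshold, edges."""

import logging

import numpy as np
import pandas as pd
import pytest

from ferronet import (
    InterClusterNetwork,
    alpha_score,
    build_network,
    estimate_mi,
    lag_align,
    lhs_sample_pairs,
    select_threshold,
)
from ferronet.network import _mi_from_rho


# ---------------------------------------------------------------------------
# Latin hypercube pair sampling


def test_lhs_covers_clusters_whose_size_divides_n():
    gi = [f"a{k}" for k in range(10)]
    gj = [f"b{k}" for k in range(10)]
    pairs = lhs_sample_pairs(gi, gj, 10, seed=0)
    assert sorted(p[0] for p in pairs) == sorted(gi)
    assert sorted(p[1] for p in pairs) == sorted(gj)


def test_lhs_singleton_cluster_always_sampled():
    pairs = lhs_sample_pairs(["only"], ["b0", "b1", "b2"], 7, seed=1)
    assert all(p[0] == "only" for p in pairs)
    assert len(pairs) == 7


def test_lhs_deterministic_under_seed():
    gi = [f"a{k}" for k in range(5)]
    gj = [f"b{k}" for k in range(8)]
    assert lhs_sample_pairs(gi, gj, 20, seed=3) == lhs_sample_pairs(gi, gj, 20, seed=3)


def test_lhs_small_cluster_repeats():
    pairs = lhs_sample_pairs(["a0", "a1"], ["b0", "b1"], 10, seed=2)
    assert len(pairs) == 10  # repetition across strata when size < n


@pytest.mark.parametrize("n", [0, -3])
def test_lhs_rejects_nonpositive_n(n):
    with pytest.raises(ValueError):
        lhs_sample_pairs(["a"], ["b"], n)


def test_lhs_rejects_empty_cluster():
    with pytest.raises(ValueError):
        lhs_sample_pairs([], ["b"], 5)


# ---------------------------------------------------------------------------
# lag alignment


def test_lag_zero_is_identity():
    x, y = np.arange(7.0), np.arange(7.0) * 2
    ax, ay = lag_align(x, y, 0)
    np.testing.assert_array_equal(ax, x)
    np.testing.assert_array_equal(ay, y)


def test_lag_one_drops_leading_point():
    x = np.arange(1.0, 8.0)
    y = np.arange(1.0, 8.0)
    ax, ay = lag_align(x, y, 1)
    assert len(ax) == len(ay) == 6
    assert list(zip(ax, ay)) == [(k, k + 1) for k in range(1, 7)]


def test_lag_must_be_smaller_than_length():
    with pytest.raises(ValueError):
        lag_align(np.arange(5.0), np.arange(5.0), 5)


# ---------------------------------------------------------------------------
# MI estimators


def test_constant_input_gives_zero_mi(caplog):
    with caplog.at_level(logging.WARNING):
        assert estimate_mi([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0
    assert any("zero-variance" in r.message for r in caplog.records)


def test_parametric_mi_equals_closed_form_on_realized_rho():
    rng = np.random.default_rng(0)
    cov = [[1.0, 0.9], [0.9, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, size=400)
    x, y = xy[:, 0], xy[:, 1]
    rho = np.corrcoef(x, y)[0, 1]
    expected = -0.5 * np.log(1 - rho**2)
    assert estimate_mi(x, y) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.8304, abs=0.15)  # near the rho=0.9 value


def test_kde_mi_close_to_gaussian_closed_form():
    rng = np.random.default_rng(1)
    xy = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=500)
    est = estimate_mi(xy[:, 0], xy[:, 1], "kde")
    assert est == pytest.approx(-0.5 * np.log(1 - 0.64), abs=0.15)


@pytest.mark.parametrize("estimator", ["gaussian_parametric", "kde"])
def test_mi_symmetry_and_nonnegativity(estimator):
    rng = np.random.default_rng(2)
    x = rng.normal(size=60)
    y = 0.5 * x + rng.normal(size=60)
    a = estimate_mi(x, y, estimator)
    b = estimate_mi(y, x, estimator)
    assert a >= 0
    assert abs(a - b) < 1e-9


def test_kde_converges_to_closed_form_with_sample_size():
    rng = np.random.default_rng(3)
    truth = -0.5 * np.log(1 - 0.36)
    med_err = []
    for n in (50, 200, 800):
        errs = [
            abs(estimate_mi(*rng.multivariate_normal(
                [0, 0], [[1, 0.6], [0.6, 1]], size=n).T, "kde") - truth)
            for _ in range(11)
        ]
        med_err.append(np.median(errs))
    assert med_err[0] > med_err[2]


def test_unknown_estimator_rejected():
    with pytest.raises(ValueError, match="estimator"):
        estimate_mi([1.0, 2, 3], [3.0, 2, 1], "histogram")


# ---------------------------------------------------------------------------
# alpha scoring


def test_alpha_linear_interpolation_convention():
    assert alpha_score(np.arange(1, 11), q=0.9) == pytest.approx(9.1)


def test_alpha_of_constant_values():
    assert alpha_score([0.3] * 25) == pytest.approx(0.3)


def test_alpha_empty_rejected():
    with pytest.raises(ValueError):
        alpha_score([])


def test_lhs_alpha_matches_exhaustive_enumeration():
    """On tiny cluster-structured groups, LHS alpha agrees with all-pairs alpha."""
    rng = np.random.default_rng(5)
    t = np.linspace(0, 1, 7)
    base1 = np.sin(2 * np.pi * (t + rng.uniform(0, 1)))
    base2 = np.cos(2 * np.pi * (t + rng.uniform(0, 1)))
    gi = {f"a{k}": base1 + 0.25 * rng.normal(size=7) for k in range(8)}
    gj = {f"b{k}": base2 + 0.25 * rng.normal(size=7) for k in range(6)}
    exhaustive = [estimate_mi(x, y) for x in gi.values() for y in gj.values()]
    alpha_full = alpha_score(exhaustive)
    pairs = lhs_sample_pairs(list(gi), list(gj), 2000, seed=6)
    sampled = [estimate_mi(gi[a], gj[b]) for a, b in pairs]
    assert alpha_score(sampled) == pytest.approx(alpha_full, abs=0.02)


# ---------------------------------------------------------------------------
# threshold selection


def test_threshold_lands_in_bimodal_gap():
    rng = np.random.default_rng(7)
    alphas = np.concatenate([
        rng.normal(0.05, 0.01, 30), rng.normal(0.30, 0.01, 10)
    ])
    thr = select_threshold(alphas, bins=50)
    assert 0.07 < thr < 0.28


def test_threshold_fallback_without_interior_gap(caplog):
    vals = np.linspace(0.0, 1.0, 200)  # every bin occupied
    with caplog.at_level(logging.WARNING):
        thr = select_threshold(vals, bins=50)
    assert thr == pytest.approx(np.quantile(vals, 0.95))
    assert any("falling back" in r.message for r in caplog.records)


def test_threshold_needs_distinct_values():
    with pytest.raises(ValueError):
        select_threshold([0.5] * 30)


def test_threshold_tie_breaks_to_lower_gap():
    # two interior gaps of equal length; the lower one must win
    alphas = np.concatenate([
        np.full(10, 0.0), np.full(10, 0.4), np.full(10, 0.8)
    ])
    thr = select_threshold(alphas, bins=8)
    assert thr < 0.4


# ---------------------------------------------------------------------------
# edge construction and model fit


def _alpha_table(rows):
    return pd.DataFrame(rows, columns=["source", "target", "lag", "alpha"])


def test_threshold_above_everything_gives_empty_network():
    at = _alpha_table([(1, 2, 0, 0.1), (2, 3, 1, 0.2)])
    edges = build_network(at, threshold=0.5)
    assert edges.empty


def test_lag0_edges_deduplicated_keeping_max():
    at = _alpha_table([(1, 2, 0, 0.4), (2, 1, 0, 0.6), (1, 2, 1, 0.5)])
    edges = build_network(at, threshold=0.3)
    lag0 = edges[edges["lag"] == 0]
    assert len(lag0) == 1
    assert lag0.iloc[0]["alpha"] == pytest.approx(0.6)
    assert not lag0.iloc[0]["directed"]
    lag1 = edges[edges["lag"] == 1]
    assert len(lag1) == 1 and bool(lag1.iloc[0]["directed"])


@pytest.fixture(scope="module")
def fitted_network(small_sim_module):
    cfg, expr, truth = small_sim_module
    from ferronet import compute_de, max_normalize_frame
    from ferronet.de import post_zero_times

    de = compute_de(expr, "per_time_control")
    genes = sorted(de.de_genes(times=post_zero_times(de)))
    traj = max_normalize_frame(expr.mean_trajectories("stress").loc[genes])
    clusters = truth.cluster_of[truth.cluster_of.index.isin(traj.index)]
    model = InterClusterNetwork(traj, clusters, min_cluster_size=2)
    return truth, model


@pytest.fixture(scope="module")
def small_sim_module():
    from ferronet import SimulationConfig, simulate_trajectories

    cfg = SimulationConfig(n_genes=2000, n_tfs=200, n_clusters=10,
                           planted_edges=((1, 2, 1), (3, 4, 1)), seed=17)
    expr, truth = simulate_trajectories(cfg)
    return cfg, expr, truth


def test_fit_is_deterministic(fitted_network):
    _, model = fitted_network
    a = model.fit(seed=11)
    b = model.fit(seed=11)
    pd.testing.assert_frame_equal(a.alpha_table, b.alpha_table)
    assert a.threshold == b.threshold
    pd.testing.assert_frame_equal(a.edges, b.edges)


def test_planted_alpha_exceeds_background(fitted_network):
    """Planted-edge MI distributions carry heavier upper tails."""
    truth, model = fitted_network
    res = model.fit(seed=11)
    at = res.alpha_table
    planted_pairs = {frozenset((i, j)) for i, j, _ in truth.true_edges}
    is_planted = at.apply(
        lambda r: frozenset((r["source"], r["target"])) in planted_pairs, axis=1
    )
    assert at.loc[is_planted, "alpha"].mean() > at.loc[~is_planted, "alpha"].mean()


def test_planted_edges_recovered(fitted_network):
    truth, model = fitted_network
    res = model.fit(seed=11)
    for i, j, lag in truth.true_edges:
        hit = ((res.edges["source"] == i) & (res.edges["target"] == j)
               & (res.edges["lag"] == lag)).any()
        assert hit, f"planted edge {(i, j, lag)} not accepted"


def test_summary_mentions_threshold_and_edges(fitted_network):
    _, model = fitted_network
    res = model.fit(seed=11)
    text = res.summary()
    assert f"{res.threshold:.4f}" in text
    assert str(len(res.edges)) in text
    g = res.to_networkx()
    assert g.number_of_edges() == len(res.edges)


def test_closed_form_helper_clips():
    assert _mi_from_rho(1.0) == pytest.approx(-0.5 * np.log1p(-0.9999**2))
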