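"""Network construction, restart-walk diffusion, CV recovery and the filter."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from oatargets.diffusion import (
    build_network,
    count_oa_interactions,
    cross_validate,
    diffuse,
    diffuse_exact,
    prioritise,
    rank_genes,
    rank_significance,
    read_edge_list,
)
from oatargets.synthdata import synth_network, write_edge_list


# ---------------------------------------------------------------------------
# build_network

def test_build_network_cleans_and_keeps_lcc():
    net = build_network([("a", "B"), ("B", "A"), ("B", "B"), ("C", "D")])
    assert set(net.nodes) == {"A", "B"}  # size-2 tie broken toward 'A'
    assert net.n_self_loops_removed == 1
    assert net.n_duplicates_removed == 1
    assert net.n_nodes_dropped == 2


def test_build_network_triangle_beats_dyad():
    net = build_network([("X", "Y"), ("Y", "Z"), ("Z", "X"), ("P", "Q")])
    assert set(net.nodes) == {"X", "Y", "Z"}


def test_build_network_empty_rejected():
    with pytest.raises(ValueError):
        build_network([])


def test_synthetic_network_contract():
    edges, truth = synth_network(n_nodes=2000, module_size=50, rng_seed=5)
    net = build_network(edges)
    assert net.n_nodes == 2000  # generator output is already connected
    assert net.n_self_loops_removed == 0
    assert set(truth.planted_module) <= set(net.nodes)


def test_edge_list_roundtrip_and_extra_column_warning(tmp_path):
    edges, _ = synth_network(n_nodes=50, module_size=5, rng_seed=2)
    path = tmp_path / "edges.tsv"
    write_edge_list(edges, path)
    net = read_edge_list(path)
    assert net.n_nodes == 50
    with_conf = tmp_path / "edges3.tsv"
    with_conf.write_text("A\tB\t0.9\nB\tC\t0.8\n")
    with pytest.warns(UserWarning, match="extra columns"):
        net3 = read_edge_list(with_conf)
    assert set(net3.nodes) == {"A", "B", "C"}


# ---------------------------------------------------------------------------
# diffuse

def test_restart_only_limit_returns_seed_distribution():
    net = build_network([("A", "B"), ("B", "C")])
    scores = diffuse(net, {"A", "C"}, r=1.0)
    expected = {"A": 0.5, "B": 0.0, "C": 0.5}
    assert scores.as_series().to_dict() == pytest.approx(expected)


def test_path_graph_matches_hand_built_linear_solve():
    """A-B-C with seed {A}: fixed point of F = (1-r) W F + r F0 solved by a
    dense 3x3 system built by hand."""
    net = build_network([("A", "B"), ("B", "C")])
    r = 0.5
    w = np.zeros((3, 3))
    order = {g: i for i, g in enumerate(net.nodes)}
    for a, b in [("A", "B"), ("B", "C")]:
        w[order[a], order[b]] = 1.0
        w[order[b], order[a]] = 1.0
    w = w / w.sum(axis=0, keepdims=True)
    f0 = np.zeros(3)
    f0[order["A"]] = 1.0
    expected = np.linalg.solve(np.eye(3) - (1 - r) * w, r * f0)
    scores = diffuse(net, {"A"}, r=r, tol=1e-14)
    assert scores.scores == pytest.approx(expected, abs=1e-10)
    assert scores.converged


def test_scores_conserve_mass_and_stay_nonnegative():
    edges, truth = synth_network(n_nodes=300, module_size=20, rng_seed=9)
    net = build_network(edges)
    scores = diffuse(net, truth.planted_module, r=0.3)
    assert scores.scores.sum() == pytest.approx(1.0, abs=1e-12)
    assert (scores.scores >= 0).all()


def test_symmetric_nodes_get_equal_scores():
    # star: leaves are exchangeable under automorphism when seeding the hub
    net = build_network([("HUB", f"L{i}") for i in range(6)])
    scores = diffuse(net, {"HUB"}, r=0.4).as_series()
    leaves = scores[[f"L{i}" for i in range(6)]]
    assert np.allclose(leaves, leaves.iloc[0])


def test_iterative_matches_closed_form_on_random_graphs():
    """Power iteration and the sparse linear solve agree on 200 random
    connected graphs of <= 50 nodes (L-inf within 10x the L1 tolerance)."""
    rng = np.random.default_rng(21)
    tol = 1e-10
    for trial in range(200):
        n = int(rng.integers(3, 51))
        p = float(rng.uniform(0.1, 0.5))
        edges = [
            (f"N{i}", f"N{j}")
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        edges += [(f"N{i}", f"N{i+1}") for i in range(n - 1)]  # ensure connected
        net = build_network(edges)
        n_seeds = int(rng.integers(1, net.n_nodes + 1))
        seeds = list(rng.choice(net.nodes, size=n_seeds, replace=False))
        r = float(rng.uniform(0.05, 0.95))
        it = diffuse(net, seeds, r=r, tol=tol)
        exact = diffuse_exact(net, seeds, r=r)
        assert np.abs(it.scores - exact.scores).max() <= 10 * tol, trial
        assert exact.scores.sum() == pytest.approx(1.0, abs=1e-9)


def test_monotone_locality_on_path_graph():
    nodes = [f"P{i:02d}" for i in range(12)]
    net = build_network(list(zip(nodes, nodes[1:])))
    scores = diffuse(net, {nodes[0]}, r=0.3).as_series()
    values = scores[nodes].to_numpy()
    assert (np.diff(values) < 0).all()


def test_invalid_diffusion_inputs():
    net = build_network([("A", "B")])
    with pytest.raises(ValueError):
        diffuse(net, {"ZZZ"})
    with pytest.raises(ValueError):
        diffuse(net, {"A"}, r=0.0)


# ---------------------------------------------------------------------------
# rank_genes

def test_ranks_distinct_and_tied():
    edges, _ = synth_network(n_nodes=30, module_size=4, rng_seed=3)
    net = build_network(edges)
    scores = diffuse(net, [net.nodes[0]], r=0.3)
    # hand-build: distinct scores -> a permutation of 1..n
    ranks = rank_genes(scores)
    assert sorted(ranks.values()) == sorted(
        stats.rankdata(-scores.scores).tolist()
    )
    # force a tie by overwriting two scores
    scores.scores[:] = 0.0
    scores.scores[0] = scores.scores[1] = 0.5
    tied = rank_genes(scores)
    assert tied[net.nodes[0]] == tied[net.nodes[1]] == 1.5


def test_excluded_seeds_leave_ranking_domain():
    edges, _ = synth_network(n_nodes=40, module_size=4, rng_seed=4)
    net = build_network(edges)
    seeds = net.nodes[:5]
    scores = diffuse(net, seeds, r=0.3)
    ranks = rank_genes(scores, exclude=seeds)
    assert set(ranks) == set(net.nodes) - set(seeds)
    assert sorted(ranks.values()) == list(
        stats.rankdata(sorted(ranks.values())).tolist()
    ) or max(ranks.values()) <= net.n_nodes - len(seeds)


# ---------------------------------------------------------------------------
# cross_validate

def test_cv_shape_bounds_and_determinism():
    edges, truth = synth_network(n_nodes=300, module_size=50, rng_seed=6)
    net = build_network(edges)
    seeds = truth.planted_module
    cv1 = cross_validate(net, seeds, k=5, repeats=2, rng_seed=77)
    cv2 = cross_validate(net, seeds, k=5, repeats=2, rng_seed=77)
    assert cv1.heldout_ranks == cv2.heldout_ranks
    assert cv1.unlabelled_ranks == cv2.unlabelled_ranks
    assert len(cv1.heldout_ranks) == 50 * 2
    n_retained_max = 50 - 50 // 5
    assert all(1 <= rk <= 300 - n_retained_max for rk in cv1.heldout_ranks)
    with pytest.raises(ValueError):
        cross_validate(net, seeds, k=1)


def test_cv_star_graph_ranks_within_bounds():
    net = build_network([("HUB", f"L{i}") for i in range(20)])
    seeds = [f"L{i}" for i in range(10)]
    cv = cross_validate(net, seeds, k=5, repeats=1, rng_seed=0)
    n_retained = 8
    assert all(1 <= rk <= net.n_nodes - n_retained for rk in cv.heldout_ranks)


def test_cv_recovers_planted_module():
    """Held-out module genes rank far better than unlabelled genes on a
    module-boosted graph; no separation when the module is not boosted."""
    n, module, n_seeds = 2000, 50, 40
    edges, truth = synth_network(
        n_nodes=n, module_size=module, intra_module_edge_prob=0.5, rng_seed=13
    )
    net = build_network(edges)
    seeds = truth.planted_module[:n_seeds]
    cv = cross_validate(net, seeds, k=5, repeats=2, rng_seed=13)
    assert np.median(cv.heldout_ranks) <= 0.25 * n
    assert 0.4 * n <= np.median(cv.unlabelled_ranks) <= 0.6 * n
    mw = stats.mannwhitneyu(
        cv.heldout_ranks, cv.unlabelled_ranks, alternative="less"
    )
    assert mw.pvalue < 0.01

    null_edges, null_truth = synth_network(
        n_nodes=n, module_size=module, intra_module_edge_prob=0.0, rng_seed=13
    )
    null_net = build_network(null_edges)
    null_cv = cross_validate(
        null_net, null_truth.planted_module[:n_seeds], k=5, repeats=2, rng_seed=13
    )
    null_mw = stats.mannwhitneyu(
        null_cv.heldout_ranks, null_cv.unlabelled_ranks, alternative="less"
    )
    assert null_mw.pvalue > 0.05


# ---------------------------------------------------------------------------
# rank_significance

def signed_rank_oracle(ranks, null_median):
    """Exact one-sided signed-rank p by enumerating all sign vectors."""
    diffs = [rk - null_median for rk in ranks if rk != null_median]
    magnitudes = [abs(d) for d in diffs]
    w_obs = sum(m for d, m in zip(diffs, magnitudes) if d < 0)
    n = len(diffs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(m for s, m in zip(signs, magnitudes) if s)
        if w >= w_obs:  # at least as extreme toward "smaller ranks"
            count += 1
    return count / 2**n


def test_all_better_ranks_give_exact_tail_probability():
    """Nine distinct ranks all beating the null median: p = 1/2^9."""
    ranks = [10, 20, 30, 40, 60, 70, 80, 90, 100]
    p = rank_significance(ranks, n_candidates=1000)
    assert p == pytest.approx(1 / 512)
    assert p == pytest.approx(0.001953, abs=5e-7)
    assert p == pytest.approx(signed_rank_oracle(ranks, 500.5))


def test_signed_rank_matches_enumeration_on_mixed_ranks():
    ranks = [5, 40, 90, 120, 300, 800]
    p = rank_significance(ranks, n_candidates=1000)
    assert p == pytest.approx(signed_rank_oracle(ranks, 500.5))


def test_rank_significance_edge_cases():
    with pytest.raises(ValueError):
        rank_significance([], 10)
    with pytest.raises(ValueError):
        rank_significance([11], 10)
    # a single rank exactly at the null median leaves nothing to test
    with pytest.raises(ValueError):
        rank_significance([50.5], 100)
    # symmetric ranks around the null median are not significant
    p = rank_significance([400, 601, 399, 602], 1000)
    assert p >= 0.4


def test_rank_sum_flavour_available():
    p = rank_significance([1, 2, 3], 100, flavour="rank_sum")
    assert 0 < p < 0.05


# ---------------------------------------------------------------------------
# count_oa_interactions and prioritise

def test_count_oa_interactions():
    net = build_network(
        [("CENT", f"OA{i}") for i in range(4)] + [("CENT", "OTHER"), ("OTHER", "FAR")]
    )
    oa = {f"OA{i}" for i in range(4)}
    assert count_oa_interactions(net, "CENT", oa) == 4
    assert count_oa_interactions(net, "FAR", oa) == 0
    with pytest.raises(KeyError):
        count_oa_interactions(net, "MISSING", oa)


def test_prioritise_filter_logic():
    ranks = {"ACKR2": 241.0, "LOWDE": 100.0, "KNOWN1": 50.0, "WEAKNET": 10.0}
    de = {"ACKR2": 4, "LOWDE": 2, "KNOWN1": 5, "WEAKNET": 5}
    inter = {"ACKR2": 4, "LOWDE": 10, "KNOWN1": 5, "WEAKNET": 3}
    out = prioritise(ranks, de, inter, known={"KNOWN1"})
    assert [c.gene for c in out] == ["ACKR2"]
    rec = out[0]
    assert rec.network_rank == 241.0
    assert rec.n_oa_interactions == 4
    assert rec.n_human_de_datasets == 4
    assert rec.known is False


def test_prioritise_sorted_by_rank_and_thresholds_configurable():
    ranks = {"A": 30.0, "B": 10.0, "C": 20.0}
    de = {"A": 3, "B": 3, "C": 1}
    inter = {"A": 4, "B": 4, "C": 9}
    assert [c.gene for c in prioritise(ranks, de, inter, known=set())] == ["B", "A"]
    relaxed = prioritise(ranks, de, inter, known=set(), min_de=1, min_interactions=1)
    assert [c.gene for c in relaxed] == ["B", "C", "A"]
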