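"""Balance score, local-search optimizer vs enumeration oracle, K sweep."""

import numpy as np
import pytest

from tomonet import (
    balance_score,
    exhaustive_optimum,
    optimize_partition,
    select_model,
    sweep_classes,
)
from tomonet.balance import SweepResult, TrialResult, _canonical
from tomonet.simulate import random_signed_network
from tomonet.ties import PairEvidence, SignedNetwork


def _net(edges, extra_nodes=()):
    nodes = set(extra_nodes)
    for u, v in edges:
        nodes.update((u, v))
    ev = {}
    signed = {}
    for (u, v), s in edges.items():
        pair = tuple(sorted((u, v)))
        signed[pair] = s
        ev[pair] = PairEvidence(pair, 1, 1 if s > 0 else 0, 0 if s > 0 else 1)
    return SignedNetwork(
        nodes=frozenset(nodes), edges=signed, contested=frozenset(), evidence=ev
    )


def _two_cliques(size=5):
    """Two positive cliques bridged only by negative edges: perfectly balanced."""
    edges = {}
    left = [f"L{i}" for i in range(size)]
    right = [f"R{i}" for i in range(size)]
    for grp in (left, right):
        for i in range(size):
            for j in range(i + 1, size):
                edges[(grp[i], grp[j])] = +1
    for u in left:
        for v in right:
            edges[(u, v)] = -1
    return _net(edges), left, right


class TestBalanceScore:
    def test_balanced_two_clique_split_scores_zero(self):
        net, left, right = _two_cliques(4)
        assignment = {v: 1 for v in left} | {v: 2 for v in right}
        assert balance_score(net, assignment) == (0.0, 0, 0)

    def test_moved_node_counts_by_hand(self):
        net, left, right = _two_cliques(4)
        assignment = {v: 1 for v in left} | {v: 2 for v in right}
        assignment["L0"] = 2  # L0 now sits with the right clique
        # within-class negatives: L0 vs the 4 right nodes; cross positives: L0 vs L1..L3
        r, n_c, p_c = balance_score(net, assignment, alpha_w=0.5)
        assert (n_c, p_c) == (4, 3)
        assert r == pytest.approx(0.5 * 4 + 0.5 * 3)

    def test_all_positive_single_class_scores_zero(self):
        net = _net({("a", "b"): +1, ("b", "c"): +1})
        assert balance_score(net, {v: 1 for v in "abc"})[0] == 0.0

    def test_unassigned_node_rejected(self):
        net = _net({("a", "b"): +1})
        with pytest.raises(ValueError, match="misses"):
            balance_score(net, {"a": 1})

    def test_relabel_invariance(self):
        net = random_signed_network(8, seed=3)
        rng = np.random.default_rng(0)
        a = {v: int(c) for v, c in zip(sorted(net.nodes), rng.integers(1, 4, 8))}
        b = {v: {1: 3, 2: 1, 3: 2}[c] for v, c in a.items()}
        assert balance_score(net, a)[0] == balance_score(net, b)[0]


class TestExhaustive:
    def test_frustrated_triangle(self):
        net = _net({("a", "b"): +1, ("b", "c"): +1, ("a", "c"): -1})
        r_star, optima, _nodes = exhaustive_optimum(net, 2, min_size=1, alpha_w=0.5)
        assert r_star == pytest.approx(0.5)

    def test_balanced_four_cycle(self):
        # alternating +,-,+,-: splitting {a,b} (+) / {c,d} (+) breaks nothing
        net = _net({("a", "b"): +1, ("b", "c"): -1, ("c", "d"): +1, ("d", "a"): -1})
        r_star, optima, _ = exhaustive_optimum(net, 2, min_size=1)
        assert r_star == 0.0
        assert _canonical(np.array([1, 1, 2, 2])) in optima

    def test_all_positive_one_class(self):
        net = _net({("a", "b"): +1, ("b", "c"): +1})
        r_star, optima, _ = exhaustive_optimum(net, 1, min_size=1)
        assert r_star == 0.0 and optima == ((1, 1, 1),)

    def test_guard_on_large_instances(self):
        net = random_signed_network(16, seed=0)
        with pytest.raises(ValueError, match="guard"):
            exhaustive_optimum(net, 2)


class TestOptimizer:
    def test_recovers_planted_cliques_uniquely(self):
        net, left, right = _two_cliques(5)
        tr = optimize_partition(net, 2, min_size=3, repetitions=20, seed=1)
        assert tr.best_r == 0.0
        assert tr.unique
        part = tr.best_partition(net)
        classes = {frozenset(v for v, c in part.assignment.items() if c == k)
                   for k in (1, 2)}
        assert classes == {frozenset(left), frozenset(right)}

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_matches_exhaustive_on_random_graphs(self, n_classes):
        hits = 0
        trials = 25
        for s in range(trials):
            net = random_signed_network(9, edge_prob=0.45, neg_frac=0.5, seed=100 + s)
            r_star, _, _ = exhaustive_optimum(net, n_classes, min_size=1)
            tr = optimize_partition(
                net, n_classes, min_size=1, repetitions=50, seed=s
            )
            assert tr.best_r >= r_star - 1e-9, "heuristic must never beat the oracle"
            hits += abs(tr.best_r - r_star) < 1e-9
        assert hits == trials

    def test_singleton_classes_remove_all_negatives(self):
        edges = {(f"v{i}", f"v{j}"): -1 for i in range(5) for j in range(i + 1, 5)}
        net = _net(edges)
        tr = optimize_partition(net, 5, min_size=1, repetitions=5, seed=0)
        assert tr.best_r == 0.0

    def test_min_size_respected(self):
        net = random_signed_network(10, seed=5)
        tr = optimize_partition(net, 3, min_size=3, repetitions=10, seed=2)
        for part in tr.partitions:
            assert min(np.bincount(part, minlength=4)[1:]) >= 3

    def test_seed_determinism(self):
        net = random_signed_network(12, seed=9)
        a = optimize_partition(net, 3, min_size=2, repetitions=30, seed=4)
        b = optimize_partition(net, 3, min_size=2, repetitions=30, seed=4)
        assert a == b

    def test_infeasible_configuration_rejected(self):
        net = random_signed_network(6, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            optimize_partition(net, 4, min_size=2, repetitions=1)


def _planted_communities_network(sizes, seed=0):
    """Positive edges within blocks, negative between, with light noise."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    members = [f"P{i:02d}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() > 0.7:
                continue
            same = labels[i] == labels[j]
            sign = +1 if same else -1
            if rng.random() < 0.05:
                sign = -sign
            edges[(members[i], members[j])] = sign
    return _net(edges)


class TestSweep:
    def test_planted_three_communities_selects_three(self):
        net = _planted_communities_network((7, 7, 7), seed=2)
        sweep = sweep_classes(net, range(2, 6), trials=3, repetitions=20,
                              min_size=2, base_seed=0)
        summary = sweep.summary().set_index("n_classes")
        assert summary["median_r"].idxmin() == 3
        assert select_model(sweep) == 3

    def test_degenerate_single_trial_single_repetition(self):
        net = random_signed_network(8, seed=1)
        sweep = sweep_classes(net, [2, 3], trials=1, repetitions=1,
                              min_size=1, base_seed=0)
        rec = sweep.records()
        assert len(rec) == 2
        assert set(rec["n_classes"]) == {2, 3}

    def test_tie_broken_by_fewer_outliers(self):
        nodes = ("a", "b", "c")

        def trial(k, r, n_solutions):
            # distinct placeholder partitions
            parts = tuple(tuple(1 if i < j + 1 else 2 for i in range(3))
                          for j in range(n_solutions))
            return TrialResult(n_classes=k, best_r=r, partitions=parts,
                               nodes=nodes, repetitions=1, alpha_w=0.5)

        sweep = SweepResult(trials={
            2: [trial(2, 1.0, 2)],   # outlier trial (2 solutions)
            3: [trial(3, 1.0, 1)],   # unique
        })
        assert select_model(sweep) == 3
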