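import itertools
import math

import numpy as np
import pytest

import triplenet as tn
from triplenet.graph_metrics import WeightedGraph


def _random_symmetric(k, rng, sparsity=1.0):
    z = rng.normal(0, 0.5, size=(k, k))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    if sparsity < 1.0:
        drop = rng.random((k, k)) > sparsity
        drop = np.triu(drop, 1)
        z[drop | drop.T] = 0.0
    return z


def brute_force_clustering(g: WeightedGraph) -> float:
    """Exhaustive Onnela clustering: geometric mean of normalized triangle
    weights averaged over neighbor pairs, zero for degree < 2 nodes."""
    w = {}
    for (i, j), weight in g.edges.items():
        w[(i, j)] = w[(j, i)] = weight
    w_max = max(g.edges.values())
    total = 0.0
    for node in range(g.n_nodes):
        nbrs = [m for m in range(g.n_nodes) if (node, m) in w]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            if (a, b) in w:
                acc += ((w[(node, a)] / w_max) * (w[(node, b)] / w_max) * (w[(a, b)] / w_max)) ** (1 / 3)
        total += 2 * acc / (k * (k - 1))
    return total / g.n_nodes


def brute_force_avg_path_length(g: WeightedGraph) -> float:
    """All-simple-paths enumeration of shortest lengths (length = 1/weight),
    averaged over reachable unordered pairs of the largest component."""
    adj = {n: {} for n in range(g.n_nodes)}
    for (i, j), weight in g.edges.items():
        adj[i][j] = adj[j][i] = 1.0 / weight

    def shortest(a, b):
        best = math.inf
        stack = [(a, 0.0, {a})]
        while stack:
            node, dist, seen = stack.pop()
            if node == b:
                best = min(best, dist)
                continue
            for nxt, length in adj[node].items():
                if nxt not in seen and dist + length < best:
                    stack.append((nxt, dist + length, seen | {nxt}))
        return best

    # largest connected component by flood fill
    unseen = set(range(g.n_nodes))
    components = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nxt in adj[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    frontier.append(nxt)
        unseen -= comp
        components.append(comp)
    comp = max(components, key=len)
    lengths = [shortest(a, b) for a, b in itertools.combinations(sorted(comp), 2)]
    return float(np.mean(lengths))


class TestThresholdByDensity:
    def test_seven_nodes_ceil_rule_gives_eight_edges(self, rng):
        z = _random_symmetric(7, rng)
        g = tn.threshold_by_density(z, 0.37)
        assert len(g.edges) == 8  # ceil(0.37 * 21)
        assert 0.35 < g.density < 0.40  # realized density 8/21 in the interval

    def test_keeps_strongest_absolute_edges(self, rng):
        z = _random_symmetric(5, rng)
        g = tn.threshold_by_density(z, 0.3)  # ceil(3) = 3 edges
        kept = sorted(g.edges, key=lambda p: -abs(z[p]))
        all_edges = sorted(
            ((i, j) for i in range(5) for j in range(i + 1, 5)),
            key=lambda p: -abs(z[p]),
        )
        assert set(g.edges) == set(all_edges[:3])
        assert all(g.edges[p] == abs(z[p]) for p in kept)

    def test_density_near_one_keeps_all_nonzero(self, rng):
        z = _random_symmetric(6, rng, sparsity=0.6)
        g = tn.threshold_by_density(z, 0.999)
        nonzero = {(i, j) for i in range(6) for j in range(i + 1, 6) if z[i, j] != 0}
        assert set(g.edges) == nonzero

    def test_exactly_eight_nonzero_entries(self, rng):
        z = np.zeros((7, 7))
        pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (0, 6), (1, 4)]
        for i, j in pairs:
            z[i, j] = z[j, i] = rng.uniform(0.1, 1.0)
        g = tn.threshold_by_density(z, 0.37)
        assert set(g.edges) == set(pairs)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            tn.threshold_by_density(np.zeros((4, 4)), 0.37)


class TestGlobalClustering:
    def test_equal_weight_triangle_is_one(self):
        g = WeightedGraph(3, {(0, 1): 0.5, (1, 2): 0.5, (0, 2): 0.5}, 1.0)
        assert tn.global_clustering(g) == pytest.approx(1.0)

    def test_star_graph_is_zero(self):
        g = WeightedGraph(4, {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0}, 0.5)
        assert tn.global_clustering(g) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_triangle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = _random_symmetric(7, rng, sparsity=0.7)
        g = tn.threshold_by_density(z, rng.uniform(0.2, 0.8))
        assert tn.global_clustering(g) == pytest.approx(
            brute_force_clustering(g), abs=1e-10
        )

    def test_invariant_to_uniform_weight_scaling(self, rng):
        z = _random_symmetric(6, rng)
        g1 = tn.threshold_by_density(z, 0.4)
        g2 = WeightedGraph(6, {e: 3.7 * w for e, w in g1.edges.items()}, g1.density)
        c1, c2 = tn.global_clustering(g1), tn.global_clustering(g2)
        assert 0.0 <= c1 <= 1.0
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestAvgPathLength:
    def test_unit_triangle(self):
        g = WeightedGraph(3, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0}, 1.0)
        assert tn.avg_path_length(g) == pytest.approx(1.0)

    def test_three_node_path(self):
        g = WeightedGraph(3, {(0, 1): 1.0, (1, 2): 1.0}, 2 / 3)
        assert tn.avg_path_length(g) == pytest.approx(4 / 3)

    def test_inverse_weight_length_convention(self):
        g = WeightedGraph(2, {(0, 1): 0.5}, 1.0)
        assert tn.avg_path_length(g) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_paths_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        z = _random_symmetric(7, rng, sparsity=0.6)
        g = tn.threshold_by_density(z, rng.uniform(0.25, 0.9))
        value, flag = tn.avg_path_length(g, return_flag=True)
        assert value == pytest.approx(brute_force_avg_path_length(g), abs=1e-10)

    def test_monotone_in_edge_weight(self, rng):
        z = _random_symmetric(6, rng)
        g = tn.threshold_by_density(z, 0.5)
        edge = next(iter(g.edges))
        heavier = dict(g.edges)
        heavier[edge] = heavier[edge] * 4.0  # shorter length on that edge
        g2 = WeightedGraph(6, heavier, g.density)
        assert tn.avg_path_length(g2) <= tn.avg_path_length(g) + 1e-12

    def test_disconnected_flag_and_largest_component(self):
        g = WeightedGraph(5, {(0, 1): 1.0, (1, 2): 1.0, (3, 4): 1.0}, 0.3)
        value, flag = tn.avg_path_length(g, return_flag=True)
        assert flag is True
        assert value == pytest.approx(4 / 3)  # path 0-1-2


class TestDescriptorCurve:
    def test_constant_over_admissible_density_interval_for_seven_nodes(self, rng):
        """Every density in (0.35, 8/21] keeps ceil(d * 21) = 8 edges while the
        realized density stays inside the admissible (0.35, 0.40) band, so the
        descriptor curve must be exactly flat on that interval."""
        z = _random_symmetric(7, rng)
        for name in ("clustering", "path_length"):
            curve = tn.descriptor_curve(z, (0.351, 0.36, 0.37, 0.38, 8 / 21), name)
            assert len(set(curve.values)) == 1
            assert curve.auc == pytest.approx(curve.values[0])

    def test_trapezoid_over_range(self):
        z = _random_symmetric(7, np.random.default_rng(3))
        curve = tn.descriptor_curve(z, (0.35, 0.39), "path_length")
        expected = np.trapezoid(curve.values, curve.thresholds) / 0.04
        assert curve.auc == pytest.approx(expected)

    def test_hand_trapezoid_values(self):
        # values {1, 3} at thresholds {0.35, 0.39} average to 2
        assert np.trapezoid([1.0, 3.0], [0.35, 0.39]) / 0.04 == pytest.approx(2.0)

    def test_single_threshold_auc_is_value(self, rng):
        z = _random_symmetric(7, rng)
        curve = tn.descriptor_curve(z, (0.37,), "clustering")
        assert curve.auc == curve.values[0]

    def test_nonincreasing_thresholds_rejected(self, rng):
        z = _random_symmetric(7, rng)
        with pytest.raises(ValueError):
            tn.descriptor_curve(z, (0.39, 0.35), "clustering")


class TestCompareGroupDescriptors:
    def test_identical_groups_not_significant(self, rng):
        curves, labels = [], []
        for i in range(10):
            z = _random_symmetric(7, np.random.default_rng(i % 5))  # mirrored groups
            for name in ("clustering", "path_length"):
                curves.append(tn.descriptor_curve(z, (0.35, 0.37, 0.39), name))
                labels.append("patient" if i < 5 else "control")
        table = tn.compare_group_descriptors(curves, labels)
        assert (table["p_raw"] > 0.9).all()

    def test_bh_adjustment_across_two_descriptors(self):
        # raw {0.028, 0.54} must adjust to {0.056, 0.54}
        import triplenet.edge_stats as es

        assert np.allclose(es.bh_fdr([0.028, 0.54]), [0.056, 0.54])

    def test_global_attenuation_raises_patient_path_length(self):
        """Patients with uniformly weakened couplings have longer weighted
        paths (1/weight lengths), matching the expected direction."""
        rng = np.random.default_rng(7)
        curves, labels = [], []
        for i in range(40):
            base = _random_symmetric(7, rng) + 0.6 * np.sign(_random_symmetric(7, rng))
            np.fill_diagonal(base, 0)
            group = "patient" if i < 20 else "control"
            z = base * (0.6 if group == "patient" else 1.0)
            curves.append(tn.descriptor_curve(z, (0.35, 0.37, 0.39), "path_length"))
            labels.append(group)
        table = tn.compare_group_descriptors(curves, labels)
        row = table.iloc[0]
        assert row["mean_patient"] > row["mean_control"]
        assert row["p_raw"] < 0.05

    def test_zero_variance_rejected(self):
        z = _random_symmetric(7, np.random.default_rng(0))
        curves = [tn.descriptor_curve(z, (0.37,), "clustering") for _ in range(6)]
        with pytest.raises(ValueError, match="zero variance"):
            tn.compare_group_descriptors(curves, ["patient"] * 3 + ["control"] * 3)
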