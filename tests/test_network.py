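"""Item network construction, walktrap communities, centralities, selection."""

import itertools

import numpy as np
import pytest

from scalenet.network import (
    CentralityTable,
    CommunityPartition,
    SelectionParams,
    build_network,
    centralities,
    select_items,
    walktrap_communities,
)


def _corr_from_edges(n, edges, value=0.8):
    corr = np.eye(n)
    for i, j in edges:
        corr[i, j] = corr[j, i] = value
    return corr


def _hand_modularity(nodes, edges, assignment):
    """Independent weighted-modularity formula: sum over communities of
    (w_in / W) - (strength_c / 2W)^2."""
    total = sum(w for _, _, w in edges)
    strength = {v: 0.0 for v in nodes}
    for a, b, w in edges:
        strength[a] += w
        strength[b] += w
    q = 0.0
    for c in set(assignment.values()):
        members = {v for v in nodes if assignment[v] == c}
        w_in = sum(w for a, b, w in edges if a in members and b in members)
        s_c = sum(strength[v] for v in members)
        q += w_in / total - (s_c / (2 * total)) ** 2
    return q


def _partitions(items):
    """All set partitions (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestBuildNetwork:
    def test_identity_all_isolated(self):
        net = build_network(np.eye(5), 0.7)
        assert net.edges == [] and len(net.isolated_items) == 5

    def test_triangle(self):
        net = build_network(_corr_from_edges(3, [(0, 1), (0, 2), (1, 2)]), 0.7)
        assert len(net.edges) == 3 and net.isolated_items == []
        cent = centralities(net)
        assert all(d == 2 for d in cent.degree.values())

    def test_strict_threshold(self):
        corr = _corr_from_edges(2, [(0, 1)], value=0.70)
        net = build_network(corr, 0.70)
        assert net.edges == []  # strictly greater than required

    def test_near_one_threshold_empty(self, rng):
        z = rng.normal(size=(50, 6))
        corr = np.corrcoef(z, rowvar=False)
        net = build_network(corr, 1.0 - 1e-9)
        assert net.edges == []

    def test_asymmetric_error(self):
        corr = np.eye(3)
        corr[0, 1] = 0.9
        with pytest.raises(ValueError):
            build_network(corr, 0.7)


class TestWalktrap:
    def test_two_disjoint_triangles(self):
        corr = _corr_from_edges(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])
        net = build_network(corr, 0.7)
        part = walktrap_communities(net)
        assert part.n_communities == 2
        assert part.assignment["IP1"] == part.assignment["IP2"] == part.assignment["IP3"]
        assert part.assignment["IP4"] == part.assignment["IP5"] == part.assignment["IP6"]

    def test_barbell_matches_exhaustive_modularity(self):
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
        net = build_network(_corr_from_edges(6, edges), 0.7)
        part = walktrap_communities(net)
        best_q = max(
            _hand_modularity(
                net.nodes,
                net.edges,
                {v: c for c, block in enumerate(p) for v in block},
            )
            for p in _partitions(net.nodes)
        )
        q = _hand_modularity(net.nodes, net.edges, part.assignment)
        assert part.n_communities == 2
        assert q == pytest.approx(best_q, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_within_005_of_exhaustive_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.45:
                    corr[i, j] = corr[j, i] = rng.uniform(0.71, 0.99)
        net = build_network(corr, 0.7)
        if not net.edges:
            return
        part = walktrap_communities(net)
        q = _hand_modularity(net.nodes, net.edges, part.assignment)
        best_q = max(
            _hand_modularity(
                net.nodes,
                net.edges,
                {v: c for c, block in enumerate(p) for v in block},
            )
            for p in _partitions(net.nodes)
        )
        assert q >= best_q - 0.05

    def test_modularity_beats_singletons(self, rng):
        corr = np.eye(8)
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.5:
                    corr[i, j] = corr[j, i] = rng.uniform(0.71, 0.95)
        net = build_network(corr, 0.7)
        if not net.edges:
            return
        part = walktrap_communities(net)
        q = _hand_modularity(net.nodes, net.edges, part.assignment)
        singles = {v: i for i, v in enumerate(net.nodes)}
        assert q >= _hand_modularity(net.nodes, net.edges, singles) - 1e-12

    def test_steps_validation(self):
        net = build_network(_corr_from_edges(3, [(0, 1)]), 0.7)
        with pytest.raises(ValueError):
            walktrap_communities(net, steps=0)


class TestCentralities:
    def test_star(self):
        corr = _corr_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        net = build_network(corr, 0.7)
        cent = centralities(net)
        assert cent.degree["IP1"] == 4
        assert all(cent.degree[f"IP{i}"] == 1 for i in range(2, 6))
        assert cent.eigenvector["IP1"] == pytest.approx(1.0)

    def test_cycle_symmetry(self):
        corr = _corr_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        net = build_network(corr, 0.7)
        cent = centralities(net)
        vals = list(cent.eigenvector.values())
        assert np.allclose(vals, vals[0])

    def test_matches_dense_eigendecomposition(self, rng):
        n = 7
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    corr[i, j] = corr[j, i] = rng.uniform(0.72, 0.95)
        net = build_network(corr, 0.7)
        if not net.nodes:
            return
        cent = centralities(net)
        # oracle on the largest component only
        idx = {v: i for i, v in enumerate(net.nodes)}
        w = np.zeros((len(net.nodes), len(net.nodes)))
        for a, b, weight in net.edges:
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = weight
        vals, vecs = np.linalg.eigh(w)
        lead = np.abs(vecs[:, -1])
        # compare within the component containing the leading eigenvector
        comp = lead > 1e-10
        lead = lead / lead.max()
        for v in net.nodes:
            if comp[idx[v]]:
                assert cent.eigenvector[v] == pytest.approx(lead[idx[v]], abs=1e-8)


class TestSelection:
    def test_union_dedup_single_item(self):
        corr = _corr_from_edges(3, [(0, 1), (0, 2)], value=0.9)
        net = build_network(corr, 0.7)
        part = walktrap_communities(net)
        cent = centralities(net)
        d = {"IP1": 2.0, "IP2": 0.5, "IP3": 0.4}
        sel = select_items(d, net, part, cent, SelectionParams(1, 1, 1, 1))
        assert sel.selected == ["IP1"]
        assert sel.provenance["IP1"] == {
            "community_representative",
            "central_hub",
            "top_discriminator",
        }

    def test_hand_enumerated_union(self):
        # two planted triangles (IP1-3, IP4-6), two isolated discriminators,
        # and IP12 as the global top item
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        corr = _corr_from_edges(12, edges, value=0.9)
        net = build_network(corr, 0.7)
        part = walktrap_communities(net)
        cent = centralities(net)
        d = {f"IP{i}": 0.1 * i for i in range(1, 12)}
        d["IP12"] = 5.0
        sel = select_items(
            d, net, part, cent, SelectionParams(min_community_size=2, k_isolated=2,
                                                k_hubs=0, k_top=1)
        )
        # community reps: IP3 (first triangle), IP6 (second); isolated top-2:
        # IP12, IP11; global top: IP12
        assert set(sel.selected) == {"IP3", "IP6", "IP11", "IP12"}
        assert sel.provenance["IP12"] == {"isolated_discriminator", "top_discriminator"}
        assert sel.communities_covered == 2

    def test_item_order_permutation_invariant(self, rng):
        n = 10
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    corr[i, j] = corr[j, i] = rng.uniform(0.72, 0.95)
        ids = [f"IP{i + 1}" for i in range(n)]
        d = {it: float(rng.uniform(0.5, 2.5)) for it in ids}
        perm = rng.permutation(n)
        corr_p = corr[np.ix_(perm, perm)]
        ids_p = [ids[i] for i in perm]

        def run(c, names):
            net = build_network(c, 0.7, names)
            part = walktrap_communities(net)
            cent = centralities(net)
            return select_items(d, net, part, cent, SelectionParams(2, 2, 2, 3))

        assert set(run(corr, ids).selected) == set(run(corr_p, ids_p).selected)

    def test_exports(self, tmp_path):
        corr = _corr_from_edges(4, [(0, 1), (1, 2)], value=0.85)
        net = build_network(corr, 0.7)
        net.to_edge_csv(tmp_path / "edges.csv")
        net.to_graphml(tmp_path / "net.graphml")
        import pandas as pd

        back = pd.read_csv(tmp_path / "edges.csv")
        assert len(back) == 2 and set(back.columns) == {"item_a", "item_b", "weight"}
        assert (tmp_path / "net.graphml").read_text().startswith("<?xml")

    def test_empty_error(self):
        net = build_network(np.eye(2), 0.7)
        part = CommunityPartition({}, {}, 0, 0.0)
        cent = CentralityTable({}, {})
        with pytest.raises(ValueError):
            select_items({}, type(net)([], [], 0.7, []), part, cent)
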