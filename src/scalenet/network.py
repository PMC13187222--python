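"""Thresholded item correlation network, communities, centralities, selection.

The item-reduction engine: items whose pairwise correlation exceeds a cutoff
(default 0.70, strict inequality) form a weighted graph; walktrap community
detection and degree/eigenvector centralities describe its structure; four
complementary strategies then pick a reduced item set balancing network
coverage with discriminative power:

1. community representation — per sufficiently large community, the member
   with the highest group discrimination (Cohen's d);
2. isolated discriminators — the best-discriminating items that fell below
   the correlation threshold;
3. central hubs — networked items with the highest eigenvector centrality;
4. top discriminators — the globally highest-d items.

The selected set is the deduplicated union, with per-item provenance tags.
Ties are broken by higher d first, then lexicographic item id, so the
selection is invariant to item order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd


@dataclass
class ItemNetwork:
    """Graph of items with supra-threshold correlations; the rest are isolated."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float
    isolated_items: list[str]

    @property
    def all_items(self) -> list[str]:
        return self.nodes + self.isolated_items

    def to_igraph(self) -> ig.Graph:
        index = {v: i for i, v in enumerate(self.nodes)}
        g = ig.Graph(
            n=len(self.nodes),
            edges=[(index[a], index[b]) for a, b, _ in self.edges],
        )
        g.vs["name"] = self.nodes
        g.es["weight"] = [w for _, _, w in self.edges]
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["item_a", "item_b", "weight"])

    def to_edge_csv(self, path) -> None:
        self.edge_frame().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        self.to_igraph().write_graphml(str(path))


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    sizes: dict[int, int]
    n_communities: int
    modularity: float

    def members(self, community: int) -> list[str]:
        return [v for v, c in self.assignment.items() if c == community]


@dataclass
class CentralityTable:
    degree: dict[str, int]
    eigenvector: dict[str, float]


@dataclass(frozen=True)
class SelectionParams:
    """Cardinalities of the four selection strategies.

    Defaults produce an 18-item-scale-sized selection on the default
    two-factor synthetic fixture; they are free configuration, not estimates
    of any published instrument's derivation.
    """

    min_community_size: int = 2
    k_isolated: int = 5
    k_hubs: int = 8
    k_top: int = 10


@dataclass
class SelectionResult:
    selected: list[str]
    provenance: dict[str, set[str]]
    communities_covered: int

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "provenance": {k: sorted(v) for k, v in self.provenance.items()},
            "communities_covered": self.communities_covered,
        }


def build_network(
    corr: np.ndarray | pd.DataFrame,
    threshold: float = 0.70,
    item_ids: list[str] | None = None,
) -> ItemNetwork:
    """Threshold a correlation matrix into an item graph (edge iff r > threshold)."""
    if isinstance(corr, pd.DataFrame):
        item_ids = list(corr.columns)
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if item_ids is None:
        item_ids = [f"IP{i + 1}" for i in range(p)]
    if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    edges = []
    connected = np.zeros(p, dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            if corr[i, j] > threshold:
                edges.append((item_ids[i], item_ids[j], float(corr[i, j])))
                connected[i] = connected[j] = True
    return ItemNetwork(
        nodes=[item_ids[i] for i in range(p) if connected[i]],
        edges=edges,
        threshold=float(threshold),
        isolated_items=[item_ids[i] for i in range(p) if not connected[i]],
    )


def walktrap_communities(net: ItemNetwork, steps: int = 4) -> CommunityPartition:
    """Walktrap communities of the weighted item graph.

    Short random walks define node distances; communities are merged
    agglomeratively (igraph's walktrap) and the cut with maximum weighted
    modularity along the merge path is returned. Because walks longer than
    the mixing time wash out structure on small dense graphs, every walk
    length from 1 to ``steps`` is tried and the best-modularity partition
    across those merge paths is kept; ``steps`` acts as the resolution
    ceiling.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not net.nodes:
        raise ValueError("network has no nodes")
    g = net.to_igraph()
    best_membership, best_q = None, -np.inf
    for t in range(1, steps + 1):
        dendro = g.community_walktrap(weights="weight", steps=t)
        for k in range(1, g.vcount() + 1):
            try:
                cl = dendro.as_clustering(k)
            except (ValueError, ig.InternalError):
                continue
            q = g.modularity(cl.membership, weights="weight")
            if q > best_q:
                best_q, best_membership = q, list(cl.membership)
    assignment = {name: int(c) for name, c in zip(g.vs["name"], best_membership)}
    sizes: dict[int, int] = {}
    for c in assignment.values():
        sizes[c] = sizes.get(c, 0) + 1
    return CommunityPartition(
        assignment=assignment,
        sizes=sizes,
        n_communities=len(sizes),
        modularity=float(best_q),
    )


def modularity(net: ItemNetwork, assignment: dict[str, int]) -> float:
    """Newman weighted modularity of a node partition of ``net``."""
    g = net.to_igraph()
    membership = [assignment[v] for v in g.vs["name"]]
    return float(g.modularity(membership, weights="weight"))


def centralities(net: ItemNetwork) -> CentralityTable:
    """Degree (edge count) and per-component max-normalized eigenvector centrality."""
    if not net.nodes:
        raise ValueError("network has no nodes")
    g = net.to_igraph()
    degree = {name: int(d) for name, d in zip(g.vs["name"], g.degree())}
    eigen: dict[str, float] = {}
    index = {v: i for i, v in enumerate(net.nodes)}
    w = np.zeros((len(net.nodes), len(net.nodes)))
    for a, b, weight in net.edges:
        w[index[a], index[b]] = weight
        w[index[b], index[a]] = weight
    for comp in g.connected_components():
        idx = np.array(comp)
        sub = w[np.ix_(idx, idx)]
        vals, vecs = np.linalg.eigh(sub)
        lead = np.abs(vecs[:, -1])
        lead = lead / lead.max() if lead.max() > 0 else lead
        for k, i in enumerate(idx):
            eigen[net.nodes[i]] = float(lead[k])
    return CentralityTable(degree=degree, eigenvector=eigen)


def _rank_by_d(items, d_values):
    """Sort descending by d, ties by lexicographic item id."""
    return sorted(items, key=lambda it: (-d_values[it], it))


def select_items(
    d_values: dict[str, float],
    net: ItemNetwork,
    part: CommunityPartition,
    cent: CentralityTable,
    params: SelectionParams = SelectionParams(),
) -> SelectionResult:
    """Four-strategy item selection; returns the deduplicated union with provenance."""
    all_items = net.all_items
    if not all_items:
        raise ValueError("empty item set")
    missing = [i for i in all_items if i not in d_values]
    if missing:
        raise ValueError(f"d_values missing items: {missing}")

    provenance: dict[str, set[str]] = {}

    def tag(item: str, label: str) -> None:
        provenance.setdefault(item, set()).add(label)

    covered = set()
    for community, size in part.sizes.items():
        if size < params.min_community_size:
            continue
        best = _rank_by_d(part.members(community), d_values)[0]
        tag(best, "community_representative")
        covered.add(community)

    for item in _rank_by_d(net.isolated_items, d_values)[: params.k_isolated]:
        tag(item, "isolated_discriminator")

    hubs = sorted(net.nodes, key=lambda it: (-cent.eigenvector[it], -d_values[it], it))
    for item in hubs[: params.k_hubs]:
        tag(item, "central_hub")

    for item in _rank_by_d(all_items, d_values)[: params.k_top]:
        tag(item, "top_discriminator")

    selected = sorted(provenance, key=lambda it: (-d_values[it], it))
    covered |= {part.assignment[i] for i in selected if i in part.assignment}
    return SelectionResult(
        selected=selected,
        provenance=provenance,
        communities_covered=len(covered),
    )
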