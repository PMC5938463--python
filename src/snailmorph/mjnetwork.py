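"""Median-joining network over clonal multilocus genotypes.

Bandelt-style construction: the epsilon-relaxed minimum spanning network
(MSN) is built over the observed genotypes; median (position-wise consensus)
vectors of connected triplets are added while they shorten the network;
obsolete median vectors (degree < 3) are removed.  Everything is
deterministic under a fixed input order, with lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .genetics import MISSING, AlignmentError, MultilocusGenotype, mlg_distance


@dataclass
class HaplotypeNetwork:
    """Genealogical network: observed genotypes plus inferred median vectors."""

    graph: nx.Graph
    epsilon: int = 0

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "observed"]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "median"]

    def edge_list(self):
        """Long-format edge table: node_a, node_b, weight, kinds."""
        import pandas as pd

        rows = [
            {
                "node_a": a, "node_b": b, "weight": d["weight"],
                "kind_a": self.graph.nodes[a]["kind"],
                "kind_b": self.graph.nodes[b]["kind"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "kind_a", "kind_b"])

    def write_edge_csv(self, path) -> None:
        self.edge_list().to_csv(path, index=False)

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, kind=d.get("kind", ""), count=int(d.get("count", 0)))
        for a, b, d in self.graph.edges(data=True):
            g.add_edge(a, b, weight=int(d["weight"]))
        nx.write_graphml(g, str(path))


def _msn_edges(sequences: dict[str, str], epsilon: int = 0) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum spanning network over a set of sequences.

    Distance classes are processed in increasing order.  At each class the
    component structure is frozen; every link of that length joining two
    frozen-distinct components is kept (so all alternative equally short
    connections survive), then the components are merged.  Construction
    stops ``epsilon`` distance classes after the network first becomes
    connected, which for epsilon = 0 is the classical minimum spanning
    network.  Candidate links are processed in lexicographic (weight,
    node-id) order, making the result deterministic.
    """
    names = list(sequences)
    if len(names) == 1:
        return []
    pairs = sorted(
        (mlg_distance(sequences[a], sequences[b]), a, b)
        for i, a in enumerate(names)
        for b in names[i + 1:]
    )

    def components(max_weight: int) -> dict[str, str]:
        parent = {n: n for n in names}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for w, a, b in pairs:
            if w <= max_weight:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
        return {n: find(n) for n in names}

    edges: list[tuple[str, str, int]] = []
    for w, a, b in pairs:
        # keep a link iff its endpoints are still disconnected using only
        # strictly shorter links, with epsilon classes of extra slack
        frozen = components(w - 1 - epsilon)
        if frozen[a] != frozen[b]:
            edges.append((a, b, w))
    return edges


def _median_sequence(a: str, b: str, c: str) -> str:
    """Position-wise majority consensus of three equal-length sequences."""
    out = []
    for x, y, z in zip(a, b, c):
        symbols = [s for s in (x, y, z) if s != MISSING]
        if not symbols:
            out.append(MISSING)
            continue
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def _mst_cost(sequences: dict[str, str]) -> int:
    g = nx.Graph()
    names = list(sequences)
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            g.add_edge(a, b, weight=mlg_distance(sequences[a], sequences[b]))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))


def median_joining_network(genotypes: list[MultilocusGenotype], epsilon: int = 0,
                           max_medians: int = 50) -> HaplotypeNetwork:
    """Reconstruct a median-joining network from multilocus genotypes.

    Every observed genotype is a node; inferred median vectors are added
    while they reduce the minimum-spanning cost of the node set, then median
    vectors of degree < 3 are pruned.  The graph is connected and edge
    weights are substitution counts (>= 1).
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    length = len(genotypes[0].encoded)
    for g in genotypes:
        if len(g.encoded) != length:
            raise AlignmentError("genotype encoded lengths differ")

    sequences = {g.genotype_id: g.encoded for g in genotypes}
    counts = {g.genotype_id: g.count for g in genotypes}
    observed = set(sequences)
    known = set(sequences.values())

    n_median = 0
    while n_median < max_medians:
        edges = _msn_edges(sequences, epsilon)
        adj: dict[str, set[str]] = {n: set() for n in sequences}
        for a, b, _ in edges:
            adj[a].add(b)
            adj[b].add(a)
        base_cost = _mst_cost(sequences)
        best = None  # (new_cost, median_string)
        for u in sorted(sequences):
            for v in sorted(adj[u]):
                for w in sorted(adj[u]):
                    if w <= v:
                        continue
                    m = _median_sequence(sequences[u], sequences[v], sequences[w])
                    if m in known:
                        continue
                    trial = dict(sequences)
                    trial[f"_m{n_median}"] = m
                    cost = _mst_cost(trial)
                    if cost < base_cost and (best is None or (cost, m) < best):
                        best = (cost, m)
        if best is None:
            break
        name = f"median_{n_median + 1}"
        sequences[name] = best[1]
        known.add(best[1])
        n_median += 1

    # prune obsolete medians (degree < 3), iterating because pruning can
    # lower the degree of other medians
    while True:
        edges = _msn_edges(sequences, epsilon)
        degree: dict[str, int] = {n: 0 for n in sequences}
        for a, b, _ in edges:
            degree[a] += 1
            degree[b] += 1
        obsolete = [n for n in sequences if n not in observed and degree[n] < 3]
        if not obsolete:
            break
        for n in obsolete:
            del sequences[n]

    graph = nx.Graph()
    for name, seq in sequences.items():
        graph.add_node(
            name,
            kind="observed" if name in observed else "median",
            sequence=seq,
            count=counts.get(name, 0),
        )
    for a, b, w in _msn_edges(sequences, epsilon):
        if w >= 1:
            graph.add_edge(a, b, weight=w)
    # a single observed genotype yields a single node and no edges
    return HaplotypeNetwork(graph=graph, epsilon=epsilon)
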