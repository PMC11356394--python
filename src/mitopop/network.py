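"""Weighted median-joining haplotype networks with regional projections.

A median-joining network generalizes the minimum spanning network (MSN) over
observed haplotypes by adding inferred intermediate ("median vector")
sequences — quasi-medians of connected triplets — whenever they reduce the
total weighted length of the network.  Position weights let hypervariable
columns count less, reducing spurious cross-links; the relaxation parameter
``epsilon`` admits alternative connections slightly longer than the minimal
ones.  Regional projections re-annotate the fixed global topology with one
region's sample counts so that geographic structure can be drawn on a shared
backbone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, MetadataError
from .haplotypes import HaplotypeTable, pairwise_distances


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str                # "observed" | "median"
    bases: str
    total_count: int
    region_counts: Mapping[str, int]


@dataclass(frozen=True)
class NetworkEdge:
    u: str
    v: str
    positions: tuple[int, ...]   # mutated DRS positions along the edge
    weight: float


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[NetworkEdge, ...]
    epsilon: float
    positions: tuple[int, ...]
    weights: Mapping[int, float] | None = None

    def node(self, node_id: str) -> NetworkNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind, bases=n.bases, total_count=n.total_count,
                       **{f"count_{r}": c for r, c in n.region_counts.items()})
        for e in self.edges:
            g.add_edge(e.u, e.v, weight=e.weight,
                       positions=",".join(map(str, e.positions)))
        return g

    @property
    def total_length(self) -> float:
        return sum(e.weight for e in self.edges)


def _column_weights(positions: Sequence[int],
                    weights: Mapping[int, float] | None) -> np.ndarray:
    w = np.ones(len(positions))
    if weights:
        for i, pos in enumerate(positions):
            if pos in weights:
                w[i] = weights[pos]
    return w


def _dist(a: str, b: str, w: np.ndarray) -> float:
    return pairwise_distances(a, b, w)


def _msn_edges(seqs: Sequence[str], w: np.ndarray, epsilon: float) -> list[tuple[int, int, float]]:
    """Epsilon-relaxed minimum spanning network over the given sequences.

    Edge (u, v) with weight d is kept iff u and v are not already connected
    using only edges of weight < d - epsilon (epsilon = 0 gives the classic
    MSN, a superset of every minimum spanning tree).
    """
    n = len(seqs)
    pairs = sorted(
        ((_dist(seqs[i], seqs[j], w), i, j)
         for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    kept: list[tuple[int, int, float]] = []
    for d, i, j in pairs:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((a, b) for a, b, dd in kept if dd < d - epsilon - 1e-12)
        if not nx.has_path(g, i, j):
            kept.append((i, j, d))
    return kept


def _quasi_medians(a: str, b: str, c: str) -> list[str]:
    """Quasi-medians of a triplet: majority per segregating column, all
    resolutions where the three states are pairwise distinct."""
    options: list[tuple[str, ...]] = []
    for x, y, z in zip(a, b, c):
        states = {x, y, z}
        if len(states) == 1:
            options.append((x,))
        elif len(states) == 2:
            # majority state
            maj = x if (x == y or x == z) else y
            options.append((maj,))
        else:
            options.append(tuple(sorted(states)))
    out = ["".join(combo) for combo in itertools.product(*options)]
    return sorted(set(out))


def build_mjn(table: HaplotypeTable,
              weights: Mapping[int, float] | None = None,
              epsilon: float = 0.0,
              max_median_rounds: int = 20) -> HaplotypeNetwork:
    """Construct the median-joining network of a haplotype table.

    Iterates: (1) epsilon-relaxed MSN over the current node set; (2) for every
    connected triplet, propose quasi-median sequences; (3) greedily add the
    median that most reduces total network length, repeating to a fixpoint;
    (4) remove obsolete medians (degree <= 2 and on no shortest observed-pair
    connection).  Deterministic under lexicographic tie-breaks.
    """
    seqs = list(table.sequences())
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("haplotypes of unequal length")
    names = list(table.names())
    kinds = ["observed"] * len(seqs)
    w = _column_weights(table.positions, weights)

    def total_len(sequences):
        return sum(d for _, _, d in _msn_edges(sequences, w, epsilon))

    median_counter = 0
    for _ in range(max_median_rounds):
        edges = _msn_edges(seqs, w, epsilon)
        current_total = sum(d for _, _, d in edges)
        adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        # candidate triplets: connected through at least one shared neighbour
        # or mutually linked
        triplets = set()
        for v, nb in adj.items():
            for i, j in itertools.combinations(sorted(nb), 2):
                triplets.add(tuple(sorted((v, i, j))))
        candidates = set()
        existing = set(seqs)
        for i, j, k in sorted(triplets):
            for med in _quasi_medians(seqs[i], seqs[j], seqs[k]):
                if med not in existing:
                    candidates.add(med)
        best = None
        for med in sorted(candidates):
            new_total = total_len(seqs + [med])
            if new_total < current_total - 1e-12:
                if best is None or new_total < best[1] - 1e-12 or (
                        abs(new_total - best[1]) <= 1e-12 and med < best[0]):
                    best = (med, new_total)
        if best is None:
            break
        median_counter += 1
        seqs.append(best[0])
        names.append(f"mv{median_counter:03d}")
        kinds.append("median")

    # final edge set, then prune obsolete medians
    while True:
        edges = _msn_edges(seqs, w, epsilon)
        g = nx.Graph()
        g.add_nodes_from(range(len(seqs)))
        for i, j, d in edges:
            g.add_edge(i, j, weight=d)
        observed_idx = [i for i, k in enumerate(kinds) if k == "observed"]
        removable = None
        for m in sorted(i for i, k in enumerate(kinds) if k == "median"):
            if g.degree(m) > 2:
                continue
            on_shortest = False
            sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            for a, b in itertools.combinations(observed_idx, 2):
                if abs(sp[a].get(m, np.inf) + sp[m].get(b, np.inf) - sp[a][b]) <= 1e-9:
                    on_shortest = True
                    break
            if not on_shortest:
                removable = m
                break
        if removable is None:
            break
        del seqs[removable], names[removable], kinds[removable]

    edges = _msn_edges(seqs, w, epsilon)
    count_of = {e.bases: (e.total_count, dict(e.group_counts)) for e in table.entries}
    nodes = []
    for name, seq, kind in zip(names, seqs, kinds):
        total, regions = count_of.get(seq, (0, {}))
        nodes.append(NetworkNode(name, kind, seq, total, regions))
    wcols = w
    out_edges = []
    for i, j, d in sorted(edges, key=lambda t: (min(names[t[0]], names[t[1]]),
                                                max(names[t[0]], names[t[1]]))):
        mutated = tuple(
            table.positions[c]
            for c in range(len(seqs[i]))
            if seqs[i][c] != seqs[j][c] and "N" not in (seqs[i][c], seqs[j][c])
        )
        u, v = sorted((names[i], names[j]))
        out_edges.append(NetworkEdge(u, v, mutated, d))
    return HaplotypeNetwork(tuple(nodes), tuple(out_edges), epsilon,
                            tuple(table.positions), weights)


def regional_projection(net: HaplotypeNetwork, region: str) -> pd.DataFrame:
    """Project one region onto the global backbone as a drawing-ready table.

    The topology is unchanged; each node's size becomes the region's count and
    nodes unobserved in the region are flagged backbone-only.
    """
    known = {r for n in net.nodes for r in n.region_counts}
    if region not in known:
        raise MetadataError(f"unknown region {region!r} (known: {sorted(known)})")
    rows = []
    for n in net.nodes:
        c = n.region_counts.get(region, 0)
        rows.append({
            "node": n.id, "kind": n.kind, "global_count": n.total_count,
            "region": region, "region_count": c,
            "backbone_only": c == 0,
        })
    return pd.DataFrame(rows)


def export_network(net: HaplotypeNetwork, path, fmt: str = "graphml") -> None:
    """Export the network as GraphML or node/edge TSV tables."""
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "edge-tsv":
        pd.DataFrame(
            [(e.u, e.v, e.weight, ",".join(map(str, e.positions))) for e in net.edges],
            columns=["u", "v", "weight", "positions"],
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "node-tsv":
        regions = sorted({r for n in net.nodes for r in n.region_counts})
        rows = []
        for n in net.nodes:
            row = {"node": n.id, "kind": n.kind, "total_count": n.total_count,
                   "bases": n.bases}
            for r in regions:
                row[f"count_{r}"] = n.region_counts.get(r, 0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown network export format {fmt!r}")


def import_graphml(path) -> nx.Graph:
    """Read back a GraphML export (round-trip helper)."""
    return nx.read_graphml(path)
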