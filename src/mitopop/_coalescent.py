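"""n-coalescent with an instantaneous population-size change, in mutational units.

Time ``x`` is measured in units of expected pairwise nucleotide differences:
any pair of lineages coalesces at rate ``1/theta`` per unit ``x`` when the
scaled population parameter is ``theta`` (per sequence), and mutations fall on
each lineage at rate ``1/2`` per unit ``x``, so a pair whose common ancestor
sits at time ``x`` carries Poisson(``x``) differences in expectation.

The sudden-expansion demography has the present parameter ``theta1`` for
``x < tau`` (looking backwards) and the ancestral ``theta0`` beyond;
``theta1 = inf`` (the default fitted model) means no coalescence more recent
than the expansion, which yields a star-like genealogy with mean pairwise
difference ``tau + theta0``.  Mutations follow the infinite-sites model: each
hit is a new column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class Genealogy:
    """A realized coalescent tree: leaves 0..n-1, merges recorded bottom-up."""

    n: int
    node_time: np.ndarray          # time of every node (leaves first)
    children: list[tuple[int, int] | None]  # None for leaves
    parent: np.ndarray             # -1 for the root

    @property
    def root(self) -> int:
        return len(self.children) - 1

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.node_time[p] - self.node_time[node])

    def leaves_below(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            ch = self.children[v]
            if ch is None:
                out.append(v)
            else:
                stack.extend(ch)
        return out


def simulate_genealogy(n: int, theta0: float, tau: float = 0.0,
                       theta1: float = math.inf,
                       rng: np.random.Generator | None = None) -> Genealogy:
    """Simulate one genealogy under the sudden-expansion demography."""
    if n < 2:
        raise ValueError("need at least 2 lineages")
    if theta0 < 0 or tau < 0 or theta1 <= 0:
        raise ValueError("parameters out of domain")
    rng = np.random.default_rng() if rng is None else rng

    n_nodes = 2 * n - 1
    node_time = np.zeros(n_nodes)
    children: list[tuple[int, int] | None] = [None] * n_nodes
    parent = np.full(n_nodes, -1, dtype=int)

    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        pairs = k * (k - 1) / 2.0
        if t < tau:
            # recent epoch at theta1; rely on memorylessness at the boundary
            if math.isinf(theta1):
                t = tau
                continue
            w = rng.exponential(theta1 / pairs)
            if t + w >= tau:
                t = tau
                continue
            t += w
        else:
            if theta0 == 0:
                # instantaneous coalescence of everything at tau
                w = 0.0
            else:
                w = rng.exponential(theta0 / pairs)
            t += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        node_time[next_node] = t
        children[next_node] = (a, b)
        parent[a] = parent[b] = next_node
        active[j] = active[-1]
        active.pop()
        active[i] = next_node
        next_node += 1
    return Genealogy(n=n, node_time=node_time, children=children, parent=parent)


def drop_mutations(gen: Genealogy, rng: np.random.Generator) -> np.ndarray:
    """Place infinite-sites mutations on branches (rate 1/2 per unit time).

    Returns a boolean incidence matrix of shape (n_mutations, n_leaves):
    entry [m, i] is True when leaf i carries the derived state of mutation m.
    """
    incidence_rows = []
    for node in range(len(gen.children) - 1):  # root excluded
        length = gen.branch_length(node)
        m = rng.poisson(length / 2.0)
        if m == 0:
            continue
        row = np.zeros(gen.n, dtype=bool)
        row[gen.leaves_below(node)] = True
        incidence_rows.extend([row] * m)
    if not incidence_rows:
        return np.zeros((0, gen.n), dtype=bool)
    return np.array(incidence_rows)


def pairwise_difference_matrix(incidence: np.ndarray) -> np.ndarray:
    """Pairwise difference counts between leaves from a mutation incidence matrix."""
    a = incidence.astype(np.float64)
    n = a.shape[1]
    if a.shape[0] == 0:
        return np.zeros((n, n))
    # differences = mutations where exactly one of the pair is derived
    cross = a.T @ (1.0 - a)
    return cross + cross.T


def simulate_sample_differences(n: int, theta0: float, tau: float = 0.0,
                                theta1: float = math.inf,
                                rng: np.random.Generator | None = None) -> np.ndarray:
    """One coalescent replicate, returned as the leaves' pairwise-difference matrix."""
    rng = np.random.default_rng() if rng is None else rng
    gen = simulate_genealogy(n, theta0, tau, theta1, rng)
    return pairwise_difference_matrix(drop_mutations(gen, rng))
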