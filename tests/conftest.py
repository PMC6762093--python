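"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
import pytest

from celltreeq import CellTree, GroupMap
from celltreeq.likelihood import transition_prob

# Worked evaluation example: 15 cell-types in three groups; one Epithelial
# intruder (EP1) sits inside the subtree holding all eight Fibroblasts, so
# the largest pure Fibroblast clades are (F1,F2) and (F7,F8) while a clade
# of nine leaves houses the whole group.
WORKED_EXAMPLE_NEWICK = (
    "(((F1,F2),(F3,(F4,(F5,(F6,(EP1,(F7,F8))))))),"
    "((Ep2,(Ep3,Ep4)),(B1,(B2,B3))));"
)

WORKED_EXAMPLE_GROUPS = {
    **{f"F{i}": "Fibroblast" for i in range(1, 9)},
    "EP1": "Epithelial",
    "Ep2": "Epithelial",
    "Ep3": "Epithelial",
    "Ep4": "Epithelial",
    "B1": "Blood",
    "B2": "Blood",
    "B3": "Blood",
}


@pytest.fixture()
def worked_example_tree() -> CellTree:
    return CellTree.from_newick(WORKED_EXAMPLE_NEWICK)


@pytest.fixture()
def worked_example_groups() -> GroupMap:
    return GroupMap(WORKED_EXAMPLE_GROUPS)


def brute_force_quartet_loglik(shape, matrix4, model) -> float:
    """Exhaustive-state oracle: sum over the 4 internal-state assignments.

    The quartet tree ab|cd has two internal nodes u (joining a, b) and v
    (joining c, d); per site the likelihood is the sum over the 2 x 2
    internal-state assignments of pi(u) * P(u->v) * the four pendant terms.
    Independent of the pruning implementation.
    """
    a, b, c, d = shape.labels
    Pa = transition_prob(model, shape.pendant[a])
    Pb = transition_prob(model, shape.pendant[b])
    Pc = transition_prob(model, shape.pendant[c])
    Pd = transition_prob(model, shape.pendant[d])
    Pint = transition_prob(model, shape.internal)
    rows = {l: matrix4.row(l) for l in (a, b, c, d)}
    total = 0.0
    for j in range(matrix4.n_cols):
        xa, xb = int(rows[a][j]), int(rows[b][j])
        xc, xd = int(rows[c][j]), int(rows[d][j])
        site = 0.0
        for u in (0, 1):
            for v in (0, 1):
                site += (
                    model.pi[u]
                    * Pint[u, v]
                    * Pa[u, xa]
                    * Pb[u, xb]
                    * Pc[v, xc]
                    * Pd[v, xd]
                )
        total += math.log(site)
    return total


def graph_distance_pairing(tree: CellTree, four_labels) -> tuple:
    """Topology oracle by unit-length path distances (four-point condition).

    Restricting an unrooted tree to four leaves gives ab|cd exactly when
    d(a,b) + d(c,d) is strictly the smallest pair-sum of the three
    pairings, with every edge counted as length one.  Uses breadth-first
    search on the adjacency only -- independent of the split machinery.
    """
    adj = tree.adjacency()

    def bfs(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        return dist

    a, b, c, d = four_labels
    da, dc = bfs(a), bfs(c)
    sums = {
        ((a, b), (c, d)): da[b] + dc[d],
        ((a, c), (b, d)): da[c] + bfs(b)[d],
        ((a, d), (b, c)): da[d] + bfs(b)[c],
    }
    ranked = sorted(sums.items(), key=lambda kv: kv[1])
    if ranked[0][1] == ranked[1][1]:
        return None  # unresolved (polytomy)
    return ranked[0][0]


def random_quartet_tree_newick(labels, rng, internal=None, low=0.05, high=0.6):
    """Newick for a quartet tree ab|cd with drawn pendant lengths."""
    a, b, c, d = labels
    ta, tb, tc, td = rng.uniform(low, high, size=4)
    t5 = float(rng.uniform(low, high)) if internal is None else internal
    return f"({a}:{ta:.6f},{b}:{tb:.6f},({c}:{tc:.6f},{d}:{td:.6f}):{t5:.6f});"
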