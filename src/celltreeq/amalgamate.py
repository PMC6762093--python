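"""Quartet amalgamation: combine C(n,4) quartets into one unrooted tree.

Finding the tree consistent with the maximum number of quartets is NP-hard,
so two solvers are provided:

* :func:`exact_amalgamate` -- enumerate all (2n-5)!! unrooted binary
  topologies by stepwise leaf addition and keep the best (guarded to
  n <= 10); this is the small-n oracle.
* :func:`qfm_amalgamate` -- recursive divide-and-conquer in the spirit of
  quartet-FM methods: each level bipartitions the current taxon set (plus a
  dummy taxon standing for the rest of the tree) to maximize
  satisfied-minus-violated quartets, refined by Fiduccia-Mattheyses-style
  local search (best single-taxon move, lock until pass end, keep the best
  prefix of the pass), with random restarts.

A quartet ``ab|cd`` is *satisfied* by a bipartition (A|B) when one pair
lies wholly in A and the other wholly in B, *violated* when both pairs
straddle the cut, and *deferred* otherwise; deferred quartets pass down the
recursion attached to whichever side holds at least three of their taxa,
with the dummy standing in for the far side.
"""

from __future__ import annotations

import itertools
import random
from collections import defaultdict
from typing import Sequence

from .quartets import Quartet, QuartetSet
from .trees import CellTree, adjacency_to_newick, rf_distance

__all__ = [
    "is_consistent",
    "consistency_count",
    "induced_quartets",
    "exact_amalgamate",
    "qfm_amalgamate",
    "rf_distance",
]


# ------------------------------------------------------------ consistency


def is_consistent(tree: CellTree, q: Quartet) -> bool:
    """True iff restricting the tree to q's four leaves yields q's topology.

    Equivalently: some edge of the tree separates q's two pairs.
    """
    leaf_set = set(tree.leaves)
    for label in q.labels:
        if label not in leaf_set:
            raise ValueError(f"label {label!r} is not a leaf of the tree")
    p1, p2 = set(q.pair1), set(q.pair2)
    for side in tree.clade_sides():
        if p1 <= side and not (p2 & side):
            return True
    return False


def consistency_count(tree: CellTree, qs: QuartetSet) -> int:
    """Number of quartets in ``qs`` consistent with the tree."""
    return sum(1 for q in qs if is_consistent(tree, q))


def induced_quartets(tree: CellTree) -> QuartetSet:
    """The C(n,4) quartets obtained by restricting a binary tree."""
    labels = tree.leaves
    index = {l: i for i, l in enumerate(labels)}
    masks = []
    for split in tree.splits():
        side = min(split, key=lambda s: sorted(s))  # either side works
        m = 0
        for l in side:
            m |= 1 << index[l]
        masks.append(m)
    out = []
    for subset in itertools.combinations(labels, 4):
        bits = [1 << index[l] for l in subset]
        found = None
        for m in masks:
            inside = [l for l, b in zip(subset, bits) if m & b]
            if len(inside) == 2:
                outside = [l for l in subset if l not in inside]
                found = Quartet(tuple(inside), tuple(outside))
                break
        if found is None:
            raise ValueError(
                f"tree is unresolved on subset {subset}; induced quartets "
                "require a binary tree"
            )
        out.append(found)
    return QuartetSet(out)


# --------------------------------------------------------- exact solver


def _quartet_index_masks(qs: QuartetSet, index: dict[str, int]):
    """Per quartet, the bitmasks of its two pairs."""
    pairs = []
    for q in qs:
        m1 = (1 << index[q.pair1[0]]) | (1 << index[q.pair1[1]])
        m2 = (1 << index[q.pair2[0]]) | (1 << index[q.pair2[1]])
        pairs.append((m1, m2))
    return pairs


def _split_consistency_table(qs: QuartetSet, n: int, index: dict[str, int]):
    """table[mask] = bitset of quartets separated by the split ``mask``."""
    pair_masks = _quartet_index_masks(qs, index)
    table = [0] * (1 << n)
    for mask in range(1, (1 << n) - 1):
        bits = 0
        for qi, (m1, m2) in enumerate(pair_masks):
            a, b = mask & m1, mask & m2
            if (a == m1 and b == 0) or (a == 0 and b == m2):
                bits |= 1 << qi
        table[mask] = bits
    return table


def _enumerate_edge_lists(n: int):
    """Yield edge lists of all unrooted binary trees on leaves 0..n-1.

    Internal nodes are numbered n, n+1, ...; generation is by stepwise leaf
    addition (each tree appears exactly once).
    """

    def insert(edges: list, k: int, next_internal: int):
        if k == n:
            yield edges
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (v, w), (k, w)]
            yield from insert(new_edges, k + 1, next_internal + 1)

    yield from insert([(0, n), (1, n), (2, n)], 3, n + 1)


def _edge_list_masks(edges: Sequence[tuple], n: int):
    """Leaf masks below each edge, rooted at leaf 0; (child, parent, mask)."""
    adj = defaultdict(list)
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    parent = {0: None}
    order = [0]
    stack = [0]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y != parent[x]:
                parent[y] = x
                order.append(y)
                stack.append(y)
    mask = {}
    for x in reversed(order):
        if x < n:
            mask[x] = 1 << x
        else:
            mask[x] = 0
            for y in adj[x]:
                if y != parent[x]:
                    mask[x] |= mask[y]
    return parent, mask


def _edges_to_adjacency(edges: Sequence[tuple], labels: Sequence[str]):
    n = len(labels)
    adj: dict = {}

    def node_id(x):
        return labels[x] if x < n else x

    for u, v in edges:
        adj.setdefault(node_id(u), []).append(node_id(v))
        adj.setdefault(node_id(v), []).append(node_id(u))
    return adj


def exact_amalgamate(qs: QuartetSet) -> tuple[CellTree, int]:
    """Exhaustive maximum-quartet-consistency tree search (4 <= n <= 10).

    Returns the optimal tree and its consistency count; ties are broken by
    the lexicographically smallest canonical newick.
    """
    labels = sorted(qs.taxa)
    n = len(labels)
    if not 4 <= n <= 10:
        raise ValueError(
            f"exact search supports 4..10 taxa (got {n}); use qfm_amalgamate"
        )
    index = {l: i for i, l in enumerate(labels)}
    table = _split_consistency_table(qs, n, index)
    full = (1 << n) - 1

    best_count = -1
    best_key: str | None = None
    best_edges = None
    for edges in _enumerate_edge_lists(n):
        parent, mask = _edge_list_masks(edges, n)
        bits = 0
        for x, p in parent.items():
            if p is not None and x >= n and p >= n:
                m = mask[x]
                bits |= table[m] | table[full ^ m]
        count = bits.bit_count()
        if count > best_count:
            best_count, best_edges, best_key = count, list(edges), None
        elif count == best_count:
            if best_key is None:
                best_key = CellTree.from_adjacency(
                    _edges_to_adjacency(best_edges, labels)
                ).canonical_newick()
            key = CellTree.from_adjacency(
                _edges_to_adjacency(edges, labels)
            ).canonical_newick()
            if key < best_key:
                best_edges, best_key = list(edges), key
    tree = CellTree.from_adjacency(_edges_to_adjacency(best_edges, labels))
    assert consistency_count(tree, qs) == best_count
    return tree, best_count


# ------------------------------------------------------- QFM-style solver

_DUMMY_PREFIX = "\x00dummy"


def _partition_score(assign: dict, quartets, indices=None) -> float:
    """Satisfied-minus-violated weight over (a subset of) the quartets."""
    total = 0.0
    items = quartets if indices is None else [quartets[i] for i in indices]
    for (a, b), (c, d), w in items:
        sa, sb, sc, sd = assign[a], assign[b], assign[c], assign[d]
        if sa == sb and sc == sd:
            if sa != sc:
                total += w
        elif sa != sb and sc != sd:
            total -= w
    return total


def _fm_refine(assign: dict, taxa: Sequence, quartets, incident) -> float:
    """Fiduccia-Mattheyses passes; mutates ``assign``; returns final score."""
    score = _partition_score(assign, quartets)
    sizes = [0, 0]
    for t in taxa:
        sizes[assign[t]] += 1
    while True:
        locked: set = set()
        seq: list = []
        cum = best_cum = 0.0
        best_k = 0
        while True:
            best_gain, best_t = None, None
            for t in taxa:  # taxa sorted: deterministic tie-break
                # each side must keep >= 2 taxa: guarantees the recursion's
                # side-plus-dummy subproblems strictly shrink
                if t in locked or sizes[assign[t]] <= 2:
                    continue
                before = _partition_score(assign, quartets, incident[t])
                assign[t] ^= 1
                after = _partition_score(assign, quartets, incident[t])
                assign[t] ^= 1
                gain = after - before
                if best_gain is None or gain > best_gain:
                    best_gain, best_t = gain, t
            if best_t is None:
                break
            sizes[assign[best_t]] -= 1
            assign[best_t] ^= 1
            sizes[assign[best_t]] += 1
            locked.add(best_t)
            seq.append(best_t)
            cum += best_gain
            if cum > best_cum + 1e-12:
                best_cum, best_k = cum, len(seq)
        for t in seq[best_k:]:  # keep only the best prefix of the pass
            sizes[assign[t]] -= 1
            assign[t] ^= 1
            sizes[assign[t]] += 1
        if best_cum <= 1e-12:
            return score
        score += best_cum


def _best_partition(taxa: Sequence, quartets, rng: random.Random, restarts: int):
    incident = defaultdict(list)
    for i, ((a, b), (c, d), _) in enumerate(quartets):
        for t in (a, b, c, d):
            incident[t].append(i)
    taxa = sorted(taxa)
    best_score, best_assign = None, None
    for _ in range(max(1, restarts)):
        perm = list(taxa)
        rng.shuffle(perm)
        half = len(perm) // 2
        assign = {t: (0 if i < half else 1) for i, t in enumerate(perm)}
        score = _fm_refine(assign, taxa, quartets, incident)
        if best_score is None or score > best_score + 1e-12:
            best_score, best_assign = score, dict(assign)
    side_a = [t for t in taxa if best_assign[t] == 0]
    side_b = [t for t in taxa if best_assign[t] == 1]
    return side_a, side_b


def _project_quartets(quartets, side: set, dummy: str):
    """Quartets relevant to one side; far-side taxa replaced by the dummy."""
    out = []
    for (a, b), (c, d), w in quartets:
        inside = sum(t in side for t in (a, b, c, d))
        if inside == 4:
            out.append(((a, b), (c, d), w))
        elif inside == 3:
            sub = lambda t: t if t in side else dummy
            out.append(((sub(a), sub(b)), (sub(c), sub(d)), w))
    return out


def _join_subtrees(adj_a: dict, dummy_a: str, adj_b: dict, dummy_b: str) -> dict:
    adj = {**adj_a, **adj_b}
    va = adj.pop(dummy_a)[0]
    adj[va] = [u for u in adj[va] if u != dummy_a]
    vb = adj.pop(dummy_b)[0]
    adj[vb] = [u for u in adj[vb] if u != dummy_b]
    adj[va].append(vb)
    adj[vb].append(va)
    return adj


def _qfm_solve(
    taxa: Sequence,
    quartets,
    rng: random.Random,
    restarts: int,
    dummy_counter,
    node_counter,
) -> dict:
    taxa = sorted(taxa)
    if len(taxa) == 2:
        a, b = taxa
        return {a: [b], b: [a]}
    if len(taxa) == 3:
        hub = next(node_counter)
        adj = {hub: list(taxa)}
        for t in taxa:
            adj[t] = [hub]
        return adj
    side_a, side_b = _best_partition(taxa, quartets, rng, restarts)
    dummy_a = f"{_DUMMY_PREFIX}{next(dummy_counter)}"
    dummy_b = f"{_DUMMY_PREFIX}{next(dummy_counter)}"
    qa = _project_quartets(quartets, set(side_a), dummy_a)
    qb = _project_quartets(quartets, set(side_b), dummy_b)
    adj_a = _qfm_solve(
        [*side_a, dummy_a], qa, rng, restarts, dummy_counter, node_counter
    )
    adj_b = _qfm_solve(
        [*side_b, dummy_b], qb, rng, restarts, dummy_counter, node_counter
    )
    return _join_subtrees(adj_a, dummy_a, adj_b, dummy_b)


def qfm_amalgamate(
    qs: QuartetSet,
    restarts: int = 20,
    seed: int = 42,
    weighted: bool = False,
) -> CellTree:
    """Divide-and-conquer quartet amalgamation (binary output tree).

    With ``weighted=True`` the partition objective sums quartet weights
    (satisfied minus violated) instead of counts; with all weights equal to
    one the two objectives coincide.  Deterministic given ``seed``.
    """
    taxa = sorted(qs.taxa)
    if len(taxa) < 4:
        raise ValueError(f"need at least 4 taxa, got {len(taxa)}")
    for t in taxa:
        if t.startswith(_DUMMY_PREFIX):
            raise ValueError(f"taxon label {t!r} collides with internal names")
    quartets = [
        (
            q.pair1,
            q.pair2,
            (q.weight if (weighted and q.weight is not None) else 1.0),
        )
        for q in qs
    ]
    rng = random.Random(int(seed))
    adj = _qfm_solve(
        taxa, quartets, rng, max(1, int(restarts)),
        itertools.count(), itertools.count(),
    )
    return CellTree.from_newick(adjacency_to_newick(adj))
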