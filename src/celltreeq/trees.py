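"""Unrooted leaf-labeled trees (newick-serializable).

`CellTree` wraps a dendropy tree but exposes only unrooted semantics: the
split set, the leaf-set sides of every edge, Robinson-Foulds distance and a
canonical newick rendering used for deterministic tie-breaking.  Rooted
renderings are display-only; all metrics depend on the split set alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy

__all__ = ["CellTree", "rf_distance"]


class CellTree:
    """An unrooted tree with uniquely labeled leaves."""

    def __init__(self, tree: dendropy.Tree) -> None:
        if len(tree.leaf_nodes()) >= 3:
            tree.deroot()
        tree.is_rooted = False
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise ValueError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        self._tree = tree

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_newick(cls, text: str) -> "CellTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def read(cls, path) -> "CellTree":
        """Read the first newick tree in a file; '#' comment lines skipped."""
        lines = [
            ln
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls.from_newick("\n".join(lines))

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        return s

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # ------------------------------------------------------------ topology

    @property
    def leaves(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self._tree.leaf_node_iter())

    def __len__(self) -> int:
        return len(self._tree.leaf_nodes())

    def _below_sets(self) -> dict:
        below = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
            else:
                below[node] = frozenset().union(
                    *(below[c] for c in node.child_nodes())
                )
        return below

    def clade_sides(self) -> list[frozenset]:
        """Both leaf-set sides of every edge (2 x #edges entries).

        On an unrooted tree a "clade"/"subtree" is one side of an edge, so
        trivial single-leaf sides are included and every side's complement
        is present as well.
        """
        all_leaves = frozenset(self.leaves)
        below = self._below_sets()
        sides: list[frozenset] = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = below[node]
            sides.append(s)
            sides.append(all_leaves - s)
        return sides

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions as frozensets of the two sides."""
        all_leaves = frozenset(self.leaves)
        n = len(all_leaves)
        out: set[frozenset] = set()
        below = self._below_sets()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = below[node]
            if 2 <= len(s) <= n - 2:
                out.add(frozenset((s, all_leaves - s)))
        return out

    def is_binary(self) -> bool:
        for node in self._tree.preorder_node_iter():
            deg = len(node.child_nodes()) + (0 if node.parent_node is None else 1)
            if node.is_leaf():
                continue
            expected = 3
            if deg != expected:
                return False
        return True

    def branch_lengths(self) -> dict[frozenset, float]:
        """Edge lengths keyed by the (one-side) leaf set below the edge."""
        below = self._below_sets()
        out = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out[below[node]] = node.edge.length
        return out

    # --------------------------------------------------------- adjacency

    def adjacency(self) -> dict:
        """Adjacency over node ids: leaves are their labels, internals ints."""
        ids: dict = {}
        counter = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                ids[node] = node.taxon.label
            else:
                ids[node] = ("int", counter)
                counter += 1
        adj: dict = {v: [] for v in ids.values()}
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                adj[ids[node]].append(ids[child])
                adj[ids[child]].append(ids[node])
        return adj

    @classmethod
    def from_adjacency(cls, adj: dict, lengths: dict | None = None) -> "CellTree":
        """Build from an adjacency dict (leaf nodes are string labels)."""
        return cls.from_newick(adjacency_to_newick(adj, lengths))

    def canonical_newick(self) -> str:
        """Label-deterministic newick: identical trees render identically."""
        return canonical_newick_from_adjacency(self.adjacency())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"CellTree({len(self)} leaves)"


def rf_distance(t1: CellTree, t2: CellTree) -> int:
    """Robinson-Foulds distance: |symmetric difference of nontrivial splits|."""
    if set(t1.leaves) != set(t2.leaves):
        raise ValueError("trees must share the same leaf set")
    return len(t1.splits() ^ t2.splits())


def _is_leaf(adj: dict, node) -> bool:
    return len(adj[node]) <= 1


def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def adjacency_to_newick(adj: dict, lengths: dict | None = None) -> str:
    """Render an unrooted adjacency as newick, children ordered by min label.

    ``lengths`` optionally maps frozenset({u, v}) edge keys to branch
    lengths.
    """
    leaves = sorted(n for n in adj if _is_leaf(adj, n))
    if not leaves:
        raise ValueError("tree has no leaves")
    if len(adj) == 1:
        return _quote(leaves[0]) + ";"
    start = leaves[0]
    root = adj[start][0]

    def edge_len(u, v) -> str:
        if lengths is None:
            return ""
        t = lengths.get(frozenset((u, v)))
        return "" if t is None else f":{t:.10g}"

    def rec(node, parent):
        kids = [y for y in adj[node] if y != parent]
        if not kids:
            return _quote(str(node)), str(node)
        subs = []
        for y in kids:
            s, key = rec(y, node)
            subs.append((s + edge_len(node, y), key))
        subs.sort(key=lambda t: t[1])
        return "(" + ",".join(s for s, _ in subs) + ")", subs[0][1]

    if _is_leaf(adj, root):  # two-leaf tree
        other = [n for n in adj if n != root][0]
        return f"({_quote(str(root))},{_quote(str(other))});"
    s, _ = rec(root, None)
    return s + ";"


def canonical_newick_from_adjacency(adj: dict) -> str:
    return adjacency_to_newick(adj, None)
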