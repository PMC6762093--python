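"""Synthetic data: model trees, simulated binary characters, peak libraries.

Real analyses start from ChIP-Seq peak calls; this module generates
stand-ins so every stage of the pipeline is testable without downloads.
The premise matches the biology the encoding assumes: histone marks are
gained and lost independently across regions, so characters are i.i.d.
columns evolved along a known cell-type tree under the two-state model.
``matrix_to_peaks`` then inverts the overlap representation, emitting one
BED-style anchor interval per matrix column on a synthetic chromosome, so
that re-encoding the peak libraries reproduces the planted matrix (up to
all-zero columns, which the overlap representation cannot express).

Default conditions: 10 taxa, 5000 sites, branch lengths uniform on
[0.05, 0.6] with internal branches floored at 0.3 -- a regime where the
pipeline is expected to recover the generating tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import GroupMap
from .likelihood import SYMMETRIC_MODEL, TwoStateModel, transition_prob
from .representation import BinaryMatrix, PeakInterval, PeakLibrary
from .trees import CellTree, adjacency_to_newick

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "random_tree",
    "simulate_matrix",
    "matrix_to_peaks",
    "paint_groups",
    "SYNTHETIC_CHROM",
]

#: name of the synthetic chromosome used by :func:`matrix_to_peaks`
SYNTHETIC_CHROM = "chrS"


@dataclass
class SimulationConfig:
    """Study conditions for synthetic cell-type data."""

    n_taxa: int = 10
    n_sites: int = 5000
    blen_low: float = 0.05
    blen_high: float = 0.6
    internal_floor: float = 0.3
    model: TwoStateModel = field(default_factory=TwoStateModel)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0 < self.blen_low <= self.blen_high):
            raise ValueError("branch-length range must be positive and ordered")

    def label(self, i: int) -> str:
        width = len(str(self.n_taxa))
        return f"T{i + 1:0{width}d}"


def random_tree(config: SimulationConfig, rng=None) -> CellTree:
    """Uniform random binary topology by sequential random leaf attachment.

    Pendant branch lengths are uniform on [blen_low, blen_high]; internal
    branch lengths are additionally floored at ``internal_floor``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_taxa
    labels = [config.label(i) for i in range(n)]
    adj: dict = {labels[0]: [0], labels[1]: [0], labels[2]: [0],
                 0: [labels[0], labels[1], labels[2]]}
    edges = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    next_internal = 1
    for k in range(3, n):
        u, v = edges[int(rng.integers(len(edges)))]
        w = next_internal
        next_internal += 1
        adj[u] = [w if x == v else x for x in adj[u]]
        adj[v] = [w if x == u else x for x in adj[v]]
        adj[w] = [u, v, labels[k]]
        adj[labels[k]] = [w]
        edges.remove((u, v))
        edges.extend([(u, w), (v, w), (labels[k], w)])
    lengths = {}
    for u, v in edges:
        t = float(rng.uniform(config.blen_low, config.blen_high))
        if isinstance(u, int) and isinstance(v, int):  # internal edge
            t = max(t, config.internal_floor)
        lengths[frozenset((u, v))] = t
    return CellTree.from_newick(adjacency_to_newick(adj, lengths))


def simulate_matrix(tree: CellTree, config: SimulationConfig, rng=None) -> BinaryMatrix:
    """Evolve i.i.d. binary characters along the tree.

    Root states are drawn from the model's stationary frequencies and
    propagated along each branch with the two-state transition
    probabilities; rows are ordered by sorted leaf label.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    model = config.model
    n_sites = config.n_sites
    dtree = tree._tree  # simulation walks the underlying rooted representation
    states: dict = {}
    root = dtree.seed_node
    states[root] = (rng.random(n_sites) < model.pi1).astype(np.int8)
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        P = transition_prob(model, float(t))
        parent_states = states[node.parent_node]
        # P[parent, 1] = probability the child is in state 1
        p1 = P[parent_states, 1]
        states[node] = (rng.random(n_sites) < p1).astype(np.int8)
    leaf_rows = {
        lf.taxon.label: states[lf] for lf in dtree.leaf_node_iter()
    }
    labels = sorted(leaf_rows)
    return BinaryMatrix(labels, np.vstack([leaf_rows[l] for l in labels]))


def matrix_to_peaks(
    matrix: BinaryMatrix, region_length: int = 500, gap: int = 100
) -> list[PeakLibrary]:
    """Inverse of the overlap representation, on a synthetic chromosome.

    Column j maps to the anchor interval
    ``[j * (region_length + gap), j * (region_length + gap) + region_length)``
    and library i receives that peak iff cell (i, j) = 1.  Re-encoding the
    libraries with ``overlap_matrix`` reproduces the input matrix up to
    all-zero columns (which are logged and dropped).
    """
    if region_length < 1 or gap < 1:
        raise ValueError("region_length and gap must be >= 1")
    zero_cols = np.flatnonzero(matrix.data.sum(axis=0) == 0)
    if zero_cols.size:
        logger.warning(
            "matrix_to_peaks: %d all-zero column(s) cannot be represented as "
            "peaks and will be absent from the recovered matrix",
            zero_cols.size,
        )
    stride = region_length + gap
    libraries = []
    for i, label in enumerate(matrix.row_labels):
        intervals = [
            PeakInterval(SYNTHETIC_CHROM, j * stride, j * stride + region_length)
            for j in np.flatnonzero(matrix.data[i])
        ]
        libraries.append(PeakLibrary(label, intervals))
    return libraries


def paint_groups(tree: CellTree, n_groups: int) -> GroupMap:
    """Assign group labels to contiguous blocks of leaves in tree order.

    Leaves are taken in the order of a deterministic traversal so each
    group is a contiguous patch of the tree (exact clades when block
    boundaries line up with edges); groups are named G1, G2, ...
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    adj = tree.adjacency()
    leaves = sorted(n for n in adj if len(adj[n]) <= 1)
    order: list[str] = []
    seen = set()
    stack = [leaves[0]]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        if isinstance(node, str):
            order.append(node)
        # ascending push order pops leaf neighbors before internal ones,
        # keeping each subtree a contiguous run of the leaf order
        for nb in sorted(adj[node], key=str):
            if nb not in seen:
                stack.append(nb)
    n = len(order)
    n_groups = min(n_groups, n)
    block = -(-n // n_groups)  # ceil division
    assignment = {
        leaf: f"G{i // block + 1}" for i, leaf in enumerate(order)
    }
    return GroupMap(assignment)
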