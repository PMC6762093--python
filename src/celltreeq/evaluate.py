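"""Cell-type-tree evaluation: groupings score and the alpha-ratio profile.

Cell-types carry group labels (Fibroblast, Epithelial, Blood, ...).  Two
metrics summarize how well a tree clusters each group.  Because the trees
are unrooted, a "subtree" (clade) is one side of an edge, and both sides of
every edge are considered.

* **Groupings score (m1, m2)** -- the sizes of the two largest disjoint
  maximal clades containing *only* members of the group.  Sensitive to a
  single alien intrusion.
* **alpha profile** -- for increasing member counts m, the size s of the
  smallest clade housing at least m group members; alpha = m / s.  An
  intruder then costs little: alpha stays near 1 when the group is nearly
  contiguous.  The profile starts at the largest pure clade and ends at the
  full group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trees import CellTree

__all__ = [
    "GroupMap",
    "GroupingScore",
    "AlphaProfile",
    "clade_sides",
    "groupings_score",
    "alpha_profile",
    "evaluation_report",
    "read_group_map",
    "write_group_map",
]


class GroupMap:
    """Assignment of leaf labels to group names."""

    def __init__(self, assignment: Mapping[str, str]) -> None:
        self._assignment = {str(k): str(v) for k, v in assignment.items()}

    def group_of(self, leaf: str) -> str:
        return self._assignment[leaf]

    def members(self, group: str) -> set[str]:
        return {l for l, g in self._assignment.items() if g == group}

    @property
    def groups(self) -> list[str]:
        return sorted(set(self._assignment.values()))

    @property
    def leaves(self) -> list[str]:
        return sorted(self._assignment)

    def __contains__(self, leaf: str) -> bool:
        return leaf in self._assignment

    def __len__(self) -> int:
        return len(self._assignment)

    def check_covers(self, tree: CellTree) -> None:
        missing = [l for l in tree.leaves if l not in self]
        if missing:
            raise ValueError(f"leaves with no group assignment: {missing}")


@dataclass(frozen=True)
class GroupingScore:
    """Sizes of the two largest disjoint maximal pure clades of a group."""

    m1: int
    m2: int

    def __post_init__(self) -> None:
        if not (self.m1 >= self.m2 >= 0):
            raise ValueError(f"require m1 >= m2 >= 0, got ({self.m1}, {self.m2})")

    def as_tuple(self) -> tuple[int, int]:
        return (self.m1, self.m2)


@dataclass(frozen=True)
class AlphaProfile:
    """Ordered (m, s) entries; alpha(m) = m / s."""

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_s = 0
        for m, s in self.entries:
            if not (s >= m >= 1):
                raise ValueError(f"require s >= m >= 1, got ({m}, {s})")
            if s < prev_s:
                raise ValueError("clade sizes must be non-decreasing in m")
            prev_s = s

    @property
    def alphas(self) -> list[float]:
        return [m / s for m, s in self.entries]

    def to_string(self) -> str:
        return ", ".join(f"{m}/{s}" for m, s in self.entries)


def clade_sides(tree: CellTree) -> list[frozenset]:
    """Both leaf-set sides of every edge of the tree."""
    return tree.clade_sides()


def _group_members(tree: CellTree, groups: GroupMap, g: str) -> set[str]:
    if g not in groups.groups:
        raise ValueError(f"unknown group {g!r}")
    members = groups.members(g) & set(tree.leaves)
    if not members:
        raise ValueError(f"group {g!r} has no members among the tree's leaves")
    return members


def groupings_score(tree: CellTree, groups: GroupMap, g: str) -> GroupingScore:
    """The (m1, m2) pure-clade score for group ``g``.

    Among edge sides whose leaves all belong to ``g``, only maximal ones
    (not contained in a larger pure side) count; m1 and m2 are the sizes of
    the two largest, with m2 = 0 when only one maximal pure side exists.
    If every leaf belongs to ``g`` (degenerate), the score is (n, 0).
    """
    members = _group_members(tree, groups, g)
    n = len(tree.leaves)
    if len(members) == n:
        return GroupingScore(n, 0)
    pure = [s for s in tree.clade_sides() if s <= members]
    maximal = [s for s in pure if not any(s < t for t in pure)]
    # maximal pure sides of a tree are pairwise disjoint, so the two largest
    # are automatically disjoint
    sizes = sorted((len(s) for s in set(maximal)), reverse=True)
    m1 = sizes[0] if sizes else 0
    m2 = sizes[1] if len(sizes) > 1 else 0
    return GroupingScore(m1, m2)


def alpha_profile(
    tree: CellTree,
    groups: GroupMap,
    g: str,
    ms: Sequence[int] | None = None,
) -> AlphaProfile:
    """Minimal clade sizes housing increasing numbers of group members.

    ``ms`` defaults to every count from the largest pure clade size up to
    the group size.  For each m, s is the minimum over all edge sides of
    the side size subject to containing at least m members of ``g``.
    """
    members = _group_members(tree, groups, g)
    size = len(members)
    if len(members) == len(tree.leaves):  # degenerate: one single group
        return AlphaProfile(((size, size),))
    m1 = groupings_score(tree, groups, g).m1
    if ms is None:
        ms = range(max(1, m1), size + 1)
    ms = sorted(set(int(m) for m in ms))
    for m in ms:
        if m < 1 or m > size:
            raise ValueError(f"member count {m} outside 1..{size}")
    sides = tree.clade_sides()
    entries = []
    for m in ms:
        s = min(len(side) for side in sides if len(side & members) >= m)
        entries.append((m, s))
    return AlphaProfile(tuple(entries))


def evaluation_report(
    tree: CellTree,
    groups: GroupMap,
    group_names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-group summary table: size, (m1, m2) and the alpha profile."""
    groups.check_covers(tree)
    leaves = set(tree.leaves)
    if group_names is None:
        group_names = [
            g for g in groups.groups if groups.members(g) & leaves
        ]
    rows = []
    for g in group_names:
        members = _group_members(tree, groups, g)
        score = groupings_score(tree, groups, g)
        profile = alpha_profile(tree, groups, g)
        rows.append(
            {
                "group": g,
                "size": len(members),
                "m1": score.m1,
                "m2": score.m2,
                "alpha_profile": profile.to_string(),
            }
        )
    return pd.DataFrame(rows, columns=["group", "size", "m1", "m2", "alpha_profile"])


def read_group_map(path) -> GroupMap:
    """Two-column TSV (leaf label, group name); '#' comments skipped."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path} line {lineno}: expected two columns (leaf, group)"
                )
            assignment[parts[0]] = parts[1]
    if not assignment:
        raise ValueError(f"{path}: empty group map")
    return GroupMap(assignment)


def write_group_map(groups: GroupMap, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for leaf in groups.leaves:
            fh.write(f"{leaf}\t{groups.group_of(leaf)}\n")
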