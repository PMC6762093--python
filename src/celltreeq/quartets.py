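"""Quartet enumeration and the IQA / MLQA inference schemes.

A quartet ``q = ab|cd`` is an unrooted four-leaf tree whose internal edge
separates {a, b} from {c, d}.  For a binary matrix on n cell-types both
schemes produce one quartet per 4-subset of rows (C(n, 4) in total):

* **MLQA** (most-likely quartet amalgamation): for each 4-subset, fit all
  three possible topologies by maximum likelihood on the corresponding
  4-row submatrix and keep the one with the highest log-likelihood.
* **IQA** (induced quartet amalgamation): for each 4-subset, run a genuine
  per-subset ML tree search -- the starting topology comes from pairwise
  CFN distances via the four-point condition, branch lengths are optimized,
  and nearest-neighbour-interchange moves are accepted while they strictly
  improve the log-likelihood.

Where the likelihood surface separates the best topology clearly the two
schemes coincide; the test suite asserts this.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .likelihood import (
    SYMMETRIC_MODEL,
    TwoStateModel,
    canonical_topology,
    optimize_branch_lengths,
    pairwise_cfn_distances,
)
from .representation import BinaryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Quartet",
    "QuartetSet",
    "QuartetParseError",
    "enumerate_topologies",
    "mlqa_quartets",
    "iqa_quartets",
    "write_quartets",
    "read_quartets",
]

#: two optimized log-likelihoods closer than this count as a tie
LIKELIHOOD_TIE_TOL = 1e-9


class QuartetParseError(ValueError):
    """Raised when a quartet file cannot be parsed."""


class Quartet:
    """A quartet ``ab|cd`` in canonical form, with an optional weight.

    Canonical form: labels sorted within each pair, pairs sorted by their
    first element.  Two quartets are equal iff their canonical forms are
    equal; the weight (a log-likelihood, when present) is carried along but
    ignored by equality and hashing.
    """

    __slots__ = ("pair1", "pair2", "weight")

    def __init__(
        self,
        pair1: Sequence[str],
        pair2: Sequence[str],
        weight: float | None = None,
    ) -> None:
        p1, p2 = canonical_topology(tuple(pair1), tuple(pair2))
        labels = set(p1) | set(p2)
        if len(labels) != 4:
            raise ValueError(
                f"quartet requires four distinct labels, got {sorted(labels)}"
            )
        self.pair1 = p1
        self.pair2 = p2
        self.weight = None if weight is None else float(weight)

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return tuple(sorted((*self.pair1, *self.pair2)))  # type: ignore[return-value]

    @property
    def topology(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.pair1, self.pair2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Quartet):
            return NotImplemented
        return self.pair1 == other.pair1 and self.pair2 == other.pair2

    def __hash__(self) -> int:
        return hash((self.pair1, self.pair2))

    def to_string(self) -> str:
        return f"{self.pair1[0]},{self.pair1[1]}|{self.pair2[0]},{self.pair2[1]}"

    @classmethod
    def from_string(cls, text: str, weight: float | None = None) -> "Quartet":
        try:
            left, right = text.split("|")
            p1 = tuple(x.strip() for x in left.split(","))
            p2 = tuple(x.strip() for x in right.split(","))
            if len(p1) != 2 or len(p2) != 2 or not all(p1 + p2):
                raise ValueError
        except ValueError:
            raise QuartetParseError(f"malformed quartet {text!r}") from None
        return cls(p1, p2, weight)

    def __repr__(self) -> str:
        w = "" if self.weight is None else f", weight={self.weight:.6g}"
        return f"Quartet({self.to_string()!r}{w})"


class QuartetSet:
    """A collection of quartets with at most one quartet per 4-subset."""

    def __init__(self, quartets: Iterable[Quartet]) -> None:
        by_subset: dict[tuple, Quartet] = {}
        for q in quartets:
            key = q.labels
            if key in by_subset:
                raise ValueError(f"duplicate quartet for subset {key}")
            by_subset[key] = q
        self._by_subset = dict(sorted(by_subset.items()))
        self.taxa: set[str] = set()
        for q in self._by_subset.values():
            self.taxa.update(q.labels)

    @property
    def quartets(self) -> list[Quartet]:
        return list(self._by_subset.values())

    def get(self, labels: Iterable[str]) -> Quartet | None:
        """The quartet on a given 4-subset, or None."""
        return self._by_subset.get(tuple(sorted(labels)))

    def __len__(self) -> int:
        return len(self._by_subset)

    def __iter__(self) -> Iterator[Quartet]:
        return iter(self._by_subset.values())

    def __contains__(self, q: Quartet) -> bool:
        return self._by_subset.get(q.labels) == q

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuartetSet):
            return NotImplemented
        return self._by_subset == other._by_subset

    def is_complete(self) -> bool:
        """True iff every 4-subset of the taxon set is covered."""
        n = len(self.taxa)
        expected = n * (n - 1) * (n - 2) * (n - 3) // 24
        return len(self) == expected

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"QuartetSet({len(self)} quartets on {len(self.taxa)} taxa)"


def enumerate_topologies(labels: Sequence[str]) -> list[Quartet]:
    """The three possible pairings of four labels, in canonical order."""
    ls = sorted(str(x) for x in labels)
    if len(labels) != 4 or len(set(ls)) != 4:
        raise ValueError(f"exactly four distinct labels required, got {labels!r}")
    a, b, c, d = ls
    return [
        Quartet((a, b), (c, d)),
        Quartet((a, c), (b, d)),
        Quartet((a, d), (b, c)),
    ]


def _resolve_model(model, submatrix: BinaryMatrix) -> TwoStateModel:
    if isinstance(model, TwoStateModel):
        return model
    if model in (None, "cfn"):
        return SYMMETRIC_MODEL
    if model == "empirical":
        return TwoStateModel.empirical(submatrix)
    raise ValueError(f"unknown model {model!r}; expected 'cfn' or 'empirical'")


def _check_matrix(matrix: BinaryMatrix) -> list[str]:
    if matrix.n_rows < 4:
        raise ValueError(
            f"need at least 4 rows to infer quartets, got {matrix.n_rows}"
        )
    return sorted(matrix.row_labels)


def mlqa_quartets(matrix: BinaryMatrix, model="cfn") -> QuartetSet:
    """Most-likely quartet per 4-subset (exhaustive 3-topology ML ranking).

    Each quartet's weight is the winning optimized log-likelihood.  Exact
    ties are broken in canonical topology order with a logged warning.
    """
    labels = _check_matrix(matrix)
    out: list[Quartet] = []
    for subset in itertools.combinations(labels, 4):
        sub = matrix.subset(subset)
        m = _resolve_model(model, sub)
        fits = []
        for cand in enumerate_topologies(subset):
            _, ll = optimize_branch_lengths(cand.topology, sub, m)
            fits.append((ll, cand))
        best_ll = max(ll for ll, _ in fits)
        winners = [cand for ll, cand in fits if ll >= best_ll - LIKELIHOOD_TIE_TOL]
        if len(winners) > 1:
            logger.warning(
                "likelihood tie on subset %s; keeping canonical-first topology",
                subset,
            )
        out.append(Quartet(winners[0].pair1, winners[0].pair2, weight=best_ll))
    return QuartetSet(out)


def iqa_quartets(matrix: BinaryMatrix, model="cfn") -> QuartetSet:
    """Per-subset ML tree search (distance-initialized, NNI-refined).

    The starting pairing minimizes the sum of within-pair CFN distances
    (four-point condition); branch lengths are then optimized and the two
    alternative topologies are accepted whenever their optimized
    log-likelihood is strictly greater, repeating until no move improves.
    """
    labels = _check_matrix(matrix)
    out: list[Quartet] = []
    for subset in itertools.combinations(labels, 4):
        sub = matrix.subset(subset)
        m = _resolve_model(model, sub)
        dists = pairwise_cfn_distances(sub)
        candidates = enumerate_topologies(subset)

        def within_pair_sum(q: Quartet) -> float:
            return (
                dists[frozenset(q.pair1)] + dists[frozenset(q.pair2)]
            )

        current = min(candidates, key=lambda q: (within_pair_sum(q), q.topology))
        fitted: dict[tuple, float] = {}

        def fit(q: Quartet) -> float:
            key = q.topology
            if key not in fitted:
                _, ll = optimize_branch_lengths(key, sub, m)
                fitted[key] = ll
            return fitted[key]

        best_ll = fit(current)
        improved = True
        while improved:  # one NNI sweep, repeated until no improvement
            improved = False
            for alt in candidates:
                if alt == current:
                    continue
                ll = fit(alt)
                if ll > best_ll:
                    current, best_ll = alt, ll
                    improved = True
        out.append(Quartet(current.pair1, current.pair2, weight=best_ll))
    return QuartetSet(out)


def write_quartets(qs: QuartetSet, path, header: str | None = None) -> None:
    """One quartet per line: ``a,b|c,d<TAB>weight`` (weight omitted if absent)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for q in qs:
            if q.weight is None:
                fh.write(q.to_string() + "\n")
            else:
                fh.write(f"{q.to_string()}\t{q.weight!r}\n")


def read_quartets(path) -> QuartetSet:
    """Inverse of :func:`write_quartets`; lines canonicalize on read."""
    out: list[Quartet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            weight: float | None = None
            if len(parts) == 2:
                try:
                    weight = float(parts[1])
                except ValueError:
                    raise QuartetParseError(
                        f"{path} line {lineno}: bad weight {parts[1]!r}"
                    ) from None
            elif len(parts) != 1:
                raise QuartetParseError(
                    f"{path} line {lineno}: expected 'quartet[<TAB>weight]'"
                )
            try:
                out.append(Quartet.from_string(parts[0], weight))
            except QuartetParseError as err:
                raise QuartetParseError(f"{path} line {lineno}: {err}") from None
    return QuartetSet(out)
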