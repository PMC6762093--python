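"""Two-state Markov model and quartet maximum likelihood.

Characters are binary (mark present/absent).  The default model is the
symmetric two-state Cavender-Farris-Neyman (CFN) model: stationary
frequencies pi0 = pi1 = 1/2 and, over a branch of length ``t`` (expected
substitutions per character),

    P(change) = (1 - exp(-2 t)) / 2.

A general stationary two-state chain with frequencies (pi0, pi1) is also
supported; its transition probabilities are

    P_ij(t) = pi_j + (delta_ij - pi_j) * exp(-t / (2 pi0 pi1)),

with the rate scaled so that branch lengths remain expected substitutions
per character.  Quartet log-likelihoods are computed by Felsenstein pruning
with the (virtual) root on the internal edge; under this reversible model
the result does not depend on root placement.  Site patterns are compressed
to unique patterns with counts, so the cost is independent of matrix length.

No rate heterogeneity and no ascertainment correction are applied: constant
columns are retained (they inform branch lengths, not topology, under the
symmetric model).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .representation import BinaryMatrix

__all__ = [
    "TwoStateModel",
    "SYMMETRIC_MODEL",
    "QuartetTreeShape",
    "MIN_BRANCH_LENGTH",
    "MAX_BRANCH_LENGTH",
    "transition_prob",
    "quartet_log_likelihood",
    "optimize_branch_lengths",
    "cfn_distance",
    "pairwise_cfn_distances",
]

#: branch-length box constraints used everywhere (optimizer bounds and
#: the "effectively infinite" saturation length)
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0


@dataclass(frozen=True)
class TwoStateModel:
    """Stationary two-state substitution model.

    pi0, pi1 are the stationary frequencies of states 0 and 1; the default
    is the symmetric CFN model (1/2, 1/2).
    """

    pi0: float = 0.5
    pi1: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.pi0 < 1.0 and 0.0 < self.pi1 < 1.0):
            raise ValueError("stationary frequencies must lie in (0, 1)")
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-12:
            raise ValueError("stationary frequencies must sum to 1")

    @property
    def pi(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1])

    @classmethod
    def empirical(cls, matrix: BinaryMatrix, floor: float = 1e-3) -> "TwoStateModel":
        """Model with frequencies set to the matrix's observed 0/1 fractions."""
        if matrix.data.size == 0:
            return cls()
        p1 = float(np.mean(matrix.data))
        p1 = min(max(p1, floor), 1.0 - floor)
        return cls(pi0=1.0 - p1, pi1=p1)


SYMMETRIC_MODEL = TwoStateModel()


@dataclass
class QuartetTreeShape:
    """A four-leaf unrooted tree: a pairing plus five branch lengths.

    ``topology`` is ``((a, b), (c, d))`` in canonical order (labels sorted
    within pairs, pairs sorted by first element); ``pendant`` maps each leaf
    label to its branch length and ``internal`` is the internal edge length.
    ``degenerate`` flags a fit on an all-constant matrix (all lengths zero).
    """

    topology: tuple[tuple[str, str], tuple[str, str]]
    pendant: dict[str, float] = field(default_factory=dict)
    internal: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.topology
        labels = {a, b, c, d}
        if len(labels) != 4:
            raise ValueError("quartet topology needs four distinct labels")
        if not self.pendant:
            self.pendant = {l: 0.0 for l in labels}
        if set(self.pendant) != labels:
            raise ValueError("pendant lengths must cover exactly the four labels")
        for t in (*self.pendant.values(), self.internal):
            if not (0.0 <= t <= MAX_BRANCH_LENGTH):
                raise ValueError(
                    f"branch length {t} outside [0, {MAX_BRANCH_LENGTH}]"
                )

    @property
    def labels(self) -> tuple[str, str, str, str]:
        (a, b), (c, d) = self.topology
        return (a, b, c, d)


def transition_prob(model: TwoStateModel, t: float) -> np.ndarray:
    """2x2 transition-probability table P_ij(t); rows sum to 1."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    rate = 1.0 / (2.0 * model.pi0 * model.pi1)
    e = math.exp(-t * rate)
    pi = model.pi
    return pi[None, :] + (np.eye(2) - pi[None, :]) * e


def canonical_topology(
    pair1: tuple[str, str], pair2: tuple[str, str]
) -> tuple[tuple[str, str], tuple[str, str]]:
    p1 = tuple(sorted(map(str, pair1)))
    p2 = tuple(sorted(map(str, pair2)))
    if p2 < p1:
        p1, p2 = p2, p1
    return p1, p2  # type: ignore[return-value]


_STATES16 = np.array(
    [[(c >> 3) & 1, (c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(16)],
    dtype=np.intp,
)


def _pattern_counts(matrix4: BinaryMatrix, order) -> np.ndarray:
    """Counts of the 16 possible site patterns in leaf order ``order``."""
    rows = [matrix4.row(l).astype(np.int64) for l in order]
    codes = rows[0] * 8 + rows[1] * 4 + rows[2] * 2 + rows[3]
    return np.bincount(codes, minlength=16).astype(np.float64)


def _pattern_log_likelihood(
    counts: np.ndarray,
    model: TwoStateModel,
    ta: float,
    tb: float,
    tc: float,
    td: float,
    t_int: float,
) -> float:
    """Pruning log-likelihood over compressed patterns (a,b | c,d order)."""
    Pa = transition_prob(model, ta)
    Pb = transition_prob(model, tb)
    Pc = transition_prob(model, tc)
    Pd = transition_prob(model, td)
    Pint = transition_prob(model, t_int)
    sa, sb, sc, sd = (_STATES16[:, k] for k in range(4))
    La = Pa[:, sa]  # (2, 16): row = internal state at node u
    Lb = Pb[:, sb]
    Lc = Pc[:, sc]
    Ld = Pd[:, sd]
    upper = model.pi[:, None] * La * Lb  # root at node u
    lower = Lc * Ld
    site = np.einsum("xp,xy,yp->p", upper, Pint, lower)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logs = np.log(site[mask])
    return float(np.dot(counts[mask], logs))


def quartet_log_likelihood(
    shape: QuartetTreeShape,
    matrix4: BinaryMatrix,
    model: TwoStateModel = SYMMETRIC_MODEL,
) -> float:
    """Log-likelihood of a 4-row matrix under a quartet tree shape."""
    if set(matrix4.row_labels) != set(shape.labels):
        raise ValueError(
            f"matrix rows {matrix4.row_labels} do not match quartet labels "
            f"{shape.labels}"
        )
    counts = _pattern_counts(matrix4, shape.labels)
    a, b, c, d = shape.labels
    return _pattern_log_likelihood(
        counts,
        model,
        shape.pendant[a],
        shape.pendant[b],
        shape.pendant[c],
        shape.pendant[d],
        shape.internal,
    )


def cfn_distance(x: np.ndarray, y: np.ndarray) -> float:
    """CFN distance d = -(1/2) ln(1 - 2 p) from the mismatch fraction p.

    The mismatch fraction is clamped to [1e-6, 0.499] so the estimate stays
    finite on identical or saturated row pairs.
    """
    p = float(np.mean(np.asarray(x) != np.asarray(y)))
    p = min(max(p, 1e-6), 0.499)
    return -0.5 * math.log1p(-2.0 * p)


def pairwise_cfn_distances(matrix: BinaryMatrix) -> dict[frozenset, float]:
    """All pairwise CFN distances between rows, keyed by label pair."""
    out: dict[frozenset, float] = {}
    for la, lb in itertools.combinations(matrix.row_labels, 2):
        out[frozenset((la, lb))] = cfn_distance(matrix.row(la), matrix.row(lb))
    return out


def _initial_lengths(matrix4: BinaryMatrix, order) -> np.ndarray:
    """Starting branch lengths from pairwise CFN distances (additive logic)."""
    d = pairwise_cfn_distances(matrix4)
    a, b, c, d4 = order

    def dist(x, y):
        return d[frozenset((x, y))]

    ta = 0.5 * (dist(a, b) + 0.5 * (dist(a, c) + dist(a, d4)) - 0.5 * (dist(b, c) + dist(b, d4)))
    tb = 0.5 * (dist(a, b) + 0.5 * (dist(b, c) + dist(b, d4)) - 0.5 * (dist(a, c) + dist(a, d4)))
    tc = 0.5 * (dist(c, d4) + 0.5 * (dist(a, c) + dist(b, c)) - 0.5 * (dist(a, d4) + dist(b, d4)))
    td = 0.5 * (dist(c, d4) + 0.5 * (dist(a, d4) + dist(b, d4)) - 0.5 * (dist(a, c) + dist(b, c)))
    t_int = 0.5 * (
        0.5 * (dist(a, c) + dist(a, d4) + dist(b, c) + dist(b, d4))
        - dist(a, b)
        - dist(c, d4)
    )
    init = np.array([ta, tb, tc, td, t_int])
    return np.clip(init, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH)


def _maximize_affine(
    cnt: np.ndarray, a: np.ndarray, b: np.ndarray, lo: float, hi: float
) -> tuple[float, float]:
    """Maximize sum(cnt * log(a + b * e)) over e in [lo, hi].

    The objective is strictly concave in e, so the derivative is monotone
    decreasing: a safeguarded Newton iteration with bisection fallback
    converges to the unique interior optimum (or the active bound).
    """

    def deriv(e: float) -> float:
        return float(cnt @ (b / (a + b * e)))

    if deriv(hi) >= 0.0:
        e = hi
    elif deriv(lo) <= 0.0:
        e = lo
    else:
        e = 0.5 * (lo + hi)
        for _ in range(100):
            r = a + b * e
            ratio = b / r
            d1 = float(cnt @ ratio)
            if d1 > 0.0:
                lo = e
            else:
                hi = e
            d2 = -float(cnt @ (ratio * ratio))
            e_new = e - d1 / d2 if d2 < 0.0 else 0.5 * (lo + hi)
            if not (lo < e_new < hi):
                e_new = 0.5 * (lo + hi)
            if abs(e_new - e) < 1e-12:
                e = e_new
                break
            e = e_new
    return e, float(cnt @ np.log(a + b * e))


def optimize_branch_lengths(
    topology,
    matrix4: BinaryMatrix,
    model: TwoStateModel = SYMMETRIC_MODEL,
    tol: float = 1e-6,
    max_cycles: int = 100,
) -> tuple[QuartetTreeShape, float]:
    """Maximum-likelihood branch lengths for a fixed quartet topology.

    Coordinate ascent cycled over the five branches until the
    log-likelihood improves by less than ``tol`` (or ``max_cycles``).  Each
    coordinate subproblem is solved exactly: in e = exp(-rate * t) the
    per-pattern likelihood is affine, the 1-D objective strictly concave,
    and a safeguarded Newton step finds its unique bounded maximum.
    Initial lengths come from pairwise CFN distances.  The log-likelihood
    is non-decreasing across cycles by construction.

    An all-constant matrix yields zero lengths with a warning (flagged on
    the returned shape), not an error.
    """
    topology = canonical_topology(*topology)
    (a, b), (c, d) = topology
    order = (a, b, c, d)
    if set(matrix4.row_labels) != set(order):
        raise ValueError("matrix rows do not match the topology's labels")
    if matrix4.n_cols < 1:
        raise ValueError("matrix must have at least one column")

    counts = _pattern_counts(matrix4, order)

    if np.all(matrix4.data == matrix4.data[:1, :]):
        warnings.warn(
            "all-constant matrix: branch lengths are not identifiable; "
            "returning zero lengths",
            RuntimeWarning,
            stacklevel=2,
        )
        shape = QuartetTreeShape(
            topology, {l: 0.0 for l in order}, 0.0, degenerate=True
        )
        return shape, _pattern_log_likelihood(counts, model, 0, 0, 0, 0, 0)

    # Work in e_i = exp(-rate * t_i) in (0, 1]: every transition matrix is
    # affine in its own e, so the site likelihoods are affine in each single
    # e_i with the others held fixed.  Each coordinate step then needs only
    # two full pattern evaluations (e_i = 0 and e_i = 1) before an exact
    # 1-D concave maximization of sum(cnt * log(a + b * e)).
    rate = 1.0 / (2.0 * model.pi0 * model.pi1)
    e_lo = math.exp(-MAX_BRANCH_LENGTH * rate)
    e_hi = math.exp(-MIN_BRANCH_LENGTH * rate)
    nz = counts > 0
    cnt = counts[nz]
    sa, sb, sc, sd = (_STATES16[nz, k] for k in range(4))
    pi = model.pi
    PI = pi[None, :]
    D = np.eye(2) - PI

    def site_vec(es: np.ndarray) -> np.ndarray:
        Pa = PI + D * es[0]
        Pb = PI + D * es[1]
        Pc = PI + D * es[2]
        Pd = PI + D * es[3]
        Pint = PI + D * es[4]
        upper = pi[:, None] * Pa[:, sa] * Pb[:, sb]
        return ((Pint.T @ upper) * (Pc[:, sc] * Pd[:, sd])).sum(axis=0)

    def loglik(es: np.ndarray) -> float:
        return float(cnt @ np.log(site_vec(es)))

    es = np.exp(-rate * _initial_lengths(matrix4, order))
    ll = loglik(es)
    for _ in range(max_cycles):
        prev = ll
        for i in range(5):
            trial = es.copy()
            trial[i] = 0.0
            a_coef = site_vec(trial)
            trial[i] = 1.0
            b_coef = site_vec(trial) - a_coef

            e_best, cand = _maximize_affine(cnt, a_coef, b_coef, e_lo, e_hi)
            if cand > ll:  # accept only improvements: monotone by construction
                es[i] = e_best
                ll = cand
        if ll - prev < tol:
            break
    x = np.clip(-np.log(es) / rate, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH)
    shape = QuartetTreeShape(
        topology,
        {a: float(x[0]), b: float(x[1]), c: float(x[2]), d: float(x[3])},
        float(x[4]),
    )
    return shape, ll
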