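"""Exhaustive two-marker linear-separation search.

"Complete discrimination" by a pair of small RNAs means a straight line in
their 2-D log2-CPM expression plane classifies every training sample
correctly.  That is a geometric fact — the two classes' convex hulls are
disjoint — so the primary decision procedure here is exact: coordinates are
lifted to rational numbers (floats are exact rationals) and hull
disjointness is decided with integer-exact orientation predicates.  A
large-cost linear soft-margin SVM is retained as a cross-check mirroring
common practice; disagreements (never observed, but floating-point SVM
convergence is not guaranteed) are counted and logged.

Strict separation is required: a sample lying exactly on the candidate
boundary is a failure, since complete discrimination admits no boundary
ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .screen import ComparisonSpec

logger = logging.getLogger(__name__)

DEFAULT_SVM_COST = 1e6

Point = tuple[Fraction, Fraction]


def _cross(o: Point, a: Point, b: Point) -> Fraction:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _convex_hull(points: list[Point]) -> list[Point]:
    """Monotone-chain hull, exact arithmetic; collinear points dropped.
    Degenerate inputs yield a 1-point or 2-point 'hull'."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts
    lower: list[Point] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[Point] = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]  # collinear input degenerates to 2 points
    return hull


def _on_segment(p: Point, a: Point, b: Point) -> bool:
    if _cross(a, b, p) != 0:
        return False
    return (
        min(a[0], b[0]) <= p[0] <= max(a[0], b[0])
        and min(a[1], b[1]) <= p[1] <= max(a[1], b[1])
    )


def _segments_intersect(a: Point, b: Point, c: Point, d: Point) -> bool:
    """Closed-segment intersection with exact predicates (touching counts)."""
    d1, d2 = _cross(c, d, a), _cross(c, d, b)
    d3, d4 = _cross(a, b, c), _cross(a, b, d)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != d2 and d3 != d4:
        return True
    return (
        _on_segment(a, c, d)
        or _on_segment(b, c, d)
        or _on_segment(c, a, b)
        or _on_segment(d, a, b)
    )


def _point_in_hull(p: Point, hull: list[Point]) -> bool:
    """Point inside or on the boundary of a (possibly degenerate) hull."""
    if len(hull) == 1:
        return p == hull[0]
    if len(hull) == 2:
        return _on_segment(p, hull[0], hull[1])
    for a, b in zip(hull, hull[1:] + hull[:1]):
        if _cross(a, b, p) < 0:
            return False
    return True


def _hulls_intersect(h1: list[Point], h2: list[Point]) -> bool:
    edges1 = list(zip(h1, h1[1:] + h1[:1])) if len(h1) > 1 else []
    edges2 = list(zip(h2, h2[1:] + h2[:1])) if len(h2) > 1 else []
    for a, b in edges1:
        for c, d in edges2:
            if _segments_intersect(a, b, c, d):
                return True
    return any(_point_in_hull(p, h2) for p in h1) or any(
        _point_in_hull(p, h1) for p in h2
    )


def _to_points(xy: np.ndarray) -> list[Point]:
    return [(Fraction(float(x)), Fraction(float(y))) for x, y in xy]


def separable_exact_2d(xy: np.ndarray, labels: np.ndarray, strict: bool = True) -> bool:
    """Decide 2-D linear separability exactly.

    ``strict=True`` (the default and the criterion used throughout) demands a
    line with no sample on it, which holds iff the closed convex hulls of the
    two classes are disjoint — decided here with rational arithmetic.
    ``strict=False`` merely requires a direction whose projections weakly
    order the classes (boundary samples allowed).
    """
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) != len(labels):
        raise ValueError("expected n x 2 coordinates and n labels")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes, both non-empty")
    a = _to_points(xy[labels == classes[0]])
    b = _to_points(xy[labels == classes[1]])
    if strict:
        return not _hulls_intersect(_convex_hull(a), _convex_hull(b))
    # weak separation: some candidate direction orders the projections
    pts = a + b
    dirs: list[Point] = []
    for p, q in combinations(set(pts), 2):
        d = (q[0] - p[0], q[1] - p[1])
        dirs.append(d)
        dirs.append((-d[1], d[0]))
    dirs.append((Fraction(1), Fraction(0)))
    for dx, dy in dirs:
        pa = [dx * px + dy * py for px, py in a]
        pb = [dx * px + dy * py for px, py in b]
        if max(pa) <= min(pb) or max(pb) <= min(pa):
            return True
    return False


def separable_bruteforce_2d(xy: np.ndarray, labels: np.ndarray) -> bool:
    """Independent strict-separability check by candidate-line enumeration.

    If a strictly separating line exists it can be translated/rotated until
    it runs parallel to a line through two data points (or the whole dataset
    is a single point per class).  So it suffices to test, for every point
    pair, the pair's normal direction and two slight rational perturbations
    of it, asking whether class projections are strictly ordered.  Used as a
    cross-oracle for :func:`separable_exact_2d`; quadratic and slower, but
    independent of the hull machinery.
    """
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes, both non-empty")
    a = _to_points(xy[labels == classes[0]])
    b = _to_points(xy[labels == classes[1]])
    pts = sorted(set(a + b))
    eps = Fraction(1, 10**9)
    dirs: list[Point] = [(Fraction(1), Fraction(0)), (Fraction(0), Fraction(1))]
    for p, q in combinations(pts, 2):
        dx, dy = q[0] - p[0], q[1] - p[1]
        base = (-dy, dx)
        for e in (0, eps, -eps):
            dirs.append((base[0] + e * dx, base[1] + e * dy))
    for dx, dy in dirs:
        if dx == 0 and dy == 0:
            continue
        pa = [dx * px + dy * py for px, py in a]
        pb = [dx * px + dy * py for px, py in b]
        if max(pa) < min(pb) or max(pb) < min(pa):
            return True
    return False


def _fit_linear_svm(xy: np.ndarray, labels: np.ndarray, cost: float) -> LinearSVC:
    # liblinear: large-cost soft margin stays fast on non-separable inputs,
    # where the libsvm solver effectively stalls
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return LinearSVC(C=cost, max_iter=100_000, random_state=0).fit(xy, labels)


def separable_svm(
    xy: np.ndarray, labels: np.ndarray, cost: float = DEFAULT_SVM_COST
) -> bool:
    """Linear SVM surrogate: large-cost soft margin on standardized
    coordinates; separable iff training accuracy is 100%."""
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes, both non-empty")
    sd = xy.std(axis=0)
    sd[sd == 0] = 1.0
    z = (xy - xy.mean(axis=0)) / sd
    if not np.any(np.ptp(z, axis=0)):  # all points identical, mixed labels
        return False
    clf = _fit_linear_svm(z, labels, cost)
    return bool(np.all(clf.predict(z) == labels))


def _margin(xy: np.ndarray, labels: np.ndarray, cost: float) -> float:
    """Geometric margin of the (approximately hard-margin) separating line."""
    y = (labels == np.unique(labels)[1]).astype(int)
    clf = _fit_linear_svm(xy, y, cost)
    w = np.linalg.norm(clf.coef_)
    return float(2.0 / w) if w > 0 else np.nan


@dataclass
class PairTable:
    """All evaluated feature pairs for one comparison."""

    comparison: ComparisonSpec
    records: pd.DataFrame  # small_rna_1, small_rna_2, separable, margin
    pool: str
    svm_disagreements: int

    @property
    def separating_pairs(self) -> list[tuple[str, str]]:
        sep = self.records[self.records["separable"]]
        return list(zip(sep["small_rna_1"], sep["small_rna_2"]))

    @property
    def n_separating(self) -> int:
        return int(self.records["separable"].sum())


def enumerate_separating_pairs(
    log_cpm: pd.DataFrame,
    candidate_ids: list[str],
    metadata: pd.DataFrame,
    comparison: ComparisonSpec,
    pool: str = "significant",
    svm_cost: float = DEFAULT_SVM_COST,
    cross_check: bool = True,
) -> PairTable:
    """Evaluate every unordered candidate pair for complete separation.

    ``log_cpm`` holds the log2(CPM+1) expression matrix (features x samples).
    Pairs are emitted in lexicographic order, each once (id1 < id2).  The
    exact geometric test decides; the SVM surrogate is run as a logged
    cross-check when ``cross_check`` is true.
    """
    if len(candidate_ids) < 2:
        raise ValueError("need at least 2 candidate features")
    if len(set(candidate_ids)) != len(candidate_ids):
        raise ValueError("duplicate candidate ids")
    missing = [f for f in candidate_ids if f not in log_cpm.index]
    if missing:
        raise KeyError(f"candidates absent from matrix: {missing}")
    ref, tgt = comparison.split_samples(metadata)
    samples = ref + tgt
    labels = np.concatenate([np.zeros(len(ref)), np.ones(len(tgt))])
    sub = log_cpm.loc[candidate_ids, samples]
    rows = []
    disagreements = 0
    for id1, id2 in combinations(sorted(candidate_ids), 2):
        xy = np.column_stack([sub.loc[id1].to_numpy(), sub.loc[id2].to_numpy()])
        sep = separable_exact_2d(xy, labels, strict=True)
        if cross_check:
            svm_sep = separable_svm(xy, labels, cost=svm_cost)
            if svm_sep != sep:
                disagreements += 1
                logger.warning(
                    "SVM/exact disagreement for pair (%s, %s): exact=%s svm=%s",
                    id1, id2, sep, svm_sep,
                )
        margin = _margin(xy, labels, svm_cost) if sep else np.nan
        rows.append(
            {"small_rna_1": id1, "small_rna_2": id2, "separable": sep, "margin": margin}
        )
    records = pd.DataFrame(rows)
    return PairTable(comparison, records, pool, disagreements)
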