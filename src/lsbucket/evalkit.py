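"""Evaluation of bucketing functions: collisions, accuracy, analytic bounds.

A pair collides when some *aligned* pair of its k binary hash-codes is
bitwise equal.  A pair in edit-distance category d is predicted correctly
when it collides and d <= d1, or collides nowhere and d >= d2.  The
categorized accuracy is the fraction of correct pairs per category; the
overall accuracy averages the per-category values, excluding gap
categories (d1 < d < d2), for which correctness is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .seqsim import CategoryDataset, LabeledPair

__all__ = [
    "AccuracyReport",
    "collide",
    "collide_many",
    "predict_correct",
    "accuracy_report",
    "accuracy_from_collisions",
    "bucket_universe_size",
    "lsh_accuracy_bound",
]


@dataclass
class AccuracyReport:
    """Per-category and overall accuracy of a bucketing function."""

    d1: int
    d2: int
    per_category: dict[int, float] = field(default_factory=dict)
    overall: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "d1": self.d1,
            "d2": self.d2,
            "per_category": {str(d): v for d, v in sorted(self.per_category.items())},
            "overall": self.overall,
        }


def collide(f_s: np.ndarray, f_t: np.ndarray) -> bool:
    """True iff some aligned code index i has f_i(s) == f_i(t) bitwise."""
    f_s, f_t = np.asarray(f_s), np.asarray(f_t)
    if f_s.shape != f_t.shape or f_s.ndim != 2:
        raise ValueError("hash-code stacks must share a (k, m) shape")
    return bool(np.all(f_s == f_t, axis=1).any())


def collide_many(f_s: np.ndarray, f_t: np.ndarray) -> np.ndarray:
    """Vectorized :func:`collide` over stacks of shape (N, k, m)."""
    f_s, f_t = np.asarray(f_s), np.asarray(f_t)
    if f_s.shape != f_t.shape or f_s.ndim != 3:
        raise ValueError("expected stacks of shape (N, k, m)")
    return np.all(f_s == f_t, axis=2).any(axis=1)


def predict_correct(pair: LabeledPair, collided: bool, d1: int, d2: int) -> bool:
    """Apply the categorized-accuracy rule to one pair with known collision."""
    if pair.d <= d1:
        return collided
    if pair.d >= d2:
        return not collided
    raise ValueError(f"pair in gap category d={pair.d}: correctness undefined")


def accuracy_from_collisions(
    dataset: CategoryDataset,
    collisions: dict[int, np.ndarray],
    d1: int,
    d2: int,
) -> AccuracyReport:
    """Build a report from per-category collision indicators.

    Each entry of ``collisions[d]`` is one pair's collision indicator —
    boolean for a deterministic bucketing, or a fraction in [0, 1] for a
    randomized family evaluated by its per-member collision rate.
    """
    report = AccuracyReport(d1=d1, d2=d2)
    for d in dataset.d_values:
        if d1 < d < d2 or not dataset.categories[d]:
            continue
        coll = np.asarray(collisions[d], dtype=np.float64)
        correct = coll if d <= d1 else 1.0 - coll
        report.per_category[d] = float(correct.mean())
    if report.per_category:
        report.overall = float(np.mean(list(report.per_category.values())))
    return report


def accuracy_report(
    dataset: CategoryDataset,
    hash_fn: Callable[[list[str]], np.ndarray],
    d1: int,
    d2: int,
) -> AccuracyReport:
    """Categorized and overall accuracy of a learned bucketing function.

    ``hash_fn`` maps a list of sequences to a ``(N, k, m)`` binary array
    (e.g. ``model.hash_codes``).  Gap categories are excluded from the
    average; empty categories are reported as absent.
    """
    collisions: dict[int, np.ndarray] = {}
    for d in dataset.d_values:
        if d1 < d < d2:
            continue
        pairs = dataset.categories[d]
        if not pairs:
            continue
        f_s = hash_fn([p.s for p in pairs])
        f_t = hash_fn([p.t for p in pairs])
        collisions[d] = collide_many(f_s, f_t)
    return accuracy_from_collisions(dataset, collisions, d1, d2)


def bucket_universe_size(n: int, sigma: int = 4) -> int:
    """Bucket-universe size n * sigma^(n-1) needed by an optimal aligned
    (1,2)-bucketing that sends each length-n sequence to n buckets."""
    if n < 1 or sigma < 1:
        raise ValueError("require n >= 1 and sigma >= 1")
    return n * sigma ** (n - 1)


def lsh_accuracy_bound(p1: float) -> tuple[float, bool]:
    """Upper bound on distance-2 accuracy of a (1,2)-sensitive LSH family.

    If every pair at edit distance 1 collides under at least a fraction
    ``p1 > 0.5`` of the family, a counting argument over a distance-2 chain
    x -> y -> z shows at least 2*p1 - 1 of the family merges x and z, so
    the probability of *avoiding* a collision at distance 2 is at most
    2*(1 - p1).  Returns ``(bound, vacuous)``; for ``p1 <= 0.5`` the
    argument gives nothing and ``(1.0, True)`` is returned.
    """
    if not (0.0 <= p1 <= 1.0):
        raise ValueError("p1 must be a probability")
    if p1 <= 0.5:
        return 1.0, True
    return 2.0 * (1.0 - p1), False
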