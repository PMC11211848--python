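"""Bucketed candidate-pair retrieval and cell-barcode rescue.

Single-cell pipelines keep a *whitelist* W of trusted cell barcodes and
discard reads whose barcode matches none exactly.  Rescue links each
erroneous barcode b to whitelist members within edit distance t:

    P* = {(b, w) : b in B, w in W, edit(b, w) <= t}      (ground truth)
    P1 = pairs sharing an aligned hash-code (bucketing function)
    P2 = pairs sharing a kmer
    P3 = P1 intersect P2

P1 and P2 are built with inverted indexes in O(|B| + |W|) insertions —
never all-versus-all — and verified pairs are scored by recall
|P cap P*| / |P*| and precision |P cap P*| / |P|.

A synthetic generator emulates the whitelist/erroneous-set structure
(length-16 barcodes, errors a small edit distance from a whitelist member,
geometric read multiplicities) so the machinery can be exercised without a
sequencing dataset.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .seqsim import DNA, bounded_edit_distance, edit_distance, fit_length, \
    apply_random_edits, random_sequence

__all__ = [
    "PairSet",
    "BucketIndex",
    "SyntheticBarcodes",
    "ground_truth_pairs",
    "lsb_pairs",
    "kmer_pairs",
    "combined_pairs",
    "retrieval_metrics",
    "synthetic_barcodes",
]


@dataclass(frozen=True)
class PairSet:
    """A set of (b index, w index) candidate pairs with a provenance tag."""

    pairs: frozenset
    tag: str

    def __len__(self) -> int:
        return len(self.pairs)


class BucketIndex:
    """Inverted index from (code index i, code bits) to sequence ids."""

    def __init__(self) -> None:
        self._index: dict[tuple[int, bytes], list[int]] = defaultdict(list)
        self.insertions = 0

    def add(self, seq_id: int, codes: np.ndarray) -> None:
        """File one sequence under its k (index, bits) keys."""
        self.insertions += 1
        for i, code in enumerate(np.asarray(codes, dtype=np.uint8)):
            self._index[(i, code.tobytes())].append(seq_id)

    def lookup(self, codes: np.ndarray) -> set[int]:
        """Ids sharing at least one aligned bucket with the given codes."""
        hits: set[int] = set()
        for i, code in enumerate(np.asarray(codes, dtype=np.uint8)):
            hits.update(self._index.get((i, code.tobytes()), ()))
        return hits


def ground_truth_pairs(B: list[str], W: list[str], t: int) -> PairSet:
    """Exact close-pair set via banded edit-distance verification."""
    if t < 0:
        raise ValueError("t must be non-negative")
    pairs = {
        (bi, wi)
        for bi, b in enumerate(B)
        for wi, w in enumerate(W)
        if bounded_edit_distance(b, w, t) is not None
    }
    return PairSet(pairs=frozenset(pairs), tag="P*")


def lsb_pairs(
    B: list[str],
    W: list[str],
    hash_fn: Callable[[list[str]], np.ndarray],
) -> PairSet:
    """Pairs with an aligned hash-code collision, via an index join.

    ``hash_fn`` maps sequences to (N, k, m) binary code stacks (e.g.
    ``model.hash_codes``).  Each whitelist entry is filed under its k
    buckets; each erroneous barcode then probes its own k buckets, so the
    work is linear in |B| + |W| index operations plus output size.
    """
    codes_w = np.asarray(hash_fn(W), dtype=np.uint8)
    codes_b = np.asarray(hash_fn(B), dtype=np.uint8)
    if codes_w.shape[1:] != codes_b.shape[1:]:
        raise ValueError("hash-code shapes of B and W disagree")
    index = BucketIndex()
    for wi in range(len(W)):
        index.add(wi, codes_w[wi])
    pairs = {
        (bi, wi) for bi in range(len(B)) for wi in index.lookup(codes_b[bi])
    }
    return PairSet(pairs=frozenset(pairs), tag="P1")


def kmer_pairs(B: list[str], W: list[str], k: int) -> PairSet:
    """Pairs sharing at least one kmer, via an inverted kmer index."""
    if not B or not W:
        return PairSet(pairs=frozenset(), tag="P2")
    n = len(W[0])
    if not (1 <= k <= n):
        raise ValueError("require 1 <= k <= barcode length")
    index: dict[str, set[int]] = defaultdict(set)
    for wi, w in enumerate(W):
        for j in range(len(w) - k + 1):
            index[w[j : j + k]].add(wi)
    pairs: set[tuple[int, int]] = set()
    for bi, b in enumerate(B):
        hits: set[int] = set()
        for j in range(len(b) - k + 1):
            hits |= index.get(b[j : j + k], set())
        pairs.update((bi, wi) for wi in hits)
    return PairSet(pairs=frozenset(pairs), tag="P2")


def combined_pairs(p1: PairSet, p2: PairSet) -> PairSet:
    """Pairs passing both the hash-collision and the shared-kmer filters."""
    return PairSet(pairs=p1.pairs & p2.pairs, tag="P3")


def retrieval_metrics(
    p: PairSet, p_star: PairSet
) -> tuple[float | None, float | None]:
    """(recall, precision) of a candidate set against the ground truth.

    Either metric is ``None`` when its denominator is empty (undefined,
    not zero).
    """
    hits = len(p.pairs & p_star.pairs)
    recall = hits / len(p_star.pairs) if p_star.pairs else None
    precision = hits / len(p.pairs) if p.pairs else None
    return recall, precision


@dataclass
class SyntheticBarcodes:
    """A synthetic whitelist/erroneous-barcode instance with provenance."""

    whitelist: list[str]
    erroneous: list[str]
    multiplicities: list[int]  # reads carrying each erroneous barcode
    origins: list[int | None]  # whitelist index, or None for unrelated
    n_edits: list[int]  # edits applied (0 for unrelated barcodes)

    @property
    def erroneous_reads(self) -> int:
        return int(sum(self.multiplicities))


def synthetic_barcodes(
    n: int = 16,
    whitelist_size: int = 806,
    erroneous_size: int = 1000,
    error_profile: dict[int, float] | None = None,
    unrelated_prob: float = 0.0,
    mean_multiplicity: float = 2.0,
    min_spacing: int = 0,
    seed: int = 0,
    alphabet: str = DNA,
) -> SyntheticBarcodes:
    """Generate a whitelist W and an erroneous set B emulating barcode data.

    Whitelist members are distinct uniform n-mers (optionally enforcing a
    minimum pairwise edit distance).  Each erroneous barcode is a random
    whitelist member mutated by e edits, with e drawn from
    ``error_profile`` (default mass 0.6/0.3/0.1 on e = 1/2/3), then
    padded/truncated back to length n — or, with probability
    ``unrelated_prob``, an unrelated random n-mer.  Read multiplicities
    follow a geometric law with the given mean.
    """
    if whitelist_size < 1 or erroneous_size < 1:
        raise ValueError("sizes must be >= 1")
    profile = error_profile or {1: 0.6, 2: 0.3, 3: 0.1}
    edits = np.array(sorted(profile))
    weights = np.array([profile[e] for e in edits], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)

    whitelist: list[str] = []
    attempts = 0
    while len(whitelist) < whitelist_size:
        attempts += 1
        if attempts > 1000 * whitelist_size:
            raise RuntimeError("whitelist spacing constraint looks infeasible")
        cand = random_sequence(n, rng, alphabet)
        if cand in whitelist:
            continue
        if min_spacing > 1 and any(
            bounded_edit_distance(cand, w, min_spacing - 1) is not None
            for w in whitelist
        ):
            continue
        whitelist.append(cand)

    whitelist_set = set(whitelist)
    erroneous: list[str] = []
    origins: list[int | None] = []
    n_edits: list[int] = []
    for _ in range(erroneous_size):
        if unrelated_prob > 0 and rng.random() < unrelated_prob:
            erroneous.append(random_sequence(n, rng, alphabet))
            origins.append(None)
            n_edits.append(0)
            continue
        wi = int(rng.integers(len(whitelist)))
        e = int(rng.choice(edits, p=weights))
        # pad/truncate can push the distance past the drawn budget and
        # edits can cancel back to the origin; resample until the barcode
        # is genuinely erroneous (not whitelisted) and within e edits
        for _attempt in range(1000):
            mutated = fit_length(
                apply_random_edits(whitelist[wi], e, rng, alphabet), n, rng, alphabet
            )
            d = edit_distance(mutated, whitelist[wi])
            if 1 <= d <= e and mutated not in whitelist_set:
                break
        else:
            raise RuntimeError("could not realize the drawn edit budget")
        erroneous.append(mutated)
        origins.append(wi)
        n_edits.append(e)

    # geometric on {1, 2, ...} with the requested mean
    p_geom = min(1.0, 1.0 / mean_multiplicity)
    multiplicities = rng.geometric(p_geom, size=erroneous_size).tolist()
    return SyntheticBarcodes(
        whitelist=whitelist,
        erroneous=erroneous,
        multiplicities=[int(x) for x in multiplicities],
        origins=origins,
        n_edits=n_edits,
    )
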