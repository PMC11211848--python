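"""Order Min Hash (OMH): a locality-sensitive hash for edit distance.

A sequence x of length n has n - k + 1 kmers; attaching to each its
occurrence number within x (1-based, left to right) makes them distinct
("uniquified").  One hash code is built by ranking all uniquified kmers
under a random permutation, taking the lowest-ranked ``l`` of them,
re-ordering those by their position in x, and concatenating the kmer
strings into a k*l-mer.  A sketch repeats this with ``m`` independent
permutations; two sequences collide when their codes match in at least one
aligned group, which boosts a single-group collision probability p to
1 - (1 - p)^m.

Rather than materializing a permutation of the astronomically large
universe of (kmer, occurrence) pairs, each group uses a seeded 64-bit
integer mixing function as a random rank; only the relative ranks of the
pairs actually observed matter, and the same rank function is shared by
every sequence in a run.  Rank ties (vanishingly rare) are broken by the
lexicographic order of (kmer, occurrence), which the integer key encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalkit import AccuracyReport, accuracy_from_collisions
from .seqsim import DNA, CategoryDataset

__all__ = [
    "OMHParams",
    "UniquifiedKmer",
    "OMHSketch",
    "uniquified_kmers",
    "omh_code",
    "sketch",
    "sketch_many",
    "omh_collision",
    "omh_accuracy",
    "grid_search",
]

_OCC_BITS = 8  # occurrence index packed into the low byte of the rank key


@dataclass(frozen=True)
class OMHParams:
    """OMH parameters: kmer length k, kmers per code l, groups m."""

    k: int
    l: int
    m: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("kmer length k must be >= 2")
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass(frozen=True)
class UniquifiedKmer:
    kmer: str
    occ: int  # 1-based occurrence number of this kmer within the sequence
    pos: int  # 0-based start position


@dataclass(frozen=True)
class OMHSketch:
    """m concatenated k*l-mers, one per permutation group."""

    codes: tuple[str, ...]


def uniquified_kmers(x: str, k: int) -> list[UniquifiedKmer]:
    """All n - k + 1 kmers of x with occurrence numbers attached."""
    if k > len(x):
        raise ValueError("kmer length exceeds sequence length")
    seen: dict[str, int] = {}
    out = []
    for pos in range(len(x) - k + 1):
        kmer = x[pos : pos + k]
        seen[kmer] = seen.get(kmer, 0) + 1
        out.append(UniquifiedKmer(kmer=kmer, occ=seen[kmer], pos=pos))
    return out


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Stateless 64-bit finalizer used as the per-group random rank."""
    with np.errstate(over="ignore"):  # modular 64-bit wrap is the point
        z = x.astype(np.uint64, copy=True)
        z ^= z >> np.uint64(30)
        z *= np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return z


def _group_salts(seed: int, m: int) -> np.ndarray:
    rng = np.random.default_rng(int(seed))
    return rng.integers(0, 2**63, size=m, dtype=np.uint64)


def _kmer_key(kmer: str, occ: int, alphabet: str = DNA) -> int:
    """Pack (kmer, occurrence) into one integer, lexicographic in (kmer, occ)."""
    if occ >= (1 << _OCC_BITS):
        raise ValueError("occurrence index too large to pack")
    v = 0
    for c in kmer:
        v = v * len(alphabet) + alphabet.index(c)
    return (v << _OCC_BITS) | occ


def _rank(key: np.ndarray | int, salt: int) -> np.ndarray | int:
    arr = np.asarray(key, dtype=np.uint64)
    r = _splitmix64(arr + np.uint64(salt))
    return int(r) if np.isscalar(key) or arr.ndim == 0 else r


def default_rank_fn(seed: int, group: int, alphabet: str = DNA):
    """The rank function of one permutation group, as a plain callable."""
    salt = int(_group_salts(seed, group + 1)[group])

    def rank(kmer: str, occ: int) -> tuple[int, int]:
        key = _kmer_key(kmer, occ, alphabet)
        return (int(_rank(key, salt)), key)  # key breaks rank ties

    return rank


def omh_code(x: str, params: OMHParams, rank_fn) -> str:
    """One k*l-mer code: the l minimum-rank uniquified kmers of x, re-ordered
    by their position in x and concatenated."""
    kmers = uniquified_kmers(x, params.k)
    if params.l > len(kmers):
        raise ValueError("l exceeds the number of kmers")
    ranked = sorted(kmers, key=lambda u: rank_fn(u.kmer, u.occ))
    chosen = sorted(ranked[: params.l], key=lambda u: u.pos)
    return "".join(u.kmer for u in chosen)


def sketch(x: str, params: OMHParams, alphabet: str = DNA) -> OMHSketch:
    """The m-group OMH sketch of a single sequence."""
    codes = sketch_many([x], params, alphabet=alphabet)
    k = params.k
    decoded = []
    for g in range(params.m):
        parts = []
        for v in codes[0, g]:
            v = int(v)
            chars = []
            for _ in range(k):
                chars.append(alphabet[v % len(alphabet)])
                v //= len(alphabet)
            parts.append("".join(reversed(chars)))
        decoded.append("".join(parts))
    return OMHSketch(codes=tuple(decoded))


def sketch_many(
    seqs: list[str], params: OMHParams, alphabet: str = DNA
) -> np.ndarray:
    """Vectorized sketches: integer-coded kmers of shape (N, m, l).

    Entry [i, g, j] is the integer code of the j-th (in position order)
    selected kmer of sequence i under permutation group g.  Aligned-group
    equality of these arrays is exactly code-string equality.
    """
    if not seqs:
        return np.zeros((0, params.m, params.l), dtype=np.uint64)
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("all sequences must share one length")
    k, l = params.k, params.l
    P = n - k + 1
    if k > n or l > P:
        raise ValueError("invalid (k, l) for this sequence length")
    if 2 * k + _OCC_BITS > 63:
        raise ValueError("kmer length too large for integer rank keys")

    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), n)
    base = lut[raw]
    if np.any(base < 0):
        raise ValueError("sequence contains non-alphabet characters")

    # rolling integer kmers: kmer[:, j] encodes x[j:j+k] base-|alphabet|
    A = len(alphabet)
    kmer = np.zeros((len(seqs), P), dtype=np.uint64)
    for i in range(k):
        kmer = kmer * np.uint64(A) + base[:, i : i + P].astype(np.uint64)

    # 1-based occurrence number of each kmer within its sequence
    occ = np.ones((len(seqs), P), dtype=np.uint64)
    for j in range(1, P):
        for j2 in range(j):
            occ[:, j] += kmer[:, j2] == kmer[:, j]

    keys = (kmer << np.uint64(_OCC_BITS)) | occ
    salts = _group_salts(params.seed, params.m)
    out = np.empty((len(seqs), params.m, l), dtype=np.uint64)
    for g in range(params.m):
        ranks = _splitmix64(keys + salts[g])
        order = np.lexsort((keys, ranks), axis=-1)  # rank, ties by (kmer, occ)
        sel = np.sort(order[:, :l], axis=1)  # re-order chosen kmers by position
        out[:, g, :] = np.take_along_axis(kmer, sel, axis=1)
    return out


def omh_collision(a: OMHSketch, b: OMHSketch) -> bool:
    """True iff the sketches match in at least one aligned group."""
    if len(a.codes) != len(b.codes):
        raise ValueError("sketches have different numbers of groups")
    return any(ca == cb for ca, cb in zip(a.codes, b.codes))


def group_collide_many(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Per-group collision indicators (N, m) over ``sketch_many`` outputs."""
    if codes_a.shape != codes_b.shape:
        raise ValueError("code arrays must share a shape")
    return np.all(codes_a == codes_b, axis=2)


def collide_many(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Vectorized any-aligned-group collision over ``sketch_many`` outputs."""
    return group_collide_many(codes_a, codes_b).any(axis=1)


def omh_accuracy(
    dataset: CategoryDataset,
    params: OMHParams,
    d1: int,
    d2: int,
    alphabet: str = DNA,
    mode: str = "family",
) -> AccuracyReport:
    """Categorized/overall accuracy of OMH as a (d1,d2)-sensitive hash.

    ``mode="family"`` (default) scores each pair by the fraction of the m
    permutation groups whose single code collides — the empirical collision
    probability over the hash family, which is the accuracy notion under
    which a randomized LSH is judged.  ``mode="boosted"`` instead scores
    the deterministic m-bucket sketch: a pair collides when *some* aligned
    group matches (collision probability 1 - (1-p)^m), which is how the
    sketch behaves when used for bucketed retrieval.
    """
    if mode not in ("family", "boosted"):
        raise ValueError("mode must be 'family' or 'boosted'")
    collisions: dict[int, np.ndarray] = {}
    for d in dataset.d_values:
        if d1 < d < d2 or not dataset.categories[d]:
            continue
        pairs = dataset.categories[d]
        ca = sketch_many([p.s for p in pairs], params, alphabet)
        cb = sketch_many([p.t for p in pairs], params, alphabet)
        per_group = group_collide_many(ca, cb)
        collisions[d] = (
            per_group.mean(axis=1) if mode == "family" else per_group.any(axis=1)
        )
    return accuracy_from_collisions(dataset, collisions, d1, d2)


def grid_search(
    dataset: CategoryDataset,
    d1: int,
    d2: int,
    m: int = 20,
    seed: int = 0,
    alphabet: str = DNA,
    mode: str = "family",
) -> tuple[OMHParams, AccuracyReport, list[dict]]:
    """Exhaustive sweep over 2 <= k <= n and 2 <= l <= n - k.

    Returns the best setting (ties: smaller k, then smaller l), its report,
    and the full per-setting table.
    """
    n = dataset.n
    table: list[dict] = []
    best: tuple[OMHParams, AccuracyReport] | None = None
    for k in range(2, n + 1):
        for l in range(2, n - k + 1):
            params = OMHParams(k=k, l=l, m=m, seed=seed)
            report = omh_accuracy(dataset, params, d1, d2, alphabet, mode)
            table.append({"k": k, "l": l, "overall": report.overall})
            if best is None or report.overall > best[1].overall:
                best = (params, report)
    if best is None:
        raise ValueError("empty grid: n too small for any (k, l)")
    return best[0], best[1], table
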