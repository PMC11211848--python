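"""Simulation of edit-distance-stratified sequence pairs.

Training, validation and test data for locality-sensitive bucketing (LSB)
functions are fully simulated: a random length-``n`` sequence ``s`` is
mutated by a prescribed number of random edits into ``t``, the pair is
re-measured with an exact Levenshtein computation, and pairs are collected
into categories indexed by their *true* edit distance.  Labels ``y = -1``
(similar, ``d <= d1``) and ``y = +1`` (dissimilar, ``d >= d2``) are assigned
afterwards; pairs falling in the open gap ``d1 < d < d2`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

DNA = "ACGT"

__all__ = [
    "DNA",
    "LabeledPair",
    "CategoryDataset",
    "edit_distance",
    "random_sequence",
    "apply_random_edits",
    "fit_length",
    "generate_pair",
    "build_dataset",
    "label_pairs",
]


def _check_alphabet(s: str, alphabet: str) -> None:
    if not set(s) <= set(alphabet):
        bad = sorted(set(s) - set(alphabet))
        raise ValueError(f"sequence contains non-alphabet characters: {bad}")


def edit_distance(s: str, t: str) -> int:
    """Exact Levenshtein distance (unit-cost substitutions, indels).

    Backed by edlib's bit-parallel dynamic programming in NW (global) mode.
    """
    if s == t:
        return 0
    return edlib.align(s, t, mode="NW", task="distance")["editDistance"]


def bounded_edit_distance(s: str, t: str, bound: int) -> int | None:
    """Levenshtein distance if it is <= ``bound``, else ``None``.

    Uses a banded computation (band width ``2*bound + 1``) with early
    termination, so the cost per pair is O(bound * n) rather than O(n^2).
    """
    d = edlib.align(s, t, mode="NW", task="distance", k=bound)["editDistance"]
    return None if d == -1 else d


def random_sequence(n: int, rng: np.random.Generator, alphabet: str = DNA) -> str:
    """Uniform random sequence of length ``n`` over ``alphabet``."""
    idx = rng.integers(0, len(alphabet), size=n)
    lut = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    return lut[idx].tobytes().decode("ascii")


def apply_random_edits(
    s: str, count: int, rng: np.random.Generator, alphabet: str = DNA
) -> str:
    """Apply exactly ``count`` sequential random edits to ``s``.

    Each edit is a substitution, insertion, or deletion with probability 1/3,
    at a position chosen uniformly among the valid positions at that step.
    A substitution always changes the character (uniform over the other
    alphabet letters).  If the intermediate sequence is empty, edit types
    that need a character to act on are resampled.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    _check_alphabet(s, alphabet)
    chars = list(s)
    A = len(alphabet)
    # all randomness drawn up front (one stream read per kind, cheap for
    # the rejection-sampling loops upstream); the uniform floats are
    # floored against the step-dependent position counts
    kinds = rng.integers(3, size=count)
    pos_u = rng.random(size=count)
    char_u = rng.random(size=count)
    for i in range(count):
        kind = int(kinds[i])
        while not chars and kind != 1:  # only insertion is valid on empty
            kind = int(rng.integers(3))
        if kind == 0:  # substitution: always a different character
            pos = int(pos_u[i] * len(chars))
            others = alphabet.replace(chars[pos], "")
            chars[pos] = others[int(char_u[i] * (A - 1))]
        elif kind == 1:  # insertion
            pos = int(pos_u[i] * (len(chars) + 1))
            chars.insert(pos, alphabet[int(char_u[i] * A)])
        else:  # deletion
            pos = int(pos_u[i] * len(chars))
            del chars[pos]
    return "".join(chars)


def fit_length(
    s: str, n: int, rng: np.random.Generator, alphabet: str = DNA
) -> str:
    """Pad (uniform random characters, appended) or truncate ``s`` to length ``n``."""
    if len(s) > n:
        return s[:n]
    if len(s) < n:
        return s + random_sequence(n - len(s), rng, alphabet)
    return s


@dataclass(frozen=True)
class LabeledPair:
    """A pair of equal-length sequences with its true edit distance.

    ``y`` is -1 for similar pairs (``d <= d1``), +1 for dissimilar pairs
    (``d >= d2``), or ``None`` before labeling.
    """

    s: str
    t: str
    d: int
    y: int | None = None


@dataclass
class CategoryDataset:
    """Pairs grouped by their true edit distance ``d``."""

    n: int
    categories: dict[int, list[LabeledPair]] = field(default_factory=dict)

    @property
    def d_values(self) -> list[int]:
        return sorted(self.categories)

    def all_pairs(self) -> list[LabeledPair]:
        return [p for d in self.d_values for p in self.categories[d]]

    def __len__(self) -> int:
        return sum(len(v) for v in self.categories.values())


def generate_pair(
    n: int,
    d: int,
    delta: int,
    rng: np.random.Generator,
    alphabet: str = DNA,
) -> LabeledPair:
    """Generate one pair by applying ``d + delta`` edits to a random sequence.

    ``delta`` extra edits offset the cancellation of opposing edits.  The
    mutated sequence is padded/truncated back to length ``n`` and the pair is
    re-measured, so the stored distance ``d'`` may differ from the requested
    ``d``; the caller bins by ``d'``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if d < 0:
        raise ValueError("d must be non-negative")
    s = random_sequence(n, rng, alphabet)
    t = apply_random_edits(s, d + delta, rng, alphabet)
    t = fit_length(t, n, rng, alphabet)
    return LabeledPair(s=s, t=t, d=edit_distance(s, t))


def _category_rng(master_seed: int, d: int) -> np.random.Generator:
    # independent, reproducible stream per requested distance
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(d)]))


def build_dataset(
    n: int,
    d_range: list[int],
    count_per_category: int,
    delta: int = 2,
    seed: int = 0,
    alphabet: str = DNA,
    attempt_cap_factor: int = 1000,
) -> CategoryDataset:
    """Rejection-sample pairs until every category in ``d_range`` is full.

    Requested distances sweep ``d_range`` round-robin, each with its own
    seeded stream so the result is reproducible.  A generated pair is filed
    under its measured distance ``d'`` when that category is in range and
    not yet full; otherwise it is discarded.
    """
    if not d_range:
        raise ValueError("d_range must be non-empty")
    if count_per_category <= 0:
        raise ValueError("count_per_category must be positive")
    d_range = sorted(set(int(d) for d in d_range))
    cats: dict[int, list[LabeledPair]] = {d: [] for d in d_range}
    rngs = {d: _category_rng(seed, d) for d in d_range}
    attempts = {d: 0 for d in d_range}
    cap = attempt_cap_factor * count_per_category

    while True:
        unfull = [d for d in d_range if len(cats[d]) < count_per_category]
        if not unfull:
            break
        progressed = False
        for d in unfull:  # full categories stop drawing from their streams
            if attempts[d] >= cap:
                continue
            attempts[d] += 1
            progressed = True
            pair = generate_pair(n, d, delta, rngs[d], alphabet)
            bucket = cats.get(pair.d)
            if bucket is not None and len(bucket) < count_per_category:
                bucket.append(pair)
        if not progressed:
            short = [d for d in d_range if len(cats[d]) < count_per_category]
            raise RuntimeError(
                f"attempt cap exceeded; categories still short: {short}"
            )
    return CategoryDataset(n=n, categories=cats)


def label_pairs(dataset: CategoryDataset, d1: int, d2: int) -> list[LabeledPair]:
    """Assign labels y=-1 (d <= d1), y=+1 (d >= d2); drop the gap d1 < d < d2."""
    if not (0 < d1 < d2):
        raise ValueError("require 0 < d1 < d2")
    out: list[LabeledPair] = []
    for d in dataset.d_values:
        if d1 < d < d2:
            continue
        y = -1 if d <= d1 else 1
        out.extend(LabeledPair(p.s, p.t, p.d, y) for p in dataset.categories[d])
    return out
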