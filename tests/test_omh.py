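"""Order Min Hash: uniquification, codes, sketches, collisions, grid."""

import itertools
import math

import numpy as np
import pytest

from lsbucket import seqsim
from lsbucket.omh import (
    OMHParams,
    default_rank_fn,
    grid_search,
    group_collide_many,
    collide_many,
    omh_accuracy,
    omh_code,
    omh_collision,
    sketch,
    sketch_many,
    uniquified_kmers,
)


class TestUniquifiedKmers:
    def test_repeated_kmer_numbering(self):
        got = [(u.kmer, u.occ, u.pos) for u in uniquified_kmers("AAAA", 2)]
        assert got == [("AA", 1, 0), ("AA", 2, 1), ("AA", 3, 2)]

    def test_distinct_kmers_all_first_occurrence(self):
        got = uniquified_kmers("ACGT", 2)
        assert len(got) == 3 and all(u.occ == 1 for u in got)

    def test_count_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            k = int(rng.integers(2, n))
            s = seqsim.random_sequence(n, rng)
            assert len(uniquified_kmers(s, k)) == n - k + 1

    def test_too_long_kmer_rejected(self):
        with pytest.raises(ValueError):
            uniquified_kmers("ACG", 4)


class TestOmhCode:
    def test_take_all_reconstructs_positional_concatenation(self):
        x = "ACGTAC"
        params = OMHParams(k=2, l=5, m=1)  # l = n - k + 1: selection vacuous
        code = omh_code(x, params, default_rank_fn(0, 0))
        assert code == "".join(x[i : i + 2] for i in range(5))

    def test_identical_sequences_identical_codes(self):
        params = OMHParams(k=2, l=2, m=1)
        rank = default_rank_fn(3, 0)
        assert omh_code("ACGTAC", params, rank) == omh_code("ACGTAC", params, rank)

    def test_agrees_with_materialized_permutation_oracle(self):
        """Brute-force oracle: explicitly rank all 5 uniquified kmers of
        'ACGTAC' under every permutation of them and re-derive the code."""
        x = "ACGTAC"
        params = OMHParams(k=2, l=2, m=1)
        kmers = uniquified_kmers(x, 2)
        for perm in itertools.permutations(range(5)):
            rank_of = {
                (u.kmer, u.occ): perm[i] for i, u in enumerate(kmers)
            }
            rank_fn = lambda km, occ: rank_of[(km, occ)]
            got = omh_code(x, params, rank_fn)
            chosen = sorted(kmers, key=lambda u: rank_of[(u.kmer, u.occ)])[:2]
            expect = "".join(u.kmer for u in sorted(chosen, key=lambda u: u.pos))
            assert got == expect


class TestSketch:
    def test_identical_sequences_identical_sketches(self):
        p = OMHParams(k=3, l=2, m=5, seed=1)
        assert sketch("ACGTACGTAC", p) == sketch("ACGTACGTAC", p)

    def test_deterministic_under_seed(self):
        p = OMHParams(k=3, l=2, m=4, seed=9)
        a = sketch_many(["ACGTACGTAC", "TTGGCCAATT"], p)
        b = sketch_many(["ACGTACGTAC", "TTGGCCAATT"], p)
        np.testing.assert_array_equal(a, b)

    def test_string_sketch_matches_integer_core(self):
        """The human-readable sketch decodes the vectorized integer codes."""
        x, p = "ACGTACGTAC", OMHParams(k=3, l=2, m=4, seed=5)
        s = sketch(x, p)
        assert all(len(c) == 6 for c in s.codes)
        # rebuild each code from the integer core
        core = sketch_many([x], p)[0]
        for g in range(p.m):
            decoded = ""
            for v in core[g]:
                v = int(v)
                part = ""
                for _ in range(3):
                    part = "ACGT"[v % 4] + part
                    v //= 4
                decoded += part
            assert decoded == s.codes[g]

    def test_collision_probability_matches_exhaustive_enumeration(self):
        """Single-group collision probability of a toy pair equals the
        exact value from enumerating every relative order of the union of
        their uniquified kmers.

        s = AAAAAA has kmers (AA,1..5); t = AAAAAC has (AA,1..4), (AC,1):
        union of 6 elements, 720 orderings, each equally likely under a
        random rank function.
        """
        s, t = "AAAAAA", "AAAAAC"
        k, l = 2, 2
        us, ut = uniquified_kmers(s, k), uniquified_kmers(t, k)
        union = sorted({(u.kmer, u.occ) for u in us + ut})

        def code(useq, rank_of):
            chosen = sorted(useq, key=lambda u: rank_of[(u.kmer, u.occ)])[:l]
            return "".join(u.kmer for u in sorted(chosen, key=lambda u: u.pos))

        hits = 0
        perms = list(itertools.permutations(range(len(union))))
        for perm in perms:
            rank_of = {e: perm[i] for i, e in enumerate(union)}
            hits += code(us, rank_of) == code(ut, rank_of)
        exact = hits / len(perms)

        trials = 3000
        mc = 0
        for seed in range(trials):
            p1 = OMHParams(k=k, l=l, m=1, seed=seed)
            ca, cb = sketch_many([s], p1), sketch_many([t], p1)
            mc += bool(collide_many(ca, cb)[0])
        mc /= trials
        sigma = math.sqrt(exact * (1 - exact) / trials)
        assert abs(mc - exact) < max(4 * sigma, 0.02)


class TestCollision:
    def test_self_collision(self):
        p = OMHParams(k=3, l=2, m=3, seed=2)
        sk = sketch("ACGTACGTAC", p)
        assert omh_collision(sk, sk)

    def test_group_count_mismatch(self):
        a = sketch("ACGTACGTAC", OMHParams(k=3, l=2, m=2, seed=0))
        b = sketch("ACGTACGTAC", OMHParams(k=3, l=2, m=3, seed=0))
        with pytest.raises(ValueError):
            omh_collision(a, b)

    def test_boosting_closed_form(self, rng):
        """m-group collision rate across seeds matches 1 - (1-p)^m for the
        single-group rate p of the same pair."""
        s = "ACGTACGTACGTACGTACGT"
        t = seqsim.fit_length(seqsim.apply_random_edits(s, 3, rng), 20, rng)
        trials = 800
        single = np.zeros(trials, dtype=bool)
        multi = np.zeros(trials, dtype=bool)
        for seed in range(trials):
            p1 = OMHParams(k=4, l=2, m=1, seed=seed)
            p5 = OMHParams(k=4, l=2, m=5, seed=seed)
            single[seed] = collide_many(sketch_many([s], p1), sketch_many([t], p1))[0]
            multi[seed] = collide_many(sketch_many([s], p5), sketch_many([t], p5))[0]
        p = single.mean()
        expect = 1 - (1 - p) ** 5
        sigma = math.sqrt(max(expect * (1 - expect), 1e-4) / trials)
        assert abs(multi.mean() - expect) < max(4 * sigma, 0.05)

    def test_always_collides_when_single_group_certain(self):
        # identical sequences: p = 1 so any m collides
        for m in (1, 3, 8):
            p = OMHParams(k=3, l=2, m=m, seed=4)
            a = sketch("ACGTACGTAC", p)
            b = sketch("ACGTACGTAC", p)
            assert omh_collision(a, b)

    def test_boosting_monotone_in_m_with_nested_salts(self, rng):
        """With one seed the group salts are a prefix stream, so adding
        groups can only add collisions."""
        s = "ACGTACGTACGTACGT"
        t = seqsim.fit_length(seqsim.apply_random_edits(s, 2, rng), 16, rng)
        prev = False
        for m in (1, 2, 4, 8, 16):
            p = OMHParams(k=4, l=2, m=m, seed=11)
            now = bool(collide_many(sketch_many([s], p), sketch_many([t], p))[0])
            assert now or not prev
            prev = prev or now


class TestAccuracy:
    def test_family_mode_matches_per_group_loop(self, small_dataset):
        params = OMHParams(k=4, l=2, m=6, seed=3)
        report = omh_accuracy(small_dataset, params, 1, 2)
        for d, pairs in small_dataset.categories.items():
            ca = sketch_many([p.s for p in pairs], params)
            cb = sketch_many([p.t for p in pairs], params)
            fracs = []
            for i in range(len(pairs)):
                hit = np.mean(
                    [np.array_equal(ca[i, g], cb[i, g]) for g in range(6)]
                )
                fracs.append(hit if d <= 1 else 1 - hit)
            assert report.per_category[d] == pytest.approx(np.mean(fracs))

    def test_boosted_mode_matches_sketch_collision_loop(self, small_dataset):
        params = OMHParams(k=4, l=2, m=6, seed=3)
        report = omh_accuracy(small_dataset, params, 1, 2, mode="boosted")
        for d, pairs in small_dataset.categories.items():
            correct = []
            for p in pairs:
                c = omh_collision(sketch(p.s, params), sketch(p.t, params))
                correct.append(c if d <= 1 else not c)
            assert report.per_category[d] == pytest.approx(np.mean(correct))

    def test_take_all_degenerate_accuracy_zero_for_similars(self):
        """With l = n - k + 1 the code determines the sequence, so only
        identical sequences collide and every d=1 pair is missed."""
        ds = seqsim.build_dataset(n=8, d_range=[1, 2], count_per_category=20, seed=5)
        params = OMHParams(k=2, l=7, m=4, seed=1)
        report = omh_accuracy(ds, params, 1, 2, mode="boosted")
        assert report.per_category[1] == 0.0
        assert report.per_category[2] == 1.0


@pytest.fixture(scope="module")
def grid_result():
    ds = seqsim.build_dataset(
        n=10, d_range=[1, 2, 3, 4], count_per_category=30, seed=21
    )
    return grid_search(ds, 1, 2, m=5, seed=2)


class TestGridSearch:
    def test_grid_covers_expected_settings(self, grid_result):
        _, _, table = grid_result
        n = 10
        expect = sum(max(0, n - k - 1) for k in range(2, n + 1))
        assert len(table) == expect
        assert {(r["k"], r["l"]) for r in table} == {
            (k, l) for k in range(2, n + 1) for l in range(2, n - k + 1)
        }

    def test_argmax_consistent_with_table(self, grid_result):
        best, report, table = grid_result
        top = max(r["overall"] for r in table)
        assert report.overall == top
        winners = sorted(
            (r["k"], r["l"]) for r in table if r["overall"] == top
        )
        assert (best.k, best.l) == winners[0]  # ties: smaller k then l
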