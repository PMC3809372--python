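"""Pigeonhole off-target search vs an exhaustive Hamming-scan oracle."""

import numpy as np
import pytest

from grnadesign import (
    Genome,
    SearchParams,
    Uniqueness,
    build_index,
    classify_uniqueness,
    find_hits,
    reverse_complement,
)
from oracles import brute_force_hits

RNG = np.random.default_rng(20130427)
BASES = np.array(list("ACGT"))


def random_seq(n, rng=RNG):
    return "".join(rng.choice(BASES, size=n))


def genome_with(seqs_at, length=5000, rng=RNG):
    """A random genome with given 23-mers written at given 0-based offsets."""
    arr = list(random_seq(length, rng))
    for pos, s in seqs_at:
        arr[pos : pos + 23] = list(s)
    g = Genome()
    g.add("chr1", "".join(arr))
    return g


def hits_as_tuples(summary):
    return [
        (h.region.chrom, h.region.start, h.region.strand, h.mismatches)
        for h in summary.hits
    ]


def mutate(seq, positions, rng=RNG):
    chars = list(seq)
    for p in positions:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


class TestFindHits:
    def test_implanted_query_is_its_own_unique_hit(self):
        q = random_seq(23)
        g = genome_with([(1000, q)])
        s = find_hits(q, build_index(g))
        exp = brute_force_hits(g.records, q, 1)
        assert hits_as_tuples(s) == exp
        assert s.n_hits_reported >= 1 and s.hits[0].mismatches == 0

    def test_one_mismatch_copy_found_two_excluded(self):
        q = random_seq(23)
        near = mutate(q, [7])
        far = mutate(q, [3, 15])
        g = genome_with([(500, q), (2000, near), (4000, far)])
        s = find_hits(q, build_index(g))
        assert hits_as_tuples(s) == brute_force_hits(g.records, q, 1)
        assert sorted(h.mismatches for h in s.hits) == [0, 1]

    def test_mismatch_positions_annotate_the_differing_offsets(self):
        from grnadesign.genome import GenomicRegion, fetch

        q = random_seq(23)
        near = mutate(q, [0, ])
        g = genome_with([(2000, near)])
        s = find_hits(q, build_index(g))
        (hit,) = [h for h in s.hits if h.mismatches == 1]
        fetched = fetch(g, hit.region)
        diffs = tuple(i + 1 for i, (a, b) in enumerate(zip(q, fetched)) if a != b)
        assert hit.mismatch_positions == diffs

    def test_cap_and_truncated_flag(self):
        q = random_seq(23)
        g = genome_with([(i * 100, q) for i in range(12)], length=3000)
        s = find_hits(q, build_index(g))
        assert s.n_hits_reported == 10 and s.truncated
        s0 = find_hits(q, build_index(g, SearchParams(max_hits=15)))
        assert s0.n_hits_reported == 12 and not s0.truncated

    @pytest.mark.parametrize("bad", ["ACGT", "A" * 22 + "N"])
    def test_bad_query_errors(self, bad):
        g = genome_with([])
        with pytest.raises(ValueError):
            find_hits(bad, build_index(g))

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_index(Genome())

    def test_genome_shorter_than_query_yields_nothing(self):
        g = Genome()
        g.add("chr1", "ACGTACGTACGT")
        assert find_hits(random_seq(23), build_index(g)).n_hits_reported == 0

    def test_n_in_genome_never_matches(self):
        q = random_seq(23)
        withN = q[:10] + "N" + q[11:]
        g = genome_with([(1000, withN)])
        s = find_hits(q, build_index(g))
        # the N position counts as a mismatch even where the query also had it
        assert all(11 in h.mismatch_positions for h in s.hits if h.region.start == 1001)

    def test_strand_symmetry(self):
        q = random_seq(23)
        g = genome_with([(700, q), (2500, mutate(q, [4]))])
        idx = build_index(g)
        fwd = hits_as_tuples(find_hits(q, idx))
        rev = hits_as_tuples(find_hits(reverse_complement(q), idx))
        flipped = sorted(
            (c, s, "-" if st == "+" else "+", m) for c, s, st, m in rev
        )
        assert sorted(fwd) == flipped

    def test_zero_mismatch_hits_subset_of_one(self):
        q = random_seq(23)
        g = genome_with([(500, q), (2000, mutate(q, [9]))])
        h0 = set(hits_as_tuples(find_hits(q, build_index(g, SearchParams(max_mismatches=0)))))
        h1 = set(hits_as_tuples(find_hits(q, build_index(g, SearchParams(max_mismatches=1)))))
        assert {t[:3] for t in h0} <= {t[:3] for t in h1}

    def test_rebuilt_index_is_deterministic(self):
        q = random_seq(23)
        g = genome_with([(123, q)])
        a = hits_as_tuples(find_hits(q, build_index(g)))
        b = hits_as_tuples(find_hits(q, build_index(g)))
        assert a == b

    def test_two_mismatch_mode_matches_oracle(self):
        rng = np.random.default_rng(5)
        q = random_seq(23, rng)
        g = genome_with([(500, q), (2000, mutate(q, [3, 15], rng))], rng=rng)
        s = find_hits(q, build_index(g, SearchParams(max_mismatches=2)))
        assert hits_as_tuples(s) == brute_force_hits(g.records, q, 2)


class TestOracleEquivalence:
    def test_randomized_small_genomes(self):
        """200 seeded random instances; acceptance suite runs the full sweep."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            L = int(rng.integers(100, 3000))
            g = Genome()
            g.add("chr1", random_seq(L, rng))
            if rng.random() < 0.6 and L > 50:
                pos = int(rng.integers(0, L - 23))
                q = g.records["chr1"][pos : pos + 23]
                if rng.random() < 0.5:
                    q = mutate(q, rng.choice(23, rng.integers(1, 3), replace=False), rng)
            else:
                q = random_seq(23, rng)
            for mm in (0, 1):
                got = hits_as_tuples(
                    find_hits(q, build_index(g, SearchParams(max_mismatches=mm, max_hits=1000)))
                )
                assert got == brute_force_hits(g.records, q, mm)


class TestClassifyUniqueness:
    def make(self, n, truncated=False):
        from grnadesign.genome import GenomicRegion
        from grnadesign.offtarget import AlignmentHit, HitSummary

        hits = [AlignmentHit(GenomicRegion("c", 1 + i * 30, 23 + i * 30, "+"), 0) for i in range(n)]
        return HitSummary(hits=hits, truncated=truncated)

    @pytest.mark.parametrize(
        "n,truncated,expected",
        [
            (1, False, Uniqueness.UNIQUE),
            (2, False, Uniqueness.MULTI),
            (0, False, Uniqueness.UNMAPPED),
            (1, True, Uniqueness.MULTI),
        ],
    )
    def test_classification(self, n, truncated, expected):
        assert classify_uniqueness(self.make(n, truncated)) is expected
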