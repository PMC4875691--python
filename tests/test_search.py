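import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bamphy._errors import ArgumentError, DataError
from bamphy.search import (
    FilterPolicy,
    LocalHit,
    ScoringScheme,
    bit_score_evalue,
    filter_hits,
    percent_identity,
    read_hit_table,
    score_local_alignment,
    seeded_search,
    write_hit_table,
)

from _oracles import kmers, nuc_score_fn, revcomp, sw_affine_best_score


def make_hit(evalue=1e-6, length=150, identity=0.8):
    return LocalHit(
        query_id="q", subject_id="s", raw_score=100, bit_score=50.0,
        evalue=evalue, identity=identity, aln_length=length, mismatches=0,
        gap_opens=0, q_start=0, q_end=min(length, 100), s_start=0,
        s_end=min(length, 100),
    )


class TestScoreLocalAlignment:
    def test_identical_sequences(self):
        scheme = ScoringScheme.nucleotide(match=1, mismatch=-1)
        hit = score_local_alignment("ACGTACGT", "ACGTACGT", scheme)
        assert hit.raw_score == 8
        assert hit.identity == 1.0
        assert hit.aln_length == 8

    def test_matches_brute_force_on_8mers(self):
        scheme = ScoringScheme.nucleotide(match=2, mismatch=-1, gap_open=2, gap_extend=1)
        hit = score_local_alignment("ACACACTA", "AGCACACA", scheme)
        expected = sw_affine_best_score(
            "ACACACTA", "AGCACACA", nuc_score_fn(2, -1), 2, 1
        )
        assert hit.raw_score == expected

    def test_disjoint_alphabets_give_no_hit(self):
        scheme = ScoringScheme.nucleotide(match=1, mismatch=-1)
        assert score_local_alignment("AAAA", "TTTT", scheme) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ArgumentError):
            score_local_alignment("", "ACGT")

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(DataError):
            score_local_alignment("ACGU", "ACGT")

    def test_coordinates_reproduce_aligned_residues(self, rng):
        scheme = ScoringScheme.nucleotide()
        for _ in range(25):
            q = "".join(rng.choice(list("ACGT"), 60))
            s = q[10:50] + "".join(rng.choice(list("ACGT"), 20))
            hit = score_local_alignment(q, s, scheme)
            if hit is None:
                continue
            assert hit.query_row.replace("-", "") == q[hit.q_start:hit.q_end]
            assert hit.subject_row.replace("-", "") == s[hit.s_start:hit.s_end]

    def test_symmetric_scheme_symmetric_score(self, rng):
        scheme = ScoringScheme.nucleotide()
        for _ in range(25):
            q = "".join(rng.choice(list("ACGT"), 40))
            s = "".join(rng.choice(list("ACGT"), 40))
            hq = score_local_alignment(q, s, scheme)
            hs = score_local_alignment(s, q, scheme)
            assert (hq is None) == (hs is None)
            if hq is not None:
                assert hq.raw_score == hs.raw_score


class TestSeededSearch:
    def test_exact_copy(self):
        q = "ACGTTGCAAGGCTTAACGGTACGTTGCAAGGCTTAACGGT"
        hits = seeded_search([("q", q)], [("s", q)], word_size=11)
        assert len(hits) == 1
        assert hits[0].identity == 1.0
        assert hits[0].aln_length == len(q)

    def test_reverse_complement_found_on_minus_strand(self):
        q = "ACGTTGCAAGGCTTAACGGT" * 3
        hits = seeded_search([("q", q)], [("s", revcomp(q))], word_size=11)
        assert len(hits) == 1
        assert hits[0].subject_strand == "-"
        assert hits[0].identity == 1.0

    def test_planted_similar_subject_is_top_hit(self, rng):
        scheme = ScoringScheme.nucleotide()
        query = "".join(rng.choice(list("ACGT"), 1000))
        planted = list(query)
        for i in rng.choice(1000, 100, replace=False):  # 90 % identity
            planted[i] = rng.choice([c for c in "ACGT" if c != planted[i]])
        planted = "".join(planted)
        subjects = [
            (f"r{i}", "".join(rng.choice(list("ACGT"), 1000))) for i in range(10)
        ] + [("planted", planted)]
        hits = seeded_search([("q", query)], subjects, scheme, word_size=11)
        top = max(hits, key=lambda h: h.bit_score)
        assert top.subject_id == "planted"
        # verified independently: exhaustive DP scores for every subject
        fn = nuc_score_fn(scheme.match, scheme.mismatch)
        dp = {
            sid: max(
                sw_affine_best_score(query, s, fn, scheme.gap_open, scheme.gap_extend),
                sw_affine_best_score(query, revcomp(s), fn, scheme.gap_open, scheme.gap_extend),
            )
            for sid, s in subjects
        }
        assert max(dp, key=dp.get) == "planted"

    def test_agrees_with_brute_force_on_short_pairs(self, rng):
        """Word-seeded search equals exhaustive DP whenever a seed exists
        (200 random pairs here; the full 1,000-pair sweep runs in the
        acceptance suite)."""
        scheme = ScoringScheme.nucleotide()
        fn = nuc_score_fn(scheme.match, scheme.mismatch)
        for _ in range(200):
            q = "".join(rng.choice(list("ACGT"), rng.integers(10, 31)))
            s = "".join(rng.choice(list("ACGT"), rng.integers(10, 31)))
            hits = seeded_search([("q", q)], [("s", s)], scheme, word_size=4)
            fwd_seed = bool(kmers(q, 4) & kmers(s, 4))
            rev_seed = bool(kmers(revcomp(q), 4) & kmers(s, 4))
            if not hits:
                assert not fwd_seed and not rev_seed
                continue
            best = sw_affine_best_score(q, s, fn, scheme.gap_open, scheme.gap_extend)
            if rev_seed:
                best = max(
                    best,
                    sw_affine_best_score(q, revcomp(s), fn, scheme.gap_open, scheme.gap_extend),
                )
            assert hits[0].raw_score == best

    def test_word_size_floor(self):
        with pytest.raises(ArgumentError):
            seeded_search([("q", "ACGTACGT")], [("s", "ACGTACGT")], word_size=3)


class TestStatistics:
    def test_closed_form_bits_and_evalue(self):
        scheme = ScoringScheme.nucleotide(lam=math.log(2), K=1.0)
        bits, evalue = bit_score_evalue(20, scheme, 100, 100)
        assert bits == pytest.approx(20.0)
        assert evalue == pytest.approx(1e4 * 2**-20)

    def test_monotone_in_score(self):
        scheme = ScoringScheme.nucleotide()
        pairs = [bit_score_evalue(s, scheme, 500, 500) for s in range(10, 100, 10)]
        bits = [b for b, _ in pairs]
        evs = [e for _, e in pairs]
        assert bits == sorted(bits) and len(set(bits)) == len(bits)
        assert evs == sorted(evs, reverse=True) and len(set(evs)) == len(evs)

    def test_evalue_linear_in_database_length(self):
        scheme = ScoringScheme.nucleotide()
        _, e1 = bit_score_evalue(50, scheme, 100, 1000)
        _, e2 = bit_score_evalue(50, scheme, 100, 2000)
        assert e2 == pytest.approx(2 * e1)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ArgumentError):
            bit_score_evalue(50, ScoringScheme.nucleotide(), 0, 100)


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("AC-T", "ACGT", 0.75),
            ("ACGTACGTAC", "ACGTTCGTAC", 0.9),
        ],
    )
    def test_examples(self, a, b, expected):
        assert percent_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            percent_identity("ACG", "ACGT")

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT-"), st.sampled_from("ACGT-")),
            min_size=1, max_size=50,
        ).filter(lambda cols: any(a != "-" or b != "-" for a, b in cols))
    )
    @settings(deadline=None, derandomize=True)
    def test_symmetric(self, cols):
        a = "".join(x for x, _ in cols)
        b = "".join(y for _, y in cols)
        assert percent_identity(a, b) == percent_identity(b, a)


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,length,identity,kept",
        [
            (1e-6, 150, 0.80, True),
            (1e-6, 99, 0.99, False),
            (1e-6, 150, 0.6999, False),
            (1e-6, 150, 0.70, True),
            (1e-5, 100, 0.70, True),   # thresholds inclusive
            (1.1e-5, 150, 0.80, False),
        ],
    )
    def test_threshold_boundaries(self, evalue, length, identity, kept):
        hits = filter_hits([make_hit(evalue, length, identity)])
        assert bool(hits) is kept

    def test_idempotent_and_order_preserving(self, rng):
        hits = [
            make_hit(
                float(10.0 ** rng.uniform(-8, -3)),
                int(rng.integers(50, 200)),
                float(rng.uniform(0.5, 1.0)),
            )
            for _ in range(50)
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert [id(h) for h in once] == [id(h) for h in hits if h in once]


def test_hit_table_round_trip(tmp_path, rng):
    scheme = ScoringScheme.nucleotide()
    q = "".join(rng.choice(list("ACGT"), 200))
    hits = seeded_search(
        [("q", q)], [("fwd", q), ("rev", revcomp(q))], scheme, word_size=11
    )
    path = tmp_path / "hits.tsv"
    write_hit_table(path, hits)
    back = read_hit_table(path)
    assert len(back) == len(hits) == 2
    for a, b in zip(hits, back):
        assert (a.query_id, a.subject_id, a.subject_strand) == (
            b.query_id, b.subject_id, b.subject_strand
        )
        assert (a.q_start, a.q_end, a.s_start, a.s_end) == (
            b.q_start, b.q_end, b.s_start, b.s_end
        )
        assert b.identity == pytest.approx(a.identity, abs=5e-5)
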