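from fractions import Fraction

import pytest

from softsample import (
    LocalAlignment,
    SamplingParams,
    SequenceRecord,
    brute_force_hslas,
    brute_force_mems,
    build_index,
    compute_kstar,
    compute_w0,
    dedup_alignments,
    extend_to_mem,
    extract_query_kmers,
    find_mems,
    gapped_extend,
    generate_genome,
    plant_alignment,
    search_hsla,
)
from softsample.search import Mem


class TestThresholds:
    @pytest.mark.parametrize(
        "l,t,kstar,w0",
        [(50, 0.96, 16, 5), (100, 0.97, 25, 14),
         (200, 0.97, 28, 17), (400, 0.97, 30, 19)],
    )
    def test_parameter_grid(self, l, t, kstar, w0):
        """k* and w0 derivations over the standard (l, t) grid."""
        assert compute_kstar(l, t) == kstar
        assert compute_w0(kstar, 12) == w0

    def test_zero_error_degenerate(self):
        assert compute_kstar(12, 1.0) == 12
        assert compute_w0(12, 12) == 1

    def test_kstar_below_kprime_rejected(self):
        with pytest.raises(ValueError):
            compute_w0(10, 12)


class TestQueryKmers:
    def test_every_position_extracted(self):
        q = SequenceRecord("q", "ACGTA")
        assert extract_query_kmers(q, 4) == [("ACGT", 3), ("CGTA", 4)]

    def test_homopolymer_single_kmer(self):
        assert extract_query_kmers(SequenceRecord("q", "AAAA"), 4) == \
            [("AAAA", 3)]

    def test_ambiguous_windows_skipped(self):
        assert extract_query_kmers(SequenceRecord("q", "ACNTA"), 4) == []

    def test_query_shorter_than_kprime(self):
        assert extract_query_kmers(SequenceRecord("q", "ACG"), 4) == []


class TestMemExtension:
    def test_extends_both_directions(self):
        s = SequenceRecord("s", "AAACGTTT")
        q = SequenceRecord("q", "CCACGTGG")
        mem = extend_to_mem(s, q, "s", 4, 4, 3)
        assert mem == Mem("s", 2, 2, 4)

    def test_identical_sequences_full_length(self):
        s = SequenceRecord("s", "ACGTACGT")
        mem = extend_to_mem(s, s, "s", 2, 2, 3)
        assert mem == Mem("s", 0, 0, 8)

    def test_no_extension_at_boundary_mismatch(self):
        s = SequenceRecord("s", "ACGT")
        q = SequenceRecord("q", "ACGA")
        mem = extend_to_mem(s, q, "s", 2, 2, 3)
        assert mem == Mem("s", 0, 0, 3)

    def test_mismatched_seed_rejected(self):
        s = SequenceRecord("s", "AAAA")
        q = SequenceRecord("q", "TTTT")
        with pytest.raises(ValueError, match="seed"):
            extend_to_mem(s, q, "s", 2, 2, 3)


class TestFindMems:
    @pytest.mark.parametrize("trial", range(10))
    def test_w1_equals_brute_force(self, trial):
        """Unsampled seeding discovers exactly the exhaustive MEM set."""
        g = generate_genome(200, seed=trial)
        inst = plant_alignment(g, 80, 3, seed=trial)
        g, q = inst.genome, inst.query
        ix = build_index([g], 12, 1)
        assert set(find_mems(ix, [g], q, 12)) == \
            set(brute_force_mems(g, q, min_length=12))

    def test_unrelated_query_yields_nothing(self):
        g = SequenceRecord("g", "A" * 100)
        q = SequenceRecord("q", "C" * 50)
        ix = build_index([g], 12, 1)
        assert find_mems(ix, [g], q, 12) == []

    def test_long_mem_found_at_any_phase(self):
        """A MEM of length w + k' - 1 always contains a sampled k'-mer."""
        kprime, w = 6, 5
        core = "ACGTTGCAAC"  # length w + kprime - 1
        for pad in range(w):
            g = SequenceRecord("g", "T" * (20 + pad) + core + "T" * 20)
            q = SequenceRecord("q", "G" * 5 + core + "G" * 5)
            ix = build_index([g], kprime, w)
            mems = find_mems(ix, [g], q, len(core))
            assert any(m.length >= len(core) for m in mems), pad


class TestGappedExtend:
    def test_planted_substitutions_accepted(self):
        g = generate_genome(200, seed=5)
        inst = plant_alignment(g, 50, 2, seed=5)
        g, q = inst.genome, inst.query
        ix = build_index([g], 12, 1)
        mems = find_mems(ix, [g], q, 16)
        aln = gapped_extend(g, q, mems[0], l=50, t=0.96)
        truth = inst.truth[0]
        assert aln.length == 50
        assert aln.match_count == 48
        assert aln.mp == Fraction(48, 50)
        assert aln.key() == truth.key()

    def test_identity_alignment(self):
        s = SequenceRecord("s", "ACGTACGTACGTACGTACGT")
        mem = extend_to_mem(s, s, "s", 5, 5, 3)
        aln = gapped_extend(s, s, mem, l=20, t=0.96)
        assert (aln.length, aln.mp, aln.errors) == (20, Fraction(1), 0)

    def test_short_candidate_reported_below_length(self):
        # 20 bp of identity inside otherwise unrelated sequences
        core = "ACGTTGCAACGGATCCATGC"
        s = SequenceRecord("s", "T" * 20 + core + "T" * 20)
        q = SequenceRecord("q", "G" * 20 + core + "G" * 20)
        mem = brute_force_mems(s, q, min_length=16)[0]
        aln = gapped_extend(s, q, mem, l=50, t=0.96, kstar=16)
        assert aln is not None and 16 <= aln.length < 50

    def test_negative_band_rejected(self):
        s = SequenceRecord("s", "ACGTACGTACGTACGT")
        mem = Mem("s", 0, 0, 16)
        with pytest.raises(ValueError, match="band"):
            gapped_extend(s, s, mem, l=16, t=1.0, band=-1)

    def test_metric_identities_hold(self):
        """|A| = |x| + |y| - map and E = |A| - match on every output."""
        for trial in range(10):
            g = generate_genome(300, seed=trial)
            inst = plant_alignment(g, 60, 2, indels=trial % 2, seed=trial)
            g, q = inst.genome, inst.query
            ix = build_index([g], 12, 1)
            params = SamplingParams(l=60, t=0.95, kprime=12, kstar=15, w=1)
            hslas, _ = search_hsla(ix, [g], q, params)
            assert hslas
            for a in hslas:
                assert a.length == a.db_span + a.q_span - a.map_count
                assert a.errors == a.length - a.match_count
                if a.map_count == a.db_span == a.q_span:
                    assert a.length == a.db_span


def make_alignment(db, q, map_count, match_count, seq="s"):
    return LocalAlignment(seq, db, q, map_count, match_count)


class TestDedup:
    def test_dominated_overlap_removed(self):
        a = make_alignment((0, 100), (0, 100), 100, 98)
        b = make_alignment((10, 90), (10, 90), 80, 78)
        assert dedup_alignments([a, b]) == [a]

    def test_disjoint_kept(self):
        a = make_alignment((0, 50), (0, 50), 50, 49)
        b = make_alignment((100, 150), (100, 150), 50, 49)
        assert dedup_alignments([a, b]) == [a, b]

    def test_tie_breaks_on_match_percentage(self):
        a = make_alignment((0, 100), (0, 100), 100, 98)
        b = make_alignment((0, 100), (2, 102), 100, 97)
        assert dedup_alignments([a, b]) == [a]

    def test_transitive_closure_groups_chain(self):
        a = make_alignment((0, 60), (0, 60), 60, 59)
        b = make_alignment((30, 90), (30, 90), 60, 58)
        c = make_alignment((60, 120), (60, 120), 60, 57)
        # a~b and b~c overlap 50%; a and c are disjoint but share the group
        assert dedup_alignments([a, b, c]) == [a]


class TestSearch:
    def test_planted_alignment_recovered(self):
        g = generate_genome(400, seed=7)
        inst = plant_alignment(g, 50, 2, seed=7)
        params = SamplingParams(l=50, t=0.96, kprime=12, w=1)
        ix = build_index([inst.genome], 12, 1)
        hslas, fp = search_hsla(ix, [inst.genome], inst.query, params)
        assert [a.key() for a in hslas] == [inst.truth[0].key()]

    def test_parameter_mismatch_rejected(self, genome_1kb):
        ix = build_index([genome_1kb], 12, 5)
        params = SamplingParams(l=50, t=0.96, kprime=12, w=3)
        with pytest.raises(ValueError, match="params"):
            search_hsla(ix, [genome_1kb], genome_1kb, params)

    def test_kstar_match_that_cannot_reach_l_is_false_positive(self):
        core = "ACGTTGCAACGGATCC"  # 16 bp = k* for l=50, t=0.96
        g = SequenceRecord("g", "T" * 30 + core + "T" * 30)
        q = SequenceRecord("q", "G" * 30 + core + "G" * 30)
        params = SamplingParams(l=50, t=0.96, kprime=12, w=1)
        ix = build_index([g], 12, 1)
        hslas, fp = search_hsla(ix, [g], q, params)
        assert hslas == [] and fp == 1

    @pytest.mark.parametrize("w", [2, 3, 5])
    def test_hard_sampling_equals_unsampled(self, w):
        """Any w <= w0 returns exactly the w = 1 result."""
        for trial in range(20):
            g = generate_genome(500, seed=trial)
            inst = plant_alignment(g, 50, 2, seed=trial)
            g = inst.genome
            h1, _ = search_hsla(
                build_index([g], 12, 1), [g], inst.query,
                SamplingParams(l=50, t=0.96, kprime=12, w=1))
            hw, _ = search_hsla(
                build_index([g], 12, w), [g], inst.query,
                SamplingParams(l=50, t=0.96, kprime=12, w=w))
            assert {a.key() for a in h1} == {a.key() for a in hw}

    def test_seed_soundness(self):
        """Every reported HSLA contains a sampled k'-mer extending to >= k*."""
        for trial in range(10):
            g = generate_genome(600, seed=100 + trial)
            inst = plant_alignment(g, 50, 2, seed=trial)
            g = inst.genome
            w = 8
            params = SamplingParams(l=50, t=0.96, kprime=12, w=w)
            ix = build_index([g], 12, w)
            hslas, _ = search_hsla(ix, [g], inst.query, params)
            mems = find_mems(ix, [g], inst.query, params.kstar)
            for a in hslas:
                assert any(
                    a.db_interval[0] <= m.db_start
                    and m.db_end <= a.db_interval[1]
                    for m in mems
                )

    def test_reverse_strand_found_when_enabled(self):
        g = generate_genome(300, seed=11)
        inst = plant_alignment(g, 50, 1, seed=11)
        g = inst.genome
        rc_query = inst.query.reverse_complement()
        params = SamplingParams(l=50, t=0.96, kprime=12, w=1)
        ix = build_index([g], 12, 1)
        fwd, _ = search_hsla(ix, [g], rc_query, params)
        assert fwd == []
        both, _ = search_hsla(ix, [g], rc_query, params, both_strands=True)
        assert len(both) == 1 and both[0].strand == "-"


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(20))
    def test_search_matches_exhaustive_dp(self, trial):
        """w=1 search and the unbanded DP oracle agree on the best (|A|, mp)."""
        if trial % 2 == 0:
            inst = plant_alignment(
                generate_genome(60, seed=100 + trial), 30, 1, seed=trial)
            g, q = inst.genome, inst.query
        else:
            g = generate_genome(60, seed=100 + trial)
            q = generate_genome(60, seed=500 + trial, seq_id="q")
        params = SamplingParams(l=30, t=0.96, kprime=8, w=1)
        ix = build_index([g], 8, 1)
        hslas, _ = search_hsla(ix, [g], q, params)
        oracle = brute_force_hslas(g, q, 30, 0.96)
        got = max(((a.length, a.mp) for a in hslas), default=None)
        want = max(((a.length, a.mp) for a in oracle), default=None)
        assert got == want
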