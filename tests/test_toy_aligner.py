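"""The toy seed-filter-extend aligner: seeds, HSPs, y-drop DP, suppression."""

import numpy as np
import pytest

from diagpart import Segment, align, coverage, find_seeds, simulate_pair
from diagpart._ydrop import ydrop_extend
from diagpart.scoring import encode, hoxd70, revcomp, simple_scheme
from diagpart.toy_aligner import gapped_extend, ungapped_extend


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# small scheme with low thresholds so short test sequences produce HSPs
SMALL = simple_scheme(10, -9, gap_open=15, gap_extend=5, x_drop=40, y_drop=60,
                      hsp_threshold=30)


class TestFindSeeds:
    def test_self_match(self):
        seeds = find_seeds("ACGTACGT", "ACGTACGT", k=8)
        fwd = [s for s in seeds if s.strand == "+"]
        assert [(s.target_pos, s.query_pos) for s in fwd] == [(0, 0)]

    def test_no_shared_words(self):
        assert find_seeds("A" * 20, "C" * 20, k=8) == []

    def test_palindromic_word_seeds_both_strands(self):
        # ACGTACGT is its own reverse complement
        seeds = find_seeds("ACGTACGT", "ACGTACGT", k=8)
        assert {s.strand for s in seeds} == {"+", "-"}

    def test_n_never_matches(self):
        assert find_seeds("ACGTNACGT", "ACGTNACGT", k=9) == []

    def test_k_below_four_rejected(self):
        with pytest.raises(ValueError):
            find_seeds("ACGTACGT", "ACGTACGT", k=3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t, q = random_seq(rng, 40), random_seq(rng, 35)
        k = 5
        got = {(s.target_pos, s.query_pos, s.strand) for s in find_seeds(t, q, k=k)}
        expected = set()
        for strand, qs in (("+", q), ("-", revcomp(q))):
            for i in range(len(t) - k + 1):
                for j in range(len(qs) - k + 1):
                    if t[i : i + k] == qs[j : j + k]:
                        expected.add((i, j, strand))
        assert got == expected


class TestUngappedExtend:
    def test_identical_sequences_single_full_segment(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 120)
        seeds = find_seeds(seq, seq, k=12)
        segs = [s for s in ungapped_extend(seeds, seq, seq, SMALL) if s.strand == "+"]
        assert segs == [Segment("target", 0, 120, "query", 0, 120, "+", 1200)]

    def test_below_threshold_dropped(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 20)
        scheme = simple_scheme(10, -9, x_drop=40, hsp_threshold=10_000)
        seeds = find_seeds(seq, seq, k=12)
        assert ungapped_extend(seeds, seq, seq, scheme) == []

    def test_confined_to_homologous_span(self):
        """With homology embedded in random flanks, the HSP matches the
        brute-force best ungapped interval on the seed's diagonal."""
        rng = np.random.default_rng(3)
        core = random_seq(rng, 60)
        t = random_seq(rng, 50) + core + random_seq(rng, 50)
        q = random_seq(rng, 50) + core + random_seq(rng, 50)
        scheme = simple_scheme(10, -9, x_drop=10**6, hsp_threshold=100)
        seeds = [s for s in find_seeds(t, q, k=12) if s.strand == "+"
                 and s.target_pos - s.query_pos == 0]
        segs = [s for s in ungapped_extend(seeds, t, q, scheme) if s.strand == "+"]
        assert len(segs) == 1
        # brute force best interval on the main diagonal
        scores = [scheme.match_score(a, b) for a, b in zip(t, q)]
        best = (0, 0, 0)
        for lo in range(len(scores)):
            run = 0
            for hi in range(lo, len(scores)):
                run += scores[hi]
                if run > best[0]:
                    best = (run, lo, hi + 1)
        assert (segs[0].score, segs[0].target_start, segs[0].target_end) == best


class TestYdropDP:
    def brute_best(self, t, q, M, go, ge):
        """Full Gotoh extension from the origin, max over all cells."""
        n, m = len(t), len(q)
        NEG = -(10**9)
        H = [[NEG] * (m + 1) for _ in range(n + 1)]
        E = [[NEG] * (m + 1) for _ in range(n + 1)]
        F = [[NEG] * (m + 1) for _ in range(n + 1)]
        H[0][0] = 0
        best = 0
        for i in range(n + 1):
            for j in range(m + 1):
                if i == 0 and j == 0:
                    continue
                e = max(H[i][j - 1] - go - ge, E[i][j - 1] - ge) if j else NEG
                f = max(H[i - 1][j] - go - ge, F[i - 1][j] - ge) if i else NEG
                d = H[i - 1][j - 1] + M[t[i - 1], q[j - 1]] if i and j else NEG
                E[i][j], F[i][j] = e, f
                H[i][j] = max(d, e, f)
                best = max(best, H[i][j])
        return best

    @pytest.mark.parametrize("prefer_horizontal", [False, True])
    def test_matches_brute_force_with_unbounded_ydrop(self, prefer_horizontal):
        """For sequences <= 30 nt with y_drop = inf the extension score
        equals an exhaustive global extension from the anchor."""
        rng = np.random.default_rng(42)
        M = SMALL.matrix
        for _ in range(120):
            n, m = rng.integers(0, 31, 2)
            t = rng.integers(0, 4, n).astype(np.uint8)
            q = rng.integers(0, 4, m).astype(np.uint8)
            res = ydrop_extend(t, q, M, 15, 5, 10**9, prefer_horizontal)
            assert res.score == self.brute_best(t, q, M, 15, 5)

    def test_path_score_is_consistent_with_blocks_and_gaps(self):
        rng = np.random.default_rng(7)
        M = SMALL.matrix
        for _ in range(60):
            n, m = rng.integers(1, 31, 2)
            t = rng.integers(0, 4, n).astype(np.uint8)
            q = rng.integers(0, 4, m).astype(np.uint8)
            res = ydrop_extend(t, q, M, 15, 5, 10**9, False)
            if not res.pairs:
                continue
            s = 0
            prev = None
            for i, j in res.pairs:
                s += int(M[t[i], q[j]])
                if prev is not None:
                    di, dj = i - prev[0], j - prev[1]
                    if di > 1:
                        s -= 15 + 5 * (di - 1)
                    if dj > 1:
                        s -= 15 + 5 * (dj - 1)
                prev = (i, j)
            i0, j0 = res.pairs[0]
            if i0:
                s -= 15 + 5 * i0
            if j0:
                s -= 15 + 5 * j0
            assert s == res.score

    def test_opposite_directions_place_ambiguous_gaps_differently(self):
        """Traversing the same region forward vs backward (as two split
        anchors would) yields equally scoring but different paths when an
        indel sits in a repeated-base run — the source of 'additional'
        straddling alignments."""
        t = encode("ACGTAAAACGT")  # one extra A: gap placement is ambiguous
        q = encode("ACGTAAACGT")
        M = SMALL.matrix
        fwd = ydrop_extend(t, q, M, 15, 5, 10**9, False)
        back = ydrop_extend(t[::-1].copy(), q[::-1].copy(), M, 15, 5, 10**9, True)
        mapped = sorted(
            (len(t) - 1 - i, len(q) - 1 - j) for i, j in back.pairs
        )
        assert fwd.score == back.score
        assert fwd.pairs != mapped


class TestGappedExtend:
    def test_exact_self_alignment_single_block(self):
        rng = np.random.default_rng(11)
        seq = random_seq(rng, 80)
        seg = Segment("target", 0, 80, "query", 0, 80, "+", 800)
        (aln,) = gapped_extend([seg], seq, seq, SMALL)
        assert aln.blocks == ((0, 80, 0, 80),)
        assert aln.score == 10 * 80

    def test_dependent_anchor_is_suppressed(self):
        rng = np.random.default_rng(12)
        seq = random_seq(rng, 300)
        s1 = Segment("target", 10, 60, "query", 10, 60, "+", 500)
        s2 = Segment("target", 150, 250, "query", 150, 250, "+", 400)
        assert len(gapped_extend([s1, s2], seq, seq, hoxd70())) == 1

    def test_split_anchors_extend_twice_with_overlap(self):
        rng = np.random.default_rng(12)
        seq = random_seq(rng, 300)
        s1 = Segment("target", 10, 60, "query", 10, 60, "+", 500)
        s2 = Segment("target", 150, 250, "query", 150, 250, "+", 400)
        a1 = gapped_extend([s1], seq, seq, hoxd70())
        a2 = gapped_extend([s2], seq, seq, hoxd70())
        assert len(a1) == len(a2) == 1
        # both re-extend the full homology: envelopes overlap
        e1, e2 = a1[0].blocks, a2[0].blocks
        assert min(b[1] for b in e1) is not None
        t1 = (min(b[0] for b in e1), max(b[1] for b in e1))
        t2 = (min(b[0] for b in e2), max(b[1] for b in e2))
        assert t1[0] < t2[1] and t2[0] < t1[1]

    def test_no_two_outputs_share_a_block_within_one_run(self):
        """Suppression soundness: a single run never emits duplicates."""
        for seed in range(5):
            p = simulate_pair(1000, 5, seed=500 + seed)
            res = align(p.seq_a, p.seq_b, partitioner="none")
            blocks = [b for a in res.alignments for b in a.blocks]
            assert len(blocks) == len(set(blocks))

    def test_anchor_outside_bounds_rejected(self):
        seg = Segment("t", 90, 110, "q", 90, 110, "+", 1)
        with pytest.raises(ValueError):
            gapped_extend([seg], "ACGT" * 25, "ACGT" * 5, SMALL)


class TestAlignHarness:
    def test_single_partition_reports_clean(self):
        p = simulate_pair(1000, 8, seed=99)
        res = align(p.seq_a, p.seq_b, partitioner="diagonal", max_segments=10**9)
        assert res.report.clean

    def test_empty_seed_set_gives_empty_output(self):
        res = align("A" * 50, "C" * 50, partitioner="none")
        assert res.segments == [] and res.alignments == [] and res.report.clean

    def test_deterministic(self):
        p = simulate_pair(1000, 12, seed=7)
        r1 = align(p.seq_a, p.seq_b, partitioner="diagonal", max_segments=4)
        r2 = align(p.seq_a, p.seq_b, partitioner="diagonal", max_segments=4)
        assert r1.alignments == r2.alignments
        assert r1.report == r2.report

    def test_unknown_partitioner_rejected(self):
        with pytest.raises(ValueError):
            align("ACGT" * 10, "ACGT" * 10, partitioner="spiral")


class TestCoverage:
    def test_self_alignment_full_core_coverage(self):
        rng = np.random.default_rng(21)
        seq = random_seq(rng, 2000)
        res = align(seq, seq, partitioner="none")
        ct, cq = coverage(res.alignments, (0, 2000), (0, 2000), query_length=2000)
        assert ct == 1.0 and cq == 1.0

    def test_no_alignments_zero_coverage(self):
        assert coverage([], (0, 100), (0, 100)) == (0.0, 0.0)

    def test_overlapping_alignments_count_union_not_sum(self):
        from diagpart.toy_aligner import Alignment

        a = Alignment("t", "q", "+", ((0, 60, 0, 60),), 0)
        b = Alignment("t", "q", "+", ((50, 100, 50, 100),), 0)
        ct, cq = coverage([a, b], (0, 120), (0, 120))
        assert ct == pytest.approx(100 / 120)

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError):
            coverage([], (10, 10), (0, 100))
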