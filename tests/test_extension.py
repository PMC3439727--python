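"""The extension engine: placement arithmetic, consensus clustering,
filtering/trimming, the step loop, and its stop labels."""

import numpy as np
import pytest

import matefill as mf
from matefill import (
    ExtensionParams,
    FingerprintParams,
    MATE_FOUND,
    NO_MORE_EXTENSION,
    LENGTH_EXCEED,
    OverlapRead,
    build_consensus,
    consensus_bounds,
    extend_contig,
    extend_seed,
    extension_step,
    filter_and_trim,
    mate_check,
    positions,
    seq_to_codes,
)
from matefill.extension import HIGH_REPRESENTED, LOW_REPRESENTED, NON_REPRESENTED


def ov(codes, I, S_len, rid=0, is_rc=False, mismatches=0):
    codes = np.asarray(codes, dtype=np.uint8)
    l = S_len - I
    return OverlapRead(rid, is_rc, l, I, I + codes.size - 1, mismatches, codes, codes.size)


# -- placement ---------------------------------------------------------------


def test_positions_worked_example():
    # contig of length 18, overlap 8, read of length 11
    assert positions(18, 8, 11) == (10, 20)


def test_positions_full_cover_and_length_identity():
    assert positions(30, 30, 40)[0] == 0
    rng = np.random.default_rng(0)
    for _ in range(50):
        S_len = int(rng.integers(10, 500))
        l = int(rng.integers(1, S_len + 1))
        rlen = int(rng.integers(1, 200))
        I, F = positions(S_len, l, rlen)
        assert F - I + 1 == rlen
    with pytest.raises(ValueError):
        positions(10, 11, 50)


# -- consensus bounds --------------------------------------------------------


def test_bounds_two_identical_overlaps():
    a = ov(np.zeros(10), 5, 10)
    b = ov(np.zeros(10), 5, 10, rid=1)
    assert consensus_bounds([a, b], 2, 10) == (5, 14)


def test_bounds_pick_mth_largest_end():
    S_len = 12
    overlaps = [
        ov(np.zeros(F - I + 1), I, S_len, rid=i)
        for i, (I, F) in enumerate([(4, 20), (5, 16), (6, 19), (7, 21)])
    ]
    assert consensus_bounds(overlaps, 2, S_len) == (4, 20)


def test_bounds_halt_signals():
    assert consensus_bounds([ov(np.zeros(8), 2, 6)], 2, 6) is None  # depth < m
    inside = ov(np.zeros(3), 2, 6)  # ends at 4 <= |S| - 1
    assert consensus_bounds([inside, inside], 2, 6) is None
    assert consensus_bounds([], 2, 6) is None


# -- consensus columns -------------------------------------------------------


def naive_consensus(overlaps, I_C, F_C, T1, T2):
    """Column-by-column counting oracle with the same tie-break rule."""
    order = sorted(range(len(overlaps)), key=lambda i: (overlaps[i].I, i))
    cols = []
    for j in range(I_C, F_C + 1):
        counts = [0, 0, 0, 0]
        for o in overlaps:
            if o.I <= j <= o.I + o.effective_len - 1:
                counts[int(o.codes[j - o.I])] += 1
        depth = sum(counts)
        top = max(counts)
        char = counts.index(top)
        if depth and counts.count(top) > 1:
            for oi in order:
                o = overlaps[oi]
                if o.I <= j <= o.I + o.effective_len - 1:
                    c = int(o.codes[j - o.I])
                    if counts[c] == top:
                        char = c
                        break
        pi = top / depth if depth else 0.0
        klass = (
            NON_REPRESENTED if pi <= T1 else LOW_REPRESENTED if pi <= T2 else HIGH_REPRESENTED
        )
        cols.append((char, depth, pi, klass))
    return cols


def test_unanimous_column_is_high_represented():
    S_len = 4
    overlaps = [ov([1, 1, 2], 2, S_len, rid=i) for i in range(3)]
    cons = build_consensus(overlaps, 2, 4, 0.6, 0.9)
    assert list(cons.pi) == [1.0, 1.0, 1.0]
    assert all(k == HIGH_REPRESENTED for k in cons.klass)
    assert cons.seq == "CCG"


def test_four_way_split_hits_quarter_floor():
    overlaps = [ov([c], 0, 1, rid=c) for c in range(4)]
    cons = build_consensus(overlaps, 0, 0, 0.6, 0.9)
    assert cons.pi[0] == pytest.approx(0.25)
    assert cons.column(0).klass == NON_REPRESENTED


def test_tie_break_prefers_earliest_read():
    # column 3 is covered by both reads with different chars at equal count;
    # the read with smaller I wins
    a = ov([0, 0, 2, 2], 1, 3, rid=0)  # covers 1..4, char at 3 is G
    b = ov([3, 3], 3, 3, rid=1)  # covers 3..4, char at 3 is T
    cons = build_consensus([a, b], 1, 4, 0.6, 0.9)
    assert cons.column(3).consensus_char == 2


def test_consensus_matches_counting_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(30):
        S_len = int(rng.integers(8, 25))
        overlaps = []
        for rid in range(int(rng.integers(2, 9))):
            I = int(rng.integers(max(0, S_len - 8), S_len))
            length = int(rng.integers(S_len - I + 1, S_len - I + 12))
            overlaps.append(ov(rng.integers(0, 4, length), I, S_len, rid=rid))
        bounds = consensus_bounds(overlaps, 2, S_len)
        if bounds is None:
            continue
        cons = build_consensus(overlaps, *bounds, 0.6, 0.9)
        want = naive_consensus(overlaps, *bounds, 0.6, 0.9)
        got = [
            (int(c.consensus_char), c.depth, c.pi, c.klass) for c in cons.columns()
        ]
        for (wc, wd, wp, wk), (gc, gd, gp, gk) in zip(want, got):
            assert (wc, wd, wk) == (gc, gd, gk)
            assert gp == pytest.approx(wp)


# -- filtering and trimming --------------------------------------------------


def _cluster(chars_per_read, I_per_read, S_len):
    return [
        ov(seq_to_codes(chars), I, S_len, rid=i)
        for i, (chars, I) in enumerate(zip(chars_per_read, I_per_read))
    ]


def test_clean_cluster_passes_untouched():
    S_len = 6
    overlaps = _cluster(["GGTT", "GGTT", "GGTT"], [4, 4, 4], S_len)
    cons = build_consensus(overlaps, 4, 7, 0.6, 0.9)
    survivors = filter_and_trim(overlaps, cons)
    assert len(survivors) == 3
    assert all(o.effective_len == 4 for o in survivors)


def test_mismatch_at_low_represented_column_discards_read():
    S_len = 6
    # column 7: three reads say T, one says A -> pi = 0.75, low for T2 = 0.9
    overlaps = _cluster(["GGTT", "GGTT", "GGTT", "GGTA"], [4] * 4, S_len)
    cons = build_consensus(overlaps, 4, 7, 0.6, 0.9)
    assert cons.column(7).klass == LOW_REPRESENTED
    survivors = filter_and_trim(overlaps, cons)
    assert [o.read_id for o in survivors] == [0, 1, 2]


def test_non_represented_column_trims_tails_regardless_of_match():
    S_len = 6
    # column 7 is a four-way split -> non-represented; every read covering it
    # is cut back to column 6, including the one matching the consensus
    overlaps = _cluster(["GGTA", "GGTC", "GGTG", "GGTT"], [4] * 4, S_len)
    cons = build_consensus(overlaps, 4, 7, 0.6, 0.9)
    assert cons.column(7).klass == NON_REPRESENTED
    survivors = filter_and_trim(overlaps, cons)
    assert len(survivors) == 4
    assert all(o.effective_len == 3 for o in survivors)
    assert all(o.F_eff == 6 for o in survivors)


def test_read_trimmed_to_nothing_is_dropped():
    S_len = 4
    # non-represented column right at a late read's start
    overlaps = _cluster(["AATC", "AATG", "CT", "GA"], [2, 2, 4, 4], S_len)
    cons = build_consensus(overlaps, 2, 5, 0.6, 0.9)
    assert cons.column(4).klass == NON_REPRESENTED
    survivors = filter_and_trim(overlaps, cons)
    # reads starting at the non-represented column vanish entirely
    assert {o.read_id for o in survivors} == {0, 1}


# -- contig update -----------------------------------------------------------


def test_extension_length_identity():
    S = seq_to_codes("ACGTACGTAC")
    overlaps = _cluster(["TACGG", "TACGG"], [7, 7], 10)
    new = extend_contig(S, overlaps, ExtensionParams(L=3, Delta=2, avg_read_len=10))
    assert new is not None
    # |S_new| = I(C) + |C|
    assert new.size == 7 + 5
    assert mf.codes_to_seq(new) == "ACGTACG" + "TACGG"


def test_no_read_past_the_end_halts():
    S = seq_to_codes("ACGTACGTAC")
    overlaps = _cluster(["TAC", "TAC"], [7, 7], 10)
    assert extend_contig(S, overlaps, ExtensionParams(L=3, Delta=2, avg_read_len=10)) is None


# -- mate check --------------------------------------------------------------


def test_mate_check_examples():
    S = seq_to_codes("AAAACGTAAAA")
    assert mate_check(S, seq_to_codes("ACGT"), 0) == 3
    assert mate_check(S, seq_to_codes("AGGT"), 0) is None  # 1 mismatch, M = 0
    assert mate_check(S, seq_to_codes("AGGT"), 2) == 3  # ACGT vs AGGT: 1 mismatch
    assert mate_check(seq_to_codes("ACG"), seq_to_codes("ACGT"), 10) is None


def test_mate_check_agrees_with_naive_scan():
    rng = np.random.default_rng(9)
    for _ in range(50):
        S = rng.integers(0, 4, int(rng.integers(20, 120))).astype(np.uint8)
        mate = rng.integers(0, 4, int(rng.integers(5, 20))).astype(np.uint8)
        M = int(rng.integers(0, 8))
        start = int(rng.integers(0, 5))
        naive = None
        for p in range(start, S.size - mate.size + 1):
            if int(np.count_nonzero(S[p : p + mate.size] != mate)) <= M:
                naive = p
                break
        assert mate_check(S, mate, M, start) == naive


# -- overlap verification against a brute-force all-pairs scan ---------------


def test_verified_overlaps_match_naive_all_pairs_scan(mini_world, mini_index, mini_params):
    genome, lib, pairs = mini_world
    contig = genome.seq[1000:1180]
    overlaps = mf.collect_overlaps(contig, mini_index, mini_params)
    got = {(o.read_id, o.is_rc, o.l, o.mismatches) for o in overlaps}

    S = seq_to_codes(contig)
    want = set()
    p = mini_params
    for rid in mini_index.reads:
        for is_rc in (False, True):
            codes = mini_index.oriented_codes(rid, is_rc)
            x = (p.L - 20) if is_rc else 0
            for l in range(min(p.L + p.Delta, S.size, codes.size), p.L - 1, -1):
                # candidate only if the orientation's b-window matches exactly
                y = S.size - l + x
                if y < 0 or not np.array_equal(codes[x : x + 20], S[y : y + 20]):
                    continue
                mism = int(np.count_nonzero(codes[:l] != S[S.size - l :]))
                if mism <= p.delta(l):
                    want.add((rid, is_rc, l, mism))
                    break  # largest valid l wins
    assert got == want
    assert all(o.mismatches == 0 for o in overlaps)  # error-free library


# -- the full loop -----------------------------------------------------------


def test_seed_with_no_overlaps_stops_immediately():
    seqs = ["".join("ACGT"[c] for c in np.random.default_rng(5).integers(0, 4, 100))]
    reads = [mf.Read(0, mf.encode_seq(seqs[0]))]
    index = mf.build_index(reads, FingerprintParams(), 50)
    rng = np.random.default_rng(6)
    seed = "".join("ACGT"[c] for c in rng.integers(0, 4, 100))
    mate = "".join("ACGT"[c] for c in rng.integers(0, 4, 100))
    contig = extend_seed(
        seq_to_codes(seed), seq_to_codes(mate), index, ExtensionParams(Lmax=500)
    )
    assert contig.label == NO_MORE_EXTENSION
    assert contig.seq == seed
    assert contig.steps == 0


def test_error_free_seed_reconstructs_the_genomic_insert(mini_world, mini_index, mini_params):
    genome, lib, pairs = mini_world
    plus = lib.truth[lib.truth.strand == "+"].iloc[0]
    i = int(plus.name)
    seed = seq_to_codes(lib.reads1[i])
    mate = mf.revcomp_codes(seq_to_codes(lib.reads2[i]))
    contig = extend_seed(seed, mate, mini_index, mini_params, seed_id=plus.pair_id)
    assert contig.label == MATE_FOUND
    x = int(plus.seed_start)
    assert contig.seq == genome.seq[x : x + len(contig.seq)]
    assert contig.mate_pos == int(plus.insert_len) - 100
    # the mate certificate is re-assertable post hoc
    mate_str = mf.codes_to_seq(mate)
    got = contig.seq[contig.mate_pos : contig.mate_pos + 100]
    assert sum(a != b for a, b in zip(got, mate_str)) <= mini_params.M


def test_prefix_preservation_and_monotone_growth(mini_world, mini_index, mini_params):
    genome, lib, pairs = mini_world
    S = seq_to_codes(lib.reads1[3])
    for _ in range(4):
        step = extension_step(S, mini_index, mini_params)
        assert step.halt_label is None
        new = step.new_contig
        assert new.size > S.size  # monotone growth
        I_C = step.bounds[0]
        assert np.array_equal(new[:I_C], S[:I_C])  # prefix untouched
        # error-free, repeat-free: nothing filtered, nothing trimmed
        assert step.dropped_ids == set()
        assert step.trimmed_ids == set()
        assert all(c.pi == 1.0 for c in step.consensus.columns())
        S = new


def test_forced_length_exceed(mini_world, mini_index):
    _, lib, _ = mini_world
    params = ExtensionParams(avg_read_len=100, Lmax=150)
    seed = seq_to_codes(lib.reads1[0])
    mate = seq_to_codes("A" * 100)  # unfindable mate
    contig = extend_seed(seed, mate, mini_index, params)
    assert contig.label == LENGTH_EXCEED
    assert len(contig.seq) > 150


def test_extension_is_deterministic(mini_world, mini_index, mini_params):
    _, lib, _ = mini_world
    seed = seq_to_codes(lib.reads1[10])
    mate = mf.revcomp_codes(seq_to_codes(lib.reads2[10]))
    a = extend_seed(seed, mate, mini_index, mini_params)
    b = extend_seed(seed, mate, mini_index, mini_params)
    assert (a.seq, a.label, a.mate_pos, a.steps) == (b.seq, b.label, b.mate_pos, b.steps)
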