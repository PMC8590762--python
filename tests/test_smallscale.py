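import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmeval import _kernels, _seq
from asmeval.alignment import AlignmentSegment
from asmeval.smallscale import (BASE_SUBSTITUTION, SMALL_COLLAPSE,
                                SMALL_EXPANSION, PileupColumn,
                                binomial_pvalue, call_from_pileup_arrays,
                                call_small_errors, candidate_small_errors,
                                pileup)


def exact_tail(k, n, p):
    """Enumeration oracle: sum of binomial point masses from k to n."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def seg(read_id, start, cigar, seq):
    ref_span = sum(ln for op, ln in cigar if op in (0, 2, 3, 7, 8))
    return AlignmentSegment(read_id, "ctg", start, start + ref_span, 0,
                            len(seq), "+", 60, True, False, list(cigar),
                            len(seq), seq)


class TestBinomialPvalue:
    @pytest.mark.parametrize(
        "k, n, p, expected",
        [
            (10, 10, 0.5, 0.0009765625),
            (2, 4, 0.5, 0.6875),
            (0, 17, 0.3, 1.0),
        ],
    )
    def test_exact_values(self, k, n, p, expected):
        assert binomial_pvalue(k, n, p) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 12), st.integers(0, 12),
           st.floats(0.05, 0.95))
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration(self, k, n, p):
        if k > n:
            k, n = n, k
        assert binomial_pvalue(k, n, p) == pytest.approx(
            exact_tail(k, n, p), abs=1e-12)

    def test_monotone_in_support(self):
        vals = [binomial_pvalue(k, 40, 0.4) for k in range(41)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_pvalue(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_pvalue(1, 4, 0.0)


class TestPileup:
    def test_perfect_reads(self):
        contig = "ACGTACGTAC"
        segs = [seg(f"r{i}", 0, [(0, 10)], contig) for i in range(3)]
        cols = list(pileup(segs, "ctg", contig))
        # no disagreement anywhere: no alternative-event columns
        assert all(not c.base_counts and not c.ins_counts for c in cols)

    def test_mismatch_counts(self):
        contig = "AAAAAAAAAA"
        segs = [seg("r1", 0, [(0, 10)], "AAAAACAAAA"),
                seg("r2", 0, [(0, 10)], "AAAAACAAAA"),
                seg("r3", 0, [(0, 10)], "AAAAAAAAAA")]
        cols = {c.pos: c for c in pileup(segs, "ctg", contig)}
        assert cols[5].base_counts == {"C": 2}
        assert cols[5].depth == 3

    def test_insertion_anchored_before(self):
        contig = "ACGTACGTACGTACGT"
        # 11M 1I(G) 5M : insertion after consuming 11 ref bases -> anchor 10
        read = contig[:11] + "G" + contig[11:]
        segs = [seg("r1", 0, [(0, 11), (1, 1), (0, 5)], read)]
        cols = {c.pos: c for c in pileup(segs, "ctg", contig)}
        assert cols[10].ins_counts == {"G": 1}

    def test_deletion_counted_at_each_column(self):
        contig = "ACGTACGTACGT"
        segs = [seg("r1", 0, [(0, 4), (2, 3), (0, 5)], contig[:4] + contig[7:])]
        cols = {c.pos: c for c in pileup(segs, "ctg", contig)}
        assert cols[4].del_counts == {3: 1}
        assert all(cols[p].n_deleting == 1 for p in (4, 5, 6))


class TestCandidates:
    def col(self, n_supp, depth=30, pos=7):
        c = PileupColumn("ctg", pos, depth, "A")
        c.base_counts = {"C": n_supp}
        return c

    @pytest.mark.parametrize("n_supp, kept", [(5, False), (6, True), (29, True)])
    def test_twenty_percent_prefilter_inclusive(self, n_supp, kept):
        out = candidate_small_errors([self.col(n_supp)])
        assert bool(out) is kept

    def test_low_depth_skipped(self):
        out = candidate_small_errors([self.col(3, depth=4)])
        assert out == []

    def test_top_alternative_only(self):
        c = PileupColumn("ctg", 3, 30, "A")
        c.base_counts = {"C": 9, "G": 4}
        c.ins_counts = {"T": 5}
        (cand,) = candidate_small_errors([c])
        assert cand.kind == BASE_SUBSTITUTION and cand.read_allele == "C"
        assert cand.n_supp == 9


class TestCallSmallErrors:
    def test_hifi_clear_error_called(self):
        from asmeval.smallscale import SmallCandidate
        cand = SmallCandidate("ctg", 1, BASE_SUBSTITUTION, "A", "C", 20, 19)
        (e,) = call_small_errors([cand], "hifi")
        assert e.p_value == pytest.approx(exact_tail(19, 20, 0.5), rel=1e-9)
        assert e.p_value < 0.01

    def test_hifi_heterozygous_rejected(self):
        from asmeval.smallscale import SmallCandidate
        cand = SmallCandidate("ctg", 1, BASE_SUBSTITUTION, "A", "C", 20, 10)
        assert call_small_errors([cand], "hifi") == []
        assert binomial_pvalue(10, 20, 0.5) == pytest.approx(
            exact_tail(10, 20, 0.5), abs=1e-12)

    def test_clr_uses_lower_null_probability(self):
        from asmeval.smallscale import SmallCandidate
        cand = SmallCandidate("ctg", 1, BASE_SUBSTITUTION, "A", "C", 20, 13)
        (e,) = call_small_errors([cand], "clr")
        assert e.p_value == pytest.approx(exact_tail(13, 20, 0.4), rel=1e-9)
        assert e.p_value < 0.05
        # the same support fails the HiFi threshold at p0=0.5
        assert call_small_errors([cand], "hifi") == []


class TestKernelAgainstReferencePileup:
    """The compiled accumulator must agree with the straightforward
    Python pileup on random segment sets."""

    def run_kernel(self, segs, contig):
        L = len(contig)
        codes = _seq.encode(contig)
        sub = np.zeros((4, L), dtype=np.uint16)
        ins = np.zeros(L, dtype=np.uint16)
        insb = np.zeros((4, L), dtype=np.uint16)
        inss = np.zeros(L, dtype=np.uint32)
        dele = np.zeros(L, dtype=np.uint16)
        cov = np.zeros(L + 1, dtype=np.int32)
        ops = np.concatenate([np.array([o for o, _ in s.cigar], dtype=np.int8)
                              for s in segs])
        lens = np.concatenate([np.array([l for _, l in s.cigar], dtype=np.int32)
                               for s in segs])
        n_ops = np.array([len(s.cigar) for s in segs], dtype=np.int32)
        op_start = np.zeros(len(segs), dtype=np.int32)
        np.cumsum(n_ops[:-1], out=op_start[1:])
        rcodes = np.concatenate([_seq.encode(s.read_sequence) for s in segs])
        rlens = np.array([len(s.read_sequence) for s in segs], dtype=np.int64)
        roff = np.zeros(len(segs), dtype=np.int64)
        np.cumsum(rlens[:-1], out=roff[1:])
        starts = np.array([s.contig_start for s in segs], dtype=np.int32)
        cap = 16
        _kernels.accumulate_batch(
            ops, lens, op_start, n_ops, starts, roff, rcodes, codes, sub,
            ins, insb, inss, dele, cov, 50, 50,
            np.zeros(cap, np.int8), np.zeros(cap, np.int32),
            np.zeros(cap, np.int32), np.zeros(cap, np.int32))
        return sub, ins, dele, np.cumsum(cov[:-1])

    def test_random_segments_agree(self):
        rng = np.random.default_rng(12)
        contig = _seq.random_sequence(300, rng)
        for trial in range(10):
            segs = []
            for i in range(int(rng.integers(2, 12))):
                start = int(rng.integers(0, 200))
                cigar = []
                read = []
                rem = int(rng.integers(30, 100))
                cpos = start
                while rem > 0 and cpos < 290:
                    choice = rng.random()
                    if choice < 0.7:
                        ln = int(rng.integers(1, max(2, min(rem, 40) + 1)))
                        frag = list(contig[cpos : cpos + ln])
                        if rng.random() < 0.5 and frag:
                            frag[int(rng.integers(0, len(frag)))] = "ACGT"[
                                int(rng.integers(0, 4))]
                        read += frag
                        cigar.append((0, len(frag)))
                        cpos += len(frag)
                    elif choice < 0.85:
                        ln = int(rng.integers(1, 5))
                        read += list(_seq.random_sequence(ln, rng))
                        cigar.append((1, ln))
                    else:
                        ln = int(rng.integers(1, min(5, 290 - cpos) + 1))
                        cigar.append((2, ln))
                        cpos += ln
                    rem -= ln
                if not cigar or cigar[0][0] != 0 or cigar[-1][0] != 0:
                    continue
                segs.append(seg(f"r{trial}_{i}", start, cigar, "".join(read)))
            if not segs:
                continue
            sub, ins, dele, depth = self.run_kernel(segs, contig)
            cols = {c.pos: c for c in pileup(segs, "ctg", contig)}
            L = len(contig)
            for pos in range(L):
                c = cols.get(pos)
                mism = sum((c.base_counts or {}).values()) if c else 0
                assert sub[:, pos].sum() == mism
                assert ins[pos] == (sum(c.ins_counts.values()) if c else 0)
                assert dele[pos] == (c.n_deleting if c else 0)
                if c:
                    assert depth[pos] == c.depth


class TestArrayCalls:
    def test_adjacent_deletion_columns_merge(self):
        contig = "ACGTACGTACGTACGTACGT"
        codes = _seq.encode(contig)
        L = len(contig)
        depth = np.full(L, 30, dtype=np.int32)
        sub = np.zeros((4, L), dtype=np.uint16)
        ins = np.zeros(L, dtype=np.uint16)
        insb = np.zeros((4, L), dtype=np.uint16)
        inss = np.zeros(L, dtype=np.uint32)
        dele = np.zeros(L, dtype=np.uint16)
        dele[8:10] = 28
        errors = call_from_pileup_arrays("ctg", codes, depth, sub, ins, insb,
                                         inss, dele, "hifi")
        (e,) = errors
        assert e.kind == SMALL_EXPANSION
        assert (e.pos, e.size) == (8, 2)
        assert e.contig_allele == contig[8:10]

    def test_insertion_call_reports_majority_base(self):
        contig = "ACGTACGTAC"
        codes = _seq.encode(contig)
        L = len(contig)
        depth = np.full(L, 40, dtype=np.int32)
        sub = np.zeros((4, L), dtype=np.uint16)
        ins = np.zeros(L, dtype=np.uint16)
        insb = np.zeros((4, L), dtype=np.uint16)
        inss = np.zeros(L, dtype=np.uint32)
        dele = np.zeros(L, dtype=np.uint16)
        ins[4] = 38
        inss[4] = 38
        insb[2, 4] = 35   # G
        insb[0, 4] = 3
        (e,) = call_from_pileup_arrays("ctg", codes, depth, sub, ins, insb,
                                       inss, dele, "hifi")
        assert e.kind == SMALL_COLLAPSE and e.read_allele == "G"
        assert e.n_supp == 35
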