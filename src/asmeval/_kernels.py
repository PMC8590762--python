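"""Numba kernels for CIGAR walking over read-to-contig alignments.

A 50x long-read alignment of even a few megabases contains tens of millions
of CIGAR operations; these kernels do the per-base accumulation (pileup
counts, coverage, large-indel event extraction) that would dominate runtime
in pure Python.

CIGAR op codes follow the SAM/BAM numeric convention:
M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# kinds for extracted structural events
EVT_EXPANSION = 0  # deletion in read alignment: contig has extra sequence
EVT_COLLAPSE = 1   # insertion in read: contig is missing sequence


@njit(cache=False)
def accumulate_batch(
    ops,            # int8[n_ops]   concatenated cigar op codes
    lens,           # int32[n_ops]  concatenated cigar op lengths
    seg_op_start,   # int32[n_seg]  first op index of each segment
    seg_n_ops,      # int32[n_seg]
    seg_ref_start,  # int32[n_seg]  contig coordinate of first aligned base
    seg_read_off,   # int64[n_seg]  offset into the concatenated read codes
    read_codes,     # uint8[total_read_bases]
    contig_codes,   # uint8[L]
    sub_counts,     # uint16[4, L]  mismatch counts per alternative base
    ins_count,      # uint16[L]     small-insertion count per anchor position
    ins_base_counts,  # uint16[4, L] first-base counts of small insertions
    ins_len_sum,    # uint32[L]     summed small-insertion lengths per anchor
    del_count,      # uint16[L]     small-deletion count per deleted column
    cov_diff,       # int32[L+1]    coverage difference array (span counts)
    small_limit,    # indels shorter than this feed the pileup counters
    struct_limit,   # indels at least this long become structural events
    evt_kind,       # int8[cap]   outputs: structural event records
    evt_pos,        # int32[cap]
    evt_size,       # int32[cap]
    evt_seg,        # int32[cap]
):
    """Walk every segment's CIGAR once, filling pileup accumulators and
    extracting >=struct_limit indel events. Returns the number of events
    (may exceed the output capacity; caller must check and retry bigger)."""
    cap = evt_kind.shape[0]
    n_evt = 0
    for s in range(seg_op_start.shape[0]):
        pos = seg_ref_start[s]
        roff = seg_read_off[s]
        cov_diff[pos] += 1
        for k in range(seg_op_start[s], seg_op_start[s] + seg_n_ops[s]):
            op = ops[k]
            ln = lens[k]
            if op == 0 or op == 7 or op == 8:  # M / = / X
                for j in range(ln):
                    rb = read_codes[roff + j]
                    if rb < 4 and rb != contig_codes[pos + j]:
                        sub_counts[rb, pos + j] += 1
                pos += ln
                roff += ln
            elif op == 1:  # I
                if ln < small_limit:
                    a = pos - 1 if pos > 0 else 0
                    ins_count[a] += 1
                    ins_len_sum[a] += ln
                    fb = read_codes[roff]
                    if fb < 4:
                        ins_base_counts[fb, a] += 1
                if ln >= struct_limit:
                    if n_evt < cap:
                        evt_kind[n_evt] = EVT_COLLAPSE
                        evt_pos[n_evt] = pos
                        evt_size[n_evt] = ln
                        evt_seg[n_evt] = s
                    n_evt += 1
                roff += ln
            elif op == 2 or op == 3:  # D / N
                if ln < small_limit:
                    for j in range(ln):
                        del_count[pos + j] += 1
                if ln >= struct_limit:
                    if n_evt < cap:
                        evt_kind[n_evt] = EVT_EXPANSION
                        evt_pos[n_evt] = pos
                        evt_size[n_evt] = ln
                        evt_seg[n_evt] = s
                    n_evt += 1
                pos += ln
            elif op == 4:  # S
                roff += ln
            # H and P consume nothing
        cov_diff[pos] -= 1
    return n_evt
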