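"""Numba inner loops: pileup accumulation, per-read alignment maps, and the
scaled (banded) pair-HMM forward recursion.

The forward kernel works in probability space with per-row rescaling, so a
single pass costs O(m*b) multiplies with no exp/log per cell; the log of
the accumulated scale is returned together with the terminal cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: log(0) sentinel for paths excluded by the band (or empty matrices).
NEG_INF = -1.0e300

# CIGAR op codes used by the kernels: 0=M, 1=I, 2=D, 4=S (H never reaches here).
OP_M, OP_I, OP_D, OP_S = 0, 1, 2, 4


@njit(cache=True)
def pileup_read(opcodes, oplens, seq_codes, err, start, strand, lo, hi,
                counts, s_match, s_err, s_het):
    """Accumulate one read's aligned bases into the pileup arrays.

    ``counts[p, b, strand]`` counts base b at region offset p; the three
    float arrays accumulate, per (position, base), the log-likelihood
    contributions log(1-e), log(e/3) and log((1-e)/2 + e/6) needed for
    hom-match, mismatch and het-member terms of the genotype likelihood.
    """
    q = 0
    r = start
    for k in range(opcodes.shape[0]):
        op = opcodes[k]
        n = oplens[k]
        if op == OP_M:
            for j in range(n):
                p = r + j
                if lo <= p < hi:
                    b = seq_codes[q + j]
                    if b < 4:
                        pp = p - lo
                        counts[pp, b, strand] += 1
                        e = err[q + j]
                        s_match[pp, b] += np.log1p(-e)
                        s_err[pp, b] += np.log(e / 3.0)
                        s_het[pp, b] += np.log((1.0 - e) / 2.0 + e / 6.0)
            q += n
            r += n
        elif op == OP_I or op == OP_S:
            q += n
        elif op == OP_D:
            r += n


@njit(cache=True)
def alignment_map(opcodes, oplens, seq_codes, ref_codes, start, lo):
    """Per-reference-offset view of one read's alignment.

    ``ref_codes`` covers the region starting at absolute position ``lo``.
    Returns (qpos, good, contig) arrays over the read's reference span:
    qpos[r] = query index aligned at span offset r (-1 for deletions),
    good[r] = aligned and base-identical to the reference,
    contig[r] = the next span offset continues the query with no indel.
    """
    span = 0
    for k in range(opcodes.shape[0]):
        if opcodes[k] == OP_M or opcodes[k] == OP_D:
            span += oplens[k]
    qpos = np.full(span, -1, dtype=np.int64)
    good = np.zeros(span, dtype=np.bool_)
    q = 0
    r = 0
    for k in range(opcodes.shape[0]):
        op = opcodes[k]
        n = oplens[k]
        if op == OP_M:
            for j in range(n):
                qpos[r + j] = q + j
                b = seq_codes[q + j]
                rb = ref_codes[start - lo + r + j]
                good[r + j] = (b < 4) and (b == rb)
            q += n
            r += n
        elif op == OP_I or op == OP_S:
            q += n
        elif op == OP_D:
            r += n
    contig = np.zeros(span, dtype=np.bool_)
    for r in range(span - 1):
        contig[r] = qpos[r] >= 0 and qpos[r + 1] == qpos[r] + 1
    return qpos, good, contig


@njit(cache=True)
def forward_scaled(q, h, band, t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd, sub):
    """Banded pair-HMM forward log-probability of query ``q`` given
    haplotype ``h`` (uint8 codes, 4 = N).

    Three states M/I/D with no I<->D transitions; the path starts from a
    virtual match at (0,0) and terminates in the M state at (m,n).  N bases
    always take the mismatch emission sub/3.  The band admits cells with
    |j - i*n/m| <= band; ``band >= max(m, n)`` reproduces the full forward
    recursion exactly.  Returns NEG_INF when no in-band path survives.
    """
    m = q.shape[0]
    n = h.shape[0]
    if m == 0 or n == 0:
        return NEG_INF
    prev_m = np.zeros(n + 1)
    prev_i = np.zeros(n + 1)
    prev_d = np.zeros(n + 1)
    cur_m = np.zeros(n + 1)
    cur_i = np.zeros(n + 1)
    cur_d = np.zeros(n + 1)
    prev_m[0] = 1.0
    for j in range(1, n + 1):
        prev_d[j] = t_md * prev_m[j - 1] + t_dd * prev_d[j - 1]
    logscale = 0.0
    for i in range(1, m + 1):
        center = (i * n) // m
        lo = center - band
        if lo < 0:
            lo = 0
        hi = center + band
        if hi > n:
            hi = n
        for j in range(n + 1):
            cur_m[j] = 0.0
            cur_i[j] = 0.0
            cur_d[j] = 0.0
        qi = q[i - 1]
        for j in range(lo, hi + 1):
            if j > 0:
                hj = h[j - 1]
                if qi < 4 and hj < 4 and qi == hj:
                    em = 1.0 - sub
                else:
                    em = sub / 3.0
                cur_m[j] = em * (t_mm * prev_m[j - 1] + t_im * prev_i[j - 1]
                                 + t_dm * prev_d[j - 1])
            cur_i[j] = 0.25 * (t_mi * prev_m[j] + t_ii * prev_i[j])
            if j > 0:
                cur_d[j] = t_md * cur_m[j - 1] + t_dd * cur_d[j - 1]
        mx = 0.0
        for j in range(lo, hi + 1):
            if cur_m[j] > mx:
                mx = cur_m[j]
            if cur_i[j] > mx:
                mx = cur_i[j]
            if cur_d[j] > mx:
                mx = cur_d[j]
        if mx <= 0.0:
            return NEG_INF
        inv = 1.0 / mx
        for j in range(lo, hi + 1):
            cur_m[j] *= inv
            cur_i[j] *= inv
            cur_d[j] *= inv
        logscale += np.log(mx)
        prev_m, cur_m = cur_m, prev_m
        prev_i, cur_i = cur_i, prev_i
        prev_d, cur_d = cur_d, prev_d
    if prev_m[n] <= 0.0:
        return NEG_INF
    return np.log(prev_m[n]) + logscale


_CIGAR_TO_CODE = {"M": OP_M, "I": OP_I, "D": OP_D, "S": OP_S}


def cigar_arrays(cigar):
    """Convert a [(op, len), ...] CIGAR to the int arrays the kernels take."""
    ops = np.array([_CIGAR_TO_CODE[op] for op, _ in cigar], dtype=np.int64)
    lens = np.array([n for _, n in cigar], dtype=np.int64)
    return ops, lens


@njit(cache=True)
def event_chain(span, p_ins, p_del, ext, seed):
    """Markov alignment-event chain consuming exactly ``span`` haplotype
    bases.

    Events are aligned bases (0), insertion runs (1) and deletion runs (2)
    with geometric run lengths (extension probability ``ext``).  Adjacent
    same-type indel runs are forbidden and the transition probabilities are
    solved so the stationary fraction of emitted ops equals ``p_ins`` /
    ``p_del`` exactly; op-opening counts per alignment event therefore
    recover the configured rates.
    """
    np.random.seed(seed)
    f_m = 1.0 - p_ins - p_del
    c = p_del / (f_m + p_del) if p_del > 0.0 else 0.0
    d = p_ins / (f_m + p_ins) if p_ins > 0.0 else 0.0
    a = (p_ins - d * p_del) / f_m
    b = (p_del - c * p_ins) / f_m
    if a < 0.0:
        a = 0.0
    if b < 0.0:
        b = 0.0
    cap = 2 * span + 64
    types = np.zeros(cap, dtype=np.int8)
    lengths = np.zeros(cap, dtype=np.int64)
    consumed = 0
    k = 0
    prev = 0
    while consumed < span:
        if k >= cap:
            new_t = np.zeros(cap * 2, dtype=np.int8)
            new_l = np.zeros(cap * 2, dtype=np.int64)
            new_t[:cap] = types
            new_l[:cap] = lengths
            types = new_t
            lengths = new_l
            cap *= 2
        u = np.random.random()
        if prev == 0:
            t = 1 if u < a else (2 if u < a + b else 0)
        elif prev == 1:
            t = 2 if u < c else 0
        else:
            t = 1 if u < d else 0
        if t == 0:
            ln = 1
            consumed += 1
        else:
            ln = 1
            while np.random.random() < ext:
                ln += 1
            if t == 2:
                if consumed + ln > span:
                    ln = span - consumed
                consumed += ln
        types[k] = t
        lengths[k] = ln
        k += 1
        prev = t
    return types[:k], lengths[:k]


@njit(cache=True)
def hmm_counts(opcodes, oplens, seq_codes, ref_codes, start):
    """Alignment-event counts for pair-HMM parameter estimation.

    Returns [aligned_positions, ins_openings, ins_bases, del_openings,
    del_bases, mismatches]; mismatches are counted only where both read and
    reference bases are ACGT.
    """
    out = np.zeros(6, dtype=np.int64)
    q = 0
    r = start
    for k in range(opcodes.shape[0]):
        op = opcodes[k]
        n = oplens[k]
        if op == OP_M:
            out[0] += n
            for j in range(n):
                b = seq_codes[q + j]
                rb = ref_codes[r + j]
                if b < 4 and rb < 4 and b != rb:
                    out[5] += 1
            q += n
            r += n
        elif op == OP_I:
            out[1] += 1
            out[2] += n
            q += n
        elif op == OP_D:
            out[3] += 1
            out[4] += n
            r += n
        elif op == OP_S:
            q += n
    return out
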