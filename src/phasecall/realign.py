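"""Pair-HMM local realignment: per-read allele calls at candidate SNVs.

For each read covering a candidate site, a realignment window is delimited
by the innermost non-repetitive length-k anchors (default k=6) at which the
read matches the reference exactly.  The forward algorithm on a three-state
(match/insert/delete) pair-HMM then gives p_ref = P(read(W) | ref(W)) and
p_alt = P(read(W) | alt(W)); the read's allele is the argmax and its
quality is phred(1 - p_max / (p_ref + p_alt)).  Calls below quality 7.0 are
discarded.  Nearby candidate SNVs share one window and the per-site allele
is obtained by marginalizing over the 2^n local haplotypes.

An anchor k-mer qualifies when it has at least three distinct bases, is not
a repetition of a unit of period 1 or 2, and occurs exactly once within the
anchor search span of the reference.  HMM transition/emission parameters
are estimated from the input alignments themselves: insertion and deletion
opening rates as CIGAR op openings per alignment event, extension rates
from the op-length mass, and the substitution rate from mismatches at
aligned bases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from . import _kernels
from .candidates import CandidateSite
from .formats import AlignedRead, seq_to_codes

log = logging.getLogger(__name__)

NEG_INF = _kernels.NEG_INF


@dataclass
class PairHmmParams:
    """Three-state pair-HMM parameters, probability scale.

    No I<->D transitions; match self-transition is the complement
    ``1 - match_to_ins - match_to_del``.
    """

    match_to_ins: float
    match_to_del: float
    ins_extend: float
    del_extend: float
    sub_rate: float

    def __post_init__(self) -> None:
        for p in (self.match_to_ins, self.match_to_del, self.ins_extend,
                  self.del_extend, self.sub_rate):
            if not 0.0 < p < 1.0:
                raise ValueError("pair-HMM probabilities must lie in (0,1)")
        if self.match_to_ins + self.match_to_del >= 1.0:
            raise ValueError("match outgoing transitions exceed 1")

    @property
    def match_to_match(self) -> float:
        return 1.0 - self.match_to_ins - self.match_to_del

    def as_tuple(self) -> tuple:
        return (self.match_to_match, self.match_to_ins, self.match_to_del,
                1.0 - self.ins_extend, self.ins_extend,
                1.0 - self.del_extend, self.del_extend, self.sub_rate)

    @classmethod
    def default(cls) -> "PairHmmParams":
        """CLR-scale defaults (insertion-dominated single-pass errors)."""
        return cls(match_to_ins=0.11, match_to_del=0.04,
                   ins_extend=1.0 / 3.0, del_extend=1.0 / 3.0, sub_rate=0.01)


def estimate_hmm_params(reads: Sequence[AlignedRead], ref_seq: str,
                        max_reads: int = 10000, ref_offset: int = 0,
                        min_rate: float = 1e-6) -> PairHmmParams:
    """Estimate pair-HMM parameters from aligned reads.

    ``ref_seq`` covers the reads' reference span starting at absolute
    position ``ref_offset``.  Opening rates are I/D op openings divided by
    total alignment events (aligned positions + openings); extension rates
    are the (length-1)/length mass of the op-length distribution; the
    substitution rate is the mismatch fraction of aligned bases.
    """
    ref_codes = seq_to_codes(ref_seq)
    totals = np.zeros(6, dtype=np.int64)
    for read in list(reads)[:max_reads]:
        ops, lens = read.cigar_arrays()
        totals += _kernels.hmm_counts(ops, lens, read.seq_codes(), ref_codes,
                                      read.pos - ref_offset)
    m_pos, ins_open, ins_len, del_open, del_len, mismatches = totals
    if m_pos == 0:
        raise ValueError("no usable alignments for HMM parameter estimation")
    events = m_pos + ins_open + del_open
    clip = lambda x: min(max(x, min_rate), 0.5)
    return PairHmmParams(
        match_to_ins=clip(ins_open / events),
        match_to_del=clip(del_open / events),
        ins_extend=clip((ins_len - ins_open) / ins_len if ins_len else 0.0),
        del_extend=clip((del_len - del_open) / del_len if del_len else 0.0),
        sub_rate=clip(mismatches / m_pos),
    )


def forward_prob(query_seq: str, hap_seq: str, params: PairHmmParams) -> float:
    """Full pair-HMM forward log-probability of query given haplotype."""
    q = seq_to_codes(query_seq)
    h = seq_to_codes(hap_seq)
    band = max(len(q), len(h)) + 1
    return float(_kernels.forward_scaled(q, h, band, *params.as_tuple()))


def banded_forward_prob(query_seq: str, hap_seq: str, params: PairHmmParams,
                        band: int = 20) -> float:
    """Banded forward log-probability; NEG_INF when the band excludes every
    complete path."""
    if band < 1:
        raise ValueError("band must be >= 1")
    q = seq_to_codes(query_seq)
    h = seq_to_codes(hap_seq)
    return float(_kernels.forward_scaled(q, h, band, *params.as_tuple()))


# ---------------------------------------------------------------------------
# anchors and windows

def is_nonrepetitive_kmer(kmer: str) -> bool:
    """At least three distinct bases and not a period-1 or period-2 repeat."""
    if len(set(kmer)) < 3:
        return False
    k = len(kmer)
    for period in (1, 2):
        if k > period and all(kmer[i] == kmer[i % period] for i in range(k)):
            return False
    return True


def anchor_is_valid(ref_seq: str, ref_offset: int, a: int, k: int,
                    span_lo: int, span_hi: int) -> bool:
    """Reference-side anchor check: non-repetitive k-mer, unique within the
    search span [span_lo, span_hi) (absolute coordinates)."""
    i = a - ref_offset
    if i < 0 or i + k > len(ref_seq):
        return False
    kmer = ref_seq[i : i + k]
    if "N" in kmer or not is_nonrepetitive_kmer(kmer):
        return False
    lo = max(span_lo - ref_offset, 0)
    hi = min(span_hi - ref_offset, len(ref_seq))
    return ref_seq.count(kmer, lo, hi) == 1


@dataclass
class RealignmentWindow:
    """An anchor-delimited realignment window for one read.

    ``start``/``end`` are absolute reference coordinates, half-open, with
    both k-anchors inside; every covered site lies strictly between the
    anchors.  ``query_seq`` is the read sequence spanned by the window.
    """

    chrom: str
    start: int
    end: int
    sites: List[CandidateSite]
    query_start: int
    query_end: int
    query_seq: str
    ref_hap: str

    def haplotype(self, alleles: Sequence[int]) -> str:
        """Local haplotype with the given 0/1 allele at each covered site."""
        hap = list(self.ref_hap)
        for site, al in zip(self.sites, alleles):
            if al:
                hap[site.pos - self.start] = site.alt_allele
        return "".join(hap)


class ReadAlignmentIndex:
    """Cached per-reference-offset view of one read's alignment, shared by
    all window searches on that read."""

    def __init__(self, read: AlignedRead, ref_seq, ref_offset: int = 0):
        self.read = read
        ops, lens = read.cigar_arrays()
        ref_codes = (ref_seq if isinstance(ref_seq, np.ndarray)
                     else seq_to_codes(ref_seq))
        self.qpos, self.good, self.contig = _kernels.alignment_map(
            ops, lens, read.seq_codes(), ref_codes,
            read.pos - ref_offset, 0)
        self.span = len(self.qpos)

    def anchor_matches(self, a: int, k: int) -> bool:
        """Read matches the reference exactly and contiguously on [a, a+k)."""
        i = a - self.read.pos
        if i < 0 or i + k > self.span:
            return False
        if not self.good[i : i + k].all():
            return False
        return k == 1 or self.contig[i : i + k - 1].all()


def find_window(read: AlignedRead, ref_seq: str, sites, k: int = 6,
                max_dist: int = 200, ref_offset: int = 0,
                index: Optional[ReadAlignmentIndex] = None,
                _anchor_cache: Optional[dict] = None) -> Optional[RealignmentWindow]:
    """Innermost anchor-delimited window around a site (or site cluster).

    Returns None when no valid anchor pair exists within ``max_dist`` of
    the outermost site, or when the read does not span the window.
    """
    if isinstance(sites, CandidateSite):
        sites = [sites]
    sites = sorted(sites, key=lambda s: s.pos)
    left_site, right_site = sites[0].pos, sites[-1].pos
    if index is None:
        index = ReadAlignmentIndex(read, ref_seq, ref_offset)
    span_lo = left_site - max_dist - k
    span_hi = right_site + max_dist + k + 1

    def ref_ok(a: int) -> bool:
        if _anchor_cache is not None:
            hit = _anchor_cache.get(a)
            if hit is None:
                hit = anchor_is_valid(ref_seq, ref_offset, a, k, span_lo, span_hi)
                _anchor_cache[a] = hit
            return hit
        return anchor_is_valid(ref_seq, ref_offset, a, k, span_lo, span_hi)

    left = None
    a = left_site - k
    while a >= left_site - max_dist:
        if ref_ok(a) and index.anchor_matches(a, k):
            left = a
            break
        a -= 1
    if left is None:
        return None
    right = None
    b = right_site + 1
    while b + k <= right_site + max_dist:
        if ref_ok(b) and index.anchor_matches(b, k):
            right = b
            break
        b += 1
    if right is None:
        return None

    qs = int(index.qpos[left - read.pos])
    qe = int(index.qpos[right + k - 1 - read.pos]) + 1
    start, end = left, right + k
    return RealignmentWindow(
        chrom=read.chrom, start=start, end=end, sites=sites,
        query_start=qs, query_end=qe, query_seq=read.sequence[qs:qe],
        ref_hap=ref_seq[start - ref_offset : end - ref_offset])


# ---------------------------------------------------------------------------
# allelotyping

@dataclass
class AlleleCall:
    """One read's allele observation at one candidate site."""

    read_id: str
    site: CandidateSite
    allele: str  # "ref" or "alt"
    quality: float
    strand: str

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError("negative allele quality")


def _phred_from_logs(lp_max: float, lp_other: float) -> float:
    """phred(1 - p_max/(p_ref+p_alt)) computed stably in log space."""
    total = np.logaddexp(lp_max, lp_other)
    return -10.0 * (lp_other - total) / math.log(10.0)


def allelotype(read: AlignedRead, window: RealignmentWindow,
               params: PairHmmParams, qual_threshold: float = 7.0,
               band: int = 20) -> Optional[AlleleCall]:
    """Single-site allele call; None when the call is discarded.

    Ties go to the reference allele; a tie yields quality -10*log10(0.5)
    ~= 3.01, below the default 7.0 threshold, so the choice is inert.
    """
    site = window.sites[0]
    lp_ref = banded_forward_prob(window.query_seq, window.haplotype([0]),
                                 params, band)
    lp_alt = banded_forward_prob(window.query_seq, window.haplotype([1]),
                                 params, band)
    if lp_ref <= NEG_INF and lp_alt <= NEG_INF:
        return None
    if lp_ref >= lp_alt:
        allele, lp_max, lp_other = "ref", lp_ref, lp_alt
    else:
        allele, lp_max, lp_other = "alt", lp_alt, lp_ref
    qual = _phred_from_logs(lp_max, lp_other)
    if qual < qual_threshold:
        return None
    return AlleleCall(read.read_id, site, allele, qual, read.strand)


def allelotype_cluster(read: AlignedRead, window: RealignmentWindow,
                       params: PairHmmParams, qual_threshold: float = 7.0,
                       band: int = 20) -> List[Optional[AlleleCall]]:
    """Per-site allele calls for a multi-SNV window.

    The forward probability is computed against all 2^n local haplotypes;
    each site's allele is chosen from the marginal probability over the
    other sites, with the same quality formula and discard rule as the
    single-site case.  With n = 1 this reduces to :func:`allelotype`.
    """
    n = len(window.sites)
    lps = np.empty(2 ** n)
    for h in range(2 ** n):
        alleles = [(h >> s) & 1 for s in range(n)]
        lps[h] = banded_forward_prob(window.query_seq,
                                     window.haplotype(alleles), params, band)
    calls: List[Optional[AlleleCall]] = []
    for s, site in enumerate(window.sites):
        ref_lps = [lps[h] for h in range(2 ** n) if not (h >> s) & 1]
        alt_lps = [lps[h] for h in range(2 ** n) if (h >> s) & 1]
        lp_ref = _logsumexp(ref_lps)
        lp_alt = _logsumexp(alt_lps)
        if lp_ref <= NEG_INF and lp_alt <= NEG_INF:
            calls.append(None)
            continue
        if lp_ref >= lp_alt:
            allele, lp_max, lp_other = "ref", lp_ref, lp_alt
        else:
            allele, lp_max, lp_other = "alt", lp_alt, lp_ref
        qual = _phred_from_logs(lp_max, lp_other)
        calls.append(AlleleCall(read.read_id, site, allele, qual, read.strand)
                     if qual >= qual_threshold else None)
    return calls


def _logsumexp(values) -> float:
    arr = np.asarray([v for v in values if v > NEG_INF])
    if arr.size == 0:
        return NEG_INF
    mx = arr.max()
    return float(mx + np.log(np.sum(np.exp(arr - mx))))


def cluster_sites(sites: Sequence[CandidateSite], gap: int = 10,
                  cap: int = 3) -> List[List[CandidateSite]]:
    """Group candidate SNVs in close proximity into shared windows.

    Consecutive sites closer than ``gap`` bp share a cluster; clusters
    larger than ``cap`` are split recursively at their widest gap to bound
    the 2^n haplotype enumeration.
    """
    sites = sorted(sites, key=lambda s: s.pos)
    clusters: List[List[CandidateSite]] = []
    for site in sites:
        if clusters and site.pos - clusters[-1][-1].pos <= gap:
            clusters[-1].append(site)
        else:
            clusters.append([site])

    def split(cluster):
        if len(cluster) <= cap:
            return [cluster]
        gaps = [cluster[i + 1].pos - cluster[i].pos for i in range(len(cluster) - 1)]
        cut = int(np.argmax(gaps)) + 1
        return split(cluster[:cut]) + split(cluster[cut:])

    out = []
    for c in clusters:
        out.extend(split(c))
    return out


def strand_bias_filter(site: CandidateSite, allele_calls: Sequence[AlleleCall],
                       alpha: float = 0.01) -> bool:
    """True when the site is kept; False when strand bias filters it out.

    Builds the 2x2 table of ref/alt calls on forward/reverse strands and
    applies a two-tailed Fisher exact test; an empty table (no calls) keeps
    the site for lack of evidence.
    """
    table = np.zeros((2, 2), dtype=int)
    for call in allele_calls:
        row = 0 if call.allele == "ref" else 1
        col = 0 if call.strand == "+" else 1
        table[row, col] += 1
    if table.sum() == 0:
        return True
    _, p = fisher_exact(table, alternative="two-sided")
    return not p < alpha
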