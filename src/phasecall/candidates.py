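"""Candidate SNV identification from the read pileup.

A samtools-style genotype likelihood is computed at every covered column:
with per-observation error probability ``e_i`` (from the base quality, or a
flat phred-10 stand-in when qualities are absent — CLR base qualities are
largely uninformative and the realignment stage re-estimates quality),

    P(b_i | hom aa)   = 1 - e_i         if b_i == a, else e_i / 3
    P(b_i | het ab)   = P(b_i|a)/2 + P(b_i|b)/2

A Li-style prior over the ten diploid genotypes (het rate theta, hom-alt
theta/2, non-reference alleles equally likely) converts the likelihoods to
a posterior; sites are kept as candidates when the posterior probability of
a non-reference genotype exceeds 0.01 and the pileup passes minimum
coverage (6), alternate-allele count (3) and fraction (0.125, inclusive).

Two equivalent paths exist: an explicit per-observation path over
:class:`PileupColumn` objects, and a vectorized whole-region scan
(:func:`scan_pileup` / :func:`select_candidates_from_scan`) used by the
pipeline on multi-megabase regions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .formats import AlignedRead, Region, seq_to_codes

log = logging.getLogger(__name__)

BASES = "ACGT"
#: The ten diploid genotypes as ordered base-code pairs (a <= b).
DIPLOID_GENOTYPES = [(a, b) for a in range(4) for b in range(a, 4)]

_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


@dataclass(frozen=True)
class Observation:
    read_id: str
    base: str
    qual: float
    strand: str

    @property
    def error_prob(self) -> float:
        return 10.0 ** (-float(self.qual) / 10.0)


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref_base: str
    observations: List[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class GenotypePrior:
    """Prior over the ten diploid genotypes at a reference base.

    ``het_rate`` is the population heterozygosity theta; homozygous
    non-reference genotypes get ``theta * hom_alt_scale`` in total, and
    heterozygous genotypes with two non-reference alleles get theta**2.
    With ``ts_tv_weighting`` transitions receive twice the weight of each
    transversion when mass is split among the three alternate bases.
    """

    het_rate: float = 0.001
    hom_alt_scale: float = 0.5
    ts_tv_weighting: bool = False

    def _alt_weights(self, ref_code: int) -> dict:
        alts = [b for b in range(4) if b != ref_code]
        if not self.ts_tv_weighting:
            return {b: 1.0 / 3.0 for b in alts}
        w = {b: (2.0 if _TRANSITION[ref_code] == b else 1.0) for b in alts}
        tot = sum(w.values())
        return {b: v / tot for b, v in w.items()}

    def genotype_priors(self, ref_base: str) -> dict:
        """Return {(a, b): prior} over DIPLOID_GENOTYPES, summing to 1."""
        ref = BASES.index(ref_base)
        theta = self.het_rate
        w = self._alt_weights(ref)
        p_hom_alt = theta * self.hom_alt_scale
        p_het_alt = theta * theta
        priors = {}
        for a, b in DIPLOID_GENOTYPES:
            if a == b == ref:
                priors[(a, b)] = 1.0 - theta - p_hom_alt - p_het_alt
            elif a == b:
                priors[(a, b)] = p_hom_alt * w[a]
            elif ref in (a, b):
                alt = b if a == ref else a
                priors[(a, b)] = theta * w[alt]
            else:
                wa, wb = w[a], w[b]
                tot = sum(w[x] * w[y] for x, y in itertools.combinations(w, 2))
                priors[(a, b)] = p_het_alt * wa * wb / tot
        return priors

    def zygosity_priors(self) -> Tuple[float, float, float]:
        """(P(hom-ref), P(het), P(hom-alt)) for a known biallelic site."""
        theta = self.het_rate
        p11 = theta * self.hom_alt_scale
        return 1.0 - theta - p11, theta, p11


@dataclass
class CandidateSite:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count_fwd: int
    ref_count_rev: int
    alt_count_fwd: int
    alt_count_rev: int
    other_count: int
    depth: int
    genotype_loglik: np.ndarray  # log L for {0/0, 0/1, 1/1}
    posterior_nonref: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele identical")
        if not np.all(np.isfinite(self.genotype_loglik)):
            raise ValueError("non-finite genotype log-likelihood")

    @property
    def ref_count(self) -> int:
        return self.ref_count_fwd + self.ref_count_rev

    @property
    def alt_count(self) -> int:
        return self.alt_count_fwd + self.alt_count_rev


def build_pileup(reads: Sequence[AlignedRead], region: Region, ref_seq: str,
                 default_qual: float = 10.0) -> List[PileupColumn]:
    """One column per reference position covered by >= 1 aligned base.

    ``ref_seq`` is the sequence of ``region`` itself.  Deletions contribute
    no observation at deleted positions; insertions and soft clips are
    skipped (SNV-only caller); N read bases are excluded.
    """
    columns: dict = {}
    skipped = 0
    for read in reads:
        qlen = sum(n for op, n in read.cigar if op in "MIS")
        if qlen != len(read.sequence):
            skipped += 1
            log.warning("build_pileup: skipping %s (CIGAR/sequence mismatch)", read.read_id)
            continue
        q, r = 0, read.pos
        for op, n in read.cigar:
            if op == "M":
                for j in range(n):
                    p = r + j
                    if region.start <= p < region.end:
                        base = read.sequence[q + j]
                        if base == "N":
                            continue
                        qual = (float(read.base_qualities[q + j])
                                if read.base_qualities is not None
                                else default_qual)
                        columns.setdefault(p, []).append(
                            Observation(read.read_id, base, qual, read.strand))
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op == "D":
                r += n
    return [
        PileupColumn(region.chrom, p, ref_seq[p - region.start], obs)
        for p, obs in sorted(columns.items())
    ]


def genotype_likelihoods(column: PileupColumn, candidate_alt: str) -> np.ndarray:
    """Log-likelihoods of {0/0, 0/1, 1/1} for the column's ref and alt."""
    if column.depth == 0:
        raise ValueError("zero-depth column")
    ref, alt = column.ref_base, candidate_alt
    l00 = l01 = l11 = 0.0
    for ob in column.observations:
        e = ob.error_prob
        p_ref = (1.0 - e) if ob.base == ref else e / 3.0
        p_alt = (1.0 - e) if ob.base == alt else e / 3.0
        l00 += np.log(p_ref)
        l11 += np.log(p_alt)
        l01 += np.log(0.5 * p_ref + 0.5 * p_alt)
    return np.array([l00, l01, l11])


def genotype_posteriors(column: PileupColumn, prior: GenotypePrior) -> dict:
    """Posterior over the ten diploid genotypes at this column."""
    priors = prior.genotype_priors(column.ref_base)
    loglik = {}
    for a, b in DIPLOID_GENOTYPES:
        ll = 0.0
        for ob in column.observations:
            e = ob.error_prob
            pa = (1.0 - e) if ob.base == BASES[a] else e / 3.0
            pb = (1.0 - e) if ob.base == BASES[b] else e / 3.0
            ll += np.log(0.5 * pa + 0.5 * pb)
        loglik[(a, b)] = ll + np.log(priors[(a, b)])
    mx = max(loglik.values())
    w = {g: np.exp(v - mx) for g, v in loglik.items()}
    tot = sum(w.values())
    return {g: v / tot for g, v in w.items()}


def posterior_nonref(column: PileupColumn, prior: GenotypePrior) -> float:
    ref = BASES.index(column.ref_base)
    post = genotype_posteriors(column, prior)
    return 1.0 - post[(ref, ref)]


def _top_alt(counts_by_base: dict, ref_base: str) -> Optional[str]:
    """Most frequent non-reference base; ties broken A<C<G<T."""
    best, best_n = None, 0
    for base in BASES:
        if base == ref_base:
            continue
        n = counts_by_base.get(base, 0)
        if n > best_n:
            best, best_n = base, n
    return best


def select_candidates(columns: Sequence[PileupColumn], prior: GenotypePrior,
                      min_cov: int = 6, min_alt_count: int = 3,
                      min_alt_frac: float = 0.125,
                      posterior_cutoff: float = 0.01) -> List[CandidateSite]:
    """Retain biallelic candidate SNVs passing count and posterior filters.

    A site survives iff depth >= min_cov AND alt count >= min_alt_count AND
    alt fraction >= min_alt_frac (inclusive: 3/24 passes the default) AND
    posterior(non-reference genotype) > posterior_cutoff.  Count filters are
    applied first; they are independent of the posterior so the retained
    set is unchanged by the ordering.
    """
    out = []
    for col in columns:
        if col.ref_base not in BASES:
            continue
        depth = col.depth
        if depth < min_cov:
            continue
        by_base: dict = {}
        for ob in col.observations:
            by_base[ob.base] = by_base.get(ob.base, 0) + 1
        alt = _top_alt(by_base, col.ref_base)
        if alt is None:
            continue
        alt_n = by_base[alt]
        if alt_n < min_alt_count or alt_n / depth < min_alt_frac:
            continue
        p_nonref = posterior_nonref(col, prior)
        if not p_nonref > posterior_cutoff:
            continue
        rc = {s: sum(1 for ob in col.observations
                     if ob.base == col.ref_base and ob.strand == s)
              for s in "+-"}
        ac = {s: sum(1 for ob in col.observations
                     if ob.base == alt and ob.strand == s) for s in "+-"}
        out.append(CandidateSite(
            chrom=col.chrom, pos=col.pos, ref_allele=col.ref_base,
            alt_allele=alt, ref_count_fwd=rc["+"], ref_count_rev=rc["-"],
            alt_count_fwd=ac["+"], alt_count_rev=ac["-"],
            other_count=depth - rc["+"] - rc["-"] - ac["+"] - ac["-"],
            depth=depth, genotype_loglik=genotype_likelihoods(col, alt),
            posterior_nonref=p_nonref))
    return out


@dataclass
class PileupScan:
    """Vectorized pileup statistics over a region.

    ``counts[p, b, s]``: base counts by strand; the three S arrays hold the
    per-(position, base) log-likelihood accumulators described in
    :mod:`phasecall._kernels`.
    """

    region: Region
    ref_codes: np.ndarray
    counts: np.ndarray
    s_match: np.ndarray
    s_err: np.ndarray
    s_het: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))


def scan_pileup(reads: Sequence[AlignedRead], region: Region, ref_seq: str,
                default_qual: float = 10.0) -> PileupScan:
    """Single pass over all reads accumulating pileup statistics."""
    L = len(region)
    counts = np.zeros((L, 4, 2), dtype=np.int32)
    s_match = np.zeros((L, 4))
    s_err = np.zeros((L, 4))
    s_het = np.zeros((L, 4))
    for read in reads:
        ops, lens = read.cigar_arrays()
        codes = read.seq_codes()
        if read.base_qualities is not None:
            err = 10.0 ** (-np.asarray(read.base_qualities, dtype=float) / 10.0)
        else:
            err = np.full(len(codes), 10.0 ** (-default_qual / 10.0))
        _kernels.pileup_read(ops, lens, codes, err, read.pos,
                             0 if read.strand == "+" else 1,
                             region.start, region.end,
                             counts, s_match, s_err, s_het)
    return PileupScan(region, seq_to_codes(ref_seq), counts, s_match, s_err, s_het)


def _scan_loglik(scan: PileupScan, p: int, a: int, b: int) -> float:
    """Genotype log-likelihood at region offset p from the accumulators."""
    if a == b:
        ll = scan.s_match[p, a]
        for c in range(4):
            if c != a:
                ll += scan.s_err[p, c]
    else:
        ll = scan.s_het[p, a] + scan.s_het[p, b]
        for c in range(4):
            if c != a and c != b:
                ll += scan.s_err[p, c]
    return ll


def select_candidates_from_scan(scan: PileupScan, prior: GenotypePrior,
                                min_cov: int = 6, min_alt_count: int = 3,
                                min_alt_frac: float = 0.125,
                                posterior_cutoff: float = 0.01) -> List[CandidateSite]:
    """Same retention rule as :func:`select_candidates`, on a PileupScan."""
    region = scan.region
    base_counts = scan.counts.sum(axis=2)
    depth = base_counts.sum(axis=1)
    ref = scan.ref_codes
    nonref = base_counts.copy()
    valid = ref < 4
    idx = np.arange(len(ref))
    nonref[idx[valid], ref[valid]] = -1
    alt = np.argmax(nonref, axis=1)  # ties -> lowest code = A<C<G<T order
    alt_n = np.take_along_axis(base_counts, alt[:, None], axis=1)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_ok = alt_n >= np.maximum(min_alt_frac * depth, min_alt_count)
    cand = valid & (depth >= min_cov) & frac_ok
    out = []
    for p in np.flatnonzero(cand):
        r, a = int(ref[p]), int(alt[p])
        priors = prior.genotype_priors(BASES[r])
        logpost = np.array([
            _scan_loglik(scan, p, g[0], g[1]) + np.log(priors[g])
            for g in DIPLOID_GENOTYPES
        ])
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        p_nonref = 1.0 - w[DIPLOID_GENOTYPES.index((r, r))]
        if not p_nonref > posterior_cutoff:
            continue
        gll = np.array([
            _scan_loglik(scan, p, r, r),
            _scan_loglik(scan, p, min(r, a), max(r, a)),
            _scan_loglik(scan, p, a, a),
        ])
        out.append(CandidateSite(
            chrom=region.chrom, pos=region.start + int(p),
            ref_allele=BASES[r], alt_allele=BASES[a],
            ref_count_fwd=int(scan.counts[p, r, 0]),
            ref_count_rev=int(scan.counts[p, r, 1]),
            alt_count_fwd=int(scan.counts[p, a, 0]),
            alt_count_rev=int(scan.counts[p, a, 1]),
            other_count=int(depth[p] - base_counts[p, r] - base_counts[p, a]),
            depth=int(depth[p]), genotype_loglik=gll,
            posterior_nonref=float(p_nonref)))
    return out
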