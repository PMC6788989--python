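"""End-to-end SNV calling: pileup candidates -> pair-HMM allelotyping ->
haplotype-informed genotyping -> filtering -> VCF.

The stages are the library modules; this module only wires them together
and owns the default thresholds a command-line run uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import candidates as cand_mod
from . import filters as filt_mod
from . import phase as phase_mod
from . import realign as realign_mod
from .candidates import CandidateSite, GenotypePrior
from .filters import FilterConfig
from .formats import AlignedRead, Region, load_alignments, read_reference, write_vcf
from .phase import Fragment, PhasedCall, PhasingResult
from .realign import PairHmmParams, ReadAlignmentIndex

log = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    """All tunable thresholds of the caller, with their defaults."""

    min_mapq: int = 30
    # candidate nomination
    min_cov: int = 6
    min_alt_count: int = 3
    min_alt_frac: float = 0.125
    potential_snv_cutoff: float = 0.01
    pileup_default_qual: float = 10.0
    # realignment
    anchor_k: int = 6
    max_window: int = 200
    band_width: int = 20
    min_allele_qual: float = 7.0
    strand_bias_pvalue_cutoff: float = 0.01
    hmm_sample_reads: int = 10000
    cluster_gap: int = 10
    cluster_cap: int = 3
    # phased genotyping
    delta: float = 1e-5
    max_iter: int = 10
    # filtering
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    prior: GenotypePrior = field(default_factory=GenotypePrior)


@dataclass
class CallResult:
    calls: List[PhasedCall]             # all calls, filters annotated
    candidate_sites: List[CandidateSite]
    #: candidates surviving the strand-bias filter; Fragment.sites index here
    kept_sites: List[CandidateSite]
    fragments: List[Fragment]
    phasing: Optional[PhasingResult]
    hmm_params: Optional[PairHmmParams]
    median_depth: float
    strand_bias_failed: List[int]       # candidate indices removed pre-phasing

    @property
    def pass_calls(self) -> List[PhasedCall]:
        return [c for c in self.calls if not c.filters]


def _initial_genotype(n_ref: int, n_alt: int, err_ref: Sequence[float],
                      err_alt: Sequence[float], prior: GenotypePrior):
    """MAP unphased genotype (and its GQ) from realigned allele calls."""
    l00 = sum(math.log1p(-e) for e in err_ref) + sum(math.log(e) for e in err_alt)
    l11 = sum(math.log(e) for e in err_ref) + sum(math.log1p(-e) for e in err_alt)
    l01 = (n_ref + n_alt) * math.log(0.5)
    p00, phet, p11 = prior.zygosity_priors()
    scores = np.array([l00 + math.log(p00), l01 + math.log(phet),
                       l11 + math.log(p11)])
    post = np.exp(scores - scores.max())
    post /= post.sum()
    best = int(np.argmax(post))
    gq = 500.0 if post[best] >= 1.0 else min(
        500.0, -10.0 * math.log10(1.0 - post[best]))
    return [(0, 0), (0, 1), (1, 1)][best], gq


def call_variants(ref_seq: str, reads: Sequence[AlignedRead], region: Region,
                  config: Optional[CallerConfig] = None) -> CallResult:
    """Run the full caller on reads over one region.

    ``ref_seq`` is the sequence of ``region``.  Returns every call with its
    filter annotations; the PASS subset is the final call set.
    """
    cfg = config or CallerConfig()

    # 1. candidate SNVs from the pileup
    scan = cand_mod.scan_pileup(reads, region, ref_seq,
                                default_qual=cfg.pileup_default_qual)
    sites = cand_mod.select_candidates_from_scan(
        scan, cfg.prior, min_cov=cfg.min_cov, min_alt_count=cfg.min_alt_count,
        min_alt_frac=cfg.min_alt_frac, posterior_cutoff=cfg.potential_snv_cutoff)
    depth_per_pos = scan.depth
    median_depth = float(np.median(depth_per_pos)) if len(depth_per_pos) else 0.0
    log.info("candidates: %d sites, median depth %.1f", len(sites), median_depth)
    if not sites:
        return CallResult([], [], [], [], None, None, median_depth, [])

    # 2. pair-HMM parameters from the alignments themselves
    params = realign_mod.estimate_hmm_params(
        list(reads), ref_seq, max_reads=cfg.hmm_sample_reads,
        ref_offset=region.start)

    # 3. local realignment: per-read allele calls at each candidate site
    clusters = realign_mod.cluster_sites(sites, gap=cfg.cluster_gap,
                                         cap=cfg.cluster_cap)
    site_index = {id(s): k for k, s in enumerate(sites)}
    cluster_starts = np.array([c[0].pos for c in clusters])
    cluster_ends = np.array([c[-1].pos + 1 for c in clusters])
    from .formats import seq_to_codes
    ref_codes = seq_to_codes(ref_seq)
    anchor_caches: List[dict] = [{} for _ in clusters]
    calls_by_site: Dict[int, List[realign_mod.AlleleCall]] = {
        k: [] for k in range(len(sites))}
    calls_by_read: Dict[str, List[realign_mod.AlleleCall]] = {}
    k_flank = cfg.anchor_k
    for read in reads:
        lo = np.searchsorted(cluster_ends, read.pos + k_flank, side="right")
        hi = np.searchsorted(cluster_starts, read.reference_end - k_flank,
                             side="left")
        if lo >= hi:
            continue
        index = ReadAlignmentIndex(read, ref_codes, region.start)
        for ci in range(int(lo), int(hi)):
            cluster = clusters[ci]
            window = realign_mod.find_window(
                read, ref_seq, cluster, k=cfg.anchor_k,
                max_dist=cfg.max_window, ref_offset=region.start,
                index=index, _anchor_cache=anchor_caches[ci])
            if window is None:
                continue
            if len(cluster) == 1:
                made = [realign_mod.allelotype(read, window, params,
                                               cfg.min_allele_qual,
                                               cfg.band_width)]
            else:
                made = realign_mod.allelotype_cluster(read, window, params,
                                                      cfg.min_allele_qual,
                                                      cfg.band_width)
            for call in made:
                if call is None:
                    continue
                calls_by_site[site_index[id(call.site)]].append(call)
                calls_by_read.setdefault(read.read_id, []).append(call)

    # 4. strand-bias filter before genotyping
    sb_failed = [k for k, site in enumerate(sites)
                 if not realign_mod.strand_bias_filter(
                     site, calls_by_site[k], cfg.strand_bias_pvalue_cutoff)]
    sb_failed_set = set(sb_failed)

    keep = [k for k in range(len(sites)) if k not in sb_failed_set]
    keep_pos = {k: j for j, k in enumerate(keep)}

    # 5. fragments and initial genotypes over surviving sites
    fragments: List[Fragment] = []
    for read_id, rc in sorted(calls_by_read.items()):
        obs = sorted(((keep_pos[site_index[id(c.site)]], c) for c in rc
                      if site_index[id(c.site)] in keep_pos),
                     key=lambda t: t[0])
        if not obs:
            continue
        fragments.append(Fragment(
            read_id=read_id,
            sites=np.array([j for j, _ in obs]),
            alleles=np.array([0 if c.allele == "ref" else 1 for _, c in obs]),
            quals=np.array([c.quality for _, c in obs]),
            strand=rc[0].strand))

    def realignment_genotype(k):
        site_calls = calls_by_site[k]
        err_ref = [10.0 ** (-c.quality / 10.0) for c in site_calls
                   if c.allele == "ref"]
        err_alt = [10.0 ** (-c.quality / 10.0) for c in site_calls
                   if c.allele == "alt"]
        return _initial_genotype(len(err_ref), len(err_alt),
                                 err_ref, err_alt, cfg.prior)

    initial = [realignment_genotype(k)[0] for k in keep]

    # 6. iterative haplotype-informed genotyping
    phasing = phase_mod.iterate(fragments, initial, cfg.prior,
                                delta=cfg.delta, max_iter=cfg.max_iter)

    # 7. assemble calls (non-reference genotypes only) and filter
    ps_of = phasing.phase_set_of()
    calls: List[PhasedCall] = []
    for j, k in enumerate(keep):
        site = sites[k]
        genotype = phasing.pair.genotype(j)
        if genotype == (0, 0):
            continue
        ps = ps_of.get(j)
        calls.append(PhasedCall(
            chrom=site.chrom, pos=site.pos, ref_allele=site.ref_allele,
            alt_allele=site.alt_allele, genotype=genotype,
            gq=float(phasing.gq[j]), depth=site.depth,
            phase_set=(sites[keep[ps]].pos + 1 if ps is not None else None)))
    # strand-biased sites are excluded from haplotype-informed genotyping
    # but still emitted, FILTER-labelled, with their realignment genotype
    for k in sb_failed:
        site = sites[k]
        genotype, gq = realignment_genotype(k)
        if genotype == (0, 0):
            continue
        calls.append(PhasedCall(
            chrom=site.chrom, pos=site.pos, ref_allele=site.ref_allele,
            alt_allele=site.alt_allele, genotype=genotype, gq=gq,
            depth=site.depth, phase_set=None, filters={"strand_bias"}))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    if median_depth > 0:
        calls = filt_mod.apply_filters(calls, cfg.filter_config, median_depth)
    return CallResult(calls, sites, [sites[k] for k in keep], fragments,
                      phasing, params, median_depth, sb_failed)


def call_from_files(fasta_path: str, sam_path: str, region: Region,
                    config: Optional[CallerConfig] = None) -> CallResult:
    ref_seq = read_reference(fasta_path, region)
    cfg = config or CallerConfig()
    reads = load_alignments(sam_path, region, min_mapq=cfg.min_mapq)
    return call_variants(ref_seq, reads, region, cfg)


def write_calls(result: CallResult, path: str, sample_name: str,
                contigs: dict, pass_only: bool = False) -> None:
    calls = result.pass_calls if pass_only else result.calls
    write_vcf(path, calls, sample_name, contigs)
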