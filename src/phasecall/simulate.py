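"""Diploid genome and CLR-like long-read simulation with ground truth.

The simulator emulates single-pass SMS (single-molecule sequencing) long
reads: indel-dominated errors (insertion 0.11, deletion 0.04, substitution
0.01 by default), log-normally distributed read lengths (median 7.5 kb),
and a diploid genome carrying heterozygous SNVs at rate 1e-3 and homozygous
SNVs at rate 5e-4.

Errors are generated by a Markov event chain: each alignment event is an
insertion run (probability ``ins_rate``), a deletion run (``del_rate``) or
an aligned base (otherwise), with run lengths geometric (mean
``indel_ext_mean``) and aligned bases substituted with probability
``sub_rate``.  Counting CIGAR op openings per alignment event therefore
recovers the configured rates in expectation, which is exactly the scheme
the realignment module uses to estimate its pair-HMM parameters.

Reads are emitted with their TRUE alignment (CIGAR from the simulator's own
error trace) so the pipeline is testable without an external aligner.  Read
start positions are drawn uniformly over ``[-len+1, L-1]`` and clipped to
the region, so expected coverage is uniform all the way to the region
edges, as for a window cut out of a larger genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np

from .formats import AlignedRead, codes_to_seq, seq_to_codes, write_fasta, write_sam


@dataclass
class SimConfig:
    """Study conditions for the diploid/long-read simulation."""

    region_length: int = 1_000_000
    het_snv_rate: float = 0.001
    hom_snv_rate: float = 0.0005
    coverage: float = 30.0
    median_read_length: float = 7500.0
    read_length_sigma: float = 0.35
    min_read_length: int = 300
    ins_rate: float = 0.11
    del_rate: float = 0.04
    sub_rate: float = 0.01
    indel_ext_mean: float = 1.5
    #: emitted per-base quality; None = phred of sub_rate (calibrated
    #: instrument), capped at Q60
    base_quality: Optional[int] = None
    chrom: str = "sim1"
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.het_snv_rate, self.hom_snv_rate, self.ins_rate,
                  self.del_rate, self.sub_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def emitted_base_quality(self) -> int:
        if self.base_quality is not None:
            return self.base_quality
        if self.sub_rate <= 0.0:
            return 60
        return int(min(60, round(-10.0 * np.log10(self.sub_rate))))


@dataclass
class TruthVariant:
    pos: int
    ref: str
    alt: str
    genotype: Tuple[int, int]  # (hap1 allele, hap2 allele)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


@dataclass
class TruthSet:
    """Ground truth: phased variants plus per-read provenance."""

    chrom: str
    region_length: int
    variants: List[TruthVariant] = field(default_factory=list)
    read_provenance: List[dict] = field(default_factory=list)

    def het_positions(self) -> set:
        return {v.pos for v in self.variants if v.is_het}

    def positions(self) -> set:
        return {v.pos for v in self.variants}

    def write_vcf(self, path: str, sample_name: str = "truth") -> None:
        """Write the phased truth as a VCF 4.2 file (hets phased with |)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom},length={self.region_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n"
                     % sample_name)
            for v in sorted(self.variants, key=lambda v: v.pos):
                gt = f"{v.genotype[0]}|{v.genotype[1]}"
                fh.write(f"{self.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}"
                         f"\t.\tPASS\t.\tGT\t{gt}\n")


def random_reference(length: int, seed: int, homopolymer_runs: int = 0,
                     run_length: Tuple[int, int] = (5, 12)) -> str:
    """A random uniform-composition reference, optionally salted with
    homopolymer runs to exercise anchor selection."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    for _ in range(homopolymer_runs):
        rl = int(rng.integers(run_length[0], run_length[1] + 1))
        start = int(rng.integers(0, max(1, length - rl)))
        codes[start : start + rl] = rng.integers(0, 4)
    return codes_to_seq(codes)


def simulate_diploid(ref_seq: str, config: SimConfig,
                     rng: Optional[np.random.Generator] = None):
    """Plant SNVs on two haplotypes of ``ref_seq``.

    Each position independently becomes a homozygous SNV (both haplotypes)
    with probability ``hom_snv_rate`` or a heterozygous SNV (one haplotype,
    chosen fairly) with probability ``het_snv_rate``; the alternate base is
    uniform over the three non-reference bases.

    Returns ``(hap1_seq, hap2_seq, TruthSet)``.
    """
    if len(ref_seq) < 1000:
        raise ValueError("reference must be at least 1 kb")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = seq_to_codes(ref_seq)
    L = len(ref)
    u = rng.random(L)
    hom = u < config.hom_snv_rate
    het = (~hom) & (u < config.hom_snv_rate + config.het_snv_rate)
    # alt base: shift ref code by 1..3 (mod 4) => uniform over non-ref bases
    shift = rng.integers(1, 4, size=L, dtype=np.uint8)
    alt = (ref + shift) % 4
    which_hap = rng.integers(0, 2, size=L)

    hap1 = ref.copy()
    hap2 = ref.copy()
    hap1[hom] = alt[hom]
    hap2[hom] = alt[hom]
    het1 = het & (which_hap == 0)
    het2 = het & (which_hap == 1)
    hap1[het1] = alt[het1]
    hap2[het2] = alt[het2]

    truth = TruthSet(chrom=config.chrom, region_length=L)
    for pos in np.flatnonzero(hom | het):
        g = (int(hap1[pos] != ref[pos]), int(hap2[pos] != ref[pos]))
        truth.variants.append(
            TruthVariant(int(pos), codes_to_seq(ref[pos : pos + 1]),
                         codes_to_seq(alt[pos : pos + 1]), g)
        )
    return codes_to_seq(hap1), codes_to_seq(hap2), truth


def _event_chain(span: int, cfg: SimConfig, rng: np.random.Generator):
    """Draw the Markov alignment-event chain (see
    :func:`phasecall._kernels.event_chain`) and trim leading/trailing
    non-aligned events so the read starts and ends on an aligned base."""
    from . import _kernels

    ext = 1.0 - 1.0 / cfg.indel_ext_mean
    seed = int(rng.integers(0, 2**31 - 1))
    types, lengths = _kernels.event_chain(span, cfg.ins_rate, cfg.del_rate,
                                          ext, seed)
    m_idx = np.flatnonzero(types == 0)
    if len(m_idx) == 0:
        return None
    first, last = m_idx[0], m_idx[-1]
    lead_hap = int(np.sum(np.where(types[:first] == 1, 0, lengths[:first])))
    return types[first : last + 1], lengths[first : last + 1], lead_hap


def _build_read(hap: np.ndarray, start: int, span: int, cfg: SimConfig,
                rng: np.random.Generator):
    """Apply the error chain to hap[start:start+span]; return
    (codes, cigar, pos_shift, stats) or None for a degenerate draw."""
    chain = _event_chain(span, cfg, rng)
    if chain is None:
        return None
    types, lengths, lead_hap = chain
    # haplotype index consumed before each event
    hap_used = np.where(types == 1, 0, lengths)
    hap_before = start + lead_hap + np.concatenate([[0], np.cumsum(hap_used)[:-1]])
    qlen = np.where(types == 2, 0, lengths)
    total_q = int(qlen.sum())
    event_of = np.repeat(np.arange(len(types)), qlen)
    offset = np.arange(total_q) - np.repeat(np.cumsum(qlen) - qlen, qlen)
    is_ins = types[event_of] == 1
    codes = np.empty(total_q, dtype=np.uint8)
    m_mask = ~is_ins
    codes[m_mask] = hap[hap_before[event_of[m_mask]]]
    n_ins_bases = int(is_ins.sum())
    if n_ins_bases:
        codes[is_ins] = rng.integers(0, 4, size=n_ins_bases, dtype=np.uint8)
    # substitutions on aligned bases
    sub = m_mask & (rng.random(total_q) < cfg.sub_rate)
    n_sub = int(sub.sum())
    if n_sub:
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=n_sub, dtype=np.uint8)) % 4
    del offset
    # run-length encode events into CIGAR (merge adjacent same-type runs)
    boundaries = np.flatnonzero(np.diff(types) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(types)]])
    opchar = {0: "M", 1: "I", 2: "D"}
    cigar = []
    for s, e in zip(starts, ends):
        cigar.append((opchar[int(types[s])], int(lengths[s:e].sum())))
    stats = {
        "n_events": int(len(types)),
        "n_aligned": int((types == 0).sum()),
        "n_sub": n_sub,
        "n_ins_open": int((types == 1).sum()),
        "n_ins_bases": n_ins_bases,
        "n_del_open": int((types == 2).sum()),
        "n_del_bases": int(lengths[types == 2].sum()),
    }
    return codes, cigar, lead_hap, stats


def simulate_reads(hap1: str, hap2: str, config: SimConfig,
                   rng: Optional[np.random.Generator] = None):
    """Simulate CLR-like reads from the two haplotypes.

    Returns ``(reads, provenance)`` where reads carry their true alignment
    to the reference coordinate system (haplotypes are SNV-only, so hap and
    reference coordinates coincide).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    haps = (seq_to_codes(hap1), seq_to_codes(hap2))
    L = len(hap1)
    target = config.coverage * L
    mu = np.log(config.median_read_length)
    reads = []
    provenance = []
    total = 0
    i = 0
    while total < target:
        length = int(np.exp(rng.normal(mu, config.read_length_sigma)))
        length = max(config.min_read_length, min(length, L))
        start = int(rng.integers(-length + 1, L - 1))
        end = min(start + length, L)
        start = max(start, 0)
        span = end - start
        if span < config.min_read_length // 2:
            continue
        hap_idx = i % 2  # alternate haplotypes for exact balance
        strand = "+" if rng.random() < 0.5 else "-"
        built = _build_read(haps[hap_idx], start, span, config, rng)
        i += 1
        if built is None:
            continue
        codes, cigar, lead_hap, stats = built
        read_id = f"sim_{i:06d}_h{hap_idx + 1}"
        quals = np.full(len(codes), config.emitted_base_quality, dtype=np.uint8)
        reads.append(
            AlignedRead(
                read_id=read_id,
                chrom=config.chrom,
                pos=start + lead_hap,
                strand=strand,
                mapq=60,
                cigar=cigar,
                sequence=codes_to_seq(codes),
                base_qualities=quals,
            )
        )
        provenance.append(
            {"read_id": read_id, "haplotype": hap_idx + 1, "start": start + lead_hap,
             "end": end, "strand": strand, **stats}
        )
        total += span
    return reads, provenance


def simulate_dataset(config: SimConfig, ref_seq: Optional[str] = None):
    """Full simulation: reference, diploid haplotypes, reads, truth.

    Returns ``(ref_seq, reads, truth)``; the truth set carries per-read
    provenance.  Deterministic in ``config.seed``.
    """
    if ref_seq is None:
        ref_seq = random_reference(config.region_length, config.seed)
    hap1, hap2, truth = simulate_diploid(ref_seq, config)
    reads, provenance = simulate_reads(hap1, hap2, config)
    truth.read_provenance = provenance
    return ref_seq, reads, truth


def write_dataset(outdir: str, config: SimConfig, ref_seq: Optional[str] = None):
    """Simulate and write ref.fa(+.fai), reads.sam, truth.vcf, provenance.json."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    ref_seq, reads, truth = simulate_dataset(config, ref_seq)
    contigs = {config.chrom: len(ref_seq)}
    write_fasta(os.path.join(outdir, "ref.fa"), {config.chrom: ref_seq})
    write_sam(os.path.join(outdir, "reads.sam"), reads, contigs)
    truth.write_vcf(os.path.join(outdir, "truth.vcf"))
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump({"config": asdict(config), "reads": truth.read_provenance}, fh)
    return ref_seq, reads, truth
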