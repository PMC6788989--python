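"""Scoring called variants and haplotypes against a truth set.

Precision/recall use exact biallelic SNV matching on (chrom, pos, ref,
alt): a site matching in position and alleles but not in unphased genotype
counts as both a false positive and a false negative (the convention of
vcfeval-style comparators).  Phasing accuracy is the combined switch +
mismatch error over adjacent heterozygous pairs, evaluated at sites called
heterozygous in both call set and truth, with the gauge (global flip) of
each block chosen to minimize the error count.  Block completeness is
summarized by N50 over block spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .formats import Region, VcfRecord


def _unphased(gt: Tuple[int, int]) -> Tuple[int, int]:
    return tuple(sorted(gt))


def _in_regions(rec: VcfRecord, regions: Optional[Sequence[Region]]) -> bool:
    if regions is None:
        return True
    return any(r.chrom == rec.chrom and r.start <= rec.pos < r.end
               for r in regions)


@dataclass
class PRResult:
    tp: int
    fp: int
    fn: int
    fp_sites: List[Tuple[str, int]] = field(default_factory=list)
    fn_sites: List[Tuple[str, int]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def pr_vs_truth(called: Sequence[VcfRecord], truth: Sequence[VcfRecord],
                regions: Optional[Sequence[Region]] = None) -> PRResult:
    """Precision/recall of biallelic SNV calls against the truth set."""
    called = [c for c in called if _in_regions(c, regions)]
    truth = [t for t in truth if _in_regions(t, regions)]
    c_contigs = {c.chrom for c in called}
    t_contigs = {t.chrom for t in truth}
    if called and truth and not c_contigs & t_contigs:
        raise ValueError(f"contig mismatch: called on {sorted(c_contigs)}, "
                         f"truth on {sorted(t_contigs)}")
    truth_by_key: Dict[tuple, VcfRecord] = {
        (t.chrom, t.pos, t.ref, t.alt): t for t in truth}
    tp = fp = 0
    fp_sites: List[Tuple[str, int]] = []
    matched = set()
    for c in called:
        key = (c.chrom, c.pos, c.ref, c.alt)
        t = truth_by_key.get(key)
        if t is not None and _unphased(c.genotype) == _unphased(t.genotype):
            tp += 1
            matched.add(key)
        else:
            fp += 1
            fp_sites.append((c.chrom, c.pos))
    fn_sites = [(t.chrom, t.pos) for k, t in truth_by_key.items()
                if k not in matched]
    return PRResult(tp=tp, fp=fp, fn=len(fn_sites),
                    fp_sites=fp_sites, fn_sites=sorted(fn_sites))


@dataclass
class SwitchMismatchResult:
    switches: int
    mismatches: int
    pairs_assessed: int

    @property
    def error_rate(self) -> Optional[float]:
        """Combined (switch + mismatch) errors per adjacent het pair; None
        when no pairs could be assessed."""
        if self.pairs_assessed == 0:
            return None
        return (self.switches + self.mismatches) / self.pairs_assessed


def _count_errors(d: List[int]) -> Tuple[int, int]:
    """Decompose a disagreement vector into (switches, mismatches).

    An interior run of disagreement of length 1 is one mismatch (a
    short/point switch); every other transition between agreement and
    disagreement is one long-switch error.
    """
    n = len(d)
    switches = mismatches = 0
    i = 0
    while i < n:
        if d[i] == 0:
            i += 1
            continue
        j = i
        while j < n and d[j] == 1:
            j += 1
        run = j - i
        interior = i > 0 and j < n
        if run == 1 and interior:
            mismatches += 1
        else:
            switches += (1 if i > 0 else 0) + (1 if j < n else 0)
        i = j
    return switches, mismatches


def switch_mismatch_error(called: Sequence[VcfRecord],
                          truth: Sequence[VcfRecord]) -> SwitchMismatchResult:
    """Combined switch + mismatch error of called haplotype blocks.

    Evaluated at sites heterozygous (with identical alleles) in both call
    set and truth; within each phase-set block the gauge minimizing the
    error count is chosen (ties: fewer disagreeing sites, then identity).
    The denominator counts adjacent het pairs within blocks.
    """
    truth_by_key = {(t.chrom, t.pos, t.ref, t.alt): t
                    for t in truth if t.is_het}
    blocks: Dict[tuple, List[Tuple[int, int, int]]] = {}
    for c in called:
        if not c.is_het:
            continue
        t = truth_by_key.get((c.chrom, c.pos, c.ref, c.alt))
        if t is None:
            continue
        ps = c.phase_set if c.phase_set is not None else c.pos
        blocks.setdefault((c.chrom, ps), []).append(
            (c.pos, c.genotype[0], t.genotype[0]))
    switches = mismatches = pairs = 0
    for sites in blocks.values():
        if len(sites) < 2:
            continue
        sites.sort()
        d = [c ^ t for _, c, t in sites]
        flipped = [1 - x for x in d]
        cand = []
        for vec in (d, flipped):
            s, m = _count_errors(vec)
            cand.append((s + m, sum(vec), s, m))
        cand.sort()
        _, _, s, m = cand[0]
        switches += s
        mismatches += m
        pairs += len(sites) - 1
    return SwitchMismatchResult(switches, mismatches, pairs)


def n50(block_spans: Sequence[int]) -> int:
    """N50 of haplotype block lengths in bp: the length N such that half of
    the total phased span lies in blocks of length >= N."""
    spans = sorted((s for s in block_spans if s > 0), reverse=True)
    if not spans:
        return 0
    half = sum(spans) / 2.0
    acc = 0
    for s in spans:
        acc += s
        if acc >= half:
            return s
    return spans[-1]


def block_spans(called: Sequence[VcfRecord]) -> List[int]:
    """Block spans (last minus first phased het coordinate) from PS tags."""
    by_ps: Dict[tuple, List[int]] = {}
    for c in called:
        if c.is_het and c.phase_set is not None:
            by_ps.setdefault((c.chrom, c.phase_set), []).append(c.pos)
    return [max(p) - min(p) for p in by_ps.values() if len(p) > 1]
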