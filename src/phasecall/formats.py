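"""File formats and coordinate conventions shared across the pipeline.

All coordinates inside the package are 0-based, half-open.  The single
conversion to VCF's 1-based POS happens in :func:`write_vcf`; nothing else
ever adds or subtracts one.

FASTA, SAM/BAM and VCF access goes through :mod:`pysam`.  CIGAR ``=``/``X``
operations are normalized to ``M`` on input (the realignment model only
needs query/reference consumption); hard clips are dropped and soft clips
are retained in the CIGAR but never contribute to pileups or windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

log = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Map an ACGTN string to uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()

#: CIGAR operation characters indexed by the BAM numeric op code.
_BAM_OPS = "MIDNSHP=X"

#: Ops that consume query sequence / reference sequence.
QUERY_OPS = frozenset("MIS")
REF_OPS = frozenset("MDN")

#: FILTER labels the pipeline can attach to a call.
FILTER_LABELS = ("depth", "density", "strand_bias", "low_gq")


@dataclass(frozen=True)
class Region:
    """A reference interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignedRead:
    """A mapped read with its alignment, in internal 0-based coordinates.

    ``cigar`` is a list of ``(op, length)`` pairs with op one of
    ``M I D S H`` after normalization (``=``/``X`` folded into ``M``).
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    mapq: int
    cigar: list
    sequence: str
    base_qualities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for read {self.read_id}")
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if qlen != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.sequence)}"
            )
        self._codes = None
        self._cigar_arrays = None

    def seq_codes(self) -> "np.ndarray":
        """Cached uint8 base codes of the read sequence."""
        if self._codes is None:
            self._codes = seq_to_codes(self.sequence)
        return self._codes

    def cigar_arrays(self):
        """Cached (opcodes, lengths) int arrays for the numba kernels."""
        if self._cigar_arrays is None:
            from . import _kernels
            self._cigar_arrays = _kernels.cigar_arrays(self.cigar)
        return self._cigar_arrays

    @property
    def reference_end(self) -> int:
        """One past the last reference position consumed by the alignment."""
        return self.pos + sum(n for op, n in self.cigar if op in REF_OPS)

    def overlaps(self, start: int, end: int) -> bool:
        return self.pos < end and self.reference_end > start


def read_reference(fasta_path: str, region: Optional[Region] = None) -> str:
    """Fetch an uppercase reference sequence (whole contig or a region)."""
    with pysam.FastaFile(fasta_path) as fa:
        if region is None:
            if len(fa.references) != 1:
                raise ValueError("region required for multi-contig FASTA")
            return fa.fetch(fa.references[0]).upper()
        if region.chrom not in fa.references:
            raise KeyError(f"contig {region.chrom!r} not in {fasta_path}")
        return fa.fetch(region.chrom, region.start, region.end).upper()


def _normalize_cigar(cigartuples) -> list:
    out = []
    for code, length in cigartuples:
        op = _BAM_OPS[code]
        if op in "=X":
            op = "M"
        if op == "H":
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return out


# SAM flag mask matching `samtools view -F 3844`: unmapped, secondary,
# qcfail, duplicate, supplementary.
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800


def load_alignments(sam_path: str, region: Region, min_mapq: int = 30) -> list:
    """Load primary, well-mapped reads overlapping ``region``.

    Keeps only mapped, primary, non-duplicate, non-supplementary records
    with ``mapq >= min_mapq`` (default 30).  Unparseable records are
    skipped with a warning.
    """
    reads = []
    skipped = 0
    with pysam.AlignmentFile(sam_path, require_index=False) as af:
        indexed = af.has_index()
        it = (
            af.fetch(region.chrom, region.start, region.end)
            if indexed
            else af.fetch(until_eof=True)
        )
        for rec in it:
            if rec.flag & _EXCLUDE_FLAGS or rec.mapping_quality < min_mapq:
                continue
            if not indexed:
                if rec.reference_name != region.chrom:
                    continue
                if rec.reference_end is None or rec.reference_start is None:
                    continue
                if rec.reference_end <= region.start or rec.reference_start >= region.end:
                    continue
            try:
                if rec.cigartuples is None or rec.query_sequence is None:
                    raise ValueError("missing CIGAR or sequence")
                if any(_BAM_OPS[c] == "N" for c, _ in rec.cigartuples):
                    raise ValueError("N (ref-skip) op unsupported")
                quals = rec.query_qualities
                reads.append(
                    AlignedRead(
                        read_id=rec.query_name,
                        chrom=rec.reference_name,
                        pos=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                        cigar=_normalize_cigar(rec.cigartuples),
                        sequence=rec.query_sequence.upper(),
                        base_qualities=list(quals) if quals is not None else None,
                    )
                )
            except ValueError as exc:
                skipped += 1
                log.warning("skipping unparseable record %s: %s", rec.query_name, exc)
    if skipped:
        log.info("load_alignments: skipped %d records", skipped)
    return reads


def write_vcf(path: str, calls: Iterable, sample_name: str, contigs: dict) -> None:
    """Write phased calls as a VCF 4.2 file.

    ``calls`` must be sorted by (chrom, pos) and expose the attributes of
    :class:`phasecall.phase.PhasedCall`.  Heterozygous calls carry a PS
    (phase set) tag naming their haplotype block; POS is the internal
    0-based position plus one.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=phasecall')
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for lab, desc in [
        ("depth", "Depth above maximum-depth cutoff d+5*sqrt(d)"),
        ("density", "More than the allowed SNVs within the density window"),
        ("strand_bias", "Allele observations strand-biased (Fisher exact test)"),
        ("low_gq", "Genotype quality below cutoff"),
    ]:
        header.filters.add(lab, None, None, desc)
    header.formats.add("GT", 1, "String", "Phased genotype")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    header.formats.add("PS", 1, "Integer", "Phase set (haplotype block) identifier")
    header.add_sample(sample_name)

    last = None
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            key = (call.chrom, call.pos)
            if last is not None and key < last:
                raise ValueError(f"calls not sorted at {key}")
            last = key
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.pos + 1,
                alleles=(call.ref_allele, call.alt_allele),
            )
            flt = getattr(call, "filters", None) or ()
            if flt:
                for lab in sorted(flt):
                    rec.filter.add(lab)
            else:
                rec.filter.add("PASS")
            sample = rec.samples[sample_name]
            sample["GT"] = tuple(call.genotype)
            sample.phased = True
            if call.gq is not None:
                sample["GQ"] = int(round(min(call.gq, 9999)))
            if call.depth is not None:
                sample["DP"] = int(call.depth)
            if call.phase_set is not None:
                sample["PS"] = int(call.phase_set)
            out.write(rec)


@dataclass
class VcfRecord:
    """A parsed single-sample VCF row in internal coordinates."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: tuple
    phased: bool
    gq: Optional[int] = None
    depth: Optional[int] = None
    phase_set: Optional[int] = None
    filters: frozenset = field(default_factory=frozenset)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_pass(self) -> bool:
        return not self.filters


def read_vcf(path: str) -> list:
    """Parse a single-sample VCF back into :class:`VcfRecord` objects."""
    records = []
    with pysam.VariantFile(path) as vf:
        sample = vf.header.samples[0]
        for rec in vf:
            s = rec.samples[sample]
            gt = s["GT"]
            if gt is None or gt[0] is None:
                continue
            filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
            alt = rec.alts[0] if rec.alts else "."
            records.append(
                VcfRecord(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=alt,
                    genotype=tuple(gt),
                    phased=s.phased,
                    gq=s.get("GQ"),
                    depth=s.get("DP"),
                    phase_set=s.get("PS"),
                    filters=filters,
                )
            )
    return records


def read_bed(path: str) -> list:
    """Parse a BED file (0-based half-open) into Regions; ignores browser/
    track lines and columns beyond the third."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_fasta(path: str, sequences: dict) -> None:
    """Write sequences to FASTA and index it with faidx."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(path)


def write_sam(path: str, reads: Iterable[AlignedRead], contigs: dict) -> None:
    """Write reads (sorted by position) as a SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in contigs.items()],
    }
    names = {n: i for i, n in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (names[r.chrom], r.pos))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.query_sequence = read.sequence
            rec.flag = 16 if read.strand == "-" else 0
            rec.reference_id = names[read.chrom]
            rec.reference_start = read.pos
            rec.mapping_quality = read.mapq
            rec.cigartuples = [(_BAM_OPS.index(op), n) for op, n in read.cigar]
            if read.base_qualities is not None:
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.base_qualities)
                )
            out.write(rec)
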