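"""Aligned-read access and subgenome extraction.

The pipeline consumes an existing coordinate alignment (SAM/BAM).  When the
alignment was made against a whole genome, the organellar subgenome of
interest (e.g. the chloroplast, ``ChrC``) is extracted by reference name and
library statistics are accumulated: ``mappable_reads`` is the number of
distinct aligned reads in the input (primary records), ``mapped_reads`` the
number of those placed on the target subgenome.

Read filtering policy: unmapped, QC-fail and supplementary records are
excluded everywhere.  Secondary records (the upstream aligner may report up
to two placements, for the chloroplast inverted repeat) are kept in the
extracted stream so coverage stays symmetric across the repeats, but each
read is counted once, by its primary record, in library statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pysam

Strandness = str  # {"forward", "reverse", "unstranded"}

# CIGAR operation codes (SAM spec): M I D N S H P = X
_REF_ALIGNED = {0, 2, 7, 8}  # M, D, =, X: contiguous genomic alignment
_REF_GAP = 3  # N: reference skip (spliced-out intron)
_QUERY_ONLY = {1, 4}  # I, S


class AlignmentError(ValueError):
    """Raised for alignment inputs that violate preconditions."""


@dataclass
class LibraryStats:
    """Read counts for one library against one target subgenome."""

    mappable_reads: int
    mapped_reads: int
    target_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.mapped_reads <= self.mappable_reads:
            raise AlignmentError(
                f"mapped_reads {self.mapped_reads} outside "
                f"[0, mappable_reads={self.mappable_reads}]"
            )


def mapped_fraction(stats: LibraryStats) -> float:
    """Percentage of mappable reads placed on the target, 100*mapped/mappable.

    Rounded half-up to one decimal, matching how alignment-rate tables are
    conventionally printed (30.252 -> 30.3).
    """
    if stats.mappable_reads == 0:
        raise AlignmentError("mappable_reads is zero; mapped fraction undefined")
    pct = Decimal(100 * stats.mapped_reads) / Decimal(stats.mappable_reads)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def usable(read: pysam.AlignedSegment) -> bool:
    """True for records that participate in any analysis."""
    return not (read.is_unmapped or read.is_qcfail or read.is_supplementary)


def extract_subgenome(
    alignment: str | pysam.AlignmentFile,
    target_name: str,
    genome_size: int | None = None,
) -> tuple[list[pysam.AlignedSegment], LibraryStats]:
    """Extract all usable records on ``target_name`` plus library statistics.

    ``genome_size``, when given, is checked against the header's reference
    length for the target.  Raises :class:`AlignmentError` when the target is
    absent from the header (listing available names) or the size mismatches.
    """
    opened_here = isinstance(alignment, str)
    af = pysam.AlignmentFile(alignment) if opened_here else alignment
    try:
        names = list(af.references or [])
        if target_name not in names:
            raise AlignmentError(
                f"target {target_name!r} not in alignment header; "
                f"available references: {', '.join(names) or '(none)'}"
            )
        header_len = af.get_reference_length(target_name)
        if genome_size is not None and genome_size != header_len:
            raise AlignmentError(
                f"genome size {genome_size} does not match header length "
                f"{header_len} for {target_name}"
            )

        mappable = 0
        mapped = 0
        extracted: list[pysam.AlignedSegment] = []
        saw_paired = False
        for read in af:
            if not usable(read):
                continue
            on_target = read.reference_name == target_name
            if not read.is_secondary:
                mappable += 1
                if on_target:
                    mapped += 1
            if read.is_paired:
                saw_paired = True
            if on_target:
                extracted.append(read)
        if saw_paired:
            warnings.warn(
                "paired-end records found; mates are treated independently "
                "(no proper-pair logic)",
                stacklevel=2,
            )
        stats = LibraryStats(
            mappable_reads=mappable, mapped_reads=mapped, target_name=target_name
        )
        return extracted, stats
    finally:
        if opened_here:
            af.close()


def assign_strand(read: pysam.AlignedSegment, strandness: Strandness) -> str:
    """Transcript strand for one record under the library's strand protocol.

    ``forward``: transcript strand equals the alignment strand; ``reverse``:
    flipped (dUTP-style libraries); ``unstranded``: every read is assigned to
    the plus strand (documented limitation — no half-weighting).
    """
    aligned = "-" if read.is_reverse else "+"
    if strandness == "forward":
        return aligned
    if strandness == "reverse":
        return "-" if aligned == "+" else "+"
    if strandness == "unstranded":
        return "+"
    raise AlignmentError(f"unknown strandness {strandness!r}")


def aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Maximal contiguous genomic blocks [start, end) covered by the alignment.

    M/=/X/D advance within a block; N (spliced-out intron) splits blocks;
    I/S consume only the query.
    """
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    block_start = pos
    for op, length in read.cigartuples or []:
        if length == 0:
            continue
        if op in _REF_ALIGNED:
            pos += length
        elif op == _REF_GAP:
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        elif op in _QUERY_ONLY or op in (5, 6):
            continue
        else:  # pragma: no cover - SAM defines no further ops
            raise AlignmentError(f"unsupported CIGAR op {op}")
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks


def gap_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic [start, end) spans of N (reference-skip) CIGAR operations."""
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in _REF_ALIGNED:
            pos += length
        elif op == _REF_GAP:
            gaps.append((pos, pos + length))
            pos += length
    return gaps


@dataclass
class AlignedReadSummary:
    """Plain-data view of one alignment record."""

    seq_id: str
    start: int
    cigar_blocks: list[tuple[str, int]]
    strand_of_read: str
    is_primary: bool
    base_qualities: Sequence[int]
    query_bases: str

    @classmethod
    def from_pysam(cls, read: pysam.AlignedSegment) -> "AlignedReadSummary":
        blocks: list[tuple[str, int]] = []
        for op, length in read.cigartuples or []:
            if op in _REF_ALIGNED:
                if blocks and blocks[-1][0] == "aligned":
                    blocks[-1] = ("aligned", blocks[-1][1] + length)
                else:
                    blocks.append(("aligned", length))
            elif op == _REF_GAP:
                blocks.append(("gap", length))
        return cls(
            seq_id=read.reference_name or "",
            start=read.reference_start,
            cigar_blocks=blocks,
            strand_of_read="-" if read.is_reverse else "+",
            is_primary=not read.is_secondary,
            base_qualities=list(read.query_qualities or []),
            query_bases=read.query_sequence or "",
        )


def total_mapped(reads: Iterable[pysam.AlignedSegment]) -> int:
    """Number of distinct reads (primary records) in a stream."""
    return sum(1 for r in reads if not r.is_secondary)
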