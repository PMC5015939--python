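"""Intron splicing efficiency from junction- and boundary-spanning reads.

For each annotated intron, three read classes are counted:

* ``jR`` — spliced reads whose alignment contains a reference-skip (N) gap
  matching the intron's (donor, acceptor) coordinates exactly, with at least
  ``min_overhang`` aligned nt on each side;
* ``liR`` — unspliced reads with a contiguous aligned block straddling the
  5' exon/intron boundary (the donor);
* ``riR`` — likewise at the 3' intron/exon boundary (the acceptor).

Splicing efficiency is SE = jR / (jR + (liR + riR) / 2): an unspliced
transcript presents two boundaries where a spliced one presents a single
junction, so the boundary counts are averaged.  A read that traverses the
whole intron unspliced is counted at both boundaries.  Reads must match the
host gene's strand.  Exact junction coordinates are required for jR —
annotated junctions are treated as authoritative (as when novel-junction
discovery is disabled during alignment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from .alignment import Strandness, aligned_blocks, assign_strand, gap_blocks
from .annotation import IntronModel


class SplicingError(ValueError):
    """Raised for invalid splicing-analysis inputs."""


@dataclass(frozen=True)
class SplicingRecord:
    """One intron's junction/boundary read counts and efficiency."""

    intron_id: str
    seq_id: str
    start: int  # 0-based half-open internally; writers emit 1-based inclusive
    end: int
    strand: str
    junction_reads: int  # jR
    left_boundary_reads: int  # liR
    right_boundary_reads: int  # riR
    efficiency: float  # NaN when no supporting reads

    @property
    def total_support(self) -> int:
        return self.junction_reads + self.left_boundary_reads + self.right_boundary_reads


def _spans(block: tuple[int, int], pos: int, overhang: int) -> bool:
    """Contiguous aligned block covers [pos - overhang, pos + overhang)."""
    return block[0] <= pos - overhang and block[1] >= pos + overhang


def classify_read(
    read: pysam.AlignedSegment,
    intron: IntronModel,
    min_overhang: int = 1,
    strandness: Strandness = "forward",
) -> tuple[bool, bool, bool]:
    """(counts toward jR, toward liR, toward riR) for one record."""
    if intron.strand in "+-" and assign_strand(read, strandness) != intron.strand:
        return False, False, False
    blocks = aligned_blocks(read)
    is_junction = False
    for gap in gap_blocks(read):
        if gap == (intron.donor, intron.acceptor):
            left_ok = any(b[1] == intron.donor and b[1] - b[0] >= min_overhang for b in blocks)
            right_ok = any(b[0] == intron.acceptor and b[1] - b[0] >= min_overhang for b in blocks)
            if left_ok and right_ok:
                is_junction = True
            break
    left = any(_spans(b, intron.donor, min_overhang) for b in blocks)
    right = any(_spans(b, intron.acceptor, min_overhang) for b in blocks)
    return is_junction, left, right


def count_splice_support(
    reads: Iterable[pysam.AlignedSegment],
    intron: IntronModel,
    min_overhang: int = 1,
    strandness: Strandness = "forward",
) -> tuple[int, int, int]:
    """Tally (jR, liR, riR) for one intron over a read stream."""
    if min_overhang < 1:
        raise SplicingError("min_overhang must be >= 1")
    jr = lir = rir = 0
    for read in reads:
        j, l, r = classify_read(read, intron, min_overhang, strandness)
        jr += j
        lir += l
        rir += r
    return jr, lir, rir


def splicing_efficiency(jr: int, lir: int, rir: int) -> float:
    """SE = jR / (jR + (liR + riR)/2); NaN when jR + liR + riR = 0."""
    if min(jr, lir, rir) < 0:
        raise SplicingError("read counts must be non-negative")
    if jr + lir + rir == 0:
        return math.nan
    return jr / (jr + (lir + rir) / 2)


def splicing_table(
    reads: Sequence[pysam.AlignedSegment],
    introns: Sequence[IntronModel],
    min_overhang: int = 1,
    strandness: Strandness = "forward",
    min_support: int = 0,
) -> list[SplicingRecord]:
    """One :class:`SplicingRecord` per intron, in annotation order.

    ``min_support`` suppresses rows whose total read support falls below the
    threshold (e.g. tRNA introns in size-selected libraries); by default all
    introns are reported, with NaN efficiency at zero support.
    """
    records: list[SplicingRecord] = []
    for intron in introns:
        jr, lir, rir = count_splice_support(reads, intron, min_overhang, strandness)
        if jr + lir + rir < min_support:
            continue
        records.append(
            SplicingRecord(
                intron_id=intron.intron_id or intron.host_gene,
                seq_id=intron.intron.seq_id,
                start=intron.intron.start,
                end=intron.intron.end,
                strand=intron.strand,
                junction_reads=jr,
                left_boundary_reads=lir,
                right_boundary_reads=rir,
                efficiency=splicing_efficiency(jr, lir, rir),
            )
        )
    return records
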