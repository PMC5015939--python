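"""Coverage analysis: per-nucleotide stranded depth, overlapping-window
coverage, and exon/intron RPKM.

RPKM follows the classic definition RPKM = C * Ri / (Ti * L) with C = 1e9,
where Ri is the number of read alignments intersecting the feature by at
least one aligned nucleotide on the feature's strand, Ti the normalization
read total (by default the reads mapped to the target subgenome), and L the
feature length in nucleotides.

Window coverage uses overlapping windows (default 100 nt stepping by 50 nt)
whose raw depth sums are normalized per million reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .alignment import Strandness, aligned_blocks, assign_strand
from .annotation import FeatureAnnotation

RPKM_CONSTANT = 1e9
WINDOW_SCALE = 1e6


class CoverageError(ValueError):
    """Raised for invalid coverage inputs."""


@dataclass
class StrandedCoverage:
    """Per-nucleotide read depth for the plus and minus strands."""

    seq_id: str
    plus_depth: np.ndarray
    minus_depth: np.ndarray

    @property
    def genome_length(self) -> int:
        return len(self.plus_depth)

    def swap_strands(self) -> "StrandedCoverage":
        return StrandedCoverage(self.seq_id, self.minus_depth.copy(), self.plus_depth.copy())


@dataclass(frozen=True)
class WindowRecord:
    start: int
    end: int
    strand: str
    raw_sum: int
    normalized_value: float


@dataclass
class WindowCoverage:
    windows: list[WindowRecord]
    window_size: int
    step: int


@dataclass(frozen=True)
class RpkmRecord:
    """One feature's read count and normalized expression."""

    feature_id: str
    kind: str
    length: int
    read_count: int
    total_reads: int
    rpkm: float


def per_nucleotide_coverage(
    reads: Iterable[pysam.AlignedSegment],
    genome_length: int,
    strandness: Strandness = "forward",
    seq_id: str = "",
) -> StrandedCoverage:
    """Accumulate stranded per-nucleotide depth from aligned blocks.

    Each aligned block of each record increments depth over its span on the
    read's assigned transcript strand; N-gap (spliced-out) blocks increment
    nothing.  A read extending past the genome end is an error (reads
    wrapping a circular genome are not supported).
    """
    plus = np.zeros(genome_length, dtype=np.int64)
    minus = np.zeros(genome_length, dtype=np.int64)
    for read in reads:
        strand = assign_strand(read, strandness)
        track = plus if strand == "+" else minus
        for start, end in aligned_blocks(read):
            if end > genome_length:
                raise CoverageError(
                    f"read {read.query_name} aligned block ends at {end}, "
                    f"beyond genome length {genome_length}"
                )
            track[start:end] += 1
    return StrandedCoverage(seq_id=seq_id, plus_depth=plus, minus_depth=minus)


def window_starts(genome_length: int, window: int, step: int) -> list[int]:
    """Window start positions: 0, step, 2*step, ... while start < genome end."""
    return list(range(0, genome_length, step))


def windowed_coverage(
    track: StrandedCoverage,
    total_reads: int,
    window: int = 100,
    step: int = 50,
) -> WindowCoverage:
    """Overlapping-window coverage, normalized per million reads.

    Consecutive same-strand windows overlap by ``window - step`` nt; the last
    windows are truncated at the genome end.  ``normalized_value`` is
    raw_sum * 1e6 / total_reads.
    """
    if not window >= step >= 1:
        raise CoverageError(f"need window >= step >= 1, got {window}, {step}")
    if total_reads <= 0:
        raise CoverageError("total_reads must be positive for normalization")
    n = track.genome_length
    records: list[WindowRecord] = []
    for strand, depth in (("+", track.plus_depth), ("-", track.minus_depth)):
        csum = np.concatenate([[0], np.cumsum(depth)])
        for start in window_starts(n, window, step):
            end = min(start + window, n)
            raw = int(csum[end] - csum[start])
            records.append(
                WindowRecord(
                    start=start,
                    end=end,
                    strand=strand,
                    raw_sum=raw,
                    normalized_value=raw * WINDOW_SCALE / total_reads,
                )
            )
    return WindowCoverage(windows=records, window_size=window, step=step)


def rpkm(read_count: int, total_reads: int, length: int) -> float:
    """RPKM = C * Ri / (Ti * L) with C = 1e9."""
    if length < 1:
        raise CoverageError("feature length must be >= 1")
    if total_reads <= 0:
        raise CoverageError("total_reads must be positive")
    if read_count < 0:
        raise CoverageError("read count must be >= 0")
    return RPKM_CONSTANT * read_count / (total_reads * length)


def feature_rpkm(
    reads: Iterable[pysam.AlignedSegment],
    features: Sequence[FeatureAnnotation],
    total_reads: int,
    strandness: Strandness = "forward",
) -> list[RpkmRecord]:
    """Count reads per feature and compute RPKM, in annotation order.

    A read alignment counts toward a feature when any of its aligned blocks
    overlaps the feature interval by >= 1 nt and the read's transcript strand
    matches the feature strand (unstranded features accept both).  Gap blocks
    create no overlap, so spliced reads do not inflate intron counts.  One
    read overlapping several features counts toward each.
    """
    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for idx, feat in enumerate(features):
        if len(feat.interval) < 1:  # pragma: no cover - interval invariant
            raise CoverageError(f"zero-length feature {feat.feature_id}")
        strands = (feat.interval.strand,) if feat.interval.strand in "+-" else ("+", "-")
        for s in strands:
            trees[s][feat.interval.start:feat.interval.end] = idx

    counts = np.zeros(len(features), dtype=np.int64)
    for read in reads:
        strand = assign_strand(read, strandness)
        hit: set[int] = set()
        for start, end in aligned_blocks(read):
            for iv in trees[strand].overlap(start, end):
                hit.add(iv.data)
        for idx in hit:
            counts[idx] += 1

    return [
        RpkmRecord(
            feature_id=feat.feature_id,
            kind=feat.kind,
            length=len(feat.interval),
            read_count=int(counts[idx]),
            total_reads=total_reads,
            rpkm=rpkm(int(counts[idx]), total_reads, len(feat.interval)),
        )
        for idx, feat in enumerate(features)
    ]
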