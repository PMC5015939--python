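"""C-to-U RNA editing efficiency at annotated sites.

Chloroplast editing converts specific transcript cytidines to uridines.  In
a plus-strand pileup an edited site in a plus-strand gene shows C -> T; in a
minus-strand gene the transcript C appears as a plus-strand G and editing
shows G -> A.  Efficiency is edited / (edited + unedited):

* plus-strand (C) site:  T / (T + C)
* minus-strand (G) site: A / (A + G)

The pileup aggregates reads from both strands, as pileup-based variant
calling does; in regions with substantial antisense transcription the
antisense reads dilute the sense-strand signal (documented limitation).
Sites with zero informative depth report NaN, never 0 — "unobserved" is
distinct from "unedited".  Only annotated sites are evaluated; there is no
de novo editing-site discovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from .alignment import _REF_ALIGNED, _REF_GAP, _QUERY_ONLY
from .annotation import AnnotationError, EditingSite


@dataclass(frozen=True)
class BaseCounts:
    """Per-base pileup tallies at one site (plus-strand orientation)."""

    site_id: str
    total_depth: int
    count_A: int
    count_C: int
    count_G: int
    count_T: int

    def count(self, base: str) -> int:
        return getattr(self, f"count_{base.upper()}")


@dataclass(frozen=True)
class EditingRecord:
    site: EditingSite
    counts: BaseCounts
    efficiency: float  # NaN when informative depth is zero


def _base_at(read: pysam.AlignedSegment, position: int) -> tuple[str | None, int]:
    """(plus-strand base or None for deletion/skip, base quality) at a ref position.

    Returns ("", -1) when the read's alignment does not touch the position.
    """
    ref = read.reference_start
    query = 0
    for op, length in read.cigartuples or []:
        if op in _REF_ALIGNED:
            if op == 2:  # deletion: consumes reference only
                if ref <= position < ref + length:
                    return None, -1
                ref += length
            else:
                if ref <= position < ref + length:
                    qpos = query + (position - ref)
                    seq = read.query_sequence or ""
                    quals = read.query_qualities
                    base = seq[qpos].upper() if qpos < len(seq) else "N"
                    qual = quals[qpos] if quals is not None and qpos < len(quals) else 0
                    return base, qual
                ref += length
                query += length
        elif op == _REF_GAP:
            if ref <= position < ref + length:
                return None, -1
            ref += length
        elif op in _QUERY_ONLY:
            query += length
    return "", -1


def pileup_base_counts(
    reads: Iterable[pysam.AlignedSegment],
    site: EditingSite,
    min_base_quality: int = 0,
) -> BaseCounts:
    """Tally the plus-strand base each overlapping record reports at a site.

    Deletions and reference skips spanning the site count toward
    ``total_depth`` but toward none of the four base counts, as do bases
    below ``min_base_quality``.
    """
    depth = 0
    tally = {"A": 0, "C": 0, "G": 0, "T": 0}
    for read in reads:
        base, qual = _base_at(read, site.position)
        if base == "":
            continue  # read does not span the site
        depth += 1
        if base is not None and base in tally and qual >= min_base_quality:
            tally[base] += 1
    return BaseCounts(
        site_id=site.site_id,
        total_depth=depth,
        count_A=tally["A"],
        count_C=tally["C"],
        count_G=tally["G"],
        count_T=tally["T"],
    )


def editing_efficiency(counts: BaseCounts, site: EditingSite) -> float:
    """edited / (edited + unedited); NaN when the informative depth is zero."""
    if site.plus_strand_base == "C":
        edited, unedited = counts.count_T, counts.count_C
    elif site.plus_strand_base == "G":
        edited, unedited = counts.count_A, counts.count_G
    else:  # pragma: no cover - EditingSite invariant
        raise AnnotationError(f"site {site.site_id}: invalid reference base")
    if edited + unedited == 0:
        return math.nan
    return edited / (edited + unedited)


def editing_table(
    reads: Sequence[pysam.AlignedSegment],
    sites: Sequence[EditingSite],
    min_base_quality: int = 0,
) -> list[EditingRecord]:
    """One :class:`EditingRecord` per annotated site, in annotation order."""
    records = []
    for site in sites:
        counts = pileup_base_counts(reads, site, min_base_quality)
        records.append(
            EditingRecord(
                site=site, counts=counts, efficiency=editing_efficiency(counts, site)
            )
        )
    return records
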