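"""Genome and feature annotation model.

Reads a genome FASTA plus up to four GFF3 feature files (exons, introns,
splice sites, editing sites) into a coordinate-normalized annotation set.
GFF3 is 1-based inclusive; internally every interval is 0-based half-open,
so interval arithmetic needs no off-by-one bookkeeping.  All text written
back out is 1-based inclusive again.

Editing sites are cross-checked against the genome sequence at load time:
a chloroplast C-to-U editing site must sit on a plus-strand C (sense gene on
the plus strand) or a plus-strand G (sense gene on the minus strand).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from gffutils.feature import feature_from_line

STRANDS = ("+", "-", ".")
FEATURE_KINDS = ("exon", "intron", "splice_site", "editing_site")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware region: 0-based half-open [start, end) on ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature (exon, intron, splice site, or editing site)."""

    interval: GenomicInterval
    feature_id: str
    kind: str
    parent_gene: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise AnnotationError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class IntronModel:
    """An intron with its donor (5') and acceptor (3') splice coordinates.

    ``donor`` is the first intronic base and ``acceptor`` the first exonic
    base after the intron, i.e. donor == intron.start and
    acceptor == intron.end in 0-based half-open coordinates regardless of
    the host gene's strand.  Trans-spliced junctions are represented as
    independent entries, one per annotated junction.
    """

    intron: GenomicInterval
    host_gene: str = ""
    intron_id: str = ""

    def __post_init__(self) -> None:
        if len(self.intron) < 1:
            raise AnnotationError(f"zero-length intron {self.intron_id!r}")

    @property
    def donor(self) -> int:
        return self.intron.start

    @property
    def acceptor(self) -> int:
        return self.intron.end

    @property
    def strand(self) -> str:
        return self.intron.strand


@dataclass(frozen=True)
class EditingSite:
    """An annotated C-to-U editing site.

    ``plus_strand_base`` is C for sites in plus-strand genes and G for
    minus-strand genes (where the transcript C appears as a plus-strand G).
    """

    seq_id: str
    position: int
    plus_strand_base: str
    site_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.plus_strand_base not in ("C", "G"):
            raise AnnotationError(
                f"editing site {self.site_id}: plus-strand base must be C or G, "
                f"got {self.plus_strand_base!r}"
            )


@dataclass
class AnnotationSet:
    """All annotation needed by the three analyses, coordinate-normalized."""

    seq_id: str
    genome_length: int
    genome_seq: str = ""
    features: list[FeatureAnnotation] = field(default_factory=list)
    introns: list[IntronModel] = field(default_factory=list)
    editing_sites: list[EditingSite] = field(default_factory=list)

    def exons(self) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == "exon"]

    def intron_features(self) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == "intron"]

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise AnnotationError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.interval.end > self.genome_length:
                raise AnnotationError(
                    f"feature {f.feature_id} ends at {f.interval.end} beyond "
                    f"genome length {self.genome_length}"
                )
        for s in self.editing_sites:
            if not 0 <= s.position < self.genome_length:
                raise AnnotationError(
                    f"editing site {s.site_id} at {s.position} outside genome"
                )
            if self.genome_seq:
                ref = self.genome_seq[s.position].upper()
                if ref != s.plus_strand_base:
                    raise AnnotationError(
                        f"editing site {s.site_id}: annotated plus-strand base "
                        f"{s.plus_strand_base} does not match genome base {ref} "
                        f"at position {s.position + 1} (1-based)"
                    )
                if ref not in ("C", "G"):
                    raise AnnotationError(
                        f"editing site {s.site_id}: genome base {ref} is not C or G"
                    )


# ---------------------------------------------------------------------------
# GFF3 parsing


def _iter_gff3(stream: TextIO | str):
    """Yield (line_number, gffutils Feature) for every feature line."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises bare exceptions on bad lines
            raise AnnotationError(f"malformed GFF3 at line {lineno}: {exc}") from exc
        if feat.seqid is None or feat.start is None or feat.end is None:
            raise AnnotationError(f"malformed GFF3 at line {lineno}: missing fields")
        yield lineno, feat


def _feature_id(feat, default: str) -> str:
    for key in ("ID", "Name", "gene_id"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return default


def _parent(feat) -> str:
    for key in ("Parent", "gene", "Locus"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return ""


def _to_interval(feat) -> GenomicInterval:
    strand = feat.strand if feat.strand in ("+", "-") else "."
    return GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)


def read_fasta(stream: TextIO | str) -> tuple[str, str]:
    """Read a single-record FASTA; returns (seq_id, uppercase sequence)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = list(SeqIO.parse(stream, "fasta"))
    if not records:
        raise AnnotationError("FASTA contains no records")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def read_annotation(
    fasta: TextIO | str,
    exon_gff3: TextIO | str | None = None,
    intron_gff3: TextIO | str | None = None,
    splice_gff3: TextIO | str | None = None,
    editing_gff3: TextIO | str | None = None,
    derive_missing_introns: bool = True,
) -> AnnotationSet:
    """Load genome and GFF3 feature files into an :class:`AnnotationSet`.

    GFF3 coordinates (1-based inclusive) are shifted to 0-based half-open.
    Explicit intron/splice-site files take precedence over introns derived
    from exon gaps.  Editing sites are validated against the genome base.
    """
    seq_id, seq = read_fasta(fasta)
    ann = AnnotationSet(seq_id=seq_id, genome_length=len(seq), genome_seq=seq)

    if exon_gff3 is not None:
        for lineno, feat in _iter_gff3(exon_gff3):
            iv = _to_interval(feat)
            ann.features.append(
                FeatureAnnotation(
                    interval=iv,
                    feature_id=_feature_id(feat, f"exon_L{lineno}"),
                    kind="exon",
                    parent_gene=_parent(feat),
                )
            )

    explicit_introns: list[IntronModel] = []
    if intron_gff3 is not None:
        for lineno, feat in _iter_gff3(intron_gff3):
            iv = _to_interval(feat)
            fid = _feature_id(feat, f"intron_L{lineno}")
            ann.features.append(
                FeatureAnnotation(
                    interval=iv, feature_id=fid, kind="intron",
                    parent_gene=_parent(feat),
                )
            )
            explicit_introns.append(
                IntronModel(intron=iv, host_gene=_parent(feat) or fid, intron_id=fid)
            )

    if splice_gff3 is not None:
        explicit_introns = _merge_introns(
            explicit_introns, read_splice_sites(splice_gff3)
        )

    if explicit_introns:
        ann.introns = explicit_introns
    elif derive_missing_introns:
        ann.introns = derive_introns(ann)

    if editing_gff3 is not None:
        for lineno, feat in _iter_gff3(editing_gff3):
            iv = _to_interval(feat)
            if len(iv) != 1:
                raise AnnotationError(
                    f"editing site at GFF3 line {lineno} spans {len(iv)} nt; "
                    "expected a single nucleotide"
                )
            strand = iv.strand if iv.strand in ("+", "-") else "+"
            base = "C" if strand == "+" else "G"
            site_id = _feature_id(feat, f"site_{iv.start + 1}")
            ann.editing_sites.append(
                EditingSite(
                    seq_id=iv.seq_id,
                    position=iv.start,
                    plus_strand_base=base,
                    site_id=site_id,
                    strand=strand,
                )
            )
            ann.features.append(
                FeatureAnnotation(interval=iv, feature_id=site_id, kind="editing_site")
            )

    ann.validate()
    return ann


def read_splice_sites(stream: TextIO | str) -> list[IntronModel]:
    """Read a splice-site GFF3 in either of two dialects.

    Accepted encodings: one feature per intron span, or paired
    single-nucleotide donor/acceptor features grouped by Parent (or by a
    shared ID prefix before ``_donor``/``_acceptor``).  Both normalize to
    :class:`IntronModel` spans.
    """
    spans: list[IntronModel] = []
    pairs: dict[str, list[GenomicInterval]] = {}
    for lineno, feat in _iter_gff3(stream):
        iv = _to_interval(feat)
        fid = _feature_id(feat, f"junction_L{lineno}")
        if len(iv) == 1:
            key = _parent(feat)
            if not key:
                key = fid.rsplit("_donor", 1)[0].rsplit("_acceptor", 1)[0]
            pairs.setdefault(key, []).append(iv)
        else:
            spans.append(
                IntronModel(intron=iv, host_gene=_parent(feat) or fid, intron_id=fid)
            )
    for key, ivs in pairs.items():
        if len(ivs) != 2:
            raise AnnotationError(
                f"splice-site group {key!r} has {len(ivs)} single-nt features; "
                "expected a donor/acceptor pair"
            )
        a, b = sorted(ivs, key=lambda x: x.start)
        span = GenomicInterval(a.seq_id, a.start, b.end, a.strand)
        spans.append(IntronModel(intron=span, host_gene=key, intron_id=key))
    spans.sort(key=lambda m: m.intron.start)
    return spans


def _merge_introns(
    primary: list[IntronModel], extra: list[IntronModel]
) -> list[IntronModel]:
    """Union of intron models; ``primary`` wins on identical spans."""
    seen = {(m.intron.start, m.intron.end, m.strand) for m in primary}
    merged = list(primary)
    for m in extra:
        if (m.intron.start, m.intron.end, m.strand) not in seen:
            merged.append(m)
    merged.sort(key=lambda m: m.intron.start)
    return merged


def derive_introns(annotation: AnnotationSet) -> list[IntronModel]:
    """Derive introns as the gaps between consecutive same-gene exons.

    Only used when no explicit intron/splice-site annotation is supplied.
    Exons of a gene must be non-overlapping and on one strand.
    """
    by_gene: dict[str, list[FeatureAnnotation]] = {}
    for f in annotation.exons():
        key = f.parent_gene or f.feature_id
        by_gene.setdefault(key, []).append(f)

    introns: list[IntronModel] = []
    for gene, exons in by_gene.items():
        exons = sorted(exons, key=lambda f: f.interval.start)
        strands = {f.interval.strand for f in exons}
        if len(strands) > 1:
            raise AnnotationError(f"gene {gene}: exons on multiple strands")
        strand = strands.pop()
        for left, right in zip(exons, exons[1:]):
            if right.interval.start < left.interval.end:
                raise AnnotationError(
                    f"gene {gene}: overlapping exons "
                    f"{left.feature_id} and {right.feature_id}"
                )
            if right.interval.start == left.interval.end:
                continue  # abutting exons leave no intron
            iv = GenomicInterval(
                left.interval.seq_id, left.interval.end, right.interval.start, strand
            )
            n = sum(1 for m in introns if m.host_gene == gene) + 1
            introns.append(
                IntronModel(intron=iv, host_gene=gene, intron_id=f"{gene}.intron{n}")
            )
    introns.sort(key=lambda m: m.intron.start)
    return introns


# ---------------------------------------------------------------------------
# GFF3 output (round-trip support)


def _gff3_line(iv: GenomicInterval, kind: str, feature_id: str, parent: str) -> str:
    attrs = f"ID={feature_id}"
    if parent:
        attrs += f";Parent={parent}"
    return "\t".join(
        [
            iv.seq_id,
            "plastidseq",
            kind,
            str(iv.start + 1),
            str(iv.end),
            ".",
            iv.strand if iv.strand in ("+", "-") else ".",
            ".",
            attrs,
        ]
    )


def write_gff3(
    features: Iterable[FeatureAnnotation] | Sequence[IntronModel], stream: TextIO
) -> None:
    """Write features (or intron models) as GFF3, 1-based inclusive."""
    stream.write("##gff-version 3\n")
    for f in features:
        if isinstance(f, IntronModel):
            stream.write(_gff3_line(f.intron, "intron", f.intron_id, f.host_gene) + "\n")
        else:
            stream.write(
                _gff3_line(f.interval, f.kind, f.feature_id, f.parent_gene) + "\n"
            )
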