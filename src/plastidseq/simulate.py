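"""Synthetic plastid RNA-seq fixtures with exact per-read truth.

Generates a toy circular-genome-free plastome layout (genes with exons and
introns on both strands), a random genome sequence with C/G bases forced at
declared editing sites, and strand-specific single-end reads emitted as real
SAM records.  Every stochastic choice made while emitting a read —
spliced or unspliced at each intron, edited or unedited at each site, sense
vs antisense vs intergenic origin — is recorded in a :class:`TruthTable` at
emission time, so pipeline counts can be checked for exact (not statistical)
agreement.

The generator emulates the salient features of a strand-specific chloroplast
library: genic sense coverage, a minority antisense/intergenic (pncRNA-like)
read population, per-intron spliced/unspliced mixtures, and per-site
edited/unedited base mixtures.  It does not model sequencing error, quality
variation, fragment-length distributions, or the inverted repeat (no
multi-mapping); base qualities are constant at Q40.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .annotation import (
    AnnotationSet,
    EditingSite,
    FeatureAnnotation,
    GenomicInterval,
    IntronModel,
    write_gff3,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
BASE_QUALITY = 40


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: name, strand, and exon spans (0-based half-open, sorted)."""

    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]) if b[0] > a[1]
        ]


@dataclass
class SimulationConfig:
    genome_length: int = 30_000
    seq_id: str = "ChrC"
    genes: list[GeneModel] = field(default_factory=list)
    editing_positions: list[tuple[str, int]] = field(default_factory=list)
    per_intron_spliced_fraction: dict[str, float] = field(default_factory=dict)
    per_site_edited_fraction: dict[str, float] = field(default_factory=dict)
    default_spliced_fraction: float = 0.7
    default_edited_fraction: float = 0.8
    antisense_fraction: float = 0.05
    intergenic_fraction: float = 0.03
    read_length: int = 80
    reads_per_gene: int = 4_000
    seed: int = 0

    def validate(self) -> None:
        for frac in (
            self.default_spliced_fraction,
            self.default_edited_fraction,
            self.antisense_fraction,
            self.intergenic_fraction,
            *self.per_intron_spliced_fraction.values(),
            *self.per_site_edited_fraction.values(),
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"fraction {frac} outside [0, 1]")
        for gene in self.genes:
            prev_end = 0
            for start, end in gene.exons:
                if not 0 <= start < end <= self.genome_length:
                    raise SimulationError(
                        f"gene {gene.name}: exon ({start}, {end}) outside genome "
                        f"of length {self.genome_length}"
                    )
                if start < prev_end:
                    raise SimulationError(f"gene {gene.name}: exons out of order")
                prev_end = end
        if self.read_length < 2:
            raise SimulationError("read_length must be >= 2")


def default_config(seed: int = 0, reads_per_gene: int = 4_000) -> SimulationConfig:
    """A 12-gene plastome-like layout: 10 introns, 12 editing sites.

    Genes alternate strands with ~250 nt intergenic gaps; intron lengths
    (200-300 nt) exceed the read length so unspliced reads usually span a
    single boundary, as in real chloroplast group I/II introns.  A 5%
    antisense and 3% intergenic read fraction emulates the minority
    pncRNA population of stranded chloroplast libraries.
    """
    genes: list[GeneModel] = []
    cursor = 300
    gap = 250
    # eight 2-exon genes, one 3-exon gene, three single-exon genes
    for i in range(8):
        strand = "+" if i % 2 == 0 else "-"
        e1 = (cursor, cursor + 400)
        intron_len = 300 if i % 2 == 0 else 250
        e2 = (e1[1] + intron_len, e1[1] + intron_len + 400)
        genes.append(GeneModel(f"g{i + 1:02d}", strand, (e1, e2)))
        cursor = e2[1] + gap
    e1 = (cursor, cursor + 300)
    e2 = (e1[1] + 200, e1[1] + 500)
    e3 = (e2[1] + 200, e2[1] + 500)
    genes.append(GeneModel("g09", "+", (e1, e2, e3)))
    cursor = e3[1] + gap
    for i, strand in enumerate(("-", "+", "-")):
        span = (cursor, cursor + 500)
        genes.append(GeneModel(f"g{10 + i}", strand, (span,)))
        cursor = span[1] + gap

    editing_positions = []
    site_fracs = [0.0, 0.15, 0.3, 0.45, 0.55, 0.65, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0]
    per_site: dict[str, float] = {}
    for gene, frac in zip(genes, site_fracs):
        pos = gene.exons[0][0] + 57
        editing_positions.append((gene.name, pos))
        per_site[f"{gene.name}_{pos + 1}"] = frac

    spliced_fracs = [0.3, 0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.4, 0.65]
    per_intron: dict[str, float] = {}
    idx = 0
    for gene in genes:
        for n, _ in enumerate(gene.introns(), start=1):
            per_intron[f"{gene.name}.intron{n}"] = spliced_fracs[idx % len(spliced_fracs)]
            idx += 1

    return SimulationConfig(
        genome_length=cursor + 300,
        genes=genes,
        editing_positions=editing_positions,
        per_intron_spliced_fraction=per_intron,
        per_site_edited_fraction=per_site,
        reads_per_gene=reads_per_gene,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fixture construction


@dataclass
class Fixture:
    config: SimulationConfig
    annotation: AnnotationSet
    header: pysam.AlignmentHeader

    @property
    def genome_seq(self) -> str:
        return self.annotation.genome_seq


@dataclass
class TruthTable:
    """Exact per-read tallies recorded while reads were emitted."""

    per_intron: dict[str, list[int]] = field(default_factory=dict)  # id -> [jR,liR,riR]
    per_site: dict[str, dict[str, int]] = field(default_factory=dict)
    per_feature: dict[str, int] = field(default_factory=dict)
    plus_depth: np.ndarray | None = None
    minus_depth: np.ndarray | None = None
    n_reads: int = 0

    def to_frame(self):
        import pandas as pd

        rows = []
        for iid, (jr, lir, rir) in self.per_intron.items():
            rows.append(("intron", iid, jr, lir, rir))
        for sid, tally in self.per_site.items():
            rows.append(
                ("editing_site", sid, tally["edited"], tally["unedited"], tally["depth"])
            )
        for fid, count in self.per_feature.items():
            rows.append(("feature", fid, count, 0, 0))
        return pd.DataFrame(rows, columns=["kind", "id", "a", "b", "c"])


def make_fixture(config: SimulationConfig) -> Fixture:
    """Build genome sequence and annotation for a configuration.

    Deterministic given ``config.seed``.  The genome is random A/C/G/T with
    the base at each declared editing site forced to C (plus-strand gene) or
    G (minus-strand gene) so the site validates against the FASTA.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(np.array(list("ACGT")), size=config.genome_length)

    by_name = {g.name: g for g in config.genes}
    sites: list[EditingSite] = []
    for gene_name, pos in config.editing_positions:
        gene = by_name[gene_name]
        if not any(s <= pos < e for s, e in gene.exons):
            raise SimulationError(
                f"editing site at {pos} not inside an exon of {gene_name}"
            )
        base = "C" if gene.strand == "+" else "G"
        seq[pos] = base
        sites.append(
            EditingSite(
                seq_id=config.seq_id,
                position=pos,
                plus_strand_base=base,
                site_id=f"{gene_name}_{pos + 1}",
                strand=gene.strand,
            )
        )

    site_features = [
        FeatureAnnotation(
            interval=GenomicInterval(config.seq_id, s.position, s.position + 1, s.strand),
            feature_id=s.site_id,
            kind="editing_site",
            parent_gene=s.site_id.rsplit("_", 1)[0],
        )
        for s in sites
    ]

    features: list[FeatureAnnotation] = []
    introns: list[IntronModel] = []
    for gene in config.genes:
        for n, (start, end) in enumerate(gene.exons, start=1):
            features.append(
                FeatureAnnotation(
                    interval=GenomicInterval(config.seq_id, start, end, gene.strand),
                    feature_id=f"{gene.name}.exon{n}",
                    kind="exon",
                    parent_gene=gene.name,
                )
            )
        for n, (start, end) in enumerate(gene.introns(), start=1):
            iv = GenomicInterval(config.seq_id, start, end, gene.strand)
            iid = f"{gene.name}.intron{n}"
            features.append(
                FeatureAnnotation(
                    interval=iv, feature_id=iid, kind="intron", parent_gene=gene.name
                )
            )
            introns.append(IntronModel(intron=iv, host_gene=gene.name, intron_id=iid))
    features.extend(site_features)

    ann = AnnotationSet(
        seq_id=config.seq_id,
        genome_length=config.genome_length,
        genome_seq="".join(seq),
        features=features,
        introns=introns,
        editing_sites=sites,
    )
    ann.validate()
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.seq_id, "LN": config.genome_length}],
        }
    )
    return Fixture(config=config, annotation=ann, header=header)


# ---------------------------------------------------------------------------
# Read emission


def _make_record(
    header: pysam.AlignmentHeader,
    name: str,
    start: int,
    cigar: list[tuple[int, int]],
    seq: str,
    reverse: bool,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = cigar
    rec.flag = 16 if reverse else 0
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(
        chr(BASE_QUALITY + 33) * len(seq)
    )
    return rec


def _walk_gene_read(
    gene: GeneModel,
    start: int,
    read_length: int,
    spliced: dict[tuple[int, int], bool],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Genomic (aligned blocks, gap blocks) for a read of a gene transcript.

    Walks rightward from ``start`` collecting aligned nucleotides; at the
    donor of an intron whose transcript copy is spliced, jumps to the
    acceptor (an N gap).  Truncated at the gene end.
    """
    introns = gene.introns()
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = start
    remaining = read_length
    block_start = pos
    while remaining > 0 and pos < gene.end:
        jumped = False
        for donor, acceptor in introns:
            if pos == donor and pos > start and spliced.get((donor, acceptor), False):
                if pos > block_start:
                    blocks.append((block_start, pos))
                gaps.append((donor, acceptor))
                pos = acceptor
                block_start = pos
                jumped = True
                break
        if not jumped:
            pos += 1
            remaining -= 1
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks, gaps


def _blocks_to_cigar(
    blocks: list[tuple[int, int]], gaps: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    for i, (bs, be) in enumerate(blocks):
        cigar.append((0, be - bs))  # M
        if i < len(gaps):
            gs, ge = gaps[i]
            cigar.append((3, ge - gs))  # N
    return cigar


def simulate_reads(
    config: SimulationConfig, fixture: Fixture
) -> tuple[list[pysam.AlignedSegment], TruthTable]:
    """Emit strand-specific SAM records and their exact truth table.

    Each read is drawn from a gene (or, with the configured probabilities,
    antisense to a gene or from an intergenic gap).  A sense read crossing an
    intron donor is spliced — an N gap with the exact annotated junction —
    with the intron's configured probability; a sense read covering an
    editing site of its own gene carries the edited base with the site's
    configured probability.  Antisense and intergenic reads are contiguous
    and unedited.  Truth counts use the same read-classification rules as
    the analyses (exact junction, >= 1 nt overhang, strand match) applied by
    brute force to each emitted read's geometry.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome = fixture.genome_seq
    ann = fixture.annotation
    genes = config.genes
    n_total = config.reads_per_gene * len(genes)

    site_by_gene: dict[str, list[EditingSite]] = {}
    for site in ann.editing_sites:
        gene_name = site.site_id.rsplit("_", 1)[0]
        site_by_gene.setdefault(gene_name, []).append(site)

    gaps = _intergenic_gaps(config)

    truth = TruthTable(
        per_intron={m.intron_id: [0, 0, 0] for m in ann.introns},
        per_site={
            s.site_id: {"edited": 0, "unedited": 0, "depth": 0}
            for s in ann.editing_sites
        },
        per_feature={f.feature_id: 0 for f in ann.features},
        plus_depth=np.zeros(config.genome_length, dtype=np.int64),
        minus_depth=np.zeros(config.genome_length, dtype=np.int64),
    )

    reads: list[pysam.AlignedSegment] = []
    for i in range(n_total):
        u = rng.random()
        if u < config.intergenic_fraction and gaps:
            blocks, gblocks, strand, edits = _emit_intergenic(config, gaps, rng)
        elif u < config.intergenic_fraction + config.antisense_fraction:
            blocks, gblocks, strand, edits = _emit_antisense(config, genes, rng)
        else:
            blocks, gblocks, strand, edits = _emit_sense(
                config, genes, site_by_gene, rng
            )
        seq = _read_sequence(genome, blocks, edits)
        rec = _make_record(
            fixture.header,
            f"read{i:07d}",
            blocks[0][0],
            _blocks_to_cigar(blocks, gblocks),
            seq,
            reverse=(strand == "-"),
        )
        reads.append(rec)
        _tally(truth, ann, blocks, gblocks, strand, seq)

    truth.n_reads = len(reads)
    reads.sort(key=lambda r: r.reference_start)
    return reads, truth


def _intergenic_gaps(config: SimulationConfig) -> list[tuple[int, int]]:
    spans = sorted((g.start, g.end) for g in config.genes)
    gaps = []
    prev = 0
    for s, e in spans:
        if s - prev >= config.read_length:
            gaps.append((prev, s))
        prev = e
    if config.genome_length - prev >= config.read_length:
        gaps.append((prev, config.genome_length))
    return gaps


def _emit_sense(config, genes, site_by_gene, rng):
    # Draw (molecule, start) so read density is uniform over each transcript:
    # splice decisions are made per molecule first, and starts landing inside
    # a spliced-out intron are rejected (those positions do not exist on the
    # molecule).  This makes jR vs liR/riR proportions reflect the configured
    # spliced fraction, as in a real library.
    while True:
        gene = genes[rng.integers(len(genes))]
        spliced = {
            (d, a): rng.random()
            < config.per_intron_spliced_fraction.get(
                f"{gene.name}.intron{n}", config.default_spliced_fraction
            )
            for n, (d, a) in enumerate(gene.introns(), start=1)
        }
        start = int(rng.integers(gene.start, gene.end - 1))
        if not any(d <= start < a and spl for (d, a), spl in spliced.items()):
            break
    blocks, gblocks = _walk_gene_read(gene, start, config.read_length, spliced)
    edits = {}
    for site in site_by_gene.get(gene.name, []):
        if any(bs <= site.position < be for bs, be in blocks):
            frac = config.per_site_edited_fraction.get(
                site.site_id, config.default_edited_fraction
            )
            if rng.random() < frac:
                edits[site.position] = "T" if site.plus_strand_base == "C" else "A"
    return blocks, gblocks, gene.strand, edits


def _emit_antisense(config, genes, rng):
    gene = genes[rng.integers(len(genes))]
    hi = max(gene.start + 1, gene.end - config.read_length)
    start = int(rng.integers(gene.start, hi))
    end = min(start + config.read_length, gene.end)
    strand = "-" if gene.strand == "+" else "+"
    return [(start, end)], [], strand, {}


def _emit_intergenic(config, gaps, rng):
    gs, ge = gaps[rng.integers(len(gaps))]
    start = int(rng.integers(gs, ge - config.read_length + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return [(start, start + config.read_length)], [], strand, {}


def _read_sequence(genome: str, blocks, edits: dict[int, str]) -> str:
    parts = []
    for bs, be in blocks:
        chunk = genome[bs:be]
        local_edits = {p - bs: b for p, b in edits.items() if bs <= p < be}
        if local_edits:
            chunk = "".join(
                local_edits.get(i, c) for i, c in enumerate(chunk)
            )
        parts.append(chunk)
    return "".join(parts)


def _tally(truth: TruthTable, ann: AnnotationSet, blocks, gblocks, strand, seq) -> None:
    """Brute-force per-read truth bookkeeping (mirrors the analysis rules)."""
    track = truth.plus_depth if strand == "+" else truth.minus_depth
    for bs, be in blocks:
        track[bs:be] += 1

    for feat in ann.features:
        iv = feat.interval
        if iv.strand in "+-" and iv.strand != strand:
            continue
        if any(bs < iv.end and iv.start < be for bs, be in blocks):
            truth.per_feature[feat.feature_id] += 1

    for m in ann.introns:
        if m.strand in "+-" and m.strand != strand:
            continue
        counts = truth.per_intron[m.intron_id]
        if (m.donor, m.acceptor) in gblocks:
            left = any(be == m.donor and be - bs >= 1 for bs, be in blocks)
            right = any(bs == m.acceptor and be - bs >= 1 for bs, be in blocks)
            if left and right:
                counts[0] += 1
        if any(bs <= m.donor - 1 and be >= m.donor + 1 for bs, be in blocks):
            counts[1] += 1
        if any(bs <= m.acceptor - 1 and be >= m.acceptor + 1 for bs, be in blocks):
            counts[2] += 1

    offset = 0
    spans = []  # (genomic start, genomic end, query offset)
    for bs, be in blocks:
        spans.append((bs, be, offset))
        offset += be - bs
    for site in ann.editing_sites:
        tallied = False
        for bs, be, qoff in spans:
            if bs <= site.position < be:
                base = seq[qoff + (site.position - bs)]
                tally = truth.per_site[site.site_id]
                tally["depth"] += 1
                edited_base = "T" if site.plus_strand_base == "C" else "A"
                if base == edited_base:
                    tally["edited"] += 1
                elif base == site.plus_strand_base:
                    tally["unedited"] += 1
                tallied = True
                break
        if not tallied:
            for gs, ge in gblocks:
                if gs <= site.position < ge:
                    truth.per_site[site.site_id]["depth"] += 1
                    break


# ---------------------------------------------------------------------------
# Focused simulators for parameter-recovery studies


def simulate_junction_reads(
    n: int,
    spliced_fraction: float,
    read_length: int = 80,
    intron_length: int = 40,
    donor: int = 200,
    seed: int = 0,
    seq_id: str = "chr",
    strand: str = "+",
) -> tuple[list[pysam.AlignedSegment], IntronModel, int]:
    """n reads all informative for one short intron; returns (reads, intron, jR_true).

    The intron is shorter than the read length, so every unspliced read spans
    both boundaries and every spliced read spans the junction: the SE
    estimator is then exactly binomial in the spliced count.
    """
    if intron_length > read_length - 2:
        raise SimulationError("intron must be shorter than read_length - 2")
    acceptor = donor + intron_length
    genome_length = donor + read_length + intron_length + 400
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": seq_id, "LN": genome_length}]}
    )
    intron = IntronModel(
        intron=GenomicInterval(seq_id, donor, acceptor, strand),
        host_gene="gene",
        intron_id="gene.intron1",
    )
    rng = np.random.default_rng(seed)
    reads = []
    jr_true = 0
    for i in range(n):
        o = int(rng.integers(1, read_length - intron_length))  # left overhang
        spliced = rng.random() < spliced_fraction
        if spliced:
            jr_true += 1
            cigar = [(0, o), (3, intron_length), (0, read_length - o)]
        else:
            cigar = [(0, read_length)]
        reads.append(
            _make_record(
                header,
                f"jread{i:06d}",
                donor - o,
                cigar,
                "A" * read_length,
                reverse=(strand == "-"),
            )
        )
    return reads, intron, jr_true


def simulate_site_reads(
    n: int,
    edited_fraction: float,
    site_strand: str = "+",
    read_length: int = 60,
    position: int = 150,
    seed: int = 0,
    seq_id: str = "chr",
) -> tuple[list[pysam.AlignedSegment], EditingSite, int]:
    """n reads covering one editing site; returns (reads, site, edited_true)."""
    base = "C" if site_strand == "+" else "G"
    edited_base = "T" if base == "C" else "A"
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": seq_id, "LN": position + read_length + 200}]}
    )
    site = EditingSite(
        seq_id=seq_id,
        position=position,
        plus_strand_base=base,
        site_id=f"gene_{position + 1}",
        strand=site_strand,
    )
    rng = np.random.default_rng(seed)
    reads = []
    edited_true = 0
    for i in range(n):
        offset = int(rng.integers(0, read_length))
        start = position - offset
        edited = rng.random() < edited_fraction
        if edited:
            edited_true += 1
        seq = list("G" * read_length if base == "C" else "C" * read_length)
        seq[offset] = edited_base if edited else base
        reads.append(
            _make_record(
                header,
                f"eread{i:06d}",
                start,
                [(0, read_length)],
                "".join(seq),
                reverse=(site_strand == "-"),
            )
        )
    return reads, site, edited_true


# ---------------------------------------------------------------------------
# File output


def write_fixture(
    fixture: Fixture,
    reads: Sequence[pysam.AlignedSegment],
    truth: TruthTable,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, four GFF3 files, a SAM, and the truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = fixture.annotation
    paths = {
        "fasta": outdir / "genome.fasta",
        "exons": outdir / "exon.gff3",
        "introns": outdir / "intron.gff3",
        "splice_sites": outdir / "splice_sites.gff3",
        "editing_sites": outdir / "editing_sites.gff3",
        "sam": outdir / "reads.sam",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{ann.seq_id}\n")
        seq = ann.genome_seq
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(paths["exons"], "w") as fh:
        write_gff3(ann.exons(), fh)
    with open(paths["introns"], "w") as fh:
        write_gff3(ann.intron_features(), fh)
    with open(paths["splice_sites"], "w") as fh:
        write_gff3(ann.introns, fh)
    with open(paths["editing_sites"], "w") as fh:
        write_gff3(
            [f for f in ann.features if f.kind == "editing_site"], fh
        )
    with pysam.AlignmentFile(str(paths["sam"]), "wh", header=fixture.header) as sam:
        for rec in reads:
            sam.write(rec)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
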