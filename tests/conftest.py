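import numpy as np
import pysam
import pytest

from plastidseq import (
    default_config,
    extract_subgenome,
    make_fixture,
    read_annotation,
    simulate_reads,
    write_fixture,
)


def make_header(seq_id: str = "chr", length: int = 10_000) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": seq_id, "LN": length}]}
    )


def cigar_query_length(cigarstring: str) -> int:
    length = 0
    num = ""
    for ch in cigarstring:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                length += int(num)
            num = ""
    return length


def make_read(
    header: pysam.AlignmentHeader,
    start: int,
    cigar: str,
    name: str = "read",
    seq: str | None = None,
    reverse: bool = False,
    quality: int = 40,
    secondary: bool = False,
    ref_id: int = 0,
) -> pysam.AlignedSegment:
    """Build one in-memory alignment record from a CIGAR string."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = ref_id
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    if seq is None:
        seq = "A" * cigar_query_length(cigar)
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(chr(quality + 33) * len(seq))
    flag = 0
    if reverse:
        flag |= 16
    if secondary:
        flag |= 256
    rec.flag = flag
    return rec


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Large simulated library (~50k reads, 12 genes, 10 introns, 12 sites).

    Returns (config, fixture, truth, file paths, extracted reads, stats,
    reloaded annotation): everything downstream of the real file formats.
    """
    config = default_config(seed=11, reads_per_gene=4_200)
    fixture = make_fixture(config)
    reads, truth = simulate_reads(config, fixture)
    outdir = tmp_path_factory.mktemp("sim")
    paths = write_fixture(fixture, reads, truth, outdir)
    extracted, stats = extract_subgenome(str(paths["sam"]), config.seq_id)
    annotation = read_annotation(
        open(paths["fasta"]),
        exon_gff3=open(paths["exons"]),
        intron_gff3=open(paths["introns"]),
        editing_gff3=open(paths["editing_sites"]),
    )
    return config, fixture, truth, paths, extracted, stats, annotation


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """Small on-disk fixture for pipeline/CLI tests."""
    config = default_config(seed=3, reads_per_gene=300)
    fixture = make_fixture(config)
    reads, truth = simulate_reads(config, fixture)
    outdir = tmp_path_factory.mktemp("small")
    paths = write_fixture(fixture, reads, truth, outdir)
    return config, truth, paths


@pytest.fixture
def rng():
    return np.random.default_rng(42)
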