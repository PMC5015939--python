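import io

import numpy as np
import pytest

from plastidseq import (
    AnnotationError,
    AnnotationSet,
    FeatureAnnotation,
    GenomicInterval,
    derive_introns,
    read_annotation,
    write_gff3,
)
from plastidseq.annotation import read_splice_sites

FASTA_500 = ">chr\n" + "A" * 500 + "\n"


def gff(*rows: str) -> str:
    return "##gff-version 3\n" + "".join(r + "\n" for r in rows)


class TestReadAnnotation:
    def test_one_based_inclusive_becomes_zero_based_half_open(self):
        text = gff(
            "chr\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g",
            "chr\tsrc\texon\t201\t300\t.\t+\t.\tID=e2;Parent=g",
        )
        ann = read_annotation(FASTA_500, exon_gff3=text)
        assert [(f.interval.start, f.interval.end) for f in ann.exons()] == [
            (0, 100),
            (200, 300),
        ]

    def test_empty_gff3_body_yields_empty_annotation(self):
        ann = read_annotation(FASTA_500, exon_gff3="##gff-version 3\n")
        assert ann.genome_length == 500
        assert ann.features == []

    def test_editing_site_base_checked_against_fasta(self):
        # genome is all A: neither C (plus) nor G (minus) matches
        sites = gff("chr\tsrc\tediting_site\t50\t50\t.\t+\t.\tID=geneX_50")
        with pytest.raises(AnnotationError, match="geneX_50"):
            read_annotation(FASTA_500, editing_gff3=sites)

    def test_editing_site_accepted_when_base_matches(self):
        seq = "A" * 49 + "C" + "A" * 450
        fasta = f">chr\n{seq}\n"
        sites = gff("chr\tsrc\tediting_site\t50\t50\t.\t+\t.\tID=geneX_50")
        ann = read_annotation(fasta, editing_gff3=sites)
        (site,) = ann.editing_sites
        assert site.position == 49 and site.plus_strand_base == "C"

    def test_minus_strand_site_expects_plus_strand_g(self):
        seq = "A" * 49 + "G" + "A" * 450
        ann = read_annotation(
            f">chr\n{seq}\n",
            editing_gff3=gff("chr\tsrc\tediting_site\t50\t50\t.\t-\t.\tID=geneY_50"),
        )
        assert ann.editing_sites[0].plus_strand_base == "G"

    def test_malformed_line_error_names_line_number(self):
        text = "##gff-version 3\nchr\tonly three\tfields\n"
        with pytest.raises(AnnotationError, match="line 2"):
            read_annotation(FASTA_500, exon_gff3=text)

    def test_feature_beyond_genome_length_rejected(self):
        text = gff("chr\tsrc\texon\t400\t600\t.\t+\t.\tID=e1")
        with pytest.raises(AnnotationError, match="beyond"):
            read_annotation(FASTA_500, exon_gff3=text)


class TestDeriveIntrons:
    @staticmethod
    def _annotation(exons, strand="+", gene="g", length=1000):
        feats = [
            FeatureAnnotation(
                interval=GenomicInterval("chr", s, e, strand),
                feature_id=f"{gene}.e{i}",
                kind="exon",
                parent_gene=gene,
            )
            for i, (s, e) in enumerate(exons, start=1)
        ]
        return AnnotationSet(seq_id="chr", genome_length=length, features=feats)

    def test_gap_between_two_exons_is_one_intron(self):
        introns = derive_introns(self._annotation([(0, 100), (200, 300)]))
        assert [(m.donor, m.acceptor) for m in introns] == [(100, 200)]

    def test_single_exon_gene_has_no_introns(self):
        assert derive_introns(self._annotation([(0, 100)])) == []

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError, match="overlapping"):
            derive_introns(self._annotation([(0, 150), (100, 300)]))

    @pytest.mark.parametrize("seed", range(5))
    def test_exons_and_introns_tile_gene_span(self, seed):
        # oracle: brute-force gap enumeration over sorted random exon layouts
        rng = np.random.default_rng(seed)
        cuts = np.sort(rng.choice(np.arange(1, 900), size=2 * rng.integers(2, 6), replace=False))
        exons = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, len(cuts), 2)]
        introns = derive_introns(self._annotation(exons))
        expected_gaps = [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]
        assert [(m.donor, m.acceptor) for m in introns] == expected_gaps
        # exons + introns tile the gene span exactly, with no overlap
        pieces = sorted(exons + expected_gaps)
        assert pieces[0][0] == exons[0][0] and pieces[-1][1] == exons[-1][1]
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2

    def test_explicit_introns_take_precedence_over_derivation(self):
        exons = gff(
            "chr\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g",
            "chr\tsrc\texon\t201\t300\t.\t+\t.\tID=e2;Parent=g",
        )
        explicit = gff("chr\tsrc\tintron\t90\t210\t.\t+\t.\tID=weird;Parent=g")
        ann = read_annotation(FASTA_500, exon_gff3=exons, intron_gff3=explicit)
        assert [(m.donor, m.acceptor) for m in ann.introns] == [(89, 210)]


class TestSpliceSiteDialects:
    def test_intron_span_dialect(self):
        models = read_splice_sites(
            gff("chr\tsrc\tsplice_site\t101\t200\t.\t+\t.\tID=g.intron1;Parent=g")
        )
        assert [(m.donor, m.acceptor, m.strand) for m in models] == [(100, 200, "+")]

    def test_paired_single_nucleotide_dialect_matches_span_dialect(self):
        paired = read_splice_sites(
            gff(
                "chr\tsrc\tsplice_site\t101\t101\t.\t+\t.\tID=g.intron1_donor;Parent=g.intron1",
                "chr\tsrc\tsplice_site\t200\t200\t.\t+\t.\tID=g.intron1_acceptor;Parent=g.intron1",
            )
        )
        assert [(m.donor, m.acceptor) for m in paired] == [(100, 200)]

    def test_unpaired_single_nucleotide_feature_rejected(self):
        with pytest.raises(AnnotationError, match="pair"):
            read_splice_sites(
                gff("chr\tsrc\tsplice_site\t101\t101\t.\t+\t.\tID=x;Parent=p")
            )


def test_gff3_round_trip_preserves_internal_coordinates(sim_bundle):
    _, fixture, _, _, _, _, _ = sim_bundle
    ann = fixture.annotation
    buf = io.StringIO()
    write_gff3(ann.exons(), buf)
    reread = read_annotation(
        f">{ann.seq_id}\n{ann.genome_seq}\n", exon_gff3=buf.getvalue()
    )
    original = [(f.feature_id, f.interval.start, f.interval.end, f.interval.strand) for f in ann.exons()]
    round_tripped = [(f.feature_id, f.interval.start, f.interval.end, f.interval.strand) for f in reread.exons()]
    assert round_tripped == original


def test_interval_invariants():
    with pytest.raises(AnnotationError):
        GenomicInterval("chr", 10, 10)
    with pytest.raises(AnnotationError):
        GenomicInterval("chr", -1, 10)
    with pytest.raises(AnnotationError):
        GenomicInterval("chr", 0, 10, "x")
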