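"""Pipeline orchestration: run the three analyses and write their tables.

One :func:`run_pipeline` call reproduces the classic organellar RNA-seq
workflow: extract the target subgenome from the alignment, then produce

* coverage outputs — ``counts``, ``bam_name``, ``nt_coverage.txt``,
  ``window_coverage.txt``, ``exon_rpkm.txt``, ``intron_rpkm.txt`` (plus
  ``coverage_plus.csv``/``coverage_minus.csv``/``window_plus.csv``/
  ``window_minus.csv`` when intermediates are kept);
* splicing output — ``splicing_efficiency.txt`` (plus ``splice_junctions.sam``,
  ``spliced_coverage.txt``, ``unspliced_coverage.txt``);
* editing outputs — ``editing.pileup`` and ``editing_efficiency.txt``.

All tables are tab-delimited with one header line; coordinates in text
outputs are 1-based inclusive.  The ``counts`` file holds the total
subgenome read count and ``bam_name`` the extracted alignment's file name
(both schemas are this package's interpretation of the classic outputs).

:func:`compare_conditions` compares a metric table between two samples:
per-feature log2 fold changes, distribution summaries, and two-sample
t-tests (pooled-variance "Student" and Welch, both reported, since either
reading of "Student's t-test" should be reproducible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from . import __version__
from .alignment import extract_subgenome, total_mapped
from .annotation import AnnotationSet, read_annotation
from .coverage import feature_rpkm, per_nucleotide_coverage, windowed_coverage
from .editing import editing_table
from .splicing import classify_read, splicing_table

ANALYSES = ("coverage", "splicing", "editing", "all")


class ConfigurationError(ValueError):
    """Raised before any computation when required inputs are missing."""


@dataclass
class RunConfig:
    alignment: str
    fasta: str
    output_dir: str
    analysis: str = "all"
    exon_gff3: str | None = None
    intron_gff3: str | None = None
    splice_gff3: str | None = None
    editing_gff3: str | None = None
    target_name: str = "ChrC"
    genome_size: int | None = None
    strandness: str = "forward"
    keep_intermediates: bool = False
    min_overhang: int = 1
    min_base_quality: int = 0
    min_splice_support: int = 0
    window: int = 100
    step: int = 50
    ti_mode: str = "subgenome"  # or "library": Ti = whole-library mappable reads

    def validate(self) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigurationError(
                f"analysis must be one of {ANALYSES}, got {self.analysis!r}"
            )
        wants = (
            {self.analysis} if self.analysis != "all" else {"coverage", "splicing", "editing"}
        )
        if "coverage" in wants and self.exon_gff3 is None:
            raise ConfigurationError("coverage analysis requires an exon GFF3 (-e)")
        if "splicing" in wants and self.splice_gff3 is None and self.intron_gff3 is None:
            raise ConfigurationError(
                "splicing analysis requires a splice-site (-s) or intron (-i) GFF3"
            )
        if "editing" in wants and self.editing_gff3 is None:
            raise ConfigurationError("editing analysis requires an editing-site GFF3 (-v)")
        if self.ti_mode not in ("subgenome", "library"):
            raise ConfigurationError(f"unknown ti_mode {self.ti_mode!r}")


def _fmt(value: float, nd: int = 4) -> str:
    return "NA" if value is None or (isinstance(value, float) and math.isnan(value)) else f"{value:.{nd}f}"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the selected analyses; returns the map of written output files."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    wants = (
        {config.analysis}
        if config.analysis != "all"
        else {"coverage", "splicing", "editing"}
    )

    ann = read_annotation(
        open(config.fasta),
        exon_gff3=open(config.exon_gff3) if config.exon_gff3 else None,
        intron_gff3=open(config.intron_gff3) if config.intron_gff3 else None,
        splice_gff3=open(config.splice_gff3) if config.splice_gff3 else None,
        editing_gff3=open(config.editing_gff3) if config.editing_gff3 else None,
    )
    reads, stats_ = extract_subgenome(
        config.alignment, config.target_name, config.genome_size
    )
    ti = total_mapped(reads) if config.ti_mode == "subgenome" else stats_.mappable_reads

    outputs: dict[str, Path] = {}
    log_lines = [
        f"plastidseq {__version__}",
        f"alignment={config.alignment}",
        f"target={config.target_name} genome_length={ann.genome_length}",
        f"strandness={config.strandness} ti_mode={config.ti_mode} Ti={ti}",
        f"mappable_reads={stats_.mappable_reads} mapped_reads={stats_.mapped_reads}",
        f"analysis={config.analysis} min_overhang={config.min_overhang} "
        f"min_base_quality={config.min_base_quality}",
    ]

    if "coverage" in wants:
        outputs.update(_run_coverage(config, ann, reads, ti, outdir, log_lines))
    if "splicing" in wants:
        outputs.update(_run_splicing(config, ann, reads, outdir, log_lines))
    if "editing" in wants:
        outputs.update(_run_editing(config, ann, reads, outdir, log_lines))

    log_path = outdir / "plastidseq_run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    return outputs


def _run_coverage(config, ann, reads, ti, outdir, log_lines):
    track = per_nucleotide_coverage(
        reads, ann.genome_length, config.strandness, seq_id=ann.seq_id
    )
    windows = windowed_coverage(track, ti, config.window, config.step)
    exon_records = feature_rpkm(reads, ann.exons(), ti, config.strandness)
    intron_feats = ann.intron_features()
    if not intron_feats and ann.introns:
        # introns known only via splice sites / derivation
        from .annotation import FeatureAnnotation

        intron_feats = [
            FeatureAnnotation(
                interval=m.intron, feature_id=m.intron_id or m.host_gene,
                kind="intron", parent_gene=m.host_gene,
            )
            for m in ann.introns
        ]
    intron_records = feature_rpkm(reads, intron_feats, ti, config.strandness)

    out = {}
    out["counts"] = outdir / "counts"
    out["counts"].write_text(f"{total_mapped(reads)}\n")
    out["bam_name"] = outdir / "bam_name"
    out["bam_name"].write_text(Path(config.alignment).name + "\n")

    out["nt_coverage"] = outdir / "nt_coverage.txt"
    with open(out["nt_coverage"], "w") as fh:
        fh.write("seq_id\tposition\tplus_depth\tminus_depth\n")
        for i in range(ann.genome_length):
            fh.write(
                f"{ann.seq_id}\t{i + 1}\t{track.plus_depth[i]}\t{track.minus_depth[i]}\n"
            )

    out["window_coverage"] = outdir / "window_coverage.txt"
    with open(out["window_coverage"], "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\traw_sum\tnormalized\n")
        for w in windows.windows:
            fh.write(
                f"{ann.seq_id}\t{w.start + 1}\t{w.end}\t{w.strand}\t{w.raw_sum}\t"
                f"{_fmt(w.normalized_value)}\n"
            )

    for name, records, feats in (
        ("exon_rpkm", exon_records, ann.exons()),
        ("intron_rpkm", intron_records, intron_feats),
    ):
        out[name] = outdir / f"{name}.txt"
        with open(out[name], "w") as fh:
            fh.write("feature_id\tseq_id\tstart\tend\tstrand\tlength\treads\ttotal_reads\trpkm\n")
            for rec, feat in zip(records, feats):
                iv = feat.interval
                fh.write(
                    f"{rec.feature_id}\t{iv.seq_id}\t{iv.start + 1}\t{iv.end}\t"
                    f"{iv.strand}\t{rec.length}\t{rec.read_count}\t{rec.total_reads}\t"
                    f"{_fmt(rec.rpkm)}\n"
                )

    if config.keep_intermediates:
        for strand, name in (("plus", "coverage_plus.csv"), ("minus", "coverage_minus.csv")):
            depth = track.plus_depth if strand == "plus" else track.minus_depth
            path = outdir / name
            with open(path, "w") as fh:
                fh.write("position,depth\n")
                for i, d in enumerate(depth):
                    fh.write(f"{i + 1},{d}\n")
            out[name] = path
        for strand, name in (("+", "window_plus.csv"), ("-", "window_minus.csv")):
            path = outdir / name
            with open(path, "w") as fh:
                fh.write("start,end,raw_sum,normalized\n")
                for w in windows.windows:
                    if w.strand == strand:
                        fh.write(
                            f"{w.start + 1},{w.end},{w.raw_sum},{_fmt(w.normalized_value)}\n"
                        )
            out[name] = path

    log_lines.append(
        f"coverage: positions={ann.genome_length} windows={len(windows.windows)} "
        f"exons={len(exon_records)} introns={len(intron_records)}"
    )
    return out


def _run_splicing(config, ann, reads, outdir, log_lines):
    records = splicing_table(
        reads,
        ann.introns,
        min_overhang=config.min_overhang,
        strandness=config.strandness,
        min_support=config.min_splice_support,
    )
    out = {}
    out["splicing_efficiency"] = outdir / "splicing_efficiency.txt"
    with open(out["splicing_efficiency"], "w") as fh:
        fh.write("intron_id\tseq_id\tstart\tend\tstrand\tjR\tliR\triR\tSE\n")
        for r in records:
            fh.write(
                f"{r.intron_id}\t{r.seq_id}\t{r.start + 1}\t{r.end}\t{r.strand}\t"
                f"{r.junction_reads}\t{r.left_boundary_reads}\t{r.right_boundary_reads}\t"
                f"{_fmt(r.efficiency)}\n"
            )

    if config.keep_intermediates:
        junction_reads = [
            read
            for read in reads
            if any(
                classify_read(read, m, config.min_overhang, config.strandness)[0]
                for m in ann.introns
            )
        ]
        path = outdir / "splice_junctions.sam"
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": ann.seq_id, "LN": ann.genome_length}]}
        )
        with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
            for read in junction_reads:
                sam.write(read)
        out["splice_junctions.sam"] = path
        for name in ("spliced_coverage.txt", "unspliced_coverage.txt"):
            path = outdir / name
            with open(path, "w") as fh:
                fh.write("intron_id\tcount\n")
                for r in records:
                    n = (
                        r.junction_reads
                        if name.startswith("spliced")
                        else r.left_boundary_reads + r.right_boundary_reads
                    )
                    fh.write(f"{r.intron_id}\t{n}\n")
            out[name] = path

    log_lines.append(f"splicing: introns={len(records)}")
    return out


def _run_editing(config, ann, reads, outdir, log_lines):
    records = editing_table(reads, ann.editing_sites, config.min_base_quality)
    out = {}
    out["editing_efficiency"] = outdir / "editing_efficiency.txt"
    with open(out["editing_efficiency"], "w") as fh:
        fh.write("site_id\tseq_id\tposition\tplus_strand_base\tdepth\tA\tC\tG\tT\tefficiency\n")
        for r in records:
            c = r.counts
            fh.write(
                f"{r.site.site_id}\t{r.site.seq_id}\t{r.site.position + 1}\t"
                f"{r.site.plus_strand_base}\t{c.total_depth}\t{c.count_A}\t{c.count_C}\t"
                f"{c.count_G}\t{c.count_T}\t{_fmt(r.efficiency)}\n"
            )
    out["editing.pileup"] = outdir / "editing.pileup"
    with open(out["editing.pileup"], "w") as fh:
        for r in records:
            c = r.counts
            fh.write(
                f"{r.site.seq_id}\t{r.site.position + 1}\t{r.site.plus_strand_base}\t"
                f"{c.total_depth}\tA:{c.count_A},C:{c.count_C},G:{c.count_G},T:{c.count_T}\n"
            )
    log_lines.append(f"editing: sites={len(records)}")
    return out


# ---------------------------------------------------------------------------
# Condition comparison


@dataclass
class ConditionComparison:
    """Per-feature fold changes and distribution-level tests for one metric."""

    metric: str
    table: pd.DataFrame  # feature_id, value_a, value_b, log2_fc
    summary_a: dict[str, float] = field(default_factory=dict)
    summary_b: dict[str, float] = field(default_factory=dict)
    t_statistic: float = math.nan  # pooled-variance (Student)
    p_value: float = math.nan
    welch_t_statistic: float = math.nan
    welch_p_value: float = math.nan
    n: int = 0


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "mean": float(np.mean(values)),
    }


def compare_conditions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str,
    id_column: str = "feature_id",
    pseudocount: float = 0.0,
) -> ConditionComparison:
    """Compare one metric between two samples' tables.

    Tables must share feature identifiers.  Rows where either value is NA
    are excluded pairwise; log2 fold change is computed only where both
    (value + pseudocount) are positive, NA otherwise (no silent pseudocount:
    fabricating signal at zero-coverage features is worse than a hole).
    """
    for tbl, label in ((table_a, "a"), (table_b, "b")):
        if id_column not in tbl.columns or metric not in tbl.columns:
            raise KeyError(f"table {label} lacks column {id_column!r} or {metric!r}")
    merged = table_a[[id_column, metric]].merge(
        table_b[[id_column, metric]], on=id_column, suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("tables share no feature identifiers")
    a = pd.to_numeric(merged[f"{metric}_a"], errors="coerce")
    b = pd.to_numeric(merged[f"{metric}_b"], errors="coerce")
    keep = a.notna() & b.notna()
    merged = merged.loc[keep].reset_index(drop=True)
    a, b = a[keep].to_numpy(float), b[keep].to_numpy(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (b + pseudocount) / (a + pseudocount)
        log2_fc = np.where(
            (a + pseudocount > 0) & (b + pseudocount > 0), np.log2(ratio), np.nan
        )
    table = pd.DataFrame(
        {
            id_column: merged[id_column],
            "value_a": a,
            "value_b": b,
            "log2_fc": log2_fc,
        }
    )
    if len(a) >= 2:  # t statistics undefined for a single paired feature
        student = stats.ttest_ind(a, b, equal_var=True)
        welch = stats.ttest_ind(a, b, equal_var=False)
        t_s, p_s = float(student.statistic), float(student.pvalue)
        t_w, p_w = float(welch.statistic), float(welch.pvalue)
    else:
        t_s = p_s = t_w = p_w = math.nan
    return ConditionComparison(
        metric=metric,
        table=table,
        summary_a=_summary(a),
        summary_b=_summary(b),
        t_statistic=t_s,
        p_value=p_s,
        welch_t_statistic=t_w,
        welch_p_value=p_w,
        n=len(table),
    )


def read_metric_table(path: str | Path) -> pd.DataFrame:
    """Read one of the pipeline's tab-delimited output tables."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
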