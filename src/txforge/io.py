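"""Readers and writers for GTF, BED, FASTA and the pipeline's TSV tables.

Parsing of the standard formats is delegated to pyranges (GTF), pandas
(BED/TSV) and Biopython (FASTA); this module only converts between the file
conventions and the internal 0-based half-open types.  No other module
touches files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    HOMOLOGY_COLUMNS,
    GeneModel,
    GenomicInterval,
    HomologyTable,
    PeakSet,
    SequenceStore,
    TranscriptModel,
    ValidationError,
)

log = logging.getLogger(__name__)


class AnnotationParseError(ValueError):
    pass


def _check_gtf_lines(path: str | Path) -> int:
    # cheap structural pre-scan so parse failures report a line number
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            n_features += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValidationError(f"{path}: line {lineno}: end < start")
    return n_features


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF file (1-based inclusive) into internal gene models."""
    if _check_gtf_lines(path) == 0:
        log.warning("no features in %s", path)
        return []
    ranges = pr.read_gtf(str(path))
    df = ranges.df if ranges is not None else pd.DataFrame()
    if df.empty:
        log.warning("no features in %s", path)
        return []
    df = df[df["Feature"] == "exon"]
    if df.empty:
        log.warning("no exon features in %s", path)
        return []

    genes: dict[str, list[TranscriptModel]] = {}
    gene_biotypes: dict[str, str | None] = {}
    for (gid, tid), sub in df.groupby(["gene_id", "transcript_id"], sort=True):
        exons = [
            GenomicInterval(r.Chromosome, int(r.Start), int(r.End), r.Strand)
            for r in sub.itertuples()
        ]
        first = sub.iloc[0]
        tissues = frozenset(
            str(first["source_tissues"]).split(",")
            if "source_tissues" in sub.columns and pd.notna(first["source_tissues"])
            and str(first["source_tissues"])
            else []
        )
        biotype = None
        if "transcript_biotype" in sub.columns and pd.notna(first["transcript_biotype"]):
            biotype = str(first["transcript_biotype"])
        dataset = (
            str(first["dataset"])
            if "dataset" in sub.columns and pd.notna(first["dataset"])
            else "rnaseq"
        )
        genes.setdefault(gid, []).append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                exons=tuple(exons),
                source_tissues=tissues,
                source_dataset=dataset,
                biotype=biotype,
            )
        )
        if "gene_biotype" in sub.columns and pd.notna(first["gene_biotype"]):
            gene_biotypes[gid] = str(first["gene_biotype"])

    return [
        GeneModel(gene_id=gid, transcripts=ts, biotype=gene_biotypes.get(gid))
        for gid, ts in sorted(genes.items())
    ]


def _gtf_attributes(t: TranscriptModel, gene: GeneModel) -> str:
    attrs = [f'gene_id "{gene.gene_id}"', f'transcript_id "{t.transcript_id}"']
    if t.source_tissues:
        attrs.append(f'source_tissues "{",".join(sorted(t.source_tissues))}"')
    attrs.append(f'dataset "{t.source_dataset}"')
    if t.biotype:
        attrs.append(f'transcript_biotype "{t.biotype}"')
    if gene.biotype:
        attrs.append(f'gene_biotype "{gene.biotype}"')
    return "; ".join(attrs) + ";"


def write_annotation(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as Ensembl-dialect GTF (exact read/write round trip)."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs = _gtf_attributes(t, gene)
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "txforge",
                            "transcript",
                            str(t.start + 1),
                            str(t.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                "txforge",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def read_peaks(path: str | Path, track_name: str) -> PeakSet:
    """Read BED3+ (0-based half-open, native) into a PeakSet.

    ``track``/``browser``/``#`` lines are skipped; column 6 supplies the
    strand when present, else '.'.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t")
            if len(fields) < 3:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: BED needs >=3 columns"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0:
                raise ValidationError(f"{path}: line {lineno}: negative coordinate")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return PeakSet(track_name=track_name, intervals=intervals)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.track_name}_{i}\t0\t{iv.strand}\n"
            )


def read_genome(path: str | Path) -> SequenceStore:
    return SequenceStore(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_genome(store: SequenceStore, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(store.fetch(GenomicInterval(c, 0, store.length(c)))), id=c, description="")
        for c in store.chroms()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_homology(path: str | Path) -> HomologyTable:
    df = pd.read_csv(path, sep="\t")
    return HomologyTable(rows=df[HOMOLOGY_COLUMNS])


def write_homology(table: HomologyTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    """Trait-QTL TSV (trait, qtl_id, chrom, start, end; 1-based inclusive on
    disk) converted to internal 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t")
    out = df.copy()
    out["start"] = df["start"] - 1
    if (out["start"] < 0).any():
        raise ValidationError("QTL start < 1 in 1-based input")
    return out


def write_qtl_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_flag_table(path: str | Path, id_col: str, flag_col: str) -> dict[str, bool]:
    """Generic boolean-flag TSV (coding potential, signal peptide, ...)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df[id_col], df[flag_col].astype(bool)))
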