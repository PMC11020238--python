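"""Transcript-level QC filters applied to per-tissue assemblies.

Rules (all configurable, defaults as used throughout the package):

* minimum 3x per-base coverage in every tissue the transcript was
  assembled in;
* every splice junction canonical (GT..AG / GC..AG / AT..AC on the
  transcript strand) and spanned by >=1 read with a 5-nt overhang;
* spliced transcripts whose junction chain is a subset of a reference
  transcript's chain but which retain >=1 reference intron are dropped as
  likely pre-mRNA;
* unspliced transcripts with a >=20-A stretch (1 mismatch allowed) within
  30 bp downstream of the terminal site are dropped as genomic priming
  artifacts;
* unspliced transcripts expressed in a single tissue, and single-exon genes
  with no H3K4me3/H3K4me1/H3K27ac/ATAC peak in their promoter, are dropped
  as likely noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, SequenceStore, TranscriptModel

log = logging.getLogger(__name__)

CANONICAL_JUNCTIONS = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))

RULES = (
    "low_coverage",
    "unsupported_junction",
    "noncanonical_junction",
    "premrna",
    "genomic_polya",
    "single_tissue_unspliced",
    "single_exon_no_evidence",
)

Junction = tuple[str, str, int, int]  # chrom, strand, intron start, intron end


class MissingSupportError(KeyError):
    pass


@dataclass
class SupportTables:
    """Coverage and junction support consumed as tables (not from BAM).

    ``base_coverage[(tid, tissue)]`` is the minimum per-base coverage fold of
    the transcript in that tissue.  ``junction_support[(junction, tissue)]``
    counts reads spanning the junction with >= ``overhang_nt`` on both sides.
    ``canonical_flag`` may be filled from the genome with
    :func:`junction_canonical_flags`.
    """

    base_coverage: dict[tuple[str, str], float] = field(default_factory=dict)
    junction_support: dict[tuple[Junction, str], int] = field(default_factory=dict)
    canonical_flag: dict[Junction, bool] = field(default_factory=dict)
    overhang_nt: int = 5

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_coverage.values()):
            raise ValueError("negative coverage")
        if any(v < 0 for v in self.junction_support.values()):
            raise ValueError("negative junction count")


def junction_canonical_flags(
    transcripts: Iterable[TranscriptModel],
    genome: SequenceStore,
    accepted: Sequence[tuple[str, str]] = CANONICAL_JUNCTIONS,
) -> dict[Junction, bool]:
    """Donor/acceptor dinucleotides read from the genome on the transcript
    strand, checked against the accepted canonical set."""
    flags: dict[Junction, bool] = {}
    for t in transcripts:
        for intron in t.introns:
            key = (t.chrom, t.strand, intron.start, intron.end)
            if key in flags:
                continue
            seq = genome.fetch(intron)  # sense orientation
            flags[key] = (seq[:2], seq[-2:]) in set(map(tuple, accepted))
    return flags


@dataclass
class FilterRecord:
    transcript_id: str
    failed: set[str] = field(default_factory=set)

    @property
    def kept(self) -> bool:
        return not self.failed


@dataclass
class FilterReport:
    records: dict[str, FilterRecord] = field(default_factory=dict)

    def record(self, tid: str) -> FilterRecord:
        return self.records.setdefault(tid, FilterRecord(tid))

    def kept_ids(self) -> set[str]:
        return {tid for tid, r in self.records.items() if r.kept}

    def failed_ids(self, rule: str | None = None) -> set[str]:
        return {
            tid
            for tid, r in self.records.items()
            if (r.failed if rule is None else rule in r.failed)
        }

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport()
        for rep in (self, other):
            for tid, r in rep.records.items():
                out.record(tid).failed |= r.failed
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": tid,
                    "kept": r.kept,
                    "failed_rules": ",".join(sorted(r.failed)),
                }
                for tid, r in sorted(self.records.items())
            ]
        )


def filter_support(
    transcripts: Sequence[TranscriptModel],
    support: SupportTables,
    min_coverage: float = 3.0,
    min_overhang: int = 5,
) -> FilterReport:
    """Coverage (inclusive: exactly 3x passes) and junction support/canonical
    rules, evaluated over each transcript's assembled tissues."""
    if support.overhang_nt < min_overhang:
        raise ValueError(
            f"support table built at {support.overhang_nt}-nt overhang, "
            f"need >= {min_overhang}"
        )
    report = FilterReport()
    for t in transcripts:
        rec = report.record(t.transcript_id)
        for tissue in sorted(t.source_tissues):
            key = (t.transcript_id, tissue)
            if key not in support.base_coverage:
                raise MissingSupportError(
                    f"no coverage entry for transcript {t.transcript_id} "
                    f"in tissue {tissue}"
                )
            if support.base_coverage[key] < min_coverage:
                rec.failed.add("low_coverage")
        for intron in t.introns:
            jkey = (t.chrom, t.strand, intron.start, intron.end)
            if not support.canonical_flag.get(jkey, False):
                rec.failed.add("noncanonical_junction")
            spanned = any(
                support.junction_support.get((jkey, tissue), 0) >= 1
                for tissue in t.source_tissues
            )
            if not spanned:
                rec.failed.add("unsupported_junction")
    return report


def flag_premrna(
    transcripts: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
) -> set[str]:
    """Spliced transcripts whose junctions all match a same-strand reference
    transcript while retaining >=1 of its introns (likely pre-mRNA)."""
    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for r in reference:
        by_loc.setdefault((r.chrom, r.strand), []).append(r)
    flagged: set[str] = set()
    for t in transcripts:
        if not t.is_spliced:
            continue
        chain = set(t.junctions)
        for r in by_loc.get((t.chrom, t.strand), []):
            if not chain <= set(r.junctions):
                continue
            retained = any(
                e.start <= ri.start and ri.end <= e.end
                for ri in r.introns
                for e in t.exons
            )
            if retained:
                flagged.add(t.transcript_id)
                break
    return flagged


def _best_polya_run(window: str, min_a: int, max_mismatch: int) -> bool:
    """True if the window holds a run of >= min_a bases with <= max_mismatch
    non-A characters, starting and ending with A."""
    n = len(window)
    for i in range(n):
        if window[i] != "A":
            continue
        mismatches = 0
        for j in range(i, n):
            if window[j] != "A":
                mismatches += 1
                if mismatches > max_mismatch:
                    break
            elif j - i + 1 >= min_a:
                return True
    return False


def flag_genomic_polya(
    transcripts: Sequence[TranscriptModel],
    genome: SequenceStore,
    window: int = 30,
    min_a: int = 20,
    max_mismatch: int = 1,
) -> set[str]:
    """Unspliced transcripts with a genomically templated poly(A) stretch in
    the 30 bp downstream of the terminal site (internal-priming artifacts)."""
    flagged: set[str] = set()
    for t in transcripts:
        if t.is_spliced:
            continue
        chrom_len = genome.length(t.chrom)
        if t.strand == "+":
            start, end = t.end, min(t.end + window, chrom_len)
            if end <= start:
                log.warning("%s: downstream window off contig end", t.transcript_id)
                continue
            seq = genome.fetch(type(t.exons[0])(t.chrom, start, end, "+"))
        else:
            start, end = max(0, t.start - window), t.start
            if end <= start:
                log.warning("%s: downstream window off contig end", t.transcript_id)
                continue
            seq = genome.fetch(type(t.exons[0])(t.chrom, start, end, "-"))
        if end - start < window:
            log.warning("%s: downstream window truncated", t.transcript_id)
        if _best_polya_run(seq, min_a, max_mismatch):
            flagged.add(t.transcript_id)
    return flagged


RESCUE_TRACKS = ("H3K4me3", "H3K4me1", "H3K27ac", "ATAC")


def filter_locus_rules(
    genes: Sequence[GeneModel],
    expressed: np.ndarray,
    feature_ids: Sequence[str],
    promoter_evidence: Mapping[str, Mapping[str, list]],
    rescue_tracks: Sequence[str] = RESCUE_TRACKS,
) -> FilterReport:
    """Cross-tissue locus rules.

    ``expressed`` is the transcript x tissue boolean matrix (rows ordered by
    ``feature_ids``); ``promoter_evidence`` maps track -> gene_id -> assigned
    peaks (from :func:`txforge.structcmp.assign_peaks_to_promoter`).  Only
    the listed rescue tracks count; CTCF peaks do not rescue a single-exon
    gene.
    """
    idx = {f: i for i, f in enumerate(feature_ids)}
    report = FilterReport()
    for g in genes:
        single_exon_gene = all(not t.is_spliced for t in g.transcripts)
        rescued = any(
            promoter_evidence.get(track, {}).get(g.gene_id)
            for track in rescue_tracks
        )
        for t in g.transcripts:
            rec = report.record(t.transcript_id)
            if not t.is_spliced and t.transcript_id in idx:
                n_tissues = int(expressed[idx[t.transcript_id]].sum())
                if n_tissues == 1:
                    rec.failed.add("single_tissue_unspliced")
            if single_exon_gene and not rescued:
                rec.failed.add("single_exon_no_evidence")
    return report
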