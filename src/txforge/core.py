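"""Domain types shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)`` on the forward
reference strand.  GTF input/output converts to and from the 1-based
inclusive convention at the file boundary; BED is native.  Transcripts are
always stranded; peak tracks may be unstranded (strand ``"."``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

STRANDS = ("+", "-", ".")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """An object violated a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Stranded interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValidationError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A stranded exon chain with provenance and border-support flags.

    Exons are sorted by start, non-overlapping, and all on the same
    chromosome and strand.  ``tss``/``tts`` are the 0-based positions of the
    first and last transcribed base (strand-aware).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    source_tissues: frozenset[str] = frozenset()
    source_dataset: str = "rnaseq"
    tss_supported: bool = False
    tts_supported: bool = False
    biotype: str | None = None

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(f"{self.transcript_id}: exons span chrom/strand")
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: transcripts must be stranded")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end < 1:
                raise ValidationError(
                    f"{self.transcript_id}: intron < 1 bp between "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """0-based position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Intron (start, end) pairs in genomic order."""
        return tuple((i.start, i.end) for i in self.introns)

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) > 1

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def with_exons(self, exons: Sequence[GenomicInterval]) -> "TranscriptModel":
        return replace(self, exons=tuple(exons))


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    biotype: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene needs >=1 transcript")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(f"{self.gene_id}: transcripts span chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tts(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start


@dataclass
class PeakSet:
    """A named evidence track (H3K4me3, ATAC, RAMPAGE, WTTS, ...)."""

    track_name: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.track_name:
            raise ValidationError("track_name must be non-empty")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


class SequenceStore:
    """chrom -> nucleotide string, with strand-aware fetching."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seq = {c: str(s).upper() for c, s in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    def chroms(self) -> list[str]:
        return list(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of the interval; reverse-complemented for strand '-'."""
        s = self._seq[interval.chrom][interval.start : interval.end]
        return revcomp(s) if interval.strand == "-" else s

    def spliced_sequence(self, t: TranscriptModel) -> str:
        """5'->3' sense sequence of a transcript (exons joined, stranded)."""
        parts = [self._seq[t.chrom][e.start : e.end] for e in t.exons]
        seq = "".join(parts)
        return revcomp(seq) if t.strand == "-" else seq


HOMOLOGY_COLUMNS = [
    "query_id",
    "subject_id",
    "evalue",
    "coverage_pct",
    "identity_pct",
    "search_kind",
]


@dataclass
class HomologyTable:
    """Pre-computed homology hits (stand-in for Blastp/Blastx/Blastn output)."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=HOMOLOGY_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = set(HOMOLOGY_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValidationError(f"homology table missing columns: {sorted(missing)}")
        if len(self.rows):
            if (self.rows["evalue"] < 0).any():
                raise ValidationError("negative E-value")
            for col in ("coverage_pct", "identity_pct"):
                if ((self.rows[col] < 0) | (self.rows[col] > 100)).any():
                    raise ValidationError(f"{col} outside [0, 100]")

    def passing(
        self,
        evalue_max: float,
        min_cov: float,
        min_ident: float,
        search_kind: str | None = None,
    ) -> pd.DataFrame:
        df = self.rows
        mask = (
            (df["evalue"] <= evalue_max)
            & (df["coverage_pct"] >= min_cov)
            & (df["identity_pct"] >= min_ident)
        )
        if search_kind is not None:
            mask &= df["search_kind"] == search_kind
        return df[mask]


def oriented_window(
    anchor: int, strand: str, up: int, down: int, chrom: str, chrom_len: int | None = None
) -> GenomicInterval | None:
    """Genomic window spanning ``up`` bases 5' and ``down`` bases 3' of a
    0-based anchor position, in the transcription direction.

    On '+' this is ``[anchor-up, anchor+down)`` (the anchor base counts as the
    first 3' base); on '-' it is the exact strand mirror
    ``[anchor-down+1, anchor+up+1)``.  Windows are truncated at contig bounds;
    a window that truncates to nothing returns None.
    """
    if strand == "-":
        start, end = anchor - down + 1, anchor + up + 1
    else:
        start, end = anchor - up, anchor + down
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    if end <= start:
        return None
    return GenomicInterval(chrom, start, end, ".")


def transcripts_of(genes: Iterable[GeneModel]) -> list[TranscriptModel]:
    return [t for g in genes for t in g.transcripts]
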