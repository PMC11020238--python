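"""Structural equivalence, cross-tissue collapsing, gene grouping,
reference assignment, border-extension detection and evidence windows.

Two transcripts are structurally equivalent when their splice-junction
chains match within a 15-bp fuzz and their borders agree: ends supported by
5'/3' evidence (RAMPAGE peaks / WTTS reads) must share a supporting peak,
unsupported ends may differ by up to 100 nt.  Fuzzy similarity is not
transitive, so collapsing takes the transitive closure (union-find) and
keeps the longest-span member as representative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, PeakSet, TranscriptModel, oriented_window


@dataclass(frozen=True)
class EquivalenceParams:
    junction_fuzz: int = 15
    border_fuzz: int = 100

    def __post_init__(self) -> None:
        if self.junction_fuzz < 0 or self.border_fuzz < 0:
            raise ValueError("fuzz parameters must be >= 0")


@dataclass(frozen=True)
class BorderSupport:
    """Evidence support for a transcript's two ends.

    ``tss_peaks``/``tts_peaks`` hold ids of the supporting evidence
    intervals; None means the end is unsupported and falls back to the
    border fuzz.
    """

    tss_peaks: frozenset[int] | None = None
    tts_peaks: frozenset[int] | None = None


UNSUPPORTED = BorderSupport()


def _junctions_match(a: TranscriptModel, b: TranscriptModel, fuzz: int) -> bool:
    ja, jb = a.junctions, b.junctions
    if len(ja) != len(jb):
        return False
    return all(
        abs(sa - sb) <= fuzz and abs(ea - eb) <= fuzz
        for (sa, ea), (sb, eb) in zip(ja, jb)
    )


def _ends_match(
    pos_a: int,
    pos_b: int,
    peaks_a: frozenset[int] | None,
    peaks_b: frozenset[int] | None,
    border_fuzz: int,
) -> bool:
    if peaks_a is not None and peaks_b is not None:
        return bool(peaks_a & peaks_b)
    return abs(pos_a - pos_b) <= border_fuzz


def transcripts_equivalent(
    a: TranscriptModel,
    b: TranscriptModel,
    params: EquivalenceParams = EquivalenceParams(),
    a_support: BorderSupport = UNSUPPORTED,
    b_support: BorderSupport = UNSUPPORTED,
) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.is_spliced != b.is_spliced:
        return False
    if not _junctions_match(a, b, params.junction_fuzz):
        return False
    return _ends_match(
        a.tss, b.tss, a_support.tss_peaks, b_support.tss_peaks, params.border_fuzz
    ) and _ends_match(
        a.tts, b.tts, a_support.tts_peaks, b_support.tts_peaks, params.border_fuzz
    )


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def collapse_transcripts(
    per_source_sets: Sequence[tuple[str, Sequence[TranscriptModel]]],
    params: EquivalenceParams = EquivalenceParams(),
    support: Mapping[str, BorderSupport] | None = None,
) -> list[TranscriptModel]:
    """Collapse structurally equivalent transcripts across tissues/datasets.

    Transitive closure over pairwise equivalence; the representative of each
    class is the member with the longest genomic span (ties broken by
    transcript_id) and carries the union of member tissues.  Output is
    canonically sorted and therefore invariant to input order.
    """
    entries: list[tuple[str, TranscriptModel]] = [
        (source, t) for source, ts in per_source_sets for t in ts
    ]
    entries.sort(key=lambda e: e[1].transcript_id)
    ts = [t for _, t in entries]
    support = support or {}

    # bucket by invariants of the equivalence relation to avoid full n^2
    buckets: dict[tuple, list[int]] = {}
    for i, t in enumerate(ts):
        buckets.setdefault((t.chrom, t.strand, len(t.exons)), []).append(i)
    dsu = _DSU(len(ts))
    for members in buckets.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if transcripts_equivalent(
                    ts[i],
                    ts[j],
                    params,
                    support.get(ts[i].transcript_id, UNSUPPORTED),
                    support.get(ts[j].transcript_id, UNSUPPORTED),
                ):
                    dsu.union(i, j)

    classes: dict[int, list[int]] = {}
    for i in range(len(ts)):
        classes.setdefault(dsu.find(i), []).append(i)
    out: list[TranscriptModel] = []
    for members in classes.values():
        rep_i = max(members, key=lambda i: (len(ts[i].span), ts[i].transcript_id))
        # longest span wins; among equal spans prefer the lexicographically
        # smallest id for determinism
        best_len = len(ts[rep_i].span)
        rep_i = min(
            (i for i in members if len(ts[i].span) == best_len),
            key=lambda i: ts[i].transcript_id,
        )
        tissues = frozenset().union(*(ts[i].source_tissues for i in members))
        out.append(replace(ts[rep_i], source_tissues=tissues))
    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    return out


def group_into_genes(
    transcripts: Sequence[TranscriptModel],
    gene_prefix: str = "XLOC",
    overlap: str = "span",
) -> list[GeneModel]:
    """Single-linkage clustering of same-strand transcripts with >=1 nt
    overlap into putative gene models.

    ``overlap='span'`` (default) clusters on transcript spans; ``'exon'``
    requires exon-level overlap.
    """
    ts = sorted(transcripts, key=lambda t: (t.chrom, t.strand, t.start, t.end))
    dsu = _DSU(len(ts))
    groups: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(ts):
        groups.setdefault((t.chrom, t.strand), []).append(i)
    for members in groups.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                a, b = ts[i], ts[j]
                if b.start >= a.end:
                    continue
                if overlap == "span" or any(
                    ea.overlaps(eb) for ea in a.exons for eb in b.exons
                ):
                    dsu.union(i, j)
    clusters: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(ts):
        clusters.setdefault(dsu.find(i), []).append(t)
    genes = []
    for k, members in enumerate(
        sorted(clusters.values(), key=lambda ms: (ms[0].chrom, ms[0].start))
    ):
        gid = f"{gene_prefix}_{k + 1:06d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                transcripts=[replace(t, gene_id=gid) for t in members],
            )
        )
    return genes


def assign_to_annotated_genes(
    predicted_genes: Sequence[GeneModel],
    reference_genes: Sequence[GeneModel],
) -> dict[str, list[tuple[str, int]]]:
    """Predicted gene -> annotated reference genes, by same-strand exon
    overlap; each hit carries its total exon-overlap in nt, largest first
    (the first entry is the primary reference).  Unannotated genes map to []."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for rg in reference_genes:
        tree = trees.setdefault((rg.chrom, rg.strand), IntervalTree())
        for t in rg.transcripts:
            for e in t.exons:
                tree.addi(e.start, e.end, rg.gene_id)
    out: dict[str, list[tuple[str, int]]] = {}
    for pg in predicted_genes:
        overlaps: dict[str, int] = {}
        tree = trees.get((pg.chrom, pg.strand))
        if tree is not None:
            for t in pg.transcripts:
                for e in t.exons:
                    for hit in tree.overlap(e.start, e.end):
                        nt = min(e.end, hit.end) - max(e.start, hit.begin)
                        overlaps[hit.data] = overlaps.get(hit.data, 0) + nt
        out[pg.gene_id] = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
    return out


@dataclass(frozen=True)
class BorderExtension:
    predicted_gene_id: str
    reference_gene_id: str
    kind: str  # five_prime | three_prime | both
    ext5_nt: int
    ext3_nt: int
    validated5: bool = False
    validated3: bool = False


def detect_border_extensions(
    predicted_genes: Sequence[GeneModel],
    reference_genes: Sequence[GeneModel],
    assignment: Mapping[str, list[tuple[str, int]]],
) -> list[BorderExtension]:
    """Strand-aware 5'/3' gene-span extensions beyond the primary annotated
    reference gene.  Predicted genes fully inside their reference yield no
    record."""
    refs = {g.gene_id: g for g in reference_genes}
    out = []
    for pg in predicted_genes:
        hits = assignment.get(pg.gene_id, [])
        if not hits:
            continue
        rg = refs[hits[0][0]]
        if pg.strand == "+":
            ext5 = max(0, rg.span.start - pg.span.start)
            ext3 = max(0, pg.span.end - rg.span.end)
        else:
            ext5 = max(0, pg.span.end - rg.span.end)
            ext3 = max(0, rg.span.start - pg.span.start)
        if ext5 == 0 and ext3 == 0:
            continue
        kind = "both" if ext5 and ext3 else ("five_prime" if ext5 else "three_prime")
        out.append(
            BorderExtension(
                predicted_gene_id=pg.gene_id,
                reference_gene_id=rg.gene_id,
                kind=kind,
                ext5_nt=ext5,
                ext3_nt=ext3,
            )
        )
    return out


def summarize_extensions(extensions: Sequence[BorderExtension]) -> pd.DataFrame:
    """Per-kind counts and median extension lengths (Table-style summary)."""
    rows = []
    for kind in ("five_prime", "three_prime", "both"):
        sub = [e for e in extensions if e.kind == kind]
        exts = [e.ext5_nt for e in sub if e.ext5_nt] + [
            e.ext3_nt for e in sub if e.ext3_nt
        ]
        rows.append(
            {
                "kind": kind,
                "count": len(sub),
                "median_extension_nt": float(np.median(exts)) if exts else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _window_hits(
    features: Sequence,
    peaks: PeakSet,
    up: int,
    down: int,
    anchor: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[GenomicInterval]]:
    tree: dict[str, IntervalTree] = {}
    for iv in peaks:
        tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    out: dict[str, list[GenomicInterval]] = {}
    for f in features:
        fid = f.gene_id if isinstance(f, GeneModel) else f.transcript_id
        pos = f.tss if anchor == "tss" else f.tts
        clen = chrom_lengths.get(f.chrom) if chrom_lengths else None
        win = oriented_window(pos, f.strand, up, down, f.chrom, clen)
        hits = []
        if win is not None and f.chrom in tree:
            hits = sorted(
                (h.data for h in tree[f.chrom].overlap(win.start, win.end)),
                key=lambda iv: (iv.start, iv.end),
            )
        out[fid] = hits
    return out


def assign_peaks_to_promoter(
    features: Sequence,
    peaks: PeakSet,
    up: int = 500,
    down: int = 100,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Peaks overlapping the promoter window (500 bp 5' to 100 bp 3' of the
    start site) of each gene/transcript."""
    return _window_hits(features, peaks, up, down, "tss", chrom_lengths)


def validate_tss(
    features: Sequence,
    rampage: PeakSet,
    up: int = 30,
    down: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, bool]:
    """Start-site support: >=1 RAMPAGE peak in the 30 bp 5' / 10 bp 3'
    window around the TSS."""
    hits = _window_hits(features, rampage, up, down, "tss", chrom_lengths)
    return {fid: bool(h) for fid, h in hits.items()}


def validate_tts(
    features: Sequence,
    wtts: PeakSet,
    up: int = 10,
    down: int = 165,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, bool]:
    """Terminal-site support: >=1 WTTS read in the 10 bp 5' / 165 bp 3'
    window around the TTS."""
    hits = _window_hits(features, wtts, up, down, "tts", chrom_lengths)
    return {fid: bool(h) for fid, h in hits.items()}


def tss_peak_ids(
    features: Sequence,
    rampage: PeakSet,
    up: int = 30,
    down: int = 10,
) -> dict[str, frozenset[int]]:
    """Indices of supporting RAMPAGE peaks per feature (for BorderSupport)."""
    order = {iv: i for i, iv in enumerate(rampage.intervals)}
    hits = _window_hits(features, rampage, up, down, "tss")
    return {fid: frozenset(order[iv] for iv in h) for fid, h in hits.items() if h}


def tts_peak_ids(
    features: Sequence,
    wtts: PeakSet,
    up: int = 10,
    down: int = 165,
) -> dict[str, frozenset[int]]:
    order = {iv: i for i, iv in enumerate(wtts.intervals)}
    hits = _window_hits(features, wtts, up, down, "tts")
    return {fid: frozenset(order[iv] for iv in h) for fid, h in hits.items() if h}


def validate_extensions(
    extensions: Sequence[BorderExtension],
    predicted_genes: Sequence[GeneModel],
    rampage: PeakSet,
    wtts: PeakSet,
) -> list[BorderExtension]:
    """Mark each extension validated at the 5'/3' end when the predicted
    (extended) border carries RAMPAGE/WTTS support."""
    genes = {g.gene_id: g for g in predicted_genes}
    feats = [genes[e.predicted_gene_id] for e in extensions]
    tss_ok = validate_tss(feats, rampage)
    tts_ok = validate_tts(feats, wtts)
    return [
        replace(
            e,
            validated5=bool(e.ext5_nt and tss_ok[e.predicted_gene_id]),
            validated3=bool(e.ext3_nt and tts_ok[e.predicted_gene_id]),
        )
        for e in extensions
    ]
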