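"""Alternative-splicing event enumeration (local, pairwise definitions).

Eight event types over pairs of isoforms of one gene: skipped exon (SE),
retained intron (RI), alternative 5'/3' splice site (A5/A3), mutually
exclusive exons (MX), alternative first/last exon (AF/AL), and the
unique-splice-site exon (USE): two overlapping exons that share neither of
their flanking splice junctions.  Events are deduplicated per gene by
(type, defining coordinates); A5/A3 and AF/AL are strand-aware, so
mirroring a gene to the opposite strand swaps them while preserving
SE/RI/MX/USE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import GeneModel, TranscriptModel

EVENT_TYPES = ("SE", "RI", "A5", "A3", "MX", "AF", "AL", "USE")


@dataclass
class ASEvent:
    gene_id: str
    event_type: str
    involved_transcripts: frozenset[str]
    defining_coordinates: tuple[tuple[int, int], ...]
    chrom: str = ""
    strand: str = "+"

    @property
    def key(self) -> tuple:
        return (self.event_type, self.defining_coordinates)


def _pair_events(
    a: TranscriptModel, b: TranscriptModel
) -> Iterable[tuple[str, tuple[tuple[int, int], ...]]]:
    """Events distinguishing one ordered pair of spliced/unspliced isoforms."""
    ja, jb = set(a.junctions), set(b.junctions)
    strand = a.strand

    # SE: internal exon of a absent from b, with b joining a's flanks directly
    for i in range(1, len(a.exons) - 1):
        up = a.junctions[i - 1]
        dn = a.junctions[i]
        merged = (up[0], dn[1])
        if merged in jb and up not in jb and dn not in jb:
            e = a.exons[i]
            yield "SE", ((up[0], up[1]), (e.start, e.end), (dn[0], dn[1]))

    # RI: intron of a retained inside an exon of b sharing both outer
    # boundaries with a's flanking exons
    for i, intron in enumerate(a.introns):
        flank5, flank3 = a.exons[i], a.exons[i + 1]
        for eb in b.exons:
            if eb.start == flank5.start and eb.end == flank3.end:
                yield "RI", ((eb.start, intron.start), (intron.start, intron.end), (intron.end, eb.end))

    # A5/A3: introns sharing exactly one boundary, with the variant splice
    # site inside overlapping flanking exons (otherwise the difference is a
    # skipped/alternative exon, not an alternative site)
    for i, (sa, ea) in enumerate(a.junctions):
        for j, (sb, eb) in enumerate(b.junctions):
            if (sa, ea) == (sb, eb):
                continue
            if ea == eb and sa != sb and a.exons[i].overlaps(b.exons[j]):
                # shared acceptor side on '+' (intron end), donors differ
                kind = "A5" if strand == "+" else "A3"
                yield kind, tuple(sorted([(sa, ea), (sb, eb)]))
            elif sa == sb and ea != eb and a.exons[i + 1].overlaps(b.exons[j + 1]):
                kind = "A3" if strand == "+" else "A5"
                yield kind, tuple(sorted([(sa, ea), (sb, eb)]))

    # MX: internal exon of a and internal exon of b, non-overlapping, each
    # absent from the other, sharing outer flanking junction boundaries
    for i in range(1, len(a.exons) - 1):
        ea_up, ea_dn = a.junctions[i - 1], a.junctions[i]
        ea = a.exons[i]
        for j in range(1, len(b.exons) - 1):
            eb_up, eb_dn = b.junctions[j - 1], b.junctions[j]
            eb = b.exons[j]
            if ea.overlaps(eb):
                continue
            if ea_up[0] == eb_up[0] and ea_dn[1] == eb_dn[1]:
                if not any(x.overlaps(ea) for x in b.exons) and not any(
                    x.overlaps(eb) for x in a.exons
                ):
                    first, second = sorted(
                        [(ea.start, ea.end), (eb.start, eb.end)]
                    )
                    yield "MX", (first, second)

    # AF/AL: distinct non-overlapping terminal exons whose terminal introns
    # share the inner boundary
    if len(a.exons) > 1 and len(b.exons) > 1:
        fa, fb = a.exons[0], b.exons[0]
        if not fa.overlaps(fb) and a.junctions[0][1] == b.junctions[0][1]:
            kind = "AF" if strand == "+" else "AL"
            coords = tuple(sorted([(fa.start, fa.end), (fb.start, fb.end)]))
            yield kind, coords
        la, lb = a.exons[-1], b.exons[-1]
        if not la.overlaps(lb) and a.junctions[-1][0] == b.junctions[-1][0]:
            kind = "AL" if strand == "+" else "AF"
            coords = tuple(sorted([(la.start, la.end), (lb.start, lb.end)]))
            yield kind, coords


def enumerate_events(gene: GeneModel, include_use: bool = True) -> list[ASEvent]:
    """All local AS events of a gene, deduplicated by (type, coordinates)."""
    if len(gene.transcripts) < 2:
        return []
    events: dict[tuple, ASEvent] = {}
    ts = gene.transcripts
    for i in range(len(ts)):
        for j in range(len(ts)):
            if i == j:
                continue
            for etype, coords in _pair_events(ts[i], ts[j]):
                ev = ASEvent(
                    gene_id=gene.gene_id,
                    event_type=etype,
                    involved_transcripts=frozenset(
                        {ts[i].transcript_id, ts[j].transcript_id}
                    ),
                    defining_coordinates=coords,
                    chrom=gene.chrom,
                    strand=gene.strand,
                )
                if ev.key in events:
                    events[ev.key].involved_transcripts |= ev.involved_transcripts
                else:
                    events[ev.key] = ev
    if include_use:
        for ev in detect_use(gene):
            if ev.key in events:
                events[ev.key].involved_transcripts |= ev.involved_transcripts
            else:
                events[ev.key] = ev
    return sorted(events.values(), key=lambda e: (e.event_type, e.defining_coordinates))


def detect_use(
    gene: GeneModel, internal_only: bool = True
) -> list[ASEvent]:
    """Unique splice site exons: pairs of exons from different isoforms that
    overlap by >=1 nt while sharing no boundary splice site.

    By default only internal exons qualify (transcript termini are not
    splice junctions).
    """
    if len(gene.transcripts) < 2:
        return []
    events: dict[tuple, ASEvent] = {}
    ts = gene.transcripts
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            a, b = ts[i], ts[j]
            arange = range(1, len(a.exons) - 1) if internal_only else range(len(a.exons))
            brange = range(1, len(b.exons) - 1) if internal_only else range(len(b.exons))
            for ia in arange:
                for ib in brange:
                    ea, eb = a.exons[ia], b.exons[ib]
                    if not ea.overlaps(eb):
                        continue
                    if {ea.start, ea.end} & {eb.start, eb.end}:
                        continue
                    coords = tuple(sorted([(ea.start, ea.end), (eb.start, eb.end)]))
                    ev = ASEvent(
                        gene_id=gene.gene_id,
                        event_type="USE",
                        involved_transcripts=frozenset(
                            {a.transcript_id, b.transcript_id}
                        ),
                        defining_coordinates=coords,
                        chrom=gene.chrom,
                        strand=gene.strand,
                    )
                    if ev.key in events:
                        events[ev.key].involved_transcripts |= ev.involved_transcripts
                    else:
                        events[ev.key] = ev
    return sorted(events.values(), key=lambda e: e.defining_coordinates)


def summarize_as(
    genes: Sequence[GeneModel],
    expressed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene event counts plus per-transcript involvement flags.

    With a transcript x tissue boolean ``expressed`` frame, also reports the
    per-tissue fraction of expressed spliced transcripts involved in >=1
    event.
    """
    gene_rows = []
    involved: set[str] = set()
    for g in genes:
        events = enumerate_events(g)
        for e in events:
            involved |= e.involved_transcripts
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "n_events": len(events),
                **{
                    etype: sum(1 for e in events if e.event_type == etype)
                    for etype in EVENT_TYPES
                },
            }
        )
    summary = pd.DataFrame(gene_rows).set_index("gene_id")
    summary.attrs["involved_transcripts"] = involved
    if expressed is not None:
        spliced = {
            t.transcript_id for g in genes for t in g.transcripts if t.is_spliced
        }
        frac = {}
        for tissue in expressed.columns:
            expr = set(expressed.index[expressed[tissue]]) & spliced
            frac[tissue] = (
                len(expr & involved) / len(expr) if expr else float("nan")
            )
        summary.attrs["fraction_expressed_spliced_with_event"] = frac
    return summary


def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "event_type": e.event_type,
                "chrom": e.chrom,
                "strand": e.strand,
                "coordinates": ";".join(f"{s}-{t}" for s, t in e.defining_coordinates),
                "transcripts": ",".join(sorted(e.involved_transcripts)),
            }
            for e in events
        ]
    )
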