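"""ORF finding and the transcript/gene biotype decision tree.

Transcript labels, in decision order:

1. representative ORF with a stop codon and > 44 aa:
   NMD (nonsense-mediated decay) if the stop lies > 50 nt upstream of the
   final exon-exon junction in spliced coordinates, else protein_coding;
2. ORF with a start but no stop before the poly(A) site: NSD (nonstop decay);
3. otherwise noncoding: < 200 nt and clear of miRNA precursors -> sncRNA;
   >= 200 nt -> lncRNA subtype (antisense > sense_intronic > intragenic >
   intergenic precedence).  Short noncoding transcripts overlapping a miRNA
   precursor are labelled ``mirna_precursor`` (they belong to the miRNA
   pipeline, not to the sncRNA class).

All boundaries are strict ("longer than 44 aa", "more than 50 bp",
"> 50% PAT"); a transcript of exactly 200 nt goes to the lncRNA branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import GeneModel, HomologyTable, PeakSet, TranscriptModel

STANDARD_START = ("ATG",)
# vertebrate alternative initiation codons (NCBI transl_table 1 alternatives)
ALTERNATIVE_STARTS = ("ATG", "CTG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

TRANSCRIPT_LABELS = (
    "protein_coding",
    "nmd",
    "nsd",
    "sncRNA",
    "lncRNA_antisense",
    "lncRNA_sense_intronic",
    "lncRNA_intragenic",
    "lncRNA_intergenic",
    "mirna_precursor",
)


@dataclass(frozen=True)
class OpenReadingFrame:
    """ORF in spliced (sense) transcript coordinates.

    ``stop_end`` is the offset just past the stop codon, or None when the
    frame runs off the transcript end (nonstop-decay precursor).
    ``length_aa`` counts codons from the start codon, excluding the stop.
    """

    transcript_id: str
    start: int
    stop_end: int | None
    length_aa: int
    start_codon: str

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}:{self.start}"


def find_orfs(
    spliced_sequence: str,
    transcript_id: str = "",
    allow_alternative_starts: bool = True,
) -> list[OpenReadingFrame]:
    """All maximal ORFs in the three sense frames, longest first.

    Maximal: per (frame, stop) segment, the ORF opens at the earliest start
    codon; nested starts do not spawn separate ORFs.  A frame that reaches
    the sequence end without a stop yields an ORF with ``stop_end=None``.
    """
    seq = spliced_sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    starts = ALTERNATIVE_STARTS if allow_alternative_starts else STANDARD_START
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        open_start: int | None = None
        open_codon = ""
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    orfs.append(
                        OpenReadingFrame(
                            transcript_id=transcript_id,
                            start=open_start,
                            stop_end=pos + 3,
                            length_aa=(pos - open_start) // 3,
                            start_codon=open_codon,
                        )
                    )
                    open_start = None
            elif open_start is None and codon in starts:
                open_start, open_codon = pos, codon
        if open_start is not None:
            length = (len(seq) - open_start) // 3
            if length >= 1:
                orfs.append(
                    OpenReadingFrame(
                        transcript_id=transcript_id,
                        start=open_start,
                        stop_end=None,
                        length_aa=length,
                        start_codon=open_codon,
                    )
                )
    orfs.sort(key=lambda o: (-o.length_aa, o.start))
    return orfs


def select_representative_orf(
    orfs: Sequence[OpenReadingFrame],
    homology: HomologyTable,
    evalue_max: float = 1e-6,
    min_cov: float = 60.0,
    min_ident: float = 95.0,
) -> OpenReadingFrame | None:
    """Among the longest 3 ORFs, the one whose best protein hit passes the
    thresholds with the lowest E-value; with no passing hit, the longest ORF."""
    if not orfs:
        return None
    candidates = orfs[:3]
    hits = homology.passing(evalue_max, min_cov, min_ident, search_kind="protein")
    best: tuple[float, OpenReadingFrame] | None = None
    if len(hits):
        by_query = hits.groupby("query_id")["evalue"].min()
        for orf in candidates:
            if orf.orf_id in by_query.index:
                ev = float(by_query[orf.orf_id])
                if best is None or ev < best[0]:
                    best = (ev, orf)
    return best[1] if best else orfs[0]


@dataclass(frozen=True)
class TranscriptBiotype:
    transcript_id: str
    label: str
    fired_rule: str
    representative_orf: OpenReadingFrame | None = None


def _final_junction_spliced_pos(t: TranscriptModel) -> int | None:
    """Spliced-coordinate position of the final exon-exon junction (5' base
    of the last exon), or None for unspliced transcripts."""
    if not t.is_spliced:
        return None
    lengths = [len(e) for e in t.exons]
    if t.strand == "-":
        lengths = lengths[::-1]
    return sum(lengths[:-1])


def classify_transcript(
    t: TranscriptModel,
    rep_orf: OpenReadingFrame | None,
    coding_potential: bool,
    mirna_precursors: PeakSet,
    coding_genes: Sequence[GeneModel],
    min_orf_aa: int = 44,
    nmd_distance_nt: int = 50,
    lncrna_min_nt: int = 200,
) -> TranscriptBiotype:
    length = t.spliced_length
    if rep_orf is not None and rep_orf.stop_end is not None and rep_orf.length_aa > min_orf_aa:
        junction = _final_junction_spliced_pos(t)
        if junction is not None and junction - rep_orf.stop_end > nmd_distance_nt:
            return TranscriptBiotype(
                t.transcript_id,
                "nmd",
                f"stop {junction - rep_orf.stop_end} nt (> {nmd_distance_nt}) "
                "upstream of final junction",
                rep_orf,
            )
        return TranscriptBiotype(
            t.transcript_id,
            "protein_coding",
            f"representative ORF {rep_orf.length_aa} aa (> {min_orf_aa})",
            rep_orf,
        )
    if rep_orf is not None and rep_orf.stop_end is None:
        return TranscriptBiotype(
            t.transcript_id, "nsd", "start codon but no stop before poly(A) site", rep_orf
        )
    # noncoding branch; CPC2 flag can only rescue short-ORF transcripts here
    if coding_potential and rep_orf is not None:
        return TranscriptBiotype(
            t.transcript_id,
            "protein_coding",
            "short ORF with coding potential (CPC2)",
            rep_orf,
        )
    if length < lncrna_min_nt:
        if any(e.overlaps(p) for e in t.exons for p in mirna_precursors):
            return TranscriptBiotype(
                t.transcript_id,
                "mirna_precursor",
                f"< {lncrna_min_nt} nt, overlaps miRNA precursor",
                rep_orf,
            )
        return TranscriptBiotype(
            t.transcript_id, "sncRNA", f"noncoding, < {lncrna_min_nt} nt", rep_orf
        )
    sub = classify_lncrna_subtype(t, coding_genes)
    return TranscriptBiotype(
        t.transcript_id, sub, f"noncoding, >= {lncrna_min_nt} nt -> {sub}", rep_orf
    )


def classify_lncrna_subtype(
    t: TranscriptModel, coding_genes: Sequence[GeneModel]
) -> str:
    """lncRNA subtype with precedence antisense > sense_intronic >
    intragenic > intergenic."""
    same_chrom = [g for g in coding_genes if g.chrom == t.chrom]
    # antisense: any exon overlaps the span of an opposite-strand coding gene
    for g in same_chrom:
        if g.strand != t.strand and any(e.overlaps(g.span) for e in t.exons):
            return "lncRNA_antisense"
    # sense-intronic: whole transcript inside one intron of a same-strand gene
    for g in same_chrom:
        if g.strand != t.strand:
            continue
        for ref_t in g.transcripts:
            if any(i.contains(t.span) for i in ref_t.introns):
                return "lncRNA_sense_intronic"
    # intragenic: >=1 exon overlaps a same-strand coding gene's exons
    for g in same_chrom:
        if g.strand != t.strand:
            continue
        ref_exons = [e for rt in g.transcripts for e in rt.exons]
        if t.transcript_id in {rt.transcript_id for rt in g.transcripts}:
            ref_exons = [
                e
                for rt in g.transcripts
                if rt.transcript_id != t.transcript_id
                for e in rt.exons
            ]
        if any(e.overlaps(r) for e in t.exons for r in ref_exons):
            return "lncRNA_intragenic"
    return "lncRNA_intergenic"


@dataclass
class GeneBiotype:
    gene_id: str
    label: str  # protein_coding | noncoding | pseudogene
    bifunctional_per_tissue: dict[str, bool]
    pat_gene: bool = False
    pat_main_per_tissue: dict[str, bool] | None = None
    pseudogene_derived_lncRNA: bool = False
    orphan: bool = False
    switch_gene: bool = False


PAT_LABELS = frozenset({"nmd", "nsd"})


def classify_gene(
    g: GeneModel,
    transcript_biotypes: Mapping[str, TranscriptBiotype],
    homology: HomologyTable,
    evalue_max: float = 1e-6,
    min_cov: float = 90.0,
    min_ident: float = 95.0,
) -> GeneBiotype:
    """Gene label: protein_coding if any transcript is; pseudogene if the
    gene has vertebrate nucleotide homology but transcribes only NMD/NSD;
    else noncoding."""
    labels = []
    for t in g.transcripts:
        if t.transcript_id not in transcript_biotypes:
            raise ValueError(f"{g.gene_id}: unclassified transcript {t.transcript_id}")
        labels.append(transcript_biotypes[t.transcript_id].label)
    if "protein_coding" in labels:
        label = "protein_coding"
    else:
        hits = homology.passing(evalue_max, min_cov, min_ident, search_kind="nucleotide")
        has_hit = len(hits) and (
            hits["query_id"].isin([g.gene_id] + [t.transcript_id for t in g.transcripts]).any()
        )
        if has_hit and set(labels) <= PAT_LABELS:
            label = "pseudogene"
        else:
            label = "noncoding"
    return GeneBiotype(gene_id=g.gene_id, label=label, bifunctional_per_tissue={})


def flag_pseudogene_derived_lncrnas(
    gene_biotypes: Mapping[str, GeneBiotype],
    transcript_biotypes: Mapping[str, TranscriptBiotype],
    genes: Sequence[GeneModel],
) -> set[str]:
    """lncRNA transcripts transcribed from pseudogene loci."""
    out = set()
    for g in genes:
        gb = gene_biotypes[g.gene_id]
        if gb.label != "pseudogene":
            continue
        for t in g.transcripts:
            if transcript_biotypes[t.transcript_id].label.startswith("lncRNA"):
                gb.pseudogene_derived_lncRNA = True
                out.add(t.transcript_id)
    return out


def flag_orphan_genes(
    genes: Sequence[GeneModel],
    homology: HomologyTable,
    protein_thresholds: tuple[float, float, float] = (1e-6, 60.0, 95.0),
    nucleotide_thresholds: tuple[float, float, float] = (1e-6, 90.0, 95.0),
) -> set[str]:
    """Genes with no passing cross-species protein or nucleotide homology."""
    pe, pc, pi = protein_thresholds
    ne, nc, ni = nucleotide_thresholds
    # protein hits are keyed by ORF id ("<tid>:<start>"); fold back to the tid
    prot = {q.split(":")[0] for q in homology.passing(pe, pc, pi, "protein")["query_id"]}
    nucl = set(homology.passing(ne, nc, ni, "nucleotide")["query_id"])
    orphans = set()
    for g in genes:
        ids = {g.gene_id} | {t.transcript_id for t in g.transcripts}
        if not (ids & prot) and not (ids & nucl):
            orphans.add(g.gene_id)
    return orphans


def flag_bifunctional_and_pat(
    genes: Sequence[GeneModel],
    transcript_biotypes: Mapping[str, TranscriptBiotype],
    expressed_transcripts_per_tissue: Mapping[str, Iterable[str]],
    gene_biotypes: Mapping[str, GeneBiotype],
    pat_main_cut: float = 0.5,
) -> None:
    """Per-tissue bifunctional/PAT flags, updated in place on GeneBiotype.

    bifunctional: the gene expresses >=1 protein-coding and >=1 non-coding
    transcript in the tissue.  PAT gene: expresses >=1 NMD/NSD transcript
    anywhere.  pat_main: PATs are strictly > 50% of the gene's expressed
    transcripts in the tissue.  switch_gene: noncoding-only in some tissue
    and coding in another.
    """
    expressed_sets = {
        tis: set(tids) for tis, tids in expressed_transcripts_per_tissue.items()
    }
    for g in genes:
        gb = gene_biotypes[g.gene_id]
        gb.bifunctional_per_tissue = {}
        gb.pat_main_per_tissue = {}
        coding_tissues, noncoding_only_tissues = set(), set()
        for tis, expr in expressed_sets.items():
            labels = [
                transcript_biotypes[t.transcript_id].label
                for t in g.transcripts
                if t.transcript_id in expr
            ]
            if not labels:
                continue
            n_coding = sum(1 for x in labels if x == "protein_coding")
            n_pat = sum(1 for x in labels if x in PAT_LABELS)
            gb.bifunctional_per_tissue[tis] = n_coding >= 1 and n_coding < len(labels)
            gb.pat_main_per_tissue[tis] = n_pat / len(labels) > pat_main_cut
            if n_pat:
                gb.pat_gene = True
            (coding_tissues if n_coding else noncoding_only_tissues).add(tis)
        gb.switch_gene = bool(coding_tissues) and bool(noncoding_only_tissues)
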