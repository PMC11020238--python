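"""Synthetic multi-tissue transcriptome with planted ground truth.

Every pipeline input (annotation, genome, expression, evidence peaks,
support tables, homology flags, trait-QTL table) can be generated with a
known truth so each stage is testable offline.  Sequences are built so that
each planted biotype satisfies its defining rule and violates the others:

* coding bodies use T-free codons ({A,C,G}^3), which contain no start or
  stop codon in any frame, so the single planted ATG...TAA is the only ORF;
* noncoding sequence avoids the TG dinucleotide, which removes every
  vertebrate initiation codon (ATG/CTG/GTG/TTG) in every frame;
* NMD transcripts place the stop a configurable distance upstream of the
  final junction; NSD transcripts have a start and no stop;
* lncRNA subtypes are planted by position relative to host coding genes
  (antisense/sense-intronic guests inside a long host intron, intragenic
  transcripts overlapping the host 3' UTR, intergenic loci in gaps);
* poly(A) artifacts write a >=20-A stretch directly downstream of the
  terminal site; clean single-exon loci get an A-poor downstream window.

No attempt is made at realistic codon usage or peak shapes: the classifier
and filters only inspect ORF coordinates, A-stretches and window overlaps.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    HomologyTable,
    PeakSet,
    SequenceStore,
    TranscriptModel,
    revcomp,
)
from .expression import ExpressionMatrix, compute_rpkm
from .filtering import SupportTables, junction_canonical_flags


class ConfigError(ValueError):
    pass


_DEF_FRACTIONS = {
    "protein_coding": 0.30,
    "nmd": 0.10,
    "nsd": 0.05,
    "lncRNA_antisense": 0.08,
    "lncRNA_sense_intronic": 0.07,
    "lncRNA_intragenic": 0.05,
    "lncRNA_intergenic": 0.15,
    "sncRNA": 0.10,
    "pseudogene": 0.05,
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator (desk-scale defaults)."""

    n_genes: int = 100
    n_tissues: int = 12
    biotype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_FRACTIONS)
    )
    fraction_polya_artifact: float = 0.05
    fraction_tissue_specific: float = 0.25
    fraction_housekeeping: float = 0.25
    fraction_bifunctional: float = 0.3  # of protein-coding genes
    fraction_validated: float = 0.8  # TSS/TTS evidence support
    fraction_promoter_evidence: float = 0.8  # single-exon gene rescue
    fraction_extension: float = 0.3  # of >=3-exon genes get shrunk references
    fraction_unannotated: float = 0.2  # genes absent from the reference
    fraction_assembled: float = 0.7  # of expressed tissues
    fraction_qtl_inside: float = 0.7
    sncrna_length: int = 150
    lncrna_length: int = 400
    coding_n_aa: int = 60
    nmd_stop_to_junction: int = 80
    expression_sigma: float = 0.3
    count_noise: bool = True  # Poisson counts; False -> deterministic
    high_rpkm: float = 20.0
    low_rpkm: float = 0.02
    library_size_mean: float = 8.0e7
    wtts_read_length: int = 161
    n_traits: int = 20
    qtls_per_trait: int = 5
    planted_similar_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_similar_overlap: float = 0.8
    junction_jitter: int = 5
    border_jitter: int = 40
    jitter_mode: str = "uniform"  # or "exact"
    gap_nt: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tissues < 2:
            raise ConfigError("need >=1 gene and >=2 tissues")
        total = sum(self.biotype_fractions.values())
        if total > 1.0 + 1e-9:
            raise ConfigError(f"biotype fractions sum to {total} > 1")
        if any(f < 0 for f in self.biotype_fractions.values()):
            raise ConfigError("negative biotype fraction")
        if self.sncrna_length >= 200:
            raise ConfigError("sncRNA length must be < 200 nt")
        if self.lncrna_length < 200:
            raise ConfigError("lncRNA length must be >= 200 nt")
        if not (0 <= self.fraction_tissue_specific + self.fraction_housekeeping <= 1):
            raise ConfigError("profile fractions must sum to <= 1")


@dataclass
class TruthSet:
    """Planted ground truth for every emitted entity."""

    biotype: dict[str, str] = field(default_factory=dict)
    orf: dict[str, tuple[int, int | None, int]] = field(default_factory=dict)
    expressed_tissues: dict[str, frozenset[str]] = field(default_factory=dict)
    profile: dict[str, str] = field(default_factory=dict)
    duplicate_group: dict[str, str] = field(default_factory=dict)
    border_validated: dict[str, tuple[bool, bool]] = field(default_factory=dict)
    polya_artifact: set[str] = field(default_factory=set)
    promoter_evidence: dict[str, bool] = field(default_factory=dict)
    gene_extension: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    trait_assoc: dict[str, set[str]] = field(default_factory=dict)
    similar_pairs: list[tuple[str, str]] = field(default_factory=list)
    gene_label: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "biotype": self.biotype,
            "orf": {k: list(v) for k, v in self.orf.items()},
            "expressed_tissues": {k: sorted(v) for k, v in self.expressed_tissues.items()},
            "profile": self.profile,
            "duplicate_group": self.duplicate_group,
            "border_validated": {k: list(v) for k, v in self.border_validated.items()},
            "polya_artifact": sorted(self.polya_artifact),
            "promoter_evidence": self.promoter_evidence,
            "gene_extension": {k: list(v) for k, v in self.gene_extension.items()},
            "trait_assoc": {k: sorted(v) for k, v in self.trait_assoc.items()},
            "similar_pairs": [list(p) for p in self.similar_pairs],
            "gene_label": self.gene_label,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------- sequences

_BASES = "ACGT"


def _safe_seq(rng: np.random.Generator, n: int, prev: str = "") -> str:
    """Random sequence with no TG dinucleotide: start-codon free in every
    sense frame."""
    out = []
    last = prev[-1:] if prev else ""
    for _ in range(n):
        choices = "ACT" if last == "T" else _BASES
        base = choices[rng.integers(len(choices))]
        out.append(base)
        last = base
    return "".join(out)


def _cds_body(rng: np.random.Generator, n_codons: int) -> str:
    """T-free codons: no start, no stop, in any frame."""
    alphabet = "ACG"
    return "".join(alphabet[i] for i in rng.integers(3, size=3 * n_codons))


def _intron_seq(rng: np.random.Generator, n: int) -> str:
    if n < 6:
        raise ConfigError("introns must be >=6 nt for canonical sites")
    return "GT" + _safe_seq(rng, n - 4, prev="T") + "AG"


# --------------------------------------------------------------- blueprints


@dataclass
class _Blueprint:
    """Sense-strand layout of one transcript before genomic placement."""

    sense_seq: str
    exon_lens: list[int]
    intron_lens: list[int]
    biotype: str
    orf: tuple[int, int | None, int] | None = None  # start, stop_end, aa

    @property
    def spliced_length(self) -> int:
        return len(self.sense_seq)


def orf_transcript_blueprint(
    rng: np.random.Generator,
    *,
    n_aa: int = 60,
    stop_to_junction: int | None = None,
    stopless: bool = False,
    utr5: int = 120,
    biotype: str | None = None,
) -> _Blueprint:
    """Transcript carrying exactly one ORF.

    ``stop_to_junction`` is the spliced distance from the stop codon end to
    the final exon-exon junction: > 50 plants an NMD isoform, <= 50 (or
    None, stop in the last exon) a protein-coding one.  ``stopless`` plants
    a nonstop-decay isoform instead.
    """
    head = _safe_seq(rng, utr5)
    orf_start = utr5
    if stopless:
        body = _cds_body(rng, n_aa - 1)
        seq = head + "ATG" + body
        exon_lens = [60, len(seq) - 60]
        return _Blueprint(
            sense_seq=seq,
            exon_lens=exon_lens,
            intron_lens=[int(rng.integers(80, 200))],
            biotype=biotype or "nsd",
            orf=(orf_start, None, (len(seq) - orf_start) // 3),
        )
    cds = "ATG" + _cds_body(rng, n_aa - 1) + "TAA"
    stop_end = orf_start + len(cds)
    if stop_to_junction is None:
        utr3 = 150
        seq = head + cds + _safe_seq(rng, utr3, prev="A")
        junction = utr5 + 33  # mid-CDS: stop lies in the last exon
        label = "protein_coding"
    else:
        utr3 = stop_to_junction + 100
        seq = head + cds + _safe_seq(rng, utr3, prev="A")
        junction = stop_end + stop_to_junction
        label = "nmd" if stop_to_junction > 50 else "protein_coding"
    if seq[59] == "T":
        # an exon-skipping isoform joins position 59 to the last exon; keep
        # that new spliced adjacency free of xTG initiation codons
        seq = seq[:59] + "C" + seq[60:]
    exon_lens = [60, junction - 60, len(seq) - junction]
    if min(exon_lens) < 1:
        raise ConfigError("infeasible exon layout")
    return _Blueprint(
        sense_seq=seq,
        exon_lens=exon_lens,
        intron_lens=[int(rng.integers(80, 200)) for _ in range(2)],
        biotype=biotype or label,
        orf=(orf_start, stop_end, n_aa),
    )


def noncoding_blueprint(
    rng: np.random.Generator,
    *,
    length: int,
    n_exons: int = 1,
    biotype: str = "lncRNA_intergenic",
) -> _Blueprint:
    seq = _safe_seq(rng, length)
    if n_exons == 1:
        exon_lens = [length]
    else:
        cut = length // n_exons
        exon_lens = [cut] * (n_exons - 1) + [length - cut * (n_exons - 1)]
    return _Blueprint(
        sense_seq=seq,
        exon_lens=exon_lens,
        intron_lens=[60 + int(rng.integers(0, 40)) for _ in range(n_exons - 1)],
        biotype=biotype,
    )


# ----------------------------------------------------------------- placement


def _place_transcript(
    rng: np.random.Generator, bp: _Blueprint, strand: str
) -> tuple[str, list[tuple[int, int]]]:
    """Genomic-orientation segment string and exon offsets within it."""
    pieces, exon_offsets = [], []
    pos = cursor = 0
    for i, elen in enumerate(bp.exon_lens):
        pieces.append(bp.sense_seq[cursor : cursor + elen])
        exon_offsets.append((pos, pos + elen))
        cursor += elen
        pos += elen
        if i < len(bp.intron_lens):
            pieces.append(_intron_seq(rng, bp.intron_lens[i]))
            pos += bp.intron_lens[i]
    sense_segment = "".join(pieces)
    if strand == "-":
        exon_offsets = [(pos - e, pos - s) for s, e in exon_offsets][::-1]
        return revcomp(sense_segment), exon_offsets
    return sense_segment, exon_offsets


@dataclass
class _PlacedGene:
    gene_id: str
    strand: str
    segment: str
    # transcript_id -> (exon offsets within segment, blueprint)
    transcripts: dict[str, tuple[list[tuple[int, int]], _Blueprint]]


def _biotype_counts(config: SimulationConfig) -> dict[str, int]:
    counts = {
        b: int(np.floor(f * config.n_genes))
        for b, f in config.biotype_fractions.items()
    }
    # distribute the rounding remainder deterministically, largest fraction first
    remainder = config.n_genes - sum(counts.values())
    order = sorted(config.biotype_fractions, key=lambda b: -config.biotype_fractions[b])
    for b in order[:remainder]:
        counts[b] += 1
    n_hosts_needed = counts.get("lncRNA_antisense", 0) + counts.get(
        "lncRNA_sense_intronic", 0
    )
    n_tails = counts.get("lncRNA_intragenic", 0)
    n_pc = counts.get("protein_coding", 0)
    if n_pc < n_hosts_needed or n_pc < n_tails:
        raise ConfigError(
            f"{n_pc} protein-coding genes cannot host "
            f"{n_hosts_needed} intronic guests and {n_tails} intragenic lncRNAs"
        )
    return counts


def simulate_annotation(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[GeneModel], SequenceStore, TruthSet]:
    """Generate genes, genome and truth with planted biotypes.

    Each planted biotype satisfies its classification rule by construction
    (and violates the others); poly(A)-artifact loci carry a genomic A
    stretch downstream of their terminal site.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = TruthSet()
    counts = _biotype_counts(config)
    n_artifacts = max(1, round(config.fraction_polya_artifact * config.n_genes))

    placed: list[_PlacedGene] = []
    gene_no = 0

    def next_gid() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"G{gene_no:05d}"

    host_queue: list[str] = []  # guests still to be embedded: biotype names
    host_queue += ["lncRNA_antisense"] * counts.get("lncRNA_antisense", 0)
    host_queue += ["lncRNA_sense_intronic"] * counts.get("lncRNA_sense_intronic", 0)
    tails_left = counts.get("lncRNA_intragenic", 0)
    n_bifunctional = round(config.fraction_bifunctional * counts.get("protein_coding", 0))

    # --- protein-coding genes (hosts for guests/tails/bifunctional isoforms)
    for k in range(counts.get("protein_coding", 0)):
        gid = next_gid()
        strand = "+" if rng.random() < 0.6 else "-"
        bp = orf_transcript_blueprint(rng, n_aa=config.coding_n_aa, biotype="protein_coding")
        hosting = host_queue.pop() if host_queue else None
        if hosting:
            bp.intron_lens[0] = 900  # long intron 1 to hold the guest
        segment, exon_offsets = _place_transcript(rng, bp, strand)
        tid = f"{gid}.1"
        gene = _PlacedGene(gid, strand, segment, {tid: (exon_offsets, bp)})
        truth.biotype[tid] = "protein_coding"
        truth.orf[tid] = bp.orf

        if hosting:
            guest_gid = next_gid()
            guest_strand = strand if hosting == "lncRNA_sense_intronic" else (
                "-" if strand == "+" else "+"
            )
            guest_bp = noncoding_blueprint(
                rng, length=300, n_exons=2, biotype=hosting
            )
            guest_seg, guest_offsets = _place_transcript(rng, guest_bp, guest_strand)
            # intron 1 of the host, in genomic segment coordinates
            sense_intron1 = (bp.exon_lens[0], bp.exon_lens[0] + bp.intron_lens[0])
            if strand == "-":
                L = len(segment)
                intron1 = (L - sense_intron1[1], L - sense_intron1[0])
            else:
                intron1 = sense_intron1
            pad = 20
            offset = intron1[0] + pad
            if offset + len(guest_seg) > intron1[1] - pad:
                raise ConfigError("guest does not fit host intron")
            gene.segment = (
                segment[:offset] + guest_seg + segment[offset + len(guest_seg) :]
            )
            guest_tid = f"{guest_gid}.1"
            guest_offsets = [(s + offset, e + offset) for s, e in guest_offsets]
            placed.append(
                _PlacedGene(
                    guest_gid, guest_strand, "", {guest_tid: (guest_offsets, guest_bp)}
                )
            )
            placed[-1].segment = None  # embedded in the host segment
            gene.transcripts[f"__guest__{guest_tid}"] = (guest_offsets, guest_bp)
            truth.biotype[guest_tid] = hosting

        if k < n_bifunctional:
            # noncoding isoform skipping the middle exon (SE event, no ORF)
            iso = f"{gid}.2"
            skip_offsets_sense = [
                (0, bp.exon_lens[0]),
                (sum(bp.exon_lens[:2]) + sum(bp.intron_lens), sum(bp.exon_lens) + sum(bp.intron_lens)),
            ]
            L = sum(bp.exon_lens) + sum(bp.intron_lens)
            if strand == "-":
                offs = [(L - e, L - s) for s, e in skip_offsets_sense][::-1]
            else:
                offs = skip_offsets_sense
            gene.transcripts[iso] = (offs, bp)
            truth.biotype[iso] = "lncRNA_intragenic"

        if tails_left > 0:
            tails_left -= 1
            tail_tid = f"{gid}.T"
            tail_len, overlap = config.lncrna_length, 50
            new_nt = tail_len - overlap
            # continue from the host's sense-strand 3' end so the appended
            # junction cannot form a TG dinucleotide (i.e. a start codon)
            sense_last = (
                gene.segment[-1] if strand == "+" else revcomp(gene.segment[0])
            )
            tail_sense_new = _safe_seq(rng, new_nt, prev=sense_last)
            L = len(gene.segment)
            if strand == "+":
                gene.segment = gene.segment + tail_sense_new
                offs = [(L - overlap, L - overlap + tail_len)]
            else:
                gene.segment = revcomp(tail_sense_new) + gene.segment
                # shift every recorded offset by the prepended length
                for key, (o, b) in list(gene.transcripts.items()):
                    gene.transcripts[key] = ([(s + new_nt, e + new_nt) for s, e in o], b)
                offs = [(0, tail_len)]
            tail_bp = noncoding_blueprint(rng, length=tail_len, biotype="lncRNA_intragenic")
            gene.transcripts[tail_tid] = (offs, tail_bp)
            truth.biotype[tail_tid] = "lncRNA_intragenic"
        placed.append(gene)

    # --- standalone loci
    def add_simple(gid: str, bp: _Blueprint, downstream: str | None = None) -> None:
        strand = "+" if rng.random() < 0.6 else "-"
        segment, offsets = _place_transcript(rng, bp, strand)
        if downstream is not None:
            if strand == "+":
                segment = segment + downstream
            else:
                segment = revcomp(downstream) + segment
                offsets = [(s + len(downstream), e + len(downstream)) for s, e in offsets]
        tid = f"{gid}.1"
        placed.append(_PlacedGene(gid, strand, segment, {tid: (offsets, bp)}))
        truth.biotype[tid] = bp.biotype
        if bp.orf:
            truth.orf[tid] = bp.orf

    for _ in range(counts.get("nmd", 0)):
        add_simple(
            next_gid(),
            orf_transcript_blueprint(
                rng,
                n_aa=config.coding_n_aa,
                stop_to_junction=config.nmd_stop_to_junction,
                biotype="nmd",
            ),
        )
    for _ in range(counts.get("nsd", 0)):
        add_simple(
            next_gid(),
            orf_transcript_blueprint(rng, n_aa=config.coding_n_aa, stopless=True),
        )
    for _ in range(counts.get("pseudogene", 0)):
        add_simple(
            next_gid(),
            orf_transcript_blueprint(
                rng,
                n_aa=config.coding_n_aa,
                stop_to_junction=config.nmd_stop_to_junction,
                biotype="nmd",
            ),
        )
        truth.gene_label[placed[-1].gene_id] = "pseudogene"
    clean_downstream = "CACACACACACACACACACACACACACACA"
    for _ in range(counts.get("sncRNA", 0)):
        add_simple(
            next_gid(),
            noncoding_blueprint(rng, length=config.sncrna_length, biotype="sncRNA"),
            downstream=clean_downstream,
        )
    for _ in range(counts.get("lncRNA_intergenic", 0)):
        add_simple(
            next_gid(),
            noncoding_blueprint(
                rng, length=config.lncrna_length, n_exons=2, biotype="lncRNA_intergenic"
            ),
        )
    polya_run = "A" * 10 + "G" + "A" * 11 + "CCCCCCCC"  # 22-run with 1 mismatch
    for _ in range(n_artifacts):
        gid = next_gid()
        add_simple(
            gid,
            noncoding_blueprint(
                rng, length=config.lncrna_length, biotype="lncRNA_intergenic"
            ),
            downstream=polya_run,
        )
        truth.polya_artifact.add(f"{gid}.1")

    # --- assemble the chromosome and absolute coordinates
    chrom = "chr1"
    # generous leading margin: positions < ~850 stay clear of every border
    # window, so decoy evidence can live there
    parts: list[str] = [_safe_seq(rng, 1000)]
    cursor = 1000
    genes: list[GeneModel] = []
    pending: dict[str, list[TranscriptModel]] = {}
    order = [pg for pg in placed if pg.segment is not None]
    embedded = {pg.gene_id: pg for pg in placed if pg.segment is None}
    for pg in order:
        base = cursor
        parts.append(pg.segment)
        cursor += len(pg.segment)
        gap = config.gap_nt + int(rng.integers(0, 500))
        parts.append(_safe_seq(rng, gap))
        cursor += gap
        for tid, (offsets, bp) in pg.transcripts.items():
            if tid.startswith("__guest__"):
                real_tid = tid.removeprefix("__guest__")
                guest_gid = real_tid.split(".")[0]
                guest = embedded[guest_gid]
                exons = tuple(
                    GenomicInterval(chrom, base + s, base + e, guest.strand)
                    for s, e in offsets
                )
                pending.setdefault(guest_gid, []).append(
                    TranscriptModel(
                        transcript_id=real_tid, gene_id=guest_gid, exons=exons
                    )
                )
                continue
            exons = tuple(
                GenomicInterval(chrom, base + s, base + e, pg.strand)
                for s, e in offsets
            )
            pending.setdefault(pg.gene_id, []).append(
                TranscriptModel(transcript_id=tid, gene_id=pg.gene_id, exons=exons)
            )
    parts.append(_safe_seq(rng, 200))
    genome = SequenceStore({chrom: "".join(parts)})
    for gid in sorted(pending):
        genes.append(GeneModel(gene_id=gid, transcripts=sorted(
            pending[gid], key=lambda t: t.transcript_id
        )))

    # border-support and extension truth; isoforms sharing a start/end
    # position share its validation flag (they share the evidence window)
    tss_flags: dict[tuple[str, str, int], bool] = {}
    tts_flags: dict[tuple[str, str, int], bool] = {}
    for g in genes:
        for t in g.transcripts:
            k5 = (t.chrom, t.strand, t.tss)
            k3 = (t.chrom, t.strand, t.tts)
            if k5 not in tss_flags:
                tss_flags[k5] = bool(rng.random() < config.fraction_validated)
            if k3 not in tts_flags:
                tts_flags[k3] = bool(rng.random() < config.fraction_validated)
            truth.border_validated[t.transcript_id] = (tss_flags[k5], tts_flags[k3])
            truth.duplicate_group[t.transcript_id] = t.transcript_id
        if all(not t.is_spliced for t in g.transcripts):
            truth.promoter_evidence[g.gene_id] = bool(
                rng.random() < config.fraction_promoter_evidence
            )
    ext_kinds = ["five_prime", "three_prime", "both"]
    multi = [
        g
        for g in genes
        if all(len(t.exons) >= 3 for t in g.transcripts[:1]) and len(g.transcripts) == 1
    ]
    n_ext = round(config.fraction_extension * len(multi))
    for i, g in enumerate(multi[:n_ext]):
        truth.gene_extension[g.gene_id] = (ext_kinds[i % 3], 0, 0)  # filled later

    _assign_expression_truth(rng, genes, truth, config)
    return genes, genome, truth


def _assign_expression_truth(
    rng: np.random.Generator,
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
) -> None:
    tissues = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]
    n = config.n_tissues
    for g in genes:
        for t in g.transcripts:
            r = rng.random()
            if t.is_spliced and r < config.fraction_tissue_specific:
                profile = "tissue_specific"
                expr = {tissues[rng.integers(n)]}
            elif r < config.fraction_tissue_specific + config.fraction_housekeeping:
                profile = "housekeeping"
                expr = set(tissues)
            else:
                profile = "broad"
                k = int(rng.integers(n // 2 + 1, n + 1))
                expr = set(rng.choice(tissues, size=k, replace=False))
            if not t.is_spliced and len(expr) == 1:
                # unspliced single-tissue loci would be filtered; keep two
                expr.add(tissues[(tissues.index(next(iter(expr))) + 1) % n])
                profile = "broad"
            truth.profile[t.transcript_id] = profile
            truth.expressed_tissues[t.transcript_id] = frozenset(expr)


def simulate_expression(
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Counts + RPKM realizing the planted expression profiles.

    Planted tissue-specific transcripts exceed 1 RPKM in exactly their
    planted tissue; housekeepers are near-uniform; counts are Poisson around
    the log-normal RPKM targets and RPKM is recomputed from the counts.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    tissues = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]
    ts = [t for g in genes for t in g.transcripts]
    if any(t.transcript_id not in truth.expressed_tissues for t in ts):
        raise ConfigError("truth does not cover all transcripts")
    lengths = np.array([t.spliced_length for t in ts], float)
    libsizes = config.library_size_mean * rng.lognormal(0, 0.2, size=len(tissues))
    target = np.empty((len(ts), len(tissues)))
    assembled = np.zeros_like(target, bool)
    jq = np.zeros_like(target, bool)
    for i, t in enumerate(ts):
        expr = truth.expressed_tissues[t.transcript_id]
        profile = truth.profile[t.transcript_id]
        high = config.high_rpkm
        for j, tis in enumerate(tissues):
            if tis in expr:
                target[i, j] = high * rng.lognormal(0, config.expression_sigma)
                jq[i, j] = True
            else:
                target[i, j] = config.low_rpkm * rng.lognormal(0, config.expression_sigma)
                jq[i, j] = rng.random() < 0.5
        if profile == "housekeeping":
            # tighter spread: near-uniform across all tissues
            target[i, :] = 0.5 * high * rng.lognormal(
                0, config.expression_sigma / 2, size=len(tissues)
            )
            jq[i, :] = True
        expr_idx = [j for j, tis in enumerate(tissues) if tis in expr]
        chosen = [j for j in expr_idx if rng.random() < config.fraction_assembled]
        if not chosen:
            chosen = [expr_idx[int(rng.integers(len(expr_idx)))]]
        assembled[i, chosen] = True
    expected = target * (lengths[:, None] / 1e3) * (libsizes[None, :] / 1e6)
    counts = rng.poisson(expected).astype(float) if config.count_noise else expected
    rpkm = compute_rpkm(counts, lengths, libsizes)
    matrix = ExpressionMatrix(
        feature_ids=[t.transcript_id for t in ts],
        tissues=tissues,
        counts=counts,
        rpkm=rpkm,
        assembled=assembled,
        junctions_quantified=jq,
        lengths_nt=lengths,
    )
    # stamp assembled tissues onto the transcript provenance
    for i, t in enumerate(ts):
        t.source_tissues = frozenset(
            tis for j, tis in enumerate(tissues) if assembled[i, j]
        )
    return matrix


def simulate_evidence(
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
    chrom_length: int | None = None,
) -> dict[str, PeakSet]:
    """Evidence tracks placed inside (validated) or outside (unvalidated)
    the border windows, plus promoter marks for rescued single-exon genes."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    tracks: dict[str, list[GenomicInterval]] = {
        k: [] for k in ("RAMPAGE", "WTTS", "H3K4me3", "H3K4me1", "H3K27ac", "ATAC", "CTCF")
    }

    def clip(lo: int, hi: int) -> tuple[int, int]:
        lo = max(0, lo)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi

    # decoy evidence far from every border window (leading chromosome margin)
    tracks["RAMPAGE"].append(GenomicInterval("chr1", 5, 50, "."))
    tracks["WTTS"].append(GenomicInterval("chr1", 5, 50, "."))
    for g in genes:
        for t in g.transcripts:
            v5, v3 = truth.border_validated[t.transcript_id]
            jitter = int(rng.integers(-3, 4))
            if v5:
                lo, hi = clip(t.tss - 5 + jitter, t.tss + 6 + jitter)
                tracks["RAMPAGE"].append(GenomicInterval(t.chrom, lo, hi, "."))
            if v3:
                if t.strand == "+":
                    lo, hi = clip(t.tts + 2, t.tts + 2 + config.wtts_read_length)
                else:
                    lo, hi = clip(t.tts - 1 - config.wtts_read_length, t.tts - 1)
                tracks["WTTS"].append(GenomicInterval(t.chrom, lo, hi, "."))
        # promoter evidence for single-exon genes; CTCF alone for the rest
        if g.gene_id in truth.promoter_evidence:
            anchor = g.tss
            direction = 1 if g.strand == "+" else -1
            lo, hi = clip(anchor - direction * 250, anchor - direction * 150)
            lo, hi = min(lo, hi), max(lo, hi)
            if truth.promoter_evidence[g.gene_id]:
                for track in ("H3K4me3", "ATAC"):
                    tracks[track].append(GenomicInterval(g.chrom, lo, hi, "."))
            else:
                tracks["CTCF"].append(GenomicInterval(g.chrom, lo, hi, "."))
    return {k: PeakSet(track_name=k, intervals=v) for k, v in tracks.items()}


def simulate_reference(
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[GeneModel]:
    """Reference annotation (stand-in for Ensembl/NCBI): most genes copied,
    extension-planted genes shrunk by dropping terminal exons, a fraction
    left out entirely (unannotated)."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    refs: list[GeneModel] = []
    for g in genes:
        if g.gene_id not in truth.gene_extension and rng.random() < config.fraction_unannotated:
            continue
        ref_id = f"REF_{g.gene_id}"
        new_ts = []
        for t in g.transcripts:
            exons = list(t.exons)
            if g.gene_id in truth.gene_extension:
                kind = truth.gene_extension[g.gene_id][0]
                drop_first = kind in ("five_prime", "both")
                drop_last = kind in ("three_prime", "both")
                if t.strand == "-":
                    drop_first, drop_last = drop_last, drop_first
                # genomic-first exon is the 5' end on '+', 3' end on '-'
                if drop_first:
                    exons = exons[1:]
                if drop_last:
                    exons = exons[:-1]
            new_ts.append(
                TranscriptModel(
                    transcript_id=f"REF_{t.transcript_id}",
                    gene_id=ref_id,
                    exons=tuple(exons),
                    source_dataset="ensembl_ref",
                )
            )
        ref = GeneModel(gene_id=ref_id, transcripts=new_ts)
        if g.gene_id in truth.gene_extension:
            kind = truth.gene_extension[g.gene_id][0]
            if g.strand == "+":
                ext5 = max(0, ref.span.start - g.span.start)
                ext3 = max(0, g.span.end - ref.span.end)
            else:
                ext5 = max(0, g.span.end - ref.span.end)
                ext3 = max(0, ref.span.start - g.span.start)
            truth.gene_extension[g.gene_id] = (kind, ext5, ext3)
        refs.append(ref)
    return refs


def simulate_homology(
    genes: list[GeneModel], truth: TruthSet, config: SimulationConfig, seed: int | None = None
) -> tuple[HomologyTable, dict[str, bool]]:
    """Homology hits and CPC2-style coding-potential flags consistent with
    the planted biotypes: coding ORFs get passing protein hits, pseudogene
    loci get passing nucleotide hits, everything else fails the thresholds."""
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    rows = []
    coding_potential: dict[str, bool] = {}
    for g in genes:
        for t in g.transcripts:
            label = truth.biotype[t.transcript_id]
            coding_potential[t.transcript_id] = label == "protein_coding"
            if label in ("protein_coding", "nmd") and t.transcript_id in truth.orf:
                start = truth.orf[t.transcript_id][0]
                rows.append(
                    {
                        "query_id": f"{t.transcript_id}:{start}",
                        "subject_id": f"UP{rng.integers(10000, 99999)}",
                        "evalue": float(10.0 ** -rng.integers(10, 60)),
                        "coverage_pct": float(rng.uniform(70, 100)),
                        "identity_pct": float(rng.uniform(95, 100)),
                        "search_kind": "protein",
                    }
                )
            elif label.startswith("lncRNA") and rng.random() < 0.2:
                # near-miss hit that fails the coverage threshold
                rows.append(
                    {
                        "query_id": t.transcript_id,
                        "subject_id": f"NR{rng.integers(10000, 99999)}",
                        "evalue": 1e-8,
                        "coverage_pct": float(rng.uniform(10, 50)),
                        "identity_pct": float(rng.uniform(80, 94)),
                        "search_kind": "nucleotide",
                    }
                )
        if truth.gene_label.get(g.gene_id) == "pseudogene":
            rows.append(
                {
                    "query_id": g.gene_id,
                    "subject_id": f"NM{rng.integers(10000, 99999)}",
                    "evalue": 1e-25,
                    "coverage_pct": float(rng.uniform(92, 100)),
                    "identity_pct": float(rng.uniform(96, 100)),
                    "search_kind": "nucleotide",
                }
            )
    table = HomologyTable(
        rows=pd.DataFrame(rows) if rows else HomologyTable().rows
    )
    return table, coding_potential


def simulate_support(
    genes: list[GeneModel],
    genome: SequenceStore,
    config: SimulationConfig,
    seed: int | None = None,
    planted_low_coverage: set[str] = frozenset(),
) -> SupportTables:
    """Coverage and junction support that pass the QC filters (coverage
    >= 3x, every junction spanned), with optional planted failures."""
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    ts = [t for g in genes for t in g.transcripts]
    tables = SupportTables(canonical_flag=junction_canonical_flags(ts, genome))
    for t in ts:
        tissues = t.source_tissues or frozenset({"tissue01"})
        for tis in tissues:
            low = t.transcript_id in planted_low_coverage
            tables.base_coverage[(t.transcript_id, tis)] = (
                float(rng.uniform(0.5, 2.9)) if low else float(rng.uniform(3.0, 40.0))
            )
            for intron in t.introns:
                key = ((t.chrom, t.strand, intron.start, intron.end), tis)
                tables.junction_support[key] = int(rng.integers(2, 60))
    return tables


def simulate_assembled_tissues(
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[tuple[str, list[TranscriptModel]]]:
    """Per-tissue pre-collapse copies of each transcript with bounded
    coordinate jitter; copies record their duplicate group in the truth.

    The first copy of each group is unjittered; later copies shift all
    junction boundaries by a common non-negative offset <= junction_jitter
    (mode 'uniform') or exactly junction_jitter (mode 'exact'), and
    unsupported borders likewise by <= border_jitter, so the largest
    pairwise discrepancy within a group equals the configured jitter.
    """
    rng = np.random.default_rng(config.seed + 6 if seed is None else seed)
    tissues = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]
    out: dict[str, list[TranscriptModel]] = {tis: [] for tis in tissues}
    for g in genes:
        for t in g.transcripts:
            expr = sorted(truth.expressed_tissues.get(t.transcript_id, frozenset()))
            chosen = expr if len(expr) <= 3 else list(
                rng.choice(expr, size=3, replace=False)
            )
            if not chosen:
                chosen = [tissues[0]]
            v5, v3 = truth.border_validated.get(t.transcript_id, (False, False))
            for c, tis in enumerate(sorted(chosen)):
                if c == 0:
                    jd = bd5 = bd3 = 0
                elif config.jitter_mode == "exact":
                    jd, bd5, bd3 = (
                        config.junction_jitter,
                        config.border_jitter,
                        config.border_jitter,
                    )
                else:
                    jd = int(rng.integers(0, config.junction_jitter + 1))
                    bd5 = int(rng.integers(0, config.border_jitter + 1))
                    bd3 = int(rng.integers(0, config.border_jitter + 1))
                exons = [[e.start, e.end] for e in t.exons]
                for i in range(len(exons) - 1):
                    exons[i][1] += jd  # donor boundary
                    exons[i + 1][0] += jd  # acceptor boundary
                # genomic-left border: 5' on '+', 3' on '-'
                left_supported = v5 if t.strand == "+" else v3
                right_supported = v3 if t.strand == "+" else v5
                left_delta = 0 if left_supported else (bd5 if t.strand == "+" else bd3)
                right_delta = 0 if right_supported else (bd3 if t.strand == "+" else bd5)
                exons[0][0] = max(0, exons[0][0] - left_delta)
                exons[-1][1] += right_delta
                copy_id = f"{t.transcript_id}|{tis}"
                out[tis].append(
                    TranscriptModel(
                        transcript_id=copy_id,
                        gene_id=t.gene_id,
                        exons=tuple(
                            GenomicInterval(t.chrom, s, e, t.strand) for s, e in exons
                        ),
                        source_tissues=frozenset({tis}),
                    )
                )
                truth.duplicate_group[copy_id] = t.transcript_id
    return [(tis, out[tis]) for tis in tissues if out[tis]]


def simulate_qtl_table(
    genes: list[GeneModel],
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trait-QTL table whose nearest-expressed-gene assignment recovers the
    planted per-trait gene sets; planted similar trait pairs share the
    configured fraction of target genes."""
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    if config.n_traits < 2:
        raise ConfigError("need >=2 traits")
    # standalone target genes: spans that no other gene overlaps
    spans = sorted(((g.span.start, g.span.end, g) for g in genes))
    standalone = []
    for i, (s, e, g) in enumerate(spans):
        prev_ok = i == 0 or spans[i - 1][1] <= s
        next_ok = i == len(spans) - 1 or e <= spans[i + 1][0]
        if prev_ok and next_ok:
            standalone.append((g, spans[i + 1][0] if i + 1 < len(spans) else None))
    if len(standalone) < config.qtls_per_trait:
        raise ConfigError("not enough isolated genes for QTL targets")
    traits = [f"T{i + 1:02d}" for i in range(config.n_traits)]
    planted = [tuple(p) for p in config.planted_similar_pairs]
    truth.similar_pairs = list(planted)
    similar_b = {b: a for a, b in planted}
    target_sets: dict[str, list[GeneModel]] = {}
    pool = [g for g, _ in standalone]
    for trait in traits:
        if trait in similar_b and similar_b[trait] in target_sets:
            src = target_sets[similar_b[trait]]
            n_shared = round(config.planted_similar_overlap * len(src))
            shared = list(src[:n_shared])
            src_ids = {g.gene_id for g in src}
            others = [g for g in pool if g.gene_id not in src_ids]
            extra_idx = rng.choice(
                len(others), size=config.qtls_per_trait - n_shared, replace=False
            )
            target_sets[trait] = shared + [others[i] for i in extra_idx]
        else:
            idx = rng.choice(len(pool), size=config.qtls_per_trait, replace=False)
            target_sets[trait] = [pool[i] for i in idx]
    rows = []
    qtl_no = 0
    for trait in traits:
        for g in target_sets[trait]:
            qtl_no += 1
            span = g.span
            if rng.random() < config.fraction_qtl_inside:
                width = max(50, len(span) // 3)
                start = span.start + (len(span) - width) // 2
                end = start + width
            else:
                # downstream gap placement: the next gene is >= 2 kb away, so
                # the planted target stays the nearest gene
                d = int(rng.integers(50, 201))
                start, end = span.end + d, span.end + d + 100
            rows.append(
                {
                    "trait": trait,
                    "qtl_id": f"QTL{qtl_no:04d}",
                    "chrom": g.chrom,
                    "start": start,
                    "end": end,
                }
            )
        truth.trait_assoc[trait] = {g.gene_id for g in target_sets[trait]}
    return pd.DataFrame(rows)
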