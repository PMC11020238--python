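"""ORF finding, representative selection, and the biotype decision tree."""

import pandas as pd
import pytest

from txforge.biotype import (
    GeneBiotype,
    classify_gene,
    classify_lncrna_subtype,
    classify_transcript,
    find_orfs,
    flag_bifunctional_and_pat,
    flag_orphan_genes,
    select_representative_orf,
)
from txforge.core import GeneModel, HomologyTable, PeakSet, GenomicInterval
from .conftest import make_transcript

EMPTY_PEAKS = PeakSet("mirna", [])
NO_HOM = HomologyTable()


def hom_rows(rows):
    return HomologyTable(
        rows=pd.DataFrame(
            rows,
            columns=[
                "query_id",
                "subject_id",
                "evalue",
                "coverage_pct",
                "identity_pct",
                "search_kind",
            ],
        )
    )


def codons(n, codon="GCA"):
    return codon * n


class TestFindOrfs:
    def test_single_orf_with_stop(self):
        seq = "ATG" + codons(42) + "TAA"
        orfs = find_orfs(seq, "t")
        assert len(orfs) == 1
        assert orfs[0].length_aa == 43  # start codon + 42 codons
        assert orfs[0].stop_end == len(seq)

    def test_no_start_codon(self):
        assert find_orfs("CCACCACCACCA", "t") == []

    def test_stopless_orf_retained(self):
        orfs = find_orfs("ATG" + codons(10), "t")
        assert orfs[0].stop_end is None and orfs[0].length_aa == 11

    def test_alternative_starts_toggle(self):
        seq = "CTG" + codons(10) + "TAA"
        assert find_orfs(seq, "t", allow_alternative_starts=True)
        assert not find_orfs(seq, "t", allow_alternative_starts=False)

    def test_maximal_per_stop_segment(self):
        # nested ATG does not spawn a second ORF for the same stop
        seq = "ATG" + "GCA" + "ATG" + codons(3) + "TAA"
        assert len(find_orfs(seq, "t", allow_alternative_starts=False)) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("", "t")


class TestRepresentativeOrf:
    def setup_method(self):
        self.orfs = find_orfs(
            "ATG" + codons(100) + "TAA"  # frame 0: 101 aa
            + "ATG" + codons(60) + "TAA"  # 61 aa
            + "ATG" + codons(30) + "TAA",  # 31 aa
            "t",
        )

    def test_lowest_evalue_passing_hit_wins(self):
        mid = self.orfs[1]
        hom = hom_rows([[mid.orf_id, "P1", 1e-10, 80.0, 96.0, "protein"]])
        assert select_representative_orf(self.orfs, hom) is mid

    def test_below_coverage_hit_rejected(self):
        mid = self.orfs[1]
        hom = hom_rows([[mid.orf_id, "P1", 1e-10, 50.0, 96.0, "protein"]])
        assert select_representative_orf(self.orfs, hom) is self.orfs[0]

    def test_no_hits_longest_wins(self):
        assert select_representative_orf(self.orfs, NO_HOM) is self.orfs[0]

    def test_empty_orf_list(self):
        assert select_representative_orf([], NO_HOM) is None


def classify(seq, exons, strand="+", coding_genes=(), mirna=EMPTY_PEAKS, cpc2=False):
    t = make_transcript(exons=exons, strand=strand)
    orfs = find_orfs(seq, t.transcript_id)
    rep = select_representative_orf(orfs, NO_HOM)
    return classify_transcript(t, rep, cpc2, mirna, list(coding_genes))


class TestTranscriptClassification:
    def _orf_seq(self, utr3):
        return "CCA" * 20 + "ATG" + codons(59) + "TAA" + utr3

    def test_nmd_when_stop_far_upstream_of_last_junction(self):
        # stop_end at 243; last junction 60 nt further in spliced coordinates
        seq = self._orf_seq("CCA" * 40)
        call = classify(seq, ((0, 303), (400, 460)))
        assert call.label == "nmd"

    @pytest.mark.parametrize("d,label", [(50, "protein_coding"), (51, "nmd")])
    def test_fifty_nt_boundary_is_strict(self, d, label):
        seq = self._orf_seq("C" * 120)
        exons = ((0, 243 + d), (300 + d, 363 + d))
        assert classify(seq, exons).label == label

    @pytest.mark.parametrize("n_aa,expect", [(45, "protein_coding"), (44, "sncRNA")])
    def test_44_aa_boundary_is_strict(self, n_aa, expect):
        seq = "ATG" + codons(n_aa - 1) + "TAA"
        # pad to stay under 200 nt total for the noncoding fallback
        call = classify(seq, ((0, len(seq)),))
        assert call.label == expect

    def test_unspliced_orf_transcript_is_coding_never_nmd(self):
        seq = self._orf_seq("CCA" * 40)
        assert classify(seq, ((0, len(seq)),)).label == "protein_coding"

    def test_nsd_start_without_stop(self):
        seq = "CCA" * 10 + "ATG" + codons(80)
        assert classify(seq, ((0, 100), (200, len(seq) + 100))).label == "nsd"

    def test_short_noncoding_is_sncRNA(self):
        assert classify("CCA" * 50, ((0, 150),)).label == "sncRNA"

    def test_exactly_200_nt_goes_to_lncRNA(self):
        assert classify("CA" * 100, ((0, 200),)).label == "lncRNA_intergenic"

    def test_mirna_precursor_overlap_excluded_from_sncRNA(self):
        mirna = PeakSet("mirna", [GenomicInterval("chr1", 0, 50)])
        assert classify("CCA" * 50, ((0, 150),), mirna=mirna).label == "mirna_precursor"

    def test_cpc2_rescues_short_orf_only(self):
        seq = "ATG" + codons(10) + "TAA" + "CCA" * 60
        assert classify(seq, ((0, len(seq)),), cpc2=True).label == "protein_coding"
        assert classify(seq, ((0, len(seq)),), cpc2=False).label == "lncRNA_intergenic"


def coding_gene(gid="cg", strand="+", exons=((1000, 1500), (2000, 2500))):
    t = make_transcript(f"{gid}.t", gid, exons, strand=strand, biotype="protein_coding")
    return GeneModel(gene_id=gid, transcripts=[t], biotype="protein_coding")


class TestLncrnaSubtype:
    def test_antisense_beats_everything(self):
        t = make_transcript(exons=((1200, 1600),), strand="-")
        assert classify_lncrna_subtype(t, [coding_gene()]) == "lncRNA_antisense"

    def test_sense_intronic_inside_one_intron(self):
        t = make_transcript(exons=((1600, 1900),))
        assert classify_lncrna_subtype(t, [coding_gene()]) == "lncRNA_sense_intronic"

    def test_intragenic_exon_overlap(self):
        t = make_transcript(exons=((2400, 2800),))
        assert classify_lncrna_subtype(t, [coding_gene()]) == "lncRNA_intragenic"

    def test_intergenic_when_far(self):
        t = make_transcript(exons=((10_000, 10_400),))
        assert classify_lncrna_subtype(t, [coding_gene()]) == "lncRNA_intergenic"


class TestGeneClassification:
    def _gene(self, labels):
        ts = [make_transcript(f"t{i}", "g", ((i * 1000, i * 1000 + 100),)) for i in range(len(labels))]
        g = GeneModel(gene_id="g", transcripts=ts)
        calls = {
            t.transcript_id: type("B", (), {"label": lab})()
            for t, lab in zip(ts, labels)
        }
        return g, calls

    def test_any_coding_transcript_wins(self):
        g, calls = self._gene(["protein_coding", "nmd", "nmd", "nmd"])
        assert classify_gene(g, calls, NO_HOM).label == "protein_coding"

    def test_pseudogene_needs_hit_and_only_pats(self):
        g, calls = self._gene(["nmd", "nsd"])
        hit = hom_rows([["g", "NM1", 1e-20, 95.0, 97.0, "nucleotide"]])
        assert classify_gene(g, calls, hit).label == "pseudogene"
        assert classify_gene(g, calls, NO_HOM).label == "noncoding"

    def test_lncrna_only_gene_is_noncoding(self):
        g, calls = self._gene(["lncRNA_intergenic"])
        assert classify_gene(g, calls, NO_HOM).label == "noncoding"

    def test_unclassified_transcript_is_an_error(self):
        g, _ = self._gene(["nmd"])
        with pytest.raises(ValueError):
            classify_gene(g, {}, NO_HOM)


class TestBifunctionalAndPat:
    def test_flags(self):
        g, calls = (
            GeneModel(
                gene_id="g",
                transcripts=[
                    make_transcript("c1", "g", ((0, 100),)),
                    make_transcript("n1", "g", ((1000, 1100),)),
                ],
            ),
            {
                "c1": type("B", (), {"label": "protein_coding"})(),
                "n1": type("B", (), {"label": "nmd"})(),
            },
        )
        gb = {"g": GeneBiotype("g", "protein_coding", {})}
        flag_bifunctional_and_pat(
            [g],
            calls,
            {"liver": {"c1", "n1"}, "fetal": {"n1"}, "muscle": {"c1"}},
            gb,
        )
        out = gb["g"]
        # 1 coding + 1 PAT in liver: bifunctional, PAT fraction exactly 0.5
        assert out.bifunctional_per_tissue["liver"] is True
        assert out.pat_main_per_tissue["liver"] is False
        assert out.pat_main_per_tissue["fetal"] is True
        assert out.pat_gene is True
        # noncoding-only in fetal, coding in others -> switch gene
        assert out.switch_gene is True

    def test_no_noncoding_never_bifunctional(self):
        g = GeneModel(gene_id="g", transcripts=[make_transcript("c1", "g")])
        calls = {"c1": type("B", (), {"label": "protein_coding"})()}
        gb = {"g": GeneBiotype("g", "protein_coding", {})}
        flag_bifunctional_and_pat([g], calls, {"a": {"c1"}, "b": {"c1"}}, gb)
        assert not any(gb["g"].bifunctional_per_tissue.values())
        assert gb["g"].switch_gene is False


def test_orphan_flag_uses_both_search_kinds():
    g = coding_gene("g1")
    hom = hom_rows([["g1.t:0", "P", 1e-10, 80.0, 96.0, "protein"]])
    assert flag_orphan_genes([g], hom) == set()
    assert flag_orphan_genes([g], NO_HOM) == {"g1"}


def test_nmd_threshold_monotonic(sim):
    """Raising the NMD distance cutoff can only move labels nmd ->
    protein_coding, never the reverse."""
    from txforge.biotype import classify_transcript as ct

    cfg, genes, genome, truth = sim
    coding_genes = [g for g in genes if g.biotype == "protein_coding"]
    labels = {}
    for cut in (10, 50, 90, 200):
        for g in genes:
            for t in g.transcripts:
                orfs = find_orfs(genome.spliced_sequence(t), t.transcript_id)
                rep = select_representative_orf(orfs, NO_HOM)
                call = ct(t, rep, False, EMPTY_PEAKS, coding_genes, nmd_distance_nt=cut)
                prev = labels.get((t.transcript_id,))
                if prev is not None and prev != call.label:
                    assert (prev, call.label) == ("nmd", "protein_coding")
                labels[(t.transcript_id,)] = call.label
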