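"""Fuzzy structural equivalence, collapsing, gene grouping, reference
assignment, border extensions, and evidence windows."""

import networkx as nx
import pytest

from txforge.core import GeneModel, GenomicInterval, PeakSet
from txforge.structcmp import (
    BorderSupport,
    EquivalenceParams,
    assign_peaks_to_promoter,
    assign_to_annotated_genes,
    collapse_transcripts,
    detect_border_extensions,
    group_into_genes,
    transcripts_equivalent,
    validate_tss,
    validate_tts,
)
from .conftest import make_transcript

P = EquivalenceParams()


class TestEquivalence:
    def test_border_fuzz_without_support(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((80, 100), (200, 380)))
        assert transcripts_equivalent(a, b, P)

    def test_border_fuzz_exceeded(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((0, 100), (200, 401)))
        assert not transcripts_equivalent(a, b, P)

    def test_junction_fuzz_boundary(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b15 = make_transcript("b", exons=((0, 115), (215, 300)))
        b16 = make_transcript("c", exons=((0, 116), (216, 300)))
        assert transcripts_equivalent(a, b15, P)
        assert not transcripts_equivalent(a, b16, P)

    def test_different_junction_counts(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((0, 100), (200, 250), (260, 300)))
        assert not transcripts_equivalent(a, b, P)

    def test_supported_ends_need_shared_peak(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((10, 100), (200, 300)))
        shared = BorderSupport(tss_peaks=frozenset({1}))
        other = BorderSupport(tss_peaks=frozenset({2}))
        assert transcripts_equivalent(a, b, P, shared, shared)
        assert not transcripts_equivalent(a, b, P, shared, other)

    def test_symmetry(self):
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((5, 108), (208, 350)))
        assert transcripts_equivalent(a, b, P) == transcripts_equivalent(b, a, P)


def brute_force_classes(transcripts, params):
    """Independent oracle: connected components of the all-pairs
    equivalence graph."""
    g = nx.Graph()
    g.add_nodes_from(t.transcript_id for t in transcripts)
    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1 :]:
            if transcripts_equivalent(a, b, params):
                g.add_edge(a.transcript_id, b.transcript_id)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestCollapse:
    def test_three_tissue_duplicates_merge(self):
        sets = [
            (tis, [make_transcript(f"t_{tis}", exons=((0 + d, 100 + d), (200, 300 + d)), tissues=(tis,))])
            for tis, d in [("liver", 0), ("testis", 10), ("muscle", 20)]
        ]
        out = collapse_transcripts(sets)
        assert len(out) == 1
        assert out[0].source_tissues == {"liver", "testis", "muscle"}

    def test_extra_exon_stays_separate(self):
        sets = [
            ("a", [make_transcript("t1", exons=((0, 100), (200, 300)))]),
            ("b", [make_transcript("t2", exons=((0, 100), (150, 180), (200, 300)))]),
        ]
        assert len(collapse_transcripts(sets)) == 2

    def test_transitive_closure_chains(self):
        # a~b and b~c within fuzz, a vs c beyond it: one class of 3
        a = make_transcript("a", exons=((0, 100), (200, 300)))
        b = make_transcript("b", exons=((0, 110), (210, 300)))
        c = make_transcript("c", exons=((0, 120), (220, 300)))
        out = collapse_transcripts([("x", [a, b, c])])
        assert len(out) == 1
        assert not transcripts_equivalent(a, c, P)

    def test_matches_brute_force_on_random_set(self, rng):
        ts = []
        for i in range(120):
            locus = int(rng.integers(0, 8)) * 10_000
            jshift = int(rng.integers(0, 40))
            bshift = int(rng.integers(0, 150))
            ts.append(
                make_transcript(
                    f"t{i:03d}",
                    exons=(
                        (locus + bshift, locus + 1000 + jshift),
                        (locus + 2000 + jshift, locus + 3000 + bshift),
                    ),
                )
            )
        out = collapse_transcripts([("x", ts)])
        oracle = brute_force_classes(ts, P)
        assert len(out) == len(oracle)

    def test_idempotent(self, rng):
        ts = [
            make_transcript(f"t{i}", exons=((i * 7, 1000 + i * 7), (2000, 3000 + i * 3)))
            for i in range(20)
        ]
        once = collapse_transcripts([("x", ts)])
        twice = collapse_transcripts([("y", once)])
        assert [(t.exons, t.source_tissues) for t in twice] == [
            (t.exons, t.source_tissues) for t in once
        ]

    def test_input_order_invariance(self):
        ts = [
            make_transcript(f"t{i}", exons=((i * 5, 1000), (2000, 3000 + i * 5)))
            for i in range(10)
        ]
        a = collapse_transcripts([("x", ts)])
        b = collapse_transcripts([("x", ts[::-1])])
        assert [t.transcript_id for t in a] == [t.transcript_id for t in b]


class TestGeneGrouping:
    def test_one_nt_overlap_single_gene(self):
        a = make_transcript("a", exons=((0, 100),))
        b = make_transcript("b", exons=((99, 200),))
        assert len(group_into_genes([a, b])) == 1

    def test_opposite_strands_stay_apart(self):
        a = make_transcript("a", exons=((0, 100),), strand="+")
        b = make_transcript("b", exons=((0, 100),), strand="-")
        assert len(group_into_genes([a, b])) == 2

    def test_chained_overlap_matches_component_oracle(self, rng):
        ts = [
            make_transcript(f"t{i}", exons=((start, start + 150),))
            for i, start in enumerate(rng.integers(0, 3000, size=40))
        ]
        genes = group_into_genes(ts)
        g = nx.Graph()
        g.add_nodes_from(t.transcript_id for t in ts)
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                if a.span.overlaps(b.span, stranded=True):
                    g.add_edge(a.transcript_id, b.transcript_id)
        assert len(genes) == nx.number_connected_components(g)


class TestAnnotatedAssignment:
    def ref(self):
        t = make_transcript("r1", "ref1", ((1000, 1500), (2000, 2500)))
        return GeneModel(gene_id="ref1", transcripts=[t])

    def _pred(self, exons, strand="+"):
        t = make_transcript("p1", "pred1", exons, strand=strand)
        return GeneModel(gene_id="pred1", transcripts=[t])

    def test_one_nt_exon_overlap_assigns(self):
        assign = assign_to_annotated_genes([self._pred(((1499, 1600),))], [self.ref()])
        assert assign["pred1"][0][0] == "ref1"

    def test_intron_only_overlap_unassigned(self):
        assert assign_to_annotated_genes([self._pred(((1600, 1900),))], [self.ref()]) == {
            "pred1": []
        }

    def test_opposite_strand_unassigned(self):
        assign = assign_to_annotated_genes(
            [self._pred(((1400, 1600),), strand="-")], [self.ref()]
        )
        assert assign["pred1"] == []


class TestBorderExtensions:
    def _setup(self, strand):
        pred = GeneModel(
            gene_id="p", transcripts=[make_transcript("pt", "p", ((900, 5200),), strand=strand)]
        )
        ref = GeneModel(
            gene_id="r", transcripts=[make_transcript("rt", "r", ((1000, 5000),), strand=strand)]
        )
        return pred, ref

    def test_plus_strand_arithmetic(self):
        pred, ref = self._setup("+")
        (ext,) = detect_border_extensions([pred], [ref], {"p": [("r", 100)]})
        assert (ext.kind, ext.ext5_nt, ext.ext3_nt) == ("both", 100, 200)

    def test_minus_strand_swaps_ends(self):
        pred, ref = self._setup("-")
        (ext,) = detect_border_extensions([pred], [ref], {"p": [("r", 100)]})
        assert (ext.ext5_nt, ext.ext3_nt) == (200, 100)

    def test_contained_prediction_yields_nothing(self):
        pred = GeneModel(
            gene_id="p", transcripts=[make_transcript("pt", "p", ((1100, 4900),))]
        )
        _, ref = self._setup("+")
        assert detect_border_extensions([pred], [ref], {"p": [("r", 100)]}) == []


class TestEvidenceWindows:
    def _feat(self, tss, strand="+"):
        if strand == "+":
            return make_transcript("f", exons=((tss, tss + 2000),), strand=strand)
        return make_transcript("f", exons=((tss - 1999, tss + 1),), strand=strand)

    def test_promoter_window_plus(self):
        f = self._feat(10_000)
        inside = PeakSet("ATAC", [GenomicInterval("chr1", 9_600, 9_650)])
        outside = PeakSet("ATAC", [GenomicInterval("chr1", 9_400, 9_450)])
        assert assign_peaks_to_promoter([f], inside)["f"]
        assert not assign_peaks_to_promoter([f], outside)["f"]

    def test_promoter_window_minus(self):
        f = self._feat(10_000, strand="-")
        peaks = PeakSet("ATAC", [GenomicInterval("chr1", 10_300, 10_400)])
        assert assign_peaks_to_promoter([f], peaks)["f"]

    def test_tss_window(self):
        f = self._feat(1000)
        assert validate_tss([f], PeakSet("R", [GenomicInterval("chr1", 995, 1005)]))["f"]
        assert not validate_tss([f], PeakSet("R", [GenomicInterval("chr1", 940, 950)]))["f"]

    def test_tss_window_truncates_at_zero(self):
        f = self._feat(10)
        assert validate_tss([f], PeakSet("R", [GenomicInterval("chr1", 0, 5)]))["f"]

    def test_tts_window(self):
        f = self._feat(1000)  # tts at 2999
        assert validate_tts([f], PeakSet("W", [GenomicInterval("chr1", 3004, 3010)]))["f"]
        assert not validate_tts([f], PeakSet("W", [GenomicInterval("chr1", 3200, 3300)]))["f"]

    def test_minus_strand_mirror_symmetry(self):
        """Mirroring feature and peak coordinates gives the same verdict."""
        L = 100_000
        f_plus = self._feat(1000)
        for peak_start in (960, 970, 1009, 1010, 900):
            peak_plus = PeakSet("R", [GenomicInterval("chr1", peak_start, peak_start + 1)])
            got_plus = validate_tss([f_plus], peak_plus)["f"]
            # mirror: position x -> L-1-x
            tss_m = L - 1 - 1000
            f_minus = make_transcript(
                "f", exons=((tss_m - 1999, tss_m + 1),), strand="-"
            )
            peak_minus = PeakSet(
                "R", [GenomicInterval("chr1", L - 1 - peak_start, L - peak_start)]
            )
            assert validate_tss([f_minus], peak_minus)["f"] == got_plus
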