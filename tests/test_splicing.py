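"""Alternative-splicing event enumeration against canonical cases and an
independent exhaustive oracle."""

import numpy as np

from txforge.core import GeneModel
from txforge.splicing import detect_use, enumerate_events, summarize_as
from .conftest import make_transcript


def gene(*exon_sets, strand="+", gid="g"):
    ts = [
        make_transcript(f"{gid}.{i}", gid, exons, strand=strand)
        for i, exons in enumerate(exon_sets)
    ]
    return GeneModel(gene_id=gid, transcripts=ts)


def counts(events):
    out = {}
    for e in events:
        out[e.event_type] = out.get(e.event_type, 0) + 1
    return out


class TestCanonicalEvents:
    def test_skipped_exon(self):
        g = gene(
            ((0, 100), (200, 300), (400, 500)),
            ((0, 100), (400, 500)),
        )
        assert counts(enumerate_events(g)) == {"SE": 1}

    def test_retained_intron(self):
        g = gene(
            ((0, 100), (200, 300)),
            ((0, 300),),
        )
        assert counts(enumerate_events(g)) == {"RI": 1}

    def test_alternative_five_prime_on_plus(self):
        # shared acceptor at 200, donors differ by 12 nt
        g = gene(
            ((0, 100), (200, 300)),
            ((0, 112), (200, 300)),
        )
        assert counts(enumerate_events(g)) == {"A5": 1}

    def test_alternative_three_prime_on_plus(self):
        g = gene(
            ((0, 100), (200, 300)),
            ((0, 100), (212, 300)),
        )
        assert counts(enumerate_events(g)) == {"A3": 1}

    def test_mutually_exclusive_exons(self):
        g = gene(
            ((0, 100), (200, 250), (400, 500)),
            ((0, 100), (300, 350), (400, 500)),
        )
        assert counts(enumerate_events(g)) == {"MX": 1}

    def test_alternative_first_and_last(self):
        g = gene(
            ((0, 50), (200, 300), (400, 450)),
            ((100, 150), (200, 300), (500, 550)),
        )
        assert counts(enumerate_events(g)) == {"AF": 1, "AL": 1}

    def test_single_transcript_gene_empty(self):
        assert enumerate_events(gene(((0, 100), (200, 300)))) == []

    def test_unspliced_gene_no_events(self):
        assert enumerate_events(gene(((0, 300),), ((0, 300),))) == []


class TestUse:
    def test_overlapping_exons_without_shared_junction(self):
        g = gene(
            ((0, 50), (100, 200), (300, 350)),
            ((0, 50), (150, 250), (300, 350)),
        )
        use = detect_use(g)
        assert len(use) == 1
        assert use[0].defining_coordinates == ((100, 200), (150, 250))

    def test_shared_upstream_junction_not_use(self):
        g = gene(
            ((0, 50), (100, 200), (300, 350)),
            ((0, 50), (100, 250), (300, 350)),
        )
        assert detect_use(g) == []

    def test_non_overlapping_exons_not_use(self):
        g = gene(
            ((0, 50), (100, 140), (300, 350)),
            ((0, 50), (150, 250), (300, 350)),
        )
        assert detect_use(g) == []

    def test_terminal_exons_excluded_by_default(self):
        g = gene(
            ((0, 100), (200, 300)),
            ((50, 150), (200, 300)),
        )
        assert detect_use(g) == []
        assert detect_use(g, internal_only=False)


def mirror_gene(g):
    """Same genomic structures on the opposite strand."""
    flipped = []
    for t in g.transcripts:
        flipped.append(
            make_transcript(
                t.transcript_id,
                g.gene_id,
                tuple((e.start, e.end) for e in t.exons),
                strand="-" if g.strand == "+" else "+",
            )
        )
    return GeneModel(gene_id=g.gene_id, transcripts=flipped)


def random_gene(rng, gid="g", max_transcripts=4):
    """Random multi-isoform gene over a 6-slot exon grid with boundary
    jitter, adjacent-slot merging and slot skipping."""
    n_t = int(rng.integers(2, max_transcripts + 1))
    ts = []
    for i in range(n_t):
        n_slots = 6
        chosen = sorted(
            rng.choice(n_slots, size=int(rng.integers(2, 5)), replace=False)
        )
        exons = []
        run = [chosen[0]]
        for s in chosen[1:]:
            if s == run[-1] + 1 and rng.random() < 0.3:
                run.append(s)  # merge adjacent slots: retained intron
            else:
                exons.append(run)
                run = [s]
        exons.append(run)
        coords = []
        for slots in exons:
            start = slots[0] * 200 + int(rng.integers(0, 30))
            end = slots[-1] * 200 + 100 + int(rng.integers(0, 30))
            coords.append((start, end))
        ts.append(make_transcript(f"{gid}.{i}", gid, tuple(coords)))
    return GeneModel(gene_id=gid, transcripts=ts)


def oracle_events(g):
    """Independent exhaustive scan: re-derives every event type from first
    principles over all transcript pairs, keyed like the implementation."""
    found = set()
    strand = g.strand
    for a in g.transcripts:
        for b in g.transcripts:
            if a is b:
                continue
            ja, jb = list(a.junctions), list(b.junctions)
            # skipped exon
            for i in range(1, len(a.exons) - 1):
                up, dn = ja[i - 1], ja[i]
                if (up[0], dn[1]) in jb and up not in jb and dn not in jb:
                    e = a.exons[i]
                    found.add(("SE", (up, (e.start, e.end), dn)))
            # retained intron
            for i, intr in enumerate(a.junctions):
                s, e = a.exons[i].start, a.exons[i + 1].end
                for eb in b.exons:
                    if (eb.start, eb.end) == (s, e):
                        found.add(("RI", ((s, intr[0]), intr, (intr[1], e))))
            # alternative donors / acceptors: variant site within
            # overlapping flanking exons
            for i, pa in enumerate(ja):
                for j, pb in enumerate(jb):
                    if pa == pb:
                        continue
                    if pa[1] == pb[1] and pa[0] != pb[0] and a.exons[i].overlaps(
                        b.exons[j]
                    ):
                        kind = "A5" if strand == "+" else "A3"
                        found.add((kind, tuple(sorted([pa, pb]))))
                    if pa[0] == pb[0] and pa[1] != pb[1] and a.exons[i + 1].overlaps(
                        b.exons[j + 1]
                    ):
                        kind = "A3" if strand == "+" else "A5"
                        found.add((kind, tuple(sorted([pa, pb]))))
            # mutually exclusive exons
            for i in range(1, len(a.exons) - 1):
                for j in range(1, len(b.exons) - 1):
                    ea, eb = a.exons[i], b.exons[j]
                    if ea.overlaps(eb):
                        continue
                    if ja[i - 1][0] != jb[j - 1][0] or ja[i][1] != jb[j][1]:
                        continue
                    if any(x.overlaps(ea) for x in b.exons):
                        continue
                    if any(x.overlaps(eb) for x in a.exons):
                        continue
                    found.add(
                        ("MX", tuple(sorted([(ea.start, ea.end), (eb.start, eb.end)])))
                    )
            # alternative first / last
            if ja and jb:
                fa, fb = a.exons[0], b.exons[0]
                if not fa.overlaps(fb) and ja[0][1] == jb[0][1]:
                    kind = "AF" if strand == "+" else "AL"
                    found.add(
                        (kind, tuple(sorted([(fa.start, fa.end), (fb.start, fb.end)])))
                    )
                la, lb = a.exons[-1], b.exons[-1]
                if not la.overlaps(lb) and ja[-1][0] == jb[-1][0]:
                    kind = "AL" if strand == "+" else "AF"
                    found.add(
                        (kind, tuple(sorted([(la.start, la.end), (lb.start, lb.end)])))
                    )
    # unique splice site exons
    for ai, a in enumerate(g.transcripts):
        for b in g.transcripts[ai + 1 :]:
            for ea in a.exons[1:-1]:
                for eb in b.exons[1:-1]:
                    if not ea.overlaps(eb):
                        continue
                    if {ea.start, ea.end} & {eb.start, eb.end}:
                        continue
                    found.add(
                        ("USE", tuple(sorted([(ea.start, ea.end), (eb.start, eb.end)])))
                    )
    return found


class TestProperties:
    def test_transcript_order_invariance(self, rng):
        g = random_gene(np.random.default_rng(5))
        g_rev = GeneModel(gene_id="g", transcripts=g.transcripts[::-1])
        assert {e.key for e in enumerate_events(g)} == {
            e.key for e in enumerate_events(g_rev)
        }

    def test_strand_flip_swaps_directional_types(self, rng):
        for seed in range(20):
            g = random_gene(np.random.default_rng(seed))
            fwd = counts(enumerate_events(g))
            rev = counts(enumerate_events(mirror_gene(g)))
            assert fwd.get("A5", 0) == rev.get("A3", 0)
            assert fwd.get("A3", 0) == rev.get("A5", 0)
            assert fwd.get("AF", 0) == rev.get("AL", 0)
            assert fwd.get("AL", 0) == rev.get("AF", 0)
            for sym in ("SE", "RI", "MX", "USE"):
                assert fwd.get(sym, 0) == rev.get(sym, 0)

    def test_matches_exhaustive_oracle(self):
        for seed in range(40):
            g = random_gene(np.random.default_rng(100 + seed))
            got = {e.key for e in enumerate_events(g)}
            assert got == oracle_events(g), f"seed {seed}"


def test_summary_counts_and_involvement():
    g1 = gene(
        ((0, 100), (200, 300), (400, 500)),
        ((0, 100), (400, 500)),
        gid="g1",
    )
    g2 = gene(((0, 300),), gid="g2")
    summary = summarize_as([g1, g2])
    assert summary.loc["g1", "n_events"] == 1
    assert summary.loc["g2", "n_events"] == 0
    assert summary.attrs["involved_transcripts"] == {"g1.0", "g1.1"}
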