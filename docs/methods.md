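# Methods

txforge reimplements, as a tested library, the bespoke computations of a
multi-tissue transcriptome-annotation study design: transcript QC and
collapsing, an ORF-based biotype decision tree, evidence-window border
validation, tissue-specificity scoring, alternative-splicing enumeration,
and QTL-integration statistics. This note records the models, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic data do and do not demonstrate.

## Coordinates and containers

All internal coordinates are 0-based half-open on the forward reference
strand; GTF I/O converts to/from 1-based inclusive at the file boundary and
BED is native. Transcripts must be stranded (every window rule is
strand-aware); only evidence peaks may be unstranded. Strand-oriented
windows covering `up` bases 5' and `down` bases 3' of an anchor base are
`[anchor-up, anchor+down)` on `+` and the exact reflection
`[anchor-down+1, anchor+up+1)` on `-`; windows truncate at contig bounds.
The exact mirror makes strand-symmetry properties hold to the base, which
is what the test suite checks.

## QC filters

* **Coverage**: a transcript is kept only if its minimum per-base coverage
  is >= 3x (inclusive) in every tissue it was assembled in. The aggregation
  (minimum over bases) is the strictest reading of "3 times base coverage";
  the threshold is a parameter.
* **Junctions**: every intron must carry a canonical donor/acceptor pair on
  the transcript strand — {GT..AG, GC..AG, AT..AC}, configurable — and at
  least one spanning read with a 5-nt overhang on both sides in some
  assembled tissue. Support is consumed as a table whose documented
  overhang must meet the requested one; computing support from alignments
  is out of scope.
* **Pre-mRNA**: a spliced transcript whose junction chain is a subset of a
  same-strand reference transcript's chain, while fully containing at least
  one reference intron inside an exon, is flagged as readthrough pre-mRNA.
* **Genomic poly(A)**: an unspliced transcript is flagged when the 30-bp
  strand-oriented window immediately 3' of its terminal site contains a run
  of >= 20 bases with at most 1 non-A, the run starting and ending with A
  (internal-priming artifact). The mismatch may not be terminal — a
  deliberate resolution of an ambiguous rule.
* **Locus rules**: unspliced transcripts expressed in exactly one tissue
  are dropped; single-exon genes whose promoter (500 bp 5' to 100 bp 3' of
  the start site) holds no H3K4me3/H3K4me1/H3K27ac/ATAC peak are dropped
  with all their transcripts. CTCF peaks deliberately do not rescue.

## Biotype decision tree

ORFs are enumerated in the three sense frames with the vertebrate
alternative initiation codons {ATG, CTG, GTG, TTG} (configurable to ATG
only); per (frame, stop) segment the maximal ORF opens at the earliest
start, and stopless frames are kept because they define nonstop decay. The
representative ORF is, among the longest three, the one whose best
protein-database hit passes E <= 1e-6, coverage >= 60%, identity >= 95%
with the lowest E-value; otherwise the longest ORF.

Decision order per transcript: (1) representative ORF with a stop and
strictly more than 44 aa -> NMD if the stop lies strictly more than 50 nt
upstream of the final exon-exon junction, else protein-coding; (2) start
but no stop -> NSD; (3) otherwise noncoding: < 200 nt and clear of miRNA
precursors -> sncRNA; >= 200 nt -> lncRNA. The NMD distance is measured in
spliced (mRNA) coordinates, matching the mechanistic 50-nt rule for exon
junction complexes; a transcript of exactly 200 nt goes to the lncRNA
branch; the coding-potential (CPC2-style) flag is consulted only for ORFs
of <= 44 aa. Short noncoding transcripts overlapping a miRNA precursor
receive the explicit label `mirna_precursor` so classification remains a
total function (they belong to a miRNA pipeline, not to the sncRNA class).

lncRNA subtypes use the precedence antisense > sense-intronic > intragenic
> intergenic, needed because the four positional definitions are not
mutually exclusive; the order is configurable. Gene labels: protein-coding
if any transcript is; pseudogene if the locus has a passing nucleotide
homology hit (E <= 1e-6, coverage >= 90%, identity >= 95%) but transcribes
only NMD/NSD isoforms; else noncoding. Bifunctional (per tissue), PAT
(>= 1 NMD/NSD isoform), PAT-main (> 50%, strict) and coding/noncoding
switch flags are derived from per-tissue expressed transcript sets.

## Structural comparison and collapsing

Two same-strand transcripts are structurally equivalent when their
junction chains have equal length with every boundary within 15 nt, and
their borders agree: an end supported by RAMPAGE (5') or WTTS (3')
evidence on both transcripts must share a supporting peak; otherwise the
end may differ by up to 100 nt. Fuzzy equivalence is not transitive, so
collapsing takes the transitive closure (union-find); the representative
of each class is the member with the longest genomic span (ties broken by
transcript id) carrying the union of member tissues, and output is
canonically sorted, making the operation order-invariant and idempotent.

Gene grouping is single-linkage clustering of same-strand transcripts with
>= 1 nt span overlap (exon-level overlap available as an option).
Predicted genes map to reference genes by same-strand exon-vs-exon overlap
(>= 1 nt), the largest-overlap reference being primary; gene-border
extensions are strand-aware span differences against the primary
reference, using gene spans. A 5' extension is "validated" when the
predicted start carries a RAMPAGE peak in the 30-bp-5'/10-bp-3' window;
3' extensions symmetrically via WTTS reads in the 10-bp-5'/165-bp-3'
window.

## Expression and tissue specificity

RPKM = count / (length_kb * library_size_millions). A transcript is
"expressed" in a tissue iff it was assembled there, or its RPKM is
strictly > 1 with all junctions quantified there; a gene is expressed
wherever any of its transcripts is. The Tissue Specificity Index over N
tissues is

    TSI = sum_{i=1..N} (1 - x_i) / (N - 1),   x_i = v_i / max(v)

0 for uniform (housekeeping) profiles, 1 for single-tissue expression;
undefined (None) for all-zero vectors. Classes: expressed in exactly one
tissue -> tissue-specific; >= 2 tissues with TSI strictly > 0.9 ->
expressed in a tissue-specific manner; else broad. Tissue sharing uses
100 * |A∩B| / min(|A|,|B|) (Jaccard available), complete-linkage
clustering on 100 - sharing, and dendrograms compare via the Spearman
correlation of cophenetic distances; degenerate constant-distance trees
compare as 1 when equal.

## Alternative splicing

Events are local (SUPPA-style) over isoform pairs within a gene,
deduplicated per gene by (type, defining coordinates): skipped exon,
retained intron, alternative 5'/3' splice sites, mutually exclusive exons,
alternative first/last exons, and the unique-splice-site exon (USE): two
overlapping exons from different isoforms sharing neither flanking splice
site, restricted to internal exons by default because transcript termini
are not splice junctions. A5/A3 additionally require the variant site to
lie within overlapping flanking exons — without this restriction every
skipped exon would also register spurious alternative sites. A5<->A3 and
AF<->AL swap under strand reversal; SE/RI/MX/USE are strand-symmetric.

## QTL statistics

A trait's QTL-associated genes are the closest expressed genes to its QTL
intervals (distance 0 on overlap, else boundary gap, ties to the smaller
gene id). Set enrichment uses the right-sided Fisher exact test
(hypergeometric upper tail) with Benjamini-Hochberg correction at 0.05.
Trait A is similar to trait B when the observed overlap of associated gene
sets beats 1,000 null overlaps of random size-|B| gene sets drawn without
replacement from the expressed-gene universe; the overlap of such a draw
is exactly Hypergeometric(N, |A|, |B|), so the null is sampled as
hypergeometric variates (identical distribution, far cheaper than
materializing gene sets — a seeded test confirms the agreement). The
add-one estimator p = (1 + #{null >= obs}) / (n_perm + 1) bounds p in
[1/(n_perm+1), 1]. Both directions are tested; BH is applied globally
across directional tests (per-trait families available), and an edge is
reported when either direction is significant.

Note an interaction between the p floor and global BH: with n_perm = 1000
and 20 traits (380 directional tests), at least 8 tests must sit at the
floor before any can pass BH at 0.05, so a well-posed planted-similarity
experiment plants at least 4 similar pairs. The calibration tests plant 4
pairs at 80% gene-set overlap.

The tissue-axis correlation test takes matched-sample expression of a
source gene set and a target gene set in two tissues, computes all
pairwise Spearman correlations (rank-transforming once and using matrix
products), compares them against 1,000 random draws of |target| genes from
a candidate pool with a right-sided two-sample t-test per draw, and
reports the BH-adjusted p-value distribution with the fraction < 0.05 as
the headline scalar.

## Synthetic data: what it emulates

The generator plants ground truth for every stage. Sequence design is
rule-targeted, not realistic: coding bodies use T-free codons (no start or
stop codon can occur in any frame), noncoding regions avoid the TG
dinucleotide (removing all four initiation codons), introns carry GT..AG
ends, and poly(A) artifacts write literal A-stretches downstream of the
terminal site while clean single-exon loci get an A-poor downstream
window. lncRNA subtypes are planted positionally: antisense and
sense-intronic guests inside a lengthened host intron, intragenic isoforms
either skipping the host's CDS exon or overlapping its 3' UTR, intergenic
loci in inter-gene gaps. Expression targets are log-normal around high
(20 RPKM) and low (0.02 RPKM) levels with Poisson counts (both noise
sources can be switched off, which makes the analytic TSI limits exact on
generated data); per-tissue assembly copies jitter junctions and
unsupported borders by a common non-negative offset so the within-group
pairwise discrepancy equals the configured jitter — this is what makes the
15-nt/100-nt collapse thresholds sharp rather than probabilistic.

Default problem sizes are desk-scale by design: 100 genes, 12 tissues, 20
traits with 5 QTLs each, 1,000 permutations, gaps of ~2.5 kb on a single
chromosome. Passing tests on these data show rule-correctness
(each planted case satisfies exactly one rule), not robustness to real
data's ambiguities: overlapping gene models, non-canonical splicing,
degraded 3' ends, mosaic coverage, or reference/assembly naming mismatches
(identical chromosome names are required throughout). Homology,
coding-potential and signal-peptide inputs are consumed as tables; the
search engines themselves are out of scope.

## Known limitations

* The pre-mRNA rule needs reference isoforms; unannotated readthrough is
  not caught.
* Border-extension detection uses gene spans, not per-transcript UTRs, and
  reports no extension when the primary reference already covers the
  prediction.
* The USE definition compares only the two exons' own flanking splice
  sites (the minimal reading); a stricter variant would compare full
  junction sets.
* `nearest_expressed_gene` is exact but linear per chromosome; adequate at
  the intended scales.
* Permutation universes are genome-wide; per-chromosome nulls are a
  configuration away but untested against data.
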