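"""QTL-to-gene assignment, enrichment, the permutation trait-similarity
network, and the cross-tissue axis correlation test.

A trait's QTL-associated genes are the closest expressed genes to its QTL
intervals (distance 0 when the QTL overlaps a gene span).  Trait A is
"similar" to trait B when the overlap between their associated gene sets
exceeds what random gene sets of the same size achieve: the null overlap of
a size-|B| set drawn without replacement from the expressed-gene universe
with a fixed set A is Hypergeometric(N, |A|, |B|), and the permutation
p-value uses the add-one estimator (1 + #{null >= obs}) / (n_perm + 1).
Both directions are tested and Benjamini-Hochberg correction is applied
globally across directional tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval

log = logging.getLogger(__name__)


def nearest_expressed_gene(
    qtl: GenomicInterval, expressed_genes: Sequence[GeneModel]
) -> tuple[str, int] | None:
    """Closest expressed gene to a QTL interval, any strand.

    Distance is 0 when the QTL overlaps a gene span, else the gap between
    the nearest interval boundaries; ties break to the smaller gene_id.
    Returns None when no gene shares the QTL's chromosome.
    """
    best: tuple[int, str] | None = None
    for g in expressed_genes:
        if g.chrom != qtl.chrom:
            continue
        span = g.span
        if qtl.start < span.end and span.start < qtl.end:
            d = 0
        elif span.end <= qtl.start:
            d = qtl.start - span.end
        else:
            d = span.start - qtl.end
        cand = (d, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        log.warning("no expressed gene on chromosome %s", qtl.chrom)
        return None
    return best[1], best[0]


def trait_associated_genes(
    qtl_table: pd.DataFrame, expressed_genes: Sequence[GeneModel]
) -> dict[str, set[str]]:
    """trait -> set of QTL-associated (closest expressed) genes.

    ``qtl_table`` columns: trait, qtl_id, chrom, start, end (internal
    0-based half-open).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in expressed_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, set[str]] = {}
    for row in qtl_table.itertuples():
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), ".")
        hit = nearest_expressed_gene(iv, by_chrom.get(row.chrom, []))
        out.setdefault(row.trait, set())
        if hit is not None:
            out[row.trait].add(hit[0])
    return out


def fisher_right_p(overlap: int, set_size: int, trait_size: int, universe: int) -> float:
    """Right-sided Fisher exact p for a 2x2 overlap table (hypergeometric
    upper tail)."""
    table = [
        [overlap, set_size - overlap],
        [trait_size - overlap, universe - set_size - trait_size + overlap],
    ]
    if min(min(r) for r in table) < 0:
        raise ValueError("inconsistent 2x2 table")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def qtl_enrichment(
    gene_set: set[str],
    trait_assoc: Mapping[str, set[str]],
    expressed_universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait right-sided Fisher test of gene_set against each trait's
    QTL-associated genes, BH-corrected across traits."""
    if not expressed_universe:
        raise ValueError("empty universe")
    if not gene_set <= expressed_universe:
        raise ValueError("gene_set must be a subset of the universe")
    traits = sorted(trait_assoc)
    pvals = []
    rows = []
    for trait in traits:
        assoc = trait_assoc[trait] & expressed_universe
        k = len(gene_set & assoc)
        p = fisher_right_p(k, len(gene_set), len(assoc), len(expressed_universe))
        pvals.append(p)
        rows.append({"trait": trait, "overlap": k, "n_trait_genes": len(assoc), "p": p})
    if rows:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for row, a in zip(rows, adj):
            row["adj_p"] = float(a)
            row["enriched"] = a < alpha
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TraitSimilarityEdge:
    trait_a: str
    trait_b: str
    observed_overlap: int
    perm_p: float
    adj_p: float = float("nan")


def _null_overlaps(
    n_a: int, n_b: int, universe: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    # overlap of a uniform random size-n_b subset with a fixed size-n_a set
    return rng.hypergeometric(ngood=n_a, nbad=universe - n_a, nsample=n_b, size=n_perm)


def trait_similarity(
    trait_a: str,
    trait_b: str,
    assoc: Mapping[str, set[str]],
    universe: set[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TraitSimilarityEdge:
    """Directional permutation test of trait A's similarity to trait B."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes_a, genes_b = assoc[trait_a], assoc[trait_b]
    if not genes_a or not genes_b:
        raise ValueError("both traits need >=1 associated gene")
    if len(genes_b) > len(universe):
        raise ValueError("trait gene set larger than universe")
    observed = len(genes_a & genes_b)
    null = _null_overlaps(len(genes_a), len(genes_b), len(universe), n_perm, rng)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return TraitSimilarityEdge(trait_a, trait_b, observed, p)


def build_trait_network(
    assoc: Mapping[str, set[str]],
    universe: set[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """All ordered trait pairs tested; BH applied globally over directional
    tests; the returned frame keeps every directional test with its adjusted
    p and a ``significant`` flag (adj_p < alpha)."""
    rng = np.random.default_rng(seed)
    traits = sorted(t for t in assoc if assoc[t])
    edges: list[TraitSimilarityEdge] = []
    for a in traits:
        for b in traits:
            if a != b:
                edges.append(trait_similarity(a, b, assoc, universe, n_perm, rng))
    if not edges:
        return pd.DataFrame(
            columns=["trait_a", "trait_b", "observed_overlap", "perm_p", "adj_p", "significant"]
        )
    adj = multipletests([e.perm_p for e in edges], method="fdr_bh")[1]
    return pd.DataFrame(
        [
            {
                "trait_a": e.trait_a,
                "trait_b": e.trait_b,
                "observed_overlap": e.observed_overlap,
                "perm_p": e.perm_p,
                "adj_p": float(a),
                "significant": bool(a < alpha),
            }
            for e, a in zip(edges, adj)
        ]
    )


def significant_pairs(network: pd.DataFrame) -> tuple[int, int]:
    """(# significant directional tests, # distinct unordered trait pairs)."""
    sig = network[network["significant"]]
    directional = len(sig)
    unordered = len({frozenset((r.trait_a, r.trait_b)) for r in sig.itertuples()})
    return directional, unordered


def _rank_standardize(x: np.ndarray) -> np.ndarray:
    """Row-wise rank transform, centered and scaled; Spearman correlation
    becomes a plain dot product / (n-1) between transformed rows."""
    ranks = stats.rankdata(x, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return ranks / norm


def _cross_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All pairwise Spearman correlations between rows of a and rows of b
    (matched sample columns)."""
    return _rank_standardize(a) @ _rank_standardize(b).T


def axis_correlation_test(
    expr_source: np.ndarray,
    expr_target: np.ndarray,
    expr_pool: np.ndarray,
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Expression-similarity significance between two tissues' QTL gene sets.

    ``expr_source`` (source-tissue genes x samples) and ``expr_target``
    (target-tissue genes x samples) hold the matched-animal expression of the
    two QTL-associated sets; ``expr_pool`` is the pool of candidate target
    genes for the random draws.  Reference statistic: all pairwise Spearman
    correlations between source and target genes.  Each of ``n_random`` draws
    of |target| pool genes yields a random correlation set compared to the
    reference with a right-sided two-sample t-test; the BH-adjusted p-value
    distribution is the significance summary.
    """
    expr_source = np.asarray(expr_source, float)
    expr_target = np.asarray(expr_target, float)
    expr_pool = np.asarray(expr_pool, float)
    n_samples = expr_source.shape[1]
    if expr_target.shape[1] != n_samples or expr_pool.shape[1] != n_samples:
        raise ValueError("sample columns must match across tissues")
    if n_samples < 3:
        raise ValueError("need >=3 matched samples for rank correlation")
    reference = _cross_spearman(expr_source, expr_target).ravel()
    result = {"reference_correlations": reference}
    if n_random == 0:
        return result
    rng = np.random.default_rng(seed)
    n_target = expr_target.shape[0]
    if n_target > expr_pool.shape[0]:
        raise ValueError("target set larger than candidate pool")
    src_ranked = _rank_standardize(expr_source)
    pool_ranked = _rank_standardize(expr_pool)
    pvals = np.empty(n_random)
    for i in range(n_random):
        pick = rng.choice(expr_pool.shape[0], size=n_target, replace=False)
        random_corr = (src_ranked @ pool_ranked[pick].T).ravel()
        pvals[i] = stats.ttest_ind(reference, random_corr, alternative="greater")[1]
    adj = multipletests(pvals, method="fdr_bh")[1]
    result.update(
        {
            "p_values": pvals,
            "adj_p_values": adj,
            "fraction_significant": float((adj < 0.05).mean()),
        }
    )
    return result
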