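"""Expression normalization, tissue-expression marking, tissue specificity,
and tissue-sharing dendrograms.

A transcript counts as "expressed" in a tissue if it was either assembled
there from reads, or quantified there above 1 RPKM with every splice
junction quantified — the two-clause definition guards against the high
false-negative rate of per-tissue assembly.  The Tissue Specificity Index
(TSI) of an expression vector over N tissues is

    TSI = sum_i (1 - x_i) / (N - 1),    x_i = v_i / max(v)

which is 0 for a perfectly uniform (housekeeping) profile and 1 for
expression confined to a single tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .core import GeneModel


@dataclass
class ExpressionMatrix:
    """features x tissues abundances plus assembly/quantification flags."""

    feature_ids: list[str]
    tissues: list[str]
    counts: np.ndarray
    rpkm: np.ndarray
    assembled: np.ndarray
    junctions_quantified: np.ndarray
    lengths_nt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n, m = len(self.feature_ids), len(self.tissues)
        for name in ("counts", "rpkm", "assembled", "junctions_quantified"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, {m})")
        if (self.counts < 0).any() or (self.rpkm < 0).any():
            raise ValueError("negative abundances")

    def row(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def to_tsv(self, path: str | Path, what: str = "rpkm") -> None:
        pd.DataFrame(
            getattr(self, what), index=self.feature_ids, columns=self.tissues
        ).to_csv(path, sep="\t", index_label="feature_id")


def compute_rpkm(
    counts: np.ndarray, lengths_nt: np.ndarray, library_sizes: np.ndarray
) -> np.ndarray:
    """Reads per kilobase of transcript per million mapped reads.

    ``counts`` is features x tissues, ``lengths_nt`` per feature,
    ``library_sizes`` per tissue (total mapped reads).
    """
    counts = np.asarray(counts, dtype=float)
    lengths_nt = np.asarray(lengths_nt, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (lengths_nt <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / (lengths_nt[:, None] / 1e3) / (library_sizes[None, :] / 1e6)


def mark_expressed(matrix: ExpressionMatrix, rpkm_threshold: float = 1.0) -> np.ndarray:
    """Boolean features x tissues: assembled OR (RPKM > threshold AND all
    junctions quantified).  The RPKM inequality is strict."""
    return matrix.assembled | (
        (matrix.rpkm > rpkm_threshold) & matrix.junctions_quantified
    )


def mark_expressed_genes(
    genes: list[GeneModel], matrix: ExpressionMatrix, expressed: np.ndarray
) -> pd.DataFrame:
    """Gene x tissue expression: a gene is expressed wherever at least one of
    its transcripts is."""
    idx = {f: i for i, f in enumerate(matrix.feature_ids)}
    out = {}
    for g in genes:
        rows = [idx[t.transcript_id] for t in g.transcripts if t.transcript_id in idx]
        out[g.gene_id] = (
            expressed[rows].any(axis=0) if rows else np.zeros(len(matrix.tissues), bool)
        )
    return pd.DataFrame.from_dict(out, orient="index", columns=matrix.tissues)


@dataclass(frozen=True)
class TsiScore:
    feature_id: str
    tsi: float
    n_tissues_expressed: int


def compute_tsi(
    vector: np.ndarray, feature_id: str = "", expressed: np.ndarray | None = None
) -> TsiScore | None:
    """TSI of one expression vector; None (undefined) for an all-zero vector.

    ``expressed`` optionally supplies the boolean expressed calls used for
    ``n_tissues_expressed``; by default any nonzero entry counts.
    """
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector over >=2 tissues")
    if (v < 0).any():
        raise ValueError("negative expression")
    m = v.max()
    if m == 0:
        return None
    x = v / m
    tsi = float((1.0 - x).sum() / (v.size - 1))
    n_expr = int(np.count_nonzero(expressed if expressed is not None else v > 0))
    return TsiScore(feature_id=feature_id, tsi=tsi, n_tissues_expressed=n_expr)


def compute_tsi_matrix(matrix: ExpressionMatrix, expressed: np.ndarray) -> pd.DataFrame:
    rows = []
    for i, fid in enumerate(matrix.feature_ids):
        score = compute_tsi(matrix.rpkm[i], fid, expressed[i])
        rows.append(
            {
                "feature_id": fid,
                "tsi": np.nan if score is None else score.tsi,
                "n_tissues_expressed": 0
                if score is None
                else score.n_tissues_expressed,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def classify_specificity(
    tsi_table: pd.DataFrame, tsi_cut: float = 0.9
) -> pd.Series:
    """Per-feature class: 'tissue_specific' (expressed in exactly 1 tissue),
    'tissue_specific_manner' (>=2 tissues, TSI strictly > 0.9), else 'broad'."""
    n = tsi_table["n_tissues_expressed"]
    tsi = tsi_table["tsi"]
    out = pd.Series("broad", index=tsi_table.index, name="specificity")
    out[(n >= 2) & (tsi > tsi_cut)] = "tissue_specific_manner"
    out[n == 1] = "tissue_specific"
    return out


def tissue_sharing_matrix(
    expressed: pd.DataFrame, denominator: str = "min"
) -> pd.DataFrame:
    """Percent of expressed features shared between tissue pairs.

    ``denominator='min'`` uses 100*|A&B|/min(|A|,|B|) (default); 'jaccard'
    uses the union.  Tissues with zero expressed features are dropped.
    """
    keep = [t for t in expressed.columns if expressed[t].any()]
    if len(keep) < len(expressed.columns):
        import logging

        logging.getLogger(__name__).warning(
            "dropping tissues with no expressed features: %s",
            sorted(set(expressed.columns) - set(keep)),
        )
    x = expressed[keep].to_numpy(bool)
    sizes = x.sum(axis=0)
    inter = (x[:, :, None] & x[:, None, :]).sum(axis=0).astype(float)
    if denominator == "min":
        denom = np.minimum(sizes[:, None], sizes[None, :])
    elif denominator == "jaccard":
        denom = sizes[:, None] + sizes[None, :] - inter
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return pd.DataFrame(100.0 * inter / denom, index=keep, columns=keep)


def tissue_dendrogram(sharing: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Hierarchical clustering of tissues on distance 100 - sharing%."""
    if sharing.shape[0] < 3:
        raise ValueError("need >=3 tissues to cluster")
    dist = 100.0 - sharing.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method=method)


def cophenetic_distances(link: np.ndarray) -> np.ndarray:
    return cophenet(link)


def compare_dendrograms(coph_a: np.ndarray, coph_b: np.ndarray) -> float:
    """Spearman correlation between two dendrograms' cophenetic distances
    (tissues must be in the same order in both).

    Degenerate trees with constant cophenetic distances (e.g. every tissue
    identical) have no rank variation; two such trees compare as 1.0 when
    their distances match and 0.0 otherwise.
    """
    a, b = np.asarray(coph_a, float), np.asarray(coph_b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    rho, _ = spearmanr(a, b)
    return float(rho)
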