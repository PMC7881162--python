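"""Proteome integration: protein ranking, top-k depletion enrichment with a
one-sided hypergeometric test and bootstrap SE, RNA-protein fold-change
correlation, and the signed -log10(p) gene-ranking statistic for GSEA.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSetEnrichment:
    """Hypergeometric record for a top-k selection against a gene set.

    ``N`` universe size, ``K`` set size within the universe, ``n`` selection
    size, ``k`` overlap; ``fold = k / (n*K/N)``; ``p`` is the one-sided
    upper-tail P(X >= k).
    """

    N: int
    K: int
    n: int
    k: int
    expected: float
    fold: float
    p: float
    bootstrap_se: Optional[float] = None


def rank_proteins(table: pd.DataFrame) -> pd.DataFrame:
    """Order proteins most-downregulated first.

    Undetected proteins are assigned log2FC = 0 before sorting; sorting is
    ascending by log2FC with ties broken by gene id.
    """
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].unique()
        raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
    ranked = table.copy()
    ranked.loc[~ranked["detected"].astype(bool), "log2fc"] = 0.0
    ranked["log2fc"] = ranked["log2fc"].fillna(0.0)
    return ranked.sort_values(["log2fc", "gene"], kind="mergesort"
                              ).reset_index(drop=True)


def _enrich_ranked(ranked: pd.DataFrame, gene_set: Set[str], top_k: int
                   ) -> Tuple[int, int, int, int, float]:
    N = len(ranked)
    in_set = ranked["gene"].isin(gene_set)
    K = int(in_set.sum())
    k = int(in_set.iloc[:top_k].sum())
    expected = top_k * K / N
    fold = k / expected if expected > 0 else 0.0
    return N, K, top_k, k, fold


def enrich(ranked: pd.DataFrame, gene_set: Set[str], top_k: int
           ) -> GeneSetEnrichment:
    """Depletion enrichment of ``gene_set`` in the top-k ranked proteins."""
    if not gene_set:
        raise ValueError("empty gene set")
    if not 1 <= top_k <= len(ranked):
        raise ValueError("top_k must lie in [1, universe size]")
    outside = gene_set - set(ranked["gene"])
    if outside:
        raise ValueError(
            f"gene set members outside the ranked universe: {sorted(outside)[:5]}")
    N, K, n, k, fold = _enrich_ranked(ranked, gene_set, top_k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return GeneSetEnrichment(N=N, K=K, n=n, k=k,
                             expected=n * K / N, fold=fold, p=p)


def bootstrap_fold_se(table: pd.DataFrame, gene_set: Set[str], top_k: int,
                      B: int = 100, seed: int = 0) -> float:
    """SE of the fold enrichment over B row resamples (with replacement).

    Each resample is re-ranked from scratch; duplicated rows are counted as
    distinct universe members.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    base = table.copy()
    base.loc[~base["detected"].astype(bool), "log2fc"] = 0.0
    base["log2fc"] = base["log2fc"].fillna(0.0)
    folds = np.empty(B)
    n_rows = len(base)
    for b in range(B):
        idx = rng.integers(0, n_rows, size=n_rows)
        resampled = base.iloc[idx].sort_values(
            ["log2fc", "gene"], kind="mergesort")
        _, _, _, _, fold = _enrich_ranked(resampled, gene_set, top_k)
        folds[b] = fold
    return float(np.std(folds, ddof=1)) if B > 1 else 0.0


def rna_protein_correlation(rna_log2fc: pd.Series, protein_log2fc: pd.Series,
                            detected: Optional[pd.Series] = None,
                            restrict_to: Optional[Set[str]] = None
                            ) -> Tuple[float, int, float]:
    """Pearson correlation of RNA vs protein fold changes over shared genes.

    Undetected proteins enter at log2FC = 0 when a ``detected`` mask
    (indexed like ``protein_log2fc``) is given. Returns ``(r, n, p)`` with
    ``n`` the number of genes correlated (degrees of freedom + 2).
    """
    prot = protein_log2fc.copy()
    if detected is not None:
        prot[~detected.astype(bool)] = 0.0
    genes = rna_log2fc.index.intersection(prot.index)
    if restrict_to is not None:
        genes = genes.intersection(pd.Index(sorted(restrict_to)))
    if len(genes) < 3:
        raise ValueError("need >= 3 shared genes")
    x = rna_log2fc.loc[genes].astype(float)
    y = prot.loc[genes].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a fold-change vector")
    r, p = stats.pearsonr(x, y)
    return float(r), int(len(genes)), float(p)


def gsea_rank_statistic(lfc: pd.Series, adjusted_p: pd.Series,
                        seed: int = 0) -> pd.Series:
    """Gene scores sign(LFC) * (-log10 adjusted p), sorted descending.

    Genes with adjusted p = 0 would score infinitely; each is instead set
    to sign(LFC) * (max finite |score| + u) with u ~ Uniform(0,1), so they
    stay on top (or bottom) with distinct scores.
    """
    if ((adjusted_p < 0) | (adjusted_p > 1)).any():
        raise ValueError("adjusted p-values must lie in [0,1]")
    lfc = lfc.astype(float)
    adjusted_p = adjusted_p.reindex(lfc.index).astype(float)
    sign = np.sign(lfc)
    with np.errstate(divide="ignore"):
        score = sign * (-np.log10(adjusted_p))
    finite = np.isfinite(score)
    if (~finite).any():
        rng = np.random.default_rng(seed)
        max_abs = float(np.max(np.abs(score[finite]))) if finite.any() else 0.0
        u = rng.uniform(0.0, 1.0, size=int((~finite).sum()))
        score[~finite] = sign[~finite] * (max_abs + u)
    return score.sort_values(ascending=False)


def tail_probability_oracle(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric upper tail by direct rational summation.

    Independent of scipy; intended as a cross-check for :func:`enrich` at
    small N (exact binomial-coefficient arithmetic, no floating error until
    the final division).
    """
    num = 0
    for i in range(k, min(n, K) + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return num / math.comb(N, n)
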