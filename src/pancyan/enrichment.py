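"""Functional-category over-representation of a gene subset.

A one-sided hypergeometric test per category (does the subset hold more
genes of the category than drawing the same number of genes at random
from the background would?), with Benjamini-Hochberg FDR control across
the tested categories.  The background is the full gene complement of
the analyzed genome(s), not the whole pan-genome.  Genes may carry
several category labels; each label counts the gene once.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .io_formats import GeneAnnotation


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N background genes of which K carry the category; n genes drawn
    (the subset) of which k carry it.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float
    enrichment_ratio: float


def enrich(subset_gene_ids: set[str] | list[str],
           background: list[GeneAnnotation],
           min_category_size: int = 2) -> list[EnrichmentRow]:
    """Category over-representation of ``subset_gene_ids`` vs background.

    One row per category carried by >= ``min_category_size`` background
    genes, sorted by q then p then label.  The enrichment ratio is
    ``(k/n) / (K/N)``.
    """
    subset = set(subset_gene_ids)
    if not subset:
        raise DegenerateInputError("empty gene subset")
    by_gene = {a.gene_id: a.categories for a in background}
    missing = subset - set(by_gene)
    if missing:
        raise DegenerateInputError(
            f"subset genes absent from background: {sorted(missing)[:5]}"
        )
    N = len(by_gene)
    n = len(subset)
    categories = sorted({c for cats in by_gene.values() for c in cats})
    rows = []
    for cat in categories:
        K = sum(1 for cats in by_gene.values() if cat in cats)
        if K < min_category_size:
            continue
        k = sum(1 for g in subset if cat in by_gene[g])
        p = hypergeometric_tail(k, n, K, N)
        ratio = (k / n) / (K / N)
        rows.append((cat, N, K, n, k, p, ratio))
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[5] for r in rows], method="fdr_bh")
    out = [
        EnrichmentRow(cat, N, K, n, k, p, float(q), ratio)
        for (cat, N, K, n, k, p, ratio), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.q, r.p, r.category))
    return out
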