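"""Pathway over-representation of gene sets by the hypergeometric tail.

Given a query of n genes drawn from a background of N genes, of which K
belong to a pathway and k of the query genes do, the enrichment p-value is
the one-sided Fisher exact / hypergeometric upper tail

    p = P[X >= k],   X ~ Hypergeom(N, K, n).

The default background is every gene appearing in the pathway table, and a
pathway is called enriched at raw p < 0.05; an optional BH correction over
pathways can be switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from ._venn import venn_counts, venn_regions, shared_elements, unique_elements
from .diffexp import bh_adjust

__all__ = [
    "EnrichmentResult", "fisher_enrich", "pathway_venn",
    "venn_counts", "venn_regions", "shared_elements", "unique_elements",
]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int  # query genes in pathway
    K: int  # background genes in pathway
    n: int  # query size (after restriction to background)
    N: int  # background size
    p_value: float
    enriched: bool
    genes: tuple[str, ...]  # query genes in the pathway, sorted

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"inconsistent counts k={self.k}, K={self.K}, n={self.n}")


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    query_genes: set[str] | list[str],
    pathway_table: pd.DataFrame,
    background_genes: set[str] | None = None,
    *,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation test of ``query_genes`` in each pathway.

    ``pathway_table`` must have columns gene_id, pathway_id, pathway_name.
    Query genes absent from the background are dropped with a warning.
    Results are sorted by p-value (ties by pathway id).
    """
    if background_genes is None:
        background_genes = set(pathway_table["gene_id"])
    background_genes = set(background_genes)
    if not background_genes:
        raise ValueError("empty background gene set")

    query = set(query_genes)
    dropped = query - background_genes
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) absent from background dropped", stacklevel=2
        )
    query &= background_genes

    N, n = len(background_genes), len(query)
    results = []
    for (pid, pname), sub in pathway_table.groupby(["pathway_id", "pathway_name"], sort=True):
        members = set(sub["gene_id"]) & background_genes
        K = len(members)
        in_path = query & members
        k = len(in_path)
        p = hypergeom_tail(k, N, K, n)
        results.append(
            EnrichmentResult(pid, pname, k, K, n, N, p, p < alpha, tuple(sorted(in_path)))
        )
    if fdr:
        adj = bh_adjust([r.p_value for r in results])
        results = [
            EnrichmentResult(r.pathway_id, r.pathway_name, r.k, r.K, r.n, r.N,
                             r.p_value, a < alpha, r.genes)
            for r, a in zip(results, adj)
        ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.pathway_id, r.pathway_name, r.k, r.K, r.n, r.N, r.p_value,
             r.enriched, ",".join(r.genes))
            for r in results
        ],
        columns=["pathway_id", "pathway_name", "k", "K", "n", "N",
                 "p_value", "enriched", "genes"],
    )


def pathway_venn(per_comparison_enriched: dict[str, set[str]]) -> dict:
    """Cross-comparison pathway overlap: exclusive region sets and counts,
    the conserved core, and per-comparison unique pathways."""
    if len(per_comparison_enriched) < 2:
        raise ValueError("pathway_venn needs at least two comparisons")
    regions = venn_regions(per_comparison_enriched)
    return {
        "regions": {k: sorted(v) for k, v in regions.items()},
        "counts": {k: len(v) for k, v in regions.items()},
        "conserved": sorted(shared_elements(per_comparison_enriched)),
        "unique": {
            lab: sorted(unique_elements(per_comparison_enriched, lab))
            for lab in per_comparison_enriched
        },
    }
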