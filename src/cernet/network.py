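"""Sign-constrained ceRNA network assembly and analysis.

The competing-endogenous-RNA (sponge) hypothesis predicts, for a true
circRNA → miRNA → mRNA axis, negative expression correlation on both
regulatory edges (circ–miR, miR–mRNA) and positive correlation between
the circRNA and the mRNA it de-represses. The network is built by a
filter funnel: focal DE-circRNA selection (with a host-gene
hypoxia-pathway enrichment gate), seed-site target prediction, DE
intersection, then Pearson-correlation sign/significance filtering; axes
are enumerated on the surviving tripartite graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._venn import unique_elements

__all__ = [
    "InteractionPair", "CeRNAAxis", "pearson_with_p", "select_focal_circs",
    "correlation_filter", "assemble_network", "enumerate_axes",
    "extract_subnetwork", "hub_ranking",
]


@dataclass(frozen=True)
class InteractionPair:
    source: str  # circ id (circ-miR) or miR id (miR-mRNA)
    target: str
    edge_type: str  # "circ-miR" | "miR-mRNA"
    site_count: int
    best_site_type: str
    pearson_r: float
    r_p_value: float
    passes_sign_filter: bool


@dataclass(frozen=True)
class CeRNAAxis:
    circ_id: str
    mir_id: str
    mrna_id: str
    circ_mir_r: float
    mir_mrna_r: float
    circ_mrna_r: float

    @property
    def label(self) -> str:
        return f"{self.circ_id}–{self.mir_id}–{self.mrna_id}"


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2).

    Perfect correlation (|r| = 1) yields p = 0. Zero-variance input
    raises ValueError (callers flag the pair untestable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance expression vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_focal_circs(
    de_sets: dict[str, set[str]],
    contrast_a: str,
    contrast_b: str,
    host_gene_of: dict[str, str | None],
    enriched_hypoxia_genes: set[str],
    *,
    unique_scope: str = "pair",
) -> dict:
    """Focal DE-circRNA selection with host-gene enrichment gating.

    The focal candidates are the circRNAs DE in contrast A and either
    unique to A or shared between A and B — i.e. (A \\ others) ∪ (A ∩ B).
    ``unique_scope`` controls what "unique" means: "pair" (not in B) or
    "all" (in no other contrast of ``de_sets``). A candidate survives
    only if its parental gene belongs to an enriched hypoxia-related
    pathway (``enriched_hypoxia_genes``). Provenance per circRNA is
    recorded.
    """
    for c in (contrast_a, contrast_b):
        if c not in de_sets:
            raise ValueError(f"missing contrast {c!r}")
    a, b = de_sets[contrast_a], de_sets[contrast_b]
    if unique_scope == "pair":
        unique_a = a - b
    elif unique_scope == "all":
        unique_a = unique_elements(de_sets, contrast_a)
    else:
        raise ValueError(f"unknown unique_scope {unique_scope!r}")
    shared = a & b
    candidates = unique_a | shared
    focal, provenance = set(), {}
    for cid in sorted(candidates):
        host = host_gene_of.get(cid)
        gate = host is not None and host in enriched_hypoxia_genes
        provenance[cid] = {
            "unique_to_a": cid in unique_a,
            "shared_a_b": cid in shared,
            "host_gene": host,
            "passes_hypoxia_gate": gate,
        }
        if gate:
            focal.add(cid)
    return {"focal": focal, "candidates": candidates, "provenance": provenance}


def correlation_filter(
    pairs: pd.DataFrame,
    source_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    *,
    edge_type: str,
    required_sign: int = -1,
    alpha: float = 0.05,
) -> list[InteractionPair]:
    """Filter predicted pairs by Pearson correlation sign + significance.

    ``pairs`` needs columns mir_id/target_id (+ site_count,
    best_site_type); source is the sponge side for circ-miR edges.
    Expression frames are features x samples on a matched sample set,
    already normalized. A pair passes iff sign(r) == required_sign and
    p < alpha. Zero-variance pairs are excluded with a warning.
    """
    samples = [s for s in source_expr.columns if s in set(target_expr.columns)]
    if len(samples) < 3:
        raise ValueError("need >= 3 matched samples for correlation")
    out = []
    n_untestable = 0
    for row in pairs.itertuples():
        if edge_type == "circ-miR":
            src, tgt = row.target_id, row.mir_id  # site table: target is the circ
        else:
            src, tgt = row.mir_id, row.target_id
        x = source_expr.loc[src, samples] if src in source_expr.index else None
        y = target_expr.loc[tgt, samples] if tgt in target_expr.index else None
        if x is None or y is None:
            continue
        try:
            r, p = pearson_with_p(x, y)
        except ValueError:
            n_untestable += 1
            continue
        passes = (np.sign(r) == required_sign) and (p < alpha)
        out.append(
            InteractionPair(src, tgt, edge_type, int(row.site_count),
                            str(row.best_site_type), r, p, bool(passes))
        )
    if n_untestable:
        warnings.warn(f"{n_untestable} pair(s) untestable (zero variance), excluded",
                      stacklevel=2)
    return out


def assemble_network(
    circ_mir_pairs: list[InteractionPair],
    mir_mrna_pairs: list[InteractionPair],
    *,
    only_passing: bool = True,
) -> nx.DiGraph:
    """Tripartite directed graph circ → miR → mRNA from filtered pairs.

    Only nodes with at least one surviving edge are present.
    """
    g = nx.DiGraph()
    for p in circ_mir_pairs:
        if only_passing and not p.passes_sign_filter:
            continue
        g.add_node(p.source, kind="circ")
        g.add_node(p.target, kind="miR")
        g.add_edge(p.source, p.target, edge_type="circ-miR", r=p.pearson_r,
                   p=p.r_p_value, site_count=p.site_count, best_site_type=p.best_site_type)
    for p in mir_mrna_pairs:
        if only_passing and not p.passes_sign_filter:
            continue
        g.add_node(p.source, kind="miR")
        g.add_node(p.target, kind="mRNA")
        g.add_edge(p.source, p.target, edge_type="miR-mRNA", r=p.pearson_r,
                   p=p.r_p_value, site_count=p.site_count, best_site_type=p.best_site_type)
    return g


def node_counts(g: nx.DiGraph) -> dict[str, int]:
    kinds = nx.get_node_attributes(g, "kind")
    out = {"circ": 0, "miR": 0, "mRNA": 0}
    for k in kinds.values():
        out[k] += 1
    out["circ-miR_edges"] = sum(1 for _, _, d in g.edges(data=True) if d["edge_type"] == "circ-miR")
    out["miR-mRNA_edges"] = sum(1 for _, _, d in g.edges(data=True) if d["edge_type"] == "miR-mRNA")
    return out


def enumerate_axes(
    g: nx.DiGraph,
    circ_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    *,
    alpha: float = 0.05,
) -> list[CeRNAAxis]:
    """All (circ, miR, mRNA) triples with both edges in the network and a
    significantly positive circ–mRNA correlation.

    The circ–mRNA requirement is evaluated here (not stored as an edge):
    r > 0 with p < alpha, completing the ceRNA sign pattern.
    """
    kinds = nx.get_node_attributes(g, "kind")
    samples = [s for s in circ_expr.columns if s in set(mrna_expr.columns)]
    axes = []
    for circ in sorted(n for n, k in kinds.items() if k == "circ"):
        for mir in sorted(g.successors(circ)):
            for mrna in sorted(g.successors(mir)):
                if kinds.get(mrna) != "mRNA":
                    continue
                if circ not in circ_expr.index or mrna not in mrna_expr.index:
                    continue
                try:
                    r_cg, p_cg = pearson_with_p(
                        circ_expr.loc[circ, samples], mrna_expr.loc[mrna, samples])
                except ValueError:
                    continue
                if r_cg > 0 and p_cg < alpha:
                    axes.append(
                        CeRNAAxis(circ, mir, mrna,
                                  g[circ][mir]["r"], g[mir][mrna]["r"], r_cg)
                    )
    return axes


def extract_subnetwork(g: nx.DiGraph, gene_set: set[str]) -> nx.DiGraph:
    """Induced pathway subnetwork: the given mRNAs, their miRNA partners,
    and those miRNAs' circRNA partners."""
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    kinds = nx.get_node_attributes(g, "kind")
    mrnas = {n for n in gene_set if kinds.get(n) == "mRNA"}
    if not mrnas:
        warnings.warn("gene_set disjoint from network: empty subnetwork", stacklevel=2)
        return nx.DiGraph()
    mirs = {m for g_id in mrnas for m in g.predecessors(g_id)}
    circs = {c for m in mirs for c in g.predecessors(m) if kinds.get(c) == "circ"}
    keep = mrnas | mirs | circs
    sub = g.subgraph(keep).copy()
    # drop miR->mRNA edges pointing outside the gene set
    for u, v in list(sub.edges):
        if sub.edges[u, v]["edge_type"] == "miR-mRNA" and v not in mrnas:
            sub.remove_edge(u, v)
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    return sub


def hub_ranking(g: nx.DiGraph, *, hub_threshold: int = 3) -> pd.DataFrame:
    """circRNAs ranked by number of distinct miRNA partners (descending,
    ties lexicographic); hub flag at degree > hub_threshold."""
    kinds = nx.get_node_attributes(g, "kind")
    rows = []
    for circ in (n for n, k in kinds.items() if k == "circ"):
        mirs = {m for m in g.successors(circ) if kinds.get(m) == "miR"}
        rows.append((circ, len(mirs), len(mirs) > hub_threshold))
    df = pd.DataFrame(rows, columns=["circ_id", "n_mir_partners", "is_hub"])
    df = df.astype({"circ_id": str, "n_mir_partners": int, "is_hub": bool})
    return df.sort_values(["n_mir_partners", "circ_id"],
                          ascending=[False, True]).reset_index(drop=True)


def edge_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = [
        (u, v, d["edge_type"], d["r"], d["p"], d["site_count"], d["best_site_type"])
        for u, v, d in g.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "edge_type", "pearson_r",
                                     "r_p_value", "site_count", "best_site_type"])
    return df.sort_values(["edge_type", "source", "target"]).reset_index(drop=True)


def write_network(g: nx.DiGraph, prefix) -> None:
    """TSV edge/node tables plus SIF and GraphML exports."""
    from pathlib import Path
    prefix = Path(prefix)
    edge_table(g).to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    kinds = nx.get_node_attributes(g, "kind")
    pd.DataFrame(sorted(kinds.items()), columns=["node", "kind"]).to_csv(
        prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
    with open(prefix.with_suffix(".sif"), "w") as fh:
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{d['edge_type']}\t{v}\n")
    nx.write_graphml(g, prefix.with_suffix(".graphml"))
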