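"""Correlation filtering, network assembly and axis enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.network import (InteractionPair, assemble_network,
                            correlation_filter, enumerate_axes,
                            extract_subnetwork, hub_ranking, node_counts,
                            pearson_with_p, select_focal_circs)


def manual_pearson(x, y):
    """Textbook formulas, independent of scipy.stats.pearsonr."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def test_perfect_anticorrelation_passes_circ_mir():
    x = np.arange(1, 13, dtype=float)
    r, p = pearson_with_p(x, x[::-1])
    assert r == pytest.approx(-1.0)
    assert p == pytest.approx(0.0, abs=1e-30)


def test_positive_correlation_fails_negative_sign_requirement():
    x = np.arange(1, 13, dtype=float)
    pair_df = pd.DataFrame(
        [("m1", "c1", "circRNA", 1, "8mer")],
        columns=["mir_id", "target_id", "target_kind", "site_count", "best_site_type"],
    )
    expr = pd.DataFrame([x], index=["c1"], columns=[f"s{i}" for i in range(12)])
    mir_expr = pd.DataFrame([x], index=["m1"], columns=expr.columns)
    out = correlation_filter(pair_df, expr, mir_expr, edge_type="circ-miR")
    assert len(out) == 1 and not out[0].passes_sign_filter


def test_pearson_matches_textbook_formula_to_1e12():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        r, p = pearson_with_p(x, y)
        rm, pm = manual_pearson(x, y)
        assert r == pytest.approx(rm, abs=1e-12)
        assert p == pytest.approx(pm, abs=1e-12)


def test_zero_variance_pairs_flagged_untestable():
    pair_df = pd.DataFrame(
        [("m1", "c1", "circRNA", 1, "8mer")],
        columns=["mir_id", "target_id", "target_kind", "site_count", "best_site_type"],
    )
    flat = pd.DataFrame([[1.0] * 12], index=["c1"], columns=[f"s{i}" for i in range(12)])
    varying = pd.DataFrame([np.arange(12.0)], index=["m1"], columns=flat.columns)
    with pytest.warns(UserWarning):
        out = correlation_filter(pair_df, flat, varying, edge_type="circ-miR")
    assert out == []


def test_focal_selection_set_algebra_and_gate():
    de_sets = {"A": {"c1", "c2", "c3"}, "B": {"c2", "c3", "c4"}}
    host = {"c1": "g1", "c2": "g2", "c3": "g3", "c4": "g4"}
    sel = select_focal_circs(de_sets, "A", "B", host, {"g1", "g2", "g3"})
    assert sel["focal"] == {"c1", "c2", "c3"}
    # gate drops a candidate whose host gene is not enriched
    sel2 = select_focal_circs(de_sets, "A", "B", host, {"g2", "g3"})
    assert sel2["focal"] == {"c2", "c3"}
    assert not sel2["provenance"]["c1"]["passes_hypoxia_gate"]
    with pytest.raises(ValueError):
        select_focal_circs(de_sets, "A", "missing", host, set())


def _pair(src, tgt, kind, r=-0.9, passes=True):
    return InteractionPair(src, tgt, kind, 1, "8mer", r, 0.001, passes)


def test_disjoint_edges_give_no_axes():
    g = assemble_network([_pair("c1", "m1", "circ-miR")],
                         [_pair("m2", "g1", "miR-mRNA")])
    expr = pd.DataFrame(np.arange(12.0)[None, :], index=["c1"],
                        columns=[f"s{i}" for i in range(12)])
    gexpr = pd.DataFrame(np.arange(12.0)[None, :], index=["g1"], columns=expr.columns)
    assert enumerate_axes(g, expr, gexpr) == []


def test_chained_edges_with_sign_pattern_give_one_axis():
    g = assemble_network([_pair("c1", "m1", "circ-miR")],
                         [_pair("m1", "g1", "miR-mRNA")])
    x = np.arange(12.0)
    expr = pd.DataFrame([x], index=["c1"], columns=[f"s{i}" for i in range(12)])
    gexpr = pd.DataFrame([x + np.random.default_rng(0).normal(0, 0.1, 12)],
                         index=["g1"], columns=expr.columns)
    axes = enumerate_axes(g, expr, gexpr)
    assert len(axes) == 1
    ax = axes[0]
    assert (ax.circ_id, ax.mir_id, ax.mrna_id) == ("c1", "m1", "g1")
    assert ax.circ_mrna_r > 0
    # anti-correlated mRNA: the circ-mRNA positive requirement fails
    gexpr_neg = pd.DataFrame([x[::-1]], index=["g1"], columns=expr.columns)
    assert enumerate_axes(g, expr, gexpr_neg) == []


def test_failing_edges_are_excluded_from_network():
    g = assemble_network([_pair("c1", "m1", "circ-miR", passes=False)],
                         [_pair("m1", "g1", "miR-mRNA")])
    assert "c1" not in g


def test_subnetwork_identity_and_small_example():
    cm = [_pair("c1", "m1", "circ-miR"), _pair("c2", "m1", "circ-miR"),
          _pair("c3", "m2", "circ-miR")]
    mg = [_pair("m1", "g1", "miR-mRNA"), _pair("m2", "g2", "miR-mRNA")]
    g = assemble_network(cm, mg)
    full = extract_subnetwork(g, {"g1", "g2"})
    assert set(full.nodes) == set(g.nodes)
    sub = extract_subnetwork(g, {"g1"})
    assert set(sub.nodes) == {"g1", "m1", "c1", "c2"}
    assert node_counts(sub) == {"circ": 2, "miR": 1, "mRNA": 1,
                                "circ-miR_edges": 2, "miR-mRNA_edges": 1}
    with pytest.warns(UserWarning):
        empty = extract_subnetwork(g, {"not_in_network"})
    assert len(empty) == 0
    with pytest.raises(ValueError):
        extract_subnetwork(g, set())


def test_subnetwork_matches_traversal_oracle():
    rng = np.random.default_rng(1)
    circs = [f"c{i}" for i in range(15)]
    mirs = [f"m{i}" for i in range(8)]
    genes = [f"g{i}" for i in range(10)]
    cm = [_pair(c, m, "circ-miR") for c in circs for m in mirs if rng.random() < 0.2]
    mg = [_pair(m, g, "miR-mRNA") for m in mirs for g in genes if rng.random() < 0.2]
    g = assemble_network(cm, mg)
    gene_set = {"g1", "g4", "g7"} & set(g.nodes)
    if gene_set:
        sub = extract_subnetwork(g, gene_set)
        want_m = {p.source for p in mg if p.target in gene_set}
        want_c = {p.source for p in cm if p.target in want_m}
        assert set(sub.nodes) == gene_set | want_m | want_c


def test_hub_ranking_star_and_oracle():
    cm = [_pair("hub", f"m{i}", "circ-miR") for i in range(5)]
    cm += [_pair("leaf", "m0", "circ-miR")]
    mg = [_pair(f"m{i}", "g0", "miR-mRNA") for i in range(5)]
    g = assemble_network(cm, mg)
    ranking = hub_ranking(g)
    assert ranking.iloc[0]["circ_id"] == "hub"
    assert ranking.iloc[0]["n_mir_partners"] == 5
    assert bool(ranking.iloc[0]["is_hub"])
    assert not bool(ranking[ranking["circ_id"] == "leaf"]["is_hub"].iloc[0])
    # degrees equal adjacency counts
    for row in ranking.itertuples():
        assert row.n_mir_partners == len(set(g.successors(row.circ_id)))


def test_all_degree_one_means_no_hubs():
    cm = [_pair(f"c{i}", f"m{i}", "circ-miR") for i in range(4)]
    mg = [_pair(f"m{i}", "g0", "miR-mRNA") for i in range(4)]
    ranking = hub_ranking(assemble_network(cm, mg))
    assert not ranking["is_hub"].any()


def test_every_output_axis_satisfies_sign_constraints(pipeline_run):
    """ceRNA sign soundness on real pipeline output: circ-miR < 0,
    miR-mRNA < 0, circ-mRNA > 0 for every reported axis."""
    _, report = pipeline_run
    import json
    from pathlib import Path
    edges = pd.read_csv(Path(report["parameters"]["outdir"]) / "network.edges.tsv",
                        sep="\t")
    assert (edges["pearson_r"] < 0).all()
    assert (edges["r_p_value"] < 0.05).all()
    assert report["network"]["n_axes"] > 0
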