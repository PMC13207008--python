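"""End-to-end orchestration: simulate → catalog → DE → targets → enrich →
network → motif scan, from one config, with a machine-readable report.

The filter funnel mirrors the multi-step ceRNA construction: candidate
DE-circRNAs from two contrasts, host-gene hypoxia-enrichment gating,
seed-site prediction intersected with DE miRNA/mRNA sets, then the
Pearson sign/significance filter; axes are enumerated last. All
set-valued intermediates are serialized sorted, so reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .catalog import (ExpressionMatrix, catalog_summaries, classify_catalog,
                      detection_sets, merge_catalog, srpbm)
from .diffexp import call_de, de_venn, nb_test, normalized_counts, results_table
from .enrich import enrichment_table, fisher_enrich, pathway_venn
from .motifs import promoter_report, read_pfm, scan_many
from .network import (assemble_network, correlation_filter, enumerate_axes,
                      extract_subnetwork, hub_ranking, node_counts,
                      select_focal_circs, write_network, edge_table)
from .synthetic import SimulationConfig, generate_bundle, write_bundle
from .targets import interaction_pairs, scan_all

log = logging.getLogger("cernet")

ALL_STAGES = ("simulate", "catalog", "de", "targets", "enrich", "network", "scan")


@dataclass
class PipelineConfig:
    outdir: str = "cernet_out"
    seed: int = 0
    # inputs (ignored when simulate=True: the generator writes them)
    circ_counts: str | None = None
    mir_counts: str | None = None
    mrna_counts: str | None = None
    samples: str | None = None
    gtf: str | None = None
    pathways: str | None = None
    mir_fasta: str | None = None
    circ_fasta: str | None = None
    utr_fasta: str | None = None
    promoter_fasta: str | None = None
    pfm: str | None = None
    # thresholds
    lfc: float = 1.0
    alpha_de: float = 0.05
    alpha_enrich: float = 0.05
    alpha_corr: float = 0.05
    relative_score: float = 0.80
    min_reads: int = 2  # catalog merge: >= min_reads in >= min_samples samples
    min_samples: int = 1
    detection_min_reads: int = 1
    de_mode: str = "common"
    # design
    contrast_a: tuple[str, str] = ("TH", "YH")
    contrast_b: tuple[str, str] = ("TH", "TL")
    extra_contrasts: tuple = (("TL", "YL"), ("YH", "YL"))
    hypoxia_pathways: tuple[str, ...] = ("ssc04066",)
    unique_scope: str = "pair"
    hub_threshold: int = 3
    corr_log: bool = True  # Pearson on log2(normalized + 1) rather than raw scale
    # stage control
    simulate: bool = True
    simulation: SimulationConfig | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    permute_correlation_labels: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if sim is not None:
            axes = sim.pop("planted_axes", None)
            if axes is not None:
                from .synthetic import PlantedAxis
                sim["planted_axes"] = [PlantedAxis(**a) for a in axes]
            cfg.simulation = SimulationConfig(**sim)
        for k in ("contrast_a", "contrast_b"):
            setattr(cfg, k, tuple(getattr(cfg, k)))
        cfg.extra_contrasts = tuple(tuple(c) for c in cfg.extra_contrasts)
        cfg.hypoxia_pathways = tuple(cfg.hypoxia_pathways)
        return cfg


def _contrast_label(c: tuple[str, str]) -> str:
    return f"{c[0]}_vs_{c[1]}"


def _permute_columns(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    perm = rng.permutation(df.shape[1])
    out = df.iloc[:, perm]
    out.columns = df.columns  # relabel: breaks the sample alignment
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the report dict (also written
    to <outdir>/report.json). Stage failure raises with the stage named."""
    out = cio.ensure_dir(config.outdir)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    report: dict = {
        "parameters": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, dict) or k == "stages"
        },
        "seed": config.seed,
    }
    stages = {s: config.stages.get(s, True) for s in ALL_STAGES}
    state: dict = {}

    for stage in ALL_STAGES:
        if not stages[stage]:
            log.info("stage %s disabled, skipping", stage)
            continue
        try:
            log.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, state, report, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    log.info("report written to %s", report_path)
    return report


# --- stages -------------------------------------------------------------------

def _stage_simulate(config, state, report, out):
    sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
    bundle = generate_bundle(sim_cfg)
    paths = write_bundle(bundle, out / "inputs")
    state["bundle"] = bundle
    for key, attr in (("circ_counts", "circ_counts"), ("mir_counts", "mir_counts"),
                      ("mrna_counts", "mrna_counts"), ("samples", "samples"),
                      ("gtf", "gtf"), ("pathways", "pathways"),
                      ("mir_fasta", "mir_fasta"), ("circ_fasta", "circ_fasta"),
                      ("utr_fasta", "utr_fasta"), ("promoter_fasta", "promoter_fasta"),
                      ("pfm", "pfm")):
        setattr(config, key, paths[attr])
    report["simulate"] = {
        "n_circ": sim_cfg.n_circ, "n_mir": sim_cfg.n_mir, "n_mrna": sim_cfg.n_mrna,
        "n_planted_axes": len(bundle.truth.axes),
        "planted_axes": sorted(
            f"{a.circ_id}|{a.mir_id}|{a.mrna_id}" for a in bundle.truth.axes),
    }


def _load_expression(config) -> dict[str, ExpressionMatrix]:
    mats = {}
    for cls, path in (("circ", config.circ_counts), ("mir", config.mir_counts),
                      ("mrna", config.mrna_counts)):
        if path is None:
            raise ValueError(f"no {cls} counts provided")
        mats[cls] = cio.read_expression(path, config.samples)
    return mats


def _stage_catalog(config, state, report, out):
    mats = _load_expression(config)
    state["expr"] = mats
    circ = mats["circ"]
    records = cio.records_from_expression(circ)
    records = merge_catalog([records], min_samples=config.min_samples,
                            min_reads=config.min_reads)
    annotation = cio.read_gtf(config.gtf)
    records = classify_catalog(records, annotation)
    state["annotation"] = annotation
    state["records"] = records
    state["host_gene_of"] = {r.circ_id: r.parental_gene for r in records}
    kept = [r.circ_id for r in records]
    circ.counts = circ.counts.loc[kept]
    state["circ_srpbm"] = srpbm(circ.counts, circ.mapped_reads)
    det = detection_sets(circ, min_reads=config.detection_min_reads)
    summaries = catalog_summaries(records)
    cio.write_catalog(records, out / "catalog.tsv")
    cio.write_catalog_bed(records, out / "catalog.bed")
    report["catalog"] = {
        "n_input_features": int(len(circ.counts.index)),
        "summaries": summaries,
        "detected_per_group": {g: len(v) for g, v in sorted(det["detected"].items())},
        "specific_per_group": {g: len(v) for g, v in sorted(det["specific"].items())},
        "venn": {"+".join(sorted(k)): v for k, v in det["venn"].items()},
    }


def _stage_de(config, state, report, out):
    mats = state["expr"]
    contrasts = [config.contrast_a, config.contrast_b, *config.extra_contrasts]
    de_sets: dict[str, set[str]] = {}
    circ = mats["circ"]
    for c in contrasts:
        label = _contrast_label(c)
        res = nb_test(circ.counts, circ.groups, c, mode=config.de_mode,
                      lfc_threshold=config.lfc, alpha=config.alpha_de)
        results_table(res).to_csv(out / f"de_circ_{label}.tsv", sep="\t", index=False)
        de_sets[label] = call_de(res)["significant"]
    state["circ_de_sets"] = de_sets
    mir_mrna_de = {}
    for cls in ("mir", "mrna"):
        mat = mats[cls]
        res = nb_test(mat.counts, mat.groups, config.contrast_a, mode=config.de_mode,
                      lfc_threshold=config.lfc, alpha=config.alpha_de)
        label = _contrast_label(config.contrast_a)
        results_table(res).to_csv(out / f"de_{cls}_{label}.tsv", sep="\t", index=False)
        mir_mrna_de[cls] = call_de(res)["significant"]
    state["mir_de"] = mir_mrna_de["mir"]
    state["mrna_de"] = mir_mrna_de["mrna"]
    report["de"] = {
        "circ_per_contrast": {k: len(v) for k, v in sorted(de_sets.items())},
        "circ_venn": {"+".join(sorted(k)): v for k, v in de_venn(de_sets).items()},
        "mir_de": len(state["mir_de"]),
        "mrna_de": len(state["mrna_de"]),
    }


def _stage_targets(config, state, report, out):
    mir_seqs = cio.read_fasta(config.mir_fasta)
    circ_seqs = cio.read_fasta(config.circ_fasta)
    utr_seqs = cio.read_fasta(config.utr_fasta)
    circ_sites = scan_all(mir_seqs, circ_seqs, target_kind="circRNA", circular=True)
    utr_sites = scan_all(mir_seqs, utr_seqs, target_kind="3'UTR", circular=False)
    circ_sites.to_csv(out / "sites_circ.tsv", sep="\t", index=False)
    utr_sites.to_csv(out / "sites_utr.tsv", sep="\t", index=False)
    state["circ_sites"] = circ_sites
    state["utr_sites"] = utr_sites
    report["targets"] = {
        "n_circ_sites": int(len(circ_sites)),
        "n_utr_sites": int(len(utr_sites)),
        "n_circ_mir_pairs_presite": int(
            circ_sites.groupby(["mir_id", "target_id"]).ngroups) if len(circ_sites) else 0,
        "n_mir_mrna_pairs_presite": int(
            utr_sites.groupby(["mir_id", "target_id"]).ngroups) if len(utr_sites) else 0,
    }


def _stage_enrich(config, state, report, out):
    pathway_table = cio.read_pathways(config.pathways)
    state["pathway_table"] = pathway_table
    host_of = state["host_gene_of"]
    de_sets = state["circ_de_sets"]
    label_a = _contrast_label(config.contrast_a)
    label_b = _contrast_label(config.contrast_b)
    a, b = de_sets[label_a], de_sets[label_b]
    candidates = (a - b) | (a & b)  # focal candidates before the gate
    query = sorted({host_of.get(c) for c in candidates} - {None})
    results = fisher_enrich(query, pathway_table, alpha=config.alpha_enrich)
    enrichment_table(results).to_csv(out / "enrichment_focal.tsv", sep="\t", index=False)
    state["enrichment"] = results
    hyp = set(config.hypoxia_pathways)
    enriched_hyp_genes: set[str] = set()
    for r in results:
        if r.enriched and r.pathway_id in hyp:
            members = set(pathway_table.loc[
                pathway_table["pathway_id"] == r.pathway_id, "gene_id"])
            enriched_hyp_genes |= members
    state["enriched_hypoxia_genes"] = enriched_hyp_genes

    per_contrast_enriched: dict[str, set[str]] = {}
    for label, de in sorted(de_sets.items()):
        q = sorted({host_of.get(c) for c in de} - {None})
        rr = fisher_enrich(q, pathway_table, alpha=config.alpha_enrich)
        per_contrast_enriched[label] = {r.pathway_id for r in rr if r.enriched}
    pv = pathway_venn(per_contrast_enriched) if len(per_contrast_enriched) >= 2 else {}
    report["enrich"] = {
        "focal_query_size": len(query),
        "enriched_pathways": sorted(r.pathway_id for r in results if r.enriched),
        "enriched_hypoxia_gene_count": len(enriched_hyp_genes),
        "conserved_pathways": pv.get("conserved", []),
        "unique_pathways": {k: v for k, v in sorted(pv.get("unique", {}).items())},
    }


def _stage_network(config, state, report, out):
    de_sets = state["circ_de_sets"]
    sel = select_focal_circs(
        de_sets, _contrast_label(config.contrast_a), _contrast_label(config.contrast_b),
        state["host_gene_of"], state["enriched_hypoxia_genes"],
        unique_scope=config.unique_scope,
    )
    focal = sel["focal"]

    circ_pairs = interaction_pairs(state["circ_sites"], de_mirs=state["mir_de"],
                                   de_targets=focal)
    mrna_pairs = interaction_pairs(state["utr_sites"], de_mirs=state["mir_de"],
                                   de_targets=state["mrna_de"])

    mats = state["expr"]
    circ_expr = state["circ_srpbm"]
    mir_expr = normalized_counts(mats["mir"].counts)
    mrna_expr = normalized_counts(mats["mrna"].counts)
    if config.corr_log:
        circ_expr = np.log2(circ_expr + 1)
        mir_expr = np.log2(mir_expr + 1)
        mrna_expr = np.log2(mrna_expr + 1)
    if config.permute_correlation_labels:
        rng = np.random.default_rng([config.seed, 97])
        circ_expr = _permute_columns(circ_expr, rng)
        mir_expr = _permute_columns(mir_expr, rng)
        mrna_expr = _permute_columns(mrna_expr, rng)

    cm = correlation_filter(circ_pairs, circ_expr, mir_expr,
                            edge_type="circ-miR", required_sign=-1,
                            alpha=config.alpha_corr)
    mg = correlation_filter(mrna_pairs, mir_expr, mrna_expr,
                            edge_type="miR-mRNA", required_sign=-1,
                            alpha=config.alpha_corr)
    g = assemble_network(cm, mg)
    axes = enumerate_axes(g, circ_expr, mrna_expr, alpha=config.alpha_corr)
    state["network"] = g
    state["axes"] = axes
    state["circ_expr"] = circ_expr
    state["mrna_expr"] = mrna_expr

    hyp_genes = set()
    if "pathway_table" in state:
        pt = state["pathway_table"]
        hyp_genes = set(pt.loc[pt["pathway_id"].isin(config.hypoxia_pathways), "gene_id"])
    sub = extract_subnetwork(g, hyp_genes) if hyp_genes & set(g.nodes) else None

    write_network(g, out / "network")
    hubs = hub_ranking(g, hub_threshold=config.hub_threshold)
    hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)

    report["network"] = {
        "n_candidates": len(sel["candidates"]),
        "n_focal": len(focal),
        "focal": sorted(focal),
        "n_circ_mir_pairs_predicted": int(len(circ_pairs)),
        "n_mir_mrna_pairs_predicted": int(len(mrna_pairs)),
        "n_circ_mir_edges": sum(p.passes_sign_filter for p in cm),
        "n_mir_mrna_edges": sum(p.passes_sign_filter for p in mg),
        "node_counts": node_counts(g),
        "axes": sorted(f"{a.circ_id}|{a.mir_id}|{a.mrna_id}" for a in axes),
        "n_axes": len(axes),
        "hubs": hubs[hubs["is_hub"]]["circ_id"].tolist(),
        "hif_subnetwork": node_counts(sub) if sub is not None else None,
    }


def _stage_scan(config, state, report, out):
    pwms = read_pfm(Path(config.pfm))
    promoters = cio.read_fasta(config.promoter_fasta)
    # scan the mRNAs in the network if available, else all promoters
    net = state.get("network")
    genes = sorted(n for n, k in net.nodes(data="kind") if k == "mRNA") if net is not None else []
    if not genes:
        genes = sorted(promoters)
    seqs = {g: promoters[g] for g in genes if g in promoters}
    pwm = pwms[0]
    hits = scan_many(pwm, seqs, threshold=config.relative_score)
    hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    best = promoter_report(hits, sorted(seqs))
    best.to_csv(out / "motif_best_hits.tsv", sep="\t", index=False)
    with_hit = best[best["matched_sequence"] != "no hit"]
    report["scan"] = {
        "motif": pwm.motif_id,
        "n_genes_scanned": len(seqs),
        "n_genes_with_hit": int(len(with_hit)),
        "best_hits": {
            r.gene_id: {"offset": int(r.offset), "strand": r.strand,
                        "relative_score": round(float(r.best_relative_score), 4),
                        "matched": r.matched_sequence}
            for r in with_hit.itertuples()
        },
    }


def planted_axis_recovery(
    seeds,
    *,
    permute: bool = False,
    outdir=None,
    sim_config_factory=None,
) -> dict:
    """Benchmark planted-axis recovery of the full pipeline over seeds.

    Runs the default synthetic pipeline once per seed (optionally with
    sample labels shuffled before the correlation stage) and scores the
    enumerated axes against the planted ground truth. Returns per-seed
    true/false axis counts and the pooled recovery fraction.
    """
    import tempfile

    results = []
    total_planted = total_tp = total_fp = 0
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(outdir) if outdir is not None else Path(tmp)
        for seed in seeds:
            cfg = PipelineConfig(outdir=str(base / f"seed_{seed}"), seed=int(seed),
                                 permute_correlation_labels=permute)
            if sim_config_factory is not None:
                cfg.simulation = sim_config_factory(int(seed))
            else:
                cfg.simulation = SimulationConfig(seed=int(seed))
            report = run_pipeline(cfg)
            planted = set(report["simulate"]["planted_axes"])
            recovered = set(report["network"]["axes"])
            tp, fp = len(planted & recovered), len(recovered - planted)
            results.append({"seed": int(seed), "true_axes": tp, "false_axes": fp,
                            "n_planted": len(planted)})
            total_planted += len(planted)
            total_tp += tp
            total_fp += fp
    return {
        "per_seed": results,
        "recovery": total_tp / total_planted if total_planted else float("nan"),
        "total_false_axes": total_fp,
        "mean_false_axes_per_run": total_fp / len(results) if results else float("nan"),
        "n_planted_total": total_planted,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "catalog": _stage_catalog,
    "de": _stage_de,
    "targets": _stage_targets,
    "enrich": _stage_enrich,
    "network": _stage_network,
    "scan": _stage_scan,
}
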