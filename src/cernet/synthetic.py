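"""Synthetic study generator with planted ceRNA structure.

Emulates the data shape of a four-group (TH/TL/YH/YL, Tibetan/Yorkshire
pig at high/low altitude) x three-replicate cardiac transcriptome design:

* negative-binomial counts for circRNAs, miRNAs and mRNAs, with
  Var = mean + dispersion * mean**2 (dispersion = NB "alpha"; the NB
  size parameter is 1/dispersion);
* *planted ceRNA axes*: triples (circRNA, miRNA, mRNA) where both the
  circRNA and the mRNA 3'UTR carry a seed-match site for the miRNA, and
  group means follow the sponge sign pattern — circRNA and mRNA move
  together in the focal group while the miRNA moves oppositely;
* a gene annotation placing each circRNA to a known exonic / intronic /
  intergenic origin;
* a pathway table assigning planted host genes to a hypoxia pathway
  (HIF-1 signaling), so host-gene enrichment gating has signal;
* promoters (2000 bp, the span conventionally taken upstream of a TSS)
  where planted mRNA genes carry the consensus of a HIF-1alpha-like
  hypoxia-response-element motif, provided as a JASPAR PFM.

Decoy features are guaranteed clean: decoy sequences are re-rolled until
they contain no canonical seed site for any planted miRNA, and decoy
promoters until they contain no motif hit at the scan threshold, so
ground truth is exact rather than probabilistic. All outputs are
deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import CircRNARecord, ExpressionMatrix, GeneAnnotation
from .motifs import PWMotif, scan_promoter
from .targets import seed_sites, reverse_complement

_NT = np.array(list("ACGT"))
_MAX_REROLLS = 1000

GROUPS_DEFAULT = ("TH", "TL", "YH", "YL")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

# HIF-1alpha-like hypoxia response element, consensus GGACGTGC (RCGTG core)
HIF1A_PFM_COUNTS = np.array(
    [
        #  G    G    A    C    G    T    G    C
        [  2,   1,  94,   1,   1,   1,   1,   2],  # A
        [  2,   1,   2,  95,   2,   1,   1,  90],  # C
        [ 94,  96,   2,   2,  95,   1,  96,   4],  # G
        [  2,   2,   2,   2,   2,  97,   2,   4],  # T
    ]
)


@dataclass(frozen=True)
class PlantedAxis:
    """One ground-truth ceRNA triple.

    ``circ_id``/``mir_id``/``mrna_id`` may be left None in a config; the
    generator then assigns the axes to the first features of each class
    and returns the resolved axes in the truth object.
    """

    direction: str = "circ_up"  # "circ_up" | "circ_down" (in focal group)
    site_type: str = "8mer"
    focal_group: str = "TH"
    circ_id: str | None = None
    mir_id: str | None = None
    mrna_id: str | None = None

    def __post_init__(self):
        if self.direction not in ("circ_up", "circ_down"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


def default_axes(n: int = 5, focal_group: str = "TH") -> list[PlantedAxis]:
    """n axes with alternating directions and cycling site types."""
    return [
        PlantedAxis(
            direction="circ_up" if i % 2 == 0 else "circ_down",
            site_type=SITE_TYPES[i % len(SITE_TYPES)],
            focal_group=focal_group,
        )
        for i in range(n)
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``nb_dispersion`` is the NB "alpha": Var = mean + alpha * mean**2
    (the NB size/r parameter is 1/alpha).
    """

    groups: tuple[str, ...] = GROUPS_DEFAULT
    n_reps_per_group: int = 3
    n_circ: int = 55
    n_mir: int = 55
    n_mrna: int = 55
    nb_dispersion: float = 0.1
    baseline_mean: float = 200.0
    planted_fold_change: float = 4.0
    planted_axes: list[PlantedAxis] = field(default_factory=default_axes)
    seed: int = 0
    mapped_reads_per_sample: int = 20_000_000
    depth_jitter: float = 0.2  # library sizes drawn U(1-j, 1+j) * mapped_reads
    # sequence lengths (nt)
    mir_length: int = 22
    circ_length: int = 400
    utr_length: int = 600
    promoter_length: int = 2000
    # annotation / pathways
    class_fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)  # exonic/intronic/intergenic
    n_pathways: int = 8
    hypoxia_pathway_id: str = "ssc04066"
    hypoxia_pathway_name: str = "HIF-1 signaling pathway"
    motif_threshold: float = 0.80  # decoy promoters are kept clean below this

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.n_reps_per_group < 2:
            raise ValueError("n_reps_per_group must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.planted_fold_change < 1:
            raise ValueError("planted_fold_change must be >= 1")
        if self.mapped_reads_per_sample <= 0:
            raise ValueError("mapped_reads_per_sample must be positive")
        k = len(self.planted_axes)
        if min(self.n_circ, self.n_mir, self.n_mrna) < k:
            raise ValueError("feature counts must cover the planted axes")
        for ax in self.planted_axes:
            if ax.focal_group not in self.groups:
                raise ValueError(f"focal group {ax.focal_group!r} not in design")
        if min(self.circ_length, self.utr_length) < 30:
            raise ValueError("sequences too short to host a seed site")
        if self.promoter_length < HIF1A_PFM_COUNTS.shape[1] + 2:
            raise ValueError("promoter too short to host a motif instance")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups for i in range(self.n_reps_per_group)]

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series(
            [g for g in self.groups for _ in range(self.n_reps_per_group)],
            index=self.samples, name="group",
        )


@dataclass
class GenomeLayout:
    """Deterministic genomic layout: circRNA records with true classes,
    their host genes, mRNA genes, and the pathway table."""

    circ_records: list[CircRNARecord]  # classified, in catalog order
    circ_ids: list[str]
    mir_ids: list[str]
    mrna_ids: list[str]
    genes: pd.DataFrame  # chrom, start, end, gene_id
    exons: pd.DataFrame
    pathways: pd.DataFrame  # gene_id, pathway_id, pathway_name
    host_gene_of: dict[str, str | None]


@dataclass
class SimulatedTruth:
    axes: list[PlantedAxis]  # with resolved feature ids
    layout: GenomeLayout
    promoter_motif_offsets: dict[str, int]  # planted gene -> 0-based offset
    group_means: dict[str, pd.DataFrame]  # per class: features x groups


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    truth: SimulatedTruth
    circ: ExpressionMatrix
    mir: ExpressionMatrix
    mrna: ExpressionMatrix
    mir_seqs: dict[str, str]
    circ_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    promoter_seqs: dict[str, str]
    pfm: PWMotif


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


# --- layout -------------------------------------------------------------------

def build_layout(config: SimulationConfig) -> GenomeLayout:
    rng = _rng(config, 0)
    k = len(config.planted_axes)
    f_ex, f_in, f_ig = config.class_fractions
    n_intronic = max(0, round(config.n_circ * f_in))
    n_intergenic = max(0, round(config.n_circ * f_ig))
    n_exonic = config.n_circ - n_intronic - n_intergenic
    if n_exonic < k:
        raise ValueError("not enough exonic slots for planted axes")
    classes = ["exonic"] * n_exonic + ["intronic"] * n_intronic + ["intergenic"] * n_intergenic

    chrom_names = [str(c) for c in range(1, 6)]
    cursors = {c: 10_000 for c in chrom_names}
    genes_rows, exons_rows, records = [], [], []
    host_gene_of: dict[str, str | None] = {}

    for i, cls in enumerate(classes):
        chrom = chrom_names[i % len(chrom_names)]
        x = cursors[chrom]
        if cls == "exonic":
            gid = f"GC{i:04d}"
            e1 = (x, x + int(rng.integers(150, 300)))
            intron_len = int(rng.integers(200, 2000))
            e2_start = e1[1] + 1 + intron_len
            e2 = (e2_start, e2_start + int(rng.integers(150, 300)))
            genes_rows.append((chrom, e1[0], e2[1], gid))
            exons_rows += [(chrom, e1[0], e1[1], gid), (chrom, e2[0], e2[1], gid)]
            start = int(rng.integers(e1[0], e1[1] + 1))
            end = int(rng.integers(e2[0], e2[1] + 1))
            rec = CircRNARecord(chrom, start, end, genomic_class="exonic", parental_gene=gid)
            cursors[chrom] = e2[1] + 5000
        elif cls == "intronic":
            gid = f"GC{i:04d}"
            e1 = (x, x + 149)
            intron_len = int(rng.integers(1500, 3000))
            e2_start = e1[1] + 1 + intron_len
            e2 = (e2_start, e2_start + 149)
            genes_rows.append((chrom, e1[0], e2[1], gid))
            exons_rows += [(chrom, e1[0], e1[1], gid), (chrom, e2[0], e2[1], gid)]
            start = e1[1] + 1 + int(rng.integers(50, 200))
            end = min(start + int(rng.integers(200, intron_len - 300)), e2[0] - 1)
            rec = CircRNARecord(chrom, start, end, genomic_class="intronic", parental_gene=gid)
            cursors[chrom] = e2[1] + 5000
        else:
            start = x + int(rng.integers(0, 500))
            end = start + int(rng.integers(200, 1500))
            rec = CircRNARecord(chrom, start, end, genomic_class="intergenic", parental_gene=None)
            cursors[chrom] = end + 5000
        records.append(rec)
        host_gene_of[rec.circ_id] = rec.parental_gene

    circ_ids = [r.circ_id for r in records]
    mir_ids = [f"sim-miR-{i:04d}" for i in range(config.n_mir)]
    mrna_ids = [f"GM{i:04d}" for i in range(config.n_mrna)]

    # mRNA genes on their own chromosome (single-exon; used for promoters)
    cur = 10_000
    for gid in mrna_ids:
        genes_rows.append(("6", cur, cur + 999, gid))
        exons_rows.append(("6", cur, cur + 999, gid))
        cur += 6000

    genes = pd.DataFrame(genes_rows, columns=["chrom", "start", "end", "gene_id"])
    exons = pd.DataFrame(exons_rows, columns=["chrom", "start", "end", "gene_id"])

    # pathways: hypoxia pathway gets planted hosts + planted mRNAs + decoys
    planted_hosts = [host_gene_of[circ_ids[i]] for i in range(k)]
    planted_mrnas = mrna_ids[:k]
    all_genes = sorted(set(genes["gene_id"]))
    decoy_pool = sorted(set(all_genes) - set(planted_hosts) - set(planted_mrnas))
    hyp_extra = list(rng.choice(decoy_pool, size=min(3, len(decoy_pool)), replace=False))
    path_rows = [
        (g, config.hypoxia_pathway_id, config.hypoxia_pathway_name)
        for g in sorted(set(planted_hosts) | set(planted_mrnas) | set(hyp_extra))
    ]
    decoy_paths = [
        (f"ssc{9000 + j:05d}", f"decoy pathway {j + 1}")
        for j in range(max(1, config.n_pathways - 1))
    ]
    for g in all_genes:
        n_assign = int(rng.integers(1, 3))
        for j in rng.choice(len(decoy_paths), size=n_assign, replace=False):
            path_rows.append((g, decoy_paths[j][0], decoy_paths[j][1]))
    pathways = pd.DataFrame(path_rows, columns=["gene_id", "pathway_id", "pathway_name"])
    pathways = pathways.drop_duplicates().sort_values(
        ["pathway_id", "gene_id"]).reset_index(drop=True)

    return GenomeLayout(
        circ_records=records, circ_ids=circ_ids, mir_ids=mir_ids, mrna_ids=mrna_ids,
        genes=genes, exons=exons, pathways=pathways, host_gene_of=host_gene_of,
    )


def resolve_axes(config: SimulationConfig, layout: GenomeLayout) -> list[PlantedAxis]:
    """Assign axis slots to the first features of each class (axes with
    explicit ids are kept as given)."""
    out = []
    for i, ax in enumerate(config.planted_axes):
        out.append(
            replace(
                ax,
                circ_id=ax.circ_id or layout.circ_ids[i],
                mir_id=ax.mir_id or layout.mir_ids[i],
                mrna_id=ax.mrna_id or layout.mrna_ids[i],
            )
        )
    return out


# --- counts -------------------------------------------------------------------

def _group_mean_frame(ids, groups, baseline) -> pd.DataFrame:
    return pd.DataFrame(baseline, index=ids, columns=list(groups), dtype=float)


def group_mean_model(config: SimulationConfig, layout: GenomeLayout,
                     axes: list[PlantedAxis]) -> dict[str, pd.DataFrame]:
    """Expected (depth-1) group means per feature class with planted
    effects applied."""
    f = config.planted_fold_change
    means = {
        "circ": _group_mean_frame(layout.circ_ids, config.groups, config.baseline_mean),
        "mir": _group_mean_frame(layout.mir_ids, config.groups, config.baseline_mean),
        "mrna": _group_mean_frame(layout.mrna_ids, config.groups, config.baseline_mean),
    }
    for ax in axes:
        up = f if ax.direction == "circ_up" else 1.0 / f
        means["circ"].loc[ax.circ_id, ax.focal_group] *= up
        means["mir"].loc[ax.mir_id, ax.focal_group] /= up
        means["mrna"].loc[ax.mrna_id, ax.focal_group] *= up
    return means


def generate_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """NB counts for the three feature classes.

    Feature means scale with each sample's library depth, so size-factor
    normalization downstream is meaningful. Fully reproducible from
    ``config.seed``.
    """
    layout = build_layout(config)
    axes = resolve_axes(config, layout)
    return _counts_from_layout(config, layout, axes)[0]


def _counts_from_layout(config, layout, axes):
    rng = _rng(config, 1)
    samples = config.samples
    groups = config.sample_groups
    jit = config.depth_jitter
    depth = rng.uniform(1 - jit, 1 + jit, size=len(samples))
    mapped = pd.Series(
        np.round(config.mapped_reads_per_sample * depth).astype(np.int64),
        index=samples, name="mapped_reads",
    )
    means = group_mean_model(config, layout, axes)
    r = 1.0 / config.nb_dispersion
    matrices = {}
    for cls in ("circ", "mir", "mrna"):
        mu = means[cls][groups.values].to_numpy() * depth[None, :]
        if (mu <= 0).any():
            raise ValueError("non-positive NB mean")
        counts = rng.negative_binomial(r, r / (r + mu))
        df = pd.DataFrame(counts, index=means[cls].index, columns=samples)
        matrices[cls] = ExpressionMatrix(counts=df, mapped_reads=mapped.copy(), groups=groups.copy())
    return (matrices["circ"], matrices["mir"], matrices["mrna"]), means


# --- sequences ----------------------------------------------------------------

def _planted_site(rng: np.random.Generator, mir_seq: str, site_type: str) -> str:
    """The exact target-strand site string for one seed class."""
    seed7_rc = reverse_complement(mir_seq[1:8])
    seed6_rc = reverse_complement(mir_seq[1:7])
    if site_type == "8mer":
        return seed7_rc + "A"
    if site_type == "7mer-m8":
        non_a = "CGT"[rng.integers(0, 3)]
        return seed7_rc + non_a
    # 7mer-A1: must not extend to an 8mer on its left
    m8_comp = seed7_rc[0]
    left = [b for b in "ACGT" if b != m8_comp][rng.integers(0, 3)]
    return left + seed6_rc + "A"


def _sites_for(mir_seqs: dict[str, str], seq: str, circular: bool) -> set[str]:
    hit = set()
    for mid, ms in mir_seqs.items():
        if seed_sites(ms, seq, mir_id=mid, circular=circular):
            hit.add(mid)
    return hit


def _clean_background(rng, length, planted_mirs, circular, label) -> str:
    """Random sequence with no canonical site for any planted miRNA."""
    for _ in range(_MAX_REROLLS):
        seq = _random_seq(rng, length)
        if not _sites_for(planted_mirs, seq, circular):
            return seq
    raise RuntimeError(f"could not generate clean sequence for {label}")


def _with_planted_site(rng, length, planted_mirs, own_mir, site_type, circular, label):
    """Clean background carrying exactly the planted site for its own miRNA."""
    site = _planted_site(rng, planted_mirs[own_mir], site_type)
    others = {m: s for m, s in planted_mirs.items() if m != own_mir}
    for _ in range(_MAX_REROLLS):
        seq = _clean_background(rng, length, planted_mirs, circular, label)
        pos = int(rng.integers(1, length - len(site) - 1))
        planted = seq[:pos] + site + seq[pos + len(site):]
        # the 7mer-A1 site string carries a left guard base before the match
        expect_at = pos + (1 if site_type == "7mer-A1" else 0)
        own_sites = seed_sites(planted_mirs[own_mir], planted, circular=circular)
        if (
            len(own_sites) >= 1
            and any(s.start_offset == expect_at and s.site_type == site_type for s in own_sites)
            and not _sites_for(others, planted, circular)
        ):
            return planted
    raise RuntimeError(f"could not plant a {site_type} site in {label}")


def hif1a_motif(pseudocount: float = 0.8) -> PWMotif:
    return PWMotif("SIM0001", "HIF1A-like", HIF1A_PFM_COUNTS.astype(float),
                   pseudocount=pseudocount)


def _clean_promoter(rng, length, pwm, threshold, label) -> str:
    for _ in range(_MAX_REROLLS):
        seq = _random_seq(rng, length)
        if not scan_promoter(pwm, seq, threshold=threshold):
            return seq
    raise RuntimeError(f"could not generate motif-free promoter for {label}")


def generate_sequences(config: SimulationConfig):
    """Sequences, annotation, pathways and the motif; see module docstring.

    Returns a dict with keys mir, circ, utr, promoter (id -> sequence),
    layout (GenomeLayout), pfm (PWMotif) and promoter_offsets
    (planted gene -> 0-based motif offset).
    """
    layout = build_layout(config)
    axes = resolve_axes(config, layout)
    rng = _rng(config, 2)
    pfm = hif1a_motif()

    # planted miRNAs first: distinct seeds so axes are separable
    planted_mir_ids = [ax.mir_id for ax in axes]
    mir_seqs: dict[str, str] = {}
    seen_seeds: set[str] = set()
    for mid in layout.mir_ids:
        for _ in range(_MAX_REROLLS):
            s = _random_seq(rng, config.mir_length)
            if mid in planted_mir_ids and s[1:8] in seen_seeds:
                continue
            break
        if mid in planted_mir_ids:
            seen_seeds.add(s[1:8])
        mir_seqs[mid] = s
    planted_mirs = {m: mir_seqs[m] for m in planted_mir_ids}

    site_of = {ax.circ_id: ax for ax in axes} | {ax.mrna_id: ax for ax in axes}

    circ_seqs = {}
    for cid in layout.circ_ids:
        ax = site_of.get(cid)
        if ax is None:
            circ_seqs[cid] = _clean_background(rng, config.circ_length, planted_mirs, True, cid)
        else:
            circ_seqs[cid] = _with_planted_site(
                rng, config.circ_length, planted_mirs, ax.mir_id, ax.site_type, True, cid)

    utr_seqs = {}
    for gid in layout.mrna_ids:
        ax = site_of.get(gid)
        if ax is None:
            utr_seqs[gid] = _clean_background(rng, config.utr_length, planted_mirs, False, gid)
        else:
            utr_seqs[gid] = _with_planted_site(
                rng, config.utr_length, planted_mirs, ax.mir_id, ax.site_type, False, gid)

    promoter_seqs, promoter_offsets = {}, {}
    planted_genes = {ax.mrna_id for ax in axes}
    consensus = pfm.consensus
    for gid in layout.mrna_ids:
        base = _clean_promoter(rng, config.promoter_length, pfm, config.motif_threshold, gid)
        if gid in planted_genes:
            pos = int(rng.integers(0, config.promoter_length - len(consensus) + 1))
            promoter_seqs[gid] = base[:pos] + consensus + base[pos + len(consensus):]
            promoter_offsets[gid] = pos
        else:
            promoter_seqs[gid] = base

    return {
        "mir": mir_seqs, "circ": circ_seqs, "utr": utr_seqs,
        "promoter": promoter_seqs, "layout": layout, "pfm": pfm,
        "promoter_offsets": promoter_offsets, "axes": axes,
    }


# --- bundle -------------------------------------------------------------------

def generate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Everything the pipeline consumes, plus ground truth."""
    layout = build_layout(config)
    axes = resolve_axes(config, layout)
    (circ, mir, mrna), means = _counts_from_layout(config, layout, axes)
    seqs = generate_sequences(config)
    truth = SimulatedTruth(
        axes=axes, layout=layout,
        promoter_motif_offsets=seqs["promoter_offsets"],
        group_means=means,
    )
    return SimulatedBundle(
        config=config, truth=truth, circ=circ, mir=mir, mrna=mrna,
        mir_seqs=seqs["mir"], circ_seqs=seqs["circ"], utr_seqs=seqs["utr"],
        promoter_seqs=seqs["promoter"], pfm=seqs["pfm"],
    )


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, str]:
    """Serialize a bundle to standard formats; returns path map."""
    from . import io as cio
    from .motifs import write_pfm

    out = cio.ensure_dir(outdir)
    paths = {}

    for cls, mat in (("circ", bundle.circ), ("mir", bundle.mir), ("mrna", bundle.mrna)):
        p = out / f"{cls}_counts.tsv"
        cio.write_counts(mat.counts, p)
        paths[f"{cls}_counts"] = str(p)
    p = out / "samples.tsv"
    cio.write_sample_sheet(bundle.circ.groups, bundle.circ.mapped_reads, p)
    paths["samples"] = str(p)

    for name, seqs in (("mir", bundle.mir_seqs), ("circ", bundle.circ_seqs),
                       ("utr", bundle.utr_seqs), ("promoter", bundle.promoter_seqs)):
        p = out / f"{name}.fa"
        cio.write_fasta(seqs, p)
        paths[f"{name}_fasta"] = str(p)

    p = out / "annotation.gtf"
    cio.write_gtf(bundle.truth.layout.genes, bundle.truth.layout.exons, p)
    paths["gtf"] = str(p)
    p = out / "pathways.tsv"
    cio.write_pathways(bundle.truth.layout.pathways, p)
    paths["pathways"] = str(p)
    p = out / "motif.pfm"
    write_pfm([bundle.pfm], p)
    paths["pfm"] = str(p)
    return paths


def annotation_from_layout(layout: GenomeLayout) -> GeneAnnotation:
    return GeneAnnotation(genes=layout.genes, exons=layout.exons)
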