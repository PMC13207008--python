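# Methods

This note documents the models, conventions and design choices behind
`cernet`, in the order the pipeline runs them.

## Synthetic study generator

The generator emulates a four-group, three-replicate bulk RNA-seq design
(groups TH/TL/YH/YL: two genotypes at high and low altitude) and produces
every input the pipeline consumes: circRNA/miRNA/mRNA count tables with a
sample sheet, a GTF annotation, FASTA sets (mature miRNAs, circRNA
sequences, mRNA 3′UTRs, promoters), a pathway-membership table, and a
JASPAR-format PFM.

**Counts.** Counts are negative-binomial with the mean/dispersion
parameterization `Var = μ + α·μ²`; the `nb_dispersion` knob is α (the NB
size parameter is 1/α). Every feature has baseline mean 200 (configurable);
dispersion defaults to 0.1, a typical bulk RNA-seq magnitude for a
small-replicate design. Expected counts scale with each sample's library
depth, drawn uniformly within ±20% of 20 million mapped reads, so
size-factor estimation downstream is meaningful. All randomness flows from
a single integer seed through fixed, named substreams; identical seeds give
bit-identical outputs.

**Planted axes.** A planted axis is a triple (circRNA, miRNA, mRNA) with:

* a seed-match site of a declared class (8mer, 7mer-m8 or 7mer-A1) for the
  miRNA in both the circRNA sequence and the mRNA 3′UTR;
* group means following the sponge sign pattern in the focal group —
  `circ_up`: circ ×f, miR ÷f, mRNA ×f (f = planted fold change, default 4);
  `circ_down` is the mirror;
* the circRNA's host gene and the mRNA placed in a hypoxia pathway
  ("HIF-1 signaling") in the pathway table;
* the mRNA's promoter carrying one instance of the motif consensus at a
  recorded offset.

The default five axes alternate directions and cycle the three site
classes. Ground truth is exact, not probabilistic: decoy sequences are
re-rolled (bounded retries) until they contain **no** canonical site for
any planted miRNA (including across the circRNA junction), planted targets
until they contain **only** the intended site among planted miRNAs, and
decoy promoters until they have no motif hit at the scan threshold.
Planted miRNAs are re-rolled to have pairwise distinct seeds.

**Annotation.** Genes are laid out with explicit exon/intron structure so
that each circRNA's class is true by construction: exonic circRNAs have
both BSJ endpoints inside exons of one gene, intronic ones lie inside an
intron, intergenic ones overlap no gene. The default class mix is 90/5/5.
mRNA "genes" live on their own chromosome and anchor promoters and
pathway membership. The generator does not simulate reads, splicing-factor
biology, isoform structure, or correlated biological noise — passing
end-to-end tests demonstrates correctness of the pipeline's logic and
calibration under the stated model, not performance on real tissue data.

## circRNA catalog

BSJ identity is `(chrom, start, end)` with 1-based inclusive coordinates
(the `chrom:start|end` naming convention); strand is carried but not part
of identity. Merging collapses identical keys, sums per-sample junction
reads, and applies a support filter (default: ≥2 junction reads in ≥1
sample — the usual "at least two back-spliced reads" convention; both knobs
exposed). Span length is genomic (`end − start + 1`), not the mature
spliced length.

Classification: *exonic* iff both endpoints fall in exons of a single
gene; *intronic* if the span is inside a gene but not exonic at both ends
(fully intra-intronic spans included); *intergenic* if no gene overlaps.
A span contained in no gene but partially overlapping one is classed
intronic with that gene as parent — a documented edge convention.
Parental-gene ties among containing genes go to the gene covering the
larger fraction of the span, then lexicographically.

SRPBM = `junction_reads / mapped_reads × 10⁹`. Detection per group
defaults to ≥1 junction read in ≥1 sample of the group; group-specific
sets and all 2ⁿ Venn regions are computed by exhaustive membership
enumeration.

## Differential expression

The model is the DESeq2 family NB GLM: `K_ij ~ NB(s_j·q_ig, α)` with
median-of-ratios size factors (total-count fallback when no feature is
everywhere nonzero). Two testing modes:

* **`common`** (default): one dispersion per contrast, maximizing the
  Cox–Reid adjusted profile likelihood summed over all features — the
  information-sharing idea of edgeR/DESeq2 — followed by a likelihood-ratio
  test of the group effect against χ²(1). With three replicates per group,
  per-feature dispersion estimates are far too noisy to support a
  calibrated Wald test with useful power; sharing the dispersion across
  features restores both. Measured on null simulations (2000 features,
  3 vs 3) the raw-p type-I rate at α = 0.05 is ≈ 0.05–0.06 across
  dispersions 0.05–0.8, with ≈ 98% power on four-fold features at baseline
  mean 200.
* **`per-feature`**: the textbook variant — pooled within-group
  method-of-moments dispersion `max(0, (var − mean)/mean²)` per feature
  (floor 1e-8), Wald statistic on log₂FC against t(n₁+n₂−2). Calibrated
  but markedly less powerful at n = 3; kept for heterogeneous-dispersion
  data and as a cross-check.

Features with all-zero counts in both groups get p = NA and are excluded
from the Benjamini–Hochberg correction (standard step-up with monotonicity
enforcement; NAs passed through). BH is applied per contrast, not
globally. The reported log₂FC is the ratio of size-factor-normalized group
means; when one group mean is zero, a 0.5 pseudocount enters the reported
fold change only (flagged), never the test. Calls: up iff log₂FC ≥ 1 and
adjusted p < 0.05; down mirrored. The common-dispersion mode assumes
features share a dispersion scale; strongly dispersion-heterogeneous data
would be better served by the per-feature mode or a trended estimator
(not implemented).

## Target prediction

Canonical seed classes only, defined on the target strand with the miRNA
5′→3′: 8mer = reverse complement of miRNA positions 2–8 followed by A;
7mer-m8 = the same 7-mer without the A requirement; 7mer-A1 = reverse
complement of positions 2–7 followed by A, unless it is the tail of a
reported 8mer. U/T spellings are normalized; overlapping occurrences are
all reported left-to-right; no position is reported under two classes.
No 6mers, no alignment/energy scoring, no conservation or context
scoring — at small catalog scale the canonical classes alone keep false
positives low, and the downstream DE-intersection and correlation filters
carry the specificity burden. circRNA targets are additionally scanned
across the back-splice junction (last 7 nt joined to first 7 nt) to honor
circularity. Site-bearing pairs are kept only when both endpoints are in
their respective DE sets ("any canonical site" policy).

## Enrichment

One-sided hypergeometric tail `P[X ≥ k]`, `X ~ Hypergeom(N, K, n)` —
Fisher's exact test for over-representation. Background defaults to all
genes in the pathway table (configurable). Query genes outside the
background are dropped with a warning; each DE-circRNA contributes its
parental gene once. Enrichment is declared at raw p < 0.05 by default (an
FDR flag exists but is off, matching common practice for pathway-level
screens in this literature). The hypoxia gate then retains circRNAs whose
host gene belongs to an *enriched* pathway from the configured
hypoxia-related list (default: HIF-1 signaling; extendable to VEGF, AMPK,
glycolysis/gluconeogenesis, autophagy, mitophagy via config).

## Network

Focal candidates are the circRNAs DE in contrast A (TH vs YH) that are
either unique to A or shared with contrast B (TH vs TL); "unique" can be
scoped against B only (default) or against all contrasts. Pearson
correlations are computed across all 12 samples on log₂(normalized + 1)
expression — SRPBM for circRNAs, size-factor-normalized counts otherwise.
The log transform is the standard variance-stabilizing choice for
expression correlation; on the raw scale the NB mean–variance coupling
attenuates correlations markedly. Two-sided p from the exact t transform
`t = r√(n−2)/√(1−r²)`; |r| = 1 yields p = 0; zero-variance vectors are
excluded with a warning. Edges require r < 0 with p < 0.05; the positive
circ–mRNA requirement (r > 0, p < 0.05) is enforced at axis enumeration
rather than stored as an edge. Each filter only removes edges, so the
funnel is monotone by construction. Subnetwork extraction takes the induced
graph on a gene set, its miRNA partners, and those miRNAs' circRNA
partners; hub ranking orders circRNAs by distinct miRNA partners
(descending, ties lexicographic; hub flag at > 3 partners).

## Motif scanning

JASPAR PFM text is parsed via Biopython; weights are
`log₂((n_bj + p·bg_b)/(N_j + p)/bg_b)` with pseudocount p = 0.8
distributed by the background (uniform 0.25 by default; both
configurable). Window score = sum of per-position weights; relative score
rescales between the column-wise minimum and maximum sums, so the
consensus always attains 1.0 (a degenerate flat motif scores 1.0 by
convention). Both strands are scanned — minus-strand windows on the
reverse complement, offsets reported in plus-strand coordinates — with
hits at relative score ≥ 0.80. Ambiguous bases score the
background-weighted average of their column. The per-gene report keeps the
best hit (max relative score, ties to the leftmost offset then the plus
strand) with a "no hit" sentinel. Absolute log-odds scores depend on the
pseudocount/background convention, which published scans rarely state;
only relative scores should be compared across tools.

## Pipeline and reproducibility

Stages run in dependency order from one config (YAML-loadable); each
stage's outputs are written before the next starts, and a failure halts
with the stage named, retaining partial outputs. All set-valued
intermediates are serialized sorted, making reruns with the same config
and seed byte-identical. The report records every threshold applied plus
funnel counts at each step. A label-permutation mode shuffles each
expression matrix's sample columns independently before the correlation
stage, which destroys cross-class correlation structure and with it
planted-axis recovery — the negative control for the correlation filter.

## Validation problem sizes

The shipped validation uses 55 features per class (5 planted axes + 50
decoys), 20 simulation seeds for recovery and permutation experiments,
2000-feature null simulations per dispersion for calibration, 1000 random
miRNA/target pairs against the regex oracle, 500 random promoters against
the brute-force PWM scorer, and all hypergeometric tables with N ≤ 30
against explicit sums. These sizes give stable Monte-Carlo estimates while
keeping the full suite fast on one CPU.
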