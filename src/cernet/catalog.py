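"""circRNA catalog construction, genomic classification and SRPBM.

A circRNA is identified by its back-splice junction (BSJ): the genomic
coordinates joined by back-splicing, written 1-based inclusive as
"chrom:start|end". Classification against a gene annotation uses three
origin classes:

exonic      both BSJ endpoints fall within exons of a single gene
intronic    the span lies within one gene, but at least one endpoint
            falls outside that gene's exons (fully intra-intronic spans
            are also intronic)
intergenic  the span overlaps no annotated gene

Expression is normalized as SRPBM, spliced reads per billion mapped:
junction_reads / total_mapped_reads * 1e9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._venn import venn_counts, unique_elements

__all__ = [
    "CircRNARecord", "ExpressionMatrix", "GeneAnnotation", "merge_catalog",
    "classify_circ", "classify_catalog", "srpbm", "detection_sets",
    "catalog_summaries", "catalog_table",
]


@dataclass(frozen=True)
class CircRNARecord:
    """One back-splice junction with per-sample read support."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    per_sample_junction_reads: dict = field(default_factory=dict)
    strand: str | None = None  # carried but not part of identity
    genomic_class: str | None = None
    parental_gene: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end for {self.chrom}:{self.start}|{self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")
        if self.genomic_class not in (None, "exonic", "intronic", "intergenic"):
            raise ValueError(f"unknown genomic class {self.genomic_class!r}")
        if self.genomic_class == "intergenic" and self.parental_gene is not None:
            raise ValueError("intergenic circRNAs cannot have a parental gene")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    @property
    def span_length(self) -> int:
        """Genomic span in nt (not the mature spliced length)."""
        return self.end - self.start + 1


@dataclass
class ExpressionMatrix:
    """Feature x sample integer counts with sequencing-depth metadata."""

    counts: pd.DataFrame  # features x samples
    mapped_reads: pd.Series  # per sample
    groups: pd.Series  # per sample

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.counts.columns.equals(self.mapped_reads.index):
            self.mapped_reads = self.mapped_reads.loc[self.counts.columns]
        if not self.counts.columns.equals(self.groups.index):
            self.groups = self.groups.loc[self.counts.columns]
        if (self.mapped_reads <= 0).any():
            raise ValueError("every sample needs mapped_reads > 0")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


class GeneAnnotation:
    """Interval-indexed view of a gene annotation (from a GTF).

    Stores, per gene: its span and its exon intervals, all 1-based
    inclusive. Lookup structures are per-chromosome interval trees.
    """

    def __init__(self, genes: pd.DataFrame, exons: pd.DataFrame):
        # both frames: columns chrom, start, end, gene_id (1-based inclusive)
        self.genes = genes.reset_index(drop=True)
        self.exons = exons.reset_index(drop=True)
        self._gene_trees: dict[str, IntervalTree] = {}
        for chrom, sub in genes.groupby("chrom"):
            # IntervalTree is half-open: [start, end + 1)
            self._gene_trees[str(chrom)] = IntervalTree.from_tuples(
                (int(r.start), int(r.end) + 1, str(r.gene_id)) for r in sub.itertuples()
            )
        self._gene_span = {
            str(r.gene_id): (str(r.chrom), int(r.start), int(r.end))
            for r in genes.itertuples()
        }
        self._exons_by_gene: dict[str, list[tuple[int, int]]] = {}
        for r in exons.itertuples():
            self._exons_by_gene.setdefault(str(r.gene_id), []).append(
                (int(r.start), int(r.end))
            )

    @classmethod
    def from_gtf(cls, path) -> "GeneAnnotation":
        from .io import read_gtf
        return read_gtf(path)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._gene_trees.get(str(chrom))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def containing_genes(self, chrom: str, start: int, end: int) -> list[str]:
        out = []
        for gid in self.overlapping_genes(chrom, start, end):
            _, gs, ge = self._gene_span[gid]
            if gs <= start and end <= ge:
                out.append(gid)
        return out

    def in_exon(self, gene_id: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self._exons_by_gene.get(gene_id, []))

    def overlap_fraction(self, gene_id: str, start: int, end: int) -> float:
        _, gs, ge = self._gene_span[gene_id]
        ov = max(0, min(end, ge) - max(start, gs) + 1)
        return ov / (end - start + 1)

    def __len__(self) -> int:
        return len(self._gene_span)


def merge_catalog(
    per_sample_records: list[list[CircRNARecord]],
    min_samples: int = 1,
    min_reads: int = 2,
) -> list[CircRNARecord]:
    """Merge per-sample BSJ records into a non-redundant catalog.

    Records with identical (chrom, start, end) collapse to one record
    whose per-sample counts are merged (summed on sample-id collision).
    A record is retained if it has >= min_reads junction reads in
    >= min_samples samples. Output is sorted by (chrom, start, end).
    """
    merged: dict[tuple, CircRNARecord] = {}
    for records in per_sample_records:
        for rec in records:
            key = (rec.chrom, rec.start, rec.end)
            if key not in merged:
                merged[key] = replace(rec, per_sample_junction_reads=dict(rec.per_sample_junction_reads))
            else:
                existing = merged[key]
                if rec.strand and existing.strand and rec.strand != existing.strand:
                    raise ValueError(f"conflicting strands for {existing.circ_id}")
                counts = existing.per_sample_junction_reads
                for s, c in rec.per_sample_junction_reads.items():
                    counts[s] = counts.get(s, 0) + c
    kept = [
        rec for rec in merged.values()
        if sum(1 for c in rec.per_sample_junction_reads.values() if c >= min_reads) >= min_samples
    ]
    kept.sort(key=lambda r: (r.chrom, r.start, r.end))
    return kept


def classify_circ(record: CircRNARecord, annotation: GeneAnnotation) -> CircRNARecord:
    """Assign genomic class and parental gene to one BSJ record.

    Parental-gene ties among containing genes are broken by the larger
    span-overlap fraction, then lexicographically by gene id.
    """
    containing = annotation.containing_genes(record.chrom, record.start, record.end)
    if not containing:
        overlapping = annotation.overlapping_genes(record.chrom, record.start, record.end)
        if overlapping:
            # partially overlapping a gene without being contained: the
            # span extends past the gene; closest parental gene by overlap
            gene = max(
                overlapping,
                key=lambda g: (annotation.overlap_fraction(g, record.start, record.end), g),
            )
            return replace(record, genomic_class="intronic", parental_gene=gene)
        return replace(record, genomic_class="intergenic", parental_gene=None)
    gene = sorted(
        containing,
        key=lambda g: (-annotation.overlap_fraction(g, record.start, record.end), g),
    )[0]
    exonic = annotation.in_exon(gene, record.start) and annotation.in_exon(gene, record.end)
    return replace(record, genomic_class="exonic" if exonic else "intronic", parental_gene=gene)


def classify_catalog(records: list[CircRNARecord], annotation: GeneAnnotation) -> list[CircRNARecord]:
    if len(annotation) == 0:
        warnings.warn("empty annotation: all circRNAs classified intergenic", stacklevel=2)
    return [classify_circ(r, annotation) for r in records]


def srpbm(counts: pd.DataFrame, mapped_reads: pd.Series) -> pd.DataFrame:
    """Spliced reads per billion mapped: counts / mapped_reads * 1e9."""
    mapped = mapped_reads.loc[counts.columns]
    if (mapped <= 0).any():
        raise ValueError("mapped_reads must be positive for every sample")
    return counts / mapped * 1e9


def detection_sets(
    matrix: ExpressionMatrix,
    *,
    min_reads: int = 1,
) -> dict:
    """Per-group detected and group-specific feature sets plus full Venn.

    Detection rule: junction reads >= min_reads in at least one sample of
    the group.
    """
    group_labels = sorted(matrix.groups.unique())
    if len(group_labels) < 2:
        raise ValueError("need at least two groups")
    detected: dict[str, set[str]] = {}
    for g in group_labels:
        cols = matrix.groups[matrix.groups == g].index
        sub = matrix.counts[cols]
        detected[g] = set(sub.index[(sub >= min_reads).any(axis=1)].astype(str))
    specific = {g: unique_elements(detected, g) for g in group_labels}
    return {
        "detected": detected,
        "specific": specific,
        "venn": venn_counts(detected),
    }


def catalog_summaries(records: list[CircRNARecord]) -> dict:
    """Class distribution, chromosome counts, span-length stats and the
    circRNAs-per-parental-gene histogram."""
    classes = pd.Series([r.genomic_class for r in records]).value_counts().to_dict()
    chroms = pd.Series([r.chrom for r in records]).value_counts().to_dict()
    lengths = [r.span_length for r in records]
    per_gene = pd.Series(
        [r.parental_gene for r in records if r.parental_gene is not None]
    ).value_counts()
    per_gene_hist = per_gene.value_counts().sort_index().to_dict()  # circs-per-gene -> n genes
    return {
        "n_circ": len(records),
        "class_counts": classes,
        "chrom_counts": chroms,
        "length_min": min(lengths) if lengths else None,
        "length_max": max(lengths) if lengths else None,
        "n_parental_genes": int(per_gene.size),
        "per_gene_histogram": {int(k): int(v) for k, v in per_gene_hist.items()},
    }


def catalog_table(records: list[CircRNARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.circ_id, r.chrom, r.start, r.end, r.strand or ".",
             r.genomic_class, r.parental_gene, r.span_length)
            for r in records
        ],
        columns=["circ_id", "chrom", "start", "end", "strand",
                 "genomic_class", "parental_gene", "span_length"],
    )
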