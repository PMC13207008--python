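"""Readers and writers for the standard formats the pipeline consumes.

Conventions: genomic coordinates are 1-based inclusive internally (GTF
convention); BED export converts to 0-based half-open. Counts tables are
TSV with features as rows and a header row of sample ids; the sample
sheet is TSV with columns sample, group, mapped_reads.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import CircRNARecord, ExpressionMatrix, GeneAnnotation


# --- counts and sample sheets -------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_sample_sheet(groups: pd.Series, mapped_reads: pd.Series, path) -> None:
    pd.DataFrame(
        {"sample": groups.index, "group": groups.values,
         "mapped_reads": mapped_reads.loc[groups.index].values}
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> tuple[pd.Series, pd.Series]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    groups = pd.Series(df["group"].values, index=df["sample"], name="group")
    mapped = pd.Series(df["mapped_reads"].values, index=df["sample"], name="mapped_reads")
    return groups, mapped


def read_expression(counts_path, sample_sheet_path) -> ExpressionMatrix:
    counts = read_counts(counts_path)
    groups, mapped = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(counts=counts, mapped_reads=mapped, groups=groups)


# --- FASTA --------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- GTF ----------------------------------------------------------------------

def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Write gene and exon features (1-based inclusive) as GTF."""
    with open(path, "w") as fh:
        for r in genes.itertuples():
            attrs = f'gene_id "{r.gene_id}";'
            fh.write(
                f"{r.chrom}\tcernet\tgene\t{r.start}\t{r.end}\t.\t{getattr(r, 'strand', '+')}\t.\t{attrs}\n"
            )
            sub = exons[exons["gene_id"] == r.gene_id]
            for e in sub.itertuples():
                attrs = f'gene_id "{r.gene_id}"; transcript_id "{r.gene_id}.t1";'
                fh.write(
                    f"{e.chrom}\tcernet\texon\t{e.start}\t{e.end}\t.\t{getattr(r, 'strand', '+')}\t.\t{attrs}\n"
                )


def read_gtf(path) -> GeneAnnotation:
    """Load a GTF into an interval-indexed annotation (pyranges parser;
    pyranges' 0-based starts are converted back to 1-based inclusive)."""
    df = pr.read_gtf(str(path)).df
    df = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int) + 1  # back to 1-based inclusive
    df["end"] = df["end"].astype(int)
    genes = df[df["Feature"] == "gene"][["chrom", "start", "end", "gene_id"]]
    exons = df[df["Feature"] == "exon"][["chrom", "start", "end", "gene_id"]]
    return GeneAnnotation(genes=genes, exons=exons)


# --- catalog tables -----------------------------------------------------------

def write_catalog(records: list[CircRNARecord], path) -> None:
    from .catalog import catalog_table
    catalog_table(records).to_csv(path, sep="\t", index=False)


def write_catalog_bed(records: list[CircRNARecord], path) -> None:
    """BED6 export: 0-based half-open, score = total junction reads."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda x: (x.chrom, x.start, x.end)):
            total = sum(r.per_sample_junction_reads.values())
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.circ_id}\t{total}\t{r.strand or '.'}\n"
            )


def records_from_expression(matrix: ExpressionMatrix) -> list[CircRNARecord]:
    """Parse "chrom:start|end" feature ids of a circRNA count matrix into
    catalog records carrying the per-sample counts."""
    records = []
    for fid, row in matrix.counts.iterrows():
        chrom, rest = str(fid).split(":", 1)
        start, end = rest.split("|")
        records.append(
            CircRNARecord(
                chrom=chrom, start=int(start), end=int(end),
                per_sample_junction_reads={s: int(c) for s, c in row.items()},
            )
        )
    return records


# --- pathways -----------------------------------------------------------------

def write_pathways(table: pd.DataFrame, path) -> None:
    table[["gene_id", "pathway_id", "pathway_name"]].to_csv(path, sep="\t", index=False)


def read_pathways(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "pathway_id", "pathway_name"} - set(df.columns)
    if missing:
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
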