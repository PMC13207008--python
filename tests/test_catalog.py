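"""Catalog merging, classification, SRPBM and detection-set algebra."""

import numpy as np
import pandas as pd
import pytest

from cernet.catalog import (CircRNARecord, ExpressionMatrix, GeneAnnotation,
                            catalog_summaries, classify_circ, detection_sets,
                            merge_catalog, srpbm)


def rec(chrom, start, end, counts=None, **kw):
    return CircRNARecord(chrom, start, end, per_sample_junction_reads=counts or {}, **kw)


# --- merge -------------------------------------------------------------------

def test_merge_collapses_identical_bsj():
    merged = merge_catalog(
        [[rec("1", 100, 500, {"s1": 3})], [rec("1", 100, 500, {"s2": 5})]],
        min_samples=1, min_reads=1,
    )
    assert len(merged) == 1
    assert merged[0].per_sample_junction_reads == {"s1": 3, "s2": 5}
    assert merged[0].circ_id == "1:100|500"


def test_merge_filter_drops_underdetected():
    merged = merge_catalog([[rec("1", 1, 2, {"s1": 5})]], min_samples=2, min_reads=2)
    assert merged == []


def test_merge_threshold_scan_matches_brute_force():
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(12)]
    catalogs = []
    per_sample = []
    for j, s in enumerate(samples):
        recs = []
        for i in range(50):
            c = int(rng.integers(0, 5))
            if c > 0:
                recs.append(rec("1", 100 * (i + 1), 100 * (i + 1) + 50, {s: c}))
        per_sample.append(recs)
    all_counts = {}
    for recs in per_sample:
        for r in recs:
            all_counts.setdefault((r.chrom, r.start, r.end), {}).update(r.per_sample_junction_reads)

    for min_samples, min_reads in ((1, 1), (12, 1), (3, 2)):
        merged = merge_catalog(per_sample, min_samples=min_samples, min_reads=min_reads)
        expected = {
            key for key, counts in all_counts.items()
            if sum(1 for c in counts.values() if c >= min_reads) >= min_samples
        }
        assert {(r.chrom, r.start, r.end) for r in merged} == expected
    assert len(merge_catalog(per_sample, 1, 1)) == len(all_counts)


def test_merge_is_idempotent():
    per_sample = [
        [rec("2", 10, 99, {"a": 2}), rec("1", 5, 50, {"a": 3})],
        [rec("2", 10, 99, {"b": 4})],
    ]
    once = merge_catalog(per_sample, 1, 1)
    twice = merge_catalog([once], 1, 1)
    assert [(r.chrom, r.start, r.end, r.per_sample_junction_reads) for r in once] == \
           [(r.chrom, r.start, r.end, r.per_sample_junction_reads) for r in twice]
    assert [r.circ_id for r in once] == sorted(r.circ_id for r in once)


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        rec("1", 500, 100)
    with pytest.raises(ValueError):
        CircRNARecord("1", 10, 20, genomic_class="intergenic", parental_gene="G")


# --- classification ----------------------------------------------------------

@pytest.fixture()
def annotation():
    genes = pd.DataFrame(
        [("1", 100, 699, "GA"), ("1", 5000, 5999, "GB")],
        columns=["chrom", "start", "end", "gene_id"],
    )
    exons = pd.DataFrame(
        [("1", 100, 299, "GA"), ("1", 500, 699, "GA"), ("1", 5000, 5999, "GB")],
        columns=["chrom", "start", "end", "gene_id"],
    )
    return GeneAnnotation(genes, exons)


def test_exonic_when_both_endpoints_in_exons(annotation):
    out = classify_circ(rec("1", 150, 600), annotation)
    assert (out.genomic_class, out.parental_gene) == ("exonic", "GA")


def test_intronic_when_endpoint_in_intron(annotation):
    out = classify_circ(rec("1", 150, 400), annotation)
    assert (out.genomic_class, out.parental_gene) == ("intronic", "GA")
    fully_intronic = classify_circ(rec("1", 310, 450), annotation)
    assert fully_intronic.genomic_class == "intronic"


def test_intergenic_when_no_gene_overlap(annotation):
    out = classify_circ(rec("1", 1000, 2000), annotation)
    assert (out.genomic_class, out.parental_gene) == ("intergenic", None)
    out2 = classify_circ(rec("2", 100, 200), annotation)
    assert out2.genomic_class == "intergenic"


def test_class_partition_is_complete(annotation):
    rng = np.random.default_rng(1)
    records = [rec("1", int(s), int(s) + int(rng.integers(10, 900)))
               for s in rng.integers(1, 7000, size=60)]
    classified = [classify_circ(r, annotation) for r in records]
    classes = [r.genomic_class for r in classified]
    assert all(c in ("exonic", "intronic", "intergenic") for c in classes)
    assert len(classes) == len(records)


# --- SRPBM -------------------------------------------------------------------

def test_srpbm_formula_and_zero():
    counts = pd.DataFrame({"s1": [10, 0]}, index=["c1", "c2"])
    mapped = pd.Series({"s1": 2e7})
    out = srpbm(counts, mapped)
    assert out.loc["c1", "s1"] == pytest.approx(500.0)
    assert out.loc["c2", "s1"] == 0.0


def test_srpbm_scale_invariance():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(rng.integers(0, 100, size=(20, 4)),
                          columns=[f"s{i}" for i in range(4)])
    mapped = pd.Series(rng.integers(int(1e7), int(3e7), size=4).astype(float),
                       index=counts.columns)
    for k in (2.0, 0.5, 7.0):
        a = srpbm(counts, mapped)
        b = srpbm(counts * k, mapped * k)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)


def test_srpbm_rejects_zero_mapped():
    with pytest.raises(ValueError):
        srpbm(pd.DataFrame({"s1": [1]}), pd.Series({"s1": 0}))


# --- detection sets ----------------------------------------------------------

def _matrix(counts: pd.DataFrame, groups: pd.Series) -> ExpressionMatrix:
    mapped = pd.Series(1e7, index=counts.columns)
    return ExpressionMatrix(counts=counts, mapped_reads=mapped, groups=groups)


def test_group_specific_feature_detection():
    samples = ["TH_1", "TH_2", "YH_1", "YH_2"]
    groups = pd.Series(["TH", "TH", "YH", "YH"], index=samples)
    counts = pd.DataFrame(
        [[3, 0, 0, 0], [1, 2, 3, 4]], index=["only_th", "everywhere"], columns=samples
    )
    det = detection_sets(_matrix(counts, groups))
    assert "only_th" in det["specific"]["TH"]
    assert det["specific"]["YH"] == set()
    assert "everywhere" in det["detected"]["TH"] and "everywhere" in det["detected"]["YH"]
    assert all("everywhere" not in s for s in det["specific"].values())


def test_detection_venn_matches_membership_enumeration():
    rng = np.random.default_rng(3)
    groups = pd.Series(
        [g for g in ("TH", "TL", "YH", "YL") for _ in range(3)],
        index=[f"{g}_{i}" for g in ("TH", "TL", "YH", "YL") for i in range(3)],
    )
    counts = pd.DataFrame(rng.integers(0, 2, size=(100, 12)),
                          index=[f"f{i}" for i in range(100)], columns=groups.index)
    det = detection_sets(_matrix(counts, groups))
    # brute force over all 16 membership patterns
    membership = {}
    for f in counts.index:
        pat = frozenset(
            g for g in ("TH", "TL", "YH", "YL")
            if counts.loc[f, groups[groups == g].index].max() >= 1
        )
        if pat:
            membership[pat] = membership.get(pat, 0) + 1
    for pattern, n in det["venn"].items():
        assert n == membership.get(pattern, 0)
    assert sum(det["venn"].values()) == len(
        set().union(*det["detected"].values())
    )


# --- summaries ---------------------------------------------------------------

def test_catalog_summaries_counts():
    records = [
        rec("1", 1, 10, genomic_class="exonic", parental_gene="G1"),
        rec("1", 20, 40, genomic_class="exonic", parental_gene="G1"),
        rec("1", 50, 60, genomic_class="intronic", parental_gene="G2"),
        rec("2", 5, 9, genomic_class="intergenic"),
    ]
    s = catalog_summaries(records)
    assert s["class_counts"] == {"exonic": 2, "intronic": 1, "intergenic": 1}
    assert s["chrom_counts"] == {"1": 3, "2": 1}
    assert s["per_gene_histogram"] == {1: 1, 2: 1}  # G2 once, G1 twice
    assert sum(s["class_counts"].values()) == s["n_circ"]
    # weighted histogram mass equals gene-derived circRNAs
    assert sum(k * v for k, v in s["per_gene_histogram"].items()) == 3
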