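"""Generator contracts: determinism, NB fidelity, planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from cernet.catalog import classify_catalog
from cernet.motifs import scan_promoter
from cernet.synthetic import (PlantedAxis, SimulationConfig, annotation_from_layout,
                              build_layout, default_axes, generate_bundle,
                              generate_counts)


def test_same_seed_is_bit_identical(bundle):
    again = generate_bundle(SimulationConfig(seed=42))
    for a, b in ((bundle.circ, again.circ), (bundle.mir, again.mir), (bundle.mrna, again.mrna)):
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.mapped_reads, b.mapped_reads)
    assert bundle.mir_seqs == again.mir_seqs
    assert bundle.circ_seqs == again.circ_seqs
    assert bundle.utr_seqs == again.utr_seqs
    assert bundle.promoter_seqs == again.promoter_seqs
    assert bundle.truth.promoter_motif_offsets == again.truth.promoter_motif_offsets


def test_null_configuration_groups_exchangeable():
    """fold change 1 + no axes: group means agree to NB sampling error."""
    cfg = SimulationConfig(seed=7, planted_axes=[], planted_fold_change=1.0,
                           n_circ=400, n_mir=10, n_mrna=10, depth_jitter=0.0)
    circ, _, _ = generate_counts(cfg)
    by_group = circ.counts.T.groupby(circ.groups).mean().T
    ratios = by_group.mean(axis=0) / cfg.baseline_mean
    assert np.allclose(ratios, 1.0, rtol=0.03)


def test_planted_group_means_match_configuration():
    """circ_up, fold 4, baseline 100: focal circ mean ~400, miR ~25."""
    n = 600
    axes = [PlantedAxis(direction="circ_up", focal_group="TH") for _ in range(500)]
    cfg = SimulationConfig(seed=11, planted_axes=axes, baseline_mean=100.0,
                           planted_fold_change=4.0, n_circ=n, n_mir=n, n_mrna=n,
                           depth_jitter=0.0)
    circ, mir, mrna = generate_counts(cfg)
    th = circ.groups[circ.groups == "TH"].index
    planted_circ = circ.counts.index[:500]
    planted_mir = mir.counts.index[:500]
    assert circ.counts.loc[planted_circ, th].to_numpy().mean() == pytest.approx(400, rel=0.05)
    assert mir.counts.loc[planted_mir, th].to_numpy().mean() == pytest.approx(25, rel=0.05)
    assert mrna.counts.loc[mrna.counts.index[:500], th].to_numpy().mean() == pytest.approx(400, rel=0.05)
    # non-focal groups stay at baseline
    yl = circ.groups[circ.groups == "YL"].index
    assert circ.counts.loc[planted_circ, yl].to_numpy().mean() == pytest.approx(100, rel=0.05)


def test_nb_moment_fidelity():
    """Method-of-moments recovery of configured NB mean and dispersion."""
    cfg = SimulationConfig(seed=3, planted_axes=[], n_circ=800, n_mir=10, n_mrna=10,
                           nb_dispersion=0.2, baseline_mean=300.0, depth_jitter=0.0)
    circ, _, _ = generate_counts(cfg)
    x = circ.counts.to_numpy(dtype=float)
    m = x.mean()
    v = x.var(ddof=1, axis=1).mean()
    alpha = (v - m) / m**2
    assert m == pytest.approx(300.0, rel=0.05)
    assert alpha == pytest.approx(0.2, rel=0.20)


def test_planted_site_is_manual_reverse_complement(bundle):
    """For each axis, the target carries the reverse complement of the
    miRNA seed (positions 2-8 or 2-7 + A), computed independently here."""
    for ax in bundle.truth.axes:
        mir = bundle.mir_seqs[ax.mir_id].upper().replace("U", "T")
        if ax.site_type in ("8mer", "7mer-m8"):
            expected = str(Seq(mir[1:8]).reverse_complement())
        else:  # 7mer-A1
            expected = str(Seq(mir[1:7]).reverse_complement())
        if ax.site_type in ("8mer", "7mer-A1"):
            expected += "A"
        assert expected in bundle.circ_seqs[ax.circ_id]
        assert expected in bundle.utr_seqs[ax.mrna_id]


def test_decoy_sequences_have_no_planted_sites(bundle):
    """Regex-style oracle: no canonical site for any planted miRNA in any
    decoy circRNA or 3'UTR sequence."""
    planted_circ = {a.circ_id for a in bundle.truth.axes}
    planted_mrna = {a.mrna_id for a in bundle.truth.axes}
    comp = str.maketrans("ACGT", "TGCA")
    for ax in bundle.truth.axes:
        mir = bundle.mir_seqs[ax.mir_id].upper().replace("U", "T")
        seed7 = mir[1:8].translate(comp)[::-1]
        seed6 = mir[1:7].translate(comp)[::-1]
        for cid, seq in bundle.circ_seqs.items():
            if cid in planted_circ:
                continue
            wrapped = seq + seq[:7]
            assert seed7 not in wrapped
            for i in range(len(wrapped) - 6):
                assert not (wrapped[i:i + 6] == seed6 and wrapped[i + 6] == "A")
        for gid, seq in bundle.utr_seqs.items():
            if gid in planted_mrna:
                continue
            assert seed7 not in seq
            for i in range(len(seq) - 6):
                assert not (seq[i:i + 6] == seed6 and seq[i + 6] == "A")


def test_planted_promoter_consensus_scores_one(bundle):
    pwm = bundle.pfm
    for gid, offset in bundle.truth.promoter_motif_offsets.items():
        hits = scan_promoter(pwm, bundle.promoter_seqs[gid], sequence_id=gid,
                             threshold=0.99)
        assert any(h.offset == offset and h.relative_score == pytest.approx(1.0)
                   for h in hits)


def test_decoy_promoters_below_threshold(bundle):
    planted = set(bundle.truth.promoter_motif_offsets)
    for gid, seq in bundle.promoter_seqs.items():
        if gid in planted:
            continue
        assert scan_promoter(bundle.pfm, seq, threshold=0.80) == []


def test_generated_classes_match_downstream_classifier(bundle):
    """The annotation places each circRNA so the catalog classifier
    reproduces the generator's class labels exactly."""
    layout = bundle.truth.layout
    ann = annotation_from_layout(layout)
    classified = classify_catalog(list(layout.circ_records), ann)
    for truth_rec, rec in zip(layout.circ_records, classified):
        assert rec.genomic_class == truth_rec.genomic_class
        assert rec.parental_gene == truth_rec.parental_gene


def test_class_mix_recovered_exactly():
    cfg = SimulationConfig(seed=5, n_circ=100, class_fractions=(0.90, 0.05, 0.05))
    layout = build_layout(cfg)
    counts = pd.Series([r.genomic_class for r in layout.circ_records]).value_counts()
    assert counts["exonic"] == 90 and counts["intronic"] == 5 and counts["intergenic"] == 5


@pytest.mark.parametrize("kwargs", [
    {"nb_dispersion": -0.1}, {"nb_dispersion": 0.0}, {"baseline_mean": 0.0},
    {"planted_fold_change": 0.5}, {"n_reps_per_group": 1},
    {"n_circ": 2},  # fewer than the 5 planted axes
    {"circ_length": 10},  # too short to host a site
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, **kwargs)


def test_default_axes_shapes():
    axes = default_axes(5)
    assert len(axes) == 5
    assert {a.direction for a in axes} == {"circ_up", "circ_down"}
    assert {a.site_type for a in axes} == {"8mer", "7mer-m8", "7mer-A1"}
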