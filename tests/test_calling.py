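"""Cluster calling, skew detection, CP coding, DH corroboration."""

import numpy as np
import pandas as pd
import pytest

from tetralink import calling, cross, karyotype as kt
from tetralink.errors import InvalidParameterError, NonParentalAlleleError


def _points(thetas, r=2.0, marker="M1"):
    return pd.DataFrame({
        "marker_id": marker,
        "individual_id": [f"I{i}" for i in range(len(thetas))],
        "theta": thetas,
        "R": r,
    })


def test_cluster_three_separated_groups():
    thetas = np.concatenate([np.zeros(55), np.full(110, 0.5), np.ones(56)])
    model = calling.cluster_marker_signals(_points(thetas))
    assert model.k == 3
    assert np.allclose(model.means, [0.0, 0.5, 1.0], atol=0.01)
    assert np.allclose(model.weights, [55 / 221, 110 / 221, 56 / 221],
                       atol=0.01)


def test_cluster_single_central_cluster():
    rng = np.random.default_rng(0)
    model = calling.cluster_marker_signals(
        _points(0.5 + rng.normal(0, 0.02, 221)))
    assert model.k == 1
    assert abs(model.means[0] - 0.5) < 0.01


def test_cluster_recovers_skewed_grid_from_simulation():
    """Biallelic marker over a fixed paralog: truth grid {0.5, 0.75, 1}."""
    rng = np.random.default_rng(42)
    counts = rng.multinomial(221, [0.25, 0.5, 0.25])
    thetas = np.concatenate([
        rng.normal(g, 0.03, c)
        for g, c in zip((0.5, 0.75, 1.0), counts)])
    model = calling.cluster_marker_signals(_points(np.clip(thetas, 0, 1)))
    assert model.k == 3
    assert np.all(np.abs(model.means - np.array([0.5, 0.75, 1.0])) < 0.05)
    model = calling.classify_marker(model)
    assert model.class_label == "segregating_3"
    assert model.skew == "right"


def test_cluster_failed_when_too_few_points():
    model = calling.cluster_marker_signals(_points([0.5] * 5))
    assert model.class_label == "failed"
    low_r = _points([0.5] * 50, r=0.1)
    assert calling.cluster_marker_signals(low_r).class_label == "failed"


def _model(means, marker="M1"):
    means = np.asarray(means, dtype=float)
    return calling.ClusterModel(
        marker, len(means), means, np.full(len(means), 0.02),
        np.full(len(means), 1 / len(means)))


@pytest.mark.parametrize("means,label,skew", [
    ([0.51], "paralog_fixed", "none"),
    ([0.02], "monomorphic", "none"),
    ([0.97], "monomorphic", "none"),
    ([0.01, 0.50, 0.99], "segregating_3", "none"),
    ([0.49, 0.74, 0.99], "segregating_3", "right"),
    ([0.02, 0.26], "segregating_2", "left"),
    ([0.1, 0.3, 0.5, 0.9], "discard_multi", "none"),
])
def test_classify_marker_patterns(means, label, skew):
    model = calling.classify_marker(_model(means))
    assert model.class_label == label
    assert model.skew == skew


def test_detect_skew_examples_and_errors():
    assert calling.detect_skew([0.49, 0.74, 0.99]) == "right"
    assert calling.detect_skew([0.0, 0.5, 1.0]) == "none"
    assert calling.detect_skew([0.02, 0.26]) == "left"
    assert calling.detect_skew([0.0, 0.5]) == "none"     # tie resolves to none
    with pytest.raises(InvalidParameterError):
        calling.detect_skew([0.5])
    with pytest.raises(InvalidParameterError):
        calling.detect_skew([0.1, 0.2, 0.3, 0.4])


@pytest.mark.parametrize("means", [
    [0.0, 0.5, 1.0], [0.49, 0.74, 0.99], [0.02, 0.26], [0.51, 0.76],
])
def test_classify_invariant_under_allele_mirror(means):
    """theta -> 1 - theta swaps left and right skew, preserves the class."""
    m1 = calling.classify_marker(_model(means))
    m2 = calling.classify_marker(_model([1 - x for x in means]))
    assert m1.class_label == m2.class_label
    flip = {"left": "right", "right": "left", "none": "none"}
    assert m2.skew == flip[m1.skew]


def test_assign_cp_snv_codes_and_ratio_structure():
    prog = {"a": "AA", "b": "AB", "c": None, "d": "BB"}
    call = calling.assign_cp_snv("M1", "AB", "BB", prog)
    assert call.cp_code == "lmxll"
    assert call.calls == {"a": "--", "b": "lm", "c": "--", "d": "ll"}
    call = calling.assign_cp_snv("M1", "AB", "AB", prog)
    assert call.cp_code == "hkxhk"
    assert call.calls == {"a": "hh", "b": "hk", "c": "--", "d": "kk"}
    call = calling.assign_cp_snv("M1", "AA", "AB", prog)
    assert call.cp_code == "nnxnp"
    with pytest.raises(InvalidParameterError):
        calling.assign_cp_snv("M1", "AA", "BB", prog)


def test_assign_cp_ssr_codes():
    call = calling.assign_cp_ssr("S1", (150, 160), (170, 180),
                                 {"a": (150, 170), "b": (160, 180),
                                  "c": (), "d": (150, 180)})
    assert call.cp_code == "abxcd"
    assert call.calls == {"a": "ac", "b": "bd", "c": "--", "d": "ad"}
    call = calling.assign_cp_ssr("S2", (150, 160), (150, 170),
                                 {"a": (150,), "b": (150, 160),
                                  "c": (160, 170)})
    assert call.cp_code == "efxeg"
    assert call.calls == {"a": "ee", "b": "ef", "c": "fg"}
    with pytest.raises(NonParentalAlleleError):
        calling.assign_cp_ssr("S3", (150, 160), (150, 150),
                              {"a": (150, 244)})


def test_genotype_call_accuracy_degrades_with_noise(small_karyotype):
    """>=99% correct calls at sd<=0.03; accuracy monotone in noise."""
    markers = kt.place_markers(
        small_karyotype, 1, 0,
        class_proportions={"biallelic_unique": 1.0},
        informativeness={"both": 1.0}, seed=30)
    p1, p2 = cross.build_phased_parents(small_karyotype, markers)
    pop = cross.simulate_f1_population(p1, p2, small_karyotype, 221, seed=31)
    loc = small_karyotype.loci[markers[0].locus_id]
    truth = {ind.individual_id:
             "".join(sorted(ind.genotype(loc.lg_id, loc.locus_id)))
             for ind in pop}
    accs = []
    for sd in (0.01, 0.05, 0.1):
        table = cross.assay_population(pop, markers, small_karyotype,
                                       noise_sd=sd, seed=32)
        model = calling.classify_marker(
            calling.cluster_marker_signals(table))
        calls = calling.call_genotypes(model, table)
        ok = sum(calls[i] == truth[i] for i in truth)
        accs.append(ok / len(truth))
    assert accs[0] >= 0.99
    assert accs[0] >= accs[1] >= accs[2] - 0.01   # monotone up to mc noise


def test_corroborate_with_dh_clean_and_empty(fused_karyotype):
    markers = kt.place_markers(
        fused_karyotype, 40, 0, seed=33)
    p1, p2 = cross.build_phased_parents(fused_karyotype, markers)
    pop = cross.simulate_f1_population(p1, p2, fused_karyotype, 120, seed=34)
    table = cross.assay_population(pop, markers, fused_karyotype,
                                   noise_sd=0.02, seed=35)
    models = {}
    for mid, grp in table.groupby("marker_id"):
        models[str(mid)] = calling.classify_marker(
            calling.cluster_marker_signals(grp))
    dhs = [cross.simulate_doubled_haploid(p, fused_karyotype, seed=36 + i,
                                          individual_id=f"DH{i}")
           for i, p in enumerate((p1, p2))]
    dh_table = cross.assay_population(dhs, markers, fused_karyotype,
                                      noise_sd=0.02, seed=37)
    report = calling.corroborate_with_dh(models, dh_table)
    assert len(report) == 0
    empty = calling.corroborate_with_dh(models, dh_table.iloc[0:0])
    assert len(empty) == 0
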