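"""Meiosis, F1 population, doubled haploids, distortion, assay signal."""

import numpy as np
import pytest

from tetralink import cross, karyotype as kt
from tetralink.errors import InvalidParameterError
from tetralink.karyotype import MarkerDef

from conftest import make_two_locus_cross


def _recombinant_fraction(pop, karyo, loc_a, loc_b, gamete="gamete1"):
    """Fraction of parent-1 gametes recombinant between two loci (phase
    known by construction: parental haplotypes are A-A and B-B)."""
    rec = 0
    for ind in pop:
        g = getattr(ind, gamete)
        a = g.haplotype[loc_a.lg_id][loc_a.locus_id]
        b = g.haplotype[loc_b.lg_id][loc_b.locus_id]
        rec += a != b
    return rec / len(pop)


def test_haldane_recombination_at_50_cm():
    n = 20000
    _, _, _, pop, a, b = make_two_locus_cross(50.0, n, seed=2)
    rf = _recombinant_fraction(pop, None, a, b)
    expect = 0.5 * (1 - np.exp(-1.0))
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(rf - expect) < 3 * se


def test_zero_distance_and_independent_assortment():
    _, _, _, pop, a, b = make_two_locus_cross(0.0, 2000, seed=3)
    assert _recombinant_fraction(pop, None, a, b) == 0.0
    _, _, _, pop, a, b = make_two_locus_cross(0.0, 4000, seed=4, same_lg=False)
    rf = _recombinant_fraction(pop, None, a, b)
    assert abs(rf - 0.5) < 3 * np.sqrt(0.25 / 4000)


def test_homoeologous_loci_never_corecombine(fused_karyotype):
    """Disomic contract: alleles at paralogous loci assort independently."""
    markers = kt.place_markers(
        fused_karyotype, 20, 0,
        class_proportions={"biallelic_unique": 1.0}, seed=5)
    p1, p2 = cross.build_phased_parents(fused_karyotype, markers)
    # make every locus heterozygous in parent1 (paralog included)
    for lg, (h0, h1) in p1.haplotypes.items():
        for loc in h0:
            h0[loc], h1[loc] = "A", "B"
    pop = cross.simulate_f1_population(p1, p2, fused_karyotype, 3000, seed=6)
    m = markers[0]
    loc = fused_karyotype.loci[m.locus_id]
    par = fused_karyotype.loci[loc.paralog_id]
    rec = sum(
        ind.gamete1.haplotype[loc.lg_id][loc.locus_id]
        != ind.gamete1.haplotype[par.lg_id][par.locus_id]
        for ind in pop) / len(pop)
    assert abs(rec - 0.5) < 3 * np.sqrt(0.25 / 3000)


def test_f1_population_size_and_mendelian_ratios(small_karyotype):
    markers = kt.place_markers(
        small_karyotype, 2, 0,
        class_proportions={"biallelic_unique": 1.0},
        informativeness={"both": 1.0}, seed=8)
    p1, p2 = cross.build_phased_parents(small_karyotype, markers)
    pop = cross.simulate_f1_population(p1, p2, small_karyotype, 221, seed=9)
    assert len(pop) == 221
    loc = small_karyotype.loci[markers[0].locus_id]
    counts = {"AA": 0, "AB": 0, "BB": 0}
    for ind in pop:
        g = "".join(sorted(ind.genotype(loc.lg_id, loc.locus_id)))
        counts[g] += 1
    # 1:2:1 within chi-square 99.9% bounds
    from scipy.stats import chisquare
    _, p = chisquare(list(counts.values()), [221 / 4, 221 / 2, 221 / 4])
    assert p > 0.001


def test_distortion_identity_and_expected_ratio():
    ktr, p1, p2, pop, a, _ = make_two_locus_cross(10.0, 4000, seed=10)
    unchanged = cross.apply_segregation_distortion(
        pop, ktr, a.locus_id, {"A": 1.0, "B": 1.0}, seed=0)
    assert len(unchanged) == len(pop)
    survivors = cross.apply_segregation_distortion(
        pop, ktr, a.locus_id, {"B": 0.5}, seed=1)
    het = sum("B" in ind.genotype(a.lg_id, a.locus_id) for ind in survivors)
    hom = len(survivors) - het
    # 1:1 becomes 2:1 in expectation under 0.5 survival of the B carrier
    ratio = hom / het
    assert 1.6 < ratio < 2.5
    with pytest.raises(InvalidParameterError):
        cross.apply_segregation_distortion(pop, ktr, "nope", {"B": 0.5})
    with pytest.raises(InvalidParameterError):
        cross.apply_segregation_distortion(pop, ktr, a.locus_id, {"B": 0.0})


def test_strong_distortion_flagged_highly_distorted():
    from tetralink.segregation import classify_distortion

    ktr, p1, p2, pop, a, _ = make_two_locus_cross(10.0, 3000, seed=12)
    survivors = cross.apply_segregation_distortion(
        pop, ktr, a.locus_id, {"B": 0.05}, seed=2)
    het = sum("B" in ind.genotype(a.lg_id, a.locus_id) for ind in survivors)
    hom = len(survivors) - het
    assert hom / max(het, 1) > 10          # closed form expectation 20:1
    assert classify_distortion((hom, het), "lmxll") == "highly_distorted"


def test_doubled_haploid_homozygous_but_keeps_paralog_states(fused_karyotype):
    markers = kt.place_markers(
        fused_karyotype, 30, 0,
        class_proportions={"biallelic_unique": 0.5,
                           "paralog_fixed_only": 0.5}, seed=13)
    p1, _ = cross.build_phased_parents(fused_karyotype, markers)
    dh = cross.simulate_doubled_haploid(p1, fused_karyotype, seed=14)
    for m in markers:
        loc = fused_karyotype.loci[m.locus_id]
        g = dh.genotype(loc.lg_id, loc.locus_id)
        assert g[0] == g[1]                     # no heterozygosity
        if m.true_class == "paralog_fixed_only":
            par = fused_karyotype.loci[loc.paralog_id]
            gp = dh.genotype(par.lg_id, par.locus_id)
            assert {g[0], gp[0]} == {"A", "B"}  # both variant states present
    # sampling: DHs from a heterozygous parent differ between seeds
    genomes = set()
    for seed in range(6):
        d = cross.simulate_doubled_haploid(p1, fused_karyotype, seed=seed)
        loc = fused_karyotype.loci[markers[0].locus_id]
        genomes.add(d.genotype(loc.lg_id, loc.locus_id))
    assert len(genomes) > 1


def _signal_marker(true_class, paralog_allele, karyo):
    loc = next(iter(karyo.loci.values()))
    return MarkerDef("Mx", loc.locus_id, "snv", true_class, paralog_allele,
                     ("A", "B"), ("A", "A")), loc


def test_noiseless_dosage_thetas(small_karyotype):
    karyo = small_karyotype
    markers = kt.place_markers(karyo, 1, 0, seed=15)
    m = markers[0]
    loc = karyo.loci[m.locus_id]
    par = karyo.loci[loc.paralog_id]
    p1, _ = cross.build_phased_parents(karyo, markers)

    def individual(geno, paralog_geno):
        h = {g.lg_id: ({}, {}) for g in karyo.linkage_groups}
        for i in (0, 1):
            h[loc.lg_id][i][loc.locus_id] = geno[i]
            h[par.lg_id][i][par.locus_id] = paralog_geno[i]
        parent = cross.PhasedParent("T", h)
        g1 = cross.Gamete({lg: dict(pair[0]) for lg, pair in h.items()})
        g2 = cross.Gamete({lg: dict(pair[1]) for lg, pair in h.items()})
        return cross.Individual("T", "parent", g1, g2)

    unique = MarkerDef("Mu", loc.locus_id, "snv", "biallelic_unique", None,
                       ("A", "B"), ("A", "A"))
    skewed = MarkerDef("Ms", loc.locus_id, "snv",
                       "biallelic_with_fixed_paralog", "B",
                       ("A", "B"), ("A", "A"))
    # A/B at a unique biallelic marker -> theta 1/2
    p = cross.simulate_assay_signal(individual("AB", "AA"), unique,
                                    karyo, noise_sd=0.0)
    assert p.theta == pytest.approx(0.5)
    # A/B over a B/B-fixed paralog -> 3:1 B:A dosage, theta 3/4
    p = cross.simulate_assay_signal(individual("AB", "BB"), skewed,
                                    karyo, noise_sd=0.0)
    assert p.theta == pytest.approx(0.75)
    assert p.intensity_B / p.intensity_A == pytest.approx(3.0)
    # A/A with no paralog sampled -> theta 0
    p = cross.simulate_assay_signal(individual("AA", "BB"), unique,
                                    karyo, noise_sd=0.0)
    assert p.theta == pytest.approx(0.0)


def test_noiseless_theta_on_dosage_grid(fused_karyotype):
    """Without noise every theta lies exactly on {k/c}, c = sampled copies."""
    markers = kt.place_markers(fused_karyotype, 60, 0, seed=16)
    p1, p2 = cross.build_phased_parents(fused_karyotype, markers)
    pop = cross.simulate_f1_population(p1, p2, fused_karyotype, 30, seed=17)
    table = cross.assay_population(pop, markers, fused_karyotype,
                                   noise_sd=0.0, seed=18)
    grid = {0.0, 0.25, 0.5, 0.75, 1.0}
    assert all(min(abs(t - g) for g in grid) < 1e-12
               for t in table["theta"])


def test_ssr_calls_and_dropout(small_karyotype):
    markers = kt.place_markers(small_karyotype, 0, 5, seed=19)
    p1, p2 = cross.build_phased_parents(small_karyotype, markers)
    pop = cross.simulate_f1_population(p1, p2, small_karyotype, 50, seed=20)
    calls = cross.simulate_ssr_calls(pop, markers, small_karyotype,
                                     dropout=0.0, seed=21)
    assert len(calls) == 5 * 50
    assert (calls["sizes"] != "").all()
    dropped = cross.simulate_ssr_calls(pop, markers, small_karyotype,
                                       dropout=0.5, seed=22)
    assert (dropped["sizes"] == "").mean() > 0.3
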