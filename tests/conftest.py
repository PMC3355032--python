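import numpy as np
import pytest

from tetralink import cross, karyotype
from tetralink.io import PipelineConfig


@pytest.fixture
def small_karyotype():
    """Two fixed-length ancestral chromosomes after WGD (no fusion)."""
    genome = [
        karyotype.AncestralChromosome(1, 100.0, 40.0),
        karyotype.AncestralChromosome(2, 80.0, 50.0),
    ]
    return karyotype.apply_wgd(genome)


@pytest.fixture
def fused_karyotype():
    genome = karyotype.simulate_ancestral_genome(
        4, (90.0, 90.0), (0.4, 0.4), seed=11)
    kt = karyotype.apply_wgd(genome)
    return karyotype.apply_insertional_fusion(kt, "2b", "1b")


def make_two_locus_cross(d_cm: float, n: int, seed: int = 0,
                         same_lg: bool = True):
    """Population segregating at two loci d_cm apart (or on different LGs),
    heterozygous A/B in parent1, homozygous A/A in parent2."""
    genome = [karyotype.AncestralChromosome(1, 120.0, 50.0),
              karyotype.AncestralChromosome(2, 120.0, 50.0)]
    kt = karyotype.apply_wgd(genome)
    a, _ = kt.place_locus("X1", 1, 10.0)
    if same_lg:
        b, _ = kt.place_locus("X2", 1, 10.0 + d_cm)
    else:
        b, _ = kt.place_locus("X2", 2, 10.0)
    haps1 = {g.lg_id: ({}, {}) for g in kt.linkage_groups}
    haps2 = {g.lg_id: ({}, {}) for g in kt.linkage_groups}
    for loc in kt.loci.values():
        het = loc.locus_id in (a.locus_id, b.locus_id)
        haps1[loc.lg_id][0][loc.locus_id] = "A"
        haps1[loc.lg_id][1][loc.locus_id] = "B" if het else "A"
        haps2[loc.lg_id][0][loc.locus_id] = "A"
        haps2[loc.lg_id][1][loc.locus_id] = "A"
    p1 = cross.PhasedParent("P1", haps1)
    p2 = cross.PhasedParent("P2", haps2)
    pop = cross.simulate_f1_population(p1, p2, kt, n, seed=seed)
    return kt, p1, p2, pop, a, b


# ---------------------------------------------------------------------------
# independent mini-simulator for CP genotype tokens (used as an oracle-side
# data source by the linkage tests; deliberately does not reuse the package's
# meiosis machinery)

PARENTS = {
    "lmxll": (("l", "m"), ("l", "l")),
    "nnxnp": (("n", "n"), ("n", "p")),
    "hkxhk": (("h", "k"), ("h", "k")),
    "efxeg": (("e", "f"), ("e", "g")),
    "abxcd": (("a", "b"), ("c", "d")),
}


def simulate_cp_chain(codes, positions_cm, n, rng, marker_ids=None):
    """Token calls for a chain of CP markers on one chromosome.

    Each parent transmits a haplotype index per marker; under no
    interference, consecutive indices flip independently with the Haldane
    rf of the inter-marker distance.  Returns {marker_id: CPCall}.
    """
    from tetralink.calling import CPCall

    m = len(codes)
    ids = marker_ids or [f"T{k:03d}" for k in range(m)]
    rfs = [0.5 * (1 - np.exp(-abs(positions_cm[k + 1] - positions_cm[k]) / 50.0))
           for k in range(m - 1)]
    calls = {mid: {} for mid in ids}
    for i in range(n):
        ind = f"I{i:04d}"
        idx = {}
        for parent in (0, 1):
            a = int(rng.integers(2))
            chain = [a]
            for r in rfs:
                a = a ^ (rng.random() < r)
                chain.append(int(a))
            idx[parent] = chain
        for k, code in enumerate(codes):
            p1, p2 = PARENTS[code]
            tok = "".join(sorted((p1[idx[0][k]], p2[idx[1][k]])))
            calls[ids[k]][ind] = tok
    return {mid: CPCall(mid, codes[k], calls[mid])
            for k, mid in enumerate(ids)}


def simulate_cp_pair(code_i, code_j, r, n, rng):
    """Token calls for one marker pair at true recombination fraction r."""
    calls = simulate_cp_chain(
        [code_i, code_j],
        [0.0, -50.0 * np.log(1 - 2 * r) if r > 0 else 0.0], n, rng)
    a, b = sorted(calls)
    return calls[a], calls[b]


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full-scale pipeline run at the default study conditions.

    Session-scoped: the heavy simulation (500 SNV + 60 SSR markers,
    221 F1 individuals, full map and synteny analysis) is shared by every
    test that checks an end-to-end recovery property.
    """
    from tetralink.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PipelineConfig(seed=1), out)
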