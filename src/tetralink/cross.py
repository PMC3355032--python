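"""Outbred-cross simulation: meiosis, F1 progeny, doubled haploids, and assay signal.

Meiosis is strictly disomic: crossovers occur only between the two
homologous haplotypes of one linkage group, never between homoeologous
groups, matching the complete preferential pairing inferred from the real
mapping population.  Crossovers per LG are Poisson with mean
``length_cM / 100`` and uniform positions — the no-interference model under
which recombination fractions obey the Haldane mapping function.

The two-channel assay model is a dosage model: each channel's intensity is
``gain`` times the number of copies of its allele summed over the loci the
probe samples (the segregating locus, plus its homoeologous paralog when
the marker class involves one), plus truncated Gaussian noise.  A fixed
paralog therefore shifts the theta = B/(A+B) cluster grid from {0, 1/2, 1}
to {1/2, 3/4, 1} or {0, 1/4, 1/2} — an A/B heterozygote over a B/B-fixed
paralog yields a 3:1 B:A signal ratio, theta = 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .karyotype import KaryotypeTruth, MarkerDef


@dataclass
class PhasedParent:
    """Two phased haplotypes per linkage group, mapping locus_id -> allele."""

    parent_id: str
    haplotypes: dict[str, tuple[dict[str, object], dict[str, object]]]

    def alleles_at(self, lg_id: str, locus_id: str) -> tuple:
        h0, h1 = self.haplotypes[lg_id]
        return h0[locus_id], h1[locus_id]


@dataclass
class Gamete:
    """One meiotic product: a haplotype per LG plus crossover positions."""

    haplotype: dict[str, dict[str, object]]
    crossovers: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class Individual:
    individual_id: str
    origin: str                       # 'f1' | 'doubled_haploid' | 'parent'
    gamete1: Gamete
    gamete2: Gamete

    def genotype(self, lg_id: str, locus_id: str) -> tuple:
        return (self.gamete1.haplotype[lg_id][locus_id],
                self.gamete2.haplotype[lg_id][locus_id])


@dataclass(frozen=True)
class SignalPoint:
    marker_id: str
    individual_id: str
    intensity_A: float
    intensity_B: float

    @property
    def R(self) -> float:
        return self.intensity_A + self.intensity_B

    @property
    def theta(self) -> float:
        if self.R <= 0:
            return float("nan")
        return self.intensity_B / self.R


def build_phased_parents(karyotype: KaryotypeTruth, markers: list[MarkerDef],
                         ) -> tuple[PhasedParent, PhasedParent]:
    """Construct the two parents' phased haplotypes from marker definitions.

    The segregating locus carries the marker's phased parental genotype;
    the homoeologous locus carries the fixed paralog allele (on both
    haplotypes of both parents) when the marker class involves one, and a
    neutral fixed allele otherwise.
    """
    haps1 = {g.lg_id: ({}, {}) for g in karyotype.linkage_groups}
    haps2 = {g.lg_id: ({}, {}) for g in karyotype.linkage_groups}
    for m in markers:
        locus = karyotype.loci[m.locus_id]
        paralog = karyotype.loci[locus.paralog_id]
        for haps, geno in ((haps1, m.parent1_genotype), (haps2, m.parent2_genotype)):
            haps[locus.lg_id][0][locus.locus_id] = geno[0]
            haps[locus.lg_id][1][locus.locus_id] = geno[1]
            fixed = m.paralog_fixed_allele if m.paralog_fixed_allele else "A"
            haps[paralog.lg_id][0][paralog.locus_id] = fixed
            haps[paralog.lg_id][1][paralog.locus_id] = fixed
    return (PhasedParent("P1", haps1), PhasedParent("P2", haps2))


_LG_INDEX_CACHE: dict[tuple[int, int], dict[str, tuple[list[str], np.ndarray]]] = {}


def _lg_index(karyotype: KaryotypeTruth) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-LG (locus_ids, positions) arrays, cached per karyotype state."""
    key = (id(karyotype), len(karyotype.loci))
    cached = _LG_INDEX_CACHE.get(key)
    if cached is not None:
        return cached
    index: dict[str, list[tuple[str, float]]] = {
        g.lg_id: [] for g in karyotype.linkage_groups}
    for l in karyotype.loci.values():
        index[l.lg_id].append((l.locus_id, l.pos_cM))
    out = {lg: ([i for i, _ in pairs],
                np.array([p for _, p in pairs], dtype=float))
           for lg, pairs in index.items()}
    _LG_INDEX_CACHE.clear()
    _LG_INDEX_CACHE[key] = out
    return out


def simulate_meiosis(parent: PhasedParent, karyotype: KaryotypeTruth,
                     rng: np.random.Generator | int = 0) -> Gamete:
    """One gamete under the Haldane (no-interference) crossover model."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    index = _lg_index(karyotype)
    haplotype: dict[str, dict[str, object]] = {}
    crossovers: dict[str, list[float]] = {}
    for g in karyotype.linkage_groups:
        length = g.length_cM
        n_xo = rng.poisson(length / 100.0)
        xo = np.sort(rng.uniform(0, length, size=n_xo))
        start = int(rng.integers(2))
        h0, h1 = parent.haplotypes[g.lg_id]
        haps = (h0, h1)
        locus_ids, positions = index[g.lg_id]
        which = (start + np.searchsorted(xo, positions, side="left")) % 2
        haplotype[g.lg_id] = {
            lid: haps[w][lid] for lid, w in zip(locus_ids, which)
            if lid in haps[0]}
        crossovers[g.lg_id] = [float(x) for x in xo]
    return Gamete(haplotype=haplotype, crossovers=crossovers)


def simulate_f1_population(p1: PhasedParent, p2: PhasedParent,
                           karyotype: KaryotypeTruth, n: int,
                           seed: int = 0) -> list[Individual]:
    """An F1 full-sib family: one gamete from each parent per individual."""
    if n < 1:
        raise InvalidParameterError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    return [Individual(f"F1_{i:04d}", "f1",
                       simulate_meiosis(p1, karyotype, rng),
                       simulate_meiosis(p2, karyotype, rng))
            for i in range(n)]


def simulate_doubled_haploid(parent: PhasedParent, karyotype: KaryotypeTruth,
                             seed: int = 0, individual_id: str = "DH_0000"
                             ) -> Individual:
    """One gamete duplicated into both genome copies: homozygous everywhere
    a single locus is concerned, yet still carrying both fixed-paralog states."""
    rng = np.random.default_rng(seed)
    g = simulate_meiosis(parent, karyotype, rng)
    g2 = Gamete(haplotype={k: dict(v) for k, v in g.haplotype.items()},
                crossovers={k: list(v) for k, v in g.crossovers.items()})
    return Individual(individual_id, "doubled_haploid", g, g2)


def apply_segregation_distortion(pop: list[Individual], karyotype: KaryotypeTruth,
                                 locus_id: str,
                                 allele_survival: dict[object, float],
                                 seed: int = 0) -> list[Individual]:
    """Viability selection after gamete union.

    Each individual survives with probability equal to the product of the
    survival weights of its two alleles at ``locus_id`` (weight 1 for
    alleles not listed).  A weight of 0.5 on one allele of a 1:1 locus
    yields an expected surviving ratio of 2:1.
    """
    for w in allele_survival.values():
        if not (0 < w <= 1):
            raise InvalidParameterError("survival weights must be in (0, 1]")
    if locus_id not in karyotype.loci:
        raise InvalidParameterError(f"unknown locus {locus_id!r}")
    lg_id = karyotype.loci[locus_id].lg_id
    rng = np.random.default_rng(seed)
    out = []
    for ind in pop:
        a1, a2 = ind.genotype(lg_id, locus_id)
        p = allele_survival.get(a1, 1.0) * allele_survival.get(a2, 1.0)
        if rng.random() < p:
            out.append(ind)
    return out


def simulate_assay_signal(ind: Individual, marker: MarkerDef,
                          karyotype: KaryotypeTruth, gain: float = 1.0,
                          noise_sd: float = 0.05,
                          rng: np.random.Generator | int = 0) -> SignalPoint:
    """Two-channel intensities under the dosage model (see module docstring)."""
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    locus = karyotype.loci[marker.locus_id]
    alleles = list(ind.genotype(locus.lg_id, marker.locus_id))
    if marker.samples_paralog():
        paralog = karyotype.loci[locus.paralog_id]
        alleles += list(ind.genotype(paralog.lg_id, paralog.locus_id))
    copies_a = sum(1 for a in alleles if a == "A")
    copies_b = sum(1 for a in alleles if a == "B")
    ia = gain * copies_a
    ib = gain * copies_b
    if noise_sd > 0:
        ia = max(0.0, ia + float(rng.normal(0, noise_sd)))
        ib = max(0.0, ib + float(rng.normal(0, noise_sd)))
    return SignalPoint(marker.marker_id, ind.individual_id, ia, ib)


def assay_population(individuals: list[Individual], markers: list[MarkerDef],
                     karyotype: KaryotypeTruth, gain: float = 1.0,
                     noise_sd: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Long-format intensity table for all SNV markers x individuals."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in markers:
        if m.marker_type != "snv":
            continue
        for ind in individuals:
            p = simulate_assay_signal(ind, m, karyotype, gain, noise_sd, rng)
            rows.append((m.marker_id, ind.individual_id,
                         p.intensity_A, p.intensity_B, p.theta, p.R))
    return pd.DataFrame(rows, columns=[
        "marker_id", "individual_id", "intensity_A", "intensity_B",
        "theta", "R"])


def simulate_ssr_calls(individuals: list[Individual], markers: list[MarkerDef],
                       karyotype: KaryotypeTruth, dropout: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Fragment-analysis abstraction: observed allele-size sets per individual.

    With probability ``dropout`` per individual x marker the call is missing
    (empty size set), emulating failed amplification.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m in markers:
        if m.marker_type != "ssr":
            continue
        locus = karyotype.loci[m.locus_id]
        for ind in individuals:
            if dropout > 0 and rng.random() < dropout:
                rows.append((m.marker_id, ind.individual_id, ""))
                continue
            sizes = sorted(set(ind.genotype(locus.lg_id, m.locus_id)))
            rows.append((m.marker_id, ind.individual_id,
                         ",".join(str(s) for s in sizes)))
    return pd.DataFrame(rows, columns=["marker_id", "individual_id", "sizes"])
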