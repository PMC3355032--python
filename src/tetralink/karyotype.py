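"""Ground-truth genome simulation for a recently tetraploidized outbreeder.

The simulated history mirrors the karyotype evolution of a recently
tetraploidized grass whose diploid relative retains the ancestral
karyotype: an ancestral genome of N chromosomes
(N = 10 by default) undergoes whole-genome duplication, after
which one chromosome copy is inserted into the centromeric region of another
copy ("insertional dysploid reduction"), leaving 2N - 1 linkage groups.

Every marker locus descends from a single ancestral position and therefore
has exactly two post-duplication copies (homoeologs/paralogs).  The truth
tables produced here drive the cross simulator and serve as the reference
against which marker-class recovery, map order, and synteny detection are
scored.

Coordinates are genetic (cM), 0-based and continuous; segment intervals are
half-open ``[start, end)``.  A synthetic "physical" coordinate in Mb is an
affine image of the genetic one (``MB_PER_CM`` Mb per cM), used only for
dot plots against the ancestral reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidOperationError, InvalidParameterError

#: Synthetic physical scale: 1 cM corresponds to 0.75 Mb on the ancestral
#: reference.  Only ratios matter for dot plots, not the absolute value.
MB_PER_CM = 0.75

MARKER_CLASSES = (
    "biallelic_unique",
    "biallelic_with_fixed_paralog",
    "paralog_fixed_only",
    "monomorphic",
)

#: Default class mix for SNV markers.  One third of assayable variants are
#: fixed differences between paralogs (single central cluster); of the
#: segregating remainder, 26% have their signal skewed by a fixed paralog.
DEFAULT_CLASS_PROPORTIONS = {
    "biallelic_unique": 0.4958,
    "biallelic_with_fixed_paralog": 0.1742,
    "paralog_fixed_only": 0.33,
    "monomorphic": 0.0,
}

#: Which parent(s) are heterozygous at a segregating SNV marker, with the
#: observed relative frequencies (heterozygous in parent1 / parent2 / both).
DEFAULT_INFORMATIVENESS = {"p1": 0.32, "p2": 0.39, "both": 0.29}

SSR_CONFIGS = ("lmxll", "nnxnp", "hkxhk", "efxeg", "abxcd")
DEFAULT_SSR_CONFIG_PROPORTIONS = {
    "lmxll": 0.25,
    "nnxnp": 0.25,
    "hkxhk": 0.15,
    "efxeg": 0.20,
    "abxcd": 0.15,
}


@dataclass(frozen=True)
class AncestralChromosome:
    """One chromosome of the pre-duplication genome."""

    id: int
    length_cM: float
    centromere_cM: float

    def __post_init__(self):
        if self.length_cM <= 0:
            raise InvalidParameterError(
                f"chromosome {self.id}: length must be positive, got {self.length_cM}"
            )
        if not (0 < self.centromere_cM < self.length_cM):
            raise InvalidParameterError(
                f"chromosome {self.id}: centromere must lie strictly inside (0, length)"
            )


@dataclass(frozen=True)
class Segment:
    """A contiguous ancestral interval embedded in a linkage group.

    ``start``/``end`` are ancestral cM coordinates (half-open); ``copy``
    identifies which of the two post-WGD copies the segment descends from.
    ``orientation`` is +1 when LG position increases with ancestral
    position, -1 when reversed.
    """

    anc_chrom: int
    copy: int
    start: float
    end: float
    orientation: int = 1

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class LinkageGroup:
    """A post-duplication chromosome, possibly the product of a fusion."""

    lg_id: str
    segments: list[Segment]
    fused: bool = False

    @property
    def length_cM(self) -> float:
        return sum(s.length for s in self.segments)

    def locate(self, anc_chrom: int, copy: int, anc_pos: float) -> float | None:
        """LG position of an ancestral locus, or None if not on this LG."""
        offset = 0.0
        for seg in self.segments:
            if seg.anc_chrom == anc_chrom and seg.copy == copy and (
                seg.start <= anc_pos < seg.end
            ):
                if seg.orientation > 0:
                    return offset + (anc_pos - seg.start)
                return offset + (seg.end - anc_pos)
            offset += seg.length
        return None


@dataclass(frozen=True)
class TrueLocus:
    locus_id: str
    lg_id: str
    pos_cM: float
    ancestral_chrom: int
    ancestral_pos_cM: float
    ancestral_pos_Mb: float
    paralog_id: str | None


@dataclass
class KaryotypeTruth:
    """The simulated genome: linkage groups plus the locus registry."""

    ancestral: list[AncestralChromosome]
    linkage_groups: list[LinkageGroup]
    loci: dict[str, TrueLocus] = field(default_factory=dict)

    def lg(self, lg_id: str) -> LinkageGroup:
        for g in self.linkage_groups:
            if g.lg_id == lg_id:
                return g
        raise KeyError(lg_id)

    def chromosome(self, chrom_id: int) -> AncestralChromosome:
        for c in self.ancestral:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def place_locus(self, locus_id_base: str, anc_chrom: int, anc_pos: float
                    ) -> tuple[TrueLocus, TrueLocus]:
        """Register the two homoeologous descendants of one ancestral locus."""
        copies = []
        for copy in (0, 1):
            hit = None
            for g in self.linkage_groups:
                pos = g.locate(anc_chrom, copy, anc_pos)
                if pos is not None:
                    hit = (g.lg_id, pos)
                    break
            if hit is None:
                raise InvalidOperationError(
                    f"ancestral position {anc_chrom}:{anc_pos} has no descendant "
                    f"for copy {copy}"
                )
            copies.append(hit)
        ids = (f"{locus_id_base}a", f"{locus_id_base}b")
        pair = []
        for i, copy in enumerate((0, 1)):
            lg_id, pos = copies[i]
            pair.append(TrueLocus(
                locus_id=ids[i], lg_id=lg_id, pos_cM=pos,
                ancestral_chrom=anc_chrom, ancestral_pos_cM=anc_pos,
                ancestral_pos_Mb=anc_pos * MB_PER_CM,
                paralog_id=ids[1 - i]))
        self.loci[pair[0].locus_id] = pair[0]
        self.loci[pair[1].locus_id] = pair[1]
        return pair[0], pair[1]

    def truth_table(self) -> pd.DataFrame:
        rows = [{
            "locus_id": l.locus_id, "lg_id": l.lg_id, "pos_cM": l.pos_cM,
            "ancestral_chrom": l.ancestral_chrom,
            "ancestral_pos_Mb": l.ancestral_pos_Mb,
            "paralog_id": l.paralog_id,
        } for l in self.loci.values()]
        return pd.DataFrame(rows)


@dataclass
class MarkerDef:
    """Definition of one assayable marker on the simulated genome.

    ``locus_id`` is the (potentially) segregating locus the probe targets;
    when the marker class involves a paralog the homoeologous locus also
    contributes signal.  Parental genotypes are phased: the tuple order is
    the haplotype order used by the meiosis simulator.
    """

    marker_id: str
    locus_id: str
    marker_type: str                       # 'snv' | 'ssr'
    true_class: str
    paralog_fixed_allele: str | None       # 'A' | 'B' | None
    parent1_genotype: tuple                # phased (hap0, hap1) at locus
    parent2_genotype: tuple
    ssr_config: str | None = None          # canonical CP code for SSR markers

    def samples_paralog(self) -> bool:
        return self.true_class in ("biallelic_with_fixed_paralog",
                                   "paralog_fixed_only")


def simulate_ancestral_genome(n_chrom: int,
                              length_range_cM: tuple[float, float] = (85.0, 105.0),
                              centromere_fraction_range: tuple[float, float] = (0.35, 0.65),
                              seed: int = 0) -> list[AncestralChromosome]:
    """Draw the pre-duplication genome.

    Lengths are uniform over ``length_range_cM`` (default centred near
    1782/19 = 94 cM so the duplicated map mimics the observed one) and the
    centromere sits at a uniform fraction of the length.
    """
    if n_chrom < 2:
        raise InvalidParameterError(f"need at least 2 chromosomes, got {n_chrom}")
    lo, hi = length_range_cM
    if lo <= 0 or hi < lo:
        raise InvalidParameterError(f"invalid length range {length_range_cM}")
    flo, fhi = centromere_fraction_range
    if not (0 < flo <= fhi < 1):
        raise InvalidParameterError(
            f"invalid centromere fraction range {centromere_fraction_range}")
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(1, n_chrom + 1):
        length = float(rng.uniform(lo, hi))
        frac = float(rng.uniform(flo, fhi))
        chroms.append(AncestralChromosome(
            id=i, length_cM=length, centromere_cM=frac * length))
    return chroms


def apply_wgd(genome: list[AncestralChromosome], seed: int = 0) -> KaryotypeTruth:
    """Whole-genome duplication: every chromosome gets two disomic copies.

    Genetic lengths are conserved (the observed duplicated map is no longer
    than the ancestral one, so cM length is treated as a free parameter
    fixed at the ancestral value).  Copies are labelled ``<id>a``/``<id>b``
    and never pair in downstream meiosis.
    """
    if not genome:
        raise InvalidParameterError("empty genome")
    groups = []
    for chrom in genome:
        for copy, tag in ((0, "a"), (1, "b")):
            groups.append(LinkageGroup(
                lg_id=f"{chrom.id}{tag}",
                segments=[Segment(chrom.id, copy, 0.0, chrom.length_cM, 1)]))
    return KaryotypeTruth(ancestral=list(genome), linkage_groups=groups)


def apply_insertional_fusion(karyotype: KaryotypeTruth, inserted_lg: str,
                             target_lg: str,
                             breakpoint_cM: float | None = None) -> KaryotypeTruth:
    """Insert one whole LG into the centromeric region of another.

    The inserted chromosome is circularly permuted at ``breakpoint_cM``
    (default: its centromere) so that its original telomeric ends become
    interior to the fused chromosome, and spliced into the target at the
    target's centromere.  Genetic length is conserved; the LG count drops
    by one.  The un-inserted homoeologs of both chromosomes are untouched.
    """
    if inserted_lg == target_lg:
        raise InvalidOperationError("cannot fuse a linkage group with itself")
    ins = karyotype.lg(inserted_lg)
    tgt = karyotype.lg(target_lg)
    if ins.fused or tgt.fused:
        raise InvalidOperationError("cannot fuse an already-fused linkage group")
    if len(ins.segments) != 1 or len(tgt.segments) != 1:
        raise InvalidOperationError("fusion partners must be single-segment LGs")

    ins_seg, tgt_seg = ins.segments[0], tgt.segments[0]
    ins_chrom = karyotype.chromosome(ins_seg.anc_chrom)
    tgt_chrom = karyotype.chromosome(tgt_seg.anc_chrom)
    brk = ins_chrom.centromere_cM if breakpoint_cM is None else breakpoint_cM
    if not (0 < brk < ins_chrom.length_cM):
        raise InvalidParameterError("breakpoint must lie inside the inserted LG")
    cen = tgt_chrom.centromere_cM

    fused = LinkageGroup(
        lg_id=f"{target_lg}+{inserted_lg}",
        fused=True,
        segments=[
            Segment(tgt_seg.anc_chrom, tgt_seg.copy, 0.0, cen, 1),
            # circular permutation: distal part first, then proximal part;
            # the two original telomeres (anc pos L and 0) end up adjacent
            # in the interior of the fused chromosome
            Segment(ins_seg.anc_chrom, ins_seg.copy, brk, ins_chrom.length_cM, 1),
            Segment(ins_seg.anc_chrom, ins_seg.copy, 0.0, brk, 1),
            Segment(tgt_seg.anc_chrom, tgt_seg.copy, cen, tgt_chrom.length_cM, 1),
        ])
    groups = [g for g in karyotype.linkage_groups
              if g.lg_id not in (inserted_lg, target_lg)]
    groups.append(fused)
    groups.sort(key=lambda g: g.lg_id)
    return KaryotypeTruth(ancestral=karyotype.ancestral, linkage_groups=groups,
                          loci=dict(karyotype.loci))


def _draw_genotypes(true_class: str, informativeness: str, rng: np.random.Generator
                    ) -> tuple[tuple, tuple, str | None]:
    """Phased parental genotypes at the segregating locus + paralog allele."""
    def het():
        return ("A", "B") if rng.random() < 0.5 else ("B", "A")

    def hom():
        a = "A" if rng.random() < 0.5 else "B"
        return (a, a)

    if true_class == "monomorphic":
        return ("A", "A"), ("A", "A"), None
    if true_class == "paralog_fixed_only":
        # primary locus fixed for one allele, paralog fixed for the other
        a = "A" if rng.random() < 0.5 else "B"
        other = "B" if a == "A" else "A"
        return (a, a), (a, a), other
    p1 = het() if informativeness in ("p1", "both") else hom()
    p2 = het() if informativeness in ("p2", "both") else hom()
    paralog = None
    if true_class == "biallelic_with_fixed_paralog":
        paralog = "A" if rng.random() < 0.5 else "B"
    return p1, p2, paralog


def _draw_ssr(config: str, rng: np.random.Generator) -> tuple[tuple, tuple]:
    """Parental phased allele sizes (bp) realizing one CP configuration."""
    sizes = 150 + 2 * rng.choice(40, size=4, replace=False)
    a, b, c, d = (int(s) for s in sizes)
    if config == "lmxll":
        return (a, b), (a, a)
    if config == "nnxnp":
        return (a, a), (a, b)
    if config == "hkxhk":
        return (a, b), (a, b)
    if config == "efxeg":
        return (a, b), (a, c)
    if config == "abxcd":
        return (a, b), (c, d)
    raise InvalidParameterError(f"unknown ssr configuration {config!r}")


def place_markers(karyotype: KaryotypeTruth, n_snv: int, n_ssr: int = 0,
                  class_proportions: dict[str, float] | None = None,
                  informativeness: dict[str, float] | None = None,
                  ssr_config_proportions: dict[str, float] | None = None,
                  seed: int = 0) -> list[MarkerDef]:
    """Place markers uniformly over the genome and register their loci.

    Each marker's ancestral position is drawn length-weighted across
    chromosomes and uniformly within one; both homoeologous descendant loci
    are registered in ``karyotype.loci`` and the probe targets one of the
    two copies at random.  SNV classes follow ``class_proportions``
    (multinomial); SSR markers are scored directly from fragment sizes and
    are always segregating, with their CP configuration drawn from
    ``ssr_config_proportions``.
    """
    if n_snv < 0 or n_ssr < 0:
        raise InvalidParameterError("marker counts must be non-negative")
    props = dict(DEFAULT_CLASS_PROPORTIONS if class_proportions is None
                 else class_proportions)
    if abs(sum(props.values()) - 1.0) > 1e-6:
        raise InvalidParameterError("class proportions must sum to 1")
    for k in props:
        if k not in MARKER_CLASSES:
            raise InvalidParameterError(f"unknown marker class {k!r}")
    info = dict(DEFAULT_INFORMATIVENESS if informativeness is None
                else informativeness)
    ssr_props = dict(DEFAULT_SSR_CONFIG_PROPORTIONS
                     if ssr_config_proportions is None else ssr_config_proportions)

    rng = np.random.default_rng(seed)
    lengths = np.array([c.length_cM for c in karyotype.ancestral])
    chrom_ids = [c.id for c in karyotype.ancestral]
    weights = lengths / lengths.sum()

    classes = list(props)
    class_p = np.array([props[c] for c in classes])
    info_keys = list(info)
    info_p = np.array([info[k] for k in info_keys], dtype=float)
    info_p = info_p / info_p.sum()
    ssr_keys = list(ssr_props)
    ssr_p = np.array([ssr_props[k] for k in ssr_keys], dtype=float)
    ssr_p = ssr_p / ssr_p.sum()

    markers: list[MarkerDef] = []
    for i in range(n_snv + n_ssr):
        is_ssr = i >= n_snv
        ci = int(rng.choice(len(chrom_ids), p=weights))
        chrom = karyotype.ancestral[ci]
        pos = float(rng.uniform(0, chrom.length_cM))
        base = f"L{i:04d}"
        loc_a, loc_b = karyotype.place_locus(base, chrom.id, pos)
        target = loc_a if rng.random() < 0.5 else loc_b
        if is_ssr:
            config = str(rng.choice(ssr_keys, p=ssr_p))
            p1, p2 = _draw_ssr(config, rng)
            markers.append(MarkerDef(
                marker_id=f"S{i:04d}", locus_id=target.locus_id,
                marker_type="ssr", true_class="biallelic_unique",
                paralog_fixed_allele=None, parent1_genotype=p1,
                parent2_genotype=p2, ssr_config=config))
        else:
            true_class = str(rng.choice(classes, p=class_p))
            inf = str(rng.choice(info_keys, p=info_p))
            p1, p2, paralog = _draw_genotypes(true_class, inf, rng)
            markers.append(MarkerDef(
                marker_id=f"M{i:04d}", locus_id=target.locus_id,
                marker_type="snv", true_class=true_class,
                paralog_fixed_allele=paralog,
                parent1_genotype=p1, parent2_genotype=p2))
    return markers


def marker_table(markers: list[MarkerDef]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker_id": m.marker_id, "locus_id": m.locus_id,
        "marker_type": m.marker_type, "true_class": m.true_class,
        "paralog_fixed_allele": m.paralog_fixed_allele or "none",
        "parent1_genotype": "/".join(str(a) for a in m.parent1_genotype),
        "parent2_genotype": "/".join(str(a) for a in m.parent2_genotype),
        "ssr_config": m.ssr_config or "",
    } for m in markers])
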