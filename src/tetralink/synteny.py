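"""Comparative analysis against the ancestral reference genome.

Markers are assigned to reference positions from a BLAST-like tabular hit
list by a best-hit rule: the hit with the most identical residues wins
provided it covers at least ``min_share`` of the probe (default 80%), with
exact ties left unassigned.  The resulting dot plot (genetic position on a
linkage group vs physical position on the reference) exposes two genome
events: a whole-genome duplication appears as a 1 reference chromosome : 2
linkage group correspondence, and an insertional chromosome fusion appears
as a linkage group whose marker runs form an outer-inner-outer sandwich —
two arms of one reference chromosome flanking an essentially complete copy
of another, with the inner chromosome's original ends interior to the
block (the insertional signature: its telomeres were lost in the fusion).

Real sequence alignment is out of scope; the hit-table fabricator below
derives hits from simulated truth with configurable noise, and real tables
in the same layout can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .karyotype import KaryotypeTruth, MarkerDef, MB_PER_CM

HIT_COLUMNS = ["marker_id", "ref_chrom", "ref_pos_Mb", "identical_residues",
               "probe_length"]


@dataclass
class FusionCall:
    lg: object
    outer_ref_chrom: int
    inner_ref_chrom: int
    boundary_start_cM: float
    boundary_end_cM: float
    inner_ends_interior: bool


def generate_hit_table(karyotype: KaryotypeTruth, markers: list[MarkerDef],
                       probe_length: int = 101, p_unassignable: float = 0.05,
                       spurious_rate: float = 0.3, seed: int = 0
                       ) -> pd.DataFrame:
    """Fabricate alignment hits from simulated truth.

    Every marker descends from a single ancestral position, so its true hit
    lies there with high identity; with probability ``p_unassignable`` the
    best identity falls below the 80% share threshold (diverged probe).  A
    Poisson number of spurious lower-identity hits at random reference
    positions is added per marker.
    """
    rng = np.random.default_rng(seed)
    lengths = {c.id: c.length_cM * MB_PER_CM for c in karyotype.ancestral}
    chrom_ids = list(lengths)
    rows = []
    for m in markers:
        locus = karyotype.loci[m.locus_id]
        if rng.random() < p_unassignable:
            best = int(rng.integers(int(0.5 * probe_length),
                                    int(0.8 * probe_length)))
        else:
            best = int(rng.integers(int(0.93 * probe_length), probe_length + 1))
        rows.append((m.marker_id, locus.ancestral_chrom,
                     locus.ancestral_pos_Mb, best, probe_length))
        for _ in range(rng.poisson(spurious_rate)):
            c = chrom_ids[int(rng.integers(len(chrom_ids)))]
            pos = float(rng.uniform(0, lengths[c]))
            ident = int(rng.integers(int(0.3 * probe_length),
                                     max(best - 3, int(0.3 * probe_length) + 1)))
            rows.append((m.marker_id, c, pos, ident, probe_length))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def assign_orthologs(hits: pd.DataFrame, min_share: float = 0.8) -> pd.DataFrame:
    """Best-hit reference assignment per marker.

    Returns one row per marker with columns (marker_id, ref_chrom,
    ref_pos_Mb, assigned).  The best hit must carry strictly more identical
    residues than any competitor (exact ties -> unassigned) and share at
    least ``min_share`` of the probe residues.
    """
    if (hits["identical_residues"] > hits["probe_length"]).any():
        raise InvalidParameterError("identical_residues exceeds probe_length")
    rows = []
    for marker_id, grp in hits.groupby("marker_id", sort=True):
        best_n = grp["identical_residues"].max()
        top = grp[grp["identical_residues"] == best_n]
        share = best_n / top["probe_length"].iloc[0]
        if len(top) > 1 or share < min_share:
            rows.append((marker_id, None, np.nan, False))
        else:
            r = top.iloc[0]
            rows.append((marker_id, r["ref_chrom"], float(r["ref_pos_Mb"]), True))
    out = pd.DataFrame({
        "marker_id": [r[0] for r in rows],
        "ref_chrom": pd.Series([r[1] for r in rows], dtype=object),
        "ref_pos_Mb": [r[2] for r in rows],
        "assigned": [r[3] for r in rows],
    })
    return out


def build_dot_plot(marker_positions: dict[str, tuple[object, float]],
                   assignments: pd.DataFrame
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Join map positions with reference assignments.

    ``marker_positions`` maps marker_id -> (lg, pos_cM).  Returns the dot
    plot table (one row per assigned, mapped marker) and the list of mapped
    but unassigned markers.
    """
    rows, unassigned = [], []
    for rec in assignments.itertuples():
        if rec.marker_id not in marker_positions:
            continue
        lg, pos = marker_positions[rec.marker_id]
        if rec.assigned:
            rows.append((rec.marker_id, lg, pos, rec.ref_chrom, rec.ref_pos_Mb))
        else:
            unassigned.append(str(rec.marker_id))
    dot = pd.DataFrame(rows, columns=["marker_id", "lg", "pos_cM",
                                      "ref_chrom", "ref_pos_Mb"])
    return dot.sort_values(["lg", "pos_cM", "marker_id"]).reset_index(drop=True), \
        sorted(unassigned)


def detect_wgd(dotplot: pd.DataFrame, min_markers: int = 5
               ) -> tuple[dict[int, list], bool]:
    """Reference chromosome -> linkage groups association and the WGD flag.

    A chromosome is associated with every LG carrying at least
    ``min_markers`` of its markers; the duplication flag is raised when at
    least 80% of reference chromosomes associate with exactly two LGs.
    """
    assoc: dict[int, list] = {}
    for chrom, grp in dotplot.groupby("ref_chrom", sort=True):
        lgs = [lg for lg, cnt in grp["lg"].value_counts().items()
               if cnt >= min_markers]
        assoc[chrom] = sorted(lgs, key=str)
    if not assoc:
        return assoc, False
    n_two = sum(1 for lgs in assoc.values() if len(lgs) == 2)
    return assoc, n_two >= 0.8 * len(assoc)


def _runs(chroms: list, min_block: int) -> list[tuple[object, int, int]]:
    """Maximal same-chromosome runs of length >= min_block, after dropping
    isolated singletons (markers whose neighbors both disagree)."""
    keep = []
    for i, c in enumerate(chroms):
        prev_ok = i > 0 and chroms[i - 1] == c
        next_ok = i < len(chroms) - 1 and chroms[i + 1] == c
        if prev_ok or next_ok:
            keep.append(i)
    runs = []
    for i in keep:
        c = chroms[i]
        if runs and runs[-1][0] == c and i <= runs[-1][2] + 2:
            runs[-1] = (c, runs[-1][1], i)
        else:
            runs.append((c, i, i))
    return [(c, a, b) for c, a, b in runs if b - a + 1 >= min_block]


def detect_fusion(dotplot: pd.DataFrame, min_block: int = 4
                  ) -> list[FusionCall]:
    """Detect insertional fusions on each linkage group of a dot plot.

    A fusion is called when an LG's assigned markers form at least three
    maximal same-chromosome runs in an outer-inner-outer sandwich: the two
    outer runs are the arms of one chromosome (disjoint reference
    intervals) and the inner run covers most of the other chromosome.  The
    insertional signature is set when the inner chromosome's extreme
    reference positions lie interior to the inserted block in map order.
    """
    calls: list[FusionCall] = []
    if dotplot.empty:
        return calls
    chrom_extent = dotplot.groupby("ref_chrom")["ref_pos_Mb"].agg(["min", "max"])
    for lg, grp in dotplot.groupby("lg", sort=True):
        grp = grp.sort_values(["pos_cM", "marker_id"]).reset_index(drop=True)
        chroms = list(grp["ref_chrom"])
        runs = _runs(chroms, min_block)
        if len(runs) < 3 or len({c for c, _, _ in runs}) < 2:
            continue
        outer_c = runs[0][0]
        inner_candidates = [r for r in runs[1:-1] if r[0] != outer_c]
        if runs[-1][0] != outer_c or not inner_candidates:
            continue
        inner_c = inner_candidates[0][0]
        if any(r[0] != inner_c for r in inner_candidates):
            continue
        a0, a1 = runs[0][1], runs[0][2]
        z0, z1 = runs[-1][1], runs[-1][2]
        out1 = grp["ref_pos_Mb"].iloc[a0:a1 + 1]
        out2 = grp["ref_pos_Mb"].iloc[z0:z1 + 1]
        if not (out1.max() <= out2.min() or out2.max() <= out1.min()):
            continue   # outer runs must be the two distinct arms
        i0 = inner_candidates[0][1]
        i1 = inner_candidates[-1][2]
        inner = grp.iloc[i0:i1 + 1]
        inner = inner[inner["ref_chrom"] == inner_c]
        ext = chrom_extent.loc[inner_c]
        span = ext["max"] - ext["min"]
        covered = inner["ref_pos_Mb"].max() - inner["ref_pos_Mb"].min()
        if span > 0 and covered < 0.7 * span:
            continue   # inner block must span the inserted chromosome
        # insertional signature: the inserted chromosome was circularly
        # permuted, so its reference positions wrap inside the block — the
        # sequence is non-monotone with the extreme positions adjacent at
        # the wrap point (the lost telomeres), rather than at the ends
        seq = inner["ref_pos_Mb"].to_numpy()
        diffs = np.diff(seq)
        monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
        imax, imin = int(np.argmax(seq)), int(np.argmin(seq))
        interior = (not monotone) and abs(imax - imin) <= 2
        boundary_start = 0.5 * (grp["pos_cM"].iloc[a1] + grp["pos_cM"].iloc[i0])
        boundary_end = 0.5 * (grp["pos_cM"].iloc[i1] + grp["pos_cM"].iloc[z0])
        calls.append(FusionCall(
            lg=lg, outer_ref_chrom=outer_c, inner_ref_chrom=inner_c,
            boundary_start_cM=float(boundary_start),
            boundary_end_cM=float(boundary_end),
            inner_ends_interior=bool(interior)))
    return calls


def interpolate_reference_map_position(query_phys_Mb: float,
                                       anchors: list[tuple[float, float]]
                                       ) -> float:
    """Genetic position of a physical coordinate by linear interpolation.

    ``anchors`` is an ordered list of (physical Mb, genetic cM) pairs,
    strictly increasing in both coordinates (locally constant recombination
    rate between anchors).  Queries outside the anchor range extrapolate
    at the terminal interval's rate.
    """
    if len(anchors) < 2:
        raise InvalidParameterError("need at least 2 anchors")
    xs = np.array([a[0] for a in anchors], dtype=float)
    ys = np.array([a[1] for a in anchors], dtype=float)
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) <= 0):
        raise InvalidParameterError("anchors must be strictly increasing in "
                                    "both coordinates")
    if query_phys_Mb < xs[0]:
        rate = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + (query_phys_Mb - xs[0]) * rate)
    if query_phys_Mb > xs[-1]:
        rate = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + (query_phys_Mb - xs[-1]) * rate)
    return float(np.interp(query_phys_Mb, xs, ys))
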