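"""Two-point linkage analysis and map construction for an outbred F1 cross.

Recombination fractions are estimated per marker pair by maximizing the
joint-genotype multinomial likelihood over rf and the admissible parental
linkage phases.  Each F1 individual contributes one meiosis per parent that
is heterozygous at both markers; phase determines which transmissions count
as recombinant; classes that are ambiguous about parental transmission
(the double heterozygote of an <hkxhk> pair) are handled as latent data by
expectation-maximization.  Linkage evidence is summarized as an
independence LOD: the G statistic of the joint genotype contingency table
divided by 2 ln 10, a convention robust to segregation distortion.

Linkage groups are connected components of the graph with an edge wherever
LOD >= lod_min and rf <= rf_max (defaults 11 and 0.4).  Within a group,
markers are ordered by minimizing a weighted least-squares stress between
the 1-D coordinates the order induces and all estimable pairwise Haldane
distances; positions are the resulting coordinates.  Distances between
markers whose configurations share no informative meioses (a
parent1-testcross marker against a parent2-testcross marker) are not
estimable and such pairs simply contribute nothing — their relative
placement is constrained through markers heterozygous in both parents.
The framework procedure excludes highly distorted markers, drops markers
stranded more than ``orphan_cm`` from their nearest neighbor, and finally
re-inserts the distorted markers one at a time without permuting the
framework order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .calling import CP_TOKENS, CPCall, MISSING
from .errors import InsufficientDataError, InvalidParameterError

RF_MAX_REPORT = 0.4999   # rf reported at the 0.5 boundary, keeps Haldane finite

PARENT_ALLELES = {
    "lmxll": (("l", "m"), ("l", "l")),
    "nnxnp": (("n", "n"), ("n", "p")),
    "hkxhk": (("h", "k"), ("h", "k")),
    "efxeg": (("e", "f"), ("e", "g")),
    "abxcd": (("a", "b"), ("c", "d")),
}

INFORMATIVENESS = {"lmxll": "p1", "nnxnp": "p2", "hkxhk": "both",
                   "efxeg": "both", "abxcd": "both"}


def haldane_cm(rf: float) -> float:
    """Map distance in cM under the Haldane (no interference) function."""
    if not (0 <= rf < 0.5):
        raise InvalidParameterError(f"rf must be in [0, 0.5), got {rf}")
    return -50.0 * math.log(1.0 - 2.0 * rf)


def haldane_rf(d_cm: float) -> float:
    """Inverse Haldane function: expected rf at a map distance in cM."""
    if d_cm < 0:
        raise InvalidParameterError(f"distance must be >= 0, got {d_cm}")
    return 0.5 * (1.0 - math.exp(-d_cm / 50.0))


@dataclass
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    rf_hat: float
    phase: str             # e.g. 'cc', 'cr', '--' per parent (c=coupling)
    lod_independence: float
    loglik: float
    n: int
    n_inf: int = 1     # parents heterozygous at both markers (1 or 2)


def _token_of(a1: str, a2: str) -> str:
    return "".join(sorted((a1, a2)))


def _token_index(code: str) -> dict[str, int]:
    return {t: i for i, t in enumerate(CP_TOKENS[code])}


def _combo_tables(code_i: str, code_j: str):
    """Static structure of the 16 joint transmission combos for a code pair.

    Returns (cell_index[16], base_rec1[16], base_rec2[16], inf1, inf2,
    n_cells_i, n_cells_j) where base_rec* marks combos recombinant for that
    parent under coupling phase (phase 0).
    """
    p1_i, p2_i = PARENT_ALLELES[code_i]
    p1_j, p2_j = PARENT_ALLELES[code_j]
    inf1 = (p1_i[0] != p1_i[1]) and (p1_j[0] != p1_j[1])
    inf2 = (p2_i[0] != p2_i[1]) and (p2_j[0] != p2_j[1])
    idx_i, idx_j = _token_index(code_i), _token_index(code_j)
    cells, rec1, rec2 = [], [], []
    for ai, aj, bi, bj in itertools.product(range(2), repeat=4):
        ti = idx_i[_token_of(p1_i[ai], p2_i[bi])]
        tj = idx_j[_token_of(p1_j[aj], p2_j[bj])]
        cells.append(ti * len(idx_j) + tj)
        rec1.append(1 if ai != aj else 0)
        rec2.append(1 if bi != bj else 0)
    return (np.array(cells), np.array(rec1), np.array(rec2), inf1, inf2,
            len(idx_i), len(idx_j))


def _cell_counts(calls_i: CPCall, calls_j: CPCall) -> tuple[np.ndarray, int]:
    idx_i, idx_j = _token_index(calls_i.cp_code), _token_index(calls_j.cp_code)
    counts = np.zeros(len(idx_i) * len(idx_j))
    n = 0
    for ind, ti in calls_i.calls.items():
        tj = calls_j.calls.get(ind, MISSING)
        if ti == MISSING or tj == MISSING:
            continue
        counts[idx_i[ti] * len(idx_j) + idx_j[tj]] += 1
        n += 1
    return counts, n


def _loglik(r: float, counts: np.ndarray, cells: np.ndarray,
            nrec: np.ndarray, n_inf: int) -> float:
    q = (r ** nrec) * ((1.0 - r) ** (n_inf - nrec))
    cellp = np.bincount(cells, weights=q, minlength=len(counts))
    mask = counts > 0
    if np.any(cellp[mask] <= 0):
        return -np.inf
    return float((counts[mask] * np.log(cellp[mask])).sum())


def _em_rf(counts: np.ndarray, cells: np.ndarray, nrec: np.ndarray,
           n_inf: int, r0: float = 0.25, tol: float = 1e-9,
           max_iter: int = 500) -> float:
    n = counts.sum()
    r = r0
    for _ in range(max_iter):
        q = (r ** nrec) * ((1.0 - r) ** (n_inf - nrec))
        cellp = np.bincount(cells, weights=q, minlength=len(counts))
        cellrec = np.bincount(cells, weights=q * nrec, minlength=len(counts))
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_rec = np.where(cellp > 0, cellrec / cellp, 0.0)
        r_new = float((counts * exp_rec).sum() / (n * n_inf))
        r_new = min(max(r_new, 1e-9), RF_MAX_REPORT)
        if abs(r_new - r) < tol:
            return r_new
        r = r_new
    return r


def independence_lod_from_counts(counts: np.ndarray, n_i: int, n_j: int) -> float:
    """G statistic of independence on the joint table, in LOD units."""
    table = counts.reshape(n_i, n_j)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    table = table[rows > 0][:, cols > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = table > 0
    g = 2.0 * float((table[mask] * np.log(table[mask] / expected[mask])).sum())
    return max(g, 0.0) / (2.0 * math.log(10.0))


def independence_lod(calls_i: CPCall, calls_j: CPCall) -> float:
    counts, _ = _cell_counts(calls_i, calls_j)
    return independence_lod_from_counts(
        counts, len(CP_TOKENS[calls_i.cp_code]), len(CP_TOKENS[calls_j.cp_code]))


def estimate_rf_em(calls_i: CPCall, calls_j: CPCall, min_n: int = 20
                   ) -> PairwiseLinkage:
    """Maximum-likelihood two-point rf over admissible phases (EM).

    For pairs sharing no informative meioses the likelihood does not depend
    on rf; such pairs are reported at the 0.5 boundary with phase '--'.
    """
    counts, n = _cell_counts(calls_i, calls_j)
    if n < min_n:
        raise InsufficientDataError(
            f"{calls_i.marker_id} x {calls_j.marker_id}: only {n} shared calls "
            f"(minimum {min_n})")
    cells, rec1, rec2, inf1, inf2, n_i, n_j = _combo_tables(
        calls_i.cp_code, calls_j.cp_code)
    lod = independence_lod_from_counts(counts, n_i, n_j)
    if not inf1 and not inf2:
        return PairwiseLinkage(calls_i.marker_id, calls_j.marker_id,
                               RF_MAX_REPORT, "--", lod, 0.0, n, 0)
    n_inf = int(inf1) + int(inf2)
    phases1 = (0, 1) if inf1 else (None,)
    phases2 = (0, 1) if inf2 else (None,)
    best = None
    for s1 in phases1:
        for s2 in phases2:
            nrec = np.zeros(16)
            if inf1:
                nrec += rec1 ^ s1
            if inf2:
                nrec += rec2 ^ s2
            r = _em_rf(counts, cells, nrec, n_inf)
            ll = _loglik(r, counts, cells, nrec, n_inf)
            label = "".join("-" if s is None else ("c" if s == 0 else "r")
                            for s in (s1, s2))
            if best is None or ll > best[1] + 1e-12:
                best = (r, ll, label)
    r, ll, label = best
    return PairwiseLinkage(calls_i.marker_id, calls_j.marker_id,
                           min(r, RF_MAX_REPORT), label, lod, ll, n, n_inf)


# ---------------------------------------------------------------------------
# pairwise tables over many markers


def build_pairwise(calls: dict[str, CPCall], min_n: int = 20,
                   rf_lod_min: float = 3.0
                   ) -> dict[tuple[str, str], PairwiseLinkage]:
    """All-pairs LOD table, with rf estimated where linkage is plausible.

    The independence LOD is cheap and computed for every pair; the EM rf is
    run only for pairs whose LOD reaches ``rf_lod_min`` (pairs below it are
    far beyond any grouping or ordering threshold and are recorded at the
    0.5 boundary).  Pairs with fewer than ``min_n`` shared calls are
    recorded as unlinked.
    """
    ids = sorted(calls)
    # integer-encode tokens per marker over a shared individual list
    individuals = sorted({i for c in calls.values() for i in c.calls})
    enc: dict[str, np.ndarray] = {}
    for mid in ids:
        call = calls[mid]
        idx = _token_index(call.cp_code)
        enc[mid] = np.array([idx.get(call.calls.get(i, MISSING), -1)
                             for i in individuals])
    table: dict[tuple[str, str], PairwiseLinkage] = {}
    for a, b in itertools.combinations(ids, 2):
        ca, cb = calls[a], calls[b]
        na, nb = len(CP_TOKENS[ca.cp_code]), len(CP_TOKENS[cb.cp_code])
        ea, eb = enc[a], enc[b]
        ok = (ea >= 0) & (eb >= 0)
        n = int(ok.sum())
        if n < min_n:
            table[(a, b)] = PairwiseLinkage(a, b, RF_MAX_REPORT, "--", 0.0, 0.0, n)
            continue
        counts = np.bincount(ea[ok] * nb + eb[ok], minlength=na * nb).astype(float)
        lod = independence_lod_from_counts(counts, na, nb)
        if lod < rf_lod_min:
            table[(a, b)] = PairwiseLinkage(a, b, RF_MAX_REPORT, "--", lod, 0.0, n)
            continue
        table[(a, b)] = estimate_rf_em(ca, cb, min_n=min_n)
    return table


def _pair(table, a: str, b: str) -> PairwiseLinkage | None:
    return table.get((a, b)) or table.get((b, a))


def densify_group_pairs(calls: dict[str, CPCall], table: dict,
                        groups: list[list[str]], min_n: int = 20) -> None:
    """Estimate rf for within-group pairs skipped by the LOD prefilter.

    ``build_pairwise`` defers the EM to plausibly linked pairs; once
    groups are known, weakly linked within-group pairs still carry
    ordering information, so their rf is filled in here (in place).
    """
    for grp in groups:
        for a, b in itertools.combinations(sorted(grp), 2):
            pl = _pair(table, a, b)
            if pl is None or (pl.phase == "--" and pl.rf_hat >= RF_MAX_REPORT
                              and pl.n >= min_n):
                try:
                    key = (a, b) if (a, b) in table or (b, a) not in table \
                        else (b, a)
                    table[key] = estimate_rf_em(calls[a], calls[b], min_n)
                except InsufficientDataError:
                    pass


def form_linkage_groups(table: dict, markers: list[str], lod_min: float = 11.0,
                        rf_max: float = 0.4
                        ) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups by thresholded connectivity."""
    g = nx.Graph()
    g.add_nodes_from(markers)
    marker_set = set(markers)
    for (a, b), pl in table.items():
        if a in marker_set and b in marker_set:
            if pl.lod_independence >= lod_min and pl.rf_hat <= rf_max:
                g.add_edge(a, b)
    groups, singletons = [], []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        (groups if len(comp) > 1 else singletons).append(comp)
    groups = sorted((grp for grp in groups), key=lambda c: c[0])
    return groups, sorted(s for (s,) in singletons)


# ---------------------------------------------------------------------------
# ordering


def _rf_matrix(markers: list[str], table: dict, edge_rf_max: float = 0.45,
               edge_lod_min: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """(completed distance matrix cM, completed rf matrix) for a group.

    Direct Haldane distances are taken from estimable, plausibly linked
    pairs; remaining entries are completed by graph shortest paths.
    """
    n = len(markers)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        pl = _pair(table, markers[i], markers[j])
        if pl is None:
            continue
        if pl.rf_hat <= edge_rf_max and pl.lod_independence >= edge_lod_min:
            d[i, j] = d[j, i] = haldane_cm(min(pl.rf_hat, RF_MAX_REPORT))
    comp = shortest_path(d, method="D", directed=False)
    finite_max = np.nanmax(np.where(np.isinf(comp), np.nan, comp))
    comp = np.where(np.isinf(comp), (finite_max if np.isfinite(finite_max)
                                     else 0.0) + 80.0, comp)
    rf = np.array([[haldane_rf(min(x, 500.0)) for x in row] for row in comp])
    np.fill_diagonal(rf, 0.0)
    return comp, rf


def _sarf(order: list[int], rf: np.ndarray) -> float:
    return float(sum(rf[a, b] for a, b in zip(order, order[1:])))


def _mds_order(dist: np.ndarray) -> list[int]:
    """Seriation by the first classical-MDS coordinate of the distance matrix."""
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    coord = vecs[:, -1] * math.sqrt(max(vals[-1], 0.0))
    return [int(i) for i in np.argsort(coord, kind="stable")]


def _greedy_order(dist: np.ndarray, rf: np.ndarray) -> list[int]:
    """Seed with the farthest pair; insert each marker at the best SARF slot."""
    n = dist.shape[0]
    i0, j0 = np.unravel_index(np.argmax(dist), dist.shape)
    order = [int(min(i0, j0)), int(max(i0, j0))]
    for k in (k for k in range(n) if k not in order):
        best_slot, best_cost = 0, np.inf
        for slot in range(len(order) + 1):
            cand = order[:slot] + [k] + order[slot:]
            cost = _sarf(cand, rf)
            if cost < best_cost - 1e-12:
                best_cost, best_slot = cost, slot
        order.insert(best_slot, k)
    return order


class _StressModel:
    """Weighted least-squares distance model for one linkage group.

    Holds the estimable pairwise Haldane distances with information
    weights; for any candidate order it solves for the 1-D marker
    coordinates minimizing the weighted squared deviation between
    coordinate differences (signed by the order) and the pairwise
    distances, and reports the residual stress.  A gentle ridge term
    anchors the translational degree of freedom.
    """

    def __init__(self, markers: list[str], table: dict,
                 rf_cap: float = 0.45):
        self.n = len(markers)
        a_idx, b_idx, dists, weights = [], [], [], []
        for a, b in itertools.combinations(range(self.n), 2):
            pl = _pair(table, markers[a], markers[b])
            if pl is None or pl.rf_hat > rf_cap:
                continue
            r = pl.rf_hat
            var = ((100.0 / (1.0 - 2.0 * r)) ** 2) * max(r, 0.005) * (1 - r) \
                / max(pl.n * max(pl.n_inf, 1), 1)
            a_idx.append(a)
            b_idx.append(b)
            dists.append(haldane_cm(r))
            weights.append(1.0 / max(var, 1e-3))
        self.a = np.array(a_idx, dtype=int)
        self.b = np.array(b_idx, dtype=int)
        self.d = np.array(dists)
        self.w = np.sqrt(np.array(weights))

    @property
    def n_pairs(self) -> int:
        return len(self.d)

    def solve(self, order: list[int]) -> tuple[np.ndarray, float]:
        """(coordinates, residual stress) for a candidate order."""
        n = len(order)
        rank = np.empty(n)
        rank[order] = np.arange(n)
        sign = np.where(rank[self.b] > rank[self.a], 1.0, -1.0)
        m = np.zeros((self.n_pairs, n))
        m[np.arange(self.n_pairs), self.b] = sign
        m[np.arange(self.n_pairs), self.a] -= sign
        mw = m * self.w[:, None]
        design = np.vstack([mw, np.full(n, 0.01)])
        target = np.append(self.d * self.w, 0.0)
        sol, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = mw @ sol - self.d * self.w
        return sol, float(resid @ resid)


def _stress_polish(order: list[int], model: _StressModel,
                   max_passes: int = 40) -> tuple[list[int], float]:
    """Hill-climb on LS stress with single-marker relocations and 2-opt
    segment reversals."""
    n = len(order)
    _, best = model.solve(order)
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for i in range(n):
            for j in range(n):
                if j == i:
                    continue
                cand = list(order)
                mk = cand.pop(i)
                cand.insert(j, mk)
                _, s = model.solve(cand)
                if s < best - 1e-9:
                    order, best = cand, s
                    improved = True
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                _, s = model.solve(cand)
                if s < best - 1e-9:
                    order, best = cand, s
                    improved = True
    return order, best


def order_markers(markers: list[str], table: dict,
                  edge_rf_max: float = 0.45, edge_lod_min: float = 3.0
                  ) -> tuple[list[str], list[float]]:
    """Order a linkage group and place markers on a cM scale.

    The order minimizes the weighted least-squares stress between the 1-D
    marker coordinates it induces and all estimable pairwise Haldane
    distances — a global objective pooling every informative pair, far
    more robust to two-point noise than the sum of adjacent recombination
    fractions alone.  Optimization: two seriation starts (greedy SARF
    insertion and the first classical-MDS coordinate of the
    shortest-path-completed distance matrix), iterated coordinate
    re-sorting, then relocation/2-opt hill-climbing on the exact stress.
    Positions are the LS coordinates of the winning order, made monotone
    and anchored at 0; orientation is canonicalized so the first marker
    id precedes the last.
    """
    markers = sorted(markers)
    n = len(markers)
    if n < 2:
        return markers, [0.0] * n
    dist, rf = _rf_matrix(markers, table, edge_rf_max, edge_lod_min)
    model = _StressModel(markers, table)
    if model.n_pairs == 0:
        order = _mds_order(dist)
        positions = [0.0]
        for a, b in zip(order, order[1:]):
            positions.append(positions[-1] + dist[a, b])
        return [markers[k] for k in order], positions
    results = []
    for start in (_mds_order(dist), _greedy_order(dist, rf)):
        order = list(start)
        for _ in range(20):   # iterate: solve coordinates, re-sort by them
            sol, _ = model.solve(order)
            new = [int(i) for i in np.argsort(sol, kind="stable")]
            if new == order:
                break
            order = new
        order, stress = _stress_polish(order, model)
        results.append((stress, tuple(markers[k] for k in order), order))
    _, _, order = min(results, key=lambda t: t[:2])
    if markers[order[-1]] < markers[order[0]]:
        order = order[::-1]
    sol, _ = model.solve(order)
    x = np.maximum.accumulate(sol[order])
    x = x - x[0]
    return [markers[k] for k in order], [float(v) for v in x]


# ---------------------------------------------------------------------------
# genetic maps


@dataclass
class LGMap:
    lg_index: int
    markers: list[str]
    positions: list[float]

    @property
    def span_cM(self) -> float:
        return self.positions[-1] - self.positions[0] if self.positions else 0.0

    def nearest_neighbor_cm(self, idx: int) -> float:
        gaps = []
        if idx > 0:
            gaps.append(self.positions[idx] - self.positions[idx - 1])
        if idx < len(self.positions) - 1:
            gaps.append(self.positions[idx + 1] - self.positions[idx])
        return min(gaps) if gaps else np.inf


@dataclass
class GeneticMap:
    groups: list[LGMap]
    provenance: str = "framework"    # 'framework' | 'integrated' | 'parent1' | 'parent2'
    informativeness: dict[str, str] = field(default_factory=dict)
    singletons: list[str] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    def marker_positions(self) -> dict[str, tuple[int, float]]:
        return {m: (g.lg_index, p) for g in self.groups
                for m, p in zip(g.markers, g.positions)}


def _drop_orphans(group: list[str], table: dict, orphan_cm: float
                  ) -> tuple[list[str], list[float], list[str]]:
    """Order a group, iteratively excluding markers > orphan_cm from their
    nearest neighbor, reordering after each exclusion round."""
    dropped: list[str] = []
    markers = list(group)
    for _ in range(10):
        order, positions = order_markers(markers, table)
        lg = LGMap(0, order, positions)
        orphans = [m for i, m in enumerate(order)
                   if lg.nearest_neighbor_cm(i) > orphan_cm]
        if not orphans or len(markers) - len(orphans) < 2:
            return order, positions, dropped
        dropped.extend(orphans)
        markers = [m for m in markers if m not in orphans]
    return order, positions, dropped


def build_framework_map(calls: dict[str, CPCall],
                        distortion_classes: dict[str, str],
                        lod_min: float = 11.0, rf_max: float = 0.4,
                        orphan_cm: float = 40.0, min_n: int = 20,
                        min_group_size: int = 4,
                        table: dict | None = None,
                        provenance: str = "integrated"
                        ) -> tuple[GeneticMap, dict]:
    """The full framework -> final map procedure.

    Steps: (1) exclude highly distorted markers; (2) form linkage groups;
    (3) order each group by SARF; (4) drop markers stranded beyond
    ``orphan_cm`` and reorder; (5) re-insert each highly distorted marker
    at its best single position, keeping framework order fixed, accepting
    the placement when the nearest framework neighbor is within
    ``orphan_cm``.

    Only *major* groups (at least ``min_group_size`` markers) constitute
    the map; smaller fragments — typically a handful of markers isolated
    by a local gap in one parent's informative-marker coverage — are
    reported as unplaced, mirroring how a few markers always remain off
    the major groups of a real map.
    """
    highly = sorted(m for m, c in distortion_classes.items()
                    if c == "highly_distorted" and m in calls)
    framework_calls = {m: c for m, c in calls.items() if m not in highly}
    if table is None:
        table = build_pairwise(calls, min_n=min_n)
    fw_table = {(a, b): pl for (a, b), pl in table.items()
                if a in framework_calls and b in framework_calls}
    groups, singletons = form_linkage_groups(
        fw_table, sorted(framework_calls), lod_min, rf_max)
    fragments = [grp for grp in groups if len(grp) < min_group_size]
    groups = [grp for grp in groups if len(grp) >= min_group_size]
    densify_group_pairs(calls, table, groups, min_n=min_n)

    lgs: list[LGMap] = []
    orphaned: list[str] = []
    for gi, grp in enumerate(groups, start=1):
        order, positions, dropped = _drop_orphans(grp, table, orphan_cm)
        orphaned.extend(dropped)
        lgs.append(LGMap(gi, order, positions))

    placed_distorted: list[str] = []
    unplaced_distorted: list[str] = []
    for m in highly:
        best = None    # (norm_cost, lg_idx, x_hat, nn_dist)
        for li, lg in enumerate(lgs):
            # the marker must be linked to the group at the same thresholds
            # used to form groups, or it cannot be placed there
            linked = any(
                (pl := _pair(table, m, fm)) is not None
                and pl.lod_independence >= lod_min and pl.rf_hat <= rf_max
                for fm in lg.markers)
            if not linked:
                continue
            anchors, dists, ws = [], [], []
            for fm, p in zip(lg.markers, lg.positions):
                pl = _pair(table, m, fm)
                if pl is None or pl.rf_hat > 0.45 or pl.lod_independence < 1.0:
                    continue
                r = pl.rf_hat
                var = ((100.0 / (1.0 - 2.0 * r)) ** 2) * max(r, 0.005) \
                    * (1 - r) / max(pl.n * max(pl.n_inf, 1), 1)
                anchors.append(p)
                dists.append(haldane_cm(r))
                ws.append(1.0 / max(var, 1e-3))
            if not anchors:
                continue
            p_arr = np.array(anchors)
            d_arr = np.array(dists)
            w_arr = np.array(ws)
            # 1-D grid search for the coordinate best matching the anchor
            # distances (the absolute value makes this non-convex)
            grid = np.arange(lg.positions[0] - 60.0,
                             lg.positions[-1] + 60.0, 0.25)
            cost = (w_arr[None, :]
                    * (np.abs(grid[:, None] - p_arr[None, :])
                       - d_arr[None, :]) ** 2).sum(axis=1)
            k = int(np.argmin(cost))
            x_hat = float(grid[k])
            nn = float(np.abs(np.array(lg.positions) - x_hat).min())
            if nn > orphan_cm:
                continue
            norm_cost = float(cost[k] / w_arr.sum())
            if best is None or norm_cost < best[0] - 1e-12:
                best = (norm_cost, li, x_hat, nn)
        if best is None:
            unplaced_distorted.append(m)
            continue
        _, li, x_hat, _ = best
        lg = lgs[li]
        slot = int(np.searchsorted(np.array(lg.positions), x_hat))
        lg.markers.insert(slot, m)
        lg.positions.insert(slot, x_hat)
        if lg.positions[0] < 0:
            shift = -lg.positions[0]
            lg.positions = [p + shift for p in lg.positions]
        placed_distorted.append(m)

    info = {m: INFORMATIVENESS[c.cp_code] for m, c in calls.items()}
    fragment_markers = sorted(m for grp in fragments for m in grp)
    gmap = GeneticMap(groups=lgs, provenance=provenance, informativeness=info,
                      singletons=singletons,
                      unplaced=sorted(orphaned + unplaced_distorted
                                      + fragment_markers))
    report = {
        "n_markers_input": len(calls),
        "n_highly_distorted_excluded": len(highly),
        "n_groups": len(lgs),
        "n_minor_fragments": len(fragments),
        "n_fragment_markers": len(fragment_markers),
        "n_singletons": len(singletons),
        "n_orphans_dropped": len(orphaned),
        "n_distorted_reinserted": len(placed_distorted),
        "n_distorted_unplaced": len(unplaced_distorted),
    }
    return gmap, report


def integrate_parental_maps(map_p1: GeneticMap, map_p2: GeneticMap
                            ) -> tuple[GeneticMap, list[dict]]:
    """Merge two parental maps through their shared anchor markers.

    Linkage groups are paired by shared markers (>= 2 anchors required).
    Anchor positions are averaged after orientation matching; non-anchor
    markers are carried over by monotone piecewise-linear interpolation
    between flanking anchors (terminal-interval extrapolation at the
    ends).  Groups whose anchor orders conflict are flagged and left
    unmerged.
    """
    from .synteny import interpolate_reference_map_position as _interp

    conflicts: list[dict] = []
    merged: list[LGMap] = []
    used2 = set()
    next_idx = 1
    pos2 = {g.lg_index: dict(zip(g.markers, g.positions)) for g in map_p2.groups}
    for g1 in map_p1.groups:
        best_g2, anchors = None, []
        for g2 in map_p2.groups:
            shared = [m for m in g1.markers if m in set(g2.markers)]
            if len(shared) > len(anchors):
                best_g2, anchors = g2, shared
        if best_g2 is None or len(anchors) < 2:
            merged.append(LGMap(next_idx, list(g1.markers), list(g1.positions)))
            next_idx += 1
            continue
        used2.add(best_g2.lg_index)
        p1 = dict(zip(g1.markers, g1.positions))
        p2 = pos2[best_g2.lg_index]
        a1 = np.array([p1[m] for m in anchors])
        a2 = np.array([p2[m] for m in anchors])
        tau = np.corrcoef(a1, a2)[0, 1] if len(anchors) > 2 else (
            1.0 if (a1[1] - a1[0]) * (a2[1] - a2[0]) >= 0 else -1.0)
        if tau < 0:
            span = max(p2.values())
            p2 = {m: span - p for m, p in p2.items()}
            a2 = np.array([p2[m] for m in anchors])
        order1 = np.argsort(a1, kind="stable")
        if not (np.all(np.diff(a2[order1]) >= -1e-9)):
            conflicts.append({"lg_p1": g1.lg_index, "lg_p2": best_g2.lg_index,
                              "reason": "conflicting anchor order"})
            merged.append(LGMap(next_idx, list(g1.markers), list(g1.positions)))
            next_idx += 1
            continue
        a1s, a2s = a1[order1], a2[order1]
        integ = (a1s + a2s) / 2.0
        # de-duplicate colocated anchors for interpolation
        keep1 = np.concatenate(([True], np.diff(a1s) > 1e-9))
        keep2 = np.concatenate(([True], np.diff(a2s) > 1e-9))
        anchors1 = list(zip(a1s[keep1], integ[keep1]))
        anchors2 = list(zip(a2s[keep2], integ[keep2]))
        out = {}
        for m in g1.markers:
            out[m] = (_interp(p1[m], anchors1) if len(anchors1) >= 2
                      else p1[m])
        for m in best_g2.markers:
            if m not in out:
                out[m] = (_interp(p2[m], anchors2) if len(anchors2) >= 2
                          else p2[m])
        names = sorted(out, key=lambda m: (out[m], m))
        positions = [out[m] for m in names]
        base = positions[0]
        merged.append(LGMap(next_idx, names, [p - base for p in positions]))
        next_idx += 1
    for g2 in map_p2.groups:
        if g2.lg_index not in used2:
            merged.append(LGMap(next_idx, list(g2.markers), list(g2.positions)))
            next_idx += 1
    info = dict(map_p1.informativeness)
    info.update(map_p2.informativeness)
    return GeneticMap(groups=merged, provenance="integrated",
                      informativeness=info), conflicts


def map_length_summary(observed_cM: float, n_groups: int,
                       mean_spacing_cM: float) -> dict[str, float]:
    """Telomere-corrected total map length from summary quantities.

    Each linkage group is assumed to miss about one mean marker spacing at
    each telomeric end, so the correction is 2 x n_groups x mean spacing.
    """
    correction = 2.0 * n_groups * mean_spacing_cM
    return {
        "observed_cM": observed_cM,
        "mean_spacing_cM": mean_spacing_cM,
        "telomere_correction_cM": correction,
        "corrected_cM": observed_cM + correction,
    }


def estimate_total_map_length(gmap: GeneticMap) -> dict[str, float]:
    """Observed length, mean inter-marker spacing (colocated markers pooled),
    and the telomere-corrected total for a genetic map."""
    observed = 0.0
    n_intervals = 0
    for g in gmap.groups:
        observed += g.span_cM
        gaps = np.diff(np.array(g.positions))
        n_intervals += int((gaps > 1e-9).sum())
    mean_spacing = observed / n_intervals if n_intervals else 0.0
    out = map_length_summary(observed, len(gmap.groups), mean_spacing)
    out["n_groups"] = len(gmap.groups)
    out["n_intervals"] = n_intervals
    return out
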