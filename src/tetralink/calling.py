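"""Recover marker classes and genotypes from two-channel signal.

Clustering is one-dimensional on theta = B/(A+B); the total intensity R is
used only as a no-call floor.  The number of clusters is chosen by BIC over
Gaussian mixtures with k = 1..k_max, with ties broken toward fewer
clusters and a minimum cluster weight guarding against singleton
components.

Cluster-pattern classification follows the dosage model: a single cluster
near theta = 0.5 is a fixed difference between paralogs (every individual
"heterozygous"); one near 0 or 1 is monomorphic; two or three clusters
indicate a segregating SNP, whose cluster means lie on the unskewed grid
{0, 1/2, 1} when the probe samples one locus, or on a skewed grid
({1/2, 3/4, 1} or {0, 1/4, 1/2}) when a paralogous locus fixed for one
allele adds constant signal.  More than three clusters cannot be
interpreted under a two-locus dosage model and the marker is discarded.
These deterministic rules replace the manual cluster review used with the
commercial genotyping software.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import InvalidParameterError, NonParentalAlleleError

SKEW_GRIDS = {
    "none": (0.0, 0.5, 1.0),
    "right": (0.5, 0.75, 1.0),
    "left": (0.0, 0.25, 0.5),
}

#: Genotype attached to each grid point, in ascending theta order.
GRID_GENOTYPES = ("AA", "AB", "BB")

CP_TOKENS = {
    "lmxll": ("ll", "lm"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
    "efxeg": ("ee", "ef", "eg", "fg"),
    "abxcd": ("ac", "ad", "bc", "bd"),
}
MISSING = "--"


@dataclass
class ClusterModel:
    """Fitted 1-D mixture over theta for one marker."""

    marker_id: str
    k: int
    means: np.ndarray          # ascending
    sds: np.ndarray
    weights: np.ndarray
    class_label: str = "unclassified"
    skew: str = "none"
    grid_points: tuple[float, ...] = ()   # grid point per cluster (ascending)
    r_floor: float = 0.0
    z_max: float = 5.0

    def assign(self, theta: float, r: float) -> int | None:
        """Cluster index for one point, or None for a no-call.

        No-calls are points below the R floor and outliers more than
        ``z_max`` cluster standard deviations from every cluster mean —
        e.g. an individual whose genotype does not occur in the mapping
        population, such as a doubled haploid homozygous for an allele
        both cluster-defining parents lack.
        """
        if r < self.r_floor or not np.isfinite(theta):
            return None
        z = np.abs(theta - self.means) / np.maximum(self.sds, 0.01)
        if z.min() > self.z_max:
            return None
        dens = self.weights * np.exp(
            -0.5 * ((theta - self.means) / self.sds) ** 2) / self.sds
        return int(np.argmax(dens))

    def genotype_of_cluster(self, idx: int) -> str | None:
        if not self.grid_points or idx is None:
            return None
        g = self.grid_points[idx]
        grid = SKEW_GRIDS[self.skew]
        return GRID_GENOTYPES[grid.index(g)]


@dataclass
class CPCall:
    """JoinMap-style cross-pollinator coding of one segregating marker."""

    marker_id: str
    cp_code: str                       # 'lmxll' | 'nnxnp' | 'hkxhk' | 'efxeg' | 'abxcd'
    calls: dict[str, str] = field(default_factory=dict)  # individual -> token
    phase: str = "--"

    def tokens(self, individuals: list[str]) -> list[str]:
        return [self.calls.get(i, MISSING) for i in individuals]


def cluster_marker_signals(points: pd.DataFrame, k_max: int = 5,
                           r_floor: float = 0.5, min_weight: float = 0.02,
                           min_sep: float = 0.1, min_points: int = 10,
                           seed: int = 0) -> ClusterModel:
    """Fit 1-D Gaussian mixtures on theta and select k by BIC.

    ``points`` is a frame with columns marker_id, individual_id, theta, R.
    Points with R below ``r_floor`` are excluded from fitting (and later
    no-called).  Fewer than ``min_points`` usable points marks the assay
    failed.  Candidate fits are rejected when a component weight falls
    below ``min_weight`` or two component means lie within ``min_sep`` of
    each other: genotype clusters on the dosage grid are at least 0.25
    apart, whereas intensity truncation at zero distorts the extreme
    clusters into shapes that a mixture would otherwise shatter.
    """
    marker_id = str(points["marker_id"].iloc[0]) if len(points) else "?"
    usable = points[(points["R"] >= r_floor) & np.isfinite(points["theta"])]
    x = usable["theta"].to_numpy(dtype=float).reshape(-1, 1)
    if len(x) < min_points:
        return ClusterModel(marker_id, 0, np.array([]), np.array([]),
                            np.array([]), class_label="failed", r_floor=r_floor)
    best = None
    best_bic = np.inf
    for k in range(1, min(k_max, len(x)) + 1):
        gm = GaussianMixture(n_components=k, covariance_type="spherical",
                             reg_covar=1e-6, n_init=3, random_state=seed)
        try:
            with warnings.catch_warnings():
                # duplicate theta values (noiseless data) upset k-means init
                warnings.simplefilter("ignore")
                gm.fit(x)
        except ValueError:
            continue
        if gm.weights_.min() < min_weight:
            continue
        mu = np.sort(gm.means_.ravel())
        if k > 1 and np.diff(mu).min() < min_sep:
            continue
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:   # ties resolve toward smaller k
            best_bic = bic
            best = gm
    if best is None:
        return ClusterModel(marker_id, 0, np.array([]), np.array([]),
                            np.array([]), class_label="failed", r_floor=r_floor)
    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covariances_.ravel()[order])
    sds = np.maximum(sds, 1e-4)
    weights = best.weights_[order]
    return ClusterModel(marker_id, len(means), means, sds, weights,
                        r_floor=r_floor)


def detect_skew(cluster_means, tolerance: float = 0.08) -> str:
    """Nearest-grid skew classification for 2 or 3 cluster means.

    Each candidate grid family contributes its best order-preserving subset
    of matching size; the family with the smallest total absolute deviation
    wins, with ties (including the no-confidence case where the winner's
    worst deviation exceeds ``tolerance``) resolved to 'none'.
    """
    means = np.sort(np.asarray(cluster_means, dtype=float))
    k = len(means)
    if k not in (2, 3):
        raise InvalidParameterError(f"skew detection needs 2 or 3 clusters, got {k}")
    scores = {}
    worst = {}
    for fam, grid in SKEW_GRIDS.items():
        best = np.inf
        best_worst = np.inf
        for subset in itertools.combinations(grid, k):
            dev = np.abs(means - np.array(subset))
            if dev.sum() < best:
                best = dev.sum()
                best_worst = dev.max()
        scores[fam] = best
        worst[fam] = best_worst
    winner = min(scores, key=lambda f: (scores[f], f != "none"))
    if winner != "none":
        if abs(scores[winner] - scores["none"]) < 1e-12:
            return "none"
        if worst[winner] > tolerance:
            return "none"
    return winner


def _grid_assignment(means: np.ndarray, skew: str, k: int) -> tuple[float, ...]:
    """Best order-preserving grid subset for the winning family."""
    grid = SKEW_GRIDS[skew]
    best_subset = None
    best_score = np.inf
    for subset in itertools.combinations(grid, k):
        score = float(np.abs(means - np.array(subset)).sum())
        if score < best_score:
            best_score = score
            best_subset = subset
    return tuple(best_subset)


def classify_marker(model: ClusterModel, center_tolerance: float = 0.12,
                    skew_tolerance: float = 0.08) -> ClusterModel:
    """Attach the cluster-pattern class label (and skew) to a fitted model."""
    if model.class_label == "failed":
        return model
    if model.k > 3:
        model.class_label = "discard_multi"
        return model
    if model.k == 1:
        m = float(model.means[0])
        if abs(m - 0.5) <= center_tolerance:
            model.class_label = "paralog_fixed"
            model.grid_points = (0.5,)
        else:
            model.class_label = "monomorphic"
            model.grid_points = (0.0 if m < 0.5 else 1.0,)
        return model
    model.skew = detect_skew(model.means, skew_tolerance)
    model.class_label = f"segregating_{model.k}"
    model.grid_points = _grid_assignment(model.means, model.skew, model.k)
    return model


def call_genotypes(model: ClusterModel, points: pd.DataFrame) -> dict[str, str | None]:
    """Per-individual genotype (AA/AB/BB) from cluster assignment."""
    out: dict[str, str | None] = {}
    for row in points.itertuples():
        idx = model.assign(float(row.theta), float(row.R))
        out[str(row.individual_id)] = (
            None if idx is None else model.genotype_of_cluster(idx))
    return out


def assign_cp_snv(marker_id: str, parent1_call: str | None,
                  parent2_call: str | None,
                  progeny_calls: dict[str, str | None]) -> CPCall:
    """CP configuration of a segregating SNV from parental genotype calls.

    The heterozygous parent(s) define the configuration; progeny genotypes
    are recoded into JoinMap tokens, with no-calls (and genotypes that are
    impossible given the parents, e.g. a homozygote for the allele the
    homozygous parent lacks) coded missing.
    """
    het1 = parent1_call == "AB"
    het2 = parent2_call == "AB"
    if not het1 and not het2:
        raise InvalidParameterError(
            f"{marker_id}: neither parent heterozygous; marker is not segregating")
    if het1 and het2:
        code = "hkxhk"
        recode = {"AA": "hh", "AB": "hk", "BB": "kk"}
    elif het1:
        code = "lmxll"
        hom = parent2_call  # 'AA' or 'BB'
        recode = {hom: "ll", "AB": "lm"}
    else:
        code = "nnxnp"
        hom = parent1_call
        recode = {hom: "nn", "AB": "np"}
    calls = {}
    for ind, g in progeny_calls.items():
        calls[ind] = recode.get(g, MISSING) if g is not None else MISSING
    return CPCall(marker_id, code, calls)


def _sizes(cell: str) -> tuple[int, ...]:
    return tuple(int(s) for s in cell.split(",")) if cell else ()


def assign_cp_ssr(marker_id: str, parent1_sizes, parent2_sizes,
                  progeny_sizes: dict[str, tuple[int, ...]]) -> CPCall:
    """CP configuration of an SSR marker from parental allele-size sets.

    Supports the five canonical outbred configurations up to the fully
    informative four-allele case.  A progeny allele absent from both
    parents raises :class:`NonParentalAlleleError` (such individuals were
    removed from the real population before mapping).
    """
    s1, s2 = set(parent1_sizes), set(parent2_sizes)
    union = s1 | s2
    for ind, sizes in progeny_sizes.items():
        extra = set(sizes) - union
        if extra:
            raise NonParentalAlleleError(
                f"{marker_id}: individual {ind} carries non-parental allele(s) {sorted(extra)}")

    def recode_all(recode) -> dict[str, str]:
        return {ind: recode(set(sizes)) if sizes else MISSING
                for ind, sizes in progeny_sizes.items()}

    if len(s1) == 2 and len(s2) == 1 and s2 <= s1:
        (l,) = s2
        (m,) = s1 - s2
        return CPCall(marker_id, "lmxll",
                      recode_all(lambda s: "lm" if m in s else "ll"))
    if len(s1) == 1 and len(s2) == 2 and s1 <= s2:
        (n,) = s1
        (p,) = s2 - s1
        return CPCall(marker_id, "nnxnp",
                      recode_all(lambda s: "np" if p in s else "nn"))
    if len(s1) == 2 and s1 == s2:
        h, k = sorted(s1)

        def rc(s):
            if s == {h, k}:
                return "hk"
            return "hh" if s == {h} else "kk"
        return CPCall(marker_id, "hkxhk", recode_all(rc))
    if len(s1) == 2 and len(s2) == 2 and len(s1 & s2) == 1:
        (e,) = s1 & s2
        (f,) = s1 - s2
        (g,) = s2 - s1

        def rc(s):
            if s == {e}:
                return "ee"
            if s == {e, f}:
                return "ef"
            if s == {e, g}:
                return "eg"
            if s == {f, g}:
                return "fg"
            return MISSING
        return CPCall(marker_id, "efxeg", recode_all(rc))
    if len(s1) == 2 and len(s2) == 2 and not (s1 & s2):
        a, b = sorted(s1)
        c, d = sorted(s2)

        def rc(s):
            first = "a" if a in s else ("b" if b in s else None)
            second = "c" if c in s else ("d" if d in s else None)
            if first is None or second is None:
                return MISSING
            return first + second
        return CPCall(marker_id, "abxcd", recode_all(rc))
    raise InvalidParameterError(
        f"{marker_id}: unsupported parental allele pattern {sorted(s1)} x {sorted(s2)}")


def corroborate_with_dh(models: dict[str, ClusterModel],
                        dh_points: pd.DataFrame) -> pd.DataFrame:
    """Doubled-haploid consistency screen.

    A DH genome comes from a single doubled gamete, so (a) it can never be
    heterozygous at a segregating marker, while (b) at a fixed paralog
    difference it still carries both variant states and must fall in the
    single central cluster.  Returns a frame of violations (empty when the
    calls are consistent).
    """
    rows = []
    for marker_id, grp in dh_points.groupby("marker_id", sort=True):
        model = models.get(str(marker_id))
        if model is None or model.class_label in ("failed", "discard_multi",
                                                  "unclassified"):
            continue
        for row in grp.itertuples():
            idx = model.assign(float(row.theta), float(row.R))
            if model.class_label.startswith("segregating"):
                if idx is not None and model.genotype_of_cluster(idx) == "AB":
                    rows.append((str(marker_id), str(row.individual_id),
                                 "heterozygous_dh_at_segregating_marker"))
            elif model.class_label == "paralog_fixed":
                if idx is None:
                    rows.append((str(marker_id), str(row.individual_id),
                                 "dh_outside_single_cluster"))
    return pd.DataFrame(rows, columns=["marker_id", "individual_id", "violation"])


#: Recovered class corresponding to each simulated truth class, used when
#: scoring classification accuracy against the generator's truth tables.
def recovered_class(model: ClusterModel) -> str:
    if model.class_label.startswith("segregating"):
        return ("biallelic_with_fixed_paralog" if model.skew != "none"
                else "biallelic_unique")
    if model.class_label == "paralog_fixed":
        return "paralog_fixed_only"
    if model.class_label == "monomorphic":
        return "monomorphic"
    return model.class_label
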