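"""Two-point linkage estimation, grouping, ordering, map construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau

from tetralink import linkage as lk
from tetralink.calling import CPCall
from tetralink.errors import InsufficientDataError, InvalidParameterError

from conftest import simulate_cp_chain, simulate_cp_pair


def test_haldane_closed_forms():
    assert lk.haldane_cm(0.0) == 0.0
    assert lk.haldane_cm(0.25) == pytest.approx(-50 * math.log(0.5))
    assert lk.haldane_cm(0.4) == pytest.approx(-50 * math.log(0.2))
    assert lk.haldane_rf(34.657) == pytest.approx(0.25, abs=1e-4)
    with pytest.raises(InvalidParameterError):
        lk.haldane_cm(0.5)
    with pytest.raises(InvalidParameterError):
        lk.haldane_rf(-1.0)


@settings(deadline=None, max_examples=50)
@given(st.floats(0.0, 0.49), st.floats(0.0, 0.49))
def test_haldane_strictly_increasing_and_invertible(r1, r2):
    if r1 < r2:
        assert lk.haldane_cm(r1) < lk.haldane_cm(r2)
    assert lk.haldane_rf(lk.haldane_cm(r1)) == pytest.approx(r1, abs=1e-9)


def _testcross_pair(n, recombinants):
    """Two lmxll markers in coupling with an exact recombinant count."""
    ci, cj = {}, {}
    for k in range(n):
        a = 0 if k < n // 2 else 1
        b = a ^ (k < recombinants)
        ci[f"I{k}"] = ("ll", "lm")[a]
        cj[f"I{k}"] = ("ll", "lm")[b]
    return (CPCall("A", "lmxll", ci), CPCall("B", "lmxll", cj))


def test_rf_em_matches_count_estimator_when_fully_informative():
    a, b = _testcross_pair(100, 10)
    pl = lk.estimate_rf_em(a, b)
    assert pl.rf_hat == pytest.approx(0.10, abs=1e-6)
    assert pl.n == 100


def test_rf_em_insufficient_data():
    a, b = _testcross_pair(10, 1)
    with pytest.raises(InsufficientDataError):
        lk.estimate_rf_em(a, b)


def test_rf_em_unlinked_markers_near_half():
    rng = np.random.default_rng(1)
    devs = []
    for _ in range(20):
        a, b = simulate_cp_pair("lmxll", "lmxll", 0.5 - 1e-12, 221, rng)
        devs.append(lk.estimate_rf_em(a, b).rf_hat)
    se = math.sqrt(0.25 / 221)
    assert abs(np.mean(devs) - 0.5) < 3 * se


def test_rf_em_uninformative_pair_reported_at_boundary():
    rng = np.random.default_rng(2)
    a, _ = simulate_cp_pair("lmxll", "lmxll", 0.1, 60, rng)
    _, b = simulate_cp_pair("nnxnp", "nnxnp", 0.1, 60, rng)
    b = CPCall("B", "nnxnp", {i: t for i, t in b.calls.items()})
    pl = lk.estimate_rf_em(a, b)
    assert pl.rf_hat == lk.RF_MAX_REPORT
    assert pl.phase == "--"
    assert pl.n_inf == 0


def _grid_oracle(calls_i, calls_j):
    """Brute-force likelihood maximization over rf in {0.001..0.499} and
    all phases, by direct enumeration of parental transmissions."""
    from conftest import PARENTS

    p1_i, p2_i = PARENTS[calls_i.cp_code]
    p1_j, p2_j = PARENTS[calls_j.cp_code]
    inf1 = p1_i[0] != p1_i[1] and p1_j[0] != p1_j[1]
    inf2 = p2_i[0] != p2_i[1] and p2_j[0] != p2_j[1]
    counts = {}
    for ind, ti in calls_i.calls.items():
        tj = calls_j.calls.get(ind)
        if ti == "--" or tj in (None, "--"):
            continue
        counts[(ti, tj)] = counts.get((ti, tj), 0) + 1

    def loglik(r, s1, s2):
        probs = {}
        for ai in (0, 1):
            for aj in (0, 1):
                for bi in (0, 1):
                    for bj in (0, 1):
                        p = 1.0
                        if inf1:
                            rec = (ai != aj) ^ s1
                            p *= r if rec else (1 - r)
                        if inf2:
                            rec = (bi != bj) ^ s2
                            p *= r if rec else (1 - r)
                        key = ("".join(sorted((p1_i[ai], p2_i[bi]))),
                               "".join(sorted((p1_j[aj], p2_j[bj]))))
                        probs[key] = probs.get(key, 0.0) + p
        return sum(c * math.log(probs[k]) for k, c in counts.items())

    best = None
    for s1 in ((0, 1) if inf1 else (0,)):
        for s2 in ((0, 1) if inf2 else (0,)):
            for r in np.arange(0.001, 0.5, 0.001):
                ll = loglik(float(r), s1, s2)
                if best is None or ll > best[0]:
                    best = (ll, float(r))
    return best[1]


@pytest.mark.parametrize("codes", [("hkxhk", "hkxhk"), ("lmxll", "hkxhk"),
                                   ("abxcd", "efxeg")])
def test_em_matches_grid_oracle(codes):
    rng = np.random.default_rng(7)
    for _ in range(4):
        r = float(rng.uniform(0.05, 0.35))
        a, b = simulate_cp_pair(*codes, r, 221, rng)
        em = lk.estimate_rf_em(a, b).rf_hat
        grid = _grid_oracle(a, b)
        assert abs(em - grid) <= 0.002


def test_independence_lod_diagonal_and_invariance():
    ci = {f"I{k}": ("ll" if k < 50 else "lm") for k in range(100)}
    cj = {f"I{k}": ("nn" if k < 50 else "np") for k in range(100)}
    a = CPCall("A", "lmxll", ci)
    b = CPCall("B", "nnxnp", cj)
    lod = lk.independence_lod(a, b)
    assert lod == pytest.approx(2 * 100 * math.log(2) / (2 * math.log(10)),
                                abs=1e-6)
    # permuting class labels leaves the statistic unchanged
    swapped = CPCall("B", "nnxnp", {i: ("np" if t == "nn" else "nn")
                                    for i, t in cj.items()})
    assert lk.independence_lod(a, swapped) == pytest.approx(lod, abs=1e-9)
    # degenerate single-class table
    const = CPCall("C", "nnxnp", {f"I{k}": "nn" for k in range(100)})
    assert lk.independence_lod(a, const) == 0.0


def _table(entries):
    out = {}
    for a, b, rf, lod in entries:
        out[(a, b)] = lk.PairwiseLinkage(a, b, rf, "cc", lod, 0.0, 200, 1)
    return out


def test_form_linkage_groups_and_monotonicity():
    table = _table([("A", "B", 0.1, 30), ("A", "C", 0.45, 30),
                    ("B", "C", 0.45, 30)])
    groups, singles = lk.form_linkage_groups(table, ["A", "B", "C"], 11, 0.4)
    assert groups == [["A", "B"]]
    assert singles == ["C"]
    # raising lod_min never merges groups
    g_low, _ = lk.form_linkage_groups(table, ["A", "B", "C"], 3, 0.4)
    assert len(g_low) <= len(groups) or \
        sum(map(len, g_low)) >= sum(map(len, groups))
    g_high, s_high = lk.form_linkage_groups(table, ["A", "B", "C"], 50, 0.4)
    assert len(s_high) >= len(singles)


def test_order_markers_three_and_two():
    table = _table([("A", "B", 0.10, 40), ("B", "C", 0.10, 40),
                    ("A", "C", 0.18, 40)])
    order, pos = lk.order_markers(["A", "B", "C"], table)
    assert order in (["A", "B", "C"], ["C", "B", "A"])
    assert pos[0] == 0.0 and pos[1] < pos[2]
    order, pos = lk.order_markers(["A", "B"], _table([("A", "B", 0.1, 40)]))
    assert order == ["A", "B"]
    assert pos[1] == pytest.approx(lk.haldane_cm(0.1), rel=0.05)


def test_order_recovery_on_simulated_20_marker_group():
    """Mixed-configuration 90 cM chain, n=221: order recovered with
    Kendall tau >= 0.9 (orientation-free)."""
    rng = np.random.default_rng(0)
    m = 20
    positions = np.sort(rng.uniform(0, 90, m))
    codes = list(rng.choice(
        ["lmxll", "nnxnp", "hkxhk", "abxcd"], size=m,
        p=[0.32, 0.36, 0.22, 0.10]))
    calls = simulate_cp_chain(codes, positions, 221, rng)
    table = lk.build_pairwise(calls)
    order, pos = lk.order_markers(sorted(calls), table)
    true_pos = dict(zip(sorted(calls), positions))
    tau = kendalltau([true_pos[x] for x in order], pos).statistic
    assert abs(tau) >= 0.9


def test_framework_map_drops_stranded_marker():
    rng = np.random.default_rng(3)
    positions = [0, 3, 6, 9, 12, 57.0]   # last marker 45 cM from nearest
    codes = ["abxcd"] * 6
    calls = simulate_cp_chain(codes, positions, 221, rng)
    gmap, report = lk.build_framework_map(calls, {}, min_group_size=4)
    far = sorted(calls)[-1]
    assert report["n_groups"] == 1
    assert far in gmap.unplaced
    assert far not in gmap.groups[0].markers


def test_framework_map_reinserts_distorted_without_reordering():
    rng = np.random.default_rng(4)
    positions = list(np.linspace(0, 60, 10))
    codes = ["abxcd"] * 10
    calls = simulate_cp_chain(codes, positions, 221, rng)
    distorted = sorted(calls)[4]
    gmap, report = lk.build_framework_map(
        calls, {distorted: "highly_distorted"})
    assert report["n_highly_distorted_excluded"] == 1
    assert report["n_distorted_reinserted"] == 1
    lg = gmap.groups[0]
    framework_order = [m for m in lg.markers if m != distorted]
    gmap2, _ = lk.build_framework_map(
        {m: c for m, c in calls.items() if m != distorted}, {})
    assert framework_order in (gmap2.groups[0].markers,
                               gmap2.groups[0].markers[::-1])
    i = lg.markers.index(distorted)
    assert lg.nearest_neighbor_cm(i) <= 40.0


def _gmap(groups, provenance="parent1"):
    return lk.GeneticMap(
        groups=[lk.LGMap(i + 1, list(m), list(p))
                for i, (m, p) in enumerate(groups)],
        provenance=provenance)


def test_integrate_identical_maps_is_identity():
    g = _gmap([(["a", "b", "c"], [0.0, 10.0, 25.0])])
    merged, conflicts = lk.integrate_parental_maps(
        g, _gmap([(["a", "b", "c"], [0.0, 10.0, 25.0])], "parent2"))
    assert not conflicts
    assert merged.groups[0].markers == ["a", "b", "c"]
    assert merged.groups[0].positions == pytest.approx([0.0, 10.0, 25.0])


def test_integrate_scaled_map_gives_parent_average():
    g1 = _gmap([(["a", "b", "c"], [0.0, 10.0, 20.0])])
    g2 = _gmap([(["a", "b", "c"], [0.0, 20.0, 40.0])], "parent2")
    merged, conflicts = lk.integrate_parental_maps(g1, g2)
    assert not conflicts
    assert merged.groups[0].positions == pytest.approx([0.0, 15.0, 30.0])
    assert merged.provenance == "integrated"


def test_integrate_interpolates_private_markers():
    g1 = _gmap([(["a", "x", "b"], [0.0, 5.0, 10.0])])
    g2 = _gmap([(["a", "b", "y"], [0.0, 20.0, 30.0])], "parent2")
    merged, conflicts = lk.integrate_parental_maps(g1, g2)
    assert not conflicts
    pos = dict(zip(merged.groups[0].markers, merged.groups[0].positions))
    assert pos["x"] == pytest.approx(7.5)     # midway between the anchors
    assert pos["y"] == pytest.approx(22.5)    # terminal-rate extrapolation


def test_integrate_conflicting_anchor_order_flagged():
    g1 = _gmap([(["a", "b", "c"], [0.0, 10.0, 20.0])])
    g2 = _gmap([(["b", "a", "c"], [0.0, 10.0, 20.0])], "parent2")
    _, conflicts = lk.integrate_parental_maps(g1, g2)
    assert len(conflicts) == 1


def test_total_map_length_formula_cases():
    single = _gmap([(["a", "b", "c"], [0.0, 10.0, 30.0])])
    out = lk.estimate_total_map_length(single)
    assert out["observed_cM"] == pytest.approx(30.0)
    assert out["mean_spacing_cM"] == pytest.approx(15.0)
    assert out["corrected_cM"] == pytest.approx(30.0 + 2 * 15.0)
    colocated = _gmap([(["a", "b"], [0.0, 0.0])])
    out = lk.estimate_total_map_length(colocated)
    assert out["observed_cM"] == 0.0
    assert out["telomere_correction_cM"] == 0.0
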