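"""End-to-end pipeline: simulate -> assay -> call -> screen -> map -> synteny.

Every stage is deterministic given the config seed (stage seeds are spawned
from it), and all artifacts are written as plain-text tables so a run is
fully reconstructible from its output directory.  When the input data come
from the built-in simulator the report additionally scores recovery against
the generator's ground truth (marker-class accuracy, per-LG order
correlation, karyotype-event detection).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, cross, karyotype, linkage, segregation, synteny
from .errors import InvalidParameterError, TetralinkError
from .io import (PipelineConfig, write_cp_locus_file, write_map_tsv,
                 write_pairwise_tsv, write_tsv)

log = logging.getLogger("tetralink")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _parent_as_individual(parent: cross.PhasedParent, which: int
                          ) -> cross.Individual:
    h = parent.haplotypes
    g1 = cross.Gamete({lg: dict(pair[0]) for lg, pair in h.items()})
    g2 = cross.Gamete({lg: dict(pair[1]) for lg, pair in h.items()})
    return cross.Individual(f"P{which}", "parent", g1, g2)


def simulate_stage(config: PipelineConfig) -> dict:
    """Generate the truth karyotype, markers, population, and raw data."""
    sim = config.simulation
    seeds = _spawn_seeds(config.seed, 8)
    genome = karyotype.simulate_ancestral_genome(
        sim.n_chrom, sim.length_range_cM, sim.centromere_fraction_range,
        seed=seeds[0])
    truth = karyotype.apply_wgd(genome, seed=seeds[0])
    if sim.fusion_inserted_lg and sim.fusion_target_lg:
        truth = karyotype.apply_insertional_fusion(
            truth, sim.fusion_inserted_lg, sim.fusion_target_lg)
    markers = karyotype.place_markers(truth, sim.n_snv, sim.n_ssr,
                                      seed=seeds[1])
    p1, p2 = cross.build_phased_parents(truth, markers)

    # viability selection: simulate a surplus pool sized for the expected
    # survival rate, select, then truncate to the target population size
    n_loci = sim.n_distortion_loci
    weights = [sim.distortion_weights[k % len(sim.distortion_weights)]
               for k in range(n_loci)]
    survival = math.prod((1.0 + w) / 2.0 for w in weights) if n_loci else 1.0
    pool = int(math.ceil(sim.n_f1 / survival * 1.2)) if n_loci else sim.n_f1
    population = cross.simulate_f1_population(p1, p2, truth, pool,
                                              seed=seeds[2])
    rng = np.random.default_rng(seeds[3])
    distortion_truth = []
    if n_loci:
        # distort the B allele at testcross-like loci whose homozygous
        # parent is A/A, so genotype fitnesses are 1 (AA) vs w (AB)
        candidates = [
            m for m in markers
            if m.marker_type == "snv"
            and m.true_class in ("biallelic_unique",
                                 "biallelic_with_fixed_paralog")
            and ((set(m.parent1_genotype) == {"A", "B"}
                  and m.parent2_genotype == ("A", "A"))
                 or (set(m.parent2_genotype) == {"A", "B"}
                     and m.parent1_genotype == ("A", "A")))]
        chosen = rng.choice(len(candidates),
                            size=min(n_loci, len(candidates)), replace=False)
        for k, mi in enumerate(chosen):
            m = candidates[int(mi)]
            population = cross.apply_segregation_distortion(
                population, truth, m.locus_id, {"B": weights[k]},
                seed=int(rng.integers(2 ** 31)))
            distortion_truth.append({"locus_id": m.locus_id,
                                     "marker_id": m.marker_id,
                                     "allele": "B", "weight": weights[k]})
    population = population[:sim.n_f1]

    parents = [_parent_as_individual(p1, 1), _parent_as_individual(p2, 2)]
    dhs = [cross.simulate_doubled_haploid(p, truth, seed=seeds[4] + i,
                                          individual_id=f"DH_{i:04d}")
           for i, p in enumerate([p1, p2][:sim.n_doubled_haploid])]

    intensities = cross.assay_population(parents + population, markers, truth,
                                         sim.gain, sim.noise_sd, seed=seeds[5])
    dh_intensities = cross.assay_population(dhs, markers, truth, sim.gain,
                                            sim.noise_sd, seed=seeds[6])
    ssr_calls = cross.simulate_ssr_calls(parents + population, markers, truth,
                                         sim.ssr_dropout, seed=seeds[7])
    return {
        "truth": truth, "markers": markers, "parents": (p1, p2),
        "population": population, "doubled_haploids": dhs,
        "intensities": intensities, "dh_intensities": dh_intensities,
        "ssr_calls": ssr_calls, "distortion_truth": distortion_truth,
    }


def call_stage(sim_out: dict, config: PipelineConfig) -> dict:
    """Cluster signals, classify markers, and produce CP calls."""
    cal = config.calling
    truth_markers = {m.marker_id: m for m in sim_out["markers"]}
    progeny_ids = [ind.individual_id for ind in sim_out["population"]]
    models: dict[str, calling.ClusterModel] = {}
    cp_calls: dict[str, calling.CPCall] = {}
    class_rows = []
    for marker_id, grp in sim_out["intensities"].groupby("marker_id", sort=True):
        model = calling.cluster_marker_signals(
            grp, k_max=cal.k_max, r_floor=cal.r_floor,
            min_weight=cal.min_weight, min_sep=cal.min_sep,
            seed=config.seed % (2 ** 31))
        model = calling.classify_marker(model, cal.center_tolerance,
                                        cal.skew_tolerance)
        models[str(marker_id)] = model
        cp_code = ""
        if model.class_label.startswith("segregating"):
            genos = calling.call_genotypes(model, grp)
            try:
                call = calling.assign_cp_snv(
                    str(marker_id), genos.get("P1"), genos.get("P2"),
                    {i: genos.get(i) for i in progeny_ids})
                cp_calls[str(marker_id)] = call
                cp_code = call.cp_code
            except InvalidParameterError:
                pass   # parents not called; marker unusable for mapping
        class_rows.append({
            "marker_id": marker_id, "k": model.k,
            "class_label": model.class_label, "skew": model.skew,
            "cp_code": cp_code,
            "true_class": truth_markers[str(marker_id)].true_class
            if str(marker_id) in truth_markers else "",
        })
    # SSR markers: scored directly from fragment sizes
    ssr = sim_out["ssr_calls"]
    for marker_id, grp in ssr.groupby("marker_id", sort=True):
        sizes = {str(r.individual_id):
                 tuple(int(s) for s in r.sizes.split(",")) if r.sizes else ()
                 for r in grp.itertuples()}
        p1s, p2s = sizes.pop("P1", ()), sizes.pop("P2", ())
        if not p1s or not p2s:
            continue
        try:
            call = calling.assign_cp_ssr(str(marker_id), p1s, p2s, sizes)
        except TetralinkError:
            continue
        if call.cp_code in ("lmxll", "nnxnp") and len(set(p1s) | set(p2s)) < 2:
            continue
        cp_calls[str(marker_id)] = call
        class_rows.append({"marker_id": marker_id, "k": 0,
                           "class_label": "ssr", "skew": "none",
                           "cp_code": call.cp_code, "true_class": "ssr"})
    dh_report = calling.corroborate_with_dh(models, sim_out["dh_intensities"])
    classification = pd.DataFrame(
        class_rows, columns=["marker_id", "k", "class_label", "skew",
                             "cp_code", "true_class"])
    return {"models": models, "cp_calls": cp_calls,
            "classification": classification,
            "dh_report": dh_report}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write artifacts; returns the summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d config=%s", config.seed, config.hash())
    report: dict = {"seed": config.seed, "config_hash": config.hash()}

    stage = "simulate"
    try:
        sim_out = simulate_stage(config)
        truth: karyotype.KaryotypeTruth = sim_out["truth"]
        write_tsv(truth.truth_table(), out / "truth_loci.tsv")
        write_tsv(karyotype.marker_table(sim_out["markers"]),
                  out / "markers.tsv")
        sim_out["intensities"].to_csv(out / "intensities.csv", index=False)
        sim_out["ssr_calls"].to_csv(out / "ssr_calls.csv", index=False)

        stage = "call"
        call_out = call_stage(sim_out, config)
        cp_calls = call_out["cp_calls"]
        write_tsv(call_out["classification"], out / "marker_classes.tsv")
        progeny_ids = [i.individual_id for i in sim_out["population"]]
        write_cp_locus_file(out / "cp_locus.loc", cp_calls, progeny_ids,
                            name=f"sim_seed{config.seed}")

        stage = "segregation"
        seg = segregation.screen_markers(cp_calls, alpha=config.mapping.alpha)
        write_tsv(seg, out / "segregation.tsv")
        distortion = dict(zip(seg["marker_id"], seg["distortion_class"]))

        stage = "map"
        table = linkage.build_pairwise(cp_calls, min_n=config.mapping.min_n)
        gmap, map_report = linkage.build_framework_map(
            cp_calls, distortion, lod_min=config.mapping.lod_min,
            rf_max=config.mapping.rf_max, orphan_cm=config.mapping.orphan_cm,
            min_n=config.mapping.min_n, table=table)
        write_map_tsv(gmap, out / "map.tsv")
        write_pairwise_tsv(table, out / "pairwise.tsv")
        length = linkage.estimate_total_map_length(gmap) if gmap.groups else {}

        stage = "synteny"
        hits = synteny.generate_hit_table(
            truth, sim_out["markers"],
            p_unassignable=config.synteny.p_unassignable,
            spurious_rate=config.synteny.spurious_rate,
            seed=_spawn_seeds(config.seed, 9)[-1])
        write_tsv(hits, out / "hits.tsv")
        assignments = synteny.assign_orthologs(hits, config.synteny.min_share)
        positions = gmap.marker_positions()
        dot, unassigned = synteny.build_dot_plot(
            {m: (lg, pos) for m, (lg, pos) in positions.items()}, assignments)
        write_tsv(dot, out / "dotplot.tsv")
        assoc, wgd_flag = synteny.detect_wgd(dot, config.synteny.min_markers)
        fusions = synteny.detect_fusion(dot, config.synteny.min_block)
    except TetralinkError as exc:
        raise TetralinkError(f"stage {stage!r} failed: {exc}") from exc

    class_counts = (call_out["classification"]["class_label"]
                    .value_counts().to_dict())
    n_seg = sum(1 for s in seg["distortion_class"])
    report.update({
        "n_markers_simulated": len(sim_out["markers"]),
        "n_individuals": len(sim_out["population"]),
        "marker_class_counts": class_counts,
        "n_cp_markers": len(cp_calls),
        "n_tested": n_seg,
        "n_distorted": int((seg["p"] <= config.mapping.alpha).sum()),
        "n_highly_distorted": int(
            (seg["distortion_class"] == "highly_distorted").sum()),
        "dh_violations": len(call_out["dh_report"]),
        "map": map_report,
        "map_length": length,
        "wgd_flag": bool(wgd_flag),
        "chrom_to_lg": {str(k): [str(x) for x in v] for k, v in assoc.items()},
        "fusion_calls": [{
            "lg": str(f.lg), "outer_ref_chrom": int(f.outer_ref_chrom),
            "inner_ref_chrom": int(f.inner_ref_chrom),
            "boundary_start_cM": f.boundary_start_cM,
            "boundary_end_cM": f.boundary_end_cM,
            "inner_ends_interior": f.inner_ends_interior} for f in fusions],
        "recovery": score_recovery(sim_out, call_out, gmap),
    })
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    log.info("pipeline done: %d groups, %d markers mapped",
             map_report["n_groups"],
             sum(len(g.markers) for g in gmap.groups))
    report["_gmap"] = gmap
    report["_truth"] = truth
    report["_sim"] = sim_out
    report["_calls"] = cp_calls
    report["_dotplot"] = dot
    return report


def score_recovery(sim_out: dict, call_out: dict, gmap) -> dict:
    """Compare recovered classes, groups and orders against simulation truth."""
    from scipy.stats import kendalltau

    truth: karyotype.KaryotypeTruth = sim_out["truth"]
    markers = {m.marker_id: m for m in sim_out["markers"]}
    cls = call_out["classification"]
    snv = cls[cls["true_class"].isin(karyotype.MARKER_CLASSES)]
    recovered = [calling.recovered_class(call_out["models"][m])
                 for m in snv["marker_id"]]
    correct = sum(1 for r, t in zip(recovered, snv["true_class"]) if r == t)
    class_acc = correct / len(snv) if len(snv) else float("nan")

    # match each recovered group to the truth LG contributing most markers
    taus = []
    composition = []
    for g in gmap.groups:
        true_lgs = []
        for m in g.markers:
            md = markers.get(m)
            if md is None:
                continue
            true_lgs.append(truth.loci[md.locus_id].lg_id)
        if not true_lgs:
            continue
        major = max(set(true_lgs), key=true_lgs.count)
        composition.append(true_lgs.count(major) / len(true_lgs))
        pos_true, pos_rec = [], []
        for m, p in zip(g.markers, g.positions):
            md = markers.get(m)
            if md is None:
                continue
            locus = truth.loci[md.locus_id]
            if locus.lg_id == major:
                pos_true.append(locus.pos_cM)
                pos_rec.append(p)
        if len(pos_true) >= 3:
            tau = kendalltau(pos_true, pos_rec).statistic
            taus.append(abs(tau))
    return {
        "class_accuracy": class_acc,
        "n_groups": len(gmap.groups),
        "group_purity_min": min(composition) if composition else float("nan"),
        "order_tau_min": min(taus) if taus else float("nan"),
        "order_tau_mean": (sum(taus) / len(taus)) if taus else float("nan"),
    }
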