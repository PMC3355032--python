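#!/usr/bin/env python
"""Synteny against the ancestral reference: dot plot, WGD, fusion.

Mapped markers are assigned reference positions by the best-hit rule
(most identical residues, >= 80% of probe residues shared, ties dropped);
the dot plot is scanned for the 1 chromosome : 2 linkage-group
correspondence of a whole-genome duplication and for the outer-inner-outer
sandwich of an insertional chromosome fusion.
"""

import argparse
from pathlib import Path

from tetralink import linkage, synteny
from tetralink.io import PipelineConfig, write_tsv
from tetralink.pipeline import call_stage, simulate_stage
from tetralink.segregation import screen_markers

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/synteny"))
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed)
sim = simulate_stage(cfg)
calls = call_stage(sim, cfg)["cp_calls"]
seg = screen_markers(calls, alpha=cfg.mapping.alpha)
gmap, _ = linkage.build_framework_map(
    calls, dict(zip(seg["marker_id"], seg["distortion_class"])),
    min_n=cfg.mapping.min_n)

hits = synteny.generate_hit_table(
    sim["truth"], sim["markers"],
    p_unassignable=cfg.synteny.p_unassignable,
    spurious_rate=cfg.synteny.spurious_rate, seed=cfg.seed)
assignments = synteny.assign_orthologs(hits, cfg.synteny.min_share)
dot, unassigned = synteny.build_dot_plot(gmap.marker_positions(), assignments)
assoc, wgd_flag = synteny.detect_wgd(dot, cfg.synteny.min_markers)
fusions = synteny.detect_fusion(dot, cfg.synteny.min_block)

args.out.mkdir(parents=True, exist_ok=True)
write_tsv(hits, args.out / "hits.tsv")
write_tsv(dot, args.out / "dotplot.tsv")

print(f"{len(dot)} markers assigned to reference positions "
      f"({len(unassigned)} mapped markers unassignable)")
print(f"whole-genome duplication flag: {wgd_flag}; chromosome -> LG "
      f"associations: " + ", ".join(
          f"{c}:{len(lgs)}" for c, lgs in sorted(assoc.items())))
for f in fusions:
    print(f"fusion on LG {f.lg}: reference chromosome {f.inner_ref_chrom} "
          f"inserted into {f.outer_ref_chrom} between "
          f"{f.boundary_start_cM:.1f} and {f.boundary_end_cM:.1f} cM; "
          f"inserted chromosome's original ends interior: "
          f"{f.inner_ends_interior}")
if not fusions:
    print("no insertional fusion detected")
print(f"outputs in {args.out}/")
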