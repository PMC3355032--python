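# tetralink

Linkage mapping and comparative-genomics analysis for a recently
tetraploidized, outbreeding grass, built as a fully simulated study.

## The problem

In a genome that doubled only a few million years ago, the two copies of
every gene (homoeologs/paralogs) have diverged about as much as the two
alleles at a single locus. A variant discovered from sequencing reads can
therefore be a real segregating SNP, a fixed difference between the two
paralogous loci, or a SNP whose assay signal is contaminated by a fixed
paralog — and a two-channel genotyping array cannot tell these apart from
one sample alone. The classic solution is segregation analysis in an
outbred F1 (cross-pollinator, "CP") family: fixed paralog differences put
every individual in one central signal cluster; a paralog fixed for one
allele shifts the cluster grid from theta = {0, 1/2, 1} to {1/2, 3/4, 1}
or {0, 1/4, 1/2} (an A/B heterozygote over a B/B paralog gives a 3:1 B:A
signal ratio); doubled haploid lines corroborate the interpretation
because they cannot be heterozygous at a real locus yet still show both
variants of a paralog pair. With the markers sorted out, a genetic map
built at stringent linkage thresholds resolves the expected chromosome
number, and a dot plot against the unduplicated relative's genome exposes
the karyotype history — every reference chromosome syntenic to two
linkage groups (whole-genome duplication), except one pair fused by a
centromeric insertion that explains an odd base chromosome number.

`tetralink` implements that entire chain on synthetic data with known
ground truth: karyotype simulation (WGD + insertional fusion), disomic
Haldane meiosis in an outbred cross, the two-channel dosage assay,
mixture-model cluster calling with skew classification, chi-square
segregation screening with two-tier distortion rules (2:1 over expected
1:1, 10:1 over expected 3:1), two-point rf estimation by EM over parental
phases with independence-LOD grouping (LOD ≥ 11, rf ≤ 0.4), least-squares
marker ordering, framework-map construction with distorted-marker
re-insertion, telomere-corrected map-length estimation, and WGD/fusion
detection from the dot plot. See `docs/methods.md` for the model details.

## Worked example

```bash
tetralink run-all --seed 1 --out-dir results/run1
# or the staged drivers:
python analysis/01_simulate_cross.py --seed 1
python analysis/04_build_map.py --seed 1
python analysis/05_synteny_scan.py --seed 1
```

The map stage prints (seed 1):

```
19 linkage groups (1 singletons, 3 markers in minor fragments); 2 of 3 distorted markers re-inserted
observed length 1599 cM; mean spacing 4.72 cM; telomere correction 2 x 19 x 4.72 = 179 cM; corrected total 1779 cM
```

i.e. the 10 duplicated-and-once-fused ancestral chromosomes are recovered
as exactly 19 linkage groups; the telomere correction adds two mean
marker spacings per group for the unobserved chromosome ends. The synteny
stage prints:

```
whole-genome duplication flag: True; chromosome -> LG associations: 1:2, 2:2, ..., 10:2
fusion on LG 7: reference chromosome 7 inserted into 4 between 34.6 and 111.4 cM; inserted chromosome's original ends interior: True
```

— every reference chromosome maps to two linkage groups, and the fused
group shows the insertional signature (the inserted chromosome's original
telomeres lie interior to the block, where they were lost in the fusion).

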