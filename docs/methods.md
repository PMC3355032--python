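# Methods

`tetralink` models the marker-development and mapping problem of a
recently tetraploidized, self-incompatible grass: the genome carries two
barely diverged copies of every locus, so a variant discovered from short
sequence reads may be an allele segregating at one locus, a fixed
difference between the two paralogous loci, or both at once. The package
simulates this situation end to end and implements the inference chain
that untangles it: dosage-aware genotype calling, cross-pollinator (CP)
linkage analysis, and comparative detection of the karyotype events.

## Karyotype simulation

The ancestral genome is N chromosomes (default N = 10) with genetic
lengths drawn uniformly from 88-100 cM and a centromere at a uniform
fraction (0.35-0.65) of the length. Whole-genome duplication copies every
chromosome; the two copies are strictly disomic (they never pair at
meiosis). One insertional fusion then merges two copies: the inserted
chromosome is circularly permuted at its centromere and spliced into the
target chromosome's centromere, so the fused group reads
arm-1 / distal-insert / proximal-insert / arm-2 and the inserted
chromosome's original telomeric ends become interior, adjacent
coordinates. Genetic lengths are conserved through both events — the
observed duplicated map is no longer than the ancestral one, so cM length
is treated as a free parameter rather than doubling; the default per-group
length mimics an observed 1782 cM / 19 group map (~94 cM each). A
synthetic physical scale (0.75 Mb per cM) exists only so dot plots have a
physical axis; only its monotonicity matters.

Each marker locus descends from a single ancestral position and therefore
has exactly two registered descendants (paralogs, symmetric links). SNV
marker classes default to 33% fixed paralog differences (single central
cluster), 17.4% segregating with a fixed paralog (26% of the segregating
two-cluster markers, matching the observed skewed fraction), 49.6%
segregating unique, 0% monomorphic. Which parent is heterozygous follows
the observed SNP configuration mix (0.32 parent-1 only / 0.39 parent-2
only / 0.29 both). SSR markers are always segregating, with configurations
up to the fully informative four-allele case. Placement is uniform along
the genome; no clustering model is imposed.

## Cross and assay simulation

Meiosis is Haldane: crossovers per linkage group are Poisson with mean
length/100, positions uniform, no interference, and recombination only
between homologs. F1 individuals take one gamete from each outbred
parent; doubled haploids duplicate a single gamete. Segregation
distortion is viability selection after gamete union: an individual
survives with probability equal to the product of its two allele weights
at the selected locus. The pipeline applies this at two testcross loci
whose homozygous parent is A/A (fitness 1 vs w for the heterozygote), with
survival weights 0.3 and 0.65 — one clearly beyond the 2:1 exclusion rule,
one near the significance boundary — simulating a surplus pool sized by
the expected survival rate and truncating to the 221-individual study
population.

The assay is a pure dosage model: channel intensity = gain x copy number
of that allele summed over the loci the probe samples (the segregating
locus, plus its paralog when the marker class involves one), plus
per-channel Gaussian noise truncated at zero (default sd 0.03 x gain in
the pipeline). theta is the plain proportion B/(A+B), not the arctan
transform of commercial software, which keeps the noiseless dosage grid
exactly {0, 1/4, 1/2, 3/4, 1}: a heterozygote over a B/B-fixed paralog
contributes B:A = 3:1 and lands at theta = 0.75. SSR genotypes are
simulated directly as allele-size sets (fragment-analysis abstraction)
with optional dropout; no stutter model.

## Cluster calling

Per marker, theta values of individuals with R above a no-call floor
(default 0.5, about a quarter of the weakest expected signal) are fitted
with 1-D Gaussian mixtures for k = 1..5; k is chosen by BIC with ties
toward fewer clusters. Two guards reject pathological fits: a minimum
component weight (0.02) against singleton clusters, and a minimum
between-mean separation (0.1) — dosage-grid clusters are at least 0.25
apart, whereas the zero-truncation of intensities makes the extreme theta
clusters non-Gaussian and would otherwise be shattered by BIC. Points
below the R floor, and outliers more than 5 cluster standard deviations
from every mean, are no-calls; the latter rule is what keeps a doubled
haploid homozygous for an allele absent from the cross out of the
progeny clusters instead of forcing a wrong call.

Classification is deterministic (replacing the manual cluster review of
the original assay software): one cluster within 0.12 of theta = 0.5 is a
fixed paralog difference, one cluster near 0 or 1 is monomorphic, more
than three clusters is discarded, two or three clusters are segregating
with skew decided by nearest-grid matching against {0, 1/2, 1} (none),
{1/2, 3/4, 1} (paralog fixed B) and {0, 1/4, 1/2} (paralog fixed A); ties
go to "none" and a worst-deviation tolerance of 0.08 applies. The grid
match also fixes the cluster-to-genotype mapping used for CP recoding.

## Segregation screening

Pearson goodness of fit against the configuration's Mendelian ratio, raw
per-marker threshold p <= 0.005, no multiple-testing correction (an
optional Bonferroni flag exists, off by default, to match the original
per-marker practice). Highly distorted markers — observed majority ratio
above 2:1 where 1:1 is expected, above 10:1 where 3:1 is expected, and,
as this package's extension, above 2:1 between the homozygous classes of
a 1:2:1 marker — are excluded from framework mapping and re-inserted
afterwards. Four-class configurations have no ratio rule (p-value tier
only). `highly_distorted` is reported as a subset of the distorted set.

## Two-point linkage

For a marker pair, each parent heterozygous at both markers contributes
one meiosis per individual; the joint-genotype multinomial likelihood is
maximized over rf by EM (latent: which transmissions were recombinant,
unresolvable only for the double heterozygote of an hkxhk pair), per
admissible phase assignment, keeping the best phase. Estimates are
clipped to [0, 0.4999] so the Haldane transform stays finite. Linkage
evidence is the independence LOD: the G statistic of the joint
contingency table divided by 2 ln 10 — a convention chosen because a test
of independence is robust to segregation distortion; its exact JoinMap
counterpart is unpublished. Pairs with no shared informative meioses
(parent-1-only against parent-2-only testcross markers) carry no linkage
information and are reported at the boundary. The all-pairs table
computes the cheap LOD everywhere and defers the EM to pairs with LOD >=
3; within-group pairs skipped by that prefilter are filled in before
ordering.

Groups are connected components at LOD >= 11 and rf <= 0.4. Only major
groups (>= 4 markers) constitute the map; smaller fragments — typically a
few markers isolated by a local gap in one parent's informative-marker
coverage — are reported as unplaced, the usual accounting for real maps,
where a handful of markers always remains off the major groups.

## Ordering and positions

The prescribed-by-design first candidate, minimizing the sum of adjacent
recombination fractions (SARF) with 2-opt, proved counterproductive on
simulated data at the study conditions: with ~20 markers per group and
two-point noise of rmse ~0.03, 2-opt on SARF actively degraded correct
seeds (mean per-group Kendall tau vs truth 0.885), because an
adjacent-only objective is dominated by the noisiest local estimates and
by completed distances between cross-parent pairs. The shipped method
minimizes a *global* weighted least-squares stress: for a candidate
order, 1-D marker coordinates are solved to fit all estimable pairwise
Haldane distances (weights = inverse asymptotic variance of each rf,
using n x informative-meioses as the effective count), and the residual
is the objective. Optimization: two starts (greedy SARF insertion and
the first classical-MDS coordinate of the shortest-path-completed
distance matrix), iterated solve-and-re-sort, then relocation/2-opt
hill-climbing on the exact stress (mean tau 0.96 at the same
conditions). Positions are the LS coordinates of the final order,
monotone-projected and anchored at zero — not chained adjacent
distances, which double-count noise and are undefined for cross-parent
adjacencies. Orientation is canonicalized by marker id; all ties break
lexicographically, making the build reproducible.

A residual limitation is inherent to the design, not the optimizer: a
testcross marker of one parent placed among testcross markers of the
other parent is constrained only through nearby markers heterozygous in
both parents. In a group with a single such anchor, exhaustive
enumeration shows the stress optimum is a plateau containing the true
order — the data cannot resolve the interleaving, and order-recovery
scores for such groups saturate below ~0.9.

## Framework map procedure

(1) exclude highly distorted markers; (2) group; (3) order; (4) drop any
marker more than 40 cM from its nearest neighbor and re-order the
affected group (iterated to a fixpoint); (5) re-insert each highly
distorted marker: only groups containing a framework marker linked to it
at the grouping thresholds qualify; its coordinate is a grid/LS fit of
its anchor distances with the framework positions held fixed, the
insertion slot follows from the coordinate (framework order never
permuted), and the placement is accepted only if the nearest framework
neighbor is within 40 cM.

Parental maps (markers heterozygous in that parent) can be integrated
through shared anchors by monotone piecewise-linear alignment to the
anchor-average scale, with private markers interpolated (terminal-rate
extrapolation at the ends); groups with conflicting anchor orders are
flagged and left unmerged. The total-length estimate adds
2 x groups x mean spacing for unobserved telomeric ends, with colocated
markers pooled when computing the mean spacing.

## Synteny

Hit tables are BLAST-like TSVs; the synthetic generator fabricates them
from truth (every marker descends from one ancestral position) with a
configurable unassignable fraction (default 0.05) and Poisson spurious
hits. Assignment takes the hit with most identical residues if it covers
at least 80% of probe residues; exact ties are unassigned. Duplication
detection associates each reference chromosome with the linkage groups
holding at least 5 of its markers and raises the WGD flag when at least
80% of chromosomes associate with exactly two groups. Fusion detection
scans each group's cM-ordered assigned markers for maximal
same-chromosome runs (isolated singletons dropped, runs >= 4 markers):
an outer-inner-outer sandwich whose outer runs are disjoint arms of one
chromosome and whose inner run spans >= 70% of the other chromosome's
observed extent yields a fusion call; the insertional signature is a
non-monotone inner run whose extreme reference positions are adjacent at
the interior wrap point (the circular-permutation scar where the lost
telomeres met). Segment orientations are observable in the dot plot but
inversion detection is not implemented.

## What the simulation does and does not capture

The generator reproduces the structural features the method depends on —
two-locus dosage, disomic transmission, CP configuration mixes, viability
distortion, karyotype events — but not assay-specific artifacts:
normalization drift, intensity-dependent noise, SSR stutter, pollen
contamination, or genuine multi-locus (>2) gene families. Passing
recovery tests therefore demonstrates correctness of the inference chain
under the stated model, not robustness to every artifact of a real
genotyping run. Noise magnitudes and the R floor are free parameters, not
estimates of any particular assay.

## Problem sizes and numerics

The default pipeline (500 SNV + 60 SSR markers, 221 individuals) runs in
about a minute on one core; tests use smaller configurations except the
single full-scale recovery run, which is shared across assertions.
Numerical choices worth noting: mixture fits use spherical components
with reg_covar 1e-6 and 3 initializations at a fixed random state; EM for
rf starts at 0.25 and stops at |Δr| < 1e-9; grid searches for distorted
re-insertion step 0.25 cM; least-squares systems carry a 0.01 ridge row
to fix the translational gauge; degenerate inputs (empty marker sets,
single-marker groups, zero-signal assays) return empty/failed results
rather than raising.
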