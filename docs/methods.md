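# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions behind `reprotalk`, and what the synthetic-data generator does
and does not emulate.

## Synthetic data model

Counts are gamma-Poisson: gene `g` in cell `c` has mean
`m_gc = base_g · effect_gc · lib_c` and dispersion `θ`
(variance `m + m²/θ`).  Baseline means `base_g` are log-uniform on
(0.05, 4); the library factor `lib_c` is log-normal(0, 0.25); `θ = 2`,
a moderate overdispersion typical of UMI data for expressed genes.

Cells sampled before or at the branch day (default day 7) share one somatic
state; afterwards each cell is secretory-somatic or developmental with
probability `trajectory_mix` (0.5).  `effect_gc` composes:

* **Signature blocks** — a signature is `n_genes` genes multiplied by
  `2^log2_effect` in cells of a given trajectory inside a day window.  Two
  regimes exist.  *Graded* signatures shift well-detected genes (SASP 2.0,
  apoptosis 0.25, pathway targets 2.5, phase sets 2.0).  *On/off
  lineage-marker* signatures put the baseline at the low end of the mean
  range (detection ≈ 5%) and activate strongly: somatic and developmental
  programs (80 genes, log2 effect 6, on for the whole lifetime of the
  branch) and the endpoint signatures matrisome / late pluripotency
  (30 genes, log2 effect 8, days 13–15).
* **Day drift** — 60 genes ramp linearly (in log2) with sampling day in
  every cell, giving the time course a continuous axis.
* **Phases** — each cell is G1/S/G2M (0.5/0.25/0.25); S and G2M sets are
  up 4× in their phase.
* **Planted ligand-receptor pairs** — the ligand gene is up `2^effect` in
  the source trajectory and the receptor in the target trajectory inside
  the pair's day window (default: one pair, 2-fold, days 9–15).
* **QC violators** — ~4% of cells get either an 8× mitochondrial boost or
  a collapsed (3%) library.

Why on/off endpoint markers: with sparse counts, log2-CPM is close to a
detection indicator, so the per-cell truncated-z enrichment score of a gene
active in a fraction `p` of cells is bounded by `sqrt((1−p)/p)` no matter
how large the shift.  Graded shifts on well-detected genes therefore cannot
reach the endpoint-selection threshold (ES > 2); rare-baseline,
strongly-activated markers — the realistic regime for fate markers such as
collagens or core pluripotency factors — can, and are the planted
conditions under which the endpoint rule is exercised.

The secretome panel is `n_proteins × 7 windows × 3 replicates` with
log-normal base intensities (σ = 0.8), multiplicative replicate noise
(σ = 0.12) and per-sample protein amounts around 40 µg.  Protein classes:
planted-dynamic (ligands follow their pair's window; others ramp or
pulse, log2 effect 1.5), flat, serum-residual (2-fold decay per window, so
strictly maximal in window 1), contaminants (flagged), and sparse
(observed in exactly one replicate everywhere, to exercise the replicate
filter deterministically).  Missing values are injected at `missing_rate`
but never remove two replicates of a survivor protein, so filter outcomes
are controlled by class, not chance.

Not emulated: batch effects, doublets, ambient RNA, read-level error,
UMI saturation, protein-level FDR structure.  Passing tests therefore show
the pipeline's statistics behave correctly under its own model assumptions,
not that the assumptions hold for any particular real dataset.

All randomness flows from `SimConfig.seed` through one generator; fixed
seeds reproduce byte-identical outputs across processes (set iteration is
avoided anywhere it would touch RNG order).

## Secretome stage

Order of operations: contaminant removal → ≥2-of-3-replicates filter →
imputation (a single missing replicate per protein/window becomes the mean
of the other two; cells with ≥2 missing are left missing and logged) →
division by per-sample protein amount → per-replicate median scaling
(each replicate's distribution over all proteins and windows has median 1
afterwards).  Amount normalisation precedes median scaling; the order is a
convention of this package.

Differential accumulation uses the two-sample equal-variance Student t-test
with n = 3 per group and a plain 5% threshold, with no multiple-testing
correction at this stage — a deliberate fidelity-over-optimality choice
mirroring a plain-threshold design; downstream users can correct the
reported p-values.  Proteins whose replicate-mean profile is *strictly*
maximal at the first window are excluded beforehand (serum carry-over);
ties with a later window do not exclude.  Both groups constant and equal
gives p = 1 with a `degenerate` flag.

Profile clustering z-scores each protein's window profile (constant
profiles map to all-zero so the clustering stays total) and applies
complete-linkage hierarchical clustering on Euclidean distances; the leaf
order is scipy's deterministic order.  PCA is on mean-centred (not
variance-scaled) intensities over the (window, replicate) samples; each
component's sign is fixed so its largest-magnitude loading is positive.

## Single-cell preprocessing

Boundary semantics are literal: a cell with exactly 1,000 detected genes or
exactly 10% mitochondrial fraction is retained; a gene present in exactly
5% of cells is retained.  Mitochondrial fraction uses UMI counts.
Downsampling draws each day in ascending order from one seeded generator,
capping each day at 2,500 cells.  Gene prevalence is computed after
downsampling over all retained cells.  Normalisation is
`log2(1e6·x/total + 1)`.

Cell-cycle phases use module scores (scanpy's implementation: mean
expression of the phase set minus an expression-matched control set, 25
bins, 50 control genes per bin, seeded); the phase is the argmax of the
positive S/G2M scores, else G1.

The full-transcriptome defaults (min 1,000 genes) assume real sequencing
depth; pipeline runs on simulated data use a proportionally scaled
threshold (default 150 of ~500 genes) since simulated cells detect ~40% of
a 500-gene panel.

## Embedding, clustering, annotation

The embedding is 100 principal components plus 20 diffusion-map
components.  Diffusion maps are computed from PCA space: Gaussian kernel
with adaptive bandwidth (distance to the 15th neighbour), symmetric
normalisation `D^{-1/2} K D^{-1/2}`, top nontrivial eigenvectors scaled by
their eigenvalues, with a fixed eigensolver start vector for determinism.
Each block (PCA, DM) is scaled to unit total variance before
concatenation: the blocks contribute comparably while the within-block
eigen-hierarchy is preserved.  (Standardising every component individually
would weight the 100th noise component like the first and measurably
destroys the lineage coherence of downstream transport maps.)

The kNN graph (k = 50) is symmetrised by union.  The 2-D layout is a
ForceAtlas2-style iteration: linear attraction along edges, degree-weighted
`1/d` repulsion with an adaptive constant `1/mean(deg)²`, unit-capped
displacements with a decaying step, initialised from the first two
embedding dimensions.  Louvain runs through igraph's multilevel algorithm
at resolution 0.6 with a seeded RNG; cluster ids are ordered by size.

Annotation: a cluster is SR when its mean somatic enrichment exceeds the
developmental one and is positive, DR in the reverse case, NA when neither
mean is positive; SR/DR numbering follows ascending median sampling day.

## Gene-set statistics

The per-cell enrichment score z-scores each gene across all cells
(population SD; constant genes contribute 0), truncates at ±5 and averages
over the set's genes present in the data.

Markers: one-vs-rest Wilcoxon rank-sum, computed vectorised with mid-ranks,
tie-corrected variance and continuity correction (numerically identical to
scipy's asymptotic Mann-Whitney, which serves as the test oracle);
BH correction within each cluster; LFC is the log2 ratio of mean
linear-scale expressions (`2^x − 1`, pseudocount 1e-9).  A gene passing in
several clusters is kept only where its LFC is highest.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum with
weight exponent 1, a gene-permutation null (random same-size sets), NES
normalised by the mean |null ES| of the matching sign, add-one empirical p
and BH FDR across sets.

Target activation scores each cell as the mean z-scaled expression over
the target list and compares it with `n_null` (default 1,000) random
same-size gene sets; empirical p uses the add-one estimator
`(1 + #null ≥ ES)/(n_null + 1)` (so p ≥ 1/(n_null+1) and never 0);
a cell is active when ES > 0 and p < 0.05.  The random-gene empirical null
is the primary significance route; the hypergeometric test is provided as
a separate generic over-representation operation.

## Optimal transport

Birth-death rates: β(x) = β_min + (β_max − β_min)·σ((x − c_β)/w) on the
cell-cycle score, δ analogous on apoptosis, with centres −0.1 and 0.15.
The remaining logistic constants are free parameters (defaults: range
0.3–1.7 per day, width 0.5, so expected descendants per day stay within
e^±1.4).  Expected descendants over an interval: `exp((β−δ)·Δt)`.

Transport between consecutive days minimises squared-Euclidean cost in the
joint embedding, normalised by its median so ε = 0.2 is scale-meaningful.
Source masses are the raw expected-descendant weights; the target marginal
is uniform with the same total mass (so scaling all growth weights scales
the coupling).  The solver is log-domain Sinkhorn with KL-soft marginals:
a marginal with penalty λ uses the damped exponent λ/(λ+ε) (λ_source = 1);
λ = None means hard.  ε-scaling anneals from O(1) down to the target ε
with warm-started potentials (factor 2, rough stationarity per level,
per-level iteration cap so the final level keeps budget).  Finalisation:
hard-marginal couplings are rounded onto the exact marginals (row/column
scaling plus a rank-one deficit term), and soft-source couplings get an
exact target-marginal column rescale — in both cases the achieved target
marginal is exact to machine precision, consistent with the near-hard
target constraint.

Trajectories: the endpoint population is the uniform distribution over
final-day cells with endpoint-signature ES > 2; ancestors at each earlier
day are obtained by column-normalising the coupling (target-conditional
distribution), propagating, and renormalising to sum 1 per day; a cell is
a member when its probability exceeds that day's arithmetic mean (1/n_day).

## Interactions

The pair universe crosses secreted ligands with candidate receptors
(default: all genes, "every possible receptor") and filters in order:
receptor annotation, expression of both genes in ≥1 cell, experimental
validation.  Receptor annotation is an input CSV so the cascade is
reproducible offline.

sIS: per pair per day, raw = (mean ligand over source members) × (mean
receptor over target members); the null redraws both member sets uniformly
among that day's cells (n_perm = 1,000, shared across pairs within a day);
sIS = (raw − null mean)/null SD; empirical p is one-sided (greater) with
the add-one estimator.  Top pairs: all records sorted by descending sIS;
each day's best record marked; every unique pair whose best record falls
between the first and last day-top occurrence (inclusive) is selected.
Since the globally best record is necessarily its day's top, the rule
reduces to "best record at or above the last day-top position"; this is
the committed reading of an otherwise ambiguous selection rule.

Cluster-pair scores permute the cell-to-cluster assignment; the fuzzy-AND
score rates ligand and receptor by the fraction of random genes whose mean
expression in the cell set lies below theirs, takes the minimum, and
permutes each cell's expression vector independently for the null; the
fold-change variant first centres each gene on its whole-matrix mean.

## Problem sizes and runtime

Default test and acceptance runs use scaled-down studies chosen for
estimator stability on a single CPU: 8 days × 2 replicates at 100–250
cells/day and 300–500 genes for analysis checks; 1,600 cells/day for the
downsampling worked example (so every day exceeds the 2,500 cap after QC);
20 seeded runs for planted-pair recovery; three simulated datasets
(median) for trajectory recovery, where a single run's membership-recall
estimate carries a few points of Monte-Carlo noise.  The OT-vs-LP
comparison uses ≤6×6 instances and only those whose LP optimum is unique
(the zero-reduced-cost cell graph is acyclic) with a reduced-cost margin
≥ 0.015 — near-degenerate linear programs make the vertex comparison
meaningless regardless of solver quality.

## Known limitations

* The t-test stage reports uncorrected p-values by design.
* The FLE layout is a quality visualisation, not a converged minimiser;
  it is off by default in the pipeline (`run_layout=True` enables it).
* Louvain modularity has no stability guarantee at fixed resolution; the
  paper's cluster count (12) is data-dependent and not a target.
* The unbalanced OT source marginal is soft: the achieved source marginal
  deviates from the growth prescription by design (reported, not
  constrained).
* The generator's planted effects are block-shaped (on/off per day
  window); real programs activate gradually, which would blur, not bias,
  the downstream statistics.
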