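# Methods

This note records the models, conventions and numerical choices behind
epiminer, and what the synthetic benchmarks do and do not establish.

## Coordinates and read handling

All interval arithmetic is 0-based half-open (BED convention); 1-based
coordinates appear only in user-facing text. Reads are reduced to their 5′
position and strand (`ReadStore`); unmapped, secondary, supplementary,
duplicate and QC-fail records are excluded by default (`include_flagged`
re-admits them). Library size is the number of counted reads in the file,
not a header field. A read contributes to exactly one bin — the one
containing its 5′ end — so bin-count sums equal counted reads on every
run; overlap-proportional assignment was rejected because it breaks this
conservation and complicates testing without changing any downstream
statistic materially at 50–200 bp bins.

`extend_reads` extends from the 5′ end toward 3′ (strand-aware, the
standard ChIP fragment-extension convention), clips at chromosome bounds
and re-sorts, since minus-strand extension moves alignment starts.

Random region sets preserve each input region's length; a chromosome is
chosen with probability proportional to its number of valid start
positions (length − region length + 1) and the start drawn uniformly among
them, i.e. uniform over all valid placements without rejection.

"Closest gene" is ambiguous between gene-body distance and TSS distance;
`closest_feature` defaults to body distance (0 on overlap, else minimal
gap, ties to leftmost start then name) and uses edge-to-TSS distance
(`mode="tss"`) when linking clusters to expression, where the promoter is
the object of interest.

## Quantification pipeline

Order: bin → count → normalise → input-subtract → log2 → (scale → restrict
to ROIs) in genome-wide mode, or → restrict → scale in ROI mode.

* Depth normalisation: RPM = count × 10⁶ / library size.
* Spike-in normalisation replaces the denominator with the same sample's
  read count on the exogenous reference genome. Because the spike is
  constant across samples, a global loss of the mark scales target counts
  but not the denominator, so between-sample ratios survive — the property
  plain RPM destroys (its denominator shrinks along with the signal).
* Input subtraction is floored at zero; negative "signal" has no meaning
  downstream of 0–1 scaling. When a target is spike-normalised, its input
  is still depth-normalised (inputs have no spike), and the provenance
  flags record both facts.
* log2(x + 1): the pseudocount of 1 maps zero signal to zero and matches
  the log2 convention of the expression tables.
* Scaling maps min→0, max→1 either over the whole matrix (datasets
  sharing an antibody are directly comparable) or per column. A constant
  column (or matrix) maps to zeros. Genome-wide mode scales **bin-level**
  values over the whole genome before averaging the bins of each ROI:
  scaling inside a restricted ROI frame can over- or under-represent
  intensities when the ROI set excludes the genome-wide extremes, which is
  the reason genome-wide quantification is the default and the two modes
  are both exposed.

Per-ROI aggregation is the unweighted mean over all bins overlapping the
ROI by ≥ 1 bp.

## Profiles

Around-center matrices cover [center − flank, center + flank) in
`bin`-sized steps (defaults 5 kb / 50 bp → 200 columns); the center of an
even-length region is the left-of-middle base. Out-of-genome flank bins
are reported as 0 rather than dropped, keeping matrices rectangular for
clustering. Metagene profiles split each region into B blocks of
length // B bases with the remainder attached to the last block, and
report per-bp RPM density so unequal blocks stay comparable. Minus-strand
rows are reversed so columns always run 5′→3′ of the feature; unstranded
regions are treated as plus. Optional smoothing is a centered moving
average (edge-padded), off by default. Expression quartiles sort
descending, split sizes differ by ≤ 1, ties keep input order.

## Differential testing

The two-condition test builds, per ROI, the 2×2 table
[[in_A, in_B], [10⁶ − in_A, 10⁶ − in_B]] from rounded per-million
intensities — the "outside" universe is the rest of the genome, computed
once per dataset. Replicates are averaged within condition before table
construction. The two-sided Fisher p is the sum of hypergeometric
probabilities of all same-margin tables no more probable than the observed
one (relative guard 1 + 1e-7 against float ties); the implementation
enumerates the support vectorised per margin triple, with memoisation
across ROIs. Odds ratios apply the 0.5 Haldane correction when any cell is
zero. Because intensities are on the per-million scale, the test is
powerful: tiny composition shifts can reach significance on deep
libraries, so effect size (odds ratio) should accompany any cutoff.
Scaled (0–1) values must never be fed to the test; the pipeline functions
pass per-million counts.

The multi-condition path runs one-way Kruskal–Wallis (vectorised ranks
with tie correction; an all-tied row gets p = 1 with a warning) or ANOVA
per ROI row. Note the rank test's discreteness: with 3 groups of 5 its
smallest attainable p is ≈ 2×10⁻³, so very small designs cannot reach
stringent thresholds regardless of effect size. BH adjustment is the
step-up q(i) = min_{j≥i} p(j)·n/j mapped back to input order, capped at 1.
Row z-scores use the sample SD (n − 1); constant rows map to zeros.

## Dependency networks

Occupancy matrices are binary (≥ 1 bp overlap; threshold exposed);
constant columns are dropped with a warning. For ≤ 16 variables the joint
pattern counts of a (sub)sample are computed once and every contingency
table is a marginalisation of that 2^V array, which is what makes the
bootstrap loops cheap.

* CI test: G² = 2N·MI(x;y|z) in nats, df = 2^|z| for binary variables,
  p from the χ² upper tail; zero cells contribute nothing. Learners skip
  tests whose average cell count falls below 5 and treat the pair as
  independent (standard small-sample guard).
* Grow–shrink: per-variable blanket grow (repeatedly admit the most
  dependent candidate at level α, default 0.05) and shrink; blankets
  symmetrised by intersection; a blanket pair is adjacent unless some
  subset of the smaller blanket separates it (the separating set is
  recorded); v-structures oriented by the collider rule, conflicting
  orientations dropped, everything else left undirected. The residual
  false-adjacency rate is α-governed: a pair whose separation hinges on a
  single test is falsely kept with probability ≈ α.
* Score search: family BIC = log-likelihood − ½·ln N · 2^|parents|,
  cached per (node, parent-set); moves are single-edge add/delete/reverse
  with an ancestor check for acyclicity. Hill-climbing stops at the first
  local optimum; tabu keeps the last 10 inverse moves, accepts the best
  non-tabu move even when it degrades the score, and returns the best
  structure within 100 non-improving steps (both standard small defaults).
* Bootstrap consensus: ⌊fraction·N⌋ rows are subsampled without
  replacement each iteration ("randomly selected data" at a fraction < 1
  reads as subsampling); support is counted on skeletons because
  constraint learners return partially directed graphs, with direction
  annotated by majority vote. Defaults 0.9 / 100 / 0.8; the stricter
  0.7 / 500 / 0.95 regime is reachable by flags. The control network
  re-runs the whole pipeline on a matched random-region set; edges
  retained in both are flagged nonspecific.
* The IAMB-family constraint learners share this plumbing but are not
  implemented in this version.

## Classification

Predictors are standardised with train-fold means/SDs inside each fold
(no leakage); radial and Laplacian bandwidths use the median heuristic on
the standardised training data (γ = 1/median pairwise squared-Euclidean
resp. L1 distance), cost C = 1, all exposed. Out-of-fold decision values
are pooled into one ROC; AUC is its trapezoid area; the final model is
refit on all rows. Only two classes are supported. Feature selection is
backward elimination — at each size, drop the predictor whose removal
least degrades k-fold CV accuracy (linear SVM) — reporting the full
accuracy-vs-size curve; exhaustive subset search is exponential and the
greedy path matches what practitioners' RFE implementations actually do.
The "selected" set is the smallest size within one accuracy point of the
curve maximum.

## Post-processing

k-means is Lloyd with k-means++ initialisation, best of 10 restarts,
seeded. Hierarchical clustering defaults to average linkage on Euclidean
distance and exports the leaf order. Quantile normalisation is rank-mean
substitution with ties receiving the mean of the values their ranks span
(idempotent). Expression joins on gene name, case-sensitive, with an
optional ".N"-version-stripping flag. Renders draw saved matrices exactly
(no re-scaling) and return the drawn data layer so images are testable.

## Synthetic data and what the benchmarks show

`fixtures.simulate_chip_reads` places reads by a two-component model:
uniform background at `background_rate` reads/bp plus an extra expectation
of (fold − 1) × global_fraction × background_rate inside each enriched
region; with a requested library size the total is drawn multinomially
(exact conservation), otherwise per-segment Poisson. There is no GC or
mappability bias, no fragment-length distribution, and no sequencing-error
model; spike-in pairs hold the reference read count constant across
conditions. Expression tables are Gaussian in log2 space with per-group
shifts. Passing benchmarks therefore demonstrates that the statistics and
algorithms behave as designed under their own assumptions — calibration,
power, linearity, recovery — not that real chromatin data meets those
assumptions.

Benchmark designs (all seeded, sized for minutes on one CPU; run by
`tests/test_acceptance.py` and `scripts/acceptance.py`):

* Fisher exactness: every 2×2 table with margins ≤ 60 (~2.4M tables)
  against exact integer enumeration; BH against the direct step-up formula
  on 1000 random vectors.
* Spike-in linearity: a broad mark (fold 100 over 20% of a 200 kb genome)
  at retentions 1.0/0.75/0.5/0.25 with a constant 50k-read spike.
* Calibration: 5000 null ROIs, 3 conditions × 5 replicates.
* Two-condition power: 400 promoters, 60 planted per direction, fold 12
  vs 4 at 0.2 reads/bp.
* Network recovery: a fixed 6-node DAG (two chains from one root joined
  by a collider; children copy parents at 0.9) at N = 5000 — single-run
  skeleton F1 on a fixed-seed dataset plus 100 seeded bootstrap-consensus
  runs at the 0.9/100/0.8 defaults.
* Control specificity: 300 1 kb ROIs on a 3 Gb genome; two factors
  co-bound at 60% of ROIs only, one factor pair co-located genome-wide
  (~60% coverage), one independent.
* SVM/RFE: separable Gaussian clouds (±3 SD, 200/class), label
  permutations, and a 2-informative + 8-noise predictor pool.
* Profile geometry and clustering linkage: promoter signal proportional
  to expression for quartile ordering; a 4-condition planted z-score
  design with a +2 log2 expression shift for the linked cluster.

## Known limitations

Fisher differential inherits per-million-scale sensitivity (see above).
Constraint-based learning carries the α-level false-edge rate of any
single deciding CI test; the consensus threshold, not the single run, is
the intended inferential unit. Paired-end data are treated as single-end
5′ events. No mappability or copy-number correction exists anywhere in
the pipeline, and the renderers are deliberately minimal — matrices are
the first-class output.
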