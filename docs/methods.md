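# Methods

## Analysis model

**Network construction.** For each subject and session, the N-region ROI
time series (after discarding the first `n_discard` volumes and
regressing an intercept plus nuisance confounds — the six motion
parameters when available) yields an N × N Pearson correlation matrix.
Binary undirected networks are formed over a sparsity threshold space
S ∈ [5%, 40%] in 1% steps: at each S exactly k = round(S·N(N−1)/2)
edges are retained. Edges are ranked by |r| by default (signed ranking
is a config option); ties are broken lexicographically by (i, j), which
makes the edge sets nested across S and the edge count exact for every
subject — the point of sparsity thresholding is that all subjects'
networks have identical density.

**Nodal metrics.** On each binary network we compute, per node: degree
k_i; betweenness centrality b_i, the sum over unordered pairs s<t of
σ_st(i)/σ_st normalized by (N−1)(N−2)/2, with disconnected pairs
contributing 0; and nodal efficiency e_i = (1/(N−1)) Σ_{j≠i} 1/d_ij with
1/d_ij = 0 for unreachable j. Each (node, metric) curve over the 36
sparsity levels is summarized by its trapezoidal AUC — the quantity
entering all group statistics. Shortest-path computation is delegated to
igraph's C routines; the test suite proves equality with exhaustive
BFS path-counting oracles on every connected graph with ≤ 7 nodes.

**Hubs.** A region is a hub when the group-mean degree AUC is at least
one standard deviation above the across-node mean (population SD,
divisor N, since the node set is the entire population of regions; the
divisor is configurable). The boundary is inclusive.

**Frequent subgraph mining.** Subjects' binary networks at a single
sparsity (default S = 0.10) form a transaction database of
region-labeled graphs (uniform edge label, since edges are binarized).
The gSpan miner is written from scratch: patterns are keyed by their
canonical minimum DFS code; candidates grow only by rightmost-path
extension; candidates whose code is not minimal are pruned; support is
transaction-level (a graph with many embeddings counts once), which
makes support anti-monotone. Reported patterns have 2–6 edges; 1-edge
support is additionally computed for the appeared/disappeared edge
report. The pre/post comparison is set algebra on minimum-DFS-code keys.
The miner never assumes node labels are unique within a transaction,
although region names are. The support threshold (default
ceil(0.8·|db|)) and the mined sparsity are explicit config because no
standard values exist; both materially shape the pattern sets.

**Inference.** The permutation scheme is paired: the statistic is the
mean pre→post AUC difference, the null is generated by independent
random sign flips of each subject's difference, and
p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm) with n_perm = 10,000 by
default (the add-one estimator avoids p = 0; the same flip draws are
shared across the 270 tests, which affects only the joint distribution,
not any marginal p-value). All 270 node-metric tests are
Benjamini–Hochberg-adjusted as one family by default (per-metric
families of 90 are a config option). Age and sex are removed before the
test by regressing each AUC difference on centered covariates while
*retaining the intercept*: a full least-squares residualization would
force the residuals to sum to zero and thereby annihilate the mean
difference that the sign-flip test targets. (The full-residual form is
exposed separately as `residualize_covariates` for uses where it is the
right object.) If the covariate design is rank-deficient — e.g. a
single-sex cohort — the pipeline proceeds unadjusted with a warning.

**Brain–behavior correlations.** Pearson r between each nodal-metric AUC
change and each behavioral score change, two-sided p from
t = r√(n−2)/√(1−r²), BH-adjusted within the tested family, labeled
significant (adjusted p < 0.05) or marginal (adjusted p < 0.1, strict
inequalities; p = 0.05 is marginal). Effect sizes use
d = 2|r|/√(1−r²). The default family comprises the FDR-significant CNM
(node, metric) pairs crossed with all scales: carrying all 270 × 6 pairs
would make the family so large that no realistic coupling (true r ≈ 0.5
at n ≈ 26) could survive BH, and the adjusted p-values this workflow is
known to produce (e.g. 0.020 for r = 0.523 at n = 26) are only
consistent with a family of a few dozen tests. `correlation_family="all"`
restores the exhaustive family.

**Behavioral group tests.** Pooled-variance two-sample t (summary and
raw-data forms), Levene's variance-equality test on absolute deviations
from group means, and a 2 × 2 between-cells ANOVA with interaction
(type-II sums of squares via statsmodels). A repeated-measures ANOVA is
deliberately out of scope.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, not any
particular brain. Defaults encode the emulated design: 30 subjects, 90
AAL-labeled regions, 212 volumes with 10 discarded, ~10% of subjects
exceeding the 2.5 mm translation limit (post session), and a +0.3
correlation increment between two cross-module effect nodes (region
indices 0 and 18: PreCG.L, SMA.L).

* **Base correlation.** Five contiguous modules; within a module the
  correlation decays with index distance d as 0.3 + 0.35·exp(−(d−1)/0.5)
  (≈0.65 for adjacent pairs, →0.3), 0.1 between modules. The sharp decay
  gives each module a strong, reliable backbone of adjacent-pair edges —
  the analogue of the reproducible core of real connectomes — so that
  frequent-subgraph mining has stable patterns to find; a flat
  within-module level would make every within edge equally marginal at
  the threshold and the frequent-pattern sets empty or combinatorially
  explosive. `within_gain=0` recovers the flat block model.
* **Effect injection** acts on the correlation scale, on the pairs
  *within* the effect-node set, clipped to [−0.99, 0.99]; the matrix is
  then repaired to the nearest positive-semidefinite correlation matrix
  by eigenvalue clipping and diagonal rescaling (an error is raised if
  the repair cannot converge). An increment applied to the full rows of
  the effect nodes is not realizable as a correlation matrix at these
  magnitudes, so the pairwise form is the one that keeps the injected
  delta interpretable.
* **Sessions** are independent draws of T multivariate-normal vectors
  from the session covariance (pre: base; post: base + effect), so
  pre/post differences are exchangeable under the null — exactly the
  assumption of the sign-flip test.
* **Motion traces** are slow random walks (clipped at 2 mm); excluded
  subjects get a +3 mm translation step in the post session. Rotations
  are generated but, like the exclusion rule itself, only translations
  are consulted — the rule excludes a subject iff max |translation|
  strictly exceeds 2.5 mm in any session.
* **Behavioral coupling.** Score change = behavior_beta × (subject's
  realized mean betweenness-AUC change at the effect nodes, computed on
  a 5%-step subgrid of the threshold space) + N(0, behavior_noise_sd).
  Betweenness is the coupled metric because it is the metric a new
  cross-module edge actually moves at its endpoints (per-subject effect
  ~6–10 SE, versus ≈0 for degree, whose single-edge change is buried in
  edge-count noise). Defaults beta = 300 and noise SD = 5 give a true
  metric-change/score-change correlation ≈ 0.5 and score changes of a
  few points, matching the scale of the Wechsler quotients. Baseline
  scores: FIQ ≈ N(120, 9), MQ ≈ N(120, 10), subtests ≈ N(12, 3); an
  untreated control group (≈0.7 × n, test–retest only, no coupling) is
  generated for the behavioral ANOVA.

**What the generator does not emulate:** between-subject covariance
heterogeneity, temporal autocorrelation (volumes are i.i.d. in time),
non-Gaussian BOLD artifacts, distance-dependent noise, or realistic
anatomical module boundaries. Passing tests therefore demonstrate the
*procedures* (thresholding, metrics, mining, inference) and their
calibration under the design's statistical assumptions — not robustness
to real fMRI noise structure.

## Numerical choices

* Edge-count rounding is half-away-from-zero; k = 0 is an error.
* Tie-breaking everywhere is deterministic (lexicographic), so a fixed
  seed reproduces every artifact byte for byte; each stochastic stage
  derives its own seed from the configured seed by hashing a stage tag.
* Betweenness normalization by (N−1)(N−2)/2 is presentation-only — the
  permutation stage is scale-invariant — but keeps curves comparable.
* DFS-code node labels are ordered lexicographically by region name;
  the edge label is a single uniform token.
* Correlation matrices are clipped to [−1, 1] after `np.corrcoef` to
  absorb floating-point overshoot; constant-valued region series are an
  error naming the region.
* p-values of exactly 0 or outside (0, 1] are rejected by the FDR step
  (the add-one permutation estimator cannot produce them).

## Problem sizes used by the test and acceptance runs

Unit tests run on small synthetic cohorts (5–10 subjects, 20–30 regions)
where the quantity under test does not depend on the full design; the
design-level checks — 270-test count, parameter recovery (50 cohorts of
30 subjects × 90 regions, effect_delta 0.3), type-I calibration (1,000
null simulations), exhaustive oracle sweeps (all connected graphs ≤ 7
nodes; all two-letter labeled graphs ≤ 4 nodes; 100 random mining
databases) — run at the sizes stated in their test docstrings.

## Known limitations

* The miner is pure Python; it is exact, but databases whose frequent
  edges form dense subgraphs (hundreds of mutually overlapping frequent
  edges) grow combinatorially, as frequent-subgraph enumeration must.
  The support threshold and mined sparsity are the practical controls.
* The permutation test shares sign-flip draws across tests; joint
  (e.g. max-statistic) corrections are not implemented.
* The ANOVA treats both factors as between-subject; the paired design
  is handled by the permutation arm, not the ANOVA.
* Hub detection, mining and inference all operate on AUC or
  single-sparsity summaries; no per-threshold inference is provided
  beyond the exposed per-threshold hub sets.
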