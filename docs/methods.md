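# Methods

## Scope and model

`seednet` nominates candidate disease genes by combining two evidence
layers. Co-expression: genes whose transcript levels rise and fall
together across tumors are likely functionally related. Physical/functional
interaction: proteins that interact share pathways. The pipeline keeps
only relationships supported by both layers (the *common network*), then
asks which non-seed genes a length-limited random walk between known
disease genes passes through most often. Those linker genes, scored by
their summed subnetwork edge weights, are the candidates; a survival
analysis checks whether their joint expression stratifies patient risk.

## Co-expression adjacency

Pairwise Pearson correlation over pairwise-complete samples, with genes
excluded when they have zero variance or more than 50% missing values.
The adjacency is *a* = |r|^β.

- `beta` (default **1**): the soft-threshold power. The workflow this
  package implements uses only the adjacency step of weighted
  correlation network analysis, and with β = 1 edge weights are the
  absolute correlations that also serve as random-walk weights
  downstream. β is exposed because practitioners routinely raise it to
  sharpen module contrast.
- `abs_r_threshold` (default **0.5**): the edge-inclusion cutoff.
  0.5 marks the conventional boundary of a "strong" correlation and, at
  ~100 samples, lies far outside the null sampling spread of r
  (sd ≈ n^−1/2 ≈ 0.1), so background gene pairs essentially never pass.
  An alternative `target_edge_count` rule keeps the N largest
  adjacencies for matching a desired density.
- Correlation signs are kept as edge metadata rather than in the weight:
  transition probabilities must be nonnegative, and anti-correlated
  partners are as informative as correlated ones for module membership.

Intersection keeps exactly the edges present in both networks, weighted
by the co-expression adjacency; nodes that lose all edges drop out, so
network node counts refer to connected nodes only.

## Limited k-walks

For each seed *s* in turn, the other seeds become absorbing states of a
Markov chain with P(i→j) = w_ij / Σ_k w_ik. With forward masses
α_l(i) (probability of occupying transient node *i* after *l* steps
without prior absorption) and backward masses β_m(j) (probability of
absorption within *m* further steps from *j*), the expected number of
traversals of edge (i,j) by walks absorbed within *L* steps is

    E_s(i,j) = (1/Z_s) Σ_{l=0}^{L−1} [ α_l(i) P(i→j) β_{L−l−1}(j)
                                     + α_l(j) P(j→i) β_{L−l−1}(i) ],

with Z_s = β_L(s) the absorption mass. Node relevance is half the sum
of incident edge relevances, plus one for the start (every admissible
walk visits its start once). Final relevances are arithmetic means over
start seeds with Z_s > 0; averaging keeps scores comparable across
seed-set sizes. Starts that cannot reach any absorber within *L*
contribute nothing; if no start can, the computation aborts with advice
to raise *L*.

- `L` (default **50** steps): the walk budget. On weighted networks of
  the density this pipeline produces, absorption mass saturates well
  below 50 steps, so the limit mainly truncates negligible tails; it is
  configurable for very sparse graphs.
- Implementation: the recursion runs on a sparse transition matrix in
  O(L·|E|) per start. `brute_force_relevance` recomputes the same
  quantities by exhaustive depth-first walk enumeration, guarded to ≤ 8
  nodes and L ≤ 8, and is used in the tests as an independent oracle
  (agreement to 1e−9 demanded; observed ~1e−14).

**Subnetwork assembly.** Edges are sorted by decreasing relevance (ties
broken lexicographically by endpoint pair) and added until the seeds of
each parent-graph component share one connected component; edges tied
with the relevance at the moment of connection are then also included
("plateau rule"), optionally capped by `max_edges`. Equivalently: the
subnetwork is every edge whose relevance reaches the threshold at which
the seeds first connect. A deterministic stopping rule is required
because "connects the seeds" alone does not pin down a unique subgraph;
the rule used is recorded in the run manifest. Seeds unreachable from
every other seed remain as isolated nodes with a warning.

## Ranking score and candidate selection

RS(g) = Σ over subnetwork edges (g,h) of m·w(g,h), with m = 2 when h is
a seed — a seed–linker link carries more evidence than a linker–linker
link. Seeds are not scored. Ties in the ranking are broken
alphabetically. Selection uses a strict cutoff (`rs > cutoff`); the
packaged reference table shows why strictness matters: with cutoff 1.0,
the two linkers printed at exactly 1.0 are excluded and exactly six
candidates remain. Human-readable output rounds RS to one decimal
(matching the reference table's granularity); full precision is kept
internally.

The *smallest connecting subnetwork* for a candidate set uses a
shortest-path Steiner approximation: edge length 1 − w (floored at
1e−6 so unit-weight edges keep positive length), all-pairs Dijkstra
among targets with lexicographic tie-breaks, a Kruskal spanning tree
over the target-pair distances, and the union of realized paths. This
is a heuristic; on the small candidate sets it serves it matches the
exhaustive minimum in the tests.

## Clinical validation

- **Correlation pairs**: Pearson r with the exact two-sided p from the
  t transform (t = r·√((n−2)/(1−r²))), Benjamini–Hochberg adjustment
  across the supplied pairs (raw and adjusted p are both reported).
- **Covariate tests**: Welch (unequal-variance) t-tests — the safer
  default when group variances are unknown — per gene against a binary
  covariate, samples with missing covariate values dropped per test.
- **Risk score**: the per-sample sum of signature-gene expression on
  whatever scale the matrix is supplied in (raw vs log is the caller's
  choice; the median split is invariant to any common monotone
  transform of the scores).
- **Stratification**: samples lacking survival time or event status are
  excluded first and counted; the rest are split at the median score,
  with ties at the median assigned to the low group (a deterministic
  convention recorded in the pipeline manifest). The log-rank
  chi-square is computed directly from the risk-set tables; it is
  algebraically the score test at β = 0 of a one-covariate Cox
  proportional-hazards fit (both forms are implemented and agree to
  1e−6 on tie-free data, and both are cross-checked against
  `lifelines.statistics.logrank_test`). Kaplan–Meier curves come from
  `lifelines`. p-values are floored at 1e−300.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with planted ground truth for recovery tests.

- **Expression**: module genes (seeds + planted linkers) follow a
  one-factor model x_g = λf + ε with f, ε ~ N(0,1) per sample and
  λ = √(ρ/(1−ρ)), giving expected pairwise correlation ρ
  (`module_corr`, default **0.8**). Background genes are independent
  noise.
- **PPI**: seed–linker and linker–linker module pairs are each included
  with `ppi_cover_prob` (default **1.0**); seed–seed pairs occur only at
  the background Erdős–Rényi rate (`background_edge_prob`, default
  **0.01**). This mirrors the disease setting the pipeline targets, in
  which seed genes connect through linker genes rather than directly —
  the very reason linkers are recruited. Scores are written in the
  STRING-links dialect (integers, /1000 on read).
- **Clinical**: exponential survival with baseline median 500 days;
  samples in the top half of the latent factor carry `hazard_ratio`
  (default **3**) times the baseline hazard. A `censor_rate` fraction
  (default **0.3**, a typical cohort censoring level) is censored at a
  uniform fraction of their event time; a `missing_clinical_frac`
  fraction (default **16/179**, the reference cohort's missingness)
  loses survival fields entirely. Covariates are independent coin
  flips.
- **Sizes**: defaults of 5 seeds, 5 planted linkers, 300 background
  genes and 100 samples define the reference validation scenario; the
  survival simulations use 179 samples (retention), 1000 replicates
  (null calibration) and 200 samples × 100 replicates (power).

Everything is reproducible from a single integer seed (same seed ⇒
byte-identical files).

**What passing synthetic tests does and does not show.** The generator
produces a single clean Gaussian module, independent background genes,
exponential survival and covariates unrelated to expression. Real tumor
data have correlated background structure, batch effects, heavy-tailed
and platform-dependent expression scales, informative censoring and
confounded covariates — none of which are emulated. Recovery and
calibration results therefore validate the machinery (the algorithms do
what their definitions say under the assumed model), not the biological
discovery power on any particular cohort.

## Numerical and degenerate-input choices

- Edge weights must lie in (0, 1]; zero-score PPI rows and zero-adjacency
  pairs are dropped rather than stored.
- Reciprocal duplicate PPI rows collapse to one undirected edge (larger
  score kept if they disagree); self-loops are dropped with a logged
  count.
- Correlation pairs with fewer than 3 complete samples are skipped;
  `NA` is the missing-value token in all TSVs.
- All file outputs are sorted lexicographically so repeated runs are
  byte-identical; the pipeline manifest records input SHA-256 digests,
  all parameters and per-stage counts.
- Walk-budget and enumeration guards, median-tie handling, and the
  empty-intersection error are surfaced as typed `SeednetError`s with
  actionable messages.

## Known limitations

- The k-walks recursion is dense in *L* (no early exit on converged
  absorption); for very large L·|E| this costs time, not accuracy.
- The Steiner routine is an approximation with no optimality guarantee
  beyond the spanning-tree bound.
- The log-rank variant implemented is the unstratified two-group test;
  no multivariable Cox modelling or hazard-ratio confidence intervals
  are provided.
- ID mapping between protein and gene identifiers is a plain two-column
  table supplied by the user; no online identifier services are
  consulted.
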