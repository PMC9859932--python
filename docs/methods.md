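# Methods

## The representation

A cell's observable identity is modeled as the set of statistical
dependencies among a chosen panel of genes. The atomic object is the
*cascade*: an unordered set of one or two genes with one member marked as
dependent. `{x,y}_x` and `{x,y}_y` are distinct (dependence has a
direction); `{x}_x` records bare presence of a vertex. A dependency oracle
`dep(x, y)` induces the possessed-cascade set of a cell: every gene
contributes its singleton, every true ordered pair a pair cascade. Read as
a graph — singletons as vertices, pairs as directed edges from regulator to
dependent — the set satisfies |C| = |V| + |E| identically, which is also
the denominator convention of the comparison score below. Feedback pairs
(`{x,y}_x` together with `{x,y}_y`) are allowed in oriented sets.

### The per-cascade tropical semiring

Each cascade `l` with dependent gene `g` carries a commutative semiring on
`l ∪ {ε}`, where ε is a reserved environment element (implemented as a
sentinel object, so it can never collide with a gene symbol, and never
stored in cascade sets):

* addition: `x ⊕ y` is `x` when `x = g`, `y = ε`, or `x = y`, symmetric
  otherwise — ε is neutral and g absorbs;
* multiplication: `x ⊙ y` is `x` when `y = g`, `y` when `x = g`, and ε
  otherwise — g is neutral and everything else collapses.

The map z (g ↦ 0, ε ↦ ∞, other member ↦ 1) is a homomorphism onto
({0,1,∞}, min, +̄). The target multiplication +̄ is truncated addition
(0 neutral, ∞ absorbing, 1 +̄ 1 = ∞): on the three-point carrier this is
the unique closure consistent with the case table of ⊙ (the image of
`b ⊙ b = ε` forces 1 +̄ 1 = ∞). Both facts are enforced by an exhaustive
test over every carrier element combination for both cascade shapes.

### Gene elimination

Removing a gene subset H = G − F from a structure can be read two ways:
keep only cascades fully inside F (induced subgraph), or push each cascade
through the quotient of its semiring by the ideal generated by H ∪ {ε}.
The quotient's fiber rule says: a cascade whose dependent gene is removed
vanishes entirely; otherwise removed members are deleted, possibly
collapsing a pair to a singleton already present. On complete
possessed-cascade sets the two constructions coincide — this is what makes
"ignore off-panel genes" principled: they act exactly like exogenous
environment factors. The equivalence is tested on 1,000 random
(universe, oracle, subset) instances with up to 8 genes, along with
functoriality (restricting twice equals restricting once) and commutation
with undirected conversion.

Converting to an undirected structure merges `{x,y}_x ~ {x,y}_y` into one
edge; it is idempotent and preserves vertex counts. Quotient-semiring
element classes are never materialized as objects; only the fiber rule's
effect on cascade sets is computed.

## Structure learning

A cell class's *eigen-cascades* are estimated from its pooled cells × genes
matrix by the skeleton phase of a constraint-based search:

* **PC-stable**: starting from the complete graph over the panel, an edge
  x–y is deleted as soon as some conditioning set of size 0..`max_cond`
  drawn from the frozen neighborhoods of x or y yields p > α. Freezing the
  neighborhoods per level removes the classical order-dependence of plain
  PC; gene order and conditioning-set enumeration are lexicographic, so the
  output is invariant to row and column order. No orientation phase exists:
  the comparison operates on undirected structure, so the skeleton is the
  estimand. Defaults α = 0.01, `max_cond` = 3.
* **Continuous data**: Fisher z-test on the partial correlation obtained by
  inverting the sub-correlation matrix; the statistic is
  atanh(r)·sqrt(n − |S| − 3). The full correlation matrix is computed once
  per skeleton search. The empty-conditioning case uses the marginal
  correlation directly (no inversion), so degenerate perfect correlation is
  handled; collinear conditioning sets raise an error naming the edge.
* **Discretized data**: chi-square tests of independence stratified over
  the conditioning variables' level combinations, with statistics and
  degrees of freedom pooled across strata. Strata with any expected count
  below 5 (the classical floor) are skipped and counted; if all strata are
  skipped the test errors rather than guessing. The default binning rule
  is a median split; a callable rule or already-discrete data (`"asis"`)
  may be supplied since no canonical rule exists for log-normalized counts.

Classes below a 30-cell floor (configurable) are refused: pooled CI tests
on fewer cells are too underpowered to mean anything. Note a consequence
of pooling documented rather than "fixed": if half a class possesses an
edge and half does not, the pooled correlation is roughly halved, which a
large class still detects — the class-level structure therefore reflects
"a major proportion of cells" only for weak effects or modest class sizes.

## Comparing classes

* `hamming(a, b)` — the symmetric-difference size, the natural
  pseudo-metric between single-cell structures. It is exposed for cascade
  sets supplied externally (e.g. ground truth from the synthetic module): a
  per-cell GRN cannot honestly be inferred from one observation, so the
  package never pretends to estimate it from data.
* `d*(a, b) = 1 − |a ∩ b| / |a|` — asymmetric; 0 exactly when a ⊆ b.
  Eigen-cascade sets can be nested (a more specific class possesses a
  superset of a broader class's cascades), which symmetric-difference
  metrics cannot express. d* is *not* asserted to satisfy the triangle
  inequality — finite counterexamples exist — so tests pin only identity,
  bounds, asymmetry and the subset characterization. Comparison happens on
  unoriented sets (oriented comparison is available by simply passing
  oriented sets to `d_star` directly).

`compare(mode, centers, others, vertex_subset)` restricts every eigen set
to the vertex subset (induced subgraph), computes d* from each center, and
groups the compared classes into rings. Ring resolution is d* rounded to 4
decimals — finer than any structural difference a small panel can produce,
coarse enough to absorb float noise. Ties at the minimum are all reported
as the assignment; picking an arbitrary single winner would manufacture
precision the score does not have. Typical vertex policies: the marker
panel for labeling (reference identities are known), all shared vertices
for estimation.

## Feature selection

* **KMO/MSA** are computed from squared marginal vs anti-image partial
  correlations (in-package; verified against an independent step-by-step
  oracle to 1e-8 on random matrices). Singular correlation matrices fail by
  default; `ridge=True` adds 1e-8·I.
* **Parallel analysis** compares correlation eigenvalues rank by rank with
  the chosen percentile (default 95th, 100 permutations) of eigenvalues of
  column-permuted copies, stopping at the first rank that fails (Horn's
  leading-run rule). The stopping rule matters: since a correlation
  matrix's eigenvalues sum to p, per-rank exceedances are not independent,
  and counting non-leading exceedances would inflate the retained count on
  pure noise. Even with the leading-run rule the pure-noise retention rate
  sits at ≈ 0.95 *by construction* at the 95th percentile (the observed top
  eigenvalue is exchangeable with the null draws), so rate estimates over
  tens of runs straddle 0.95.
* **The EFA loop**: drop variables with MSA < 0.6 (re-applied each
  iteration; a flag disables re-filtering), set the starting factor count
  by parallel analysis, fit by iterated principal axis (the classical
  common-factor estimator available in statsmodels; the loop cares only
  about the common-factor space, for which PA and minres estimates agree
  closely), rotate with quartimin (oblique — latent identities are not
  orthogonal), then repeatedly drop the factor whose largest |loading| is
  smallest while it is below 0.5 and refit. One factor is removed per
  iteration — removing several at once could discard a factor that becomes
  well-loaded after refitting. Communalities are taken from the unrotated
  solution (rotation-invariant) and partition unit variance with the
  uniquenesses to 1e-6.
* **Communality selection** keeps genes with communality strictly above 0.5.
* **GBDT route**: classes are rebalanced by random undersampling to the
  minimum class size; genes may be pre-ranked by the SD of class-wise mean
  expression (top 1,000 by default); a LightGBM classifier with L1/L2
  penalties (defaults 0.1/0.1, ≤ 200 trees) is trained on each of 5
  StratifiedGroupKFold folds. Within a fold the training part is split
  75/25 into fit and validation halves and boosting stops early (patience
  10), with importances read at the best iteration — without this guard,
  late overfitted rounds hand every gene nonzero split counts and the
  stability filter becomes vacuous. Selected genes are those with nonzero
  importance in *every* fold; the report ranks genes by median importance.
  The trained model is deliberately not used as an annotator — after
  undersampling its class prior no longer matches any real population.
* **OvR metrics**: per-class ROC-AUC and average precision, macro-averaged
  AUC and micro-averaged AP, for judging whether selected features carry
  the class signal.

## Clustering

Factor scores use the regression (Thurstone) method on standardized
variables, `Z R⁻¹ Λ Φ`, with the oblique structure matrix. k-means runs
over k = 2..15 (10 restarts, fixed seed); k is chosen by maximum mean
silhouette (Euclidean, in score space), ties going to the smaller k. The
silhouette SD, the entropy of the cluster-size distribution (natural log)
and inertia differences are reported as imbalance/elbow diagnostics but
never influence the choice — reporting them while selecting on mean
silhouette alone keeps the selection rule auditable. Partition agreement
uses ARI and AMI.

## Synthetic ground truth

The generator realizes the causal picture the method assumes: per class, an
Erdős–Rényi DAG over a random topological order with weights drawn
uniformly from ±[0.5, 1.5] (bounded away from zero so every edge is in
principle detectable), and expression sampled from the linear-Gaussian
structural model — each gene is the weighted sum of its parents plus an
independent unit-variance Gaussian exogenous term, the generator's stand-in
for the per-gene environment variables. Sampled covariances match the
closed form (I−W)⁻ᵀ(I−W)⁻¹σ² (tested entrywise at n = 10,000). A binary
mode (roots are fair coins; children copy parent parity and flip with
probability 0.1) mirrors the chi-square path, and a block-loading generator
(loading 0.8, unit total variance) drives the FA and clustering studies.

`perturb_grn` edits a DAG by flipping the presence of k distinct forward
pairs (w.r.t. the original topological order, preserving acyclicity); since
no pair is touched twice, the true skeleton's Hamming distance from the
original is exactly k — the controlled divergence behind the d* trend
study.

What the generator does *not* emulate: count noise, dropout, library-size
variation, or any non-linear regulation. Passing tests therefore show that
the algebra is exact and that the estimation pipeline recovers structure
when its statistical assumptions hold; they do not certify performance on
raw scRNA-seq counts, which should be normalized (RPM + log transform, QC)
before entering the pipeline.

## Validation study designs

All studies live in `eigencascade.validation`, are seeded, and are sized to
run the whole suite in well under a minute on one core:

* algebra: exhaustive (both cascade shapes, full carriers);
* restriction equivalence: 1,000 random instances, ≤ 8 genes;
* metric axioms: 500 random triples over 6 genes;
* CI calibration: 1,000 replicates at n = 10,000, α = 0.05;
* skeleton recovery: 20 random 6-gene DAGs (edge probability 0.4),
  n = 5,000, α = 0.01 — mean edge-F1 is the score;
* annotation: 20 replicates of 3 reference + 3 query classes (1,000 cells
  each) from 3 DAGs with pairwise-distinct skeletons (redrawn on collision;
  distinctness is part of the design, not a post-hoc filter). A replicate
  is correct for a mode when every center's innermost ring contains its
  true counterpart — consistent with the tie rule, under which co-minimal
  classes jointly constitute the assignment;
* d* trend: per replicate, one reference and four queries at k = 0..3 edge
  edits; the summary is the Spearman correlation of the per-k median d*
  with k;
* FA recovery: 20 seeds of the two-block design; success is exactly 2
  factors and exactly the block genes above the communality floor;
* parallel analysis: 40 runs each of 500 × 50 pure noise (target 0) and the
  two-block design (target 2).

## Known limitations

* d* is not a metric; ranking and containment statements are meaningful,
  summed distances are not.
* Skeletons are only identified up to conditional-independence structure;
  orientation information is intentionally discarded.
* The chi-square path needs enough cells per conditioning stratum; with
  `max_cond` = 3 and median splits that means several hundred cells per
  class in practice.
* Pooled-class estimation blurs heterogeneous classes (see the note on
  statement "a major proportion of cells" above); sub-clustering before
  estimation is the remedy, not a smaller α.
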