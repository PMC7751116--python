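# Methods

## Model and scope

`sbnet` treats taxon relative abundances as continuous random variables
and learns the *structure* of a Bayesian network over them — which
conditional dependencies exist and, where identifiable, their direction.
Parameters (the local conditional distributions) are never estimated.
The learned object is a partially directed acyclic graph (PDAG): only
the skeleton and the collider orientations are identifiable from
conditional independencies alone, plus whatever the propagation rules
can derive from them; everything else stays undirected.

The working assumptions are the usual ones for Gaussian constraint-based
learning: approximate multivariate normality of the (relative-abundance)
columns, faithfulness of the data-generating distribution to a DAG, and
i.i.d. samples. Compositional data violate normality and independence of
columns in known ways; the package follows the field's practice of
applying Pearson-based tests to relative abundances directly (see
Limitations).

## Pipeline and parameters

1. **Normalization.** Rows are divided by their totals. Samples with
   zero total reads are an error, not silently dropped.
2. **Taxon filter** (`coverage`, default 0.99). Taxa are ranked by mean
   relative abundance across samples (ties broken by name); the smallest
   prefix whose cumulative share reaches the coverage is kept. Mean was
   chosen over median/sum because a per-sample ranking cannot produce a
   single cohort-level taxon set; the statistic is exposed as a
   parameter of the ranking in the code should users want to change it.
   The retained columns are deliberately **not** renormalized — closing
   the composition again would change every pairwise correlation
   downstream.
3. **Sampling time** (optional). For longitudinal designs the sampling
   time is appended as an ordinary continuous pseudo-variable
   (`__time`), letting the learner attribute shared temporal trends to
   the time node instead of spurious taxon–taxon edges.
4. **Period partitioning** (`k`, optional). The time axis is split into
   `k` equal-width half-open intervals (last closed). Equal-width, not
   equal-count: the periods are meant to isolate ecological phases, not
   to balance sample sizes.
5. **Structure learning** (`alpha`, default 0.05; `ci_test`, default
   Fisher-Z; `max_cond`, default unlimited). PC-stable with adjacency
   sets frozen per level. The significance level and the choice between
   the Fisher-Z and exact-t tests are exposed because no single default
   suits all sample sizes; both tests are asymptotically equivalent and
   agree to <1e-3 in p-value by n = 10⁴.
6. **Signing.** Pearson correlations are computed on the same matrix the
   learner saw (relative abundances post-filter; a raw-count route is
   available by skipping normalization). No p-value threshold is applied
   to the co-occurrence graph: its only role is supplying sign and
   magnitude for edges PC-stable already vetted.
7. **Bootstrap support** (`B`, default 200; `bootstrap_mode`, default
   `permute_vars`). Re-runs the learner on randomized inputs and
   reports per-orientation frequencies. Variable-order permutation is
   the default because the residual orientation rules are exactly the
   order-dependent part of PC; a row-resampling mode is provided for a
   conventional non-parametric bootstrap. Both interpretations of
   "randomized input" are implemented; neither is privileged beyond the
   default flag.
8. **Evaluation.** Direction consistency is
   `100·(labeled − late→early)/labeled`, labeled edges being those with
   both endpoints labeled; undirected labeled edges count toward the
   denominator but toward neither directional bucket. The
   "early-related" column counts labeled edges touching an early
   colonizer regardless of direction, which is the convention under
   which the summary table's columns add up. Percentages are printed to
   one decimal; aggregation over sites sums counts and recomputes
   percentages (never averages them).

## Numerical choices

- **Partial correlations** are computed by inverting the correlation
  submatrix over `{i, j} ∪ S`; a singular or numerically singular
  (condition number > 1e12) submatrix raises a dedicated degeneracy
  error. Inside the skeleton search that error causes the offending
  conditioning set to be *skipped* (treated as non-separating) rather
  than aborting the run: on compositional data the full set of taxa is
  exactly collinear, so large conditioning sets are routinely singular
  and carry no usable information.
- **|r| ≥ 1** is clamped to ±(1 − 1e-12) with a warning before the z/t
  transform, so deterministic toy inputs do not abort a run.
- **Sepsets** are the first separating set found under a canonical
  enumeration ordered by node *names* (both endpoints' neighborhoods,
  smaller-named side first). Ordering by names rather than column
  indices is what makes the recorded sepsets — and hence the collider
  decisions — invariant to the order in which variables arrive.
- **Collider conflicts** (two triples demanding opposite arrows on one
  edge) leave the contested edge undirected, with a warning. All
  candidate arrows are collected before any is applied, so the policy is
  itself order-independent.
- **Orientation rules** are applied in a fixed order (1, 2, 3),
  restarting after each orientation, to a fixpoint. The rules only ever
  orient undirected edges, so directed edges grow monotonically and are
  never reversed.
- **Ties** in the taxon filter ranking break lexicographically; all
  edge/pair iterations are sorted, making every output deterministic
  given input, parameters and seed.

## Synthetic data: what it emulates, what it does not

`sample_random_dag`/`sample_linear_gaussian` generate Erdős–Rényi DAGs
(weights uniform on ±[0.3, 1.0], bounded away from 0 to avoid
near-unfaithfulness) and linear-Gaussian samples — the standard
benchmark on which skeleton F1 and collider recovery are measured.
`d_separation_ci` wraps a known DAG as a perfect CI oracle for
exactness checks against a brute-force Markov-equivalence enumeration.

`simulate_succession` generates the study conditions for the
colonization-order experiments: each taxon's latent abundance rises
logistically after its onset (`1/(1+e^{−g(t−o)})`) and decays
exponentially (`e^{−d·max(0, t−o_next)}`) once its successor arrives;
samples get multiplicative log-normal noise and are closed to
compositions. The defaults — three classes named for the preterm-gut
succession Bacilli → Gammaproteobacteria → Clostridia, onsets 0/3/9 on
a 0–12 axis (so a k=2 split isolates one handover per period), growth
1.5, decline 1.0, noise sd 0.3, 20 subjects × 12 timepoints — are
plausible weekly-scale dynamics for an infant-gut-like cohort. A
per-subject affine clock distortion (sd 0.1, recorded times left
nominal) emulates the imperfect cross-subject temporal alignment of
semi-synthetic designs; proper time-warping alignment is out of scope.

The simulator guarantees, by construction, the one feature the method
needs — negative correlation between consecutive colonizers inside a
handover window. It does **not** emulate read-count noise, sparsity and
zero inflation, hundreds of rare taxa, or subject-level covariates, so
passing the end-to-end checks shows the pipeline recovers programmed
successions under clean compositional dynamics, not that it will do so
on any real cohort.

## Known limitations

- Pearson correlations and Gaussian CI tests on compositions are subject
  to spurious negative dependence (closure effect); no
  compositionality-corrected correlation (e.g. SparCC-style) is
  provided, matching the method being implemented.
- Constraint-based direction identification is limited to colliders and
  their consequences; with few variables (as in the worked example) many
  edges legitimately stay undirected, and identified directions need not
  match ecological causality edge-by-edge.
- Sepset-based collider detection is made order-independent here by
  canonical enumeration, but it remains alpha-sensitive; conservative or
  majority-rule collider variants are not implemented.
- The evaluation treats labels as ground truth; curation of early/late
  colonizer labels is the user's responsibility.
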