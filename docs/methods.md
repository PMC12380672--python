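# Methods

## Co-occurrence model

The cohort is an all-case series: every record is an HNSCC patient, so
the sex-stratified quantity estimable from it is the diabetic proportion
among cases, p = n_DM / n_sex (127/692 males, 5/36 females in the
emulated study).  This proportion is sometimes labelled P(HNSCC | DM) in
epidemiological write-ups of the same design; `comorbidlink` computes and
documents it as the within-cohort exposure proportion and keeps the value
as an exact ratio until display.

Scaling to a population of size N uses three deterministic roundings:

- case margin      M_h = round(N · incidence_sex)
- exposure margin  M_d = round(N · prevalence)
- joint cell       a   = round(p · M_h),  then c = M_h − a, b = M_d − a,
  d = N − a − b − c.

This "observed proportion × case margin" allocation is the one under
which the implied joint probability a/N equals (incidence × p) rather
than (prevalence × p); multiplying prevalence by the cohort proportion —
a tempting Bayes-style composition — would treat a case-conditional
proportion as an exposure-conditional risk and inflate the joint cell by
several orders of magnitude.  Parameters implying a negative cell (e.g.
a > M_d) raise an error rather than being clipped silently.

Defaults: N = 10,000,000 per sex; prevalence 0.069; incidence 1.52e-4
(male) and 7.61e-5 (female).  All three are configuration knobs.

A stochastic mode replaces the rounded expectations with one seeded
multinomial draw over the implied cell probabilities.  It exists for
simulation studies (e.g. the parameter-recovery test); the deterministic
mode is the default because the reported quantities are expectations.

### Association statistics

OR = ad/bc and RR = (a/(a+b))/(c/(c+d)).  When the outcome is rare in
both exposure arms the two coincide to the displayed precision — this is
why well-calibrated tables show identical OR and RR at 2 decimals.  A
Haldane–Anscombe 0.5 correction is available but applied only on explicit
request; confidence intervals are out of scope.

Fisher's exact test conditions on both margins; the joint cell then
follows a hypergeometric law whose support has at most min(margins)+1
points, so even 10⁷-person tables enumerate a short vector.  All pmf
values are kept in log space and combined with logsumexp; p-values
therefore never underflow internally.  The two-sided definition is
"minlike": the total probability of tables whose point probability is at
most that of the observed table, with a relative tie tolerance of 1e-7.
This is the dominant convention in mainstream statistics software; the
one-sided alternatives ("greater", "less") are plain tail sums.

## Literature association statistic

For a gene–disease pair with n_p positive-polarity findings out of N
polarity-adjusted observations, the p-value is the upper binomial tail
P(X ≥ n_p | N, p₀), evaluated with the binomial survival function (never
1 − cdf, which loses all precision for small tails).

p₀ — the null probability that a finding is positive — defaults to 0.5
("polarity at chance").  This is a modelling choice, not an estimate: a
corpus with systematic publication bias toward positive findings would
need a larger p₀, and every reported q-value depends on it.  It is a
parameter everywhere it appears.

Benjamini–Hochberg q-values are computed by the step-up rule within each
disease separately (the multiplicity family is "genes tested for this
disease"); significance is q ≤ 0.01 by default.  Filtering is a view:
all rows keep their q-values so the threshold can be revisited without
recomputation.  Regulation sign is the majority of positive vs negative
reference counts, with ties classified "mixed" and excluded from signed
downstream analyses.

## Overlap enrichment

Two gene sets A and B from a universe of size U form the table
(a = |A∩B|, b = |A|−a, c = |B|−a, d = U−|A|−|B|+a).  The test is
one-sided (greater) by default because the scientific question is
enrichment; a two-sided option exists.  U is an explicit required
argument — defaulting to |A∪B| would silently change d and the OR.
Symbols are uppercased before matching, and when a universe member list
is supplied, out-of-universe symbols are an error rather than being
dropped.  The OR exceeds 1 exactly when a exceeds its hypergeometric
expectation |A||B|/U.  p-values smaller than ~5e-319 are displayed as
the bound "< 4.95e-319" (the floor convention of literature-mining
association tables) while the exact log10 p remains available.

## Network analysis

Networks are simple signed digraphs (no self-loops, one edge per ordered
pair).  Conventions, chosen to make small dense regulatory modules
comparable across tools:

- density m/(n(n−1));
- average path length and diameter over *reachable* ordered pairs only,
  so weak connectivity still yields finite values;
- clustering on the undirected projection (directed triad census
  definitions give much smaller values on modules of this size and are
  not what interaction databases report);
- in/out-degree centrality normalized by (n−1); betweenness on directed
  shortest paths with (n−1)(n−2) normalization;
- eigenvector centrality on the undirected projection by power iteration
  scaled to max-norm 1.  Iteration runs on A + I: the spectral shift
  leaves the dominant eigenvector unchanged but removes the ±λ
  degeneracy of bipartite projections (stars in particular) that makes
  plain power iteration oscillate.  Tolerance 1e-10, cap 10,000
  iterations, optional uniform damping.

Hub genes are the top k (default 4) by unweighted mean rank across the
four centralities (rank 1 = highest, ties share the mean rank, composite
ties broken lexicographically).  No weighting is applied because none is
defensible a priori.

Degree/betweenness/path computations are delegated to networkx; the
test suite validates them against from-scratch BFS enumeration on random
digraphs with n ≤ 8.

## Cross-disease paths

A path source → gene → target exists for every gene carrying a signed,
significant regulatory edge from both diseases; it is concordant when the
two signs agree.  Genes significant in both diseases but without a
polarity majority are listed separately and never drawn as paths.  All
outputs carry a hypothesis-generating disclaimer: path assembly is set
intersection with bookkeeping, not causal inference, and no mediation or
instrumental statistic is computed.

## Synthetic data

The generators produce inputs with the *statistical structure* the
analysis assumes, seeded and byte-reproducible:

- **Cohort** (default n=728, 692 male, diabetic probabilities 127/692 and
  5/36): per-sex sizes are deterministic, diabetes status is Bernoulli,
  ages are truncated-normal with mean 61.1, SD 10.4 on [14, 91] — the
  moments and range of the emulated series.  Truncated-normal is a
  convenience; only mean/SD/range are matched, not the true age shape.
- **Literature panels**: a chosen fraction of genes draw
  n_pos ~ Binomial(n_total, p_true) with the rest at p_null; ground-truth
  labels are returned so type-I error and power are measurable.  Real
  corpora have correlated counts and gene-dependent publication volume;
  the generator does not model either, so calibration results speak to
  the statistic, not to corpus artefacts.
- **Networks**: uniform random simple digraphs with exactly m edges (or
  Erdős–Rényi), at the 9-node/29-edge scale of the hub module.
- **Gene sets**: random draws from an indexed universe, optionally with
  an exact forced intersection.

Passing tests on these inputs demonstrate correctness of the statistics
and plumbing under the stated model; they do not validate the biological
content of any particular literature corpus.

## Numerical and scale choices

- Fisher and overlap tests: log-space throughout; brute-force
  exact-rational oracles in the tests cover all tables with N ≤ 40
  (relative error < 1e-10).
- Binomial tail: checked against exact pmf summation to relative error
  1e-12 up to N = 1000.
- Null calibration runs use 10,000-gene panels with n_total in
  [100, 200]; the attained raw-p ≤ 0.05 fraction sits slightly below
  0.05 because the binomial is discrete.
- Property suites use 100–1000 random draws per invariant; the whole
  test suite completes in well under a minute on one CPU.

## Known limitations

- The population scaling inherits the cohort's selection: an all-case
  series from one centre with strong male predominance (36 females)
  makes the female stratum fragile — its joint cell rests on 5 patients.
- p₀ = 0.5 is an assumption; q-values from proprietary corpora whose
  polarity-adjustment procedure is unknown cannot be reproduced, only
  re-ranked under the stated null.
- OR/RR confidence intervals, covariate adjustment, age standardization,
  multi-set Venn analysis, external annotation-database enrichment, and
  any causal-inference statistic are explicitly out of scope.
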