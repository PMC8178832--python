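# Methods

This note documents the statistical machinery, the defaults and why they are
set where they are, the behaviour of the synthetic-data generator, and the
places where the design was genuinely open.

## Model and procedure

The input is (a) an undirected PPI network, (b) a two-condition quantitative
expression table, and (c) a pre-propagated annotation catalog (each protein
annotated by a term is also annotated by the term's ontology ancestors;
propagation itself is out of scope).

**Network construction.** Interactions are restricted to one taxon (BioGRID)
or to a confidence score strictly above 400/1000 (STRING), deduplicated,
self-loops dropped, the largest connected component (LCC) taken, and proteins
interacting with ≥ 1000 others removed. Because every downstream statistic
sums shortest-path distances, the graph must stay connected, so the LCC is
re-taken after hub removal; `--no-relcc` reproduces the literal
LCC-then-hub-filter order for comparison. Connectivity, simplicity and the
degree bound are asserted on every build.

**Fold-changes and weights.** f(v) is the ratio of condition means (means
over non-missing samples, not the mean of per-sample ratios). Unquantified
proteins, proteins with no usable value, and degenerate quantifications
(zero denominator mean) take f(v) = 1. The edge weight uses the *arithmetic*
mean m̄ of the endpoint fold-changes (a geometric-mean variant is available
via `mean="geometric"` but off by default), folded into (0, 1] as
min(m̄, 1/m̄). Up- and down-regulation are deliberately symmetric; direction-
restricted analyses and variance-aware weights (t-statistics) are out of
scope.

**Clustering statistic.** TPD(S) sums the weighted shortest-path distances
over all unordered pairs of S restricted to network vertices — proteins
outside the network cannot contribute a finite distance, so the *effective*
set S ∩ V (and its size) is what is scored and matched to a null model. The
all-pairs matrix is computed once per network with one Dijkstra pass per
source (`scipy.sparse.csgraph`), which on strictly positive weights is exact
and equal to Floyd–Warshall (also available via `method="floyd-warshall"`;
the suite checks agreement to 1e-12 and checks both against an independent
Bellman–Ford oracle). Distances are stored in float64; a dtype argument
exists for networks where the |V|² matrix dominates memory.

**Null models.** For each set size n in the catalog, `n_samples` random sets
are drawn from the proteins carrying at least one annotation, either
uniformly ("unweighted sampling") or with probability proportional to the
annotation count ("weighted sampling", the default — proteins annotated by
many terms influence many TPDs and should be represented accordingly in the
null). Weighted sampling without replacement is realised by
exponential-key order statistics (key Exp(1)/wᵢ, take the n smallest), which
is provably identical in distribution to sequential draws with renormalised
probabilities, and vectorises. The sampled TPDs are summarised by (μₙ, σₙ)
and the p-value of an observed TPD α is Φ((α − μₙ)/σₙ). Conventions: the
result is clamped to the open interval (0, 1); when σₙ = 0 (only possible
when n equals the whole eligible set) the p-value is 1 for α ≥ μₙ and the
smallest positive float otherwise.

The normal approximation exists to reach p-values far below the 1/n_samples
resolution of raw Monte-Carlo sampling. In the production configuration
(expression-weighted network, weighted sampling) the sampled TPD
distributions are right-skewed and the normal is a conservative upper bound
on the probability of strong clusterings — the suite verifies this for every
sampled TPD below μ − 2σ at three set sizes. **Limitation:** on hop-count
(unweighted-network) nulls with uniform sampling, the left tail can be
slightly *heavier* than normal (relative excess up to ~20% around μ − 2.5σ
on desk-scale graphs), so p-values in that configuration can be mildly
anti-conservative in the extreme tail; the FDR layer, which compares real
against shuffled terms scored with the *same* approximation, absorbs this in
practice.

**Sampling budgets.** The published analysis used 10⁷ samples per set size;
the pipeline default is 10⁶ (the approximation of (μ, σ) is already stable
there) and the test-suite/synthetic studies use 10⁴, which for the 200-vertex
study networks gives standard errors on μₙ far below the effect sizes probed.
`max_size` (default 1000) bounds the catalog and the null-model range
together.

**FDR.** A shuffled catalog is built by repeated random swaps of two
term–protein associations; a swap is rejected (attempt consumed, keeping the
procedure linear) when both associations share a term or either term already
annotates the other protein. Term sizes and per-protein annotation counts are
preserved exactly — asserted after every shuffle — so shuffled terms have the
same size spectrum and protein-usage profile as real ones but no biology.
Shuffled catalogs pass through the same network filter and are scored against
the same null models. FDR(p) is the shuffled-to-real ratio of counts of
p-values strictly below p (with several shuffled catalogs, the numerator is
their mean).

Default swap budget is 1000× the association count, as published; the
desk-scale studies use 100× — acceptance saturates well before that, and the
marginals are exact regardless of the budget.

**Significance calling.** Each term's own FDR is the step curve evaluated at
its p-value with inclusive counts, (#shuffled ≤ p)/(#real ≤ p) — this is
finite for every term and matches the per-term FDRs a practitioner reports.
A term is significant when its FDR is below the target (default 0.001). When
no term reaches the target, the smallest FDR estimated above zero becomes the
operative level *provided* it stays within `fallback_cap` × target (default
10×, comfortably covering fallback levels a few times the target that large
catalogs produce); an unbounded fallback would promote the lowest-p block of
any input — including pure noise at estimated FDR ~0.3 on a 50-term
catalog — which defeats the purpose of an FDR gate. The
`operative_threshold` function separately exposes the threshold-scan form
(largest evaluated p with FDR < target, fallback to the smallest positive
FDR, error when every estimate is 0/NaN because the shuffles carry no
information).

At desk scale (tens of terms) a single shuffled catalog gives the FDR
numerator a resolution of one count; the synthetic studies therefore average
over 10 independently shuffled catalogs (`n_shuffles=10`), restoring the
effective resolution that a ~14k-term production catalog has with one
shuffle. The pipeline default remains one shuffle.

**Contrast.** The whole analysis runs twice — expression-weighted and
all-ones weights — and weighted-significant terms absent from the unweighted
calls are flagged `unique_to_weighted`. Annotated proteins are innately
clustered in PPI networks, so most weighted hits also appear in the
unweighted pass; the unique ones are those whose detection required the
dysregulation signal.

## Synthetic data generator

`SyntheticSpec` defaults define the study conditions used throughout the
tests: a 200-vertex Barabási–Albert network (m = 2; PPI degree distributions
are heavy-tailed, the exact generator is a parameter not a claim), 50
background terms of size 5–15, one planted module of 10 proteins at
fold-change 4, background fold-changes log-normal around 1 with σ = 0.1, and
expression tables of 3 samples per condition whose condition-mean ratio
reproduces the planted fold-changes (per-sample scatter at half the
fold-change noise scale, so a zero-noise spec yields exactly unit weights).

Two structural choices matter and mirror observed properties of real
annotation catalogs:

* **Background terms are drawn with partial topological locality**
  (probability 0.7 of extending a term from the neighbourhood of its current
  members). Real GO terms annotate complexes and pathways and are strongly
  clustered in PPI networks even without any expression signal; a generator
  with uniformly random annotations would make the unweighted benchmark pass
  trivially empty. Null-calibration studies set the locality to 0 and plant
  nothing, so that every call is a false call.
* **Signal modules are grown as self-avoiding walks** — connected subgraphs
  (their internal edges exist, so expression weighting can contract them)
  that are only mildly hop-clustered. A breadth-first ball of 10 vertices in
  a 200-vertex scale-free graph is so tightly clustered that pure topology
  finds it without any expression signal, which would make the planted module
  unusable for testing what the weighting adds; a chain isolates the
  expression-driven detection path, which is the property the fixture exists
  to exercise.

What passing tests on these fixtures do **not** show: robustness to the
identifier-mapping noise, annotation bias and degree-distribution detail of
real repositories, or calibration at production scale (14k terms, 16k
proteins, 10⁷ samples). The fixture's role is to verify the statistical
machinery end-to-end, not to emulate BioGRID topology statistics.

## Numerical and interface conventions

* Identifiers are trimmed and upper-cased at every boundary
  (network/expression/annotations), making matching case-insensitive.
* STRING's "confidence above 0.4" is read as a strict `score > 400`;
  `inclusive=True` switches to ≥. BioGRID rows of all evidence types are
  used; `--physical-only` restricts to physical interactions.
* The term filter keeps 3 ≤ |S_T| ≤ 1000 with ≥ 50% of proteins in the
  network, and additionally requires the effective size |S_T ∩ V| ≥ 3, since
  null models only exist from size 3 up.
* Null models are cached as TSV keyed by a digest of the weighted edge list;
  cache hits change runtime, never results (the RNG stream is advanced
  identically either way).
* Every stochastic component takes an explicit seeded generator; a run
  manifest (parameters, seed, input digests) suffices to reproduce outputs
  byte-identically.
* Study sizes in the test-suite (10⁴ null samples, 10–20 seeds, 100× swap
  budget) were fixed at design time as the smallest sizes at which the
  probed effects dwarf Monte-Carlo error.

## Known limitations

* The normal approximation's left tail is validated as conservative only in
  the weighted-network / weighted-sampling configuration (see above).
* FDR estimates on catalogs of a few dozen terms are granular; prefer
  `n_shuffles` > 1 there.
* The swap procedure consumes rejected attempts rather than resampling; at
  the default 1000× budget the distinction is negligible, but the two
  schemes differ formally.
* No ontology propagation, no directed networks, no minimum-spanning-tree or
  partial-set clustering statistics, no multiple-testing correction of the
  clustering p-values themselves (terms are strongly dependent; the FDR
  layer is the control).
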