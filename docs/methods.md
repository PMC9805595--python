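# Methods

## The correlation engine

`codep` treats each gene's column of a cell-line × gene dependency
matrix as a profile and asks which profiles co-vary.  For a pair of
profiles the Pearson coefficient is computed on the *pairwise-complete*
observations — the cell lines where both values are present — rather
than listwise over rows complete everywhere.  This maximises the
information used per pair at the cost of each pair having its own
effective sample size `n`, which is therefore carried in every output
record.  The p-value is the two-sided tail of
`t = r·sqrt(n−2)/sqrt(1−r²)` on `n−2` degrees of freedom, the exact null
distribution for bivariate-normal data and a serviceable approximation
otherwise.  A perfect |r| = 1 is assigned p = 0.

Two degeneracy rules make records "missing" (`r`, `p`, `q` all NaN)
rather than misleading:

- `n < min_n` — too few complete pairs.  The default `min_n = 5`
  operationalises the panel-size floor used when restricting to a single
  tumour lineage (more than four cell lines with data).
- zero variance — a profile constant on the complete pairs has no
  defined correlation.  Constancy is detected exactly (`max == min` on
  the complete observations), not by an epsilon on centred sums, so a
  constant column never leaks an r of numerical noise.

Internally the one-target-vs-all computation is vectorised with
two-pass centred sums under the joint observation mask, which keeps it
within ~1e−12 of a naive per-pair loop; r is clipped to [−1, 1] before
the t-transform.

### Multiple testing

q-values are Benjamini–Hochberg step-up by default (`adjust` accepts the
usual `p.adjust`-style alternatives: holm, bonferroni, BY, none).
Missing p-values pass through untouched and do not count toward the
family size m.  The family is:

- `cor_targets` / `cor_target_map`: one family per target — the
  target's non-self tests with defined p.  Families are independent
  across targets, so a symmetric pair can legitimately carry different
  q in the two targets' families (r and p are identical).
- `cor_map`: one global family over the unique unordered non-self pairs;
  both directions of a pair share the q.

Self-correlations are computed and kept in the tables (they are the
`target == gene` rows) because clustering uses them, but they are never
part of a BH family and every downstream significance filter excludes
them.

### Ordering and determinism

Records are sorted by ascending q (missing last), ties by descending
|r| then gene symbol; `cor_target_map` preserves target input order.
The chunked executor splits the target list, runs chunks on a thread
pool and reduces strictly in task order, so the table is bit-identical
to a sequential run for any `workers`/`chunk_size`.

## Row filtering

Filters are declarative: a mapping from metadata column to allowed
values; a sample survives when every constrained column matches one of
its allowed values (conjunction over columns, disjunction within one).
Samples missing from the metadata cannot match a constraint.  An empty
filter is the identity and an empty result is valid (with a warning),
since lineage subsets legitimately run dry.

## Pathway z-test

For one target, the significant correlates (q below the threshold,
default 0.05) are Fisher z-transformed — `z = arctanh(r)`, which
approximately normalises the sampling distribution of r, whose raw
distribution skews as |r| → 1 — and partitioned by annotation: IN =
members of the focal set; OUT = members of at least one *other* set and
not the focal one.  The partition is exclusive (multi-annotated genes
count only as IN) and genes in no set are ignored.  The contrast is a
two-sided Welch t-test (direction readable from the group means);
Shapiro–Wilk on each group and the variance-ratio F-test are reported
as diagnostics only and never gate the test.  A result is flagged
untestable, with NaN statistics, when either group has fewer than two
members or both groups are constant.  Records with |r| exactly 1 cannot
be transformed and are dropped with a warning (they essentially never
arise off the diagonal).

The CLI's `pathway-test` additionally reports a BH-adjusted column over
the targets tested in one run, since the per-target raw p-values form a
natural family when a whole target panel is screened.

## Coverage, counting, ORA

Coverage is the pure ratio `covered / present`: `present` counts
pathway members occurring in the dataset, `covered` those significant
for at least one target (self-correlations excluded).  Significance
counting groups the same filtered records by target, by annotation (a
gene annotated to several sets counts once per set) or by any extra
table column such as a lineage tag, ranked descending with
deterministic label tie-breaks.

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k) for an overlap of k between the query and a set of K members
inside a universe of N, with a query of size n — equivalent to the
one-sided Fisher exact test.  The universe defaults to the genes the
correlation run actually tested (the list the screen could have
returned), the query is the ranked significant correlates with
out-of-universe genes removed *before* any top-k truncation, and BH runs
over the emitted sets.  Sets with no universe overlap are omitted.

## Network and clustering

Significant non-self records become an undirected graph: weight = |r|,
sign kept as a separate attribute, width = −log₁₀ q (capped when q
underflows to 0).  When the same unordered pair is significant in
several target families the smallest q — strongest evidence — wins.
Betweenness exposes three modes because the conventional encodings
disagree: `weight_as_cost` feeds |r| directly to the shortest-path
routine as a length (replicating pipelines that store |r| in the weight
attribute of a library whose centrality treats weights as distances),
`inverse_weight` uses 1/|r| so strong correlations are short, and
`unweighted` uses hop counts.  `weight_as_cost` is the default for
fidelity to that common configuration, with the caveat documented in
the docstring.  The Fruchterman–Reingold layout is seeded (default 42,
500 iterations) and uses |r| as spring strength, pulling strongly
correlated pairs together.

Clustering operates on per-target r-profiles: columns are the genes
significant for at least one clustered target, cells hold r (including
the self-correlation r = 1 where a target is itself a column), and
combinations never measured are filled with 0 — the neutral value on
the correlation scale — by a configurable `fill`.  Profiles are
clustered on Euclidean distances under the Ward.D2 criterion (minimal
increase of within-cluster sum of squares, Lance–Williams update on
squared distances, merge heights reported on the unsquared scale, so
two singletons merge at their Euclidean distance).  The dendrogram
exports as Newick with branch lengths equal to parent-minus-child merge
heights.

## Synthetic screens

The generator plants each module as a single latent factor per cell:
member gene g takes `x = s_g·sqrt(ρ)·f + sqrt(1−ρ)·ε` with f, ε
standard normal and `s_g = ±1`, so two members correlate at
`s_g·s_h·ρ` and every marginal is standard normal.  Negative-sign
members model pathway inhibitors anti-correlated with the drivers.  A
module may be restricted to one lineage: cells outside it receive pure
unit-variance noise, so the module only becomes detectable after
filtering to that lineage.  Noise genes are independent; missingness is
independent Bernoulli per entry; one seed drives all draws and the
configuration is serialised next to the outputs.

Default study conditions used by the recovery tests and the acceptance
script: 200 cell lines, three modules of 20 genes at ρ = 0.6 with 25%
negative members, 400 noise genes, 5% missing entries.  These sizes
make a single-target correlation run take milliseconds while leaving
the module signal far above the null (|r| ≈ 0.6 vs a null scale of
~1/√n ≈ 0.07), so recovery is a property of the method, not of luck.
The null study uses 200 replicates of a 100-cell × 200-noise-gene
screen.

What the generator deliberately does **not** emulate: the skewed,
heavy-tailed distribution of real dependency scores, correlated
missingness, batch structure, and overlapping/annotated-but-inactive
pathway membership.  Passing the recovery tests therefore demonstrates
correctness of the inference machinery under its own model, not
performance on a real screen.

A structural consequence worth knowing: because planted modules are
mutually independent, a target's significant correlates almost never
include genes of *other* modules, so the pathway z-test's OUT group is
usually empty on this synthetic design and the test reports itself
untestable.  On real screens — where a large fraction of the genome is
significantly correlated to some target — the OUT group is large.  The
z-test's calibration property is exercised instead by permuting set
labels among module genes, which makes both groups non-empty and the
contrast null; with unimodal z-groups (no negative-sign members) the
Welch test holds its nominal level, while strongly bimodal small groups
(mixtures of ±arctanh ρ) make it anti-conservative — a genuine
limitation of t-based contrasts on signed-correlation mixtures, visible
in the test suite.

## Numerical and I/O choices

- NA tokens on input: empty string, `NA`, `NaN` (case-insensitive).
- Floats are written with shortest-round-trip `repr`, so
  write→read→write is byte-stable; table round trips are
  value-identical including missing entries.
- Duplicate sample or gene labels are hard errors naming the
  duplicates (the raw CSV header is checked before pandas can rename
  them); non-numeric cells are reported with row/column coordinates.
- All CLI randomness (layout seed, simulation seed) is explicit;
  rerunning a command reproduces outputs byte-for-byte.

## Known limitations

- Pearson only; rank-based or partial correlations are out of scope.
- The hypergeometric ORA ignores gene-level biases (length, screen
  coverage) a permutation-based method could absorb.
- The z-test compares group means of z with gene-level independence
  assumed; correlated genes within a pathway violate this, so its p is
  best read comparatively, not as a calibrated genome-wide error rate.
- Thread-based chunking parallelises well only because numpy releases
  the GIL on the heavy operations; very small chunks gain nothing.
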