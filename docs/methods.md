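# Methods

## Model

The coefficient treats association as agreement between clusterings. A
variable x over n objects induces partitions of the objects; if x and y are
related, the partitions induced by each should match. Matching is scored by
the adjusted Rand index computed from the four pair-agreement counts
(n0: co-clustered in both partitions, n1: separated in both, n2/n3:
co-clustered in one only):

    ARI = 2 (n0 n1 − n2 n3) / [ (n0+n2)(n2+n1) + (n0+n3)(n3+n1) ]

and the coefficient is the maximum ARI over the Cartesian product of the
two candidate partition sets, clamped below at 0, hence in [0, 1]. The ARI
is chance-corrected: independently drawn partitions average to 0 whatever
their cluster counts, so the maximum over many candidate pairs does not
drift upward with kmax (verified empirically in the test suite: mean
coefficient of independent normal pairs at n=1000 stays below 0.05 for
kmax ∈ {2, 5, 10, 20}).

## Partitioning conventions

Numerical variables are cut at interior quantiles j/k (j = 1..k−1),
estimated by rank-based linear interpolation (`numpy.quantile`, method
`"linear"`). An object whose value equals a cutpoint is assigned to the
*upper* bin (left-closed bins); this choice, rather than the right-closed
alternative, makes a clean median split of an 11-point linear trend put the
median object with the upper half on both axes, which is what lets a noisy
linear relationship reach 1.0. Under heavy ties cutpoints coincide: empty
bins are dropped, labels compacted, and a split that leaves fewer than two
non-empty bins is discarded. Duplicate partitions across k (possible under
ties) are deduplicated, keeping the smallest requested k; the maximum is
unchanged because the ARI depends only on the induced set partition.

Categorical variables contribute exactly one partition — the categories
themselves, in first-appearance order (the ARI is invariant to cluster
labelling). Nominal labels are never ordered. For a mixed pair, the single
categorical partition is compared against every numerical one.

Degenerate inputs are distinguished deliberately:

* **constant variable** → no partition exists at all → the coefficient is
  *undefined* (NaN, warning logged; matrix runs continue);
* **non-constant variable whose splits all collapse** (e.g. ten identical
  values plus one outlier) → empty candidate set → the coefficient is
  exactly **0**: the comparison is well posed but no quantile structure is
  detectable.

Missing values raise by default; an opt-in pairwise-complete mode drops
objects missing in either member of a pair before partitioning (silent
deletion is too dangerous as a default).

## Parameters

| parameter | default | meaning |
|---|---|---|
| kmax | 10 | max clusters per candidate partition; bounds pattern complexity and cost (grid grows as (kmax−1)²) |
| permutations | 0 (off); 10,000 suggested for pair-level tests | permutation count for p-values |
| seed | None | seeds the single permutation RNG |
| jobs | 1 | worker count; results are bit-identical for any value |

kmax = 10 captures monotone (k = 2 suffices), quadratic (k ≈ 4) and
mixture patterns (k ≈ 5–8) at modest cost; the constant baseline means
raising it does not inflate scores on independent data.

## Significance

The p-value is the proportion of permuted-data coefficients ≥ the observed
one (ties count, "≥" taken literally). Permuting y and re-partitioning is
identical to permuting the label vectors of y's fixed partitions — quantile
cutpoints depend only on the multiset of values — so the implementation
builds partitions once and evaluates all P permutations per partition pair
in one batched contingency pass. The computation is serial and vectorized;
only the seed matters, never the worker count. The plain proportion can be
exactly 0; an opt-in smoothed estimator (r+1)/(P+1) is available.
Benjamini–Hochberg adjustment (`scipy.stats.false_discovery_control`) is
applied across pairs when requested.

Null calibration is tested directly: on independent normal pairs (n=500,
1000 permutations, 500 replicates) the p-values are uniform by a KS test at
α = 0.01.

## Numerical choices

* Scalar ARI uses exact integer arithmetic (Python ints; no overflow at any
  realistic n). The batched permutation path uses float64, exact for pair
  counts below 2^53 (n beyond 10^8).
* Degenerate ARI denominator (both partitions all-singletons or both
  one-cluster): 1 if the partitions are identical, else 0. The coefficient
  never evaluates these in practice because invalid partitions are excluded
  upstream.
* Tie-break among equal-ARI maxima: smallest kx·ky, then smallest kx —
  deterministic output, and the reported maximizing partitions are the
  least complex ones.
* Parallel matrix runs split the condensed pair index into chunks; each
  chunk is a pure function of precomputed partition sets, so reduction
  order cannot affect results.

## Synthetic data

The generators emulate the qualitative relationship types used to
characterize the coefficient; parameters the constructions do not fix were
chosen once as follows and are exposed as arguments:

* `random` — independent standard normals.
* `non_coexistence` — exactly balanced halves; the active variable is
  U(5, 10), the silenced one |N(0, 0.3²)| (one transcript high while the
  other idles near zero, as with an inhibitory regulator).
* `quadratic` — x ~ U(−2, 2), y = x² + N(0, 0.5²). The even symmetry makes
  a two-cluster split useless while four clusters lock on.
* `two_lines` — slopes +3/−3 through the origin, x ~ U(0, 5), noise
  N(0, 1), components exactly balanced. Balancing pins Pearson/Spearman
  near 0 by construction rather than by luck of the draw.
* `cat_num_assoc` — z uniform over {A, B, C}; y ~ N(0, 0.5²), N(1, 0.25²),
  N(1, 0.75²) per category (per-category means are recoverable at large n;
  tested).
* `two_cat_assoc` — z uniform; P(w=blue) = 0.85 / 0.30 / 0.50 given
  z = A / B / C (blue over-represented in A, orange more weakly in B).
* substructure — two equal Gaussian blobs (σ = 1) separated by 8σ
  diagonally, horizontally or vertically.

What these simulations do **not** emulate: library-size and count noise of
real RNA-seq, correlated gene modules, batch effects, or heavy-tailed
expression distributions. Passing tests therefore demonstrate the
statistic's behaviour on clean relationship archetypes, not end-to-end
performance on a specific expression compendium.

The Anscombe quartet is embedded verbatim (canonical 1973 values) rather
than generated.

## Known limitations

* **Small samples with large k.** With n ≈ 10 and k approaching n,
  candidate partitions are nearly all singletons and the adjusted index can
  take large values by chance alone: on the quartet's undersampled
  quadratic dataset (II) the grid maximum under this package's conventions
  is 0.65 at (kx=7, ky=9), whereas the two-cluster agreement is 0.34.
  Values computed at cluster counts close to n should be read with care
  (or kmax lowered toward √n); the permutation test is the principled
  guard, since the null distribution inflates identically.
* The coefficient is undefined for constant variables, and 0 whenever
  quantile splits collapse entirely; downstream code must expect NaN
  entries in matrix output.
* Only one-dimensional variables are supported; ordinal categories are
  treated as nominal.
* Permutation p-values cost P × (kmax−1)² batched ARI evaluations per
  pair; matrix-wide significance at large P is expensive by design (an
  allowlist flag restricts it to pairs of interest).

## Problem sizes used in the checks

Deterministic worked examples run at n = 11 (quartet); stochastic
characterization uses n = 100 with 100 seeds (categorical association,
10,000 permutations each), n = 1000 with 100 replicates (constant
baseline), and n = 500 with 500 replicates × 1000 permutations (null
calibration). Exhaustive ARI validation covers all set-partition pairs of
n ≤ 7 objects (≈ 8 × 10⁵ pairs).
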