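# Methods

This note records the statistical model behind `triadexpr`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not demonstrate.

## The sampling model and the exact test

The design is three unreplicated count libraries: paternal parent A,
maternal parent B, hybrid C.  With a single library per condition there
is no way to estimate biological variance, so the test of record is the
Audic–Claverie exact test, which models the pair of counts for one gene
as Poisson sampling from the two libraries and asks whether the two
underlying rates (per assigned read) are equal.  Conditional on `x`
reads in the first library, the count in the second follows

    p(y | x) = (n2/n1)^y (x+y)! / ( x! y! (1+n2/n1)^(x+y+1) ),

a negative-binomial with `x+1` successes and success probability
`n1/(n1+n2)`.  We evaluate the pmf via log-gamma and the tail masses via
the regularized incomplete beta function (`P(Y≤y) = I_p(x+1, y+1)` with
`p = n1/(n1+n2)`), so no factorial overflows at counts of 10^5 and the
extreme tails keep full relative precision.  The tests cross-check both
the pmf and the tails against direct term-by-term summation and against
the independent negative-binomial identity.

Two numerical conventions:

* **Two-sidedness and symmetry.** The p-value doubles the smaller of the
  two tail masses and caps at 1.  Naive conditioning on "the first"
  count is not symmetric under swapping the libraries for discrete data,
  so the conditioning member is chosen canonically — the count from the
  larger library; with equal totals, the smaller count.  This makes
  `ac_test(x, y, n1, n2) == ac_test(y, x, n2, n1)` exact, which in turn
  makes the additivity classification exactly parent-symmetric.
* **The cap at 1.** The symmetric configuration (`x == y`, `n1 == n2`)
  reaches the cap with equality; values within 1e-12 of 1 are snapped to
  1 to absorb the 1-ulp undershoot of the incomplete-beta evaluation.

A two-sided tail-doubled discrete test is conservative; a simulation in
the suite confirms the null rejection rate at p ≤ 0.05 stays below 6%.

## Thresholds and multiple testing

A gene is differentially expressed when fold change ≥ `fc_min` (default
2) **and** BH FDR ≤ `fdr_max` (default 0.001).  Fold changes are
computed on RPKM, not raw counts, so unequal sequencing depths cannot
masquerade as differential expression; zero RPKM values are floored at
`epsilon` (default 0.001 RPKM, configurable) before forming ratios.
Benjamini–Hochberg runs per comparison over the tested universe of that
comparison — genes with at least `min_count` reads (default 1) in at
least one member of the pair.  BH is delegated to statsmodels.  Note
that BH is *not* idempotent as an operator (re-adjusting adjusted values
changes them); the property the suite asserts is determinism and
order-statistic monotonicity.

## Midparent construction

The additive expectation for the hybrid is defined on expression levels:
`MPV = (RPKM_A + RPKM_B)/2`.  Because the exact test consumes counts,
the MPV is back-projected onto a pseudo-library with total
`round((N_A+N_B)/2)` and per-gene pseudo-count
`round(MPV_RPKM x length_kb x total/10^6)` (half-up rounding), which
reproduces the MPV RPKM up to rounding.  The pseudo-library is treated
as an ordinary library in the test — no variance inflation for the fact
that it is an average — matching the unreplicated design's spirit; the
alternative (defining MPV on raw counts) is sensitive to depth imbalance
between the parents and was rejected.  The tested universe is genes
expressed in the hybrid or with pseudo-count ≥ 1.  The nonadditive share
is reported as a percent of all detected genes (expressed in at least
one of the three libraries), to three decimals, half-up.

## Pattern groups and clustering

Profiles are `(log2 C/A, log2 C/B)` with the same epsilon floor.  The
four patterns are the sign quadrants; a log ratio of exactly 0 counts as
"down", so the four groups partition the DEG union deterministically.
Cluster labels (both comparisons significant) always coincide with group
labels where both exist.  The headline assignment is this sign rule.
Agglomerative clustering (average linkage, distance = 1 − Pearson
correlation) is provided for concordance but is inherently degenerate on
length-2 profiles: the correlation of two 2-vectors is ±1, determined by
which comparison is larger after centering, so it separates profile
*shape*, not quadrant.  Zero-variance profiles have no defined
correlation; they are withheld from the tree and attached to the nearest
cluster centroid in Euclidean distance, with a log notice.

## Parental bias

For each DEG, `d = |C−A|/C − |C−B|/C` on RPKM (hybrid zeros floored at
epsilon; genes at zero everywhere are excluded and counted).  `d` is
antisymmetric under swapping the parents.  |d| < 1e-12 counts as exactly
zero so "zero d" is well defined in floating point.  Sign percentages
are rounded half-up to whole percents; the sign test is binomial on
positive vs negative.

## Category contrasts

Additive-vs-nonadditive membership per functional category is tested
with Fisher's exact test on the 2x2 (in-category vs not, nonadditive vs
additive), BH across categories.  Proportions, not raw counts, drive the
direction call (odds ratio vs 1).  Annotations are always an input
table; no ontology propagation is attempted.

## Saturation analysis

Reads are subsampled without replacement (multivariate hypergeometric
over the per-gene counts).  Draws are nested — each depth's sample is a
subsample of the next deeper one — so every replicate's detection curve
is monotone by construction, not just in expectation.  The plateau depth
is the smallest grid depth after which the marginal gain, in genes per
additional million reads, drops below `gain_threshold` (default 0.5%) of
the total detected at full depth; a strictly linear curve returns none.

## The simulator

`SimulationConfig` defaults describe the experimental regime the
pipeline targets: 32,642 genes; length bins [100,500), [500,1000),
[1000,1500), [1500,2000), [2000,inf) with weights
(0.1546, 0.3071, 0.2541, 0.1362, 0.1480) (uniform within bounded bins, a
shifted-geometric tail with mean excess 1,400 bp beyond 2 kb); library
depths (8,594,083, 5,479,383, 6,267,830) assigned reads; per-library
specific-gene fractions (0.0426, 0.0284, 0.0277); 25% parent-divergent
genes with Laplace(0, 1.5) log2 effects (symmetric and heavy-tailed, so
a realistic share of divergences sit below the two-fold threshold); a
7.8% nonadditive fraction with deviation magnitude 1.0 + Exp(0.5) in
log2 and a +0.2 paternal bias (the probability a deviation moves away
from the paternal parent is (1+bias)/2 for divergent genes, a fair coin
otherwise); base expression log-normal (mean 1.0, sd 1.5 in natural
log), rescaled so library A's expected assigned reads match its
configured size.

Counts are negative-binomial via a gamma–Poisson mixture with
`var = m + alpha m^2`; the default `alpha = 0.05` is a typical bulk
RNA-seq technical+biological overdispersion, and `alpha = 0` gives the
Poisson limit.  One global seed drives three named substreams (catalog /
truth / counts) so each stage can be regenerated independently.
Library-specific silence is modeled as true-zero expression, not
dropout, so Venn-specific genes are biologically silent elsewhere.  The
truth table records, per gene, the expected RPKM per library, the signed
parent divergence, the signed midparent deviation, which parent the
deviation moves away from, two-fold true-DE flags for hybrid-vs-parent,
and the sign-quadrant pattern group.

What the simulator does **not** emulate: read-level error and mapping
ambiguity, homoeolog cross-mapping between subgenomes, transcript-length
biases within a gene, batch effects, and biological replication.
Passing recovery tests therefore demonstrate the statistical chain is
correct under its own sampling assumptions, not that those assumptions
hold for any particular real library.

## Calibration checks and problem sizes

The acceptance battery runs at sizes chosen to make the binomial noise
on each metric small while keeping the whole suite fast: type-I control
on 10,000 all-additive genes at 2M reads/library; recovery on 5,000
genes at 4M reads/library with a 10% nonadditive fraction at |log2
deviation| ≥ 2, scored on genes whose expected hybrid and midparent
counts are at least 100; bias recovery on 6,000 genes with 35%
parent-divergent, 20% nonadditive and bias +0.5 (yielding >2,000 DEGs);
the saturation fixture is 79,000 genes and ~6M reads constructed
analytically so its expected curve crosses the gain threshold at exactly
2M reads.  Type-I and recovery run in the Poisson limit (dispersion 0):
the exact test is a Poisson-ratio test and an unreplicated design has no
way to absorb extra-Poisson noise, so these checks validate the chain
under its own model.

## Known limitations

* With real overdispersion (`alpha > 0`) and no replicates, the exact
  test is anti-conservative: at `alpha = 0.05` and counts in the
  hundreds, the two-fold filter dominates and false nonadditive calls
  rise to the percent level.  This is a property of the unreplicated
  design itself; treat absolute DEG counts from such designs as
  descriptive.
* The correlation-distance clustering on two-point profiles is coarse by
  construction (see above); the sign rule is the assignment of record.
* The summed fold-change total depends on the chosen definition (sum of
  max/min ratios by default; sum of |log2 FC| available), since raw
  totals of ratios are scale-free only within one comparison.
* The saturation plateau depends on the depth grid; it is reported as a
  grid point, so its resolution is one grid step.
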