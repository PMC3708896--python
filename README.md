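# triadexpr

Three-library transcriptome comparison for allopolyploids and their
parents.

When a hybrid is formed from two parental species (for example an
allohexaploid from a paternal AA donor and a maternal BBCC donor), a
central question is how the merged genomes express their genes: does the
hybrid simply average its parents, or does it deviate — and away from
which parent?  `triadexpr` answers this from three bulk RNA-seq count
libraries — paternal parent (**A**), maternal parent (**B**), hybrid
(**C**) — with no biological replication, the classic single-library
digital-expression design.  It is aimed at researchers analysing
polyploid or hybrid expression data, and at methodologists who want a
fully simulated, ground-truth-controlled version of that analysis.

## What it computes

**Normalization.** Expression is RPKM: for a gene of length `L` bp with
`k` reads in a library of `N` assigned reads,
`RPKM = k / (L/1000) / (N/10^6)`.

**Exact count test.** Differential expression between two libraries uses
the Audic–Claverie law: given `x` reads among `n1`, the probability of
`y` reads among `n2` is

```
p(y | x) = (n2/n1)^y (x+y)! / ( x! y! (1 + n2/n1)^(x+y+1) )
```

a negative-binomial in `y` with `x+1` successes and success probability
`n1/(n1+n2)`.  The two-sided p-value doubles the smaller tail (capped at
1), evaluated in log space so counts of 10^5 pose no problem.  A gene is
a DEG when fold change ≥ 2 (on RPKM) and Benjamini–Hochberg FDR ≤ 0.001.

**Nonadditivity.** The midparent value `MPV = (RPKM_A + RPKM_B)/2` is the
additive expectation for the hybrid.  It is back-projected to a
pseudo-library (total `(N_A+N_B)/2`, pseudo-counts reproducing the MPV
RPKM), the hybrid is tested against it with the same exact test, and
genes at ≥ 2-fold / FDR ≤ 0.001 versus MPV are **nonadditive**, all
others additive.

**Patterns.** Each gene's profile `(log2 C/A, log2 C/B)` falls in one of
four sign quadrants: down/down (group 1), down/up (2), up/down (3),
up/up (4).  Genes significant in both comparisons form the clusters,
genes significant in at least one form the groups; hierarchical
clustering (average linkage, Pearson-correlation distance) is available
as a concordance check.

**Parental bias.** For each DEG,
`d = |C−A|/C − |C−B|/C` on RPKM: `d > 0` means the gene diverged more
from the paternal parent.  Sign counts plus a binomial sign test
summarize direction.

**Saturation & binning.** Read-subsampling saturation curves (nested
multivariate-hypergeometric draws, so every replicate is monotone), a
plateau-depth estimate, gene-length bins and read-coverage deciles, and
the seven-region Venn partition of expressed genes.

**Simulator.** `SimulationConfig`/`simulate_dataset` generate the whole
design with known ground truth — library-specific genes, parent-divergent
genes, a tunable nonadditive fraction and paternal-bias direction, and
negative-binomial (or Poisson) counts — enabling the recovery and
calibration tests the package ships with.

## Worked example

```python
import triadexpr as tx

cfg = tx.SimulationConfig(n_genes=2000, library_sizes=(500_000, 450_000, 480_000), seed=7)
catalog, truth, counts = tx.simulate_dataset(cfg)

rpkm = tx.compute_rpkm(counts, catalog)
flags = tx.call_expressed(counts)
venn = tx.venn_partition(flags)

deg_a = tx.call_degs(counts, rpkm, ref_lib="A")   # hybrid vs paternal
deg_b = tx.call_degs(counts, rpkm, ref_lib="B")   # hybrid vs maternal
calls = tx.classify_additivity(counts, rpkm, catalog)
summary = tx.additivity_summary(calls, n_detected=int(flags.any(axis=1).sum()))

d = tx.score_deg_union(rpkm, deg_a, deg_b)
bias = tx.bias_summary(d.to_numpy())

print("expressed:", venn.library_totals, "union:", venn.grand_total)
print("DEGs vs paternal:", tx.deg_direction_counts(deg_a))
print("DEGs vs maternal:", tx.deg_direction_counts(deg_b))
print("nonadditive:", summary["nonadditive"], f"({summary['nonadditive_percent']}% of detected)")
print("bias d>0:", bias.positive, "d<0:", bias.negative, "sign-test p:", round(bias.binomial_p, 4))
```

prints

```
expressed: {'A': 1849, 'B': 1816, 'C': 1834} union: 1993
DEGs vs paternal: {'up': 180, 'down': 157, 'total': 337}
DEGs vs maternal: {'up': 160, 'down': 142, 'total': 302}
nonadditive: 253 (12.694% of detected)
bias d>0: 220 d<0: 198 sign-test p: 0.3043
```

Reading: of 2,000 simulated genes, 1,993 are detected in at least one
library; 337 and 302 genes pass the two-fold / FDR 0.001 rule against
the paternal and maternal parent; 253 genes (12.694% of detected
genes) deviate significantly from the midparent value.  At this depth
and the default mild paternal bias (+0.2), the positive-`d` excess
(220 vs 198) is visible but not individually significant — the
calibration battery below uses a stronger setting to verify direction
recovery.

The same steps are available from the shell:

```
triadexpr simulate --out sim/ --seed 7
triadexpr report --config pipeline.yaml --out results/
```

where `pipeline.yaml` points at `counts_path` / `lengths_path` (see
`triadexpr.PipelineConfig` for all fields).

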