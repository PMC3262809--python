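# wcps — weighted change-point statistics for heterogeneous differential expression

Classical two-group tests (t-statistics and friends) assume every case
sample of a differentially expressed gene shifts. In cancer transcriptomics
that assumption routinely fails: a gene may be activated in only a handful
of case samples. `wcps` implements a nonparametric change-point approach to
this *outlier differential expression* problem: the non-parametric
change-point statistic (NPCPS) and its weighted refinement (WCPS), together
with the classical comparator scores (t, COPA, OS, ORT, MOST, LRS) and a
Monte Carlo harness for power / change-point-recovery tables and ROC/AUC
benchmarking.

## The statistic

Write a gene's values as a sequence `X = (X1, X2)`: the control block `X1`
(size `n1`, empirical CDF `F̂1`) followed by the case block `X2` (size
`n2`). If a subset of case samples is differentially expressed, the
sequence has a change point at fraction `t` with `⌊nt⌋ = n − k` for `k`
affected samples. For every candidate split the scan compares the segment
after the split against the control distribution with a Kolmogorov-type
discrepancy

    D_n(t) = √(n − ⌊nt⌋) · sup_x | F_seg(x) − F̂1(x) | ,

where `F_seg` is the ECDF of the `m = n − ⌊nt⌋` values after the split.
NPCPS takes `max_t D_n(t)`; its weakness is the right bound: when only a
few samples shift (`m` small) the statistic decays. WCPS multiplies each
step by an ascending 1/x-shaped weight

    w(t) = min(1 + 0.6 / m, 1.5),

≈1 over the left and middle of the grid and rising only at the last
positions, which restores right-bound sensitivity without inflating the
scan elsewhere. A gene is called when the scan maximum exceeds the
asymptotic Kolmogorov critical value `C(α)` (1.358 at α = 0.05, 1.628 at
α = 0.01); the argmax fraction `t̂` estimates the change point, with true
value `(n − k)/n`. Because the statistic only sees ranks, no normalization
of the expression matrix is required. Under-expression is handled by
re-running the scan on the negated profile; for unordered case groups
(real matrices) the case block is first sorted ascending, which maps any
affected subset to the right end of the sequence (see
[docs/methods.md](docs/methods.md) for what that reduction costs).

## Worked example

Reproduce a power/recovery table cell grid (standard-normal genes,
`n1 = n2 = 25`, shift μ = 2 in the last `k` case samples, 500 replicates
per `k`, threshold `C(0.01) = 1.628`):

```sh
wcps simulate-cp --n1 25 --n2 25 --mu 2 --k-grid 1,3,5,7,9,12,15,20,25 \
     --alpha 0.01 --reps 500 --seed 1 --out-dir sim
# WCPS MAE=0.033 mean miss=0.103; NPCPS MAE=0.062 mean miss=0.167
```

`sim/cp_table.tsv` holds the per-`k` rows:

```
 k  actual_cp  cp_wcps  cp_npcps  miss_wcps  miss_npcps
 1       0.98    0.847     0.708      0.696       0.838
 3       0.94    0.886     0.833      0.150       0.448
 5       0.90    0.868     0.846      0.066       0.172
 9       0.82    0.807     0.794      0.004       0.012
25       0.50    0.509     0.508      0.000       0.000
```

Reading the `k = 3` row: with only 3 of 25 case samples shifted, the
unweighted scan misses 45% of the genes while the weighted scan misses
15%, and the weighted change-point estimate (0.886) sits much closer to
the true fraction 0.94 — the weight buys most of its power exactly where
subset DGE is hardest. At `k = 25` (the whole case group shifted) both
statistics locate the group boundary (0.5) and miss nothing.

The same machinery runs on expression matrices (TSV matrix + two-column
group labels; a synthetic, ground-truthed fixture generator is built in):

```sh
wcps fixture --preset dataset1 --seed 7 --out-dir fx   # 5293 x 49 matrix
wcps detect --matrix fx/dataset1_matrix.tsv --labels fx/dataset1_labels.tsv \
     --mode wcps --alpha 0.05 --out-dir det
head -3 det/ranked_genes.tsv
# gene      statistic  cp_fraction  cp_value  direction  significant_0.05  significant_0.01
# gene_411  3.98       0.673        0.170     over       True              True
# gene_57   3.75       0.714        0.482     over       True              True
```

The top of the ranking is dominated by the planted DGE genes (here
`gene_411` and `gene_57` carry true shifts). `detect` also writes the
binary genes × case-samples DGE matrix (which case samples lie beyond each
significant gene's change-point value) plus its marginals: per-sample DGE
gene counts and the histogram of genes by affected-subset size. On sorted
real matrices treat the ranking, not the fixed-threshold calls, as the
primary output — the methods note explains why the thresholds are
permissive there.

ROC benchmarking against the comparator statistics:

```sh
wcps simulate-roc --cells 50:2:3,50:2:9 --methods wcps,npcps,t,copa,os \
     --n-genes 1000 --seed 1 --out-dir roc --plot
```

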