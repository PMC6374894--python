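# Methods

## Model and assumptions

`reodeg` detects differentially expressed genes (DEGs) between two
phenotypes using only within-sample relative expression orderings (REOs).
The underlying size-factor model: a sample measured from an equal RNA
amount `S` contains `n_k = S / T_k` cells, where `T_k` is the per-cell
total mRNA of phenotype *k*; the measured level of gene *i* is
`M_ki = r_k · N_ki · n_k = r_k · (N_ki / T_k) · S`, proportional to the
cellular concentration `C_ki = N_ki / T_k`, not to the per-cell transcript
number `N_ki`. Because `T_k` and `S` are constants within a sample, the
within-sample ordering of measurements equals the ordering of the `N_ki`.
A pair whose stable ordering reverses between phenotypes therefore
reflects a change in both concentration and absolute abundance; this is
the signal the caller tests, and it is invariant to any strictly monotone
per-sample transform (library-size scaling, RPKM with shared lengths,
log2).

Assumptions: measurements are approximately monotone in transcript number
within each sample; within-phenotype orderings are stable for most pairs
(cohorts of a homogeneous tissue); samples are exchangeable within a
phenotype (no covariate adjustment, no paired designs).

## Procedure

1. **Stable pairs** (`pairs.identify_stable_pairs`). For each unordered
   pair, count strict orderings per direction across samples; exact ties
   support neither direction and are excluded from both the count `s` and
   the effective sample size `n_eff`. The majority direction is tested
   with the exact binomial upper tail P(X ≥ s | n_eff, p₀ = 0.5).
   Benjamini–Hochberg correction runs over the family of all pairs with
   n_eff > 0; one test per pair, on its majority direction. A 50/50 split
   is never stable. Pair p-values take at most (S+1)² distinct values for
   S samples, so BH is computed exactly on a histogram of distinct values;
   pair enumeration streams over gene blocks (peak memory O(G·S + block·G)).
2. **Overlap and contingency tables** (`rankcomp`). Pairs stable in both
   phenotypes are intersected. For gene G, `a`/`b` count the non-excluded
   partners G sits above/below in the normal phenotype and `c`/`d` the
   same in the disease phenotype, taken from the stable directions (not
   raw per-sample majorities), so `a + b = c + d` by construction. Genes with no usable
   pairs get p = 1 and are outside the BH family.
3. **Fisher test.** Two-sided exact p: the sum of fixed-margin table
   probabilities whose point probability is ≤ the observed one (relative
   tolerance 1e-7). When `a = c` the observed table is modal and p = 1
   exactly (shortcut). The support pmf is evaluated in one vectorized pass
   through log-gamma functions (relative error ~1e-13, well inside the
   comparison tolerance); repeated tables are cached per fit.
4. **Iterative exclusion.** Candidates at BH q ≤ `deg_fdr` are excluded as
   partners (never from their own test) and all genes are re-tested.
   Stopping: the DEG *count* equal in two successive iterations (if
   membership differs at equal counts, a warning is logged). The exclusion
   map can enter a period-2 cycle — two self-consistent candidate sets
   whose counts alternate forever; this occurs in roughly half of
   desk-scale simulated runs. A cycle is detected when
   candidates(t) = candidates(t−2), and the smaller (more conservative) of
   the two states is reported with a warning; `max_iter = 100` remains the
   final safeguard, with plain non-convergence flagged in the run log.
   Direction: "up" iff `c > a` (equivalent to a higher G-above fraction in
   disease); `a = c` genes are never candidates, so a direction tie cannot
   be reported.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `stable_fdr` | 0.05 | BH threshold for the stable-pair background (per phenotype) |
| `deg_fdr` | 0.05 | BH threshold for the per-gene Fisher tests; exposed separately because nothing forces the two to coincide |
| `p0` | 0.5 | chance probability of one ordering in one sample |
| `max_iter` | 100 | safety cap on the exclusion iteration |
| RPKM `pseudocount` | 1.0 | added before log2; strictly monotone, hence irrelevant to REO results — it only matters for exported values |
| `rounding` (rescale / comparator) | none / nearest | rescaled counts are kept as exact reals by default; the comparator re-rounds because edgeR expects integers |

## Synthetic cohorts

`simulate.generate_baseline` emulates a normal-tissue bulk RNA-seq cohort:
per-gene means drawn once from a log-normal (natural-log location 4.0,
scale 1.5 — an SD of ≈ 2.2 on the log2 scale, a typical bulk spread;
median ≈ 55 counts) and negative-binomial sampling with dispersion 0.10
(biological CV ≈ 0.32, typical for human tissue cohorts). Shared per-gene
means induce the stable ordering structure the method assumes. Defaults
are 13,000 genes × 27 samples, mirroring a normal-lung cohort after
removing genes with zero counts in more than 75% of samples.

Disease cohorts multiply selected genes' counts by their true fold change
— `four_group` splits ups equally across FC {2, 3, 4, 5} and downs across
the reciprocals; `uniform:FC` gives one level to all — then rescale every
disease count by factor = (baseline grand total) / (modified grand total)
so both cohorts share one total. Grand-total (cohort-level) rescaling is
the default, mirroring a single "equal RNA amount" per design; the factor
is deliberately reported on the < 1 side for up-heavy designs (the
spiked cell's transcriptome is *larger*, its reciprocal is what the
rescaling multiplies by). Uniform rescaling preserves every within-sample
ordering, so the rank-based caller is provably unaffected while count
totals shift — the mechanism the evaluation probes.

What the generator does **not** emulate: gene–gene correlation beyond
shared means, transcript-length bias (simulated counts are length-free, so
they are rank-equivalent to RPKM with equal nominal lengths), batch
effects, outlier samples, or disease noise independent of the baseline
(disease samples are derived from the baseline samples, as in the
spike-in protocol). Passing tests therefore demonstrate correctness of the
machinery and the size-factor mechanism, not performance on real tissue.

## Problem sizes

Simulation experiments run at 2,000 genes with 20+20 samples (27 for null
splits), 2–5 repeats per design — chosen so the full suite and the
reproduction script each complete in minutes on one CPU while leaving the
qualitative conclusions intact. At this scale the per-design size factors
(≈ 0.71 / 0.67 / 0.60 for 400/400, 500/250, 600/120) closely track the
full-scale values, sensitivities are lower than full-scale (fewer partner
genes per reversal window), and empirical FDR and specificity are
unaffected. Null-split and FC-power experiments use the same scale.

## Numerical choices

- Exact tie handling everywhere: strict inequalities only; ties vote for
  neither direction.
- Quantile normalization uses the "average" tie dialect (tied entries get
  the mean of the rank-values they span); the procedure is idempotent.
- BH at the pair level is computed on the exact histogram of distinct
  p-values (identical to BH on the expanded vector); gene-level BH uses
  statsmodels.
- The binomial and hypergeometric kernels are scipy's exact tails; both
  are validated against integer-arithmetic enumeration in the test suite.
- All randomness flows through `numpy.random.default_rng` seeds; per-repeat
  seeds are `base_seed + repeat_index`, with a fixed offset (100003) for
  the DEG-selection stream.
- Degenerate inputs: all-zero contingency tables return p = 1; an empty
  stable-pair overlap, an all-tied matrix, and a zero grand total are hard
  errors.

## Known limitations

- Power depends on the density of partner genes inside the fold-change
  window; small cohorts or small gene panels lose sensitivity at low FC
  (at desk scale, FC 1.5 is essentially undetectable while FC ≥ 2.5 is
  well-powered).
- At high DEG density (> ~35% of genes), undetected DEGs left in the
  background can pull a few true non-DEGs across the threshold; the
  observed rate is ~0.1% of calls, consistent with the method's published
  behaviour.
- The count-equality stopping rule does not guarantee a fixed point; see
  the cycle handling above.
- No covariate adjustment, paired designs, or single-sample mode; no
  discrete-FDR correction for the binomial tests (BH is known to be
  conservative for discrete statistics).
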