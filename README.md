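# reodeg

Rank-based differential expression for cohorts whose cells differ in
**transcriptome size** (total mRNA per cell).

## The problem

Standard expression profiling extracts the *same amount* of RNA from every
sample. If a disease cell carries more total mRNA than a normal cell (global
transcriptional amplification, aneuploidy), equal-RNA-input measurements
compare cellular mRNA **concentrations**, not per-cell **absolute
abundances**: with `n_k = S / T_k` cells contributing to sample *k* (equal
extracted amount *S*, per-cell total *T_k*), the measured signal for gene
*i* is

```
M_ki = r_k · N_ki · n_k = r_k · (N_ki / T_k) · S = r_k · C_ki · S
```

where `N_ki` is the per-cell transcript number and `C_ki = N_ki / T_k` its
concentration. Count-based callers (edgeR and friends) therefore detect
concentration changes; when transcriptome sizes differ, many genes whose
absolute abundance never changed show shifted counts and are called
differential.

Within one sample, however, `T_k` and `S` are constants, so the *ordering*
of two genes' measurements equals the ordering of their absolute
abundances. A gene pair whose stable within-sample ordering **reverses**
between phenotypes must have changed in both concentration and absolute
abundance. `reodeg` implements this reversal-based caller (the RankCompV2
algorithm) for anyone analyzing case-control bulk or single-cell
expression cohorts where transcriptome-size shifts are plausible.

## The method

1. **Stable pairs.** For each phenotype and each gene pair (Gi, Gj), count
   the samples with Gi > Gj (`s`) out of `n` untied samples and test
   against chance with the exact binomial upper tail
   `P = 1 − Σ_{i<s} C(n,i) p₀^i (1−p₀)^{n−i}` (p₀ = 0.5),
   Benjamini–Hochberg-corrected across all pairs (FDR < 0.05).
2. **Contingency tables.** Intersect the two stable-pair lists. For each
   gene G, count partners above/below G in each phenotype
   (a, b vs c, d with a+b = c+d) and test the shift with a two-sided
   Fisher exact test, BH-corrected across genes.
3. **Iterative exclusion.** Pairs whose partner is a current candidate DEG
   are excluded and the tests repeated until the DEG count is stable in two
   successive iterations (a detected two-state cycle stops early and
   reports the smaller state).

The package also ships the simulation protocol that makes the
transcriptome-size mechanism executable (negative-binomial baseline
cohorts, spike-in fold-change designs, rescaling to a common grand total),
the evaluation metrics (sensitivity/specificity/F-score/empirical FDR,
POG/concordance), hypergeometric gene-set enrichment, and an optional
edgeR bridge (Rscript) as the count-based contrast.

## Worked example

Simulate a 2,000-gene, 20+20-sample cohort with 400 up- and 400
down-regulated genes (fold changes 2–5), rescale to equal totals, and call
DEGs:

```bash
reodeg simulate --genes 2000 --samples 20 --n-up 400 --n-down 400 \
    --seed 1 --out-dir demo
# transcriptome size factor: 0.7256
reodeg degs --normal demo/baseline.tsv --disease demo/disease.tsv \
    --out demo/degs.tsv --log demo/run.json
```

```
RankCompV2 results
==================
genes tested          2000
stable pairs (normal) 1778207
stable pairs (disease)1797065
overlap pairs         1666752
reversal pairs        143610
iterations            7  (NOT converged)
DEGs                  609 (297 up, 312 down)
stable-pair FDR       0.05
DEG FDR               0.05
warning: candidate set oscillates between two states; reporting the smaller one
```

The size factor 0.7256 means the spiked cohort's per-cell transcriptome
grew by ~38%, so every disease count was multiplied by 0.7256 to emulate
equal RNA input. Scoring the calls against the simulation truth:

```bash
reodeg evaluate --called demo/degs.tsv --truth demo/truth.tsv
# sensitivity 0.761, specificity 1.000, fdr 0.000
```

All 609 calls are true DEGs with the correct direction — the caller misses
some low-fold-change genes (sensitivity 76%) but does not mistake the
global concentration shift for differential expression, whereas a
count-based caller on the same rescaled matrices shows an FDR above 10%.

The same pipeline is available as a library:

```python
from reodeg import RankCompV2, read_expression_matrix

normal = read_expression_matrix("demo/baseline.tsv")
disease = read_expression_matrix("demo/disease.tsv")
result = RankCompV2(normal, disease).fit()
print(result.summary())
result.degs.head()
```

Other commands: `reodeg pog` (overlap/concordance between DEG lists),
`reodeg enrich` (GMT gene-set over-representation), `reodeg sweep`
(YAML-configured simulation sweeps).

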