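# saconflict

Analysis toolkit for studying how **intralocus sexual conflict** relates to
**recombination rate** and **gene duplication**.

A sexually antagonistic (SA) allele helps one sex and harms the other.
Population-genetic theory predicts such alleles reach higher frequencies when
their net cross-sex effect is beneficial, and one hypothesized route to
resolving the conflict is gene duplication followed by sex-specific
subfunctionalization — a process that elevated local recombination rates
should facilitate. `saconflict` implements the full statistical pipeline for
testing these ideas on a table of candidate SA variants with per-sex effect
sizes, a windowed recombination map, and a scored paralogue pair list. It is
aimed at evolutionary geneticists working with GWAS-derived candidate SA
loci (e.g. in *Drosophila* or humans).

## The statistics at its core

For a variant with sex-specific effect sizes $d_M$ and $d_F$ (Cohen's $d$;
GWAS $z$-scores are converted via $r = z/\sqrt{N}$, $d = 2r/\sqrt{1-r^2}$):

* **Effect-size ratio** — beneficial effect divided by deleterious effect;
  always negative for an SA pair, and a ratio $< -1$ means the net cross-sex
  effect is beneficial.
* **Sexual antagonism index (SAI)** — the conflict-intensity proxy

$$\mathrm{SAI} = \frac{d_M\, d_F}{\sqrt{(d_M^2 + d_F^2)/2}},$$

  negative exactly for SA pairs, symmetric in the sexes, and proportional to
  the absolute magnitude of the antagonistic effects.

Around these, the pipeline provides:

1. **Allele-frequency models** — inverse-variance-weighted least squares of
   minor-allele frequency on the effect-size ratio: pooled, with a
   functional-category interaction (nested-model F-tests), and stratified by
   category (missense / synonymous / regulatory).
2. **Recombination analysis** — per-gene pooled SAI, rate assignment from a
   cM/Mb windowed map (with optional assembly liftover), conflict-intensity
   tertiles, and a nonparametric battery: Brown–Mood k-sample median test,
   its signed two-sample Z form, Levene's dispersion test and Bonferroni-
   adjusted post-hoc pairwise median tests.
3. **Paralogue analysis** — families as connected components of gene pairs
   with DIOPT score ≥ 1, per-tertile with/without-paralogue chi-squares
   against a background panel, and Wilcoxon rank-sum comparisons of
   paralogue counts and recombination rates.
4. **A seeded synthetic-data generator** that emulates all the input tables
   with configurable built-in effects, so the entire pipeline is testable
   without any external downloads.

## Worked example

Run the whole study on synthetic data (all built-in effects active):

```sh
saconflict run-all --seed 1 --out demo --synthetic
```

```
Allele frequency ~ effect-size ratio (inverse-variance WLS)
============================================================
pooled       slope -0.1312 (SE 0.0024)  deviance 2321.07  df 2423  p 0  RSE 0.979
missense     slope -0.1293 (SE 0.0065)  deviance 373.79  df 373  p 5.1e-61  RSE 1.001
regulatory   slope -0.1324 (SE 0.0028)  deviance 1592.04  df 1707  p 0  RSE 0.966
synonymous   slope -0.1272 (SE 0.0070)  deviance 354.11  df 339  p 3.11e-52  RSE 1.022
category main effect: F = 0.279, df = 2, p = 0.756
category x ratio:     F = 0.309, df = 2, p = 0.734

Recombination rate across conflict tertiles: chi2 = 28.249, df = 2, p = 7.34e-07
Dispersion (Levene): F = 5.9806, df = (2, 220), p = 0.002957
Paralogue proportion (low): 0.378  chi2 = 0.85, p = 0.357
Paralogue proportion (medium): 0.365  chi2 = 1.27, p = 0.26
Paralogue proportion (high): 0.573  chi2 = 4.03, p = 0.0446
```

Reading the output: the pooled slope of −0.131 (the generator's true slope is
−0.126) says each unit decrease in the effect-size ratio raises the expected
minor-allele frequency by ~0.13 — net-beneficial alleles segregate at higher
frequencies. The tertile median test detects the generator's twofold rate
elevation over high-conflict genes, and the high-conflict tertile shows a
significantly larger fraction of genes with paralogues (0.573) than the
analysis set overall. The report bundle (`regression.tsv`,
`recomb_tests.tsv`, `paralog_tests.tsv`, `gene_conflicts.tsv`,
`manifest.json`) lands in `demo/`; reruns with the same seed are
byte-identical.

The same analyses are available as a library, statsmodels-style:

```python
from saconflict import ConflictStudy
from saconflict.synthetic_data import SyntheticConfig

study = ConflictStudy.from_synthetic(SyntheticConfig(seed=1))
results = study.fit()
print(results.summary())
results.regression_table()          # Table-style DataFrame
results.recomb["median_test"]       # TestResult(statistic, df, p_value, ...)
```

Real data enter through TSV tables (`saconflict.io`): a SNP table with
per-sex effects, weights and frequencies; a BED4-like recombination map; a
gene-interval BED; a scored gene-pair table; and an optional liftover block
map. `saconflict simulate --seed 1 --out syn/` writes a complete example
input set.

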