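# Methods

This note documents the statistical model behind `saconflict`, the
conventions and numerical choices baked into each stage, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Per-locus statistics

**Effect-size conversion.** GWAS association $z$-scores are converted to
Cohen's $d$ through the standard meta-analytic chain $r = z/\sqrt{N}$,
$d = 2r/\sqrt{1-r^2}$, with $N$ the per-variant sample size. The conversion
is undefined at $|r| \ge 1$ and raises a domain error there rather than
extrapolating. Both steps are exposed separately (`z_to_r`,
`z_to_cohens_d`) so an alternative chain can be substituted.

**Effect-size ratio and net effect.** The ratio divides the beneficial
effect by the deleterious one and is therefore negative for every valid SA
pair. Which sex is "beneficial" is decided per record from the signs of
$(d_M, d_F)$, not fixed a priori. Ratios below −1 are classified
net-beneficial, above −1 net-deleterious, and exactly −1 as a boundary
case. Records whose two effects share a sign are not sexually antagonistic:
they are flagged (`is_sa = False`), excluded from ratio-based statistics,
but retained for SAI (where they simply score ≥ 0).

**Sexual antagonism index.** $\mathrm{SAI} = d_M d_F / \sqrt{(d_M^2 +
d_F^2)/2}$. The denominator is the quadratic mean of the two magnitudes,
which makes the index carry units of Cohen's $d$, stay symmetric in the two
sexes, scale linearly with effect magnitude, and equal $-|d|$ for an
equal-and-opposite pair — the most negative value attainable at that
magnitude. A variant with the squared (non-root) denominator exists behind
`root_denominator=False` for sensitivity checks only; it is dimensionless
and not used anywhere in the pipeline.

## Allele-frequency models

All fits are Gaussian-identity weighted least squares with weights equal to
the inverse variance of each effect estimate (column `weight` in the input
table; only relative weights matter). The frequency response is modelled on
the raw minor-allele-frequency scale (0, 0.5] — no logit transform — which
matches the generator's linear mean structure and keeps the slope directly
interpretable as frequency change per unit ratio.

Reported per model: slope and its SE, the weighted deviance (weighted
residual sum of squares), residual degrees of freedom $n - p$, the
two-sided $t$-test p-value of the slope, and RSE $= \sqrt{\mathrm{deviance}/
\mathrm{df}}$. The category model adds nested-model F-tests: the category
main effect compares `freq ~ ratio + category` against `freq ~ ratio`, the
interaction compares the full `freq ~ ratio * category` model against the
additive one; both use the full model's residual deviance as the error
scale. Category factor ordering is fixed lexicographically (missense <
regulatory < synonymous) for determinism; the reported tests are invariant
to that choice. Stratified fits skip (and report as skipped) categories
with fewer than 3 records.

## Recombination analysis

**Coordinates.** Recombination windows, gene intervals and liftover blocks
are BED-style 0-based half-open internally; SNP positions in tables are
1-based and converted exactly once at the I/O boundary. Liftover is affine
within blocks, returns "unmapped" outside them, and unmapped records are
counted in the run manifest, never silently dropped.

**Gene pooling.** Because windowed maps have limited resolution, per-SNP
SAI values are pooled to an arithmetic mean per gene; by default only
missense SNPs qualify (they have the most direct fitness consequences), and
the filter is switchable (`--category`, including `all`). A per-SNP
granularity mode exists for analyses that treat every variant individually.
Gene rates are length-weighted means of overlapping windows, invariant to
splitting windows into equal-rate pieces; genes overlapping no window are
counted as missing.

**Tertiles.** Genes are ranked by pooled SAI; the most negative third is
the *high*-intensity group (strong conflict means large-magnitude negative
SAI). Group sizes differ by at most one, with remainders going to the
higher-intensity groups first, and ties broken by gene identifier — so
membership is deterministic under input permutation.

**Test battery.** The k-sample Brown–Mood median test counts observations
strictly above vs at-or-below the pooled grand median (ties count as
at-or-below) and applies an uncorrected Pearson chi-square with
$\mathrm{df} = k-1$; a continuity-correction flag exists but is off by
default so the $k=2$ statistic stays consistent with the k-sample formula.
The signed two-sample form uses the exact hypergeometric mean and variance
of the 2×2 table; $Z^2 = \chi^2 (N-1)/N$. An all-identical pooled sample is
a degenerate-data error. Levene's test is classic mean-centered by default
with a Brown–Forsythe (median-centered) option; the classic form is
anti-conservative on strongly skewed data such as raw cM/Mb rates, which is
why the robust option is provided and why the calibration study for Levene
uses symmetric data (see below). Post-hoc pairwise median tests recompute
the grand median per pair and report raw and Bonferroni-adjusted p-values
(3 pairs). A two-group mode (e.g. comparing SAI distributions between two
species panels) reuses the two-sample Z and Levene machinery.

## Paralogue analysis

Pairs with DIOPT score ≥ 1 (at least one supporting homology tool) define
edges; families are connected components over the gene universe, singletons
included, so family sizes always partition the universe. A gene's paralogue
count is its number of distinct direct qualifying partners (a
`family_size − 1` mode exists; a chain A–B–C illustrates the difference).
Self-pairs and duplicate pairs with conflicting scores are validation
errors; identical duplicates are collapsed.

Per-tertile enrichment is a 2×2 uncorrected Pearson chi-square
(df = 1) of with/without counts against a background panel — the genome-wide
panel when supplied, otherwise the analysis set itself (the partner genes
introduced by the pair list all carry a paralogue by construction and would
bias a universe-wide background). Results flag expected cells below 1.
Count comparisons between tertiles use the Wilcoxon rank-sum test,
excluding zero-count genes by default (the with/without margin is already
tested by the chi-square); p-values are exact by enumeration when both
samples are ≤ 25 with no ties, otherwise normal approximation with midranks
and tie correction. The reported statistic is the rank sum of the first
sample; the equivalent Mann–Whitney U is carried alongside.

## Synthetic data: what it emulates, and what it does not

The generator produces one synthetic chromosome whose structure mirrors the
scale of a real candidate-SA study: 337 genes (1–5 kb long, spaced
50–150 kb apart, i.e. a few hundred genes scattered over tens of Mb),
a zero-truncated Poisson number of SNPs per gene with mean 7, a 100 kb
windowed map with log-normal rates around 2 cM/Mb, and paralogue incidence
near one gene in two.

Per SNP, the deleterious magnitude is half-normal with scale 0.3 Cohen's
$d$; the beneficial magnitude is the deleterious one times a log-normal
cross-sex ratio (log-sd 0.35), and the benefiting sex is random. The
log-normal ratio is a deliberate choice: the ratio of two independent
half-normal magnitudes is half-Cauchy, so heavy-tailed that the linear
frequency model would be dominated by its truncation boundaries; the
log-normal keeps ratios in a band where clamping of frequencies to
(0.005, 0.5] is rare (the truth record counts clamped SNPs). Frequencies
follow `0.08 − 0.126 · ratio` plus Gaussian noise whose SD scales with each
SNP's simulated effect SE — so the inverse-variance-weighted fit is the
correctly specified estimator for these data. Weights are the inverse
squared effect SEs (log-normal around 0.05).

Built-in effects, all switchable to null: windows overlapping
high-tertile genes have their rate multiplied by `sai_recomb_effect`
(default 2; 1 = null); each gene gains a paralogue with probability
`logistic(−0.32 + 0.3·z_rate + 0.23·tertile_index)`, calibrated so tertile
proportions span roughly 0.42–0.54; positive genes receive a zero-truncated
Poisson (mean 2.5) number of fresh partner genes with uniform DIOPT scores
1–15. The liftover generator partitions the chromosome into 50–200 kb
blocks, drops ~4% of them (hard-capped at 5% unmapped), and lays the rest
out in order so the map is invertible by construction.

Everything is a pure function of (config, seed): identical seeds give
byte-identical tables, and truth records carry every latent quantity needed
to verify recovery.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, multi-chromosome structure, major-allele re-analysis, selection-based
frequency dynamics, realistic gene-length/expression correlates of
duplication, or the ascertainment noise of a real GWAS candidate list.
Passing tests therefore demonstrate that the estimators recover the effects
they target under the stated sampling model — not that those effects are
detectable in any particular real dataset.

## Calibration and validation studies

The test suite includes Monte-Carlo calibration runs whose problem sizes
were fixed as part of the study design: the tertile median test is checked
under null generator maps at 230 genes (≈ 48 pooled genes per tertile after
the missense filter), averaging over both map draws and gene structures
(5000 replicates) because the chi-square's discreteness depends on the
realised group sizes; Levene's test is checked on equal-variance Gaussian
groups of 50 (2000 replicates), the setting its reference distribution
assumes — on skewed log-normal data the classic form is known to exceed the
nominal level, which is a property of the test, not of this implementation.
Slope recovery is verified exactly in the noise-free limit (with the ratio
spread narrowed so the frequency clamp is provably inactive) and to within
3 SE of truth in ≥ 99% of 200 noisy replicates at ~2000 SNPs. Power checks
use the default effect sizes: the twofold rate elevation is detected in
≥ 80% of 200 replicates at 200 genes, and the paralogue-incidence effect is
monotone across tertiles in expectation.

## Numerical conventions and degenerate inputs

Fixed conventions: median-test ties at-or-below; no continuity corrections
by default anywhere; Bonferroni over the 3 post-hoc pairs; tertile
remainders to higher intensity; lexicographic category reference ordering;
exact Wilcoxon only for untied samples ≤ 25 per side. Degenerate inputs
raise typed errors rather than returning silently: all-identical pooled
samples (median tests), both effects zero (SAI), fewer than 3 records or a
constant ratio (regression), groups below minimum size (Levene,
interaction model). The CLI maps validation errors to exit code 2 and
degenerate-data errors to 3. Pipeline outputs are staged and moved into
place only after every analysis succeeds, and the manifest accounts for
every input record (kept, filtered, unmapped, missing rate).

## Known limitations

* The frequency model is linear on the raw frequency scale; strongly
  nonlinear frequency/ratio relationships would call for a logit-scale
  variant (the generator exposes one only through its truth record).
* Classic Levene on raw recombination rates is anti-conservative; prefer
  the Brown–Forsythe option for skewed maps.
* The per-tertile enrichment chi-square treats the background panel as
  fixed; with small backgrounds an exact test would be preferable.
* Liftover supports affine blocks only — sufficient for release-to-release
  coordinate shifts, not for complex rearrangements.
* The human-style analysis path is generic two-group machinery; no
  species-specific map-matching rules are implemented.
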