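# Methods

## Experimental design and model

The pipeline targets polysome-profiling knockdown experiments: a panel of
cell lines (one or more carrying a mutation in the factor under study),
each profiled under control and knockdown conditions, with RNA-seq
libraries from both total lysate and pooled polysome fractions, in
replicate. The default shape is 3 cell lines x 2 conditions x 2 fractions x
2 replicates = 24 libraries.

Per gene, counts follow a negative binomial with variance `mu + phi*mu^2`
(the dispersion convention of the count-GLM literature, used everywhere in
this package) and log-linear mean

```
log mu = log(effective library size) + intercept + cell line + replicate
         + gamma*KD + delta*POLY + theta*KD*POLY
```

`KD` and `POLY` are knockdown and polysome-fraction indicators under
treatment coding (reference levels: control, total, first-seen cell line
and replicate). The interaction `theta` is the parameter of interest: on
the natural-log scale it is the knockdown-induced change of the
polysome:total ratio, i.e. the change in translational efficiency. The
main effects absorb transcription changes (`gamma`), baseline TE
(`delta`), and line/batch composition; the model pools one `theta` across
cell lines, so a line-restricted response is estimated as an attenuated
average (the gene-set coordination test below recovers line specificity).

Assumptions: independent libraries, a correct log-linear mean, gene-wise
dispersions shared across samples, and — through TMM — that most genes are
not differentially expressed between libraries.

## Normalization and filtering

TMM scaling factors follow the standard trimmed weighted-mean recipe: the
reference is the sample whose 75th-percentile count fraction is closest to
the across-sample mean; per sample, genes co-expressed with the reference
contribute M (log2 ratio of count fractions) and A (mean log2 abundance);
the M tails (30% per side) and A tails (5% per side) are trimmed by
mid-rank; the kept M values are averaged with inverse delta-method-variance
weights; factors are rescaled to geometric mean 1. The implementation is
validated both against a brute-force evaluation of the formula and against
the Bioconductor reference implementation (identical to ~1e-10 in tests).

CPM uses effective (TMM-scaled) library sizes everywhere, including the
expression filter: a gene is *expressed* when CPM is strictly greater than
2 in at least 50% of all libraries (both fractions, all lines — the filter
deliberately does not condition on the design). Both thresholds are
parameters; filtering happens after normalization because the pipeline
normalizes first and nominates later, and the filter is monotone in both
parameters. Genes are *nominated* when the interaction p-value < 0.05 and
the gene is expressed; the raw p-value is used for nomination (matching the
workflow this reimplements) while Benjamini–Hochberg q-values are reported
alongside for users who prefer FDR control.

## Fitting and dispersion estimation

Coefficients are fitted by IRLS with step-halving on the log-likelihood,
converging when the relative log-likelihood change is below 1e-8 (50
iterations max, non-convergence flagged, not raised). At `phi = 0` the fit
is exactly Poisson regression; tests verify agreement with an independent
Poisson fitter to 1e-8 and with a derivative-free optimizer at positive
dispersion to 1e-6. All genes share the design matrix, so fitting is
vectorized: each IRLS iteration solves a batch of p x p normal equations.
All-zero genes are returned as degenerate fits (intercept floored, flagged
unusable); they carry missing p-values and can never be nominated.

Dispersions come from the Cox–Reid adjusted profile likelihood (APL):
`APL_g(phi) = loglik(beta_hat; phi) - 0.5*logdet(X'WX)`, evaluated on a
19-point log-spaced grid from 1e-4 to 10 with warm-started batched fits.

* **Common**: maximizes the summed APL; grid optimum refined by
  golden-section search on log-dispersion.
* **Trend**: per gene, the maximizer (quadratic interpolation on the grid)
  of a moving-window mean of APL curves along average log2 CPM (window:
  10% of genes per side, minimum 50).
* **Tagwise**: maximizes `APL_g + prior_n * (window-mean APL)` with
  `prior_n = prior_df / residual df` and `prior_df = 10` by default — an
  empirical-Bayes compromise between the gene's own likelihood and its
  abundance neighborhood. As `prior_df -> inf` the tagwise values converge
  to the trend (tested); `prior_df = 0` gives unshrunken gene-wise
  estimates. With fewer than 50 usable genes the trend is unreliable and
  everything falls back to the common value with a warning.

The interaction test is a likelihood-ratio chi-square with 1 df comparing
the full fit to the fit without the interaction column at the same tagwise
dispersion (a Wald test is available via `test="wald"`). Negative LRT
statistics within -1e-6 are clipped to zero; anything worse is flagged as
a numerical failure. On null simulations at the default settings the
observed type-I error sits at ~0.055 for a nominal 0.05 — the small
liberality expected of likelihood-ratio tests with estimated, shrunken
dispersions at n = 24 — and the p-value distribution is uniform to
KS distance ~0.01 (both recomputed by `scripts/acceptance.py`).

## TE profiles, clustering, gene sets

TE(gene, cell line, condition) = mean-over-replicates polysome CPM divided
by mean-over-replicates total CPM. Averaging before the ratio is the
default because it is stable at low counts; `order="ratio-first"` computes
per-replicate ratios (paired by replicate label) and averages them. Genes
with a zero total-fraction denominator in any cell are excluded and
listed — the analysis this mirrors likewise dropped one such gene — so the
clustered count can be one or a few lower than the nominated count.

Clustering uses Pearson-correlation similarity implemented as per-gene
z-scoring followed by Euclidean k-means: for z-scored vectors, squared
Euclidean distance is `2*(p-1)*(1 - r)`, so the objective ordering matches
correlation distance while standard solver machinery applies. The solver
is scikit-learn's KMeans with `n_init = 50` random restarts keeping the
lowest objective; empty clusters are handled by the solver's deterministic
relocation rule (given `random_state`). Flat (zero-variance) profiles are
excluded and reported. Cluster labels are renumbered 1..k by ascending
mean knockdown-minus-control TE change, so label 1 is always the most
suppressed cluster and numbering is seed-stable for separated data. `k = 4`
by default, exposed, with no model selection — choose k externally if the
data demand it.

Gene-set coordination: per cell line, the statistic is the median over the
set of (TE_KD - TE_CN). Significance comes from `n_perm` random same-size
gene sets drawn from all profiled genes, two-sided with add-one
correction, so the smallest attainable p is `1/(n_perm+1)`. The test asks
whether the set moves *more coherently than a random set of genes from the
same experiment*, which makes it robust to global TE shifts; it does not
correct across cell lines.

## Synthetic data

`simulate_dataset` draws NB counts from exactly the mean model above.
Defaults and what they emulate:

* `n_genes = 5000`, `baseline_log_mean = (3.5, 1.5)` (natural-log normal):
  a realistic right-skewed abundance distribution giving ~100 counts/gene,
  i.e. ~0.5M reads per library — a deliberately scaled-down depth that keeps
  simulation-heavy tests fast while leaving per-gene power meaningful.
* `lib_size_range = (0.5, 2.0)`: multiplicative depth factors, so TMM has
  real work to do.
* `dispersion_trend = (0.05, 1.0)`: `phi_g = 0.05 + 1/exp(b0_g)`, the
  standard decreasing mean-dispersion trend; the asymptote corresponds to a
  biological CV of ~0.22 between replicate cultures.
* `nuisance_effect_sd = 0.1`: cell-line, replicate, knockdown and fraction
  main effects are small but nonzero for every gene, so nuisance
  coefficients and normalization are genuinely exercised.
* `frac_te_shifted = 0.05`, `te_effect_range = (0.5, 1.5)` natural-log,
  random sign: individually TE-shifted genes.
* `regulon_size = 78`, `regulon_effect = -1.0`, applied only in the
  non-mutant-like cell lines: a coordinated gene set (ribosomal-protein
  style) whose knockdown response is line-restricted.

The latent mean matrix is retained in `SimTruth` for white-box tests. The
generator does not emulate gene length or GC bias, read-level error,
isoform structure, correlated counts between genes, or outlier samples —
so passing tests demonstrate correctness of the statistics under the
stated model, not robustness to those artifacts.

`simulate_mutation_table` produces MAF-like cohorts: one Gq-pathway
hotspot mutation per sample (GNAQ/GNA11, residues 209/183, mutually
exclusive), one of three driver genes per sample with strict or "almost"
(~5% double-mutant) exclusivity, Beta(5, 7) allelic fractions clipped into
(0, 1], and optional Poisson passenger mutations. The acceptance script
simulates 52 samples over 70 Mb territory with mean 32 coding mutations —
the published cohort's printed burden figures used as generator inputs —
and re-tallies them with the somatic module.

## Numerical and degenerate-input choices

* NB log-likelihood switches to the Poisson form below `phi = 1e-8`
  (gammaln differencing loses precision at size parameters ~1e12).
* Linear predictors are clipped at +/-50 to keep means finite; normal
  equations carry a 1e-10 ridge jitter against singular weight patterns.
* Quantiles use the linear-interpolation definition throughout.
* Duplicate mutation records (same sample, gene, locus, alleles) are
  dropped before every somatic tally; in-cis dinucleotide substitutions in
  one codon are one record with one protein change. Coordinates are
  1-based inclusive (MAF convention).
* Mutation burden counts all exonic classes including synonymous by
  default (`coding_classes` restricts it); the territory denominator is an
  explicit required input, never a hard-coded exome size.
* The CLI derives per-stage seeds from the run seed by fixed labels, so a
  stage rerun in isolation reproduces its in-pipeline output.

## Known limitations

* One pooled interaction across cell lines; per-line contrasts are not
  fitted (line specificity is addressed by the gene-set test).
* The LRT is mildly liberal at small n (see above); the Wald option shares
  the limitation. No quasi-likelihood/F-test machinery.
* TMM assumes mostly-null genes; simulations where a large majority of
  genes shift in one direction will mis-normalize (by construction of the
  method).
* k-means with correlation distance treats profiles with similar *shape*
  as close regardless of level; genes with near-flat profiles are
  sensitive to noise in the z-scoring.
* The permutation test treats genes as exchangeable; gene-gene correlation
  within a set (e.g. co-regulation beyond the tested effect) makes it
  anti-conservative.
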