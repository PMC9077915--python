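# Methods

This note records the statistical models implemented in refstab, the
choices made where the classic tools are ambiguous, what the synthetic
data emulate, and the package's known limits.

## Data model and units

Ct (quantification cycle) is treated throughout as a log-scale quantity:
one cycle corresponds to one factor of E in starting template, so
additive operations on Ct are multiplicative on template amounts.
Missing Ct is a dedicated NaN marker in memory and an empty cell or `NA`
on disk — never 0 and never 40, because 40 is reserved for the explicit
no-amplification imputation of genes of interest. Ct values must lie in
(0, 45]: a 40-cycle run plus the imputation value cannot legitimately
exceed that, so anything larger is rejected as a data error. Technical
replicates are collapsed by the arithmetic mean of non-missing Ct, which
equals the geometric mean of the replicate template quantities; the
collapse is idempotent and a cell is missing only when all replicates
are.

## RNA-seq screen

TPM is the within-sample length-normalized proportion × 10⁶; columns sum
to 10⁶ by construction (validated to 1e-6 relative). The screen operates
on core genes only (genes present in every individual of the pan-genome;
the flag is consumed as input metadata, not computed) and does **not**
renormalize after subsetting, so scores refer to the original TPM scale.
Standardization divides each gene's row by its own mean and the score is
the sample SD (n−1 denominator — the convention adopted wherever a bare
"standard deviation" is ambiguous). Standardization is global across all
provided samples rather than within tissue; the score is invariant to
per-gene rescaling and to sample permutation. Genes with zero mean TPM
are an error rather than silently "perfectly stable". The candidate
selector exposes an optional mean-TPM floor (default 0, i.e. no floor)
because in practice references should also be well expressed; the
tissue-specific GOI selector uses mean-TPM ≥ 500 in the target tissue and
fold change ≥ 10 (ratio of per-tissue arithmetic means) against every
other tissue, with zero off-target means counting as infinitely specific.

## geNorm

Input quantities are q = E^(minCt − Ct) with E = 2 per gene by default
(per-gene measured efficiencies may be supplied); the per-gene maximum
quantity is exactly 1. All logarithms are base 2. Samples with any
missing Ct among the analysed genes are dropped (complete-case; logged)
because the pairwise-ratio matrix requires a full table. Stepwise
exclusion removes the argmax-M gene each round; M ties within 1e-12 are
broken by excluding the gene later in the input column order — a
deterministic, documented convention. The two survivors share one M
value by construction and are reported as the best pair; for rank
aggregation they receive ranks 1 and 2 in input column order. V(n/n+1)
is computed for n = 2..K−1 from normalization factors that are geometric
means of the top-n quantities. The conventional V < 0.15 "enough
references" cut-off is exposed as a config default but labelled a
convention — it is not derived from any analysis in this package.

## NormFinder

The analysis runs directly on Ct (already log2-scale; every statistic
used is invariant to the sign flip relative to log-expression).
Ungrouped model: with k genes and n samples, residuals
z = Ct − gene mean − sample mean + grand mean give per-gene mean squares
s²_g = Σ z²/(n−1), whose expectation is σ²_g(1 − 2/k) + σ̄²/k under
heteroscedastic gene noise. Inverting by method of moments yields

    σ̂²_g = k/(k−2) · (s²_g − s̄²/(k−1)),  clipped at 0,

and the stability value is σ̂_g. This requires k ≥ 3. Grouped model
(tissues as groups): intragroup variances are estimated per group by the
same formula; the raw group deviation d_gG is the gene's group effect
minus its overall effect; the variance of true deviations γ² is
estimated by method of moments pooled over genes and groups with
sample-size weights, deviations are shrunk by γ²/(γ² + σ̂²_gG/n_G), and

    stability_g = mean_G ( |d̃_gG| + sqrt(σ̂²_gG / n_G) ).

The shrinkage target and the unshrunk standard-error term are the
package's resolution of the freedoms the published model leaves open;
both are stamped into results. The best pair minimizes the combined
stability of the pair average: ungrouped sqrt((σ̂²_a + σ̂²_b)/4) (the
variance of the mean of two independent genes — half the averaged
intragroup variance); grouped, the same halving plus the averaged shrunk
deviations. Groups need ≥ 2 samples; fewer than ~8 per group triggers a
logged warning (the method's recommended minimum) but is not enforced,
since tissue panels of 4 animals are the realistic use case. Per-tissue
analyses run ungrouped; the cross-tissue analysis groups by tissue.

## BestKeeper

Two dispersion modes are provided because the original spreadsheet tool
is described inconsistently across sources: `sd` (sample SD about the
arithmetic mean Ct, the default) and `mad_geomean` (mean absolute
deviation from the geometric mean Ct). The mode is stamped into every
report. CV% is 100·dispersion/arithmetic-mean in either mode, and fold
variation is E^SD. A gene is consistent when SD ≤ 1.0 cycle ("higher
than 1" read strictly, so the boundary is consistent). Statistics use
per-gene pairwise deletion; the index — the per-sample geometric mean Ct
over consistent genes — uses samples complete for all consistent genes.
Correlations against the index are Pearson r with the exact two-sided
t-transform p-value, no multiple-testing correction; a zero-variance
gene's correlation is undefined and reported as missing with a warning,
not an exception. Because the field uses both orderings, rankings by
ascending SD and by descending r are both available; the consensus
aggregation consumes the SD ordering.

## Efficiency and ΔCt quantification

E = 10^(−1/slope) from OLS of Ct on log10 dilution (≥ 3 distinct points;
a non-negative slope is a "no amplification trend" error). Relative
expression is E^(−ΔCt) with E = 2 by default — measured efficiencies of
real assays typically print 1.9–2.1, and a per-assay override is
available, but the common-E convention keeps two-reference aggregation
exact: the arithmetic mean of two reference Cts equals the geometric
mean of their quantities only at a shared E. Imputation at Ct = 40
applies to genes of interest only and flags the replicate, so plots can
distinguish imputed points; reference genes are never imputed, and
normalizing against an imputed gene is an error. Summaries report
mean ± SEM (sample SD/√n) over biological replicates, with SEM missing
at n = 1.

## Consensus

The comprehensive order is the geometric mean of the three per-algorithm
ranks (RefFinder-style), ascending, with ties broken by the geNorm rank
and then input gene order. This aggregation is an explicit stand-in for
the loosely defined "comprehensive stability" orderings seen in applied
studies, and the method name is written into every report so downstream
readers know which rule produced the order.

## Synthetic data

`simulate_ct` draws Ct = μ_g + b_(t,a) + τ_(g,t) + ε with Gaussian terms:
a biological-sample effect b (SD 0.5 cycles by default — extraction and
RT yield differences), a gene-by-tissue effect τ drawn once per
(gene, tissue), and technical noise ε per well (SD 0.2 by default). The
default panel mirrors a 10-gene, 5-tissue, 4-animal, 3-replicate design;
the two rRNA-like genes carry τ with SD 1.0 cycle, emulating the
tissue-dependent instability of rRNA references, and baseline Cts put
the rRNAs lowest and Act highest. Gaussian Ct noise corresponds to
multiplicative assay noise on template amounts. `simulate_counts` uses
negative-binomial counts (dispersion 0.02) around fixed means for stable
genes, with unstable genes' per-sample means multiplied by a log-normal
factor (σ uniform in 0.25–1.1, keeping the expected factor at 1), which
spans standardized-SD scores of roughly 0.2–1.5 at 51 samples — the
scale of a realistic multi-study compendium. `simulate_dilution` inverts
the efficiency model exactly in the noiseless limit. Every generator is
a pure function of (config, seed) and emits a ground-truth sidecar from
which each value can be recomputed.

What the simulations do **not** emulate: batch structure between
studies, mapping and annotation artifacts, amplification inhibitors,
primer-dimer signal, or non-Gaussian Ct outliers. Passing tests
demonstrate that the statistics behave correctly under their own model
assumptions and that the pipeline's power is adequate at the study's
design size — not that any particular real gene panel is stable.

## Verification sizes and numerical choices

Oracle-equivalence checks run 100 random 4–6-gene, 5–10-sample fixtures
against explicit-loop implementations (tolerance 1e-10; observed
deviations are at machine precision). Detection-rate checks run 200
seeded study-shaped simulations with one gene's technical noise at 5×
the 0.2-cycle baseline and no tissue effects, requiring the noisy gene
to rank last by each algorithm in ≥ 95% of seeds; the screen check uses
100 genes × 51 samples. These sizes are the package's validation
convention and complete in seconds. Floating-point scores are written
with 17 significant digits so rankings round-trip exactly; geNorm M ties
use a 1e-12 tolerance; variance estimates are clipped at zero before
square roots.

## Known limitations

* NormFinder's grouped-model shrinkage follows the derivation sketched
  above; other implementations make slightly different pooling choices,
  so grouped stability values are comparable within refstab, not
  digit-for-digit with third-party tools.
* BestKeeper's gene-versus-gene pairwise correlation matrix is not
  implemented (only gene-versus-index).
* Missingness beyond complete-case handling (geNorm, NormFinder) or
  pairwise deletion (BestKeeper) is out of scope.
* The run manifest includes a wall-clock timestamp; data outputs of
  deterministic commands are byte-reproducible, the manifest is not.
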