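# refstab

Reference-gene stability analysis for RT-qPCR, built around the validation
workflow used for the Mediterranean mussel *Mytilus galloprovincialis*:
screen an RNA-seq compendium for transcriptome-wide stable genes, measure
candidate stability from Ct data with three independent algorithms
(geNorm, NormFinder, BestKeeper), aggregate a consensus ranking, fit
amplification efficiencies from dilution series, and quantify genes of
interest by the ΔCt method against the selected references.

The intended users are molecular biologists validating reference genes in
a non-model organism, and bioinformaticians who want the three classic
stability statistics as tested, scriptable library functions instead of
spreadsheet add-ins.

## The statistics

**RNA-seq screen.** Gene-level counts are converted to transcripts per
million, TPM<sub>gs</sub> = (c<sub>gs</sub>/L<sub>g</sub>) / Σ<sub>h</sub>
(c<sub>hs</sub>/L<sub>h</sub>) × 10⁶. Each core gene's TPM profile is
divided by its own mean (centring all genes on 1) and scored by the sample
standard deviation of the standardized profile; low SD = stable.

**geNorm.** For relative quantities q = E^(minCt − Ct), the stability
measure of gene *j* is M<sub>j</sub> = mean<sub>k≠j</sub>
SD<sub>s</sub>(log₂ q<sub>js</sub>/q<sub>ks</sub>). The gene with the
highest M is discarded and M recomputed stepwise until the best pair
remains. V(n/n+1) = SD<sub>s</sub>(log₂ NF<sub>n</sub>/NF<sub>n+1</sub>),
with NF<sub>n</sub> the geometric mean of the n most stable genes'
quantities, indicates how many references are worth using.

**NormFinder.** A two-way (gene × sample) additive model on the Ct scale;
a gene's stability is the square root of its residual variance, estimated
by method of moments with the k/(k−2) bias inversion. With sample groups
(tissues), group-specific deviations are shrunk toward zero and combined
with the intragroup standard error.

**BestKeeper.** Descriptive Ct statistics per gene (geometric/arithmetic
mean, extremes, SD, CV%, fold variation E^SD); SD > 1 cycle flags a gene
inconsistent. The BestKeeper index is the per-sample geometric mean Ct
over consistent genes; genes are also judged by their Pearson r against
the index.

**Quantification.** E = 10^(−1/slope) from an OLS fit of Ct on log₁₀
dilution; relative expression of a gene of interest is E^(−ΔCt) with
ΔCt = Ct<sub>GOI</sub> − Ct<sub>ref</sub> (for two references, the mean Ct,
i.e. the geometric mean of their quantities). A GOI well with no
amplification is imputed at Ct = 40 and flagged.

**Consensus.** Geometric mean of the three per-algorithm ranks
(RefFinder-style), ascending.

## Worked example

All data here are synthetic, generated by the built-in study-shaped
simulator (10 genes × 5 tissues × 4 animals × 3 technical replicates):

```
$ refstab --seed 1 simulate --preset study --out-dir data
wrote study preset with seed 1
$ refstab run-all --ct data/sim_ct.tsv --meta data/sim_meta.tsv --all-tissues --out-dir stability
consensus (most to least stable): Act, Rps4, Cyp-A, Rpl34, Gapdh, Rpl32, Ef1a, Rpl14, 28S, 18S
```

The simulator gives the two rRNA-like genes (18S, 28S) strong
tissue-dependent shifts, and the cross-tissue consensus correctly places
them last; the remaining order reflects sampling noise among genuinely
stable genes. `stability/` now holds one ranking TSV per algorithm, the
consensus table and a run manifest. Efficiency fitting inverts a
perfect-doubling dilution series exactly:

```
$ refstab --seed 1 simulate --preset dilution --out-dir dil
$ refstab efficiency --dilution dil/sim_dilution.tsv --out-dir eff
slope -3.3219, E = 2.0000
```

and ΔCt quantification of one gene against a reference pair prints a
per-tissue mean ± SEM summary:

```
$ refstab express --ct data/sim_ct.tsv --meta data/sim_meta.tsv --goi Gapdh --refs Act,Cyp-A --out-dir ex
                     mean       sem  n
tissue
gills            2.891739  0.101870  4
digestive_gland  2.757442  0.026026  4
...
```

(Gapdh sits ~1.5 cycles below the Act/Cyp-A mean in this simulation, so
its relative expression is near 2¹·⁵ ≈ 2.8 in every tissue.)

The same operations are available as library functions
(`refstab.run_genorm`, `refstab.normfinder_stability`,
`refstab.run_bestkeeper`, `refstab.run_all`, …), which is the recommended
interface for scripted analyses.

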