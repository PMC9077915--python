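"""Seeded generators emulating the mussel reference-gene study design.

The Ct generator reproduces the structure of a multi-tissue RT-qPCR
validation experiment: 10 candidate genes measured in 5 tissues from 4
animals with 3 technical replicates per well,

    Ct_{g,(t,a,r)} = mu_g + b_{t,a} + tau_{g,t} + eps,

with a biological-sample effect b ~ N(0, sigma_b^2) shared by all genes
of one cDNA preparation (extraction and reverse-transcription yield), a
gene-by-tissue effect tau ~ N(0, sigma_tau_g^2) drawn once per
(gene, tissue) (tissue-dependent regulation; large for the rRNA-like
genes), and technical noise eps ~ N(0, sigma_g^2) per replicate well.
Gaussian noise on the Ct scale corresponds to multiplicative assay noise
on template amounts, which is the standard assumption for qPCR.

The count generator emulates the RNA-seq screen corpus: stable genes draw
negative-binomial counts around a fixed mean; unstable genes multiply the
per-sample mean by a log-normal factor whose sigma spans the range that
produces TPM-standardized SDs of roughly 0.2-1.5.

Every generator is a pure function of its configuration and seed, and
returns a ground-truth sidecar from which each simulated value can be
reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import CtTable, DilutionSeries, ExpressionMatrix

#: Gene panel of the emulated study: three ribosomal-protein candidates
#: from the RNA-seq screen plus seven conventional reference genes.
STUDY_GENES = (
    "Rpl14", "Rpl32", "Rpl34", "18S", "28S",
    "Act", "Cyp-A", "Ef1a", "Gapdh", "Rps4",
)
STUDY_TISSUES = ("gills", "digestive_gland", "gonads", "mantle", "foot")

#: Plausible baseline Cts: rRNAs are vastly abundant (low Ct), Act sits at
#: the high end of the panel, the rest are mid-range mRNAs.
STUDY_BASELINES = (22.0, 20.0, 21.0, 9.0, 11.0, 28.0, 23.0, 21.5, 24.0, 22.5)

#: rRNA-like genes get a large tissue effect (tissue-dependent shifts are
#: what makes them poor references); the mRNA candidates get none.
STUDY_TISSUE_SD = (0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimConfig:
    """Configuration of the Ct simulator; defaults mirror the study design."""

    gene_ids: tuple = STUDY_GENES
    gene_baseline_ct: tuple = STUDY_BASELINES
    noise_sd: tuple = (0.2,) * 10
    sample_effect_sd: float = 0.5
    tissues: tuple = STUDY_TISSUES
    tissue_effect_sd: tuple = STUDY_TISSUE_SD
    n_animals: int = 4
    n_tech_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.gene_ids)
        for name in ("gene_baseline_ct", "noise_sd", "tissue_effect_sd"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"{name} must have one entry per gene")
        if any(s < 0 for s in self.noise_sd) or any(
            s < 0 for s in self.tissue_effect_sd
        ) or self.sample_effect_sd < 0:
            raise ValidationError("all SDs must be >= 0")
        if self.n_animals < 1 or self.n_tech_reps < 1:
            raise ValidationError("n_animals and n_tech_reps must be >= 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-shaped configuration with optional overrides."""
    return SimConfig(seed=seed, **overrides)


def simulate_ct(c: SimConfig) -> tuple[CtTable, dict]:
    """Simulate a Ct table plus a sidecar recording every drawn effect.

    The sidecar maps baselines, sample effects b (keyed ``tissue|animal``),
    tissue effects tau (keyed ``gene|tissue``) and per-well noise eps so
    that each Ct can be recomputed as mu + b + tau + eps.
    """
    rng = np.random.default_rng(c.seed)
    genes = list(c.gene_ids)
    mu = dict(zip(genes, map(float, c.gene_baseline_ct)))
    animals = [f"a{i + 1}" for i in range(c.n_animals)]
    sample_effect = {
        f"{t}|{a}": float(rng.normal(0.0, c.sample_effect_sd))
        for t in c.tissues
        for a in animals
    }
    tissue_effect = {
        f"{g}|{t}": float(rng.normal(0.0, c.tissue_effect_sd[i]))
        for i, g in enumerate(genes)
        for t in c.tissues
    }
    rows, meta_rows, ids = [], [], []
    noise: dict = {}
    for t in c.tissues:
        for a in animals:
            for r in range(1, c.n_tech_reps + 1):
                sid = f"{t}.{a}.t{r}"
                eps = rng.normal(0.0, np.asarray(c.noise_sd, dtype=float))
                ct_row = [
                    mu[g]
                    + sample_effect[f"{t}|{a}"]
                    + tissue_effect[f"{g}|{t}"]
                    + float(eps[i])
                    for i, g in enumerate(genes)
                ]
                rows.append(ct_row)
                ids.append(sid)
                meta_rows.append((t, a, r))
                noise[sid] = {g: float(eps[i]) for i, g in enumerate(genes)}
    ct = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=genes)
    meta = pd.DataFrame(
        meta_rows,
        index=ct.index,
        columns=["tissue", "animal", "technical_replicate"],
    )
    sidecar = {
        "seed": c.seed,
        "baseline_ct": mu,
        "noise_sd": dict(zip(genes, map(float, c.noise_sd))),
        "sample_effect_sd": float(c.sample_effect_sd),
        "tissue_effect_sd": dict(zip(genes, map(float, c.tissue_effect_sd))),
        "sample_effect": sample_effect,
        "tissue_effect": tissue_effect,
        "noise": noise,
    }
    return CtTable(ct, meta), sidecar


def simulate_counts(
    n_genes: int = 100,
    n_samples: int = 51,
    stable_fraction: float = 0.5,
    seed: int = 0,
    dispersion: float = 0.02,
    unstable_sigma_range: tuple = (0.25, 1.1),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate an RNA-seq count matrix with known stability labels.

    Stable genes draw negative-binomial counts around a fixed mean with
    small dispersion; unstable genes additionally multiply the per-sample
    mean by a log-normal factor with gene-specific sigma (uniform over
    ``unstable_sigma_range``), spanning TPM-standardized SDs of roughly
    0.2-1.5 at the defaults.  Gene lengths are uniform over 500-5000 bp.
    Returns the count-mode matrix and a per-gene truth table with columns
    ``unstable`` and ``lognormal_sigma`` (0 for stable genes).
    """
    if not 0 < stable_fraction <= 1:
        raise ValidationError("stable_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    samples = [f"s{j + 1:02d}" for j in range(n_samples)]
    n_stable = int(round(stable_fraction * n_genes))
    unstable = np.zeros(n_genes, dtype=bool)
    unstable[n_stable:] = True
    mean_expr = 10.0 ** rng.uniform(np.log10(50.0), np.log10(5000.0), size=n_genes)
    sigma = np.where(
        unstable, rng.uniform(*unstable_sigma_range, size=n_genes), 0.0
    )
    lengths = rng.integers(500, 5001, size=n_genes)
    # per-sample log-normal wobble of the mean for unstable genes only;
    # the -sigma^2/2 offset keeps the expected factor at 1
    factors = np.exp(
        rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * sigma[:, None]
        - 0.5 * sigma[:, None] ** 2
    )
    means = mean_expr[:, None] * factors
    if dispersion > 0:
        shape = 1.0 / dispersion
        p = shape / (shape + means)
        counts = rng.negative_binomial(shape, p)
    else:
        counts = rng.poisson(means)
    values = pd.DataFrame(counts.astype(float), index=genes, columns=samples)
    gene_meta = pd.DataFrame(
        {"length_bp": lengths, "is_core": True}, index=pd.Index(genes)
    )
    truth = pd.DataFrame(
        {"unstable": unstable, "lognormal_sigma": sigma},
        index=pd.Index(genes, name="gene_id"),
    )
    return ExpressionMatrix(values, gene_meta, mode="counts"), truth


def simulate_dilution(
    e_true: float,
    ct_at_top: float = 20.0,
    n_points: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Simulate a 10-fold dilution series for a given true efficiency.

    Ct_i = ct_at_top - log10_dilution_i / log10(e_true) + N(0, noise_sd^2),
    with log10 dilutions 0, -1, ..., -(n_points-1).  Noiseless series
    invert exactly to E = e_true under the 10^(-1/slope) fit.
    """
    if e_true <= 1:
        raise ValidationError("e_true must be > 1")
    if n_points < 3:
        raise ValidationError("n_points must be >= 3")
    rng = np.random.default_rng(seed)
    log_dil = -np.arange(n_points, dtype=float)
    ct = ct_at_top - log_dil / np.log10(e_true)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=n_points)
    return DilutionSeries(log_dil, ct)
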