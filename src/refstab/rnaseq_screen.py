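"""Transcriptome-wide stable-gene screen and tissue-specific GOI selection.

The screen emulates a BestKeeper-style dispersion criterion applied to a
multi-dataset RNA-seq compendium: gene-level counts are converted to TPM,
restricted to core genes (present in every individual of the pan-genome),
each gene's TPM profile is divided by its own mean so all genes are centred
on 1, and the sample standard deviation of the standardized profile becomes
the gene's stability score (lower = more stable).  Candidate reference
genes are the top-ranked genes, optionally subject to a mean-TPM floor so
that lowly expressed genes are not proposed as references.

Genes of interest (GOIs) for a target tissue are selected by a high
absolute expression floor in the target tissue combined with a minimum
fold change against every other tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .io_tables import ExpressionMatrix


@dataclass
class ScreenResult:
    """Outcome of the TPM stability screen.

    ``table`` is gene-indexed with columns ``stability_score`` (SD of the
    mean-standardized TPM profile), ``mean_tpm`` and ``rank`` (1 = most
    stable; ties broken by input gene order).
    """

    table: pd.DataFrame

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)

    def ordered_genes(self) -> list:
        return list(self.table.sort_values("rank").index)


def compute_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a count matrix to transcripts per million.

    TPM_gs = (c_gs / L_g) / sum_h (c_hs / L_h) * 1e6, so every column sums
    to one million.  A sample with all-zero counts cannot be normalized and
    raises an error naming it.
    """
    if m.mode != "counts":
        raise ValidationError("compute_tpm expects a matrix in count mode")
    lengths = m.gene_meta["length_bp"].to_numpy(dtype=float)
    rates = m.values.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"sample '{m.values.columns[zero[0]]}' has all-zero counts"
        )
    tpm = rates / totals[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=m.values.index, columns=m.values.columns),
        m.gene_meta.copy(),
        mode="tpm",
    )


def filter_core(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only core genes (is_core flag); values are not renormalized."""
    mask = m.gene_meta["is_core"].to_numpy(dtype=bool)
    if not mask.any():
        raise AnalysisError("no core genes in the matrix")
    sub = ExpressionMatrix.__new__(ExpressionMatrix)
    # bypass TPM column-sum validation: the screen keeps the original scale
    sub.values = m.values.loc[mask].astype(float)
    sub.gene_meta = m.gene_meta.loc[mask].copy()
    sub.mode = m.mode
    return sub


def stability_scores(m: ExpressionMatrix) -> ScreenResult:
    """Score each gene by the SD of its mean-standardized TPM profile.

    Every gene's TPM row is divided by its own mean, producing a profile
    centred on 1; the sample standard deviation (n-1 denominator) of that
    profile is the stability score.  Ranking is ascending in the score.
    """
    if m.mode != "tpm":
        raise ValidationError("stability_scores expects a TPM-mode matrix")
    if m.values.shape[1] < 2:
        raise AnalysisError("need at least 2 samples to estimate a SD")
    means = m.values.mean(axis=1)
    zero = means.index[means == 0]
    if len(zero):
        raise AnalysisError(
            f"gene '{zero[0]}' has zero mean TPM and cannot be standardized"
        )
    standardized = m.values.div(means, axis=0)
    score = standardized.std(axis=1, ddof=1)
    rank = score.rank(method="first").astype(int)
    table = pd.DataFrame(
        {"stability_score": score, "mean_tpm": means, "rank": rank}
    )
    return ScreenResult(table)


def select_candidates(
    r: ScreenResult, top_k: int, min_mean_tpm: float = 0.0
) -> list:
    """Top ``top_k`` most stable genes with mean TPM >= ``min_mean_tpm``.

    Rank order is preserved; fewer than ``top_k`` genes may be returned
    when the expression floor removes candidates.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    eligible = r.table[r.table["mean_tpm"] >= min_mean_tpm]
    return list(eligible.sort_values("rank").index[:top_k])


def select_tissue_specific_goi(
    m: ExpressionMatrix,
    tissue_labels: Mapping | pd.Series | Sequence,
    target: str,
    min_tpm: float = 500.0,
    min_fc: float = 10.0,
) -> list:
    """Genes highly and specifically expressed in ``target``.

    A gene qualifies when its mean TPM in the target tissue is at least
    ``min_tpm`` and, for every other tissue, the ratio of target mean to
    that tissue's mean is at least ``min_fc``.  A zero off-target mean
    passes the fold-change test (infinite specificity).
    """
    if m.mode != "tpm":
        raise ValidationError("select_tissue_specific_goi expects TPM mode")
    labels = pd.Series(tissue_labels)
    if not labels.index.equals(m.values.columns):
        labels = pd.Series(list(tissue_labels), index=m.values.columns)
    tissues = pd.unique(labels)
    if target not in set(tissues):
        raise ValidationError(f"unknown target tissue: {target!r}")
    if len(tissues) < 2:
        raise AnalysisError("need at least 2 tissues for a fold-change test")
    per_tissue = m.values.T.groupby(labels).mean().T  # genes x tissues
    target_mean = per_tissue[target]
    others = [t for t in tissues if t != target]
    selected = []
    for gene in m.values.index:
        if target_mean[gene] < min_tpm:
            continue
        ok = True
        for t in others:
            other = per_tissue.at[gene, t]
            if other > 0 and target_mean[gene] / other < min_fc:
                ok = False
                break
        if ok:
            selected.append(gene)
    return selected
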