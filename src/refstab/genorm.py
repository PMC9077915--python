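"""geNorm expression-stability analysis.

geNorm judges a candidate reference gene by how constant its expression is
*relative to the other candidates*: for each pair of genes (j, k) the
sample standard deviation of the pairwise log2 expression ratio,
V_jk = SD_s(log2 q_js / q_ks), is computed, and gene j's stability measure
M_j is the mean of V_jk over all partners k.  The least stable gene
(highest M) is discarded and M recomputed on the survivors, stepwise,
until the two most stable genes — the best pair — remain.  The pairwise
variation V(n/n+1) between normalization factors built from the n and n+1
most stable genes indicates whether adding a further reference is useful.

Input is a matrix of relative quantities q = E^(minCt - Ct); by the
classic geNorm convention E = 2 (perfect doubling) per gene unless a
measured amplification efficiency is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError
from .io_tables import CtTable, StabilityRanking

logger = logging.getLogger(__name__)

#: M values within this distance are treated as tied at exclusion time.
_M_TIE_TOL = 1e-12


def _efficiency_series(columns: pd.Index, efficiency) -> pd.Series:
    if isinstance(efficiency, Mapping):
        efficiency = pd.Series(efficiency)
    if isinstance(efficiency, pd.Series):
        absent = [g for g in columns if g not in efficiency.index]
        if absent:
            raise ParameterError(f"no efficiency supplied for genes {absent}")
        e = efficiency.reindex(columns).astype(float)
    else:
        e = pd.Series(float(efficiency), index=columns)
    if (e <= 1).any():
        bad = e.index[e <= 1][0]
        raise ParameterError(
            f"amplification efficiency must be > 1 (gene '{bad}': {e[bad]})"
        )
    return e


def ct_to_relative_quantity(t: CtTable, efficiency=2.0) -> pd.DataFrame:
    """Convert Ct to relative quantities q = E^(minCt - Ct), per gene.

    The per-gene maximum quantity is exactly 1.  Samples with any missing
    Ct among the analysed genes are dropped beforehand (geNorm needs a
    complete matrix); the drop is logged.
    """
    ct = t.ct
    complete = ct.notna().all(axis=1)
    if not complete.all():
        dropped = list(ct.index[~complete])
        logger.warning(
            "dropping %d sample(s) with missing Ct: %s", len(dropped), dropped
        )
        ct = ct.loc[complete]
    if ct.shape[0] == 0:
        raise AnalysisError("no complete samples remain after missing-Ct filtering")
    e = _efficiency_series(ct.columns, efficiency)
    exponent = ct.min(axis=0).to_numpy()[None, :] - ct.to_numpy(dtype=float)
    q = e.to_numpy()[None, :] ** exponent
    return pd.DataFrame(q, index=ct.index, columns=ct.columns)


def genorm_m(q: pd.DataFrame) -> pd.Series:
    """Per-gene geNorm stability measure M (lower = more stable)."""
    if q.shape[1] < 3:
        raise AnalysisError("geNorm M needs at least 3 genes")
    if q.shape[0] < 2:
        raise AnalysisError("geNorm M needs at least 2 samples")
    vals = q.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise AnalysisError("relative quantities must be strictly positive")
    log_q = np.log2(vals)  # samples x genes
    diffs = log_q[:, :, None] - log_q[:, None, :]  # S x K x K
    v = diffs.std(axis=0, ddof=1)
    k = q.shape[1]
    m = v.sum(axis=1) / (k - 1)  # diagonal contributes 0
    return pd.Series(m, index=q.columns, name="M")


@dataclass
class GeNormResult:
    """Stepwise geNorm ranking.

    ``ranking`` lists genes from least to most stable (exclusion order;
    the final two, the best pair, close the list).  ``m_trajectory`` maps
    each exclusion round to the M values of the genes still in play;
    ``v_series`` holds V(n/n+1) (filled by :func:`pairwise_variation_v`).
    """

    ranking: list
    best_pair: tuple
    m_trajectory: list = field(default_factory=list)
    v_series: pd.Series | None = None
    #: M value attached to each gene: its M in the round it was excluded
    #: (survivors keep their final-round M).
    scores: pd.Series | None = None

    def ranks(self) -> pd.Series:
        """Integer ranks, 1 = most stable; best-pair order by input column order."""
        ordered = self.ranking[::-1]
        return pd.Series(
            range(1, len(ordered) + 1), index=pd.Index(ordered), name="rank"
        )

    def to_ranking(self) -> StabilityRanking:
        ranks = self.ranks()
        extras = {
            "best_pair": list(self.best_pair),
            "m_trajectory": [s for s in self.m_trajectory],
        }
        if self.v_series is not None:
            extras["v_series"] = self.v_series
        return StabilityRanking(
            "genorm", self.scores.reindex(ranks.index), ranks, extras
        )


def genorm_rank(q: pd.DataFrame) -> GeNormResult:
    """Stepwise exclusion: repeatedly drop the gene with the highest M.

    Ties within 1e-12 on M are resolved by excluding the gene that appears
    later in the input column order.  The two survivors form the best pair
    (their final M values are equal by construction); in the returned
    ``ranking`` they are listed with the gene later in input order first,
    so that reading the list backwards yields input order.
    """
    if q.shape[1] < 3:
        raise AnalysisError("geNorm ranking needs at least 3 genes")
    remaining = q.copy()
    excluded: list = []
    trajectory: list = []
    scores: dict = {}
    while remaining.shape[1] > 2:
        m = genorm_m(remaining)
        trajectory.append(m)
        top = m.max()
        tied = [g for g in remaining.columns if m[g] >= top - _M_TIE_TOL]
        drop = tied[-1]  # later in input column order
        scores[drop] = float(m[drop])
        excluded.append(drop)
        remaining = remaining.drop(columns=drop)
    pair = list(remaining.columns)
    # final M of the surviving pair: SD of their log ratio, identical for both
    log_ratio = np.log2(
        remaining.iloc[:, 0].to_numpy() / remaining.iloc[:, 1].to_numpy()
    )
    final_m = float(np.std(log_ratio, ddof=1))
    trajectory.append(pd.Series(final_m, index=remaining.columns, name="M"))
    for g in pair:
        scores[g] = final_m
    ranking = excluded + [pair[1], pair[0]]
    return GeNormResult(
        ranking=ranking,
        best_pair=tuple(pair),
        m_trajectory=trajectory,
        scores=pd.Series(scores).reindex(q.columns),
    )


def pairwise_variation_v(q: pd.DataFrame, result: GeNormResult) -> pd.Series:
    """V(n/n+1) for n = 2..K-1: SD of log2(NF_n / NF_{n+1}) over samples.

    NF_n is the per-sample geometric mean of the n most stable genes'
    relative quantities.  A low V(n/n+1) means the (n+1)-th reference adds
    little, so n references suffice (the classic cut-off 0.15 is a
    convention, not computed here).
    """
    k = q.shape[1]
    if k < 3:
        raise AnalysisError("pairwise variation needs at least 3 genes")
    order = result.ranks().sort_values().index  # most stable first
    log_q = np.log2(q[list(order)].to_numpy(dtype=float))
    labels, values = [], []
    for n in range(2, k):
        log_nf_n = log_q[:, :n].mean(axis=1)
        log_nf_n1 = log_q[:, : n + 1].mean(axis=1)
        values.append(float(np.std(log_nf_n - log_nf_n1, ddof=1)))
        labels.append(f"V{n}/{n + 1}")
    series = pd.Series(values, index=labels, name="V")
    result.v_series = series
    return series


def run_genorm(t: CtTable, efficiency=2.0) -> GeNormResult:
    """Convenience wrapper: Ct table -> quantities -> ranking + V series."""
    q = ct_to_relative_quantity(t, efficiency)
    result = genorm_rank(q)
    pairwise_variation_v(q, result)
    return result
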