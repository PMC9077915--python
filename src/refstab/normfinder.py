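"""Model-based (NormFinder-style) expression-stability analysis.

NormFinder treats the log-scale expression of gene g in sample i as

    y_gi = alpha_g + beta_i + eps_gi,        Var(eps_gi) = sigma_g^2,

a two-way (gene x sample) additive model, and measures a gene's stability
by its residual variance sigma_g^2: a gene with small sigma_g^2 tracks the
common sample effect faithfully and introduces little systematic error
when used for normalization.  Ct values are already log2-scale, so the
analysis operates on Ct directly (the sign flip relative to expression
does not affect any variance).

Ungrouped model
---------------
Residuals z_gi = y_gi - mean_i(y_gi) - mean_g(y_gi) + grand mean are
formed, per-gene mean squares s_g^2 = sum_i z_gi^2 / (n-1) computed, and
the residual variance recovered by method of moments.  Because every
column mean absorbs 1/k of each gene's own noise, s_g^2 underestimates
sigma_g^2; the unbiased inversion with k genes is

    sigma_g^2 = k/(k-2) * ( s_g^2 - mean_h s_h^2 / (k-1) ),

clipped at 0.  The stability value is sigma_g.

Grouped model
-------------
With sample groups (here: tissues), each gene additionally has a
group-specific deviation d_gG (its gene effect in group G minus its
overall gene effect).  The deviations are shrunk toward 0 in proportion to
how much of their spread is sampling noise, and the stability value
combines the shrunk deviation with the standard error of the group mean:

    stability_g = mean_G ( |d~_gG| + sqrt(sigma_gG^2 / n_G) ),
    d~_gG = d_gG * gamma^2 / (gamma^2 + sigma_gG^2 / n_G),

where gamma^2, the variance of the true deviations, is estimated by
method of moments pooled over genes and groups with sample-size weights.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_tables import CtTable, StabilityRanking

logger = logging.getLogger(__name__)

#: Below this many samples per group the variance estimates are noisy; the
#: original method recommends ~8.  Logged as a warning, not enforced.
RECOMMENDED_GROUP_SIZE = 8


@dataclass
class NormFinderResult:
    """Per-gene stability values and variance components.

    ``stability`` is in log2-scale SD units; lower = more stable.
    ``intragroup_var`` is a genes x groups DataFrame of residual-variance
    estimates (single column ``all`` when ungrouped); ``intergroup_dev``
    holds the shrunk group deviations d~ (grouped mode only).
    """

    stability: pd.Series
    intragroup_var: pd.DataFrame
    intergroup_dev: pd.DataFrame | None
    best_gene: str
    best_pair: tuple
    grouped: bool
    group_sizes: dict | None = None

    def ranks(self) -> pd.Series:
        return self.stability.rank(method="first").astype(int).rename("rank")

    def to_ranking(self) -> StabilityRanking:
        extras = {
            "intragroup_var": self.intragroup_var,
            "best_gene": self.best_gene,
            "best_pair": list(self.best_pair),
            "grouped": self.grouped,
        }
        if self.intergroup_dev is not None:
            extras["intergroup_dev"] = self.intergroup_dev
        return StabilityRanking("normfinder", self.stability, self.ranks(), extras)


def _complete_ct(t: CtTable | pd.DataFrame) -> pd.DataFrame:
    ct = t.ct if isinstance(t, CtTable) else t
    complete = ct.notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d sample(s) with missing Ct", int((~complete).sum())
        )
        ct = ct.loc[complete]
    return ct.astype(float)


def _residual_variances(y: np.ndarray) -> np.ndarray:
    """Method-of-moments residual variances of a samples x genes block."""
    n, k = y.shape
    z = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    s2 = (z**2).sum(axis=0) / (n - 1)
    sigma2 = k / (k - 2) * (s2 - s2.mean() / (k - 1))
    return np.clip(sigma2, 0.0, None)


def _resolve_groups(t, groups) -> pd.Series | None:
    if groups is None:
        return None
    if isinstance(groups, str):
        if not isinstance(t, CtTable):
            raise AnalysisError(
                "a metadata column name as 'groups' requires a CtTable input"
            )
        return t.sample_meta[groups]
    return pd.Series(groups)


def normfinder_stability(t, groups=None) -> NormFinderResult:
    """NormFinder stability values for every gene of a Ct table.

    ``groups`` may be None (ungrouped model), the name of a sample
    metadata column (e.g. ``"tissue"``), or an explicit per-sample label
    series.  Needs >= 3 genes (the k/(k-2) correction) and >= 2 samples
    per group; samples with any missing Ct are dropped first.
    """
    ct = _complete_ct(t)
    k = ct.shape[1]
    if k < 3:
        raise AnalysisError("NormFinder needs at least 3 genes")
    labels = _resolve_groups(t, groups)
    if labels is not None:
        labels = labels.reindex(ct.index)

    if labels is None or labels.nunique() == 1:
        if ct.shape[0] < 2:
            raise AnalysisError("NormFinder needs at least 2 samples")
        if ct.shape[0] < RECOMMENDED_GROUP_SIZE:
            logger.warning(
                "only %d samples; stability estimates are noisy below ~%d",
                ct.shape[0],
                RECOMMENDED_GROUP_SIZE,
            )
        sigma2 = _residual_variances(ct.to_numpy())
        stability = pd.Series(np.sqrt(sigma2), index=ct.columns, name="stability")
        intra = pd.DataFrame({"all": sigma2}, index=ct.columns)
        result = NormFinderResult(
            stability=stability,
            intragroup_var=intra,
            intergroup_dev=None,
            best_gene=str(stability.idxmin()),
            best_pair=("", ""),
            grouped=False,
            group_sizes={"all": int(ct.shape[0])},
        )
        result.best_pair = normfinder_best_pair(result)
        return result

    group_names = list(pd.unique(labels))
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise AnalysisError(
            f"group '{small.index[0]}' has {small.iloc[0]} sample(s); need >= 2"
        )
    if (sizes < RECOMMENDED_GROUP_SIZE).any():
        logger.warning(
            "groups with fewer than ~%d samples; stability estimates are noisy",
            RECOMMENDED_GROUP_SIZE,
        )
    grand = ct.to_numpy().mean()
    gene_mean = ct.mean(axis=0)  # over all samples
    intra = {}
    dev = {}
    n_per = {}
    for g in group_names:
        block = ct.loc[labels == g]
        intra[g] = _residual_variances(block.to_numpy())
        # raw group deviation: gene effect within group minus overall effect
        dev[g] = (
            block.mean(axis=0) - gene_mean - block.to_numpy().mean() + grand
        ).to_numpy()
        n_per[g] = block.shape[0]
    intra_df = pd.DataFrame(intra, index=ct.columns)
    dev_df = pd.DataFrame(dev, index=ct.columns)
    # method-of-moments estimate of the true-deviation variance gamma^2,
    # pooled over genes and groups with sample-size weights
    weights = np.array([n_per[g] for g in group_names], dtype=float)
    mean_d2 = float(np.average((dev_df.to_numpy() ** 2).mean(axis=0), weights=weights))
    mean_noise = float(
        np.average(
            (intra_df.to_numpy() / weights[None, :]).mean(axis=0), weights=weights
        )
    )
    gamma2 = max(0.0, mean_d2 - mean_noise)
    se2 = intra_df.to_numpy() / weights[None, :]
    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + se2)
    else:
        shrink = np.zeros_like(se2)
    dev_shrunk = pd.DataFrame(
        dev_df.to_numpy() * shrink, index=ct.columns, columns=group_names
    )
    per_group = np.abs(dev_shrunk.to_numpy()) + np.sqrt(se2)
    stability = pd.Series(per_group.mean(axis=1), index=ct.columns, name="stability")
    result = NormFinderResult(
        stability=stability,
        intragroup_var=intra_df,
        intergroup_dev=dev_shrunk,
        best_gene=str(stability.idxmin()),
        best_pair=("", ""),
        grouped=True,
        group_sizes={g: int(n_per[g]) for g in group_names},
    )
    result.best_pair = normfinder_best_pair(result)
    return result


def normfinder_best_pair(r: NormFinderResult, group_sizes=None) -> tuple:
    """Exhaustively search the gene pair minimizing the combined stability.

    Ungrouped: score(a, b) = sqrt((sigma_a^2 + sigma_b^2) / 4).  Grouped:
    score(a, b) = mean_G(|(d~_a + d~_b)/2| + sqrt((sigma_aG^2 +
    sigma_bG^2) / (4 n_G))), i.e. deviations averaged and intragroup
    variance of the pair mean halved relative to the single-gene average.
    """
    genes = list(r.stability.index)
    if len(genes) < 3:
        raise AnalysisError("best-pair search needs at least 3 genes")
    best, best_score = None, np.inf
    for a, b in itertools.combinations(genes, 2):
        score = combined_pair_score(r, a, b, group_sizes)
        if score < best_score - 1e-15:
            best, best_score = (a, b), score
    return best


def combined_pair_score(r: NormFinderResult, a: str, b: str, group_sizes=None):
    """Stability score of the (a + b)/2 pseudo-gene; see normfinder_best_pair."""
    va = r.intragroup_var.loc[a].to_numpy(dtype=float)
    vb = r.intragroup_var.loc[b].to_numpy(dtype=float)
    pair_var = (va + vb) / 4.0
    if not r.grouped:
        return float(np.sqrt(pair_var[0]))
    if group_sizes is None:
        group_sizes = r.group_sizes
    n = np.array([group_sizes[g] for g in r.intragroup_var.columns], dtype=float)
    d = (
        r.intergroup_dev.loc[a].to_numpy() + r.intergroup_dev.loc[b].to_numpy()
    ) / 2.0
    return float(np.mean(np.abs(d) + np.sqrt(pair_var / n)))
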