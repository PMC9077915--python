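"""BestKeeper-style descriptive stability analysis.

BestKeeper judges candidate reference genes on the Ct scale with
descriptive statistics: geometric and arithmetic mean Ct, extreme values,
a dispersion measure (SD of Ct, or mean absolute deviation from the
geometric mean — the two readings of the original spreadsheet tool),
the coefficient of variation, and the fold variation E^SD that the Ct
dispersion implies for starting template amounts.  A gene whose SD
exceeds 1 cycle (a two-fold template variation at perfect doubling) is
flagged inconsistent.  The BestKeeper index — the per-sample geometric
mean Ct over the consistent genes — serves as a synthetic reference
against which each gene's Pearson correlation is computed; the classic
ranking orders genes by descending r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, ParameterError
from .io_tables import CtTable, StabilityRanking

STAT_COLUMNS = [
    "n",
    "geo_mean_ct",
    "arith_mean_ct",
    "min_ct",
    "max_ct",
    "sd_ct",
    "cv_pct",
    "fold_variation",
    "consistent",
]


@dataclass
class BestKeeperStats:
    """Per-gene descriptive statistics plus index correlations.

    ``stats`` is a gene-indexed DataFrame with the columns in
    :data:`STAT_COLUMNS`; after :func:`bestkeeper_index` it gains
    ``pearson_r`` and ``pearson_p`` and the object carries the per-sample
    ``index`` series.  ``sd_mode`` records which dispersion was used.
    """

    stats: pd.DataFrame
    sd_mode: str
    sd_cutoff: float
    efficiency: float
    index: pd.Series | None = None

    def ranks_by_sd(self) -> pd.Series:
        return self.stats["sd_ct"].rank(method="first").astype(int).rename("rank")

    def ranks_by_r(self) -> pd.Series:
        r = self.stats["pearson_r"]
        return (-r).rank(method="first").astype(int).rename("rank")

    def to_ranking(self, by: str = "sd") -> StabilityRanking:
        """Ranking by ascending SD (default) or descending r-to-index."""
        extras = {
            "sd_mode": self.sd_mode,
            "sd_cutoff": self.sd_cutoff,
            "efficiency": self.efficiency,
            "stats": self.stats,
            "ranked_by": by,
        }
        if self.index is not None:
            extras["index"] = self.index
        if by == "sd":
            return StabilityRanking(
                "bestkeeper", self.stats["sd_ct"], self.ranks_by_sd(), extras
            )
        if by == "r":
            return StabilityRanking(
                "bestkeeper", self.stats["pearson_r"], self.ranks_by_r(), extras
            )
        raise ParameterError(f"unknown BestKeeper ranking key: {by!r}")


def descriptive_stats(
    t: CtTable,
    sd_mode: str = "sd",
    sd_cutoff: float = 1.0,
    efficiency: float = 2.0,
) -> BestKeeperStats:
    """Per-gene BestKeeper descriptive statistics (pairwise deletion).

    ``sd_mode`` selects the dispersion: ``"sd"`` is the sample standard
    deviation about the arithmetic mean Ct; ``"mad_geomean"`` the mean
    absolute deviation from the geometric mean Ct.  ``fold_variation`` is
    ``efficiency ** sd_ct``; a gene is consistent when sd_ct <= sd_cutoff
    (the boundary value is consistent: "higher than" read strictly).
    """
    if sd_mode not in ("sd", "mad_geomean"):
        raise ParameterError(f"unknown sd_mode: {sd_mode!r}")
    if efficiency <= 1:
        raise ParameterError("efficiency must be > 1")
    rows = {}
    for gene in t.ct.columns:
        x = t.ct[gene].dropna().to_numpy(dtype=float)
        if x.size < 2:
            raise AnalysisError(
                f"gene '{gene}' has {x.size} non-missing Ct value(s); need >= 2"
            )
        geo = float(np.exp(np.mean(np.log(x))))
        if sd_mode == "sd":
            sd = float(np.std(x, ddof=1))
        else:
            sd = float(np.mean(np.abs(x - geo)))
        rows[gene] = {
            "n": x.size,
            "geo_mean_ct": geo,
            "arith_mean_ct": float(np.mean(x)),
            "min_ct": float(np.min(x)),
            "max_ct": float(np.max(x)),
            "sd_ct": sd,
            "cv_pct": 100.0 * sd / float(np.mean(x)),
            "fold_variation": float(efficiency**sd),
            "consistent": sd <= sd_cutoff,
        }
    stats = pd.DataFrame.from_dict(rows, orient="index")[STAT_COLUMNS]
    stats.index.name = "gene"
    return BestKeeperStats(stats, sd_mode, sd_cutoff, efficiency)


def bestkeeper_index(t: CtTable, stats: BestKeeperStats) -> BestKeeperStats:
    """BestKeeper index and per-gene correlations against it.

    The index is the per-sample geometric mean Ct over consistent genes,
    computed on samples with complete Ct for all consistent genes.  Each
    gene's Pearson r (and two-sided p from the exact t-transform) versus
    the index is added to ``stats``; a zero-variance gene has no defined
    correlation and is reported as missing with a warning.
    """
    consistent = list(stats.stats.index[stats.stats["consistent"]])
    if len(consistent) < 2:
        raise AnalysisError(
            f"only {len(consistent)} consistent gene(s); the index needs >= 2"
        )
    block = t.ct[consistent].dropna(axis=0, how="any")
    if block.shape[0] < 3:
        raise AnalysisError(
            "fewer than 3 samples with complete Ct over the consistent genes"
        )
    index = pd.Series(
        np.exp(np.log(block.to_numpy(dtype=float)).mean(axis=1)),
        index=block.index,
        name="bestkeeper_index",
    )
    r_vals, p_vals = {}, {}
    for gene in t.ct.columns:
        paired = pd.concat([t.ct[gene], index], axis=1, join="inner").dropna()
        x = paired.iloc[:, 0].to_numpy(dtype=float)
        y = paired.iloc[:, 1].to_numpy(dtype=float)
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"correlation with the index undefined for gene '{gene}' "
                "(constant values or too few samples); reported as missing",
                stacklevel=2,
            )
            r_vals[gene], p_vals[gene] = np.nan, np.nan
            continue
        res = sps.pearsonr(x, y)
        r_vals[gene], p_vals[gene] = float(res.statistic), float(res.pvalue)
    out = stats.stats.copy()
    out["pearson_r"] = pd.Series(r_vals)
    out["pearson_p"] = pd.Series(p_vals)
    return BestKeeperStats(
        out, stats.sd_mode, stats.sd_cutoff, stats.efficiency, index=index
    )


def run_bestkeeper(
    t: CtTable,
    sd_mode: str = "sd",
    sd_cutoff: float = 1.0,
    efficiency: float = 2.0,
    with_index: bool = True,
) -> BestKeeperStats:
    """Descriptive statistics plus (when possible) the index correlations."""
    stats = descriptive_stats(t, sd_mode, sd_cutoff, efficiency)
    if with_index:
        try:
            stats = bestkeeper_index(t, stats)
        except AnalysisError:
            warnings.warn(
                "BestKeeper index not computable (fewer than 2 consistent "
                "genes or too few complete samples); reporting statistics only",
                stacklevel=2,
            )
    return stats
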