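"""Run all three stability algorithms and aggregate a consensus order.

Per tissue the three algorithms (geNorm on relative quantities,
ungrouped NormFinder on Ct, BestKeeper descriptive statistics) are run on
the technical-replicate-collapsed Ct table; across tissues NormFinder
uses tissue as its group factor while geNorm and BestKeeper pool all
samples.  The comprehensive stability order is the RefFinder-style
geometric mean of the three per-algorithm ranks (ascending; ties broken
by the geNorm rank, then input gene order) — an explicit aggregation
convention, stamped into every report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .bestkeeper import run_bestkeeper
from .errors import AnalysisError, ValidationError
from .genorm import run_genorm
from .io_tables import CtTable, StabilityRanking, collapse_technical_replicates
from .normfinder import normfinder_stability

CONSENSUS_METHOD = "geometric-mean-of-ranks"
ALGORITHMS = ("genorm", "normfinder", "bestkeeper")


@dataclass
class ConsensusResult:
    """Joint result for one tissue (or the pooled cross-tissue run)."""

    tissue: str
    rankings: dict  # algorithm -> StabilityRanking
    consensus: pd.DataFrame  # gene-indexed: per-algorithm ranks, score, rank
    best_pairs: dict  # algorithm -> tuple of 2 genes (where defined)
    method: str = CONSENSUS_METHOD

    def ordered_genes(self) -> list:
        return list(self.consensus.sort_values("consensus_rank").index)


def consensus_rank(rankings: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Aggregate per-algorithm integer ranks by their geometric mean.

    Every ranking must be a permutation of 1..n over the same gene set.
    Returns a gene-indexed DataFrame with one rank column per algorithm,
    the geometric-mean score and the final ``consensus_rank`` (ascending
    score; ties broken by the geNorm rank when present, then by the gene
    order of the first ranking supplied).
    """
    if not rankings:
        raise ValidationError("no rankings supplied")
    names = list(rankings)
    first = rankings[names[0]]
    genes = list(first.index)
    n = len(genes)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for name in names:
        r = rankings[name]
        if set(r.index) != set(genes):
            raise ValidationError(
                f"ranking '{name}' covers a different gene set"
            )
        if sorted(int(v) for v in r) != list(range(1, n + 1)):
            raise ValidationError(
                f"ranking '{name}' is not a permutation of 1..{n}"
            )
        table[f"rank_{name}"] = r.reindex(genes).astype(int)
    rank_cols = [f"rank_{name}" for name in names]
    score = np.exp(np.log(table[rank_cols].to_numpy(dtype=float)).mean(axis=1))
    table["consensus_score"] = score
    tie_break = (
        table["rank_genorm"]
        if "rank_genorm" in table.columns
        else pd.Series(range(n), index=table.index)
    )
    order = table.assign(_tie=tie_break, _input=range(n)).sort_values(
        ["consensus_score", "_tie", "_input"]
    )
    table["consensus_rank"] = pd.Series(
        range(1, n + 1), index=order.index
    ).reindex(table.index)
    return table


def run_all(
    t: CtTable,
    tissue: str = "all",
    efficiency=2.0,
    sd_mode: str = "sd",
    sd_cutoff: float = 1.0,
) -> ConsensusResult:
    """Collapse technical replicates, run the three algorithms, aggregate.

    ``tissue`` may be a tissue label (per-tissue run; ungrouped
    NormFinder) or ``"all"`` (pooled run; NormFinder grouped by tissue,
    which requires at least 2 tissues).  Every analysed tissue must have
    at least 2 biological replicates.
    """
    collapsed = collapse_technical_replicates(t)
    if tissue != "all":
        collapsed = collapsed.select_tissue(tissue)
        groups = None
    else:
        if len(collapsed.tissues) < 2:
            raise AnalysisError("the cross-tissue run needs at least 2 tissues")
        groups = "tissue"
    counts = collapsed.sample_meta.groupby("tissue")["animal"].nunique()
    small = counts[counts < 2]
    if len(small):
        raise AnalysisError(
            f"tissue '{small.index[0]}' has {small.iloc[0]} biological "
            "replicate(s); need >= 2"
        )

    gn = run_genorm(collapsed, efficiency=efficiency)
    nf = normfinder_stability(collapsed, groups=groups)
    eff_scalar = float(efficiency) if np.isscalar(efficiency) else 2.0
    bk = run_bestkeeper(
        collapsed, sd_mode=sd_mode, sd_cutoff=sd_cutoff, efficiency=eff_scalar
    )

    rankings = {
        "genorm": gn.to_ranking(),
        "normfinder": nf.to_ranking(),
        "bestkeeper": bk.to_ranking(by="sd"),
    }
    consensus = consensus_rank(
        {name: rankings[name].ranks for name in ALGORITHMS}
    )
    best_pairs = {
        "genorm": tuple(gn.best_pair),
        "normfinder": tuple(nf.best_pair),
    }
    return ConsensusResult(
        tissue=tissue,
        rankings=rankings,
        consensus=consensus,
        best_pairs=best_pairs,
    )


def consensus_to_ranking(c: ConsensusResult) -> StabilityRanking:
    """Package the consensus order as a StabilityRanking for writing."""
    extras = {
        "method": c.method,
        "tissue": c.tissue,
        "best_pairs": {k: list(v) for k, v in c.best_pairs.items()},
    }
    return StabilityRanking(
        "consensus",
        c.consensus["consensus_score"],
        c.consensus["consensus_rank"],
        extras,
    )
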