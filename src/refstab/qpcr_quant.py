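"""Amplification-efficiency fitting and deltaCt relative quantification.

Efficiency: the slope of an ordinary least-squares regression of Ct on
log10 input dilution yields the per-cycle amplification factor
E = 10^(-1/slope); E = 2 is perfect doubling (slope about -3.32), E = 1
no amplification.

Relative expression of a gene of interest (GOI) against one or two
reference genes uses the deltaCt method at a common efficiency (default
E = 2): per biological replicate, rel = E^-(Ct_GOI - Ct_ref), where for a
reference pair Ct_ref is the arithmetic mean of the two Ct values — on
the linear scale this is exactly the geometric mean of the two reference
quantities.  A GOI well with no amplification signal is imputed at
Ct = 40 (the cycle count of the run) and flagged; reference genes are
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, ParameterError, ValidationError
from .io_tables import CtTable, DilutionSeries

#: Ct assigned to a gene-of-interest well with no amplification signal.
NO_AMPLIFICATION_CT = 40.0


@dataclass
class EfficiencyFit:
    """Dilution-series regression: Ct = intercept + slope * log10(dilution)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def predicted_ct(self, log10_dilution) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log10_dilution, float)


def fit_efficiency(d: DilutionSeries) -> EfficiencyFit:
    """OLS fit of Ct on log10 dilution; E = 10^(-1/slope).

    Requires at least 3 distinct dilution points and a negative slope
    (Ct must rise as template is diluted).
    """
    res = sps.linregress(d.log10_dilution, d.ct)
    if res.slope >= 0:
        raise AnalysisError(
            f"no amplification trend: slope {res.slope:.4g} is not negative"
        )
    e = 10.0 ** (-1.0 / res.slope)
    return EfficiencyFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(e),
    )


def impute_no_amplification(t: CtTable, goi_genes: Sequence[str]) -> CtTable:
    """Replace missing Ct of the listed GOI columns by 40 and flag them.

    Only the listed genes are touched; missing values in reference-gene
    columns stay missing (and attempting to normalize against an imputed
    gene raises at expression time).
    """
    absent = [g for g in goi_genes if g not in t.ct.columns]
    if absent:
        raise ValidationError(f"unknown GOI gene ids: {absent}")
    ct = t.ct.copy()
    imputed = t.imputed.copy()
    for g in goi_genes:
        mask = ct[g].isna()
        ct.loc[mask, g] = NO_AMPLIFICATION_CT
        imputed.loc[mask, g] = True
    return CtTable(ct, t.sample_meta.copy(), imputed)


@dataclass
class RelativeExpressionResult:
    """Per-biological-replicate deltaCt expression of a GOI.

    ``per_replicate`` is indexed by sample id with columns ``tissue``,
    ``animal``, ``delta_ct``, ``rel_expr`` and ``imputed`` (True when the
    GOI Ct of that replicate was the no-amplification imputation).
    """

    goi: str
    refs: tuple
    efficiency: float
    per_replicate: pd.DataFrame

    @property
    def rel_expr(self) -> pd.Series:
        return self.per_replicate["rel_expr"]


def relative_expression(
    t: CtTable,
    goi: str,
    refs: Sequence[str] | str,
    efficiency: float = 2.0,
    tissue: str | None = None,
) -> RelativeExpressionResult:
    """deltaCt relative expression of ``goi`` against 1 or 2 references.

    Expects technical replicates to be collapsed already, so each row is
    a biological replicate.  Replicates missing the GOI Ct or any
    reference Ct are excluded with a warning; if none survive an error is
    raised.  References must not carry imputed values.
    """
    if isinstance(refs, str):
        refs = [refs]
    refs = list(refs)
    if not 1 <= len(refs) <= 2:
        raise ParameterError("refs must name 1 or 2 reference genes")
    if efficiency <= 1:
        raise ParameterError("efficiency must be > 1")
    for g in [goi] + refs:
        if g not in t.ct.columns:
            raise ValidationError(f"gene '{g}' not in the Ct table")
    if goi in refs:
        raise ParameterError("the GOI cannot serve as its own reference")
    if tissue is not None:
        t = t.select_tissue(tissue)
    ref_unique = list(dict.fromkeys(refs))
    if t.imputed[ref_unique].to_numpy().any():
        raise AnalysisError(
            f"reference gene(s) {ref_unique} carry imputed Ct values; "
            "references must never be imputed"
        )
    goi_ct = t.ct[goi]
    ref_ct = t.ct[refs].mean(axis=1, skipna=False)  # arithmetic mean on Ct scale
    usable = goi_ct.notna() & ref_ct.notna()
    if not usable.all():
        dropped = list(t.ct.index[~usable])
        warnings.warn(
            f"excluding {len(dropped)} replicate(s) with missing Ct: {dropped}",
            stacklevel=2,
        )
    if not usable.any():
        raise AnalysisError("no replicate has both GOI and reference Ct values")
    delta = (goi_ct - ref_ct)[usable]
    rel = efficiency ** (-delta)
    per_rep = pd.DataFrame(
        {
            "tissue": t.sample_meta.loc[usable, "tissue"],
            "animal": t.sample_meta.loc[usable, "animal"],
            "delta_ct": delta,
            "rel_expr": rel,
            "imputed": t.imputed.loc[usable, goi],
        }
    )
    return RelativeExpressionResult(goi, tuple(refs), float(efficiency), per_rep)


def summarize_expression(r: RelativeExpressionResult, by: str | None = None):
    """Mean and SEM (sample SD / sqrt(n)) of relative expression.

    With ``by=None`` all replicates in the result are pooled and a Series
    (mean, sem, n) is returned; ``by="tissue"`` (or ``"animal"``) yields a
    per-group DataFrame.  With a single replicate the SEM is missing.
    """
    def _summary(values: pd.Series) -> pd.Series:
        n = int(values.size)
        sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"mean": float(values.mean()), "sem": sem, "n": n})

    if by is None:
        return _summary(r.per_replicate["rel_expr"])
    if by not in r.per_replicate.columns:
        raise ParameterError(f"unknown grouping column: {by!r}")
    out = r.per_replicate.groupby(by, sort=False)["rel_expr"].apply(_summary).unstack()
    out["n"] = out["n"].astype(int)
    return out


def fold_variation(sd: float, efficiency: float = 2.0) -> float:
    """Fold change in starting template implied by a Ct dispersion.

    A Ct SD of 1 cycle at perfect doubling (E = 2) corresponds to a
    two-fold variation of input template: fold = efficiency ** sd.
    """
    if sd < 0:
        raise ParameterError("sd must be >= 0")
    if efficiency <= 1:
        raise ParameterError("efficiency must be > 1")
    return float(efficiency**sd)
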