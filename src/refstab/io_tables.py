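"""Tabular containers and I/O for the qPCR stability workflow.

Three table kinds circulate through the package:

* :class:`CtTable` — samples x genes quantification-cycle (Ct) values with
  per-sample metadata (tissue, animal, technical replicate).  This is the
  common currency of the stability algorithms.
* :class:`ExpressionMatrix` — genes x samples read counts or TPM with gene
  lengths and a core-gene flag, input of the RNA-seq screen.
* :class:`DilutionSeries` — (log10 dilution, Ct) pairs for efficiency fitting.

Files are plain delimiter-separated text.  The delimiter is auto-detected
between tab and comma on read; output is always tab-separated.  Missing Ct
values are encoded as empty cells or ``NA`` on disk and as NaN in memory —
never as 0 and never as 40, which is reserved for the explicit
no-amplification imputation in :mod:`refstab.qpcr_quant`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: Ct values must lie in (0, CT_MAX].  A 40-cycle run plus the explicit
#: imputation value 40 cannot legitimately produce anything above 45.
CT_MAX = 45.0

META_COLUMNS = ("tissue", "animal", "technical_replicate")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: file is empty")


def _check_unique(ids: Sequence, what: str, where: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"{where}: duplicate {what}: {dups}")


@dataclass
class CtTable:
    """Samples x genes matrix of Ct values plus per-sample metadata.

    Parameters
    ----------
    ct
        DataFrame indexed by sample id with one column per gene.  NaN marks
        a missing (undetermined) Ct.
    sample_meta
        DataFrame indexed by sample id with columns ``tissue``, ``animal``
        and ``technical_replicate`` (integer >= 1).
    imputed
        Optional boolean mask, same shape as ``ct``, flagging cells whose
        value was imputed (Ct = 40 for no amplification).  Defaults to all
        False.
    """

    ct: pd.DataFrame
    sample_meta: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.ct.index, "sample ids", "CtTable")
        _check_unique(self.ct.columns, "gene ids", "CtTable")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample metadata lacks columns {missing}")
        if not self.ct.index.equals(self.sample_meta.index):
            extra = set(self.sample_meta.index) - set(self.ct.index)
            absent = set(self.ct.index) - set(self.sample_meta.index)
            if extra:
                raise ValidationError(
                    f"metadata rows without a matching sample: {sorted(extra)}"
                )
            if absent:
                raise ValidationError(
                    f"samples without metadata: {sorted(absent)}"
                )
            self.sample_meta = self.sample_meta.loc[self.ct.index]
        reps = self.sample_meta["technical_replicate"]
        if (reps.astype(float) < 1).any() or (reps.astype(float) % 1 != 0).any():
            raise ValidationError("technical_replicate must be an integer >= 1")
        self.sample_meta = self.sample_meta.assign(
            technical_replicate=reps.astype(int)
        )
        triple = self.sample_meta[list(META_COLUMNS)]
        if triple.duplicated().any():
            bad = triple[triple.duplicated()].iloc[0]
            raise ValidationError(
                "duplicate (animal, tissue, technical_replicate) triple: "
                f"({bad['animal']}, {bad['tissue']}, {bad['technical_replicate']})"
            )
        values = self.ct.to_numpy(dtype=float)
        bad_mask = ~np.isnan(values) & ~(
            np.isfinite(values) & (values > 0) & (values <= CT_MAX)
        )
        if bad_mask.any():
            s, g = np.argwhere(bad_mask)[0]
            raise ValidationError(
                f"Ct value {values[s, g]} outside (0, {CT_MAX}] for sample "
                f"'{self.ct.index[s]}', gene '{self.ct.columns[g]}'"
            )
        self.ct = self.ct.astype(float)
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.ct.index, columns=self.ct.columns
            )
        else:
            self.imputed = self.imputed.reindex(
                index=self.ct.index, columns=self.ct.columns, fill_value=False
            ).astype(bool)

    @property
    def sample_ids(self) -> list:
        return list(self.ct.index)

    @property
    def gene_ids(self) -> list:
        return list(self.ct.columns)

    @property
    def tissues(self) -> list:
        return list(pd.unique(self.sample_meta["tissue"]))

    def select_tissue(self, tissue: str) -> "CtTable":
        """Subset to the samples of one tissue."""
        mask = self.sample_meta["tissue"] == tissue
        if not mask.any():
            raise ValidationError(f"unknown tissue label: {tissue!r}")
        return CtTable(
            self.ct.loc[mask].copy(),
            self.sample_meta.loc[mask].copy(),
            self.imputed.loc[mask].copy(),
        )

    def select_genes(self, genes: Sequence[str]) -> "CtTable":
        absent = [g for g in genes if g not in self.ct.columns]
        if absent:
            raise ValidationError(f"unknown gene ids: {absent}")
        return CtTable(
            self.ct[list(genes)].copy(),
            self.sample_meta.copy(),
            self.imputed[list(genes)].copy(),
        )

    def equals(self, other: "CtTable") -> bool:
        return (
            self.ct.equals(other.ct)
            and self.sample_meta[list(META_COLUMNS)].equals(
                other.sample_meta[list(META_COLUMNS)]
            )
        )


def _default_meta(sample_ids: Iterable) -> pd.DataFrame:
    ids = list(sample_ids)
    return pd.DataFrame(
        {
            "tissue": ["all"] * len(ids),
            "animal": ids,
            "technical_replicate": [1] * len(ids),
        },
        index=pd.Index(ids, name="sample_id"),
    )


def _parse_ct_cell(raw, sample, gene, path) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text in ("", "NA"):
        return math.nan
    # tolerate spreadsheet-export artifacts like "=52"
    if text.startswith("="):
        text = text[1:]
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"{path}: non-numeric Ct {raw!r} for sample '{sample}', gene '{gene}'"
        ) from None


def read_ct_table(path, meta_path=None) -> CtTable:
    """Read a Ct table (samples x genes) and optional sample metadata.

    The first column holds sample ids; remaining columns one gene each.
    Missing Ct values may be empty cells or ``NA``.  Without ``meta_path``
    every sample is treated as its own animal in a single pseudo-tissue
    with technical replicate 1.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "sample ids", str(path))
    _check_unique(raw.columns, "gene ids", str(path))
    ct = pd.DataFrame(
        [
            [_parse_ct_cell(raw.iat[i, j], raw.index[i], raw.columns[j], path)
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )
    if meta_path is None:
        meta = _default_meta(ct.index)
    else:
        meta_path = Path(meta_path)
        meta = pd.read_csv(meta_path, sep=_sniff_delimiter(meta_path), dtype=str)
        if "sample_id" not in meta.columns:
            raise FormatError(f"{meta_path}: missing 'sample_id' column")
        _check_unique(meta["sample_id"], "sample ids", str(meta_path))
        meta = meta.set_index("sample_id")
        meta.index = meta.index.astype(str)
    return CtTable(ct, meta)


def write_ct_table(t: CtTable, path, meta_path=None) -> None:
    """Write a Ct table (tab-separated, missing as ``NA``) and its metadata."""
    out = t.ct.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    if meta_path is not None:
        meta = t.sample_meta[list(META_COLUMNS)].copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


def collapse_technical_replicates(t: CtTable) -> CtTable:
    """Average technical replicates into one row per (animal, tissue).

    Each collapsed Ct is the arithmetic mean of the non-missing replicate
    Cts (Ct is a log2-scale quantity, so the mean Ct corresponds to the
    geometric mean of template amounts); a cell is missing only when all
    replicates are missing.  The operation is idempotent: collapsed sample
    ids are ``<tissue>.<animal>`` with technical replicate 1.
    """
    meta = t.sample_meta
    key = meta["tissue"].astype(str) + "." + meta["animal"].astype(str)
    ct = t.ct.groupby(key, sort=False).mean()  # skips NaN per cell
    imputed = t.imputed.groupby(key, sort=False).any()
    first = meta.groupby(key, sort=False).first()
    new_meta = pd.DataFrame(
        {
            "tissue": first["tissue"],
            "animal": first["animal"],
            "technical_replicate": 1,
        },
        index=ct.index,
    )
    ct.index.name = "sample_id"
    new_meta.index.name = "sample_id"
    return CtTable(ct, new_meta, imputed)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with gene metadata.

    ``mode`` is ``"counts"`` for raw digital read counts or ``"tpm"`` for
    transcripts per million; in TPM mode every column sums to 1e6 within
    relative tolerance 1e-6.  ``gene_meta`` must carry ``length_bp``
    (positive integer) and ``is_core`` (boolean: present in all individuals
    of the pan-genome, as opposed to dispensable genes).
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "tpm"):
            raise ValidationError(f"unknown expression mode: {self.mode!r}")
        _check_unique(self.values.index, "gene ids", "ExpressionMatrix")
        _check_unique(self.values.columns, "sample ids", "ExpressionMatrix")
        for col in ("length_bp", "is_core"):
            if col not in self.gene_meta.columns:
                raise ValidationError(f"gene metadata lacks column '{col}'")
        if not self.values.index.equals(self.gene_meta.index):
            absent = set(self.values.index) - set(self.gene_meta.index)
            if absent:
                raise ValidationError(f"genes without metadata: {sorted(absent)}")
            self.gene_meta = self.gene_meta.loc[self.values.index]
        lengths = self.gene_meta["length_bp"].astype(float)
        if (lengths <= 0).any():
            bad = self.gene_meta.index[lengths <= 0][0]
            raise ValidationError(f"non-positive length_bp for gene '{bad}'")
        vals = self.values.to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            g, s = np.argwhere((vals < 0) | ~np.isfinite(vals))[0]
            raise ValidationError(
                f"invalid expression value {vals[g, s]} for gene "
                f"'{self.values.index[g]}', sample '{self.values.columns[s]}'"
            )
        if self.mode == "tpm":
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                s = int(np.argmax(np.abs(sums - 1e6)))
                raise ValidationError(
                    f"TPM column '{self.values.columns[s]}' sums to {sums[s]}, "
                    "expected 1e6"
                )
        self.values = self.values.astype(float)
        self.gene_meta = self.gene_meta.assign(
            length_bp=self.gene_meta["length_bp"].astype(int),
            is_core=self.gene_meta["is_core"].astype(bool),
        )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    text = str(x).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {x!r}")


def read_expression_matrix(path, gene_meta_path, mode="counts") -> ExpressionMatrix:
    """Read a genes x samples matrix plus gene metadata (length_bp, is_core)."""
    path = Path(path)
    values = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    values.index = values.index.astype(str)
    gene_meta_path = Path(gene_meta_path)
    meta = pd.read_csv(gene_meta_path, sep=_sniff_delimiter(gene_meta_path))
    if "gene_id" not in meta.columns:
        raise FormatError(f"{gene_meta_path}: missing 'gene_id' column")
    meta = meta.set_index("gene_id")
    meta.index = meta.index.astype(str)
    if "is_core" in meta.columns:
        meta["is_core"] = [_parse_bool(v) for v in meta["is_core"]]
    return ExpressionMatrix(values, meta, mode=mode)


def write_expression_matrix(m: ExpressionMatrix, path, gene_meta_path=None) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    if gene_meta_path is not None:
        meta = m.gene_meta[["length_bp", "is_core"]].copy()
        meta.index.name = "gene_id"
        meta.to_csv(gene_meta_path, sep="\t")


@dataclass
class DilutionSeries:
    """A cDNA dilution series: log10 dilution (0 = undiluted) vs mean Ct."""

    log10_dilution: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.log10_dilution = np.asarray(self.log10_dilution, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.log10_dilution.shape != self.ct.shape:
            raise ValidationError("dilution and Ct lists differ in length")
        if self.log10_dilution.size < 3:
            raise ValidationError("a dilution series needs at least 3 points")
        diffs = np.diff(self.log10_dilution)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValidationError(
                "log10 dilutions must be strictly monotonic and distinct"
            )

    def __len__(self) -> int:
        return int(self.log10_dilution.size)


def read_dilution_series(path) -> DilutionSeries:
    """Read a two-column (log10_dilution, ct) table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    for col in ("log10_dilution", "ct"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing '{col}' column")
    return DilutionSeries(df["log10_dilution"].to_numpy(), df["ct"].to_numpy())


def write_dilution_series(d: DilutionSeries, path) -> None:
    pd.DataFrame({"log10_dilution": d.log10_dilution, "ct": d.ct}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


@dataclass
class StabilityRanking:
    """Per-gene stability score and rank from one algorithm.

    ``scores`` and ``ranks`` are gene-indexed Series; rank 1 is the most
    stable gene.  ``extras`` holds algorithm-specific results (M
    trajectory, V series, variance components, descriptive statistics) and
    is serialized to a structured sidecar next to the ranking table.
    """

    algorithm: str
    scores: pd.Series
    ranks: pd.Series
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if not self.scores.index.equals(self.ranks.index):
            self.ranks = self.ranks.reindex(self.scores.index)
        if self.scores.size:
            ranks = sorted(self.ranks)
            if ranks != list(range(1, self.scores.size + 1)):
                raise ValidationError("ranks must be a permutation of 1..n_genes")
        self.ranks = self.ranks.astype(int)

    def ordered_genes(self) -> list:
        """Genes from most to least stable."""
        return list(self.ranks.sort_values().index)


def _to_plain(obj):
    """Recursively convert pandas/numpy objects into YAML-safe builtins."""
    if isinstance(obj, pd.Series):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): _to_plain(obj[c]) for c in obj.columns}
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".meta.yaml")


def write_ranking(r: StabilityRanking, path) -> None:
    """Write a ranking as TSV (gene, score, rank, algorithm) + YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "gene": r.scores.index,
            "score": r.scores.to_numpy(),
            "rank": r.ranks.to_numpy(),
            "algorithm": r.algorithm,
        }
    ).sort_values("rank")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"algorithm": r.algorithm, "extras": _to_plain(r.extras)},
            fh,
            sort_keys=False,
        )


def read_ranking(path) -> StabilityRanking:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    extras: dict = {}
    algorithm = df["algorithm"].iloc[0] if len(df) else ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        extras = doc.get("extras", {})
        algorithm = doc.get("algorithm", algorithm)
    scores = pd.Series(df["score"].to_numpy(), index=pd.Index(df["gene"]), dtype=float)
    ranks = pd.Series(df["rank"].to_numpy(), index=pd.Index(df["gene"]))
    return StabilityRanking(algorithm, scores, ranks, extras)
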