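"""Expression-matrix containers, annotation tables and the pre-analysis normalizations.

The pipeline operates on gene-by-sample matrices of log2-scale expression
values. Two normalizations are applied before any modelling: quantile
normalization across samples (so every array shares one empirical
distribution) and per-gene standardization to mean 0 / sd 1 (so PCA loadings
are comparable across genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import stats_core

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "SampleAnnotation",
    "DEGTable",
    "read_expression_table",
    "read_annotation_table",
    "quantile_normalize",
    "standardize_genes",
    "differential_expression",
]


class Scale(str, Enum):
    """Processing state of an expression matrix."""

    RAW_LOG2 = "raw_log2"
    QUANTILE_NORMALIZED = "quantile_normalized"
    GENE_STANDARDIZED = "gene_standardized"


DISEASE_CLASSES = ("normal", "primary", "metastatic")

#: survival endpoints carried by annotation tables
ENDPOINTS = ("os", "rfs")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id. All entries finite.
    scale : Scale
        Processing state tag; analyses check it instead of guessing.
    """

    values: pd.DataFrame
    scale: Scale = Scale.RAW_LOG2

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes], self.scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.values[samples], self.scale)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample class labels, clinical covariates and survival endpoints.

    ``table`` is indexed by sample id and always carries ``disease_class``
    (one of normal / primary / metastatic) plus optional ``cohort``,
    ``os_time``/``os_event``, ``rfs_time``/``rfs_event`` and free-form
    categorical covariate columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "disease_class" not in df.columns:
            raise ValueError("annotation requires a disease_class column")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")
        bad = set(df["disease_class"].dropna()) - set(DISEASE_CLASSES)
        if bad:
            raise ValueError(f"unknown disease_class values: {sorted(bad)}")
        for ep in ENDPOINTS:
            t, e = f"{ep}_time", f"{ep}_event"
            if e in df.columns:
                orphan = df[e].notna() & (t not in df.columns or df[t].isna())
                if np.any(orphan):
                    raise ValueError(f"{e} present without {t} for some samples")
            if t in df.columns:
                times = pd.to_numeric(df[t], errors="coerce")
                if (times.dropna() < 0).any():
                    raise ValueError(f"negative {t} values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def classes(self) -> pd.Series:
        return self.table["disease_class"]

    def samples_of(self, *disease_classes: str) -> list[str]:
        mask = self.table["disease_class"].isin(disease_classes)
        return list(self.table.index[mask])

    def subset(self, samples: Iterable[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(samples)])

    def survival(self, endpoint: str = "os") -> pd.DataFrame:
        """Return (time, event) rows for samples with the endpoint observed."""
        if endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        t, e = f"{endpoint}_time", f"{endpoint}_event"
        if t not in self.table.columns:
            raise ValueError(f"annotation lacks {t}")
        sub = self.table[[t, e]].dropna()
        sub = sub.rename(columns={t: "time", e: "event"})
        return sub.astype(float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class DEGTable:
    """Differential-expression results: one row per gene.

    Columns: gene_id (index), log2fc, p_value, p_adj, direction
    ('up' iff log2fc > 0, else 'down').
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"log2fc", "p_value", "direction"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in DEG table")
        lfc = df["log2fc"].to_numpy(float)
        direction = df["direction"].to_numpy()
        want = np.where(lfc > 0, "up", "down")
        if not (direction == want).all():
            raise ValueError("direction inconsistent with sign of log2fc")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def directions(self) -> pd.Series:
        return self.table["direction"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DEGTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
        return cls(df)


# ---------------------------------------------------------------------------
# I/O


def read_expression_table(
    path: str | Path,
    sep: str = "\t",
    duplicate_gene_rule: str = "max_mean",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a genes-x-samples expression TSV/CSV.

    The first column holds gene ids; the header row holds sample ids.
    Duplicate gene rows are collapsed by ``duplicate_gene_rule``
    (``"max_mean"`` keeps the row with the highest mean expression, the
    common microarray probe-collapse rule; ``"error"`` rejects).
    Missing cells are rejected unless ``impute_missing`` is set, in which
    case they are filled with the gene's row mean.
    """
    # pandas mangles duplicate header names (a, a.1, ...), so check the raw line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_header = header[1:]
    if len(set(sample_header)) != len(sample_header):
        dups = sorted({s for s in sample_header if sample_header.count(s) > 1})
        raise ValueError(f"duplicate sample id(s) in header: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    df.index.name = None
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric values in sample column(s): {non_numeric}")
    if df.isna().any().any():
        if impute_missing:
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            r = df.index[df.isna().any(axis=1)][0]
            c = df.columns[df.loc[r].isna()][0]
            raise ValueError(f"missing value at gene {r!r}, sample {c!r}")
    if df.index.has_duplicates:
        if duplicate_gene_rule == "max_mean":
            means = df.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="stable")
            keep = ~df.index[order].duplicated()
            chosen = df.iloc[order[keep]]
            # restore first-occurrence order from the file
            first_order = df.index[~df.index.duplicated()]
            df = chosen.loc[first_order]
        else:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dups}")
    return ExpressionMatrix(df.astype(float), Scale.RAW_LOG2)


def read_annotation_table(path: str | Path, sep: str = "\t") -> SampleAnnotation:
    df = pd.read_csv(path, sep=sep, index_col="sample_id", na_values=["NA"])
    return SampleAnnotation(df)


# ---------------------------------------------------------------------------
# Normalizations


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the per-rank cross-sample mean distribution.

    After normalization all columns share one multiset of values. Ties within
    a column receive the mean of the reference values across the ranks the
    tie spans (average-rank convention).
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    arr = m.values.to_numpy(float)
    ref = np.sort(arr, axis=0).mean(axis=1)  # per-rank cross-sample means
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        mapped = ref[ranks]
        # average reference values over tied ranks
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=mapped)
            counts = np.bincount(inv)
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, Scale.QUANTILE_NORMALIZED)


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene row (mean 0, sample sd 1, n-1 denominator).

    Constant rows are undefined under z-scoring and are dropped with a
    warning; downstream PCA would gain nothing from an all-zero row.
    """
    if m.n_samples < 2:
        raise ValueError("standardization needs >= 2 samples")
    arr = m.values.to_numpy(float)
    sd = arr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(m.values.index[constant])
        warnings.warn(f"dropping {len(dropped)} constant gene(s): {dropped}")
        arr = arr[~constant]
    kept_index = m.values.index[~constant]
    mean = arr.mean(axis=1, keepdims=True)
    z = (arr - mean) / arr.std(axis=1, ddof=1, keepdims=True)
    df = pd.DataFrame(z, index=kept_index, columns=m.values.columns)
    return ExpressionMatrix(df, Scale.GENE_STANDARDIZED)


# ---------------------------------------------------------------------------
# Differential expression


def differential_expression(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    group_a: str,
    group_b: str,
) -> DEGTable:
    """Per-gene Welch t contrast of two disease classes.

    log2fc = mean(group_b) - mean(group_a) (values are log2 scale, so the
    difference of means is the log fold change). P-values from Welch's
    two-sample t with Benjamini-Hochberg adjustment. Genes where both groups
    are constant get a missing p-value but still report their log2fc.
    """
    sa = ann.samples_of(group_a)
    sb = ann.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = m.values[sa].to_numpy(float)
    b = m.values[sb].to_numpy(float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    pvals = np.full(m.n_genes, np.nan)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    for i in range(m.n_genes):
        if va[i] == 0 or vb[i] == 0:
            continue  # p stays missing; log2fc still reported
        pvals[i] = stats_core.welch_t(a[i], b[i]).p_value
    ok = ~np.isnan(pvals)
    padj = np.full_like(pvals, np.nan)
    if ok.any():
        padj[ok] = stats_core.bh_adjust(list(pvals[ok]))
    df = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=m.values.index,
    )
    return DEGTable(df)
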