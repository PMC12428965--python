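"""Count matrices, sample sheets and normalisation.

The pipeline starts from gene-by-sample tables of integer read counts, one
table per sequencing fraction (``total`` RNA or the ``polysome``-bound
fraction).  Samples are annotated in a sample sheet with condition, fraction
and replicate structure; technical repeats (resequencing of one library) are
collapsed by summation before any modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

CONDITIONS = ("Control", "Hardening", "Stress", "Combo")
FRACTIONS = ("total", "polysome")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "condition",
    "fraction",
    "biological_replicate",
    "technical_replicate",
)


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample table for one fraction."""

    counts: pd.DataFrame
    fraction: str = "mixed"

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if self.fraction not in FRACTIONS + ("mixed",):
            raise ValueError(f"unknown fraction tag: {self.fraction!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormalizedMatrix:
    """Real-valued expression table; ``scale`` records the unit.

    ``cpm`` columns sum to one million; ``log2cpm`` is log2(CPM + pseudocount);
    ``tpm`` is accepted as externally supplied length-normalised input.
    """

    values: pd.DataFrame
    scale: str = "cpm"

    _SCALES = ("cpm", "log2cpm", "tpm")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown scale tag: {self.scale!r}")
        if self.scale == "cpm":
            totals = self.values.sum(axis=0)
            if not np.allclose(totals, 1e6, rtol=1e-6):
                raise ValueError("cpm columns must each sum to 1e6")

    @property
    def is_log(self) -> bool:
        return self.scale == "log2cpm"


def read_counts(path: str | Path, fraction: str = "mixed") -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None or df.columns.empty:
        raise ValueError(f"{path}: malformed header (need gene-id column + samples)")
    for col in df.columns:
        column = df[col]
        numeric = pd.to_numeric(column, errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0)
        if bad.any():
            row = column.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-integer cell at gene {row!r}, sample {col!r}"
            )
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df, fraction=fraction)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_sheet(ss)


def validate_sample_sheet(ss: pd.DataFrame) -> pd.DataFrame:
    missing = set(SAMPLE_SHEET_COLUMNS) - set(ss.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    ss = ss.copy()
    ss["sample_id"] = ss["sample_id"].astype(str)
    if ss["sample_id"].duplicated().any():
        dup = ss.loc[ss["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in sheet: {dup!r}")
    bad_cond = set(ss["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    bad_frac = set(ss["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise ValueError(f"unknown fractions: {sorted(bad_frac)}")
    key = ss[["condition", "fraction", "biological_replicate", "technical_replicate"]]
    if key.duplicated().any():
        raise ValueError("(condition, fraction, replicate) keys are not unique")
    return ss


def write_sample_sheet(ss: pd.DataFrame, path: str | Path) -> None:
    ss.to_csv(path, sep="\t", index=False)


def collapse_technical_replicates(
    cm: CountMatrix, ss: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sum technical repeats into one column per biological library.

    Returns the collapsed matrix plus a matching sample sheet (one row per
    biological library, ``technical_replicate`` fixed at 1).  Collapsed sample
    ids follow ``{condition}_{fraction}_b{replicate}``.
    """
    ann = ss.set_index("sample_id")
    unannotated = [s for s in cm.sample_ids if s not in ann.index]
    if unannotated:
        raise ValueError(f"samples not in sample sheet: {unannotated}")

    groups: dict[str, list[str]] = {}
    meta: dict[str, tuple] = {}
    for s in cm.sample_ids:
        cond, frac, bio = (
            ann.at[s, "condition"],
            ann.at[s, "fraction"],
            int(ann.at[s, "biological_replicate"]),
        )
        new_id = f"{cond}_{frac}_b{bio}"
        groups.setdefault(new_id, []).append(s)
        meta[new_id] = (cond, frac, bio)

    collapsed = pd.DataFrame(
        {new_id: cm.counts[cols].sum(axis=1) for new_id, cols in groups.items()}
    )
    new_ss = pd.DataFrame(
        {
            "sample_id": list(groups),
            "condition": [meta[k][0] for k in groups],
            "fraction": [meta[k][1] for k in groups],
            "biological_replicate": [meta[k][2] for k in groups],
            "technical_replicate": 1,
        }
    )
    return CountMatrix(collapsed, fraction=cm.fraction), validate_sample_sheet(new_ss)


def cpm_normalize(
    cm: CountMatrix, log: bool = False, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Counts-per-million; optionally log2(CPM + pseudocount)."""
    totals = cm.library_sizes
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero column(s): {list(zero.index)}")
    cpm = cm.counts / totals.to_numpy() * 1e6
    if log:
        return NormalizedMatrix(np.log2(cpm + pseudocount), scale="log2cpm")
    return NormalizedMatrix(cpm, scale="cpm")


def filter_low_expression(
    cm: CountMatrix, min_count: int = 10, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with >= min_count reads in >= min_samples samples."""
    if min_count < 0 or min_samples < 0:
        raise ValueError("thresholds must be nonnegative")
    keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep], fraction=cm.fraction)


def pca_overview(
    nm: NormalizedMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centred log expression.

    Returns sample coordinates (samples x PCs) and the explained-variance
    fractions of the retained components.
    """
    if not nm.is_log:
        raise ValueError("pca_overview expects log-scale values (scale='log2cpm')")
    n_samples = nm.values.shape[1]
    if n_components > n_samples:
        raise ValueError(
            f"n_components={n_components} exceeds number of samples ({n_samples})"
        )
    # samples as observations, genes as features; PCA centres features
    X = nm.values.to_numpy().T
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    table = pd.DataFrame(
        coords,
        index=nm.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return table, pca.explained_variance_ratio_
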