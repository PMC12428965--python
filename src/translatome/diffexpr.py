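"""Negative-binomial differential expression between two sample groups.

Dispersion is estimated by a pooled method-of-moments estimator on
library-size-adjusted counts, shrunk toward the experiment-wide common value,
and the two-group comparison is a likelihood-ratio test of equal NB rates
with library-size offsets.  Genes are classified Up / Down / Stable at
|log2FC| = 1 with a raw p-value cutoff of 0.05; genes beyond the fold-change
threshold that fail the cutoff are labelled Unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._nb import nb_loglik, nb_mean_mle
from .io import CountMatrix

CLASS_LABELS = ("Up", "Down", "Stable", "Unclassified")


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions after shrinkage toward the common value."""

    phi_gene: pd.Series
    phi_common: float
    prior_weight: float
    single_sample_fallback: bool = False

    def reindex(self, gene_ids: Sequence[str]) -> np.ndarray:
        return self.phi_gene.reindex(gene_ids).to_numpy()


def estimate_dispersions(
    cm: CountMatrix,
    groups: Mapping[str, str] | pd.Series,
    prior_weight: float = 10.0,
) -> DispersionEstimates:
    """Moment dispersion estimates pooled across groups, with shrinkage.

    Counts are first rescaled to a common library size (mean of column
    totals).  Per gene and group, phi_hat = (s^2 - m) / m^2; group estimates
    are pooled with residual-degree-of-freedom weights, and the per-gene
    value is shrunk toward the across-gene common value with ``prior_weight``
    pseudo-degrees of freedom.  Deterministic.
    """
    groups = pd.Series(groups)
    missing = [s for s in cm.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    groups = groups.reindex(cm.sample_ids)

    counts = cm.counts.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("all-zero sample column")
    adjusted = counts * (libsize.mean() / libsize)[None, :]

    raw_num = np.zeros(counts.shape[0])
    total_df = 0.0
    fallback = False
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        if len(cols) < 2:
            fallback = True
            continue
        sub = adjusted[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        raw_num += df * phi_g
        total_df += df

    if total_df == 0:
        # no replicated group at all: nothing estimable, fall back to zero
        raw = np.zeros(counts.shape[0])
        fallback = True
    else:
        raw = raw_num / total_df
    phi_common = float(max(np.mean(raw), 0.0)) if len(raw) else 0.0
    shrunk = (prior_weight * phi_common + total_df * raw) / (prior_weight + max(total_df, 1e-12))
    shrunk = np.maximum(shrunk, 0.0)
    return DispersionEstimates(
        phi_gene=pd.Series(shrunk, index=cm.gene_ids),
        phi_common=phi_common,
        prior_weight=prior_weight,
        single_sample_fallback=fallback,
    )


def test_differential(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    disp: DispersionEstimates | None = None,
    lfc_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """NB likelihood-ratio test of equal rates, B over A.

    Returns a per-gene table with ``logFC`` (log2 of the offset-corrected
    group-B / group-A mean ratio, stabilised by ``lfc_pseudocount`` added to
    each group mean), ``PValue``, ``FDR`` (Benjamini-Hochberg) and
    ``all_zero`` flag.  Genes with no counts in either group get p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    for s in group_a + group_b:
        if s not in cm.counts.columns:
            raise ValueError(f"unknown sample: {s!r}")
    if disp is None:
        labels = pd.Series(
            ["A"] * len(group_a) + ["B"] * len(group_b), index=group_a + group_b
        )
        sub = CountMatrix(cm.counts[group_a + group_b], fraction=cm.fraction)
        disp = estimate_dispersions(sub, labels)

    counts = cm.counts
    ya = counts[group_a].to_numpy(dtype=float)
    yb = counts[group_b].to_numpy(dtype=float)
    na = counts[group_a].sum(axis=0).to_numpy(dtype=float)
    nb = counts[group_b].sum(axis=0).to_numpy(dtype=float)
    phi = np.nan_to_num(disp.reindex(cm.gene_ids), nan=disp.phi_common)

    _, ll_a = nb_mean_mle(ya, na, phi)
    _, ll_b = nb_mean_mle(yb, nb, phi)
    _, ll_0 = nb_mean_mle(np.hstack([ya, yb]), np.hstack([na, nb]), phi)
    stat = np.maximum(2.0 * (ll_a + ll_b - ll_0), 0.0)
    pvalue = chi2.sf(stat, df=1)

    # offset-corrected group means on a common per-library scale
    scale = np.hstack([na, nb]).mean()
    mean_a = (ya * (scale / na)[None, :]).mean(axis=1)
    mean_b = (yb * (scale / nb)[None, :]).mean(axis=1)
    logfc = np.log2((mean_b + lfc_pseudocount) / (mean_a + lfc_pseudocount))

    all_zero = (ya.sum(axis=1) == 0) & (yb.sum(axis=1) == 0)
    pvalue = np.where(all_zero, 1.0, pvalue)
    logfc = np.where(all_zero, 0.0, logfc)

    fdr = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "PValue": pvalue,
            "FDR": fdr,
            "all_zero": all_zero,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    return multipletests(pvalues, method="fdr_bh")[1]


def classify_genes(
    de: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    lfc_column: str = "logFC",
) -> pd.DataFrame:
    """Attach Up / Down / Stable / Unclassified labels.

    Up: logFC > threshold and p < alpha.  Down: logFC < -threshold and
    p < alpha.  Stable: |logFC| <= threshold.  The remainder (large fold
    change, insignificant p) is Unclassified.
    """
    lfc = de[lfc_column].to_numpy()
    p = de["PValue"].to_numpy()
    label = np.full(len(de), "Unclassified", dtype=object)
    label[np.abs(lfc) <= lfc_threshold] = "Stable"
    label[(lfc > lfc_threshold) & (p < alpha)] = "Up"
    label[(lfc < -lfc_threshold) & (p < alpha)] = "Down"
    out = de.copy()
    out["class"] = label
    return out


def write_de_result(de: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("logFC", "deltaTR", "PValue", "FDR", "class") if c in de.columns]
    de[cols].to_csv(path, sep="\t", float_format="%.6g")
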