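"""Translational-ratio statistics for paired total/polysome experiments.

The per-unit translational ratio of a gene is

    TR = log2((polysome abundance + c) / (total abundance + c))

computed on the CPM scale with pseudocount c (default 0.5), and differential
translation between two units is the difference of ratios,
deltaTR = TR_i - TR_j.  A model-based test of differential translation fits,
per gene, an NB regression with mean structure
fraction + condition + fraction:condition on the raw paired counts; the
interaction coefficient is the model estimate of deltaTR and its
likelihood-ratio p-value is the significance of translational (as opposed to
transcriptional) regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._nb import nb_glm_irls, nb_mean_mle
from .diffexpr import DispersionEstimates, bh_adjust, classify_genes, estimate_dispersions
from .io import CountMatrix, NormalizedMatrix

LN2 = float(np.log(2.0))


@dataclass
class TRMatrix:
    """Per-gene translational ratios (log2 polysome/total) by unit."""

    values: pd.DataFrame  # genes x units
    mode: str = "ratio"  # "ratio" (TR) or "efficiency" (TE, CDS-based input)
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("ratio", "efficiency"):
            raise ValueError(f"unknown TR mode: {self.mode!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite translational ratios")


def _unit_means(
    nm: NormalizedMatrix, ss: pd.DataFrame, fraction: str, per: str
) -> pd.DataFrame:
    """Average CPM columns of one fraction into per-condition (or keep
    per-replicate) units; unit names are shared between fractions."""
    ann = ss.set_index("sample_id")
    cols = [
        s
        for s in nm.values.columns
        if s in ann.index and ann.at[s, "fraction"] == fraction
    ]
    if not cols:
        raise ValueError(f"no {fraction!r} samples in matrix")
    if per == "condition":
        units: dict[str, list[str]] = {}
        for s in cols:
            units.setdefault(str(ann.at[s, "condition"]), []).append(s)
        return pd.DataFrame(
            {u: nm.values[group].mean(axis=1) for u, group in units.items()}
        )
    if per == "replicate":
        renamed = {}
        for s in cols:
            unit = f"{ann.at[s, 'condition']}_b{int(ann.at[s, 'biological_replicate'])}"
            if unit in renamed:
                raise ValueError(
                    f"multiple {fraction} samples map to unit {unit!r}; "
                    "collapse technical replicates first"
                )
            renamed[unit] = nm.values[s]
        return pd.DataFrame(renamed)
    raise ValueError(f"per must be 'condition' or 'replicate', got {per!r}")


def translational_ratio(
    total_nm: NormalizedMatrix,
    poly_nm: NormalizedMatrix,
    ss: pd.DataFrame,
    pseudocount: float = 0.5,
    per: str = "condition",
) -> TRMatrix:
    """TR = log2((poly CPM + c) / (total CPM + c)) per unit.

    Units are conditions (mean CPM across replicates, default) or paired
    biological replicates (``per='replicate'``).  Total and polysome matrices
    must cover the same genes and pair unit-for-unit via the sample sheet.
    """
    if total_nm.is_log or poly_nm.is_log:
        raise ValueError("translational_ratio expects linear-scale (cpm/tpm) input")
    if not total_nm.values.index.equals(poly_nm.values.index):
        raise ValueError("total and polysome matrices have different gene universes")
    total_u = _unit_means(total_nm, ss, "total", per)
    poly_u = _unit_means(poly_nm, ss, "polysome", per)
    orphans = sorted(set(total_u.columns) ^ set(poly_u.columns))
    if orphans:
        raise ValueError(f"unpairable units between fractions: {orphans}")
    poly_u = poly_u[total_u.columns]
    tr = np.log2((poly_u + pseudocount) / (total_u + pseudocount))
    return TRMatrix(tr, mode="ratio", pseudocount=pseudocount)


def delta_tr(tr: TRMatrix, unit_i: str, unit_j: str) -> pd.DataFrame:
    """Per-gene deltaTR = TR(unit_i) - TR(unit_j); antisymmetric in (i, j)."""
    for u in (unit_i, unit_j):
        if u not in tr.values.columns:
            raise ValueError(f"unknown unit: {u!r}")
    out = pd.DataFrame(
        {"deltaTR": tr.values[unit_i] - tr.values[unit_j]},
        index=tr.values.index,
    )
    out.index.name = "gene_id"
    return out


def test_differential_translation(
    total_cm: CountMatrix,
    poly_cm: CountMatrix,
    ss: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    disp: DispersionEstimates | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Interaction test of translational regulation, condition B vs A.

    Fits per gene the NB model with log-mean
    ``intercept + fraction + condition + fraction:condition`` (library-size
    offsets) and tests the interaction by likelihood ratio (alternative:
    saturated four-cell means; null: additive three-parameter model; 1 df).
    ``deltaTR`` is the interaction coefficient in log2 units; classification
    follows the Up/Down/Stable rule applied to deltaTR.
    """
    ann = ss.set_index("sample_id")

    def fraction_cols(cm: CountMatrix, frac: str, cond: str) -> list[str]:
        return [
            s
            for s in cm.sample_ids
            if s in ann.index
            and ann.at[s, "fraction"] == frac
            and ann.at[s, "condition"] == cond
        ]

    cells = {}
    for cond in (condition_a, condition_b):
        for frac, cm in (("total", total_cm), ("polysome", poly_cm)):
            cols = fraction_cols(cm, frac, cond)
            if not cols:
                raise ValueError(f"no {frac!r} samples for condition {cond!r}")
            cells[(cond, frac)] = cols
    if not total_cm.counts.index.equals(poly_cm.counts.index):
        raise ValueError("total and polysome matrices have different gene universes")
    genes = total_cm.gene_ids

    # assemble counts and offsets; library sizes come from each full matrix
    blocks, libs, frac_ind, cond_ind = [], [], [], []
    for (cond, frac), cols in cells.items():
        cm = total_cm if frac == "total" else poly_cm
        blocks.append(cm.counts[cols].to_numpy(dtype=float))
        libs.append(cm.counts[cols].sum(axis=0).to_numpy(dtype=float))
        frac_ind += [1.0 if frac == "polysome" else 0.0] * len(cols)
        cond_ind += [1.0 if cond == condition_b else 0.0] * len(cols)
    y = np.hstack(blocks)
    libsize = np.hstack(libs)
    frac_ind, cond_ind = np.asarray(frac_ind), np.asarray(cond_ind)

    if disp is None:
        labels = []
        sheet_cols = []
        for (cond, frac), cols in cells.items():
            labels += [f"{cond}:{frac}"] * len(cols)
            sheet_cols += [f"{cond}:{frac}:{i}" for i in range(len(cols))]
        joint = CountMatrix(
            pd.DataFrame(y.astype(np.int64), index=genes, columns=sheet_cols)
        )
        disp = estimate_dispersions(joint, pd.Series(labels, index=sheet_cols))
    phi = np.nan_to_num(disp.reindex(genes), nan=disp.phi_common)

    # alternative: independent rate per cell (saturated in the 2x2 design)
    ll_alt = np.zeros(len(genes))
    rates = {}
    for (cond, frac), cols in cells.items():
        cm = total_cm if frac == "total" else poly_cm
        yc = cm.counts[cols].to_numpy(dtype=float)
        nc = cm.counts[cols].sum(axis=0).to_numpy(dtype=float)
        r, ll = nb_mean_mle(yc, nc, phi)
        rates[(cond, frac)] = r
        ll_alt += ll

    # null: additive model fraction + condition
    X0 = np.column_stack([np.ones_like(frac_ind), frac_ind, cond_ind])
    _, ll_null = nb_glm_irls(y, X0, libsize, phi)

    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    pvalue = chi2.sf(stat, df=1)

    # interaction estimate in log2 units, stabilised against zero cells
    eps = 0.5 / libsize.mean()
    dtr = np.log2(
        ((rates[(condition_b, "polysome")] + eps) * (rates[(condition_a, "total")] + eps))
        / ((rates[(condition_b, "total")] + eps) * (rates[(condition_a, "polysome")] + eps))
    )

    all_zero = y.sum(axis=1) == 0
    pvalue = np.where(all_zero, 1.0, pvalue)
    dtr = np.where(all_zero, 0.0, dtr)

    table = pd.DataFrame(
        {
            "deltaTR": dtr,
            "PValue": pvalue,
            "FDR": bh_adjust(pvalue),
            "all_zero": all_zero,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return classify_genes(table, lfc_threshold, alpha, lfc_column="deltaTR")


def tr_normalize_million(tr: TRMatrix) -> NormalizedMatrix:
    """Map ratios to the linear scale (2^TR) and rescale columns to 1e6.

    Log-ratios can be negative and cannot meaningfully sum to one million,
    so the per-million renormalisation applied before translational
    co-expression analysis operates on 2^TR.
    """
    if tr.mode != "ratio":
        raise ValueError("tr_normalize_million requires ratio-mode input")
    linear = np.exp2(tr.values)
    totals = linear.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("column with non-positive total on the linear scale")
    return NormalizedMatrix(linear / totals * 1e6, scale="cpm")
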