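"""Weighted gene co-expression analysis (WGCNA-style), self-contained.

Pipeline: Pearson correlation of gene profiles -> soft-thresholded adjacency
(unsigned |r|^beta by default, beta picked by scale-free topology fit) ->
topological overlap matrix (TOM) -> average-linkage clustering of 1 - TOM
with a static height cut -> module eigengenes (first principal component of
the standardised module expression) -> module-trait correlations and hub
genes ranked by kME.  Everything is deterministic: there is no random
initialisation anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

# fixed label list; "grey" is reserved for unassigned genes
MODULE_COLOURS = (
    "peachpuff",
    "lightgrey",
    "darksalmon",
    "gainsboro",
    "darkgrey",
    "coral",
    "brown",
    "saddlebrown",
    "turquoise",
    "blue",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
    "lightgreen",
    "lightyellow",
    "royalblue",
    "darkred",
    "darkgreen",
    "darkturquoise",
    "orange",
    "darkorange",
    "skyblue",
    "steelblue",
    "violet",
    "plum",
    "sienna",
    "orchid",
    "ivory",
    "honeydew",
    "lavender",
)
GREY = "grey"


def _gene_values(nm) -> pd.DataFrame:
    """Accept a NormalizedMatrix or a bare genes x samples DataFrame."""
    return nm.values if hasattr(nm, "values") and hasattr(nm, "scale") else nm


def _drop_constant(values: pd.DataFrame, action: str = "warn") -> pd.DataFrame:
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        if action == "error":
            raise ValueError(
                f"zero-variance genes present (e.g. {values.index[constant][0]!r}); "
                "filter before network construction"
            )
        warnings.warn(f"dropping {int(constant.sum())} constant gene(s)")
        values = values.loc[~constant]
    return values


def pick_soft_threshold(
    nm,
    candidate_powers=range(1, 21),
    target_r2: float = 0.8,
    sign_mode: str = "unsigned",
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
) -> tuple[int, pd.DataFrame, bool]:
    """Choose the soft power by the scale-free topology criterion.

    For each candidate power the connectivities k_i = sum_j a_ij are binned
    (10 bins); the signed fit is R^2 of log10(frequency) on log10(mean k)
    negated when the slope is positive.  When the mean connectivity drops
    below ``min_mean_connectivity`` the network is essentially empty — any
    degree distribution then looks heavy-tailed — so the fit is reported as
    0 for that power.  Returns the smallest power whose fit reaches
    ``target_r2``; if none does, the best-fit power together with a low-fit
    warning flag (third return value True).
    """
    values = _drop_constant(_gene_values(nm))
    cor = np.corrcoef(values.to_numpy())
    rows = []
    for beta in candidate_powers:
        if sign_mode == "unsigned":
            a = np.abs(cor) ** beta
        else:
            a = ((1.0 + cor) / 2.0) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        mean_k = k.mean()
        fit = _scale_free_fit(k, n_bins) if mean_k >= min_mean_connectivity else 0.0
        rows.append({"power": beta, "fit": fit, "mean_k": mean_k, "max_k": k.max()})
    table = pd.DataFrame(rows)
    passing = table[table["fit"] >= target_r2]
    if len(passing):
        return int(passing["power"].iloc[0]), table, False
    best = int(table.loc[table["fit"].idxmax(), "power"])
    warnings.warn(
        f"no power reaches scale-free fit {target_r2}; returning best fit "
        f"(power {best})"
    )
    return best, table, True


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the log-log degree distribution (negative slope required)."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / len(k)))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * r2)


def adjacency(nm, beta: float, sign_mode: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency with unit diagonal.

    unsigned: a_ij = |cor|^beta; signed: a_ij = ((1 + cor)/2)^beta.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    values = _drop_constant(_gene_values(nm), action="error")
    cor = np.corrcoef(values.to_numpy())
    cor = np.clip(cor, -1.0, 1.0)
    if sign_mode == "unsigned":
        a = np.abs(cor) ** beta
    elif sign_mode == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError(f"unknown sign_mode: {sign_mode!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=values.index, columns=values.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), unit diagonal,
    with l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu."""
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleAssignment:
    """gene -> module-colour mapping; 'grey' marks unassigned genes."""

    labels: pd.Series

    @property
    def module_names(self) -> list[str]:
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_height`` x (maximum merge height); clusters
    smaller than ``min_module_size`` become 'grey'.  Colour labels are
    assigned to the remaining clusters by decreasing size (ties broken by
    first gene position), so the partition is order-invariant up to names.
    """
    genes = tom.index
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; everything is grey")
        return ModuleAssignment(pd.Series(GREY, index=genes))
    dis = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2.0
    Z = linkage(squareform(dis, checks=False), method="average")
    height = cut_height * Z[:, 2].max()
    raw = fcluster(Z, t=height, criterion="distance")

    sizes: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for pos, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first_pos.setdefault(c, pos)
    keep = [c for c in sizes if sizes[c] >= min_module_size]
    keep.sort(key=lambda c: (-sizes[c], first_pos[c]))
    if len(keep) > len(MODULE_COLOURS):
        keep = keep[: len(MODULE_COLOURS)]
    colour_of = {c: MODULE_COLOURS[i] for i, c in enumerate(keep)}
    labels = pd.Series([colour_of.get(c, GREY) for c in raw], index=genes)
    return ModuleAssignment(labels)


def module_eigengene(nm, ma: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardised expression.

    Rows are modules (grey excluded), columns samples; each eigengene has
    unit norm and nonnegative correlation with the module's mean
    standardised profile.
    """
    values = _gene_values(nm)
    eigengenes = {}
    for module in ma.module_names:
        sub = values.loc[ma.members(module)].to_numpy(dtype=float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        if z.shape[0] == 1:
            e = z[0] / np.linalg.norm(z[0])
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            e = vt[0]
        reference = z.mean(axis=0)
        if np.dot(e, reference) < 0:
            e = -e
        eigengenes[module] = e
    return pd.DataFrame(eigengenes, index=values.columns).T


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (module, trait) pair.

    p comes from the t-transform t = r sqrt(n-2) / sqrt(1-r^2) with n-2
    degrees of freedom; |r| = 1 gives p = 0; a constant trait gives NaN.
    """
    common = [s for s in eigengenes.columns if s in traits.index]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for module in eigengenes.index:
        e = eigengenes.loc[module, common].to_numpy(dtype=float)
        for trait in traits.columns:
            x = traits.loc[common, trait].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(e) == 0:
                r, p = np.nan, np.nan
            else:
                r = float(np.corrcoef(e, x)[0, 1])
                p = correlation_pvalue(r, len(common))
            rows.append(
                {"module": module, "trait": trait, "r": r, "p_value": p,
                 "n_samples": len(common)}
            )
    return pd.DataFrame(rows)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t-transform (df = n-2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


def hub_genes(
    nm, ma: ModuleAssignment, eigengenes: pd.DataFrame, top_n: int = 10
) -> pd.DataFrame:
    """Top-n genes per module by kME (correlation with the eigengene).

    Ties in kME are broken by gene id for determinism.
    """
    values = _gene_values(nm)
    rows = []
    for module in eigengenes.index:
        e = eigengenes.loc[module].to_numpy(dtype=float)
        members = ma.members(module)
        sub = values.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        centred = sub - sub.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = sd * len(e) * ec.std(ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            kme = np.where(denom > 0, centred @ ec / np.maximum(denom, 1e-300), 0.0)
        order = sorted(range(len(members)), key=lambda i: (-kme[i], members[i]))
        for rank, i in enumerate(order[:top_n], start=1):
            rows.append(
                {"module": module, "gene_id": members[i], "kME": float(kme[i]),
                 "rank": rank}
            )
    return pd.DataFrame(rows)
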