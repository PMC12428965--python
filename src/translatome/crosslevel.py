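"""Comparison of transcriptional vs translational module partitions.

Every non-grey module pair is scored by its Jaccard index on the shared gene
universe and by a one-sided hypergeometric overlap test; pairs with
Jaccard >= 5% and BH-adjusted p < 0.05 are reported as related.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .network import GREY, ModuleAssignment


def module_overlap(
    ma_transcription: ModuleAssignment,
    ma_translation: ModuleAssignment,
    threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Module x module overlap table across the two regulatory levels.

    Restricted to the intersection of the two gene universes; grey
    (unassigned) genes are excluded from pairing.  Returns one row per
    (transcription module, translation module) pair with overlap count,
    Jaccard, hypergeometric p (upper tail), BH FDR across all pairs, and the
    ``related`` flag (jaccard >= threshold AND fdr < alpha).
    """
    universe = ma_transcription.labels.index.intersection(ma_translation.labels.index)
    if len(universe) == 0:
        raise ValueError("empty common gene universe")
    lab1 = ma_transcription.labels.loc[universe]
    lab2 = ma_translation.labels.loc[universe]
    modules1 = [m for m in lab1.value_counts().index if m != GREY]
    modules2 = [m for m in lab2.value_counts().index if m != GREY]

    M = len(universe)
    rows = []
    for m1 in modules1:
        set1 = set(lab1.index[lab1 == m1])
        for m2 in modules2:
            set2 = set(lab2.index[lab2 == m2])
            overlap = len(set1 & set2)
            union = len(set1 | set2)
            jac = overlap / union if union else 0.0
            p = float(hypergeom.sf(overlap - 1, M, len(set1), len(set2)))
            rows.append(
                {
                    "module_transcription": m1,
                    "module_translation": m2,
                    "size_transcription": len(set1),
                    "size_translation": len(set2),
                    "overlap": overlap,
                    "universe": M,
                    "jaccard": jac,
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
        table["related"] = (table["jaccard"] >= threshold) & (table["fdr"] < alpha)
    return table
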