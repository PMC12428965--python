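"""Gene-set comparison: exclusive (UpSet-style) intersections, Jaccard
matrices and the stable core shared by every comparison."""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd


def upset_intersections(sets: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive-region decomposition of a set collection.

    One row per non-empty combination of sets, boolean membership columns
    plus ``size`` = number of elements belonging to exactly that combination.
    Region sizes partition the union.  Rows sorted by size descending, then
    by membership pattern for determinism.
    """
    if not sets:
        raise ValueError("need at least one set")
    names = list(sets)
    regions: dict[tuple[bool, ...], int] = {}
    universe = set().union(*sets.values())
    for element in universe:
        key = tuple(element in sets[n] for n in names)
        regions[key] = regions.get(key, 0) + 1
    rows = [dict(zip(names, key), size=count) for key, count in regions.items()]
    table = pd.DataFrame(rows, columns=names + ["size"])
    table = table.sort_values(
        ["size"] + names, ascending=[False] + [False] * len(names)
    ).reset_index(drop=True)
    return table


def jaccard_matrix(sets: Mapping[str, set]) -> pd.DataFrame:
    """Pairwise Jaccard indices |A&B| / |A|B| as a symmetric matrix.

    Two empty sets get J = 0 (with a warning); a non-empty set has J = 1
    with itself.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    J = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            union = sets[a] | sets[b]
            if not union:
                warnings.warn(f"Jaccard of two empty sets ({a!r}, {b!r}) set to 0")
                value = 0.0
            else:
                value = len(sets[a] & sets[b]) / len(union)
            J.loc[a, b] = J.loc[b, a] = value
    return J


def stable_core(stable_sets: Iterable[set]) -> set:
    """Genes Stable in every comparison: the intersection of all Stable sets."""
    stable_sets = list(stable_sets)
    if len(stable_sets) < 2:
        raise ValueError("need at least two comparisons")
    core = set(stable_sets[0])
    for s in stable_sets[1:]:
        core &= s
    return core


def comparison_name(cond_b: str, cond_a: str, fraction: str | None = None) -> str:
    """Build 'X_vs_Y' labels, with the '_T' suffix for transcriptional sets."""
    if fraction == "total":
        return f"{cond_b}_T_vs_{cond_a}_T"
    return f"{cond_b}_vs_{cond_a}"
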