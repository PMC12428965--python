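"""Over/under-representation analysis against a GMT annotation.

Hypergeometric tails with Benjamini-Hochberg correction per direction;
terms are filtered BEFORE testing by maximum term size (annotated genes in
the universe, default <= 250) and minimum query-term overlap (default >= 10).
Runs entirely offline on a user-supplied annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


@dataclass
class AnnotationDB:
    """term_id -> (name, member gene set); member sets are non-empty."""

    terms: dict[str, tuple[str, set]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term_id: str) -> set:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


def read_gmt(path: str | Path) -> AnnotationDB:
    """Read a GMT file: term_id <TAB> description <TAB> members..."""
    terms: dict[str, tuple[str, set]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line with < 3 fields")
            term_id, description = fields[0], fields[1]
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (description, set(fields[2:]))
    return AnnotationDB(terms)


def write_gmt(db: AnnotationDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term_id, (name, members) in db.terms.items():
            handle.write("\t".join([term_id, name] + sorted(members)) + "\n")


def enrich(
    query: Iterable,
    db: AnnotationDB,
    universe: Iterable,
    term_size_max: int = 250,
    intersection_min: int = 10,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of ``query`` in each term.

    Term membership is intersected with ``universe`` first.  Terms with more
    than ``term_size_max`` annotated genes or fewer than ``intersection_min``
    query genes in the term are excluded before testing.  p_over is the upper
    hypergeometric tail P(X >= overlap), p_under the lower tail
    P(X <= overlap); FDR is computed per direction across surviving terms.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")

    rows = []
    for term_id, (name, members) in db.terms.items():
        term = members & universe
        overlap = len(term & query)
        if len(term) == 0 or len(term) > term_size_max or overlap < intersection_min:
            continue
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "overlap": overlap,
                "term_size": len(term),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_over": float(
                    hypergeom.sf(overlap - 1, len(universe), len(term), len(query))
                ),
                "p_under": float(
                    hypergeom.cdf(overlap, len(universe), len(term), len(query))
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "overlap", "term_size", "query_size",
                "universe_size", "direction", "p_value", "fdr",
            ]
        )
    wide = pd.DataFrame(rows)
    long_rows = []
    for direction in ("over", "under"):
        part = wide[
            ["term_id", "term_name", "overlap", "term_size", "query_size",
             "universe_size"]
        ].copy()
        part["direction"] = direction
        part["p_value"] = wide[f"p_{direction}"]
        part["fdr"] = bh_adjust(part["p_value"].to_numpy())
        long_rows.append(part)
    out = pd.concat(long_rows, ignore_index=True)
    return out.sort_values(["direction", "p_value", "term_id"]).reset_index(drop=True)
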