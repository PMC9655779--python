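"""Hypergeometric over-representation of gene lists in gene-set collections.

Given a query list (typically the DEGs of one stratum) and a flat
collection of gene sets (GO-style terms, read from GMT), each term is
scored with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term size, n the query size and k
the overlap.  The universe defaults to the genes actually tested for
differential expression in the corresponding stratum, not the whole
genome.  Only over-representation (upper tail) is tested; no GO-DAG
propagation is performed -- collections are taken as given flat sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError
from .io import read_gmt

__all__ = [
    "GeneSetCollection",
    "hypergeom_enrich",
    "top_terms",
    "load_collection",
]


@dataclass
class GeneSetCollection:
    """Flat gene-set collection: term_id -> (term_name, genes) plus a universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        if not self.terms:
            raise ValidationError("collection has no terms")
        clipped = {}
        for tid, (name, genes) in self.terms.items():
            genes = frozenset(genes) & self.universe
            if not genes:
                raise ValidationError(
                    f"term {tid!r} has no genes inside the universe"
                )
            clipped[tid] = (name, genes)
        self.terms = clipped


def load_collection(gmt_path, universe) -> GeneSetCollection:
    """Read a GMT file, restricting terms to the given universe.

    Terms that lose all genes on intersection are dropped with a
    warning rather than failing the run.
    """
    raw = read_gmt(gmt_path)
    universe = frozenset(universe)
    kept = {
        tid: (name, genes)
        for tid, (name, genes) in raw.items()
        if genes & universe
    }
    dropped = sorted(set(raw) - set(kept))
    if dropped:
        warnings.warn(
            f"{len(dropped)} term(s) outside the universe dropped", stacklevel=2
        )
    return GeneSetCollection(terms=kept, universe=universe)


def hypergeom_enrich(query, coll: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query set against every term.

    Query genes outside the universe are dropped with a warning.
    Returns one row per term: k (overlap), K (term size), n (query
    size), N (universe size), p and BH-adjusted p, sorted by p_adj
    then p then term_id.
    """
    query = set(query)
    outside = query - coll.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    query &= coll.universe
    if not query:
        raise ValidationError("query is empty after universe intersection")
    N, n = len(coll.universe), len(query)
    rows = []
    for tid, (name, genes) in coll.terms.items():
        K = len(genes)
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": tid, "term_name": name, "k": k, "K": K, "n": n,
             "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(
        ["p_adj", "p", "term_id"], kind="mergesort", ignore_index=True
    )


def top_terms(t: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k smallest-p_adj terms; ties broken by larger overlap, then id."""
    if t.empty:
        raise ValidationError("enrichment table is empty")
    ranked = t.sort_values(
        ["p_adj", "k", "term_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ranked.head(k).reset_index(drop=True)


def hypergeom_enumeration_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of draws; oracle for small N.

    Enumerates all C(N, n) draws of the query from an urn with K
    marked genes and counts those with at least k marked.  Test
    helper only -- factorially slow beyond N ~ 15.
    """
    import itertools

    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total
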