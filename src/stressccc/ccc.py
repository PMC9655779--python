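"""Ligand-receptor cell-cell communication inference from upregulated DEGs.

The core rule: given, for each cell type, the set of genes upregulated
versus control in a stratum, and a curated reference of interacting
(ligand, receptor) gene pairs (the CellTalkDB dialect: a TSV with
``ligand_gene_symbol`` and ``receptor_gene_symbol`` columns), an edge

    source_type --(ligand, receptor)--> target_type

is called whenever the ligand is upregulated in the source type, the
receptor is upregulated in the target type, and the (ligand, receptor)
pair occurs in the reference.  Autocrine edges (source == target) are
allowed.  The method is presence/absence: no expression-magnitude
weighting and no per-edge permutation p-value.  An empty edge list is
a valid outcome, not an error.

Genes upregulated in *any* sub-cluster of a cell type count for that
type (the union rule); symbols are matched case-sensitively after
whitespace stripping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "LRReference",
    "InteractionEdge",
    "NetworkSummary",
    "load_lr_reference",
    "write_lr_reference",
    "infer_interactions",
    "unique_pairs",
    "network_summary",
    "run_ccc",
]

LIGAND_COL = "ligand_gene_symbol"
RECEPTOR_COL = "receptor_gene_symbol"


@dataclass(frozen=True)
class LRReference:
    """Curated set of interacting (ligand, receptor) gene-symbol pairs."""

    pairs: frozenset[tuple[str, str]]
    source_tag: str = "unspecified"

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValidationError("empty gene symbol in LR reference")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.pairs)

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(r for _, r in self.pairs)


class InteractionEdge(NamedTuple):
    source_type: str
    ligand: str
    target_type: str
    receptor: str


@dataclass
class NetworkSummary:
    """Tabular summaries of an inferred communication network."""

    pair_counts: dict[tuple[str, str], int]
    unique_pair_count: int
    out_degree: dict[str, int]  # per ligand gene
    in_degree: dict[str, int]  # per receptor gene
    n_edges: int
    adjacency: pd.DataFrame = field(repr=False, default=None)


def load_lr_reference(path, source_tag: str | None = None) -> LRReference:
    """Read a ligand-receptor TSV, matching columns by header name.

    Accepts the CellTalkDB column names (``ligand_gene_symbol``,
    ``receptor_gene_symbol``) or the short forms ``ligand`` /
    ``receptor``.  Duplicate rows are collapsed; symbols are
    whitespace-stripped but case is preserved.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip(): c for c in df.columns}
    lig = cols.get(LIGAND_COL) or cols.get("ligand")
    rec = cols.get(RECEPTOR_COL) or cols.get("receptor")
    if lig is None or rec is None:
        raise FormatError(
            f"LR reference must have {LIGAND_COL}/{RECEPTOR_COL} "
            f"(or ligand/receptor) columns; found {list(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"LR reference {path} has no rows")
    pairs = {
        (str(l).strip(), str(r).strip()) for l, r in zip(df[lig], df[rec])
    }
    return LRReference(
        pairs=frozenset(pairs), source_tag=source_tag or str(path)
    )


def write_lr_reference(path, ref: LRReference) -> None:
    df = pd.DataFrame(
        sorted(ref.pairs), columns=[LIGAND_COL, RECEPTOR_COL]
    )
    df.to_csv(path, sep="\t", index=False)


def infer_interactions(
    up_by_type: dict[str, set[str]], ref: LRReference
) -> list[InteractionEdge]:
    """All (source, ligand, target, receptor) combinations backed by the
    reference.

    Exactly the set {(x, L, y, R) : L in up(x), R in up(y), (L, R) in
    ref}; autocrine (x == y) edges included.  Output sorted by
    (source, target, ligand, receptor) so it is invariant to input
    ordering.
    """
    if not up_by_type:
        raise ValidationError("up_by_type is empty")
    cleaned = {
        t: {str(g).strip() for g in genes} for t, genes in up_by_type.items()
    }
    edges = []
    for lig, rec in ref.pairs:
        sources = [t for t, genes in cleaned.items() if lig in genes]
        targets = [t for t, genes in cleaned.items() if rec in genes]
        for s in sources:
            for t in targets:
                edges.append(InteractionEdge(s, lig, t, rec))
    edges.sort(key=lambda e: (e.source_type, e.target_type, e.ligand, e.receptor))
    return edges


def unique_pairs(edges) -> tuple[int, list[tuple[str, str]]]:
    """Distinct (ligand, receptor) pairs across all edges."""
    pairs = sorted({(e.ligand, e.receptor) for e in edges})
    return len(pairs), pairs


def network_summary(edges) -> NetworkSummary:
    """Edge counts per (source, target) cell-type pair plus gene degrees.

    ``adjacency`` is a cell-type x cell-type count matrix ready for
    circos-style export; the (ligand out-) and (receptor in-) degree
    tallies count edge incidences per gene node.
    """
    edges = list(edges)
    pair_counts = Counter((e.source_type, e.target_type) for e in edges)
    out_deg = Counter(e.ligand for e in edges)
    in_deg = Counter(e.receptor for e in edges)
    types = sorted(
        {e.source_type for e in edges} | {e.target_type for e in edges}
    )
    adj = pd.DataFrame(0, index=types, columns=types, dtype=int)
    for (s, t), c in pair_counts.items():
        adj.loc[s, t] = c
    return NetworkSummary(
        pair_counts=dict(pair_counts),
        unique_pair_count=unique_pairs(edges)[0],
        out_degree=dict(out_deg),
        in_degree=dict(in_deg),
        n_edges=len(edges),
        adjacency=adj,
    )


def edges_to_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(
        edges, columns=["source_type", "ligand", "target_type", "receptor"]
    )


def edges_to_graph(edges) -> nx.MultiDiGraph:
    """Gene-level directed multigraph (ligand -> receptor), annotated with
    the expressing cell types; mirrors the directed-graph figure export."""
    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(
            e.ligand, e.receptor, source_type=e.source_type,
            target_type=e.target_type,
        )
    return g


def upregulated_by_type(
    filtered_tables: dict, cell_type_of=None
) -> dict[str, set[str]]:
    """Union of upregulated genes (avg_logfc > 0) per cell type.

    ``filtered_tables`` maps a cluster key to a *filtered* DEG table;
    ``cell_type_of`` maps that key to its parent cell type (identity
    by default), implementing the sub-cluster union rule.
    """
    up: dict[str, set[str]] = {}
    for key, table in filtered_tables.items():
        ctype = cell_type_of(key) if cell_type_of else str(key)
        genes = set(table.loc[table["avg_logfc"] > 0, "gene"])
        up.setdefault(ctype, set()).update(genes)
    return up


def run_ccc(
    de_tables: dict,
    ref: LRReference,
    stratum: tuple[str, str],
    cell_type_of=None,
) -> tuple[list[InteractionEdge], NetworkSummary]:
    """End-to-end inference for one (group, region) stratum.

    ``de_tables`` maps stratum -> {cluster key -> filtered DEG table}.
    Upregulated genes are pooled per cell type (union over
    sub-clusters), fed to :func:`infer_interactions`, and summarized.
    An empty network is a valid result.
    """
    if stratum not in de_tables:
        raise ValidationError(
            f"stratum {stratum!r} absent from DE tables "
            f"(have {sorted(de_tables)})"
        )
    up = upregulated_by_type(de_tables[stratum], cell_type_of=cell_type_of)
    if not up:
        return [], network_summary([])
    edges = infer_interactions(up, ref)
    return edges, network_summary(edges)
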