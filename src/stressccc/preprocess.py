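"""Quality control, normalization and descriptive statistics for count matrices.

The pipeline ingests gene x cell unique-molecule counts with per-cell
metadata (mouse, experimental group, hippocampal region, hemisphere,
cell type / cluster label).  Cells are kept when their mitochondrial
read fraction is below 15% and their detected-feature count lies in
[200, 2500] (bounds inclusive); kept cells are log-normalized as
``ln(1 + count / cell_total * 10_000)``.  Clustering itself is an
upstream input -- labels arrive with the metadata -- but marker
dot-plot statistics and hypergeometric signature annotation of given
clusters are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import ValidationError
from .io import CELL_META_COLUMNS

__all__ = [
    "CellMatrix",
    "NormMatrix",
    "MarkerPanel",
    "qc_filter",
    "lognormalize",
    "select_hvg",
    "pool_hemispheres",
    "dot_stats",
    "annotate_clusters",
]


@dataclass
class MarkerPanel:
    """A named set of marker gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"marker panel {self.name!r} is empty")


@dataclass
class CellMatrix:
    """Sparse gene x cell integer counts plus per-cell metadata.

    ``counts`` rows follow ``gene_ids``; ``cell_meta`` is indexed by
    barcode, aligned with the matrix columns, and carries at least
    mouse, group, region, hemisphere and cell_type.
    """

    counts: sparse.csr_matrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = list(map(str, self.gene_ids))
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids length does not match matrix rows")
        if self.counts.shape[1] != len(self.cell_meta):
            raise ValidationError("cell_meta rows do not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene symbols must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.counts.nnz and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise ValidationError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> list[str]:
        return self.cell_meta.index.tolist()

    def subset_cells(self, mask) -> "CellMatrix":
        mask = np.asarray(mask)
        return CellMatrix(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.loc[mask]
            if mask.dtype == bool
            else self.cell_meta.iloc[mask],
        )

    def to_anndata(self):
        """Bridge to an AnnData object (cells x genes), if anndata is installed."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class NormMatrix:
    """Log-normalized expression: ``ln(1 + count / cell_total * scale)``.

    Keeps the per-cell raw totals so normalization is exactly
    invertible: ``count = expm1(value) * cell_total / scale``.
    """

    values: sparse.csr_matrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    cell_totals: np.ndarray
    scale: float = 10_000.0
    source_hash: str | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self, gene_subset=None) -> np.ndarray:
        if gene_subset is None:
            return np.asarray(self.values.todense())
        idx = [self.gene_ids.index(g) for g in gene_subset]
        return np.asarray(self.values[idx].todense())


def _mito_mask(gene_ids, prefix: str) -> np.ndarray:
    return np.array([g.startswith(prefix) for g in gene_ids])


def qc_filter(
    m: CellMatrix,
    mito_max: float = 0.15,
    min_features: int = 200,
    max_features: int = 2500,
    mito_prefix: str = "mt-",
) -> tuple[CellMatrix, pd.DataFrame]:
    """Filter cells on mitochondrial fraction and detected-feature count.

    Keeps cells with mito fraction strictly below ``mito_max`` and a
    detected-feature count in ``[min_features, max_features]``
    (inclusive on both ends).  Returns the filtered matrix and a
    per-cell QC report with the measured values and pass/fail flags.
    The operation is idempotent.
    """
    counts = m.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    n_feat = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = _mito_mask(m.gene_ids, mito_prefix)
    if mito.any():
        mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        pass_mito = mito_frac < mito_max
    else:
        if mito_max < 1:
            warnings.warn(
                f"no genes with prefix {mito_prefix!r}: mito criterion skipped",
                stacklevel=2,
            )
        mito_frac = np.zeros(m.n_cells)
        pass_mito = np.ones(m.n_cells, dtype=bool)
    pass_feat = (n_feat >= min_features) & (n_feat <= max_features)
    keep = pass_mito & pass_feat
    report = pd.DataFrame(
        {
            "total_counts": totals,
            "n_features": n_feat,
            "mito_frac": mito_frac,
            "pass_mito": pass_mito,
            "pass_features": pass_feat,
            "kept": keep,
        },
        index=m.cell_meta.index,
    )
    return m.subset_cells(keep), report


def lognormalize(m: CellMatrix, scale: float = 10_000.0) -> NormMatrix:
    """Library-size normalize to ``scale`` counts per cell, then log1p."""
    if m.n_cells == 0:
        raise ValidationError(
            "matrix has no cells (did QC remove everything?)"
        )
    counts = m.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = [m.barcodes[i] for i in np.nonzero(totals == 0)[0][:5]]
        raise ValidationError(f"cell(s) with zero total counts: {bad}")
    vals = counts.multiply(scale / totals[None, :]).tocsr()
    vals.data = np.log1p(vals.data)
    return NormMatrix(
        values=vals,
        gene_ids=list(m.gene_ids),
        cell_meta=m.cell_meta.copy(),
        cell_totals=totals,
        scale=float(scale),
    )


def invert_lognormalize(n: NormMatrix) -> sparse.csr_matrix:
    """Recover the raw counts from a NormMatrix (round-trip check)."""
    vals = n.values.copy().astype(float)
    vals.data = np.expm1(vals.data)
    return vals.multiply(n.cell_totals[None, :] / n.scale).tocsr()


def select_hvg(n: NormMatrix, n_top: int = 2000, n_bins: int = 20) -> list[str]:
    """Top highly-variable genes by binned standardized dispersion.

    Genes are binned into ``n_bins`` quantile bins of mean log
    expression; within each bin the log-value variance is z-scored, and
    genes are ranked by that z.  Ties break lexicographically on gene
    symbol so the output is invariant to input gene order.
    """
    if n_top > n.n_genes:
        raise ValidationError(
            f"n_top={n_top} exceeds the {n.n_genes}-gene universe"
        )
    vals = n.values
    mean = np.asarray(vals.mean(axis=1)).ravel()
    sq = vals.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    # quantile bins on mean expression; duplicate edges merged
    ranks = pd.Series(mean).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, n.n_genes), labels=False, duplicates="drop")
    z = np.zeros_like(var)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = var[sel].mean(), var[sel].std()
        z[sel] = (var[sel] - mu) / sd if sd > 0 else 0.0
    order = sorted(range(n.n_genes), key=lambda i: (-z[i], n.gene_ids[i]))
    return [n.gene_ids[i] for i in order[:n_top]]


def pool_hemispheres(samples: list[CellMatrix]) -> CellMatrix:
    """Concatenate per-hemisphere samples into one matrix per (mouse, region).

    Gene universes must match as sets; inputs are aligned by symbol
    before pooling.  Hemisphere stays in the metadata; colliding
    barcodes get a per-sample suffix.
    """
    if not samples:
        raise ValidationError("no samples to pool")
    ref_genes = sorted(samples[0].gene_ids)
    mats, metas = [], []
    seen: set[str] = set()
    for i, s in enumerate(samples):
        if sorted(s.gene_ids) != ref_genes:
            raise ValidationError("samples have mismatched gene universes")
        order = np.argsort(s.gene_ids)
        mats.append(s.counts[order])
        meta = s.cell_meta.copy()
        if seen & set(meta.index):
            meta.index = [f"{b}-{i}" for b in meta.index]
        seen |= set(meta.index)
        metas.append(meta)
    return CellMatrix(
        counts=sparse.hstack(mats).tocsr(),
        gene_ids=sorted(samples[0].gene_ids),
        cell_meta=pd.concat(metas),
    )


def dot_stats(
    n: NormMatrix, labels, panel: MarkerPanel
) -> pd.DataFrame:
    """Per (cluster, gene) dot-plot statistics for a marker panel.

    ``pct`` is the fraction of the cluster's cells with nonzero
    normalized expression; ``mean`` is the mean log-normalized value
    over all cells in the cluster.  Panel genes absent from the matrix
    are reported with a ``missing`` flag rather than failing.
    """
    labels = np.asarray(labels)
    if labels.size != n.n_cells:
        raise ValidationError("labels length does not match cell count")
    present = [g for g in sorted(panel.genes) if g in n.gene_ids]
    missing = sorted(panel.genes - set(present))
    if missing:
        warnings.warn(f"panel genes absent from matrix: {missing}", stacklevel=2)
    rows = []
    dense = n.dense(present) if present else np.empty((0, n.n_cells))
    for cl in np.unique(labels):
        sel = labels == cl
        if not sel.any():
            raise ValidationError(f"empty cluster {cl!r}")
        sub = dense[:, sel]
        for gi, g in enumerate(present):
            rows.append(
                {
                    "cluster": cl,
                    "gene": g,
                    "pct": float((sub[gi] > 0).mean()),
                    "mean": float(sub[gi].mean()),
                    "missing": False,
                }
            )
        for g in missing:
            rows.append(
                {"cluster": cl, "gene": g, "pct": 0.0, "mean": 0.0, "missing": True}
            )
    return pd.DataFrame(rows)


def annotate_clusters(
    n: NormMatrix,
    labels,
    signatures: dict[str, set[str]],
    n_markers: int = 10,
) -> pd.DataFrame:
    """Assign a cell type to each cluster by signature overlap of its markers.

    Each cluster's top ``n_markers`` one-vs-rest marker genes (rank-sum
    upregulation, smallest p first) are scored against every signature
    with a hypergeometric upper tail over the matrix's gene universe;
    the smallest-p signature wins.  Clusters whose best and second-best
    p are within a factor of 10 are flagged ambiguous; clusters whose
    markers overlap no signature are labeled ``unknown``.
    """
    from .diffexpr import ranksum_de

    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("need at least 2 clusters to rank markers")
    if not signatures or any(not s for s in signatures.values()):
        raise ValidationError("signatures must be non-empty")
    N = n.n_genes
    universe = set(n.gene_ids)
    rows = []
    for cl in clusters:
        sel = labels == cl
        table = ranksum_de(n, np.nonzero(sel)[0], np.nonzero(~sel)[0])
        up = table[table["avg_logfc"] > 0].sort_values(
            ["p", "avg_logfc"], ascending=[True, False], kind="mergesort"
        )
        markers = up["gene"].head(n_markers).tolist()
        if len(markers) < n_markers:
            warnings.warn(
                f"cluster {cl!r}: only {len(markers)} rankable markers",
                stacklevel=2,
            )
        best = []
        for name, sig in signatures.items():
            sig_in = set(sig) & universe
            k = len(set(markers) & sig_in)
            p = float(
                stats.hypergeom.sf(k - 1, N, len(sig_in), len(markers))
            ) if k > 0 else 1.0
            best.append((p, name, k))
        best.sort()
        p1, name1, k1 = best[0]
        ambiguous = len(best) > 1 and best[1][0] <= 10 * p1
        if k1 == 0:
            name1, ambiguous = "unknown", False
        rows.append(
            {
                "cluster": cl,
                "cell_type": name1,
                "p": p1,
                "overlap": k1,
                "markers": ";".join(markers),
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame(rows)
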