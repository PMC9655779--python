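"""Wilcoxon rank-sum differential expression for log-normalized counts.

Conventions follow the widely used single-cell toolkit defaults this
study relied on: genes are pre-filtered to those expressed (nonzero) in
at least ``min_pct`` of either group; the reported fold change is

    avg_logfc = ln(mean(expm1 x) + 1) - ln(mean(expm1 y) + 1)

over the test (x) and reference (y) cells, i.e. a natural-log fold
change of pseudocounted mean expression; p-values come from the
two-sided Wilcoxon rank-sum (Mann-Whitney) test, corrected for
multiplicity with Benjamini-Hochberg.  A gene is called differentially
expressed when |avg_logfc| > 0.25 and adjusted p < 0.05 (both strict).

Small tie-free groups (both sides <= ``exact_max_n``) use the exact
permutation distribution of the rank-sum statistic; everything else
uses the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import itertools
from math import log

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .preprocess import MarkerPanel, NormMatrix

__all__ = [
    "ranksum_de",
    "bh_adjust",
    "filter_degs",
    "pooled_de",
    "deg_count_matrix",
    "delta_pct",
    "panel_fold_changes",
]

LN2 = log(2.0)


def _cells_to_index(cells, n_cells: int) -> np.ndarray:
    idx = np.asarray(cells)
    if idx.dtype == bool:
        if idx.size != n_cells:
            raise ValidationError("boolean cell mask has wrong length")
        idx = np.nonzero(idx)[0]
    return idx.astype(int)


def _avg_logfc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.log(np.expm1(x).mean(axis=1) + 1.0) - np.log(
        np.expm1(y).mean(axis=1) + 1.0
    )


def _ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int) -> np.ndarray:
    """Two-sided rank-sum p per gene row of x (g x n1) vs y (g x n2)."""
    n1, n2 = x.shape[1], y.shape[1]
    flat = (np.ptp(x, axis=1) == 0) & (np.ptp(y, axis=1) == 0) & (
        x[:, 0] == y[:, 0]
    )
    p = np.ones(x.shape[0])
    if max(n1, n2) <= exact_max_n:
        for g in np.nonzero(~flat)[0]:
            combined = np.concatenate([x[g], y[g]])
            method = "exact" if np.unique(combined).size == combined.size else (
                "asymptotic"
            )
            p[g] = stats.mannwhitneyu(
                x[g], y[g], alternative="two-sided", method=method
            ).pvalue
    else:
        live = ~flat
        if live.any():
            res = stats.mannwhitneyu(
                x[live], y[live], alternative="two-sided",
                method="asymptotic", use_continuity=True, axis=1,
            )
            p[live] = np.atleast_1d(res.pvalue)
    return np.clip(p, 0.0, 1.0)


def ranksum_de(
    n: NormMatrix,
    cells_test,
    cells_ref,
    min_pct: float = 0.1,
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two disjoint cell sets.

    Returns a table with gene, avg_logfc (natural log), p, p_adj (BH
    over the tested genes), pct_1 and pct_2.  Genes expressed in fewer
    than ``min_pct`` of *both* sets are excluded before testing.
    """
    it = _cells_to_index(cells_test, n.n_cells)
    ir = _cells_to_index(cells_ref, n.n_cells)
    if it.size == 0 or ir.size == 0:
        raise ValidationError("both cell sets must be non-empty")
    if np.intersect1d(it, ir).size:
        raise ValidationError("test and reference cell sets overlap")
    X = np.asarray(n.values[:, it].todense())
    Y = np.asarray(n.values[:, ir].todense())
    pct1 = (X > 0).mean(axis=1)
    pct2 = (Y > 0).mean(axis=1)
    keep = (pct1 >= min_pct) | (pct2 >= min_pct)
    if not keep.any():
        return pd.DataFrame(
            columns=["gene", "avg_logfc", "p", "p_adj", "pct_1", "pct_2"]
        )
    X, Y = X[keep], Y[keep]
    genes = [g for g, k in zip(n.gene_ids, keep) if k]
    logfc = _avg_logfc(X, Y)
    p = _ranksum_p(X, Y, exact_max_n)
    return pd.DataFrame(
        {
            "gene": genes,
            "avg_logfc": logfc,
            "p": p,
            "p_adj": bh_adjust(p),
            "pct_1": pct1[keep],
            "pct_2": pct2[keep],
        }
    )


def ranksum_exact_oracle(x, y) -> float:
    """Brute-force two-sided rank-sum p by enumerating all labelings.

    Exact reference for small tie-free samples; enumerates every
    C(n1+n2, n1) assignment of the pooled values to the test group and
    counts rank sums at least as extreme (two-sided, by distance from
    the mean rank sum) as observed.  Test helper, not a pipeline path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    obs = ranks[:n1].sum()
    mu = n1 * (pooled.size + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(pooled.size), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    t: pd.DataFrame, lfc_min: float = 0.25, alpha: float = 0.05
) -> pd.DataFrame:
    """Rows with |avg_logfc| > lfc_min and p_adj < alpha (both strict)."""
    if "p_adj" not in t.columns:
        raise ValidationError("table lacks p_adj; run bh_adjust first")
    return t[(t["avg_logfc"].abs() > lfc_min) & (t["p_adj"] < alpha)].copy()


def pooled_de(
    n: NormMatrix,
    group: str,
    region: str,
    control_group: str = "control",
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """DE of one (group, region) stratum vs the control stratum, all cell
    types pooled -- the "mimic a bulk RNA-seq" comparison."""
    meta = n.cell_meta
    test = (meta["group"] == group) & (meta["region"] == region)
    ref = (meta["group"] == control_group) & (meta["region"] == region)
    if not test.any():
        raise ValidationError(f"no cells in stratum ({group}, {region})")
    if not ref.any():
        raise ValidationError(f"no control cells in region {region!r}")
    out = ranksum_de(n, test.to_numpy(), ref.to_numpy(), min_pct=min_pct)
    out["comparison"] = f"{group}_vs_{control_group}"
    out["region"] = region
    return out


def deg_count_matrix(tables, expected_grid=None) -> pd.DataFrame:
    """Count filtered DEGs per (cell_type, region, comparison) stratum.

    ``tables`` maps stratum keys to *filtered* DEG tables (or is an
    iterable of (key, table) pairs; duplicate keys are an error).
    Strata listed in ``expected_grid`` but absent from ``tables`` are
    reported as 0 with ``missing=True``.
    """
    items = list(tables.items()) if hasattr(tables, "items") else list(tables)
    seen = {}
    for key, table in items:
        if key in seen:
            raise ValidationError(f"duplicated stratum {key!r}")
        seen[key] = len(table)
    rows = []
    grid = list(seen) + [k for k in (expected_grid or []) if k not in seen]
    for key in grid:
        cell_type, region, comparison = key
        rows.append(
            {
                "cell_type": cell_type,
                "region": region,
                "comparison": comparison,
                "n_degs": seen.get(key, 0),
                "missing": key not in seen,
            }
        )
    return pd.DataFrame(rows)


def delta_pct(
    n: NormMatrix, cells_test, cells_ref, panel: MarkerPanel
) -> pd.DataFrame:
    """Difference in expressing-cell fraction (test minus reference) per
    panel gene; genes absent from the matrix are flagged missing."""
    it = _cells_to_index(cells_test, n.n_cells)
    ir = _cells_to_index(cells_ref, n.n_cells)
    if it.size == 0 or ir.size == 0:
        raise ValidationError("both cell sets must be non-empty")
    index = {g: i for i, g in enumerate(n.gene_ids)}
    rows = []
    for g in sorted(panel.genes):
        if g not in index:
            rows.append(
                {"gene": g, "pct_test": np.nan, "pct_ref": np.nan,
                 "delta_pct": np.nan, "missing": True}
            )
            continue
        row = n.values[index[g]]
        pt = float((np.asarray(row[:, it].todense()) > 0).mean())
        pr = float((np.asarray(row[:, ir].todense()) > 0).mean())
        rows.append(
            {"gene": g, "pct_test": pt, "pct_ref": pr,
             "delta_pct": pt - pr, "missing": False}
        )
    return pd.DataFrame(rows)


def panel_fold_changes(
    tables, panel: MarkerPanel, lfc_min: float = 0.25, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cluster log2 fold changes for a marker panel (dot-plot data).

    ``tables`` maps cluster label -> DEG table (with p_adj).  The
    natural-log avg_logfc is converted to log2 for display; the
    significance flag applies the standard DEG filter.  Genes absent
    from a cluster's table contribute no dot there.
    """
    items = list(tables.items()) if hasattr(tables, "items") else list(tables)
    rows = []
    for cluster, table in items:
        sub = table[table["gene"].isin(panel.genes)]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "cluster": cluster,
                    "gene": r["gene"],
                    "log2fc": r["avg_logfc"] / LN2,
                    "significant": bool(
                        abs(r["avg_logfc"]) > lfc_min and r["p_adj"] < alpha
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "significant"])
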