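"""QC filtering, log-normalization, HVG selection, pooling and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from stressccc.errors import ValidationError
from stressccc.io import read_mtx_triplet, write_mtx_triplet
from stressccc.preprocess import (
    CellMatrix,
    MarkerPanel,
    annotate_clusters,
    dot_stats,
    invert_lognormalize,
    lognormalize,
    pool_hemispheres,
    qc_filter,
    select_hvg,
)
from stressccc.simulate import default_count_spec, generate_counts

from conftest import make_cell_matrix


def qc_fixture():
    """10 cells over 2600 genes with one planted violation per criterion.

    Cell 0: 20% mitochondrial counts.  Cell 1: 150 detected features
    (< 200).  Cell 2: 2600 detected features (> 2500).  Cells 3-9 are
    healthy, including cell 3 at exactly 200 features (boundary kept).
    """
    n_genes = 2600
    genes = [f"mt-{i}" if i < 13 else f"g{i}" for i in range(n_genes)]
    dense = np.zeros((n_genes, 10), dtype=int)
    dense[13:413, 0] = 1  # 400 non-mito counts
    dense[0, 0] = 100  # 100 mito counts -> 20% mito, 401 features
    dense[13:163, 1] = 2  # 150 features
    dense[:, 2] = 1  # every gene detected
    dense[13:213, 3] = 1  # exactly 200 features
    for c in range(4, 10):
        dense[13:313, c] = 1  # 300 features, no mito
    return make_cell_matrix(dense, gene_ids=genes)


class TestQCFilter:
    def test_fixture_retains_seven(self):
        m = qc_fixture()
        kept, report = qc_filter(m)
        assert kept.n_cells == 7
        assert not report.loc["c0", "pass_mito"]
        assert not report.loc["c1", "pass_features"]
        assert not report.loc["c2", "pass_features"]
        assert report.loc["c3", "kept"]  # exactly 200 features: inclusive

    def test_idempotent(self):
        kept, _ = qc_filter(qc_fixture())
        again, _ = qc_filter(kept)
        assert again.n_cells == kept.n_cells
        assert (again.counts != kept.counts).nnz == 0

    def test_sixteen_percent_mito_removed(self):
        dense = np.zeros((20, 2), dtype=int)
        dense[0, 0] = 16  # mt- gene: 16 of 100 total counts
        dense[1:13, 0] = 7  # 84 non-mito counts
        dense[1:13, 1] = 10
        genes = ["mt-x"] + [f"g{i}" for i in range(19)]
        m = make_cell_matrix(dense, gene_ids=genes)
        kept, report = qc_filter(m, min_features=1, max_features=100)
        assert report["mito_frac"].iloc[0] == pytest.approx(0.16)
        assert kept.n_cells == 1

    def test_no_mito_genes_warns_and_skips(self):
        dense = np.ones((30, 3), dtype=int)
        m = make_cell_matrix(dense, gene_ids=[f"g{i}" for i in range(30)])
        with pytest.warns(UserWarning, match="mito"):
            kept, _ = qc_filter(m, min_features=1, max_features=100)
        assert kept.n_cells == 3


class TestLognormalize:
    def test_single_gene_cell_closed_form(self):
        dense = np.zeros((3, 1), dtype=int)
        dense[0, 0] = 7
        n = lognormalize(make_cell_matrix(dense))
        assert n.values[0, 0] == pytest.approx(np.log(1 + 10_000), abs=1e-12)
        assert n.values[1, 0] == 0.0

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, size=(50, 30))
        dense[:, dense.sum(axis=0) == 0] += 1
        m = make_cell_matrix(dense)
        n = lognormalize(m)
        rec = np.asarray(invert_lognormalize(n).todense())
        assert np.allclose(rec, dense, rtol=1e-6, atol=1e-8)

    def test_per_cell_conservation(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(2.0, size=(40, 10)) + 1
        n = lognormalize(make_cell_matrix(dense))
        v = np.asarray(n.values.todense())
        assert np.allclose(np.expm1(v).sum(axis=0), n.scale, rtol=1e-9)

    def test_zero_total_cell_named(self):
        dense = np.zeros((4, 2), dtype=int)
        dense[0, 0] = 5
        with pytest.raises(ValidationError, match="c1"):
            lognormalize(make_cell_matrix(dense))


class TestSelectHVG:
    @staticmethod
    def _norm(dense, gene_ids=None):
        return lognormalize(make_cell_matrix(dense, gene_ids=gene_ids))

    def test_constant_gene_ranks_last(self):
        rng = np.random.default_rng(2)
        dense = rng.poisson(3.0, size=(30, 50)) + 1
        dense[0, :] = 5  # constant raw counts; still library-size jitter
        dense[1, :] = np.where(np.arange(50) % 2, 40, 1)  # high dispersion
        n = self._norm(dense)
        top = select_hvg(n, n_top=10)
        assert "g1" in top

    def test_all_genes_returned_when_n_top_equals_genes(self):
        rng = np.random.default_rng(3)
        dense = rng.poisson(2.0, size=(20, 15)) + 1
        n = self._norm(dense)
        assert sorted(select_hvg(n, n_top=20)) == sorted(n.gene_ids)

    def test_n_top_exceeds_genes_rejected(self):
        rng = np.random.default_rng(3)
        n = self._norm(rng.poisson(2.0, size=(10, 5)) + 1)
        with pytest.raises(ValidationError):
            select_hvg(n, n_top=11)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        dense = rng.poisson(2.0, size=(40, 60)) + 1
        n = self._norm(dense)
        top = select_hvg(n, n_top=12)
        # permute cells
        perm_c = rng.permutation(60)
        n_c = self._norm(dense[:, perm_c])
        assert select_hvg(n_c, n_top=12) == top
        # permute genes (same symbols attached)
        perm_g = rng.permutation(40)
        n_g = self._norm(dense[perm_g], gene_ids=[f"g{i}" for i in perm_g])
        assert select_hvg(n_g, n_top=12) == top

    def test_planted_high_variance_in_top_decile(self):
        matrix, truth = generate_counts(
            default_count_spec(seed=6, n_genes=300, n_cells_per_stratum=40)
        )
        n = lognormalize(matrix)
        ranked = select_hvg(n, n_top=n.n_genes)
        # marker genes vary across cell types -> high dispersion
        for marker in ("Plp1", "C1qa", "Cldn5"):
            assert ranked.index(marker) < n.n_genes // 10


class TestPoolHemispheres:
    def test_cardinality(self):
        rng = np.random.default_rng(5)
        a = make_cell_matrix(rng.poisson(1, (10, 100)) + 1, hemisphere="left")
        b = make_cell_matrix(rng.poisson(1, (10, 100)) + 1, hemisphere="right")
        pooled = pool_hemispheres([a, b])
        assert pooled.n_cells == 200
        assert set(pooled.cell_meta["hemisphere"]) == {"left", "right"}

    def test_self_pool_doubles_totals(self):
        rng = np.random.default_rng(6)
        a = make_cell_matrix(rng.poisson(2, (8, 30)) + 1)
        pooled = pool_hemispheres([a, a])
        assert pooled.n_cells == 60
        tot_a = np.asarray(a.counts.sum(axis=1)).ravel()
        tot_p = np.asarray(pooled.counts.sum(axis=1)).ravel()
        order = np.argsort(a.gene_ids)
        assert np.array_equal(tot_p, 2 * tot_a[order])

    def test_gene_order_alignment(self):
        rng = np.random.default_rng(7)
        dense = rng.poisson(3, (6, 20)) + 1
        a = make_cell_matrix(dense, gene_ids=list("abcdef"))
        perm = [3, 1, 0, 5, 4, 2]
        b = make_cell_matrix(
            dense[perm], gene_ids=[list("abcdef")[i] for i in perm]
        )
        pooled = pool_hemispheres([a, b])
        half = pooled.counts[:, :20]
        other = pooled.counts[:, 20:]
        assert (half != other).nnz == 0

    def test_mismatched_universe_rejected(self):
        a = make_cell_matrix(np.ones((3, 2)), gene_ids=["a", "b", "c"])
        b = make_cell_matrix(np.ones((3, 2)), gene_ids=["a", "b", "d"])
        with pytest.raises(ValidationError):
            pool_hemispheres([a, b])


class TestDotStats:
    def test_examples(self):
        dense = np.zeros((2, 8))
        dense[0, :4] = 3.0  # cluster A: all express g0 at 3
        dense[1, 4:6] = 2.0  # cluster B: half express g1 at 2
        n = lognormalize(make_cell_matrix(np.ones((2, 8), dtype=int)))
        # overwrite with exact values to test the statistics directly
        n.values = sparse.csr_matrix(dense)
        labels = ["A"] * 4 + ["B"] * 4
        stats_df = dot_stats(n, labels, MarkerPanel("p", {"g0", "g1"}))
        get = lambda cl, g, col: float(
            stats_df[(stats_df["cluster"] == cl) & (stats_df["gene"] == g)][col]
        )
        assert get("A", "g0", "pct") == 1.0
        assert get("A", "g0", "mean") == pytest.approx(3.0)
        assert get("B", "g0", "pct") == 0.0
        assert get("B", "g0", "mean") == 0.0
        assert get("B", "g1", "pct") == 0.5
        assert get("B", "g1", "mean") == pytest.approx(1.0)

    def test_missing_gene_flagged(self, small_norm):
        n, labels = small_norm
        with pytest.warns(UserWarning, match="absent"):
            out = dot_stats(n, labels, MarkerPanel("p", {"g0", "nope"}))
        assert out[out["gene"] == "nope"]["missing"].all()


class TestAnnotateClusters:
    def test_synthetic_recovery(self):
        matrix, _ = generate_counts(
            default_count_spec(seed=8, n_genes=200, n_cells_per_stratum=30)
        )
        n = lognormalize(matrix)
        labels = n.cell_meta["cell_type"].to_numpy()
        signatures = {
            "microglia": {"C1qa", "Cx3cr1", "P2ry12"},
            "oligodendrocyte": {"Plp1", "Mbp", "Mog"},
            "endothelial": {"Cldn5", "Pecam1", "Flt1"},
            "mural": {"Pdgfrb", "Rgs5", "Acta2"},
        }
        out = annotate_clusters(n, labels, signatures, n_markers=10)
        assigned = dict(zip(out["cluster"], out["cell_type"]))
        assert assigned == {k: k for k in signatures}

    def test_disjoint_markers_unknown(self, small_norm):
        n, labels = small_norm
        out = annotate_clusters(n, labels, {"t1": {"zz1", "zz2"}}, n_markers=3)
        assert (out["cell_type"] == "unknown").all()

    def test_single_cluster_rejected(self, small_norm):
        n, _ = small_norm
        with pytest.raises(ValidationError):
            annotate_clusters(n, ["A"] * n.n_cells, {"t": {"g0"}})


def test_mtx_round_trip(tmp_path):
    matrix, _ = generate_counts(
        default_count_spec(seed=10, n_genes=150, n_cells_per_stratum=5)
    )
    write_mtx_triplet(tmp_path, matrix.counts, matrix.gene_ids, matrix.barcodes)
    counts, genes, barcodes = read_mtx_triplet(tmp_path)
    assert (counts != matrix.counts).nnz == 0
    assert genes == matrix.gene_ids
    assert barcodes == matrix.barcodes


def test_cell_matrix_validation():
    with pytest.raises(ValidationError, match="unique"):
        make_cell_matrix(np.ones((2, 2)), gene_ids=["a", "a"])
    with pytest.raises(ValidationError, match="integral"):
        CellMatrix(
            counts=sparse.csr_matrix(np.array([[0.5]])),
            gene_ids=["a"],
            cell_meta=pd.DataFrame(index=["c"]),
        )
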