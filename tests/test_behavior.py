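"""Behavioral indices, mixture-model stratification and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from stressccc.behavior import (
    GMMFit,
    assign_phenotype_gmm,
    assign_phenotype_threshold,
    compare_proportions,
    compute_indices,
    fit_gmm,
    msi_index,
    pca_with_loadings,
    select_extremes,
    si_index,
    variance_ratio,
)
from stressccc.errors import (
    DegenerateFitError,
    UndefinedIndexError,
    ValidationError,
)
from stressccc.simulate import BehaviorSimSpec, generate_behavior


class TestIndices:
    @pytest.mark.parametrize(
        "t_target,t_empty,expected", [(75, 50, 1.5), (42, 42, 1.0), (0, 10, 0.0)]
    )
    def test_si_index(self, t_target, t_empty, expected):
        assert si_index(t_target, t_empty) == pytest.approx(expected)

    def test_si_index_zero_denominator(self):
        with pytest.raises(UndefinedIndexError):
            si_index(10, 0)

    @pytest.mark.parametrize(
        "t_strain,hl,hr,expected",
        [(60, 40, 40, 1.5), (30, 20, 40, 1.0), (0, 10, 10, 0.0)],
    )
    def test_msi_index(self, t_strain, hl, hr, expected):
        assert msi_index(t_strain, hl, hr) == pytest.approx(expected)

    def test_msi_index_zero_habituation(self):
        with pytest.raises(UndefinedIndexError):
            msi_index(5, 0, 0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            si_index(-1, 10)
        with pytest.raises(ValidationError):
            msi_index(-1, 10, 10)


class TestSelectExtremes:
    @staticmethod
    def _table(indices, condition="defeated"):
        df = pd.DataFrame(
            {
                "id": [f"m{i}" for i in range(len(indices))],
                "condition": condition,
                "si_index": indices,
            }
        )
        return df

    def test_strict_thresholds(self):
        table = self._table([0.4, 0.7, 0.9, 1.2])
        kept = select_extremes(table)
        assert sorted(kept["si_index"]) == [0.4, 0.7, 1.2]

    def test_boundary_excluded(self):
        # an index exactly at the cut is not extreme (strict inequality)
        table = self._table([0.75, 1.15, 0.74, 1.16])
        kept = select_extremes(table)
        assert sorted(kept["si_index"]) == [0.74, 1.16]

    def test_all_middling_warns(self):
        with pytest.warns(UserWarning):
            kept = select_extremes(self._table([0.8, 0.9, 1.1]))
        assert kept[kept["condition"] == "defeated"].empty

    def test_controls_passed_through(self):
        table = pd.concat(
            [self._table([0.9], condition="control"), self._table([0.9, 0.4])]
        )
        kept = select_extremes(table)
        assert (kept["condition"] == "control").sum() == 1

    def test_empty_defeated_set_rejected(self):
        with pytest.raises(ValidationError):
            select_extremes(self._table([1.0], condition="control"))


class TestFitGMM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 0.3, 57)
        fit = fit_gmm(x, k=1, n_starts=1, seed=0)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-10)
        assert fit.variances[0] == pytest.approx(x.var(), abs=1e-10)
        assert fit.weights[0] == pytest.approx(1.0, abs=1e-12)

    def test_well_separated_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        truth = np.repeat([0, 1, 2], 20)
        x = rng.normal(np.array([0.40, 0.65, 1.30])[truth], 0.03)
        fit = fit_gmm(x, k=3, n_starts=20, seed=0)
        assert np.allclose(fit.means, [0.40, 0.65, 1.30], atol=0.03)
        labels = assign_phenotype_gmm(fit)["component"]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_matches_sklearn_loglik(self):
        # independent EM implementation should reach the same optimum
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(5, 0.5, 40)])
        ours = fit_gmm(x, k=2, n_starts=10, seed=0)
        sk = GaussianMixture(2, n_init=10, random_state=0, tol=1e-8).fit(
            x.reshape(-1, 1)
        )
        assert ours.loglik / len(x) == pytest.approx(
            sk.score(x.reshape(-1, 1)), abs=1e-4
        )
        assert np.allclose(sorted(sk.means_.ravel()), ours.means, atol=1e-2)

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4,
            max_size=40,
        ),
        st.integers(min_value=1, max_value=3),
    )
    def test_loglik_monotone(self, values, k):
        # EM with a floored variance is constrained EM: never decreases
        x = np.asarray(values)
        if np.ptp(x) == 0 or len(x) < k:
            return
        fit = fit_gmm(x, k=k, n_starts=3, seed=0)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8 * max(1, abs(fit.loglik)))

    def test_k_exceeds_n(self):
        with pytest.raises(ValidationError):
            fit_gmm([1.0, 2.0], k=3)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gmm([1.0] * 10, k=2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            fit_gmm([1.0, np.nan, 2.0], k=1)


class TestAssignPhenotype:
    def test_components_sorted_to_labels(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.normal(m, 0.03, 15) for m in (0.40, 0.65, 1.30)]
        )
        fit = fit_gmm(x, k=3, n_starts=10, seed=0)
        labels = assign_phenotype_gmm(fit)["label"].to_numpy()
        assert list(labels[:15]) == ["S"] * 15
        assert list(labels[15:30]) == ["Int"] * 15
        assert list(labels[30:]) == ["R"] * 15

    def test_tie_broken_to_lower_mean_and_flagged(self):
        fit = GMMFit(
            k=3,
            weights=np.array([0.4, 0.4, 0.2]),
            means=np.array([0.4, 0.65, 1.3]),
            variances=np.array([0.01] * 3),
            loglik=0.0,
            responsibilities=np.array([[0.4, 0.4, 0.2], [0.1, 0.2, 0.7]]),
            n_iter=10,
            converged=True,
        )
        out = assign_phenotype_gmm(fit)
        assert out.loc[0, "label"] == "S" and bool(out.loc[0, "tie"])
        assert out.loc[1, "label"] == "R" and not bool(out.loc[1, "tie"])

    def test_nonconverged_refused(self):
        fit = GMMFit(
            k=3,
            weights=np.ones(3) / 3,
            means=np.arange(3.0),
            variances=np.ones(3),
            loglik=0.0,
            responsibilities=np.ones((2, 3)) / 3,
            n_iter=500,
            converged=False,
        )
        with pytest.raises(ValidationError):
            assign_phenotype_gmm(fit)

    @pytest.mark.parametrize(
        "si,label",
        [(0.497, "S"), (1.2, "R"), (0.6, "Int"), (0.9, "unclassified"),
         (0.50, "Int"), (0.75, "Int"), (1.15, "unclassified")],
    )
    def test_threshold_binning(self, si, label):
        assert assign_phenotype_threshold(si) == label

    def test_threshold_negative_rejected(self):
        with pytest.raises(ValidationError):
            assign_phenotype_threshold(-0.1)

    def test_threshold_agrees_with_gmm_away_from_boundaries(self):
        table = generate_behavior(BehaviorSimSpec(seed=11))
        defeated = table[table["condition"] == "defeated"]
        si = defeated["si_index"].to_numpy()
        fit = fit_gmm(si, k=3, n_starts=20, seed=0)
        gmm_labels = assign_phenotype_gmm(fit)["label"].to_numpy()
        thr_labels = np.array([assign_phenotype_threshold(s) for s in si])
        sd = np.sqrt(fit.variances).max()
        far = np.all(
            np.abs(si[:, None] - np.array([0.50, 0.75, 1.15])) > 2 * sd, axis=1
        )
        classified = thr_labels != "unclassified"
        sel = far & classified
        assert sel.sum() > 15  # the default world mostly avoids boundaries
        assert (gmm_labels[sel] == thr_labels[sel]).all()


class TestPCA:
    def test_rank_one_case(self):
        x = np.arange(10.0)
        res = pca_with_loadings(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        assert res.explained_ratio[0] == pytest.approx(1.0)
        l1 = res.loadings["PC1"]
        assert abs(l1["a"]) == pytest.approx(abs(l1["b"]), abs=1e-12)

    def test_loadings_equal_correlation_oracle(self):
        # loading(var, PC) is exactly corr(standardized var, PC score)
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        res = pca_with_loadings(df)
        z = (df - df.mean()) / df.std(ddof=1)
        for pc in res.loadings.columns:
            for var in df.columns:
                r = np.corrcoef(z[var], res.scores[pc])[0, 1]
                assert res.loadings.loc[var, pc] == pytest.approx(r, abs=1e-8)

    def test_eigenvalue_sum_is_trace(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 6)))
        res = pca_with_loadings(df)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValidationError, match="flat"):
            pca_with_loadings(df)


class TestGroupStats:
    def test_variance_ratio_identity(self):
        a = np.array([1.0, 2, 3, 4])
        ratio, p = variance_ratio(a, a)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_variance_ratio_closed_form(self):
        rng = np.random.default_rng(8)
        b = rng.normal(size=10)
        b = (b - b.mean()) / b.std(ddof=1)  # exact unit sample variance
        a = 2.0 * b
        ratio, p = variance_ratio(a, b)
        assert ratio == pytest.approx(4.0, abs=1e-12)
        # frozen from the closed form 2*P(F(9,9) > 4), cross-checked in R
        assert p == pytest.approx(2 * stats.f(9, 9).sf(4.0), abs=1e-12)
        assert p == pytest.approx(0.051003, abs=5e-6)

    def test_variance_ratio_swap_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 2, 12), rng.normal(0, 1, 9)
        r1, p1 = variance_ratio(a, b)
        r2, p2 = variance_ratio(b, a)
        assert r1 == pytest.approx(1 / r2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_variance_ratio_degenerate(self):
        with pytest.raises(ValidationError):
            variance_ratio([1.0, 2.0], [3.0, 3.0])

    def test_chi2_identical_columns(self):
        chi2, df, p = compare_proportions([[5, 5], [7, 7]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_hand_computed(self):
        chi2, df, p = compare_proportions([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_chi2_permutation_invariance(self):
        t = np.array([[3, 9, 2], [8, 1, 6]])
        base = compare_proportions(t)[0]
        assert compare_proportions(t[::-1])[0] == pytest.approx(base)
        assert compare_proportions(t[:, [2, 0, 1]])[0] == pytest.approx(base)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            compare_proportions([[0, 0], [1, 2]])


def test_compute_indices_roundtrip():
    table = generate_behavior(BehaviorSimSpec(seed=3))
    derived = compute_indices(table[
        ["id", "condition", "t_target", "t_empty", "t_cd1", "t_129sv",
         "t_hab_left", "t_hab_right"]
    ])
    assert np.allclose(derived["si_index"], table["si_index"])
    assert np.allclose(derived["msi_cd1"], table["msi_cd1"])
    assert np.allclose(derived["msi_129"], table["msi_129"])
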