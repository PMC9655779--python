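"""Behavioral stratification of chronic-social-defeat mice.

After 10 days of chronic social defeat stress (CSDS), mice are profiled
with a social interaction (SI) test and a modified social interaction
(MSI) test.  The SI index is the time a mouse spends exploring a mesh
enclosure containing an aggressor-strain (CD1) mouse divided by the time
exploring the same enclosure when empty.  The MSI arena adds an
unfamiliar, non-aggressor 129/Sv mouse; each strain's MSI index is the
testing-phase exploration time divided by the mean habituation-phase
exploration of the two empty enclosures.

Defeated mice are stratified into resilient (R), intermediate (Int) and
susceptible (S) sub-phenotypes, either by fitting a three-component
univariate Gaussian mixture to the SI indices with EM, or by fixed
thresholds (R: SI > 1.15, S: SI < 0.50, Int: 0.50-0.75).  Supporting
statistics -- PCA with correlation-scale loadings, the two-sided F test
for a variance ratio, and the chi-squared test for phenotype-proportion
shifts -- live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateFitError, UndefinedIndexError, ValidationError

__all__ = [
    "si_index",
    "msi_index",
    "compute_indices",
    "select_extremes",
    "GMMFit",
    "fit_gmm",
    "assign_phenotype_gmm",
    "assign_phenotype_threshold",
    "PCAResult",
    "pca_with_loadings",
    "variance_ratio",
    "compare_proportions",
]

PHENOTYPES = ("S", "Int", "R")

#: CSV column order for a behavioral table (one row per mouse).
BEHAVIOR_COLUMNS = [
    "id",
    "condition",
    "t_target",
    "t_empty",
    "t_cd1",
    "t_129sv",
    "t_hab_left",
    "t_hab_right",
]


def si_index(t_target: float, t_empty: float) -> float:
    """Social interaction index: target exploration over empty-enclosure exploration.

    Parameters
    ----------
    t_target : float
        Seconds spent exploring the enclosure containing the CD1 mouse
        during the testing phase.
    t_empty : float
        Seconds spent exploring the empty enclosure during testing.
    """
    if t_target < 0 or t_empty < 0:
        raise ValidationError("exploration times must be non-negative")
    if t_empty == 0:
        raise UndefinedIndexError(
            "SI index undefined: zero time at the empty enclosure"
        )
    return t_target / t_empty


def msi_index(t_strain: float, t_hab_left: float, t_hab_right: float) -> float:
    """MSI index: strain exploration over mean habituation exploration.

    ``t_strain`` is the testing-phase exploration of one occupied
    enclosure (CD1 or 129/Sv); the denominator is the average of the two
    empty-enclosure exploration times during habituation.
    """
    if min(t_strain, t_hab_left, t_hab_right) < 0:
        raise ValidationError("exploration times must be non-negative")
    hab_mean = (t_hab_left + t_hab_right) / 2.0
    if hab_mean == 0:
        raise UndefinedIndexError(
            "MSI index undefined: zero mean habituation exploration"
        )
    return t_strain / hab_mean


def compute_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived ``si_index``, ``msi_cd1`` and ``msi_129`` columns.

    Expects the raw zone-time columns of :data:`BEHAVIOR_COLUMNS`.
    Mice with an undefined index raise; they should be flagged upstream,
    not silently dropped.
    """
    out = table.copy()
    out["si_index"] = [
        si_index(t, e) for t, e in zip(out["t_target"], out["t_empty"])
    ]
    out["msi_cd1"] = [
        msi_index(t, hl, hr)
        for t, hl, hr in zip(out["t_cd1"], out["t_hab_left"], out["t_hab_right"])
    ]
    out["msi_129"] = [
        msi_index(t, hl, hr)
        for t, hl, hr in zip(out["t_129sv"], out["t_hab_left"], out["t_hab_right"])
    ]
    return out


def select_extremes(
    table: pd.DataFrame, low: float = 0.75, high: float = 1.15
) -> pd.DataFrame:
    """Keep defeated mice with an extreme SI index (< low or > high, strict).

    Control mice pass through untouched.  Mirrors the study design of
    following up only socially avoiding (SI < 0.75) and non-avoiding
    (SI > 1.15) defeated animals.
    """
    if "si_index" not in table.columns:
        raise ValidationError("si_index must be computed before selection")
    defeated = table[table["condition"] == "defeated"]
    if defeated.empty:
        raise ValidationError("no defeated mice in table")
    keep = (defeated["si_index"] < low) | (defeated["si_index"] > high)
    if not keep.any():
        warnings.warn("no defeated mouse has an extreme SI index", stacklevel=2)
    controls = table[table["condition"] != "defeated"]
    return pd.concat([controls, defeated[keep]], ignore_index=True)


# ---------------------------------------------------------------------------
# Univariate Gaussian mixture EM
# ---------------------------------------------------------------------------


@dataclass
class GMMFit:
    """Result of a univariate Gaussian-mixture EM fit.

    Components are stored sorted by ascending mean.  ``loglik_trace``
    holds the observed-data log-likelihood after every EM iteration and
    is non-decreasing (a variance floor is enforced inside the M step,
    which keeps the constrained EM monotone).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    responsibilities: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)
    structure: str = "unequal"
    bic: float = np.nan


def _log_gauss(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    # x: (n,), mean/var: (k,) -> (n, k)
    d = x[:, None] - mean[None, :]
    return -0.5 * (np.log(2 * np.pi * var)[None, :] + d * d / var[None, :])


def _em_once(
    x: np.ndarray,
    means0: np.ndarray,
    var_floor: float,
    max_iter: int,
    tol: float,
    equal_var: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    k = means0.size
    n = x.size
    w = np.full(k, 1.0 / k)
    mu = means0.astype(float).copy()
    var = np.full(k, max(x.var(), var_floor))
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E step
        log_p = _log_gauss(x, mu, var) + np.log(w)[None, :]
        log_norm = logsumexp(log_p, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_p - log_norm[:, None])
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M step (variance clamped at the floor: constrained maximizer)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        d = x[:, None] - mu[None, :]
        if equal_var:
            var = np.full(k, max((resp * d * d).sum() / n, var_floor))
        else:
            var = np.maximum((resp * d * d).sum(axis=0) / nk, var_floor)
    return w, mu, var, resp, trace, converged


def fit_gmm(
    values,
    k: int = 3,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    var_floor_frac: float = 1e-6,
    var_structure: str = "bic",
) -> GMMFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    Runs ``n_starts`` initializations (quantile-spaced means, then
    seeded jitters of them) per variance structure and keeps the fit
    with the highest log-likelihood.  ``var_structure`` is ``"equal"``
    (one shared variance), ``"unequal"`` (free per-component
    variances), or ``"bic"`` (fit both and keep the lower-BIC model,
    mirroring how the commonly used packaged fitter chooses between
    its E and V univariate structures).  Convergence when the
    log-likelihood improves by less than ``tol`` or after ``max_iter``
    iterations.  Variances are floored at ``var_floor_frac`` times the
    total variance so small samples cannot collapse a component onto a
    single point.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if x.size < k:
        raise ValidationError(f"need at least k={k} observations, got {x.size}")
    if var_structure not in ("equal", "unequal", "bic"):
        raise ValidationError(f"unknown var_structure {var_structure!r}")
    total_var = x.var()
    if total_var == 0 and k > 1:
        raise DegenerateFitError("all values identical: mixture fit is degenerate")
    var_floor = max(var_floor_frac * total_var, 1e-300)

    base = np.quantile(x, (np.arange(k) + 0.5) / k)
    spread = x.std() if total_var > 0 else 1.0
    structures = (
        ("equal", "unequal") if var_structure == "bic" else (var_structure,)
    )
    best_fit = None
    for structure in structures:
        rng = np.random.default_rng(seed)
        best = None
        for s in range(max(n_starts, 1)):
            means0 = base if s == 0 else base + rng.normal(0, 0.25 * spread, size=k)
            res = _em_once(
                x, means0, var_floor, max_iter, tol, structure == "equal"
            )
            if best is None or res[4][-1] > best[4][-1]:
                best = res
        w, mu, var, resp, trace, conv = best
        # free parameters: k-1 weights, k means, 1 or k variances
        n_params = (k - 1) + k + (1 if structure == "equal" else k)
        bic = -2.0 * trace[-1] + n_params * np.log(x.size)
        order = np.argsort(mu)
        fit = GMMFit(
            k=k,
            weights=w[order],
            means=mu[order],
            variances=var[order],
            loglik=trace[-1],
            responsibilities=resp[:, order],
            n_iter=len(trace),
            converged=conv,
            loglik_trace=np.asarray(trace),
            structure=structure,
            bic=bic,
        )
        if best_fit is None or fit.bic < best_fit.bic:
            best_fit = fit
    return best_fit


def assign_phenotype_gmm(fit: GMMFit, values=None) -> pd.DataFrame:
    """Map each observation to S/Int/R by maximum responsibility.

    Components are labeled by ascending mean (S lowest, R highest),
    matching the behavioral ordering of the sub-phenotypes.  Exact
    responsibility ties break toward the lower-mean component and are
    flagged.  Requires a converged k=3 fit.
    """
    if not fit.converged:
        raise ValidationError(
            "refusing to assign phenotypes from a non-converged GMM fit "
            f"(n_iter={fit.n_iter}); increase max_iter or inspect the data"
        )
    if fit.k != len(PHENOTYPES):
        raise ValidationError(f"phenotype assignment requires k={len(PHENOTYPES)}")
    resp = fit.responsibilities
    # argmax returns the first (lowest-mean, post-sort) index on ties
    comp = np.argmax(np.isclose(resp, resp.max(axis=1, keepdims=True)), axis=1)
    tie = (np.isclose(resp, resp.max(axis=1, keepdims=True)).sum(axis=1)) > 1
    labels = np.array(PHENOTYPES)[comp]
    return pd.DataFrame(
        {"label": labels, "component": comp, "tie": tie}
    )


def assign_phenotype_threshold(si: float) -> str:
    """Threshold re-binning of an SI index into R / S / Int / unclassified.

    R: SI > 1.15; S: SI < 0.50; Int: 0.50 <= SI <= 0.75; the gap
    0.75 < SI <= 1.15 is unclassified.
    """
    if si < 0:
        raise ValidationError("SI index cannot be negative")
    if si > 1.15:
        return "R"
    if si < 0.50:
        return "S"
    if si <= 0.75:
        return "Int"
    return "unclassified"


# ---------------------------------------------------------------------------
# PCA with correlation-scale loadings
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    explained_ratio: np.ndarray


def pca_with_loadings(X) -> PCAResult:
    """PCA on mean-centered, unit-variance data with loading coefficients.

    Eigendecomposes the correlation matrix; loadings are eigenvectors
    column-scaled by the square-root eigenvalues, i.e. the correlations
    between each standardized variable and each component score.  Each
    component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    df = pd.DataFrame(X)
    if df.isna().any().any():
        raise ValidationError("missing values not allowed in PCA input")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 rows and 2 columns")
    sd = df.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValidationError(f"zero-variance column(s): {dead}")
    Z = (df - df.mean()) / sd
    R = np.asarray(Z.T @ Z) / (df.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval)[None, :], index=df.columns, columns=pcs
    )
    scores = pd.DataFrame(np.asarray(Z) @ eigvec, index=df.index, columns=pcs)
    return PCAResult(
        scores=scores,
        eigenvalues=eigval,
        loadings=loadings,
        explained_ratio=eigval / eigval.sum(),
    )


def variance_ratio(a, b) -> tuple[float, float]:
    """Two-sided F test for the ratio of two sample variances.

    Returns ``(s2_a / s2_b, p)`` with sample variances (ddof=1) and the
    two-sided p-value ``2 * min(upper, lower)`` from F(n_a-1, n_b-1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValidationError("zero variance in denominator group")
    ratio = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2 * min(dist.cdf(ratio), dist.sf(ratio))
    return ratio, min(p, 1.0)


def compare_proportions(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    ``table`` is a label x experiment contingency matrix of counts.
    Returns ``(chi2, df, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("need at least a 2x2 contingency table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("contingency counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has an all-zero row or column")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)
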