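"""Functional hypothesis tests for mean curves and curve distributions.

Two families:

1. Simulation-based likelihood-ratio tests (LRTs) for equality of mean
   curves.  The null and alternative are nested function-on-scalar
   regressions under a working-Gaussian likelihood; the statistic is the
   profiled deviance Lambda = nT log(RSS_null / RSS_alt) >= 0, and its null
   distribution is built by resampling whole residual curves across subjects
   (two-group version) or sign-flipping difference curves (paired
   weekend-vs-weekday version), which preserves within-curve dependence that
   the working likelihood ignores.

2. A projection-based two-sample Anderson-Darling (AD) test for equality of
   the distributions of two curve samples: FPCA on the pooled sample, then a
   rank-based two-sample AD test on each component's scores with a Bonferroni
   correction over components.  This is sensitive to distributional
   differences (e.g. variances) that mean tests cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.linalg import cho_solve

from .fosr import PenalizedSolver, standardize_covariates
from .fpca import fit_fpca
from .grid import DEFAULT_GRID, TimeGrid

#: log10 smoothing grid for the tested term's per-dataset GCV search
_LOG10_GRID = np.arange(-2.0, 8.5, 0.5)

#: the four covariate settings used for every mean-curve comparison
COVARIATE_SETTINGS: dict[str, tuple[str, ...]] = {
    "none": (),
    "age+bcs+ixn": ("age", "bcs", "age:bcs"),
    "+tdjd": ("age", "bcs", "age:bcs", "tdjd"),
    "+tpain": ("age", "bcs", "age:bcs", "tpain"),
}


class InferenceError(ValueError):
    pass


@dataclass
class MeanTestResult:
    """A simulation-based likelihood-ratio test of mean-curve equality."""

    statistic: float
    null_draws: np.ndarray
    p_value: float
    n_sim: int
    covariate_setting: str = "none"
    comparison: str = ""

    @property
    def reject(self) -> bool:
        return self.p_value <= 0.05


@dataclass
class ADComponentResult:
    component: int
    statistic: float
    p_value: float


@dataclass
class DistTestResult:
    """Projection-based two-sample distribution test with Bonferroni control."""

    n_components: int
    components: list[ADComponentResult]
    bonferroni_alpha: float
    overall_p: float
    decision: str  # "reject" | "retain"
    comparison: str = ""
    n_perm: int = 0

    @property
    def p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.components])

    @property
    def statistics(self) -> np.ndarray:
        return np.array([c.statistic for c in self.components])


def _deviance(rss0: float, rss1: float, n_obs: int) -> float:
    """Profiled working-Gaussian deviance; clipped at 0 against roundoff."""
    tiny = np.finfo(float).tiny
    if rss0 <= tiny:
        return 0.0
    return max(0.0, n_obs * np.log(rss0 / max(rss1, tiny)))


def _p_value(stat: float, null_draws: np.ndarray) -> float:
    return float((1 + np.sum(null_draws >= stat - 1e-12)) / (len(null_draws) + 1))


class _TermSearch:
    """Fast RSS of a penalized fit with a GCV grid search over one term.

    Shared terms keep fixed smoothing; the last term's smoothing is selected
    by GCV *per dataset*, so the test statistic is the same function of the
    data for the observed curves and for every resampled null dataset (using
    the observed data's selected smoothing inside the null draws would bias
    the test anti-conservative).  All Cholesky factors and effective degrees
    of freedom are precomputed per grid value; per-dataset work is a few
    small solves and quadratic forms.
    """

    def __init__(self, solver: PenalizedSolver, shared_lams: np.ndarray, n_obs: int):
        self.solver = solver
        self.n_obs = n_obs
        self.factors = []
        self.edfs = []
        for lg in _LOG10_GRID:
            lams = np.append(shared_lams, 10.0**lg)
            self.factors.append(solver.factor(lams))
            self.edfs.append(solver.edf(lams))

    def rss(self, Y: np.ndarray, sq: float | None = None) -> float:
        """RSS at the GCV-selected smoothing for this dataset."""
        s = self.solver
        sq = float(np.sum(Y * Y)) if sq is None else sq
        rhs = ((s.X.T @ Y) @ s.B).ravel()
        best_gcv, best_rss = np.inf, np.inf
        for f, edf in zip(self.factors, self.edfs):
            th = cho_solve(f, rhs)
            rss = max(sq - 2.0 * (th @ rhs) + th @ (s.A @ th), 0.0)
            gcv = self.n_obs * rss / (self.n_obs - edf) ** 2
            if gcv < best_gcv:
                best_gcv, best_rss = gcv, rss
        return best_rss


def lrt_mean_equality(
    curves: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    covariate_setting: str = "none",
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
    basis_dim: int = 15,
    penalty_order: int = 2,
    grid: TimeGrid = DEFAULT_GRID,
    comparison: str = "",
) -> MeanTestResult:
    """LRT of no difference between two groups' mean curves.

    Null model: covariates only (per ``covariate_setting``); alternative adds
    a standardized group-indicator coefficient function.  The alternative
    reuses the null's GCV smoothing for shared terms, so the models are
    nested at fixed bases and Lambda >= 0.  The null distribution resamples
    whole residual curves (with replacement across subjects) onto the null
    fitted values.
    """
    if n_sim < 99:
        raise InferenceError(f"n_sim must be >= 99 for usable p-resolution, got {n_sim}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.asarray(curves, dtype=float)
    n, T = Y.shape
    glabels = np.asarray(group)
    ulab = np.unique(glabels)
    if len(ulab) != 2:
        raise InferenceError(f"need exactly 2 groups, got {list(ulab)}")
    if min((glabels == g).sum() for g in ulab) == 0:
        raise InferenceError("both groups must be non-empty")

    terms = COVARIATE_SETTINGS.get(covariate_setting)
    if terms is None:
        raise InferenceError(
            f"unknown covariate setting {covariate_setting!r}; "
            f"options: {list(COVARIATE_SETTINGS)}"
        )
    if terms and covariates is None:
        raise InferenceError("covariate table required for this setting")
    if terms:
        design0_df, _ = standardize_covariates(covariates, terms)
        X0 = design0_df.to_numpy(dtype=float)
    else:
        X0 = np.ones((n, 1))
    ind = (glabels == ulab[1]).astype(float)
    ind = (ind - ind.mean()) / ind.std(ddof=1)
    X1 = np.column_stack([X0, ind])

    solver0 = PenalizedSolver(X0, basis_dim, penalty_order, grid)
    solver1 = PenalizedSolver(X1, basis_dim, penalty_order, grid)
    n_obs = n * T
    # shared-term smoothing fixed at the null model's GCV choice; the group
    # term's smoothing is re-selected by GCV inside every dataset (observed
    # and simulated alike) via the precomputed grid search
    lam0 = solver0.select_lambdas(Y)
    f0 = solver0.factor(lam0)
    search1 = _TermSearch(solver1, lam0, n_obs)

    def statistic(Ydat: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        th0 = solver0.theta(lam0, Ydat, factor=f0)
        fitted0 = solver0.fitted(th0)
        resid0 = Ydat - fitted0
        rss0 = float(np.sum(resid0 * resid0))
        rss1 = search1.rss(Ydat, sq=float(np.sum(Ydat * Ydat)))
        return _deviance(rss0, min(rss1, rss0), n_obs), fitted0, resid0

    stat, fitted0, resid0 = statistic(Y)
    null_draws = np.empty(n_sim)
    for s in range(n_sim):
        Ystar = fitted0 + resid0[rng.integers(0, n, size=n)]
        null_draws[s], _, _ = statistic(Ystar)
    return MeanTestResult(
        statistic=stat,
        null_draws=null_draws,
        p_value=_p_value(stat, null_draws),
        n_sim=n_sim,
        covariate_setting=covariate_setting,
        comparison=comparison,
    )


def lrt_paired_daytype(
    weekday: np.ndarray,
    weekend: np.ndarray,
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
    basis_dim: int = 15,
    penalty_order: int = 2,
    grid: TimeGrid = DEFAULT_GRID,
    comparison: str = "",
) -> MeanTestResult:
    """Paired LRT of weekend-vs-weekday mean-curve equality within a group.

    Works on per-subject difference curves D_i(t) = weekend - weekday; null:
    mean D == 0 (RSS is the raw sum of squares), alternative: a free
    penalized-spline mean curve.  The null distribution sign-flips whole
    difference curves, exploiting the exchangeability of +/-D under the null.
    """
    if n_sim < 99:
        raise InferenceError(f"n_sim must be >= 99, got {n_sim}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Wd = np.asarray(weekday, dtype=float)
    We = np.asarray(weekend, dtype=float)
    if Wd.shape != We.shape:
        raise InferenceError(
            f"unpaired subjects: weekday {Wd.shape} vs weekend {We.shape}"
        )
    D = We - Wd
    n, T = D.shape
    n_obs = n * T
    rss0 = float(np.sum(D * D))

    solver = PenalizedSolver(np.ones((n, 1)), basis_dim, penalty_order, grid)
    if rss0 <= np.finfo(float).tiny:
        return MeanTestResult(
            statistic=0.0,
            null_draws=np.zeros(n_sim),
            p_value=1.0,
            n_sim=n_sim,
            covariate_setting="none",
            comparison=comparison,
        )
    # the mean curve's smoothing is GCV-selected inside every dataset
    # (observed and sign-flipped alike) via the precomputed grid search
    search = _TermSearch(solver, np.empty(0), n_obs)
    stat = _deviance(rss0, min(search.rss(D, sq=rss0), rss0), n_obs)

    null_draws = np.empty(n_sim)
    for s in range(n_sim):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        Dstar = D * signs[:, None]
        # sign flips leave sum(D^2) unchanged
        null_draws[s] = _deviance(
            rss0, min(search.rss(Dstar, sq=rss0), rss0), n_obs
        )
    return MeanTestResult(
        statistic=stat,
        null_draws=null_draws,
        p_value=_p_value(stat, null_draws),
        n_sim=n_sim,
        covariate_setting="none",
        comparison=comparison,
    )


def ad_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-based two-sample Anderson-Darling statistic.

    A^2 = (1/N) sum_i (1/n_i) sum_{j=1}^{N-1} (N M_ij - j n_i)^2 / (j (N - j))
    with N = n1 + n2 and M_ij the count of sample i's values among the j
    smallest pooled values.  Depends on the data only through ranks, so it is
    invariant to strictly monotone transforms.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InferenceError("both samples must be non-empty")
    N = n1 + n2
    pooled = np.concatenate([x, y])
    labels = np.concatenate([np.ones(n1), np.zeros(n2)])
    order = np.argsort(pooled, kind="stable")
    u = labels[order]
    j = np.arange(1, N)  # 1..N-1
    M1 = np.cumsum(u)[:-1]
    M2 = j - M1
    denom = j * (N - j)
    term1 = np.sum((N * M1 - j * n1) ** 2 / denom) / n1
    term2 = np.sum((N * M2 - j * n2) ** 2 / denom) / n2
    return float((term1 + term2) / N)


def _ad_statistics_batch(U: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """AD statistics for many label arrangements at once.

    ``U`` is (m, N) with row r the 0/1 first-sample indicators in pooled
    sorted order for arrangement r.
    """
    N = n1 + n2
    j = np.arange(1, N)
    M1 = np.cumsum(U, axis=1)[:, :-1]
    denom = j * (N - j)
    t1 = ((N * M1 - j * n1) ** 2 / denom).sum(axis=1) / n1
    t2 = ((N * (j - M1) - j * n2) ** 2 / denom).sum(axis=1) / n2
    return (t1 + t2) / N


def _break_ties(pooled: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Perturb exact ties with tiny seeded uniform jitter (1e-9 x data range)."""
    if len(np.unique(pooled)) == len(pooled):
        return pooled
    rng_range = np.ptp(pooled)
    scale = 1e-9 * (rng_range if rng_range > 0 else 1.0)
    return pooled + rng.uniform(-scale, scale, size=len(pooled))


def ad_two_sample(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Two-sample AD test with a random-permutation p-value.

    Ties are broken by seeded jitter before testing (scores are continuous in
    theory; ties only arise from degenerate inputs).  Returns (A^2, p) with
    p = (1 + #{A^2* >= A^2}) / (n_perm + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = _break_ties(np.concatenate([x, y]), rng)
    stat = ad_statistic(pooled[:n1], pooled[n1:])
    # permute the sorted-order label indicators directly, in one batch
    u = np.zeros(N)
    u[np.argsort(pooled, kind="stable") < n1] = 1.0
    idx = np.argsort(rng.random((n_perm, N)), axis=1)
    null = _ad_statistics_batch(u[idx], n1, n2)
    count = int(np.sum(null >= stat - 1e-12))
    return stat, float((1 + count) / (n_perm + 1))


def distribution_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    var_threshold: float = 0.95,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    grid: TimeGrid = DEFAULT_GRID,
    comparison: str = "",
) -> DistTestResult:
    """Projection-based two-sample test of curve-distribution equality.

    FPCA on the pooled sample (common mean removed), K chosen as the smallest
    component count explaining >= ``var_threshold`` of variance, then a
    two-sample AD test on each component's scores; reject if any component's
    p-value falls below alpha / K.  The reported overall p is the Bonferroni
    min-p combination min(K * min_k p_k, 1).
    """
    A = np.asarray(curves_a, dtype=float)
    B = np.asarray(curves_b, dtype=float)
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise InferenceError("need at least 3 curves per sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.vstack([A, B])
    fpc = fit_fpca(pooled, k_select=var_threshold, grid=grid)
    K = fpc.n_components
    if K == 0 or fpc.total_var == 0:
        raise InferenceError("degenerate pooled covariance")
    scores_a = fpc.scores[: A.shape[0]]
    scores_b = fpc.scores[A.shape[0]:]
    # a Bonferroni rejection needs p-resolution finer than alpha / K: raise
    # n_perm (with a 2x margin) when the requested value cannot resolve it
    n_perm = max(n_perm, int(np.ceil(2.0 * K / alpha)) - 1)
    components = []
    for k in range(K):
        stat, p = ad_two_sample(scores_a[:, k], scores_b[:, k], n_perm=n_perm, seed=rng)
        components.append(ADComponentResult(component=k + 1, statistic=stat, p_value=p))
    p_min = min(c.p_value for c in components)
    overall_p = min(K * p_min, 1.0)
    decision = "reject" if p_min <= alpha / K else "retain"
    return DistTestResult(
        n_components=K,
        components=components,
        bonferroni_alpha=alpha / K,
        overall_p=overall_p,
        decision=decision,
        comparison=comparison,
        n_perm=n_perm,
    )
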