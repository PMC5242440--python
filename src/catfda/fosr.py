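"""Function-on-scalar regression with penalized-spline coefficient curves.

Model (per group, day type and response):

    Y_i(t) = beta_0(t) + sum_p x_ip beta_p(t) + eps_i(t)

with scalar covariates x_ip (standardized), time-varying coefficients
beta_p(t) represented in a cubic B-spline basis on [0, 24] hours with a
difference penalty on the basis coefficients, and residuals eps_i(t) treated
as independent Gaussian noise with variance sigma^2 across subjects and grid
points (working independence).  Coefficients are estimated by penalized least
squares over all n x 288 observations; per-term smoothing parameters are
selected by generalized cross-validation (GCV).

Within-curve residual dependence is not modelled in the likelihood; it is
respected by the subject-level bootstrap, which resamples whole curves with
their covariates to build pointwise percentile confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .grid import DEFAULT_GRID, TimeGrid

#: covariate terms understood by the model builder
MAIN_TERMS = ("age", "bcs", "tdjd", "tpain", "group")
INTERACTION = "age:bcs"


class FoSRError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``terms`` lists the covariates (intercept is implicit and always first);
    ``basis_dim`` cubic B-spline functions represent each coefficient curve,
    penalized by a difference penalty of order ``penalty_order``.
    """

    response: str = "activity"
    daytype: str = "weekday"
    terms: tuple[str, ...] = ("age", "bcs", "age:bcs")
    basis_dim: int = 15
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.basis_dim < self.penalty_order + 2:
            raise FoSRError("basis_dim must be >= penalty_order + 2")
        if INTERACTION in self.terms and not (
            "age" in self.terms and "bcs" in self.terms
        ):
            raise FoSRError("age:bcs requires both age and bcs in terms")
        for t in self.terms:
            if t != INTERACTION and t not in MAIN_TERMS:
                raise FoSRError(f"unknown term {t!r}")

    @property
    def all_terms(self) -> tuple[str, ...]:
        return ("intercept",) + tuple(self.terms)


@dataclass
class ScalingRecord:
    """Means/SDs used to standardize each main-effect column (for inverse maps)."""

    means: dict[str, float]
    sds: dict[str, float]


def standardize_covariates(
    covariates: pd.DataFrame, terms: tuple[str, ...] | list[str]
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Build the standardized design matrix for the requested terms.

    Main effects are centered and scaled to unit sample SD (ddof=1); the
    age:bcs interaction is the elementwise product of the two standardized
    main effects.  An intercept column of ones is always first.
    """
    n = len(covariates)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for term in terms:
        if term == INTERACTION:
            continue
        if term not in covariates.columns:
            raise FoSRError(f"covariate column {term!r} missing")
        raw = covariates[term].to_numpy(dtype=float)
        if np.isnan(raw).any():
            raise FoSRError(f"missing values in covariate {term!r}")
        m = raw.mean()
        sd = raw.std(ddof=1)
        if sd == 0:
            raise FoSRError(f"zero-variance covariate {term!r}")
        cols[term] = (raw - m) / sd
        means[term] = float(m)
        sds[term] = float(sd)
    if INTERACTION in terms:
        cols[INTERACTION] = cols["age"] * cols["bcs"]
    ordered = ["intercept"] + [t for t in terms]
    design = pd.DataFrame({t: cols[t] for t in ordered})
    return design, ScalingRecord(means=means, sds=sds)


def bspline_basis(
    t: np.ndarray, basis_dim: int, degree: int = 3, domain: tuple[float, float] = (0.0, 24.0)
) -> np.ndarray:
    """Evaluate ``basis_dim`` B-spline basis functions of ``degree`` on t."""
    n_interior = basis_dim - (degree + 1)
    if n_interior < 0:
        raise FoSRError(f"basis_dim {basis_dim} too small for degree {degree}")
    interior = np.linspace(domain[0], domain[1], n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(degree + 1, domain[0]), interior, np.full(degree + 1, domain[1])]
    )
    return BSpline.design_matrix(np.asarray(t, dtype=float), knots, degree).toarray()


def difference_penalty(basis_dim: int, order: int) -> np.ndarray:
    """D'D for the order-``order`` difference matrix on basis coefficients."""
    D = np.diff(np.eye(basis_dim), n=order, axis=0)
    return D.T @ D


class PenalizedSolver:
    """Penalized least-squares machinery for a fixed design and basis.

    Solves min_Theta ||Y - X Theta B'||_F^2 + sum_p lambda_p theta_p' Pen theta_p
    where Theta is P x K (row p = basis coefficients of beta_p).  Exposes fast
    refits at fixed smoothing for bootstrap and simulation nulls.
    """

    def __init__(
        self,
        design: np.ndarray,
        basis_dim: int = 15,
        penalty_order: int = 2,
        grid: TimeGrid = DEFAULT_GRID,
        check_rank: bool = True,
    ):
        X = np.asarray(design, dtype=float)
        if X.ndim != 2:
            raise FoSRError("design must be 2-D")
        self.X = X
        self.n, self.P = X.shape
        self.grid = grid
        self.K = basis_dim
        self.B = bspline_basis(grid.t, basis_dim)  # (T, K)
        self.Pen = difference_penalty(basis_dim, penalty_order)
        self.M = X.T @ X
        # bootstrap refits skip this: the roughness penalty regularizes a
        # rank-deficient resampled design, and a truly singular penalized
        # system still fails at the Cholesky factorization
        if check_rank and np.linalg.matrix_rank(self.M) < self.P:
            raise FoSRError("rank-deficient design matrix")
        self.G = self.B.T @ self.B
        self.A = np.kron(self.M, self.G)  # (PK, PK)

    def _system(self, lambdas: np.ndarray) -> np.ndarray:
        S = self.A.copy()
        K = self.K
        for p, lam in enumerate(lambdas):
            sl = slice(p * K, (p + 1) * K)
            S[sl, sl] += lam * self.Pen
        return S

    def factor(self, lambdas: np.ndarray):
        """Cholesky factor of the penalized normal-equation matrix."""
        return cho_factor(self._system(np.asarray(lambdas, dtype=float)))

    def theta(self, lambdas: np.ndarray, Y: np.ndarray, factor=None) -> np.ndarray:
        """Coefficient matrix Theta (P x K) at the given smoothing."""
        rhs = (self.X.T @ Y @ self.B).ravel()  # row-major vec of X'YB
        f = self.factor(lambdas) if factor is None else factor
        return cho_solve(f, rhs).reshape(self.P, self.K)

    def fitted(self, theta: np.ndarray) -> np.ndarray:
        return self.X @ theta @ self.B.T

    def rss(self, theta: np.ndarray, Y: np.ndarray) -> float:
        r = Y - self.fitted(theta)
        return float(np.sum(r * r))

    def edf(self, lambdas: np.ndarray) -> float:
        """Effective degrees of freedom: trace of the hat operator."""
        S = self._system(np.asarray(lambdas, dtype=float))
        return float(np.trace(np.linalg.solve(S, self.A)))

    def gcv(self, lambdas: np.ndarray, Y: np.ndarray) -> float:
        theta = self.theta(lambdas, Y)
        rss = self.rss(theta, Y)
        nT = self.n * Y.shape[1]
        edf = self.edf(lambdas)
        denom = nT - edf
        if denom <= 0:
            return np.inf
        return nT * rss / denom**2

    def select_lambdas(
        self,
        Y: np.ndarray,
        log10_grid: np.ndarray | None = None,
        sweeps: int = 2,
        fixed: dict[int, float] | None = None,
    ) -> np.ndarray:
        """Per-term smoothing by coordinate-descent GCV over a log10 grid.

        ``fixed`` pins selected term indices to given values (used by the
        likelihood-ratio machinery to share smoothing between nested models).
        """
        if log10_grid is None:
            log10_grid = np.arange(-2.0, 8.5, 0.5)
        fixed = fixed or {}
        lambdas = np.full(self.P, 10.0**2, dtype=float)
        for p, v in fixed.items():
            lambdas[p] = v
        free = [p for p in range(self.P) if p not in fixed]
        if not free:
            return lambdas
        for _ in range(sweeps):
            for p in free:
                best, best_gcv = lambdas[p], np.inf
                for lg in log10_grid:
                    lambdas[p] = 10.0**lg
                    g = self.gcv(lambdas, Y)
                    if g < best_gcv:
                        best, best_gcv = lambdas[p], g
                lambdas[p] = best
        return lambdas


@dataclass
class FoSRFit:
    """A fitted function-on-scalar regression."""

    spec: ModelSpec
    terms: tuple[str, ...]
    beta: np.ndarray               # (P, T) coefficient curves
    theta: np.ndarray              # (P, K) basis coefficients
    lambda_smooth: np.ndarray      # (P,) per-term smoothing parameters
    sigma2: float
    loglik: float
    rss: float
    edf: float
    scaling: ScalingRecord | None = None
    grid: TimeGrid = field(default_factory=lambda: DEFAULT_GRID)
    ci_lower: np.ndarray | None = None   # (P, T)
    ci_upper: np.ndarray | None = None
    n_boot: int = 0

    def term_index(self, term: str) -> int:
        if term not in self.terms:
            raise FoSRError(f"term {term!r} not in model: {self.terms}")
        return self.terms.index(term)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: term, bin_index, t_hours, beta, ci_lower, ci_upper."""
        t = self.grid.t
        T = len(t)
        frames = []
        for p, term in enumerate(self.terms):
            frames.append(
                pd.DataFrame(
                    {
                        "term": term,
                        "bin_index": np.arange(T),
                        "t_hours": t,
                        "beta": self.beta[p],
                        "ci_lower": self.ci_lower[p] if self.ci_lower is not None else np.nan,
                        "ci_upper": self.ci_upper[p] if self.ci_upper is not None else np.nan,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _gaussian_loglik(rss: float, n_obs: int, sigma2: float) -> float:
    return -0.5 * n_obs * np.log(2.0 * np.pi * sigma2) - rss / (2.0 * sigma2)


def fit_fosr(
    curves: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    spec: ModelSpec | None = None,
    lambdas: np.ndarray | None = None,
    scaling: ScalingRecord | None = None,
    grid: TimeGrid = DEFAULT_GRID,
) -> FoSRFit:
    """Fit the penalized function-on-scalar regression.

    ``design`` is the standardized design matrix (intercept first), e.g. from
    :func:`standardize_covariates`.  ``lambdas`` fixes the per-term smoothing;
    by default it is selected by GCV.
    """
    spec = spec or ModelSpec()
    Y = np.asarray(curves, dtype=float)
    if isinstance(design, pd.DataFrame):
        terms = tuple(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = spec.all_terms if X.shape[1] == len(spec.all_terms) else tuple(
            f"x{p}" for p in range(X.shape[1])
        )
    n, T = Y.shape
    if X.shape[0] != n:
        raise FoSRError("design and curves have different numbers of subjects")
    if n <= X.shape[1]:
        raise FoSRError(f"need n > P subjects, got n={n}, P={X.shape[1]}")

    solver = PenalizedSolver(X, spec.basis_dim, spec.penalty_order, grid)
    if lambdas is None:
        lambdas = solver.select_lambdas(Y)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.shape != (solver.P,):
            raise FoSRError("lambdas must have one value per term")
    theta = solver.theta(lambdas, Y)
    rss = solver.rss(theta, Y)
    edf = solver.edf(lambdas)
    n_obs = n * T
    dof = max(n_obs - edf, 1.0)
    sigma2 = max(rss / dof, np.finfo(float).tiny)
    return FoSRFit(
        spec=spec,
        terms=terms,
        beta=theta @ solver.B.T,
        theta=theta,
        lambda_smooth=lambdas,
        sigma2=sigma2,
        loglik=_gaussian_loglik(rss, n_obs, sigma2),
        rss=rss,
        edf=edf,
        scaling=scaling,
        grid=grid,
    )


def bootstrap_ci(
    fit: FoSRFit,
    curves: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> FoSRFit:
    """Subject-level bootstrap pointwise confidence bands.

    Resamples whole subjects (curve + covariate row) with replacement and
    refits at the original fit's smoothing parameters; returns the fit with
    per-term pointwise percentile bands attached.  Deterministic given seed.
    """
    if n_boot < 50:
        raise FoSRError(f"n_boot must be >= 50, got {n_boot}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.asarray(curves, dtype=float)
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    n, T = Y.shape
    P = X.shape[1]
    betas = np.empty((n_boot, P, T))
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            solver = PenalizedSolver(
                X[idx], fit.spec.basis_dim, fit.spec.penalty_order, fit.grid,
                check_rank=False,
            )
            theta = solver.theta(fit.lambda_smooth, Y[idx])
            betas[b] = theta @ solver.B.T
        except (FoSRError, np.linalg.LinAlgError):
            failures += 1
            betas[b] = np.nan
    if failures > 0.05 * n_boot:
        raise FoSRError(
            f"bootstrap refit failure rate {failures}/{n_boot} exceeds 5%"
        )
    alpha = 1.0 - level
    lower = np.nanpercentile(betas, 100 * alpha / 2, axis=0)
    upper = np.nanpercentile(betas, 100 * (1 - alpha / 2), axis=0)
    fit.ci_lower = lower
    fit.ci_upper = upper
    fit.n_boot = n_boot
    return fit


def significance_regions(fit: FoSRFit, term: str) -> list[tuple[float, float]]:
    """Maximal time intervals where the pointwise CI excludes zero.

    Returns [start_hour, end_hour] pairs on bin edges; a band strictly above
    or strictly below zero over the whole day yields [(0.0, 24.0)].
    """
    if fit.ci_lower is None or fit.ci_upper is None:
        raise FoSRError("fit has no confidence bands; run bootstrap_ci first")
    p = fit.term_index(term)
    sig = (fit.ci_lower[p] > 0) | (fit.ci_upper[p] < 0)
    edges = fit.grid.edges
    regions: list[tuple[float, float]] = []
    start = None
    for j, flag in enumerate(sig):
        if flag and start is None:
            start = edges[j]
        elif not flag and start is not None:
            regions.append((float(start), float(edges[j])))
            start = None
    if start is not None:
        regions.append((float(start), float(edges[-1])))
    return regions
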