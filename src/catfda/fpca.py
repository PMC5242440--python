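"""Functional principal components analysis on the daily grid.

Model: Y_i(t) = mu(t) + sum_k phi_k(t) xi_ik + eps_it, with orthonormal
eigenfunctions phi_k under the quadrature inner product and uncorrelated
scores xi_ik of variance lambda_k.

The estimator is the empirical one for dense, complete curves: pointwise mean
mu, eigendecomposition of the weighted sample covariance (weight w per grid
point, so eigenvalues carry curve-variance x hours units), and quadrature
projection scores xi_ik = <Y_i - mu, phi_k>.  No covariance smoothing is
applied; curves here are dense (288 points) and complete, and an optional
smoothing hook is deliberately left off by default.

Sign convention: each eigenfunction is oriented so that its integral over the
morning window [5 h, 9 h] is >= 0, tie-broken by the sign at the first grid
point, so that "positively loaded" subjects are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DEFAULT_GRID, TimeGrid

MORNING_WINDOW = (5.0, 9.0)


class FPCAError(ValueError):
    pass


@dataclass
class FPCAResult:
    grid: TimeGrid
    mu: np.ndarray                 # (T,)
    eigenfunctions: np.ndarray     # (K, T), orthonormal under quadrature
    eigenvalues: np.ndarray        # (K,), non-increasing, >= 0
    scores: np.ndarray             # (n, K)
    var_explained: np.ndarray      # (K,) fractions of total curve variance
    resid_var: float               # total variance not captured by the K components
    total_var: float               # trace of the weighted covariance

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """mu + sum_{j<=k} xi_j phi_j for each subject (all K by default)."""
        k = self.n_components if k is None else k
        return self.mu + self.scores[:, :k] @ self.eigenfunctions[:k]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """CSV-ready exports: eigenfunctions, variance table, scores."""
        t = self.grid.t
        K, T = self.eigenfunctions.shape
        eig = pd.DataFrame(
            {
                "component": np.repeat(np.arange(1, K + 1), T),
                "bin_index": np.tile(np.arange(T), K),
                "t_hours": np.tile(t, K),
                "phi": self.eigenfunctions.ravel(),
            }
        )
        var = pd.DataFrame(
            {
                "component": np.arange(1, K + 1),
                "eigenvalue": self.eigenvalues,
                "var_explained": self.var_explained,
                "cum_var_explained": np.cumsum(self.var_explained),
            }
        )
        return {"eigenfunctions": eig, "variance": var}


def _fix_signs(phi: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Orient each eigenfunction: integral over [5, 9] h >= 0, tie-break at t0."""
    t = grid.t
    window = (t >= MORNING_WINDOW[0]) & (t < MORNING_WINDOW[1])
    out = phi.copy()
    for k in range(out.shape[0]):
        s = out[k, window].sum() * grid.weight
        if abs(s) < 1e-12:
            s = out[k, 0]
        if s < 0:
            out[k] = -out[k]
    return out


def fit_fpca(
    curves: np.ndarray,
    k_select: int | float | None = None,
    grid: TimeGrid = DEFAULT_GRID,
    weight: float | None = None,
    center: bool = True,
) -> FPCAResult:
    """Fit FPCA to an n x T matrix of curves on the daily grid.

    ``k_select``: an integer keeps that many components; a float in (0, 1) is
    a variance-fraction threshold (smallest K whose cumulative fraction
    reaches it); None keeps every component with positive eigenvalue.
    ``weight`` overrides the grid's quadrature weight (eigenvalues scale
    linearly with it).
    """
    Y = np.asarray(curves, dtype=float)
    if Y.ndim != 2:
        raise FPCAError("curves must be an n x T matrix")
    n, T = Y.shape
    if n < 3:
        raise FPCAError(f"need at least 3 curves, got {n}")
    if T != grid.n_bins:
        raise FPCAError(f"curves have {T} points but grid has {grid.n_bins}")
    if not np.all(np.isfinite(Y)):
        raise FPCAError("non-finite values in curves")
    w = grid.weight if weight is None else float(weight)

    mu = Y.mean(axis=0) if center else np.zeros(T)
    Xc = Y - mu
    # weighted sample covariance; uniform weight -> scalar multiple
    C = (Xc.T @ Xc) / (n - 1) * w
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    lam1 = max(evals[0], 0.0)
    neg = evals < 0
    if neg.any() and lam1 > 0 and np.abs(evals[neg]).max() > 1e-10 * lam1:
        raise FPCAError("covariance has a substantially negative eigenvalue")
    evals = np.clip(evals, 0.0, None)
    total_var = float(evals.sum())

    if total_var > 0:
        frac = evals / total_var
    else:
        frac = np.zeros_like(evals)

    n_pos = int(np.sum(evals > 1e-12 * max(lam1, 1.0)))
    if k_select is None:
        K = n_pos
    elif isinstance(k_select, (int, np.integer)) and not isinstance(k_select, bool):
        K = int(k_select)
        if K < 1 or K > T:
            raise FPCAError(f"k_select out of range: {K}")
    else:
        thr = float(k_select)
        if not 0 < thr <= 1:
            raise FPCAError(f"variance threshold must be in (0, 1], got {thr}")
        if total_var == 0:
            raise FPCAError("degenerate covariance: zero total variance")
        K = int(np.searchsorted(np.cumsum(frac), thr - 1e-12) + 1)
    K = max(K, 1) if k_select is not None else K

    if K == 0:
        # all-identical curves: keep one null component for shape stability
        K = 1
    # orthonormal eigenvectors -> unit quadrature-norm eigenfunctions
    phi = (evecs[:, :K] / np.sqrt(w)).T
    phi = _fix_signs(phi, grid)
    scores = Xc @ phi.T * w
    lam = evals[:K]
    # zero out scores of numerically-null components
    null = lam <= 1e-12 * max(lam1, 1.0)
    scores[:, null] = 0.0

    return FPCAResult(
        grid=grid,
        mu=mu,
        eigenfunctions=phi,
        eigenvalues=lam,
        scores=scores,
        var_explained=frac[:K],
        resid_var=float(total_var - lam.sum()),
        total_var=total_var,
    )


def modes_of_variation(result: FPCAResult, k: int) -> tuple[np.ndarray, np.ndarray]:
    """The k-th mode pair mu(t) +/- 2 sqrt(lambda_k) phi_k(t); k is 1-based."""
    if not 1 <= k <= result.n_components:
        raise FPCAError(f"component index {k} out of range 1..{result.n_components}")
    offset = 2.0 * np.sqrt(result.eigenvalues[k - 1]) * result.eigenfunctions[k - 1]
    return result.mu + offset, result.mu - offset


def score_correlation(scores_a: np.ndarray, scores_b: np.ndarray, k: int) -> float:
    """Pearson correlation of subjects' k-th component scores across two fits.

    The two score matrices must cover the same subjects in the same order
    (e.g. weekend vs weekday fits); k is 1-based.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise FPCAError("score matrices cover different numbers of subjects")
    if a.shape[0] < 3:
        raise FPCAError("need at least 3 subjects for a correlation")
    if not (1 <= k <= a.shape[1] and k <= b.shape[1]):
        raise FPCAError(f"component index {k} out of range")
    x = a[:, k - 1]
    y = b[:, k - 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise FPCAError(f"zero-variance score column {k}: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
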