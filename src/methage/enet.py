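"""Penalized linear regression by cyclic coordinate descent.

Objective (scikit-learn parameterization, so published settings port over):

    (1/2n) ||y - b0 - X b||^2  +  lam * ( l1_ratio * ||b||_1
                                          + (1 - l1_ratio)/2 * ||b||^2 )

Features are standardized to zero mean / unit variance internally and the
response is centered; the returned model is on the original scale. The solver
is gram-based cyclic coordinate descent with soft-thresholding, an active-set
inner loop and warm starts along a descending lambda path.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ElasticNetFit",
    "CVResult",
    "standardize",
    "lambda_path",
    "fit_elastic_net",
    "cross_validate",
    "kkt_max_violation",
]


def standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize ``X`` (population std). Zero-variance columns get
    scale 1 and a warning; their coefficients stay 0 in any penalized fit."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant feature(s); coefficients forced to 0")
        sd = np.where(zero, 1.0, sd)
    return (X - mean) / sd, mean, sd


@dataclass
class ElasticNetFit:
    """A converged (or truncated) elastic-net solution on the original scale."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    l1_ratio: float
    n_iterations: int
    converged: bool
    feature_means: np.ndarray
    feature_sds: np.ndarray
    objective_trace: Optional[List[float]] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept

    @property
    def nonzero_indices(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients != 0)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "l1_ratio": self.l1_ratio,
            "intercept": self.intercept,
            "n_nonzero": int(len(self.nonzero_indices)),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    n_lambda: int = 100,
    eps: float = 1e-3,
) -> np.ndarray:
    """Geometric penalty grid from lambda_max down to eps * lambda_max.

    ``X`` must be column-standardized and ``y`` centered; lambda_max is the
    smallest penalty at which every coefficient is zero:
    max_j |<x_j, y>| / (n * l1_ratio).
    """
    if l1_ratio <= 0:
        raise ValueError("lambda_path requires l1_ratio > 0; supply lambda explicitly for ridge")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    lam_max = np.abs(X.T @ y).max() / (n * l1_ratio)
    if lam_max <= 0:
        raise ValueError("degenerate path: response is orthogonal to every feature")
    # nudge above the exact threshold so the top of the path is all-zero
    # despite floating-point rounding in the KKT comparison
    lam_max *= 1.0 + 1e-12
    return lam_max * np.power(eps, np.linspace(0.0, 1.0, n_lambda))


def _soft(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


try:  # optional compiled inner loop; the pure-Python path is the reference
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _cd_kernel(G, q, l1, l2, diag, denom, tol, max_iter, beta, c):  # pragma: no cover
        p = q.shape[0]
        n_sweeps = 0
        converged = False
        while n_sweeps < max_iter:
            maxd = 0.0
            for j in range(p):
                if denom[j] <= 0.0:
                    continue
                rho = c[j] + diag[j] * beta[j]
                if rho > l1:
                    new = (rho - l1) / denom[j]
                elif rho < -l1:
                    new = (rho + l1) / denom[j]
                else:
                    new = 0.0
                d = new - beta[j]
                if d != 0.0:
                    for k in range(p):
                        c[k] -= G[k, j] * d
                    beta[j] = new
                    ad = abs(d)
                    if ad > maxd:
                        maxd = ad
            n_sweeps += 1
            if maxd < tol:
                converged = True
                break
            while n_sweeps < max_iter:
                maxdi = 0.0
                for j in range(p):
                    if beta[j] == 0.0 or denom[j] <= 0.0:
                        continue
                    rho = c[j] + diag[j] * beta[j]
                    if rho > l1:
                        new = (rho - l1) / denom[j]
                    elif rho < -l1:
                        new = (rho + l1) / denom[j]
                    else:
                        new = 0.0
                    d = new - beta[j]
                    if d != 0.0:
                        for k in range(p):
                            c[k] -= G[k, j] * d
                        beta[j] = new
                        ad = abs(d)
                        if ad > maxdi:
                            maxdi = ad
                n_sweeps += 1
                if maxdi < tol:
                    break
        return n_sweeps, converged

except Exception:  # pragma: no cover - numba genuinely absent
    _cd_kernel = None


def _cd_solve(
    G: np.ndarray,
    q: np.ndarray,
    lam: float,
    l1_ratio: float,
    tol: float,
    max_iter: int,
    beta: np.ndarray,
    y_sq_over_2n: float = 0.0,
    trace: bool = False,
) -> Tuple[np.ndarray, int, bool, Optional[List[float]]]:
    """Coordinate descent on the standardized problem.

    G = X^T X / n, q = X^T y / n (y centered). ``beta`` is modified in place
    and also returned. Convergence: max |coefficient update| in a full sweep
    below ``tol``.
    """
    p = len(q)
    l1 = lam * l1_ratio
    l2 = lam * (1.0 - l1_ratio)
    diag = np.diag(G).copy()
    denom = diag + l2
    c = q - G @ beta  # negative gradient of the smooth part
    if not trace and _cd_kernel is not None:
        n_sweeps, converged = _cd_kernel(
            G, q, l1, l2, diag, denom, tol, max_iter, beta, c
        )
        return beta, int(n_sweeps), bool(converged), None
    objective: Optional[List[float]] = [] if trace else None

    def obj() -> float:
        quad = y_sq_over_2n - q @ beta + 0.5 * beta @ (G @ beta)
        return quad + l1 * np.abs(beta).sum() + 0.5 * l2 * beta @ beta

    def sweep(indices) -> float:
        nonlocal c
        max_delta = 0.0
        for j in indices:
            if denom[j] <= 0:  # constant column
                continue
            rho = c[j] + diag[j] * beta[j]
            new = _soft(rho, l1) / denom[j]
            delta = new - beta[j]
            if delta != 0.0:
                c -= G[:, j] * delta
                beta[j] = new
                ad = abs(delta)
                if ad > max_delta:
                    max_delta = ad
        return max_delta

    all_idx = np.arange(p)
    n_sweeps = 0
    converged = False
    while n_sweeps < max_iter:
        max_delta = sweep(all_idx)
        n_sweeps += 1
        if trace:
            objective.append(obj())
        if max_delta < tol:
            converged = True
            break
        # iterate the active set until stable, then re-check all coordinates
        active = np.flatnonzero(beta != 0.0)
        while n_sweeps < max_iter and active.size:
            inner_delta = sweep(active)
            n_sweeps += 1
            if trace:
                objective.append(obj())
            if inner_delta < tol:
                break
    return beta, n_sweeps, converged, objective


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    l1_ratio: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 10000,
    warm_start: Optional[np.ndarray] = None,
    trace: bool = False,
) -> ElasticNetFit:
    """Fit the elastic net at a single penalty value.

    ``warm_start`` is a coefficient vector on the *original* feature scale
    (e.g. the previous solution along a path). lam=0 gives OLS, l1_ratio=0
    ridge; both are exercised against closed forms in the test suite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError(f"incompatible shapes {X.shape} / {y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if lam < 0 or not 0 <= l1_ratio <= 1:
        raise ValueError("require lam >= 0 and l1_ratio in [0, 1]")
    n = X.shape[0]
    Xs, mean, sd = standardize(X)
    y_mean = y.mean()
    yc = y - y_mean

    G = (Xs.T @ Xs) / n
    q = (Xs.T @ yc) / n
    beta = np.zeros(X.shape[1])
    if warm_start is not None:
        beta = np.asarray(warm_start, dtype=float) * sd  # original -> standardized scale
    beta, n_iter, converged, objective = _cd_solve(
        G, q, lam, l1_ratio, tol, max_iter, beta,
        y_sq_over_2n=float(yc @ yc) / (2 * n), trace=trace,
    )
    if not converged:
        warnings.warn(f"coordinate descent hit max_iter={max_iter} without converging")
    coef = beta / sd
    intercept = y_mean - float(coef @ mean)
    return ElasticNetFit(
        coefficients=coef,
        intercept=intercept,
        lam=lam,
        l1_ratio=l1_ratio,
        n_iterations=n_iter,
        converged=converged,
        feature_means=mean,
        feature_sds=sd,
        objective_trace=objective,
    )


def kkt_max_violation(X: np.ndarray, y: np.ndarray, fit: ElasticNetFit) -> float:
    """Largest stationarity-condition violation of a fit, on the
    standardized scale the solver works in. Near zero at convergence."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Xs = (X - fit.feature_means) / fit.feature_sds
    beta = fit.coefficients * fit.feature_sds
    g = Xs.T @ (y - y.mean() - Xs @ beta) / n
    l1 = fit.lam * fit.l1_ratio
    l2 = fit.lam * (1.0 - fit.l1_ratio)
    active = Xs.std(axis=0) > 0
    zero = (beta == 0) & active
    nonzero = (beta != 0) & active
    violation = 0.0
    if zero.any():
        violation = max(violation, float(np.max(np.abs(g[zero]) - l1, initial=0.0)))
    if nonzero.any():
        resid = g[nonzero] - l1 * np.sign(beta[nonzero]) - l2 * beta[nonzero]
        violation = max(violation, float(np.max(np.abs(resid))))
    return violation


@dataclass
class CVResult:
    """Cross-validation curve over a descending lambda grid."""

    lambda_grid: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray
    best_lambda: float
    best_index: int
    fold_assignments: np.ndarray  # fold id per sample
    fold_mse: np.ndarray  # folds x lambdas

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    def best_lambda_1se(self) -> float:
        """Largest lambda whose mean MSE is within one SE of the minimum.

        Only grid points evaluated by every fold are considered, matching the
        selection rule for ``best_lambda``.
        """
        n_eff = np.sum(~np.isnan(self.fold_mse), axis=0)
        threshold = self.mean_mse[self.best_index] + self.se_mse[self.best_index]
        ok = np.flatnonzero((self.mean_mse <= threshold) & (n_eff == n_eff.max()))
        return float(self.lambda_grid[ok[0]])


def _stratified_folds(strata: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per sample; within every stratum fold sizes differ by <= 1."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(strata)
    assignment = np.empty(len(labels), dtype=int)
    offset = 0
    for label in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == label)
        if len(idx) < n_folds:
            warnings.warn(
                f"stratum {label!r} has {len(idx)} < {n_folds} samples; "
                "distributed one per fold"
            )
        idx = rng.permutation(idx)
        for k, i in enumerate(idx):
            assignment[i] = (offset + k) % n_folds
        offset += len(idx)  # rotate so small strata do not pile onto fold 0
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    strata: Sequence,
    n_folds: int = 10,
    l1_ratio: float = 0.5,
    lambda_grid: Optional[np.ndarray] = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10000,
    early_stop_patience: Optional[int] = 10,
) -> CVResult:
    """Stratified K-fold CV over a descending lambda path with warm starts.

    ``best_lambda`` minimizes mean validation MSE (ties break toward the
    larger penalty, i.e. the earlier grid point). With
    ``early_stop_patience`` set, a fold stops descending the path once its
    validation MSE has exceeded its running minimum for that many consecutive
    grid points; the minimum is then taken over grid points evaluated by all
    folds, so truncated tails cannot bias the selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(strata) != n:
        raise ValueError("strata length must match X")
    if n < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n} samples")
    if lambda_grid is None:
        Xs, _, _ = standardize(X)
        lambda_grid = lambda_path(Xs, y - y.mean(), l1_ratio=l1_ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    assignment = _stratified_folds(strata, n_folds, seed)
    fold_mse = np.full((n_folds, len(lambda_grid)), np.nan)
    for fold in range(n_folds):
        val = assignment == fold
        if not val.any():
            continue
        X_tr, y_tr = X[~val], y[~val]
        X_va, y_va = X[val], y[val]
        # standardize and build the Gram matrix once per fold, then walk the
        # path with warm starts in standardized coordinates
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xs, mean, sd = standardize(X_tr)
        y_mean = y_tr.mean()
        yc = y_tr - y_mean
        n_tr = len(y_tr)
        G = (Xs.T @ Xs) / n_tr
        q = (Xs.T @ yc) / n_tr
        Xva_s = (X_va - mean) / sd
        beta = np.zeros(X.shape[1])
        best_so_far = np.inf
        n_rising = 0
        for k, lam in enumerate(lambda_grid):
            beta, _, converged, _ = _cd_solve(
                G, q, lam, l1_ratio, tol, max_iter, beta
            )
            if not converged:
                warnings.warn(
                    f"fold {fold}, lambda {lam:.4g}: max_iter reached without converging"
                )
            resid = y_va - (y_mean + Xva_s @ beta)
            mse = float(resid @ resid) / len(y_va)
            fold_mse[fold, k] = mse
            if early_stop_patience is not None:
                if mse < best_so_far:
                    best_so_far = mse
                    n_rising = 0
                else:
                    n_rising += 1
                    if n_rising >= early_stop_patience:
                        break

    n_eff = np.sum(~np.isnan(fold_mse), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tail columns
        mean_mse = np.nanmean(fold_mse, axis=0)
        se_mse = np.nanstd(fold_mse, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    # only grid points every fold evaluated are candidates for the minimum
    candidates = n_eff == n_eff.max()
    search = np.where(candidates, mean_mse, np.inf)
    best_index = int(np.nanargmin(search))
    return CVResult(
        lambda_grid=lambda_grid,
        mean_mse=mean_mse,
        se_mse=se_mse,
        best_lambda=float(lambda_grid[best_index]),
        best_index=best_index,
        fold_assignments=assignment,
        fold_mse=fold_mse,
    )
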