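"""Elastic-net regression by cyclic coordinate descent.

Minimizes, for response y and predictor matrix X with N rows,

    (1/2N) sum_i (y_i - b0 - x_i' b)^2  +  lam * [ (1-alpha)/2 ||b||_2^2 + alpha ||b||_1 ]

the glmnet parameterization: alpha mixes ridge (0) and lasso (1), lam scales
the whole penalty. Columns are centered internally (the intercept is
unpenalized and recovered in closed form); the caller standardizes.

The solver cycles soft-threshold updates over a candidate set chosen by the
sequential strong rule, then verifies the full Karush-Kuhn-Tucker (KKT)
conditions and repairs any violations, so every returned fit carries a KKT
certificate at tolerance `tol * sd(y)`. Warm starts along a decreasing
lambda path make whole-path fits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to satisfy the KKT conditions; reports the gap."""


@dataclass
class ElasticNetFit:
    """One solved elastic-net problem."""

    intercept: float
    coef: np.ndarray
    lam: float
    alpha: float
    n_iter: int
    objective: float
    feature_ids: list[str] | None = None

    @property
    def selected(self) -> np.ndarray:
        """Indices of the exact support of the coefficient vector."""
        return np.flatnonzero(self.coef)

    def selected_ids(self) -> list[str]:
        if self.feature_ids is None:
            return [str(j) for j in self.selected]
        return [self.feature_ids[j] for j in self.selected]


@njit(cache=True, fastmath=True)
def _cd_sweeps(XT, r, beta, v, l1, l2, cand_mask, tol_cd, max_sweeps):  # pragma: no cover - jitted
    """Cyclic soft-threshold updates over the masked candidate set.

    XT is the centered predictor matrix transposed (p x n, C-contiguous so
    each coordinate's column is a contiguous row). Mutates `r` (residual) and
    `beta` in place; returns sweeps used. Stops when the largest scaled
    coefficient change in a sweep drops below tol_cd.
    """
    p, n = XT.shape
    # relative guard: a gradient equal to the threshold up to rounding (the
    # lambda_max boundary) must not activate a coordinate
    thr = l1 * (1.0 + 1e-12)
    sweeps = 0
    while sweeps < max_sweeps:
        # full pass over the candidate set
        max_d = 0.0
        for j in range(p):
            if not cand_mask[j]:
                continue
            vj = v[j]
            if vj <= 0.0:
                continue
            bj = beta[j]
            gj = 0.0
            for i in range(n):
                gj += XT[j, i] * r[i]
            gj /= n
            z = gj + vj * bj
            if z > thr:
                bnew = (z - l1) / (vj + l2)
            elif z < -thr:
                bnew = (z + l1) / (vj + l2)
            else:
                bnew = 0.0
            d = bnew - bj
            if d != 0.0:
                beta[j] = bnew
                for i in range(n):
                    r[i] -= XT[j, i] * d
                ad = abs(d) * np.sqrt(vj)
                if ad > max_d:
                    max_d = ad
        sweeps += 1
        if max_d < tol_cd:
            return sweeps
        # iterate only the active set until it stabilizes
        while sweeps < max_sweeps:
            max_d = 0.0
            for j in range(p):
                if not cand_mask[j] or beta[j] == 0.0:
                    continue
                vj = v[j]
                if vj <= 0.0:
                    continue
                bj = beta[j]
                gj = 0.0
                for i in range(n):
                    gj += XT[j, i] * r[i]
                gj /= n
                z = gj + vj * bj
                if z > thr:
                    bnew = (z - l1) / (vj + l2)
                elif z < -thr:
                    bnew = (z + l1) / (vj + l2)
                else:
                    bnew = 0.0
                d = bnew - bj
                if d != 0.0:
                    beta[j] = bnew
                    for i in range(n):
                        r[i] -= XT[j, i] * d
                    ad = abs(d) * np.sqrt(vj)
                    if ad > max_d:
                        max_d = ad
            sweeps += 1
            if max_d < tol_cd:
                break
    return sweeps


@njit(cache=True)
def _path_kernel(XT, yc, v, lambdas, alpha, tol_abs, max_sweeps, beta0):  # pragma: no cover - jitted
    """Warm-started strong-rule coordinate descent along a lambda path.

    Returns (betas (L, p), sweeps (L,), status, worst_gap): status 0 = every
    lambda certified by the full KKT check, 1 = the repair loop was
    exhausted somewhere (worst_gap reports the residual violation).
    """
    p, n = XT.shape
    L = lambdas.size
    betas = np.empty((L, p))
    sweeps_out = np.zeros(L, dtype=np.int64)
    beta = beta0.copy()
    r = yc - np.dot(beta, XT)
    status = 0
    worst_gap = 0.0
    lam_prev = lambdas[0]
    cand = np.zeros(p, dtype=np.bool_)
    # gradient at the current solution; refreshed by each lambda's KKT pass
    g = np.dot(XT, r) / n
    for k in range(L):
        lam = lambdas[k]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        # sequential strong rule, screened with the previous solution's gradient
        strong_cut = 2.0 * l1 - lam_prev * alpha
        if strong_cut < 0.0:
            strong_cut = 0.0
        for j in range(p):
            cand[j] = (abs(g[j]) >= strong_cut) or (beta[j] != 0.0)
        tol_cd = 0.3 * tol_abs
        sweeps = 0
        ok = False
        for _rep in range(60):
            sweeps += _cd_sweeps(XT, r, beta, v, l1, l2, cand, tol_cd, max_sweeps)
            g = np.dot(XT, r) / n
            gap = 0.0
            added = False
            for j in range(p):
                if v[j] <= 0.0:
                    continue
                if beta[j] != 0.0:
                    s = 1.0 if beta[j] > 0.0 else -1.0
                    viol = abs(g[j] - l2 * beta[j] - l1 * s)
                else:
                    viol = abs(g[j]) - l1
                    if viol < 0.0:
                        viol = 0.0
                if viol > tol_abs and not cand[j]:
                    cand[j] = True
                    added = True
                if viol > gap:
                    gap = viol
            if gap <= tol_abs:
                ok = True
                break
            if not added:
                # candidate set is right but not yet solved precisely enough
                tol_cd *= 0.25
        if not ok:
            status = 1
            if gap > worst_gap:
                worst_gap = gap
        betas[k] = beta
        sweeps_out[k] = sweeps
        lam_prev = lam
    return betas, sweeps_out, status, worst_gap


def _kkt_violations(g: np.ndarray, beta: np.ndarray, v: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Per-coordinate KKT violation, in gradient units.

    Stationarity asks g_j = l2*b_j + l1*sign(b_j) on the support and
    |g_j| <= l1 off it, where g_j = (1/N) x_j'(y - b0 - Xb).
    """
    viol = np.where(
        beta != 0.0,
        np.abs(g - l2 * beta - l1 * np.sign(beta)),
        np.maximum(np.abs(g) - l1, 0.0),
    )
    viol[v <= 0.0] = 0.0
    return viol


def elastic_net_objective(X, y, intercept, coef, lam, alpha) -> float:
    r = np.asarray(y, float) - intercept - np.asarray(X, float) @ coef
    n = len(r)
    penalty = lam * ((1.0 - alpha) * 0.5 * coef @ coef + alpha * np.abs(coef).sum())
    return float(r @ r / (2.0 * n) + penalty)


def _prepare(X: np.ndarray, y: np.ndarray, dtype=np.float64):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError(f"incompatible shapes X{X.shape}, y({len(y)},)")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    x_mean = X.mean(axis=0)
    XT = np.ascontiguousarray((X - x_mean).T, dtype=dtype)  # p x n, rows contiguous
    y_mean = float(y.mean())
    yc = (y - y_mean).astype(dtype)
    v = ((XT.astype(np.float64) ** 2).sum(axis=1) / X.shape[0]).astype(dtype)
    return XT, yc, x_mean, y_mean, v


def _run_path(XT, yc, v, lambdas, alpha, tol_abs, max_sweeps, beta0=None):
    dtype = XT.dtype
    if beta0 is None:
        beta0 = np.zeros(XT.shape[0], dtype=dtype)
    betas, sweeps, status, gap = _path_kernel(
        XT, np.ascontiguousarray(yc), v, np.asarray(lambdas, dtype), dtype.type(alpha),
        dtype.type(tol_abs), max_sweeps, beta0.astype(dtype),
    )
    if status != 0:
        raise ConvergenceError(
            f"coordinate descent did not reach KKT tolerance {tol_abs:.3e}; "
            f"final gap {gap:.3e}"
        )
    return betas, sweeps


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.5,
    warm_start: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    feature_ids: list[str] | None = None,
) -> ElasticNetFit:
    """Solve one elastic-net problem; the returned fit satisfies the KKT
    conditions at tolerance ``tol * sd(y)``."""
    if lam < 0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("need lam >= 0 and alpha in [0, 1]")
    XT, yc, x_mean, y_mean, v = _prepare(X, y)
    sdy = float(np.std(y))
    tol_abs = tol * (sdy if sdy > 0 else 1.0)
    beta0 = None if warm_start is None else np.array(warm_start, dtype=float)
    betas, sweeps = _run_path(XT, yc, v, [lam], alpha, tol_abs, max_sweeps, beta0)
    beta = betas[0]
    intercept = y_mean - float(x_mean @ beta)
    obj = elastic_net_objective(X, y, intercept, beta, lam, alpha)
    return ElasticNetFit(intercept, beta, lam, alpha, int(sweeps[0]), obj, feature_ids)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float, alpha_floor: float = 1e-3) -> float:
    """Smallest lambda at which the solution is exactly zero:
    max_j |x_j'(y - ybar)| / (N alpha). For alpha = 0 the null threshold is
    infinite; a capped value using `alpha_floor` stands in."""
    XT, yc, _, _, _ = _prepare(X, y)
    g_max = float(np.abs(XT @ yc).max() / len(yc))
    return g_max / max(alpha, alpha_floor)


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    eps: float | None = None,
) -> np.ndarray:
    """Log-spaced decreasing lambda sequence from lambda_max to eps*lambda_max.

    eps defaults to 1e-3 when N > p and 1e-2 otherwise (the high-dimensional
    case needs less of the small-lambda tail).
    """
    n, p = np.asarray(X).shape
    if eps is None:
        eps = 1e-3 if n > p else 1e-2
    lmax = lambda_max(X, y, alpha)
    if lmax <= 0:  # y constant: any positive lambda gives the null model
        lmax = 1.0
    return np.logspace(np.log10(lmax), np.log10(eps * lmax), n_lambda)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float = 0.5,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started fits along a decreasing lambda sequence.

    Returns (coefs with shape (L, p), intercepts with shape (L,)). `dtype`
    may be float32 for loose-tolerance throwaway fits (cross-validation
    curves); certified fits use the float64 default.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) > 1 and not (np.diff(lambdas) < 0).all():
        raise ValueError("lambda sequence must be strictly decreasing")
    XT, yc, x_mean, y_mean, v = _prepare(X, y, dtype=dtype)
    sdy = float(np.std(y))
    tol_abs = tol * (sdy if sdy > 0 else 1.0)
    coefs, _ = _run_path(XT, yc, v, lambdas, alpha, tol_abs, max_sweeps)
    coefs = coefs.astype(np.float64)
    intercepts = y_mean - coefs @ x_mean
    return coefs, intercepts


@dataclass
class CvLambdaResult:
    lam: float
    lambdas: np.ndarray
    cv_mse: np.ndarray
    cv_se: np.ndarray
    best_index: int
    fold_assignment: np.ndarray = field(repr=False, default=None)


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    k: int = 10,
    path: np.ndarray | None = None,
    seed: int = 0,
    rule: str = "min",
    tol: float = 1e-4,
) -> CvLambdaResult:
    """K-fold cross-validation over a lambda path; lambda* minimizes the mean
    held-out MSE (ties to the larger lambda). rule="1se" picks the largest
    lambda within one standard error of the minimum.

    The path is computed once on the full data and shared across folds, and
    fold fits are warm-started along it. Fold fits default to a loose
    KKT tolerance (1e-4 * sd(y)) in single precision: they only evaluate the
    CV error curve, which is insensitive at that scale; final models are fit
    tight in double precision.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if k > n:
        raise ValueError(f"k-fold CV needs k <= N ({k} > {n})")
    if k < 2:
        raise ValueError("need k >= 2")
    if path is None:
        path = lambda_path(X, y, alpha)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k)):
        assignment[idx] = f
    fit_dtype = np.float32 if tol >= 1e-5 else np.float64
    sq_err = np.full((n, len(path)), np.nan)
    for f in range(k):
        test = assignment == f
        coefs, intercepts = fit_path(X[~test], y[~test], path, alpha, tol=tol, dtype=fit_dtype)
        pred = X[test] @ coefs.T + intercepts[None, :]
        sq_err[test] = (pred - y[test, None]) ** 2
    cv_mse = sq_err.mean(axis=0)
    fold_means = np.array([sq_err[assignment == f].mean(axis=0) for f in range(k)])
    cv_se = fold_means.std(axis=0, ddof=1) / np.sqrt(k)
    best = int(np.argmin(cv_mse))  # first minimum = larger lambda on ties
    if rule == "1se":
        within = np.flatnonzero(cv_mse <= cv_mse[best] + cv_se[best])
        best = int(within[0])
    elif rule != "min":
        raise ValueError(f"unknown rule {rule!r}")
    return CvLambdaResult(float(path[best]), path, cv_mse, cv_se, best, assignment)


def predict(fit: ElasticNetFit, X: np.ndarray) -> np.ndarray:
    """Linear predictor b0 + X b; accepts a single row or a matrix."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != len(fit.coef):
        raise ValueError(f"predictor dimension {X.shape[1]} != model dimension {len(fit.coef)}")
    out = fit.intercept + X @ fit.coef
    return float(out[0]) if single else out


def kkt_certificate(X: np.ndarray, y: np.ndarray, fit: ElasticNetFit) -> float:
    """Maximum KKT violation of a fit, in gradient units (compare against
    tol * sd(y))."""
    XT, yc, _, _, v = _prepare(X, y)
    resid = yc - fit.coef @ XT
    g = XT @ resid / len(yc)
    l1, l2 = fit.lam * fit.alpha, fit.lam * (1.0 - fit.alpha)
    return float(_kkt_violations(g, fit.coef, v, l1, l2).max()) if len(g) else 0.0
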