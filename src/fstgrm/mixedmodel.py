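"""GBLUP mixed model: AI-REML variance components and breeding-value prediction.

Model: y = Xb + u + e on the training individuals, with u ~ N(0, G su2) over
all (training + validation) individuals and e ~ N(0, I se2).  Variance
components maximize the restricted likelihood via average-information updates
with EM-REML fallback steps; one eigendecomposition of the training block of
G makes every iteration O(n).  Breeding values for all individuals solve the
mixed-model equations jointly, so validation predictions propagate through
the genomic covariance alone.

The reported deviance is -2 log L_R = log|V| + log|X'V^-1 X| + y'Py
+ (n - p) log 2*pi, evaluated at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .grm import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "RemlResult",
    "EvaluationResult",
    "reml_fit",
    "reml_minus2logl",
    "gebv_blup",
    "gebv_backsolve",
    "evaluate",
]


@dataclass
class RemlResult:
    sigma_u2: float
    sigma_e2: float
    h2: float
    minus2logl: float
    n_iter: int
    converged: bool


@dataclass
class EvaluationResult:
    """Validation summary: accuracy and the bias regression of GEBV on TBV."""

    accuracy: float
    intercept: float
    slope: float
    n: int


class _EigenReml:
    """Restricted likelihood of (su2, se2) in the eigenbasis of G_tt."""

    def __init__(self, y: np.ndarray, X: np.ndarray, g_tt: np.ndarray):
        self.n, self.p = X.shape
        d, U = sla.eigh(g_tt)
        self.d = np.clip(d, 0.0, None)  # G is PSD up to rounding
        self.ys = U.T @ y
        self.Xs = U.T @ X

    def _core(self, su2: float, se2: float):
        v = su2 * self.d + se2
        if np.any(v <= 0):
            raise FloatingPointError("V is not positive definite")
        Xv = self.Xs / v[:, None]
        xtvx = self.Xs.T @ Xv
        xtvy = Xv.T @ self.ys
        beta = np.linalg.solve(xtvx, xtvy)
        py = self.ys / v - Xv @ beta
        return v, Xv, xtvx, py

    def minus2logl(self, su2: float, se2: float) -> float:
        v, _, xtvx, py = self._core(su2, se2)
        ypy = float(self.ys @ py)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return float(
            np.sum(np.log(v)) + logdet_x + ypy + (self.n - self.p) * np.log(2 * np.pi)
        )

    def _apply_p(self, t: np.ndarray, v: np.ndarray, Xv: np.ndarray, xtvx: np.ndarray):
        return t / v - Xv @ np.linalg.solve(xtvx, Xv.T @ t)

    def score_ai(self, su2: float, se2: float):
        """REML gradient and average-information matrix for (su2, se2)."""
        v, Xv, xtvx, py = self._core(su2, se2)
        xtvx_inv = np.linalg.inv(xtvx)
        # tr(P A) = tr(V^-1 A) - tr((X'V^-1X)^-1 X'V^-1 A V^-1 X), A diagonal here
        def tr_pa(a_diag: np.ndarray) -> float:
            t1 = float(np.sum(a_diag / v))
            W = Xv * a_diag[:, None]
            t2 = float(np.trace(xtvx_inv @ (W.T @ Xv)))
            return t1 - t2

        a_u = self.d
        a_e = np.ones(self.n)
        apy_u = a_u * py
        apy_e = py
        grad = np.array(
            [
                -0.5 * (tr_pa(a_u) - float(py @ apy_u)),
                -0.5 * (tr_pa(a_e) - float(py @ apy_e)),
            ]
        )
        p_apy_u = self._apply_p(apy_u, v, Xv, xtvx)
        p_apy_e = self._apply_p(apy_e, v, Xv, xtvx)
        ai = 0.5 * np.array(
            [
                [float(apy_u @ p_apy_u), float(apy_u @ p_apy_e)],
                [float(apy_e @ p_apy_u), float(apy_e @ p_apy_e)],
            ]
        )
        em_terms = np.array(
            [float(py @ apy_u) - tr_pa(a_u), float(py @ apy_e) - tr_pa(a_e)]
        )
        return grad, ai, em_terms


def reml_fit(
    y: np.ndarray,
    g_tt: np.ndarray | GRM,
    X: np.ndarray | None = None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RemlResult:
    """AI-REML estimates of (genetic, residual) variance for the GBLUP model.

    ``g_tt`` is the training-block relationship matrix (individuals in the
    order of ``y``); ``X`` defaults to an intercept column.  Convergence
    requires the relative change of both components below ``tol`` and a small
    gradient; non-convergence is flagged on the result, not raised.  AI
    proposals falling outside the parameter space (or a non-positive-definite
    AI matrix) trigger an EM-REML step.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if isinstance(g_tt, GRM):
        g_tt = g_tt.values
    if g_tt.shape != (n, n):
        raise ValueError("G block does not cover the training individuals")
    if X is None:
        X = np.ones((n, 1))
    if tol <= 0:
        raise ValueError("tol must be positive")
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("phenotypes have zero variance")
    floor = 1e-8 * vary
    su2, se2 = init if init is not None else (vary / 2.0, vary / 2.0)

    lik = _EigenReml(y, X, g_tt)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, ai, em_terms = lik.score_ai(su2, se2)
        theta = np.array([su2, se2])
        use_em = False
        try:
            step = np.linalg.solve(ai, grad)
            new = theta + step
            if np.any(new < floor):
                use_em = True
        except np.linalg.LinAlgError:
            use_em = True
        if use_em:
            logger.debug("AI step rejected at iter %d; EM fallback", it)
            new = theta + theta**2 / n * em_terms
            new = np.maximum(new, floor)
        rel = np.abs(new - theta) / np.maximum(np.abs(theta), floor)
        su2, se2 = float(new[0]), float(new[1])
        if np.all(rel < tol) and np.linalg.norm(grad) < 1e-6:
            converged = True
            break
    m2ll = lik.minus2logl(su2, se2)
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    return RemlResult(
        sigma_u2=su2,
        sigma_e2=se2,
        h2=su2 / (su2 + se2),
        minus2logl=m2ll,
        n_iter=it,
        converged=converged,
    )


def reml_minus2logl(
    y: np.ndarray,
    g_tt: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    X: np.ndarray | None = None,
) -> float:
    """Restricted deviance at a given variance pair (same constant as reml_fit)."""
    y = np.asarray(y, dtype=np.float64)
    if X is None:
        X = np.ones((len(y), 1))
    return _EigenReml(y, X, g_tt).minus2logl(sigma_u2, sigma_e2)


def gebv_blup(
    y: np.ndarray,
    g: GRM,
    train_ids: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    X: np.ndarray | None = None,
) -> np.ndarray:
    """GEBVs for every individual in G by solving the joint mixed-model equations.

    Phenotypes exist for ``train_ids`` only (aligned with ``y``); validation
    individuals receive predictions through their genomic covariance with the
    training set.  Requires an invertible G — blend first if a weighted
    low-rank panel makes it singular.
    """
    if sigma_u2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    y = np.asarray(y, dtype=np.float64)
    rows = g.rows_for(np.asarray(train_ids))
    n_all = len(g.ids)
    n_t = len(rows)
    if len(y) != n_t:
        raise ValueError("y length does not match the training ids")
    if X is None:
        X = np.ones((n_t, 1))
    p = X.shape[1]
    lam = sigma_e2 / sigma_u2
    try:
        g_inv = sla.cho_solve(sla.cho_factor(g.values), np.eye(n_all))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "G is singular; blend it with the identity (grm.blend) before BLUP"
        ) from e
    # coefficient matrix [[X'X, X'Z], [Z'X, Z'Z + lam*G^-1]] with Z the
    # training-row selector
    C = np.zeros((p + n_all, p + n_all))
    C[:p, :p] = X.T @ X
    ZtX = np.zeros((n_all, p))
    ZtX[rows] = X
    C[:p, p:] = ZtX.T
    C[p:, :p] = ZtX
    C[p:, p:] = lam * g_inv
    C[p + rows, p + rows] += 1.0
    rhs = np.zeros(p + n_all)
    rhs[:p] = X.T @ y
    rhs[p + rows] = y
    try:
        sol = sla.solve(C, rhs, assume_a="sym")
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "mixed-model equations are singular; consider blending G"
        ) from e
    return sol[p:]


def gebv_backsolve(
    y: np.ndarray,
    g: GRM,
    train_ids: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    X: np.ndarray | None = None,
) -> np.ndarray:
    """GEBVs via the covariance form u_hat = su2 * G[:, t] V^-1 (y - X b_gls).

    Algebraically identical to :func:`gebv_blup` (exact arithmetic) but only
    needs V = su2 G_tt + se2 I to be invertible, never G itself.
    """
    y = np.asarray(y, dtype=np.float64)
    rows = g.rows_for(np.asarray(train_ids))
    n_t = len(rows)
    if X is None:
        X = np.ones((n_t, 1))
    V = sigma_u2 * g.values[np.ix_(rows, rows)] + sigma_e2 * np.eye(n_t)
    cf = sla.cho_factor(V)
    vinv_x = sla.cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ vinv_x, vinv_x.T @ y)
    resid = y - X @ beta
    vinv_r = sla.cho_solve(cf, resid)
    return sigma_u2 * (g.values[:, rows] @ vinv_r)


def evaluate(tbv: np.ndarray, gebv: np.ndarray) -> EvaluationResult:
    """Accuracy (Pearson r) and the OLS regression of GEBV on TBV."""
    tbv = np.asarray(tbv, dtype=np.float64)
    gebv = np.asarray(gebv, dtype=np.float64)
    if len(tbv) != len(gebv):
        raise ValueError("TBV and GEBV lengths differ")
    if len(tbv) < 3:
        raise ValueError("need at least 3 individuals to evaluate")
    if np.std(tbv) == 0 or np.std(gebv) == 0:
        raise ValueError("zero-variance input; accuracy undefined")
    r = stats.pearsonr(tbv, gebv)
    reg = stats.linregress(tbv, gebv)
    return EvaluationResult(
        accuracy=float(r.statistic),
        intercept=float(reg.intercept),
        slope=float(reg.slope),
        n=len(tbv),
    )
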