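"""Basis pursuit denoising in constrained form.

Solves, for a test block ``y`` and dictionary ``D``,

    min ||x||_1   subject to   ||y - D x||_2 <= epsilon.

The production solver (:func:`bpdn_solve`) follows the residual-penalty
path: it solves the Lagrangian lasso sub-problem ``min 1/2||y - Dx||^2 +
lam*||x||_1`` by coordinate descent and bisects the penalty ``lam`` until
the residual meets the noise margin from below.  The residual norm is a
continuous non-decreasing function of the penalty, so bisection converges;
at the L1 optimum of the constrained problem the residual constraint is
active whenever ``||y||_2 > epsilon``.

:func:`bpdn_oracle` is an independent reference used only in tests: it
solves the same convex program directly with sequential quadratic
programming on the split variables ``x = u - v`` (``u, v >= 0``), or the
exact basis-pursuit linear program when ``epsilon = 0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, minimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lars_path

log = logging.getLogger(__name__)

#: relative slack allowed on the residual constraint of a converged code
TOL_FEAS = 1e-6
#: bisection stops once the residual is within this relative band below epsilon
_BISECT_BAND = 1e-5
_MAX_BISECT = 200
#: coordinate-descent settings for the lasso sub-problems; the duality-gap
#: tolerance is far below the 1e-3 relative agreement the solver guarantees
_LASSO_TOL = 1e-8
_LASSO_MAX_ITER = 20_000


@dataclass
class SparseCode:
    """Solution of one BPDN instance.

    coefficients  : one entry per atom
    epsilon       : the noise margin the instance was solved with
    residual_norm : ||y - D x||_2 at the returned coefficients
    l1_norm       : sum |x_i|
    status        : 'converged', 'infeasible' or 'max_iter'
    """

    coefficients: np.ndarray
    epsilon: float
    residual_norm: float
    l1_norm: float
    status: str

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def _check_instance(y: np.ndarray, D: np.ndarray, epsilon: float):
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[1] == 0:
        raise ValueError("D must be a nonempty 2-D matrix")
    if y.shape[0] != D.shape[0]:
        raise ValueError(f"block length {y.shape[0]} does not match dictionary "
                         f"row count {D.shape[0]}")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return y, D, float(epsilon)


def _code(x: np.ndarray, y: np.ndarray, D: np.ndarray, epsilon: float,
          status: str) -> SparseCode:
    return SparseCode(x, epsilon, float(np.linalg.norm(y - D @ x)),
                      float(np.abs(x).sum()), status)


def _lasso_path_solve(y, D, epsilon) -> SparseCode:
    s, M = D.shape
    normy = np.linalg.norm(y)
    # sklearn Lasso objective: 1/(2 n) ||y - Dx||^2 + alpha ||x||_1, n = s
    alpha_max = np.max(np.abs(D.T @ y)) / s
    if alpha_max == 0:  # D^T y = 0: x = 0 is optimal for every penalty
        status = "converged" if normy <= epsilon * (1 + TOL_FEAS) else "infeasible"
        return _code(np.zeros(M), y, D, epsilon, status)
    model = Lasso(alpha=alpha_max, fit_intercept=False, warm_start=True,
                  max_iter=_LASSO_MAX_ITER, tol=_LASSO_TOL)

    def lasso_at(alpha: float) -> np.ndarray:
        model.alpha = alpha
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(D, y)
        return model.coef_.copy()

    # find a lower penalty whose residual is within the margin
    lo = alpha_max
    x_lo = np.zeros(M)
    best = (normy, x_lo)
    for _ in range(_MAX_BISECT):
        lo /= 4.0
        x_lo = lasso_at(lo)
        r = np.linalg.norm(y - D @ x_lo)
        if r < best[0]:
            best = (r, x_lo)
        if r <= epsilon:
            break
        if lo < 1e-18 * alpha_max:
            # the margin is below the attainable residual: infeasible
            status = "infeasible" if best[0] > epsilon * (1 + TOL_FEAS) else "converged"
            log.debug("bpdn: penalty path exhausted, best residual %.3e vs "
                      "epsilon %.3e", best[0], epsilon)
            return _code(best[1], y, D, epsilon, status)
    else:  # pragma: no cover - loop always breaks or returns
        return _code(best[1], y, D, epsilon, "max_iter")

    hi = lo * 4.0  # residual(hi) > epsilon >= residual(lo)
    x = x_lo
    for _ in range(_MAX_BISECT):
        r_lo = np.linalg.norm(y - D @ x)
        if r_lo >= epsilon * (1.0 - _BISECT_BAND):
            break
        mid = np.sqrt(lo * hi)
        x_mid = lasso_at(mid)
        if np.linalg.norm(y - D @ x_mid) <= epsilon:
            lo, x = mid, x_mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-14:
            break
    # x is the solution at the feasible endpoint lo (saved, not refit: a
    # refit can drift marginally across the band and must not discard it)
    if np.linalg.norm(y - D @ x) > epsilon * (1 + TOL_FEAS):
        x = best[1] if best[0] <= epsilon else x
    return _code(x, y, D, epsilon, "converged")


def _basis_pursuit_lp(y, D) -> SparseCode:
    """epsilon = 0: min 1^T (u+v) s.t. D(u-v) = y, u,v >= 0."""
    s, M = D.shape
    res = linprog(c=np.ones(2 * M), A_eq=np.hstack([D, -D]), b_eq=y,
                  bounds=[(0, None)] * (2 * M), method="highs")
    if not res.success:
        return _code(np.zeros(M), y, D, 0.0, "infeasible")
    x = res.x[:M] - res.x[M:]
    return _code(x, y, D, 0.0, "converged")


def _lars_path_solve(y, D, epsilon) -> SparseCode | None:
    """Exact path solve: the lasso solution path is piecewise linear in the
    penalty, so the residual norm is piecewise quadratic; the constrained
    optimum sits where the residual first reaches ``epsilon`` and is found
    in closed form within that segment.  Returns None when the path
    computation degenerates (the caller then falls back to bisection)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, coefs = lars_path(D, y, method="lasso", alpha_min=0.0)
    except Exception:  # degenerate Gram / exactly correlated atoms
        return None
    prev = coefs[:, 0]
    r_prev = y - D @ prev
    n_prev = float(np.linalg.norm(r_prev))
    if n_prev <= epsilon:  # alpha_max already feasible (epsilon >= ||y||)
        return _code(prev, y, D, epsilon, "converged")
    for j in range(1, coefs.shape[1]):
        cur = coefs[:, j]
        r_cur = y - D @ cur
        n_cur = float(np.linalg.norm(r_cur))
        if n_cur <= epsilon:
            # interpolate: ||r_prev - theta*(r_prev - r_cur)|| = epsilon
            d = r_prev - r_cur
            a = float(d @ d)
            b = float(r_prev @ d)
            c = n_prev ** 2 - epsilon ** 2
            disc = b * b - a * c
            if a <= 0 or disc < 0:
                theta = 1.0
            else:
                theta = (b - np.sqrt(disc)) / a
                theta = min(max(theta, 0.0), 1.0)
            x = prev + theta * (cur - prev)
            if np.linalg.norm(y - D @ x) > epsilon * (1 + TOL_FEAS):
                x = cur  # knot itself is feasible
            return _code(x, y, D, epsilon, "converged")
        prev, r_prev, n_prev = cur, r_cur, n_cur
    # end of path: residual never reached the margin
    status = "infeasible" if n_prev > epsilon * (1 + TOL_FEAS) else "converged"
    return _code(prev, y, D, epsilon, status)


def bpdn_solve(y: np.ndarray, D: np.ndarray, epsilon: float) -> SparseCode:
    """L1-minimal sparse code of ``y`` against ``D`` at noise margin ``epsilon``.

    Returns ``x = 0`` immediately when ``||y||_2 <= epsilon`` (zero is
    feasible and has minimal L1 norm).  When the margin is unattainable
    (``epsilon`` below the least-squares residual of ``y`` on the column
    space of ``D``) the best iterate found is returned with status
    ``'infeasible'``.
    """
    y, D, epsilon = _check_instance(y, D, epsilon)
    if np.linalg.norm(y) <= epsilon:
        return _code(np.zeros(D.shape[1]), y, D, epsilon, "converged")
    if epsilon == 0.0:
        return _basis_pursuit_lp(y, D)
    code = _lars_path_solve(y, D, epsilon)
    if code is not None and code.status == "converged" and \
            code.residual_norm <= epsilon * (1 + TOL_FEAS):
        return code
    return _lasso_path_solve(y, D, epsilon)


# ---------------------------------------------------------------------------
# Independent oracle (tests only)
# ---------------------------------------------------------------------------

_ORACLE_MAX_ATOMS = 12


def bpdn_oracle(y: np.ndarray, D: np.ndarray, epsilon: float) -> SparseCode:
    """Reference BPDN solution for small instances (M <= 12 atoms).

    Direct constrained convex program on split variables, solved with
    sequential quadratic programming; exact linear program when
    ``epsilon = 0``.  Used exclusively as a cross-check in tests.
    """
    y, D, epsilon = _check_instance(y, D, epsilon)
    s, M = D.shape
    if M > _ORACLE_MAX_ATOMS:
        raise ValueError(f"oracle refuses instances with more than "
                         f"{_ORACLE_MAX_ATOMS} atoms (got {M})")
    if np.linalg.norm(y) <= epsilon:
        return _code(np.zeros(M), y, D, epsilon, "converged")
    if epsilon == 0.0:
        return _basis_pursuit_lp(y, D)

    A = np.hstack([D, -D])  # x = u - v

    def obj(z):
        return z.sum()

    def obj_grad(z):
        return np.ones_like(z)

    def cons(z):
        r = y - A @ z
        return epsilon ** 2 - r @ r

    def cons_grad(z):
        r = y - A @ z
        return 2.0 * (A.T @ r)

    # feasible start: scaled least-squares solution split into (u, v)
    x_ls, *_ = np.linalg.lstsq(D, y, rcond=None)
    z0 = np.concatenate([np.clip(x_ls, 0, None), np.clip(-x_ls, 0, None)])
    best = None
    for start in (z0, np.zeros(2 * M)):
        res = minimize(obj, start, jac=obj_grad, method="SLSQP",
                       bounds=[(0, None)] * (2 * M),
                       constraints=[{"type": "ineq", "fun": cons,
                                     "jac": cons_grad}],
                       options={"maxiter": 2000, "ftol": 1e-14})
        x = res.x[:M] - res.x[M:]
        feas = np.linalg.norm(y - D @ x) <= epsilon * (1 + 1e-7)
        if feas and (best is None or np.abs(x).sum() < best[0]):
            best = (np.abs(x).sum(), x)
    if best is None:
        return _code(x_ls, y, D, epsilon, "infeasible")
    return _code(best[1], y, D, epsilon, "converged")
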