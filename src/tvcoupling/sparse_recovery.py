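"""Row-wise sparse recovery: ADMM basis pursuit and its regularized variant.

Each unknown row of ``M_t = C(t) kron Gamma`` is the sparsest solution of an
underdetermined linear system. With accurate observations the row solves

    min ||x||_1   s.t.   A x = y                    (basis pursuit)

— the convex relaxation of the l0 (sparsest-solution) problem. With noisy
observations the equality constraint is relaxed to a quadratic data-fit
penalty with a regularization weight alpha = alpha(delta) tied to the noise
level delta:

    min  1/2 ||A x - y_delta||^2 + alpha ||x||_1    (regularized)

Both are solved by the alternating direction method of multipliers in
scaled-dual form: an auxiliary vector z carries the l1 term, the x-update is
a projection onto {Ax = y} (basis pursuit) or a damped normal-equation solve
(regularized), the z-update is soft thresholding, and the scaled dual u
accumulates the constraint violation x - z. Because every row of ``M_t`` at
a given time shares the same design matrix, the solvers accept a matrix of
right-hand sides and reuse one factorization across all rows — the key
performance lever for time sweeps.

``l1_oracle`` solves tiny basis-pursuit instances by an independent route
(linear programming via scipy's HiGHS) and exists for cross-validation in
tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linprog

__all__ = [
    "ADMMOptions",
    "ADMMState",
    "SolveReport",
    "soft_threshold",
    "admm_basis_pursuit",
    "admm_basis_pursuit_multi",
    "admm_regularized",
    "admm_regularized_multi",
    "choose_alpha",
    "l1_oracle",
    "RankDeficientError",
]


class RankDeficientError(np.linalg.LinAlgError):
    """A A^T is numerically singular; the equality-constrained projection is
    unavailable. Use the regularized solver instead."""


@dataclass(frozen=True)
class ADMMOptions:
    """Solver controls shared by both ADMM variants.

    rho is the augmented-Lagrangian penalty; alpha the regularization weight
    (regularized problem only); stopping follows the usual primal/dual
    residual rule with absolute + relative tolerances; over_relaxation in
    [1, 2) blends the x-update with the previous z for faster convergence.
    """

    rho: float = 1.0
    alpha: float = 0.0
    tol_abs: float = 1e-6
    tol_rel: float = 1e-4
    max_iter: int = 5000
    over_relaxation: float = 1.5
    adapt_rho: bool = False

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tol_abs <= 0 or self.tol_rel <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (1.0 <= self.over_relaxation < 2.0):
            raise ValueError("over_relaxation must lie in [1, 2)")


#: defaults for the noisy problem (looser, per the coarser attainable accuracy)
REGULARIZED_DEFAULTS = dict(tol_abs=1e-8, tol_rel=1e-6)


@dataclass
class ADMMState:
    """Iterates of one ADMM run (primal x, auxiliary z, scaled dual u)."""

    x: np.ndarray
    z: np.ndarray
    u: np.ndarray
    r_primal: float = np.inf
    r_dual: float = np.inf
    iter: int = 0


@dataclass(frozen=True)
class SolveReport:
    converged: bool
    iterations: int
    r_primal: float
    r_dual: float
    objective: float


def soft_threshold(v: np.ndarray, kappa: float | np.ndarray) -> np.ndarray:
    """Componentwise shrinkage sign(v) * max(|v| - kappa, 0).

    This is the proximal operator of ``kappa * ||.||_1`` — the z-update of
    both ADMM variants. ``kappa`` may broadcast (per-column thresholds).
    """
    if np.any(np.asarray(kappa) < 0):
        raise ValueError("kappa must be >= 0")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - kappa, 0.0)


def _certified_polish(
    A: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    y_scale: float,
    active_tol: float = 1e-3,
) -> Optional[np.ndarray]:
    """Exact basis-pursuit solution from a dual-guessed active set, or None.

    ``g`` is an approximate dual vector in range(A^T); entries with
    ``|g| >= 1 - active_tol`` propose the active set S. The candidate is the
    least-squares fit on S; it is accepted only with an airtight optimality
    certificate: A x = y to 1e-10 relative, and the min-norm dual nu solving
    A_S^T nu = sign(x_S) satisfies ``||A^T nu||_inf <= 1`` (weak duality then
    pins ``||x||_1 = y^T nu`` as the optimum).
    """
    m, q = A.shape
    S = np.flatnonzero(np.abs(g) >= 1.0 - active_tol)
    if S.size == 0 or S.size > m:
        return None
    for _ in range(2):  # one refit round after dropping zero entries
        AS = A[:, S]
        xs, *_ = np.linalg.lstsq(AS, y, rcond=None)
        tiny = np.abs(xs) <= 1e-10 * max(np.abs(xs).max(), 1e-300)
        if not np.any(tiny):
            break
        S = S[~tiny]
        if S.size == 0:
            return None
    if np.linalg.norm(A[:, S] @ xs - y) > 1e-10 * y_scale:
        return None
    s = np.sign(xs)
    nu, *_ = np.linalg.lstsq(A[:, S].T, s, rcond=None)  # min-norm dual
    if np.max(np.abs(A[:, S].T @ nu - s)) > 1e-9:
        return None
    if np.max(np.abs(A.T @ nu)) > 1.0 + 1e-10:
        return None
    out = np.zeros(q)
    out[S] = xs
    return out


def _stack_rhs(y: np.ndarray) -> tuple[np.ndarray, bool]:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return y[:, None], True
    return y, False


def admm_basis_pursuit_multi(
    A: np.ndarray,
    Y: np.ndarray,
    opts: ADMMOptions = ADMMOptions(),
) -> tuple[np.ndarray, list[SolveReport]]:
    """Basis pursuit for many right-hand sides sharing one design matrix.

    ``Y`` is m x R; column j is solved for min ||x||_1 s.t. A x = Y[:, j].
    The projection factorization (Cholesky of A A^T) is computed once.
    Returns the q x R solution matrix and one report per column. The
    returned iterates are the feasible x-iterates, so ``A X = Y`` holds to
    factorization accuracy whether or not a column converged.
    """
    A = np.asarray(A, dtype=float)
    Y, squeeze = _stack_rhs(Y)
    m, q = A.shape
    if Y.shape[0] != m:
        raise ValueError("right-hand side length does not match A")
    R = Y.shape[1]
    try:
        cho = cho_factor(A @ A.T)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(
            "A A^T is singular (A lacks full row rank); the basis-pursuit "
            "projection is undefined — use admm_regularized"
        ) from exc

    At = A.T
    particular = At @ cho_solve(cho, Y)  # min-norm feasible point, (q, R)

    rho = opts.rho
    relax = opts.over_relaxation
    Z = np.zeros((q, R))
    U = np.zeros((q, R))
    sqrtq = np.sqrt(q)
    conv = np.zeros(R, dtype=bool)
    r_pri = np.full(R, np.inf)
    r_dua = np.full(R, np.inf)
    X_out = particular.copy()  # always feasible
    y_scale = 1.0 + np.linalg.norm(Y, axis=0)
    it = 0
    next_check = 25
    X = particular.copy()
    for it in range(1, opts.max_iter + 1):
        V = Z - U
        X = V - At @ cho_solve(cho, A @ V) + particular
        Xh = relax * X + (1.0 - relax) * Z
        Z_old = Z
        Z = soft_threshold(Xh + U, 1.0 / rho)
        U = U + Xh - Z

        r_pri = np.linalg.norm(X - Z, axis=0)
        r_dua = rho * np.linalg.norm(Z - Z_old, axis=0)
        eps_pri = sqrtq * opts.tol_abs + opts.tol_rel * np.maximum(
            np.linalg.norm(X, axis=0), np.linalg.norm(Z, axis=0)
        )
        eps_dua = sqrtq * opts.tol_abs + opts.tol_rel * rho * np.linalg.norm(
            U, axis=0
        )
        res_conv = (r_pri <= eps_pri) & (r_dua <= eps_dua)
        X_out[:, ~conv] = X[:, ~conv]
        conv = conv | res_conv
        # periodic exact-optimality certificate: the scaled dual rho*U tracks
        # an l1 subgradient; project it into range(A^T) to guess the active
        # set, polish by least squares on that support, then verify with the
        # min-norm dual certificate (A_S^T nu = sign(x_S), ||A^T nu||_inf
        # <= 1). When it passes, the polished point is provably the l1
        # minimizer — this terminates long before the slow ADMM tail meets
        # the residual tolerances.
        if it == next_check and not np.all(conv):
            next_check *= 2
            G = rho * U
            Nu = cho_solve(cho, A @ G)
            Gt = At @ Nu
            # only plausibly-sparse active sets are worth polishing; data
            # inconsistent with any sparse model (dense optimal supports)
            # cannot be certified and would waste a least-squares solve
            size_cap = min(m, max(16, m // 2))
            for j in np.flatnonzero(~conv):
                if np.count_nonzero(np.abs(Gt[:, j]) >= 1.0 - 1e-3) > size_cap:
                    continue
                xs_full = _certified_polish(A, Y[:, j], Gt[:, j], y_scale[j])
                if xs_full is not None:
                    X_out[:, j] = xs_full
                    conv[j] = True
        if np.all(conv):
            break
        if opts.adapt_rho:
            mp, md = float(np.max(r_pri)), float(np.max(r_dua))
            if mp > 10.0 * md:
                rho *= 2.0
                U /= 2.0
            elif md > 10.0 * mp:
                rho /= 2.0
                U *= 2.0

    reports = [
        SolveReport(
            converged=bool(conv[j]),
            iterations=it,
            r_primal=float(r_pri[j]),
            r_dual=float(r_dua[j]),
            objective=float(np.abs(X_out[:, j]).sum()),
        )
        for j in range(R)
    ]
    if squeeze:
        return X_out[:, 0], reports
    return X_out, reports


def admm_basis_pursuit(
    A: np.ndarray, y: np.ndarray, opts: ADMMOptions = ADMMOptions()
) -> tuple[np.ndarray, SolveReport]:
    """min ||x||_1 subject to A x = y, by scaled-dual ADMM."""
    x, reports = admm_basis_pursuit_multi(A, y, opts)
    return x, reports[0]


def admm_regularized_multi(
    A: np.ndarray,
    Y: np.ndarray,
    opts: ADMMOptions,
    alpha: float | np.ndarray | None = None,
) -> tuple[np.ndarray, list[SolveReport]]:
    """Regularized recovery min 1/2 ||Ax - y||^2 + alpha ||x||_1, many RHS.

    ``alpha`` may be a scalar or a per-column vector (the x-update does not
    depend on alpha, so columns with different regularization still share
    the single cached factorization of A^T A + rho I).
    """
    A = np.asarray(A, dtype=float)
    Y, squeeze = _stack_rhs(Y)
    alpha = opts.alpha if alpha is None else alpha
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0 (use admm_basis_pursuit when noiseless)")
    m, q = A.shape
    R = Y.shape[1]
    rho = opts.rho
    relax = opts.over_relaxation
    cho = cho_factor(A.T @ A + rho * np.eye(q))
    Aty = A.T @ Y
    kappa = np.broadcast_to(np.atleast_1d(alpha / rho), (R,))

    Z = np.zeros((q, R))
    U = np.zeros((q, R))
    sqrtq = np.sqrt(q)
    conv = np.zeros(R, dtype=bool)
    r_pri = np.full(R, np.inf)
    r_dua = np.full(R, np.inf)
    it = 0
    X = np.zeros((q, R))
    for it in range(1, opts.max_iter + 1):
        X = cho_solve(cho, Aty + rho * (Z - U))
        Xh = relax * X + (1.0 - relax) * Z
        Z_old = Z
        Z = soft_threshold(Xh + U, kappa)
        U = U + Xh - Z

        r_pri = np.linalg.norm(X - Z, axis=0)
        r_dua = rho * np.linalg.norm(Z - Z_old, axis=0)
        eps_pri = sqrtq * opts.tol_abs + opts.tol_rel * np.maximum(
            np.linalg.norm(X, axis=0), np.linalg.norm(Z, axis=0)
        )
        eps_dua = sqrtq * opts.tol_abs + opts.tol_rel * rho * np.linalg.norm(
            U, axis=0
        )
        conv = (r_pri <= eps_pri) & (r_dua <= eps_dua)
        if np.all(conv):
            break

    resid = np.linalg.norm(A @ Z - Y, axis=0)
    alphas = np.broadcast_to(np.atleast_1d(alpha), (R,))
    reports = [
        SolveReport(
            converged=bool(conv[j]),
            iterations=it,
            r_primal=float(r_pri[j]),
            r_dual=float(r_dua[j]),
            objective=float(
                0.5 * resid[j] ** 2 + alphas[j] * np.abs(Z[:, j]).sum()
            ),
        )
        for j in range(R)
    ]
    if squeeze:
        return Z[:, 0], reports
    return Z, reports


def admm_regularized(
    A: np.ndarray,
    y_delta: np.ndarray,
    opts: ADMMOptions | None = None,
    alpha: float | None = None,
) -> tuple[np.ndarray, SolveReport]:
    """min 1/2 ||A x - y_delta||^2 + alpha ||x||_1, by scaled-dual ADMM.

    The sparse z-iterate is returned (exact zeros on the inactive set).
    """
    if opts is None:
        opts = ADMMOptions(**REGULARIZED_DEFAULTS)
    x, reports = admm_regularized_multi(A, y_delta, opts, alpha=alpha)
    return x, reports[0]


def choose_alpha(
    A: np.ndarray,
    y_delta: np.ndarray,
    delta: float,
    strategy: str = "discrepancy",
    tau: float = 1.1,
    c: float = 1.0,
    opts: ADMMOptions | None = None,
    grid_size: int = 25,
) -> float:
    """Pick the regularization weight alpha from the noise level delta.

    "discrepancy" (Morozov principle): largest alpha on a geometric grid
    whose solution keeps the data-fit residual ||A x - y|| within
    tau * delta * sqrt(m) — i.e. regularize as hard as the noise allows, no
    harder. "fixed": alpha = c * delta.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if strategy == "fixed":
        return c * delta
    if strategy != "discrepancy":
        raise ValueError(f"unknown strategy {strategy!r}")
    if delta == 0:
        raise ValueError(
            "discrepancy principle needs delta > 0; use basis pursuit for "
            "noiseless data"
        )
    if opts is None:
        opts = ADMMOptions(**REGULARIZED_DEFAULTS)
    A = np.asarray(A, dtype=float)
    y = np.asarray(y_delta, dtype=float)
    m = A.shape[0]
    bound = tau * delta * np.sqrt(m)
    if np.linalg.norm(y) <= bound:
        # even x = 0 already fits to the noise level
        return float(np.max(np.abs(A.T @ y))) if np.any(y) else c * delta
    alpha_max = float(np.max(np.abs(A.T @ y)))
    grid = alpha_max * np.geomspace(1.0, 1e-5, grid_size)
    for a in grid:  # large -> small: first alpha fitting the noise wins
        x, _ = admm_regularized(A, y, opts, alpha=float(a))
        if np.linalg.norm(A @ x - y) <= bound:
            return float(a)
    return float(grid[-1])


def l1_oracle(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent small-scale basis-pursuit reference (linear programming).

    Splits x into positive and negative parts and solves the equivalent LP
    with scipy's HiGHS simplex/IPM. Test-only cross-check for the ADMM path;
    restricted to small systems.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    m, q = A.shape
    if q > 32:
        raise ValueError("l1_oracle is a small-scale reference (q <= 32)")
    res = linprog(
        c=np.ones(2 * q),
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=[(0, None)] * (2 * q),
        method="highs",
    )
    if not res.success:
        raise ValueError(f"LP oracle failed: {res.message}")
    return res.x[:q] - res.x[q:]
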