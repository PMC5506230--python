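"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the SVR oracle solves
the box-constrained dual quadratic program directly with a generic NLP solver
plus an exact KKT active-set polish, and the spectral helpers use plain
direct-summation definitions.
"""
from __future__ import annotations

import numpy as np
from scipy import optimize


def kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str,
                  gamma: float | None = None) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    sq = (np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def svr_dual_solve(K: np.ndarray, y: np.ndarray, C: float, epsilon: float
                   ) -> tuple[np.ndarray, float]:
    """Solve the epsilon-SVR dual for coefficients u = alpha - alpha*.

    maximize  -1/2 u'Ku + y'u - epsilon * sum |u|
    s.t.      sum u = 0,  -C <= u_i <= C

    Returns (u, b).  Uses SLSQP on the split alpha/alpha* formulation, then
    polishes the free coordinates by solving the exact KKT linear system on
    the identified active set.
    """
    n = len(y)

    def neg_dual(z):
        a, a_star = z[:n], z[n:]
        u = a - a_star
        return float(0.5 * u @ K @ u - y @ u + epsilon * (a + a_star).sum())

    def neg_dual_grad(z):
        a, a_star = z[:n], z[n:]
        u = a - a_star
        ku = K @ u
        return np.concatenate([ku - y + epsilon, -ku + y + epsilon])

    cons = {"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:]),
            "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}
    bounds = [(0.0, C)] * (2 * n)
    rng = np.random.default_rng(0)
    starts = [np.zeros(2 * n), np.full(2 * n, C / 4)]
    starts += [rng.uniform(0, C, 2 * n) for _ in range(4)]
    def dual_val(v):
        return float(-0.5 * v @ K @ v + y @ v - epsilon * np.abs(v).sum())
    best_u, best_val = None, -np.inf
    for start in starts:
        res = optimize.minimize(neg_dual, start, jac=neg_dual_grad,
                                bounds=bounds, constraints=[cons],
                                method="SLSQP",
                                options={"maxiter": 2000, "ftol": 1e-14})
        u = res.x[:n] - res.x[n:]
        u = _active_set_refine(K, y, C, epsilon, u)
        if dual_val(u) > best_val:
            best_u, best_val = u, dual_val(u)
    u = best_u
    # b minimizes the primal given u (convex piecewise-linear in b); the
    # KKT-interval intercept can sit at a point with a duality gap when
    # every dual coordinate is at a bound
    f_no_b = K @ u

    def primal_b(b):
        return C * np.maximum(np.abs(y - f_no_b - b) - epsilon, 0.0).sum()

    res = optimize.minimize_scalar(primal_b, bounds=(y.min() - 10, y.max() + 10),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    b = float(res.x)
    return u, b


def _active_set_refine(K, y, C, epsilon, u0, max_iter=200):
    """Exact active-set refinement of the dual from a warm start.

    Coordinate classes: free+ (0 < u < C, stationarity h_i = eps), free-
    (-C < u < 0, h_i = -eps), zero (|h_i| <= eps), at +C (h_i >= eps),
    at -C (h_i <= -eps), where h = y - Ku - b.  Solves the equality system
    for the free coordinates, clips infeasible ones to their nearest bound,
    and releases the worst KKT violator among the fixed ones until the KKT
    conditions hold.
    """
    n = len(y)
    tol = max(C * 1e-9, 1e-12)
    # class per coordinate: +1 free+, -1 free-, 0 zero, +2 at +C, -2 at -C
    cls = np.zeros(n, dtype=int)
    for i in range(n):
        if u0[i] > C - C * 1e-6:
            cls[i] = 2
        elif u0[i] < -C + C * 1e-6:
            cls[i] = -2
        elif u0[i] > C * 1e-6:
            cls[i] = 1
        elif u0[i] < -C * 1e-6:
            cls[i] = -1
    best_u = u0.copy()

    def dual_val(v):
        return float(-0.5 * v @ K @ v + y @ v - epsilon * np.abs(v).sum())

    for _ in range(max_iter):
        free = np.abs(cls) == 1
        fixed_val = np.where(cls == 2, C, np.where(cls == -2, -C, 0.0))
        idx = np.flatnonzero(free)
        u = fixed_val.copy()
        if len(idx):
            nf = len(idx)
            A = np.zeros((nf + 1, nf + 1))
            rhs = np.zeros(nf + 1)
            A[:nf, :nf] = K[np.ix_(idx, idx)]
            A[:nf, nf] = 1.0
            A[nf, :nf] = 1.0
            rhs[:nf] = (y[idx] - epsilon * np.sign(cls[idx])
                        - K[np.ix_(idx, np.flatnonzero(~free))]
                        @ fixed_val[~free])
            rhs[nf] = -fixed_val[~free].sum()
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                break
            u[idx] = sol[:nf]
            b = float(sol[nf])
            # clip free coordinates that left their feasible interval
            moved = False
            for k, i in enumerate(idx):
                lo, hi = (0.0, C) if cls[i] == 1 else (-C, 0.0)
                if u[i] > hi + tol:
                    cls[i] = 2 if cls[i] == 1 else 0
                    moved = True
                elif u[i] < lo - tol:
                    cls[i] = 0 if cls[i] == 1 else -2
                    moved = True
            if moved:
                continue
        else:
            # b from the KKT interval of the fixed coordinates
            b = _intercept(K, y, C, epsilon, u)
        if dual_val(u) > dual_val(best_u):
            best_u = u.copy()
        # release the worst violator among fixed coordinates
        h = y - K @ u - b
        worst, worst_viol = -1, tol * 10
        for i in np.flatnonzero(~free):
            if cls[i] == 0:
                viol = abs(h[i]) - epsilon
                if viol > worst_viol:
                    worst, worst_viol = i, viol
            elif cls[i] == 2 and epsilon - h[i] > worst_viol:
                worst, worst_viol = i, epsilon - h[i]
            elif cls[i] == -2 and h[i] + epsilon > worst_viol:
                worst, worst_viol = i, h[i] + epsilon
        if worst < 0:
            best_u = u.copy()
            break
        if cls[worst] == 0:
            cls[worst] = 1 if h[worst] > 0 else -1
        else:
            cls[worst] = int(np.sign(cls[worst]))
    return best_u


def _kkt_polish(K, y, C, epsilon, u, tol_frac=1e-5):
    """Re-solve exactly for the free (interior) dual coordinates.

    At the optimum, for free u_i > 0: (Ku)_i + b = y_i - epsilon, and for
    free u_i < 0: (Ku)_i + b = y_i + epsilon.  Fixing the bound-active
    coordinates at +-C and solving the resulting linear system in the free
    u's and b removes the NLP solver's residual error.
    """
    tol = C * tol_frac
    at_upper = u > C - tol
    at_lower = u < -C + tol
    zero = np.abs(u) < tol
    free = ~(at_upper | at_lower | zero)
    if not free.any():
        return u
    sign = np.sign(u)
    u_fixed = np.where(at_upper, C, np.where(at_lower, -C, 0.0))
    idx = np.flatnonzero(free)
    nf = len(idx)
    # unknowns: u_free (nf) and b; equations: KKT stationarity on free coords
    # plus the equality constraint sum u = 0
    A = np.zeros((nf + 1, nf + 1))
    rhs = np.zeros(nf + 1)
    A[:nf, :nf] = K[np.ix_(idx, idx)]
    A[:nf, nf] = 1.0
    A[nf, :nf] = 1.0
    rhs[:nf] = (y[idx] - epsilon * sign[idx]
                - K[np.ix_(idx, np.flatnonzero(~free))] @ u_fixed[~free])
    rhs[nf] = -u_fixed[~free].sum()
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return u
    u_new = u_fixed.copy()
    u_new[idx] = sol[:nf]
    # accept the polish only if it stays feasible and does not worsen the dual
    if (np.abs(u_new) > C + 1e-12).any():
        return u
    def dual_val(v):
        return -0.5 * v @ K @ v + y @ v - epsilon * np.abs(v).sum()
    return u_new if dual_val(u_new) >= dual_val(u) - 1e-12 else u


def _intercept(K, y, C, epsilon, u, tol_frac=1e-6):
    tol = C * tol_frac
    free = (np.abs(u) > tol) & (np.abs(u) < C - tol)
    ku = K @ u
    if free.any():
        b = y[free] - ku[free] - epsilon * np.sign(u[free])
        return float(b.mean())
    # no free vectors: b is any value in the feasible interval; take midpoint
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        f_no_b = ku[i]
        if u[i] < C - tol:   # alpha_i can grow -> y_i - f - b <= epsilon
            lo = max(lo, y[i] - f_no_b - epsilon)
        if u[i] > -C + tol:  # alpha*_i can grow -> f + b - y_i <= epsilon
            hi = min(hi, y[i] - f_no_b + epsilon)
    if not np.isfinite(lo):
        lo = hi
    if not np.isfinite(hi):
        hi = lo
    return float((lo + hi) / 2.0)


def svr_primal_objective(K: np.ndarray, y: np.ndarray, C: float,
                         epsilon: float, u: np.ndarray, b: float) -> float:
    """C sum V_eps(y - f) + 1/2 ||beta||^2 with f = Ku + b in kernel space."""
    f = K @ u + b
    loss = np.maximum(np.abs(y - f) - epsilon, 0.0).sum()
    return float(C * loss + 0.5 * u @ K @ u)


def pearson_abs(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook |Pearson r| by direct summation."""
    n = len(y)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return abs(float(num / den))


def dft_power_direct(x: np.ndarray) -> np.ndarray:
    """|X_k|^2 for k = 0..N-1 by direct DFT summation (slow, tiny N only)."""
    n = len(x)
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return np.abs(W @ x) ** 2
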