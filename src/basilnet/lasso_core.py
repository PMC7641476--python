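"""In-memory warm-started elastic-net solver on a strong set.

Minimizes, for each lambda on a decreasing grid,

    f(beta) + lambda * sum_j c_j * ( alpha*|beta_j| + (1-alpha)*beta_j^2 / 2 )

where f is the family loss (see :mod:`basilnet.families`), c_j are
per-column penalty factors (0 for adjustment covariates, which are never
thresholded), and an unpenalized intercept is always present except for the
Cox family, whose partial likelihood is invariant to location shifts.

The Gaussian problem is solved by cyclic coordinate descent with an
active-set strategy (full sweep, then iterate on the nonzero coordinates
until stable, then re-check with a full sweep).  Binomial and Cox losses
are handled by an outer quadratic-approximation loop — iteratively
reweighted least squares around the current linear predictor, with
step-halving whenever the penalized objective would increase — and the same
weighted coordinate-descent kernel on the quadratic surrogate.

Columns are used as-is (no standardization by default): dosages already
share the 0..2 scale, and dividing by per-variant standard deviations would
silently up-weight rare variants in the selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize

from . import families as fam
from .errors import CollinearityError, DegenerateResponseError

__all__ = [
    "PenaltySpec",
    "FitResult",
    "CovariateFit",
    "soft_threshold",
    "fit_path_on_strong_set",
    "covariate_only_fit",
    "relaxed_refit",
]


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty configuration for one path fit.

    alpha_mix is the l1 proportion (1.0 = lasso); lambda_values must be
    strictly decreasing; penalty_factor defaults to all-ones over the
    penalized columns.
    """

    lambda_values: np.ndarray
    alpha_mix: float = 1.0
    penalty_factor: np.ndarray | None = None
    standardize: bool = False

    def __post_init__(self):
        lam = np.asarray(self.lambda_values, dtype=np.float64)
        object.__setattr__(self, "lambda_values", lam)
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("lambda_values must be a non-empty 1-d sequence")
        if np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
            raise ValueError("lambda_values must be positive and strictly decreasing")
        if not 0.0 < self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must lie in (0, 1]")
        if self.penalty_factor is not None:
            pf = np.asarray(self.penalty_factor, dtype=np.float64)
            object.__setattr__(self, "penalty_factor", pf)
            if np.any(pf < 0):
                raise ValueError("penalty factors must be nonnegative")
            if not np.any(pf > 0):
                raise ValueError("at least one penalty factor must be positive")


@dataclass
class FitResult:
    """Solution of a path fit on one strong set.

    coefficients is (n_strong_columns x n_lambda); covariate_coefficients is
    (q x n_lambda); objective holds the penalized objective at the returned
    solution; objective_traces logs the per-sweep surrogate objective for
    each lambda (non-increasing within each inner solve).
    """

    coefficients: np.ndarray
    covariate_coefficients: np.ndarray
    intercept: np.ndarray
    linear_predictor: np.ndarray
    converged: np.ndarray
    objective: np.ndarray
    objective_traces: list = field(default_factory=list)


@dataclass
class CovariateFit:
    """Unpenalized fit of the family model on (intercept, covariates)."""

    coefficients: np.ndarray   # covariate coefficients (q,)
    intercept: float
    eta: np.ndarray            # linear predictor at the fit
    residual: np.ndarray       # family residual r^(0) at the fit


def soft_threshold(z, gamma):
    """sign(z) * max(|z| - gamma, 0); the scalar lasso proximal map."""
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


# ---------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------


@njit(cache=True)
def _weighted_sweep(D, w, r, coef, xv, l1, l2, active_only, use_intercept, b0, wsum):
    """One cyclic coordinate-descent sweep; returns (new b0, max abs change)."""
    n, P = D.shape
    maxc = 0.0
    if use_intercept:
        delta = 0.0
        for i in range(n):
            delta += w[i] * r[i]
        delta /= wsum
        b0 += delta
        for i in range(n):
            r[i] -= delta
        ad = abs(delta)
        if ad > maxc:
            maxc = ad
    for j in range(P):
        bj = coef[j]
        if active_only and bj == 0.0 and l1[j] > 0.0:
            continue
        denom = xv[j] + l2[j]
        if denom <= 0.0:
            continue  # zero-variance penalized column stays at 0
        s = 0.0
        for i in range(n):
            s += w[i] * D[i, j] * r[i]
        num = s + xv[j] * bj
        # tie guard: float roundoff in the working response must not flip a
        # variable active when its gradient sits exactly at the threshold
        thr = l1[j] + 1e-12 * l1[j] + 1e-15
        if num > thr:
            new = (num - l1[j]) / denom
        elif num < -thr:
            new = (num + l1[j]) / denom
        else:
            new = 0.0
        d = new - bj
        if d != 0.0:
            coef[j] = new
            for i in range(n):
                r[i] -= d * D[i, j]
            ad = abs(d)
            if ad > maxc:
                maxc = ad
    return b0, maxc


@njit(cache=True)
def _surrogate_objective(w, r, coef, l1, l2):
    n = r.shape[0]
    P = coef.shape[0]
    obj = 0.0
    for i in range(n):
        obj += 0.5 * w[i] * r[i] * r[i]
    for j in range(P):
        obj += l1[j] * abs(coef[j]) + 0.5 * l2[j] * coef[j] * coef[j]
    return obj


@njit(cache=True)
def _enet_cd(D, w, r, coef, xv, l1, l2, use_intercept, b0, tol, max_sweeps, trace):
    """Weighted elastic-net coordinate descent with an active-set strategy.

    Minimizes 0.5*sum_i w_i (r_i)^2 + sum_j l1_j |coef_j| + 0.5*l2_j coef_j^2
    where r is maintained as the working residual.  trace (len >= max_sweeps)
    receives the surrogate objective after every sweep.  Returns
    (b0, sweeps_used, converged flag, trace length).
    """
    wsum = w.sum()
    sweeps = 0
    n_trace = 0
    converged = False
    while sweeps < max_sweeps:
        b0, maxc = _weighted_sweep(D, w, r, coef, xv, l1, l2, False, use_intercept, b0, wsum)
        trace[n_trace] = _surrogate_objective(w, r, coef, l1, l2)
        n_trace += 1
        sweeps += 1
        if maxc < tol:
            converged = True
            break
        while sweeps < max_sweeps:
            b0, maxc = _weighted_sweep(D, w, r, coef, xv, l1, l2, True, use_intercept, b0, wsum)
            trace[n_trace] = _surrogate_objective(w, r, coef, l1, l2)
            n_trace += 1
            sweeps += 1
            if maxc < tol:
                break
    return b0, sweeps, converged, n_trace


MAX_SWEEPS = 10_000
SWEEPS_PER_ROUND = 200
MAX_ROUNDS = 50
MAX_OUTER = 50
MAX_OUTER_COX = 20
FISTA_MAX_ITER = 600


def _fista_refine(D, response, family, coef, l1, l2, max_iter=FISTA_MAX_ITER,
                  rel_tol=1e-7):
    """Accelerated proximal-gradient refinement on the true objective.

    Used for the Cox family, whose diagonal-Hessian surrogate converges
    only linearly along near-flat directions of the partial likelihood.
    Backtracking line search on the smooth part, adaptive restart.  Returns
    (coef, achieved relative KKT error).
    """
    x = coef.copy()
    yk = coef.copy()
    tk = 1.0
    h = fam.cox_hessian_diag(response, D @ x)
    col_norms = np.einsum("ij,ij->j", D, D)
    L = max(float(h.max() * col_norms.max()), 1e-8)
    lam_scale = max(float(l1[l1 > 0].min()), 1e-300) if np.any(l1 > 0) else 1.0

    def smooth(c):
        eta = D @ c
        return fam.loss(family, response, eta) + 0.5 * float(np.dot(l2 * c, c))

    def smooth_grad(c):
        return D.T @ fam.gradient_vector(family, response, D @ c) + l2 * c

    def kkt_err(c):
        g = smooth_grad(c)
        act = c != 0.0
        pen = l1 > 0.0
        e = 0.0
        m_in = ~act & pen
        if m_in.any():
            e = max(e, float(np.max(np.abs(g[m_in]) - l1[m_in])))
        m_ac = act & pen
        if m_ac.any():
            e = max(e, float(np.max(np.abs(g[m_ac] + l1[m_ac] * np.sign(c[m_ac])))))
        m_un = ~pen
        if m_un.any():
            e = max(e, float(np.max(np.abs(g[m_un]))))
        return e / lam_scale

    f_prev = smooth(x) + float(np.dot(l1, np.abs(x)))
    err = kkt_err(x)
    for it in range(max_iter):
        if err <= rel_tol:
            break
        g = smooth_grad(yk)
        f_y = smooth(yk)
        for _ in range(60):
            step = yk - g / L
            xn = np.sign(step) * np.maximum(np.abs(step) - l1 / L, 0.0)
            d = xn - yk
            if smooth(xn) <= f_y + float(g @ d) + 0.5 * L * float(d @ d) + 1e-15:
                break
            L *= 2.0
        f_new = smooth(xn) + float(np.dot(l1, np.abs(xn)))
        if f_new > f_prev:       # adaptive restart
            yk = x.copy()
            tk = 1.0
            continue
        tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        yk = xn + ((tk - 1.0) / tn) * (xn - x)
        x, tk, f_prev = xn, tn, f_new
        L = max(L * 0.5, 1e-8)   # allow step growth
        if it % 20 == 19:
            err = kkt_err(x)
    return x, kkt_err(x)


# ---------------------------------------------------------------------
# family-specific working responses
# ---------------------------------------------------------------------

_WEIGHT_FLOOR = 1e-5


def _working_response(family: fam.FamilySpec, response, eta: np.ndarray):
    """Weights w and working response z for the quadratic surrogate at eta.

    The surrogate 0.5*sum_i w_i (z_i - eta_i)^2 matches the family loss to
    second order; for the Gaussian it is the loss itself.
    """
    n = eta.shape[0]
    if family.name == "gaussian":
        w = np.full(n, 1.0 / n)
        z = np.asarray(response, dtype=np.float64)
    elif family.name == "binomial":
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        pq = np.maximum(p * (1.0 - p), _WEIGHT_FLOOR)
        w = pq / n
        z = eta + (np.asarray(response, dtype=np.float64) - p) / pq
    else:  # cox
        g = fam.cox_residual(response, eta)
        h = fam.cox_hessian_diag(response, eta)
        h = np.maximum(h, _WEIGHT_FLOOR / n)
        w = h
        z = eta - g / h
    return w, z


def _penalized_objective(family, response, eta, coef_pen, lam, alpha, pf):
    pen = lam * np.sum(pf * (alpha * np.abs(coef_pen) + 0.5 * (1 - alpha) * coef_pen**2))
    return fam.loss(family, response, eta) + pen


# ---------------------------------------------------------------------
# single-lambda weighted solver: CD for support discovery + exact polish
# ---------------------------------------------------------------------

def _polish_on_support(D, w, z, coef, b0, l1, l2, use_intercept):
    """Solve the stationarity system exactly on the current support.

    With the active set and signs fixed, the elastic-net optimum satisfies
    (D_A' W D_A + diag(l2_A)) b = D_A' W (z - b0) - l1_A * sign(b), a small
    dense system.  Coordinates whose solved value flips sign are dropped and
    the system re-solved (a few times).  Returns (coef, b0, True) on success
    or the inputs unchanged with False when no consistent sign pattern is
    found; the caller falls back to more coordinate descent.
    """
    P = coef.shape[0]
    support = np.nonzero((coef != 0.0) | (l1 == 0.0))[0]
    for _ in range(6):
        k = support.size
        n_cols = k + (1 if use_intercept else 0)
        if n_cols == 0:
            return coef, b0, True
        if use_intercept:
            A = np.empty((D.shape[0], n_cols))
            A[:, 0] = 1.0
            A[:, 1:] = D[:, support]
        else:
            A = D[:, support]
        s = np.sign(coef[support])
        s[l1[support] == 0.0] = 0.0
        Aw = A * w[:, None]
        G = A.T @ Aw
        if k:
            off = 1 if use_intercept else 0
            G[np.arange(off, n_cols), np.arange(off, n_cols)] += l2[support]
        rhs = Aw.T @ z
        if use_intercept:
            rhs[1:] -= l1[support] * s
        else:
            rhs -= l1[support] * s
        try:
            sol = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(G, rhs, rcond=None)
        b_act = sol[1:] if use_intercept else sol
        flipped = (np.sign(b_act) != s) & (l1[support] > 0.0) & (b_act != 0.0)
        if not flipped.any():
            new_coef = np.zeros(P)
            new_coef[support] = b_act
            new_b0 = float(sol[0]) if use_intercept else b0
            return new_coef, new_b0, True
        support = support[~flipped]
    return coef, b0, False


def _weighted_enet_solve(D, w, z, coef, b0, xv, l1, l2, use_intercept, tol, traces):
    """Minimize 0.5 sum w_i (z_i - b0 - D coef)_i^2 + penalty to high precision.

    Alternates short coordinate-descent runs (support discovery) with exact
    solves on the discovered support, until the full in-memory KKT residual
    is at float resolution.  Returns (coef, b0, converged, sweeps_used).
    """
    trace_buf = np.empty(SWEEPS_PER_ROUND)
    total_sweeps = 0
    kkt_eps = 1e-11 * max(float(np.max(l1)), 1.0) + 1e-12
    for _ in range(MAX_ROUNDS):
        r = z - b0 - D @ coef
        budget = min(SWEEPS_PER_ROUND, MAX_SWEEPS - total_sweeps)
        if budget <= 0:
            return coef, b0, False, total_sweeps
        b0, sweeps, cd_ok, n_tr = _enet_cd(
            D, w, r, coef, xv, l1, l2, use_intercept, b0, tol, budget, trace_buf
        )
        traces.append(trace_buf[:n_tr].copy())
        total_sweeps += sweeps
        coef_p, b0_p, ok = _polish_on_support(D, w, z, coef, b0, l1, l2, use_intercept)
        if ok:
            coef, b0 = coef_p, b0_p
        # exact in-memory KKT residual at the (possibly polished) point
        r = z - b0 - D @ coef
        g = D.T @ (w * r)
        stat = g - l2 * coef
        active = coef != 0.0
        viol_inact = np.any(~active & (np.abs(g) > l1 + kkt_eps))
        viol_act = np.any(
            active & (l1 > 0.0)
            & (np.abs(stat - l1 * np.sign(coef)) > kkt_eps)
        )
        # unpenalized columns: plain zero-gradient condition
        viol_unpen = np.any((l1 == 0.0) & (np.abs(stat) > kkt_eps))
        if use_intercept and abs(np.dot(w, r)) > kkt_eps:
            viol_unpen = True
        if ok and not (viol_inact or viol_act or viol_unpen):
            return coef, b0, True, total_sweeps
    return coef, b0, False, total_sweeps


def fit_path_on_strong_set(
    X_S: np.ndarray,
    Z: np.ndarray | None,
    response,
    family: fam.FamilySpec,
    penalty: PenaltySpec,
    warm_start: tuple[np.ndarray, float] | None = None,
    tol: float | None = None,
    fit_intercept: bool = True,
) -> FitResult:
    """Solve the penalized problem on the in-memory strong-set columns.

    Z holds unpenalized adjustment covariates (may be None/empty).  Each
    lambda is warm-started from the previous lambda's solution; warm_start,
    if given, seeds the first lambda as (stacked [covariates, strong]
    coefficient vector, intercept).
    """
    X_S = np.asarray(X_S, dtype=np.float64)
    if not np.all(np.isfinite(X_S)):
        raise ValueError("non-finite values in the strong-set matrix")
    n = X_S.shape[0]
    p_s = X_S.shape[1]
    if Z is None:
        Z = np.empty((n, 0))
    Z = np.asarray(Z, dtype=np.float64)
    q = Z.shape[1]

    if family.name == "cox":
        y_arr = response
    else:
        y_arr = np.asarray(response, dtype=np.float64)
        if not np.all(np.isfinite(y_arr)):
            raise ValueError("non-finite values in the response")

    D = np.asfortranarray(np.hstack([Z, X_S]))
    P = q + p_s
    pf = penalty.penalty_factor
    if pf is None:
        pf = np.ones(p_s)
    pf_full = np.concatenate([np.zeros(q), pf])
    alpha = penalty.alpha_mix
    lams = penalty.lambda_values
    L = lams.size
    use_intercept = fit_intercept and family.name != "cox"

    if family.name == "gaussian":
        scale = max(1.0, float(np.max(np.abs(y_arr)))) if n else 1.0
    else:
        scale = 1.0
    if tol is None:
        tol = 1e-7 * scale

    coef = np.zeros(P)
    b0 = 0.0
    if warm_start is not None:
        ws_coef, ws_b0 = warm_start
        if ws_coef.shape[0] != P:
            raise ValueError("warm_start coefficient length mismatch")
        coef = np.array(ws_coef, dtype=np.float64)
        b0 = float(ws_b0)
    elif family.name == "binomial" and use_intercept:
        # start at the null model so the first lambda's gradients line up
        # with the grid computed from the covariate-only fit
        null = covariate_only_fit(Z if q else None, y_arr, family)
        coef[:q] = null.coefficients
        b0 = null.intercept

    coefs = np.zeros((p_s, L))
    cov_coefs = np.zeros((q, L))
    intercepts = np.zeros(L)
    etas = np.zeros((n, L))
    converged = np.zeros(L, dtype=bool)
    objective = np.zeros(L)
    traces: list[list[np.ndarray]] = []

    if family.name == "gaussian":
        w_gauss, z_gauss = _working_response(family, y_arr, np.zeros(n))
        xv_gauss = (w_gauss[:, None] * D * D).sum(axis=0)
    for li, lam in enumerate(lams):
        l1 = lam * alpha * pf_full
        l2 = lam * (1.0 - alpha) * pf_full
        lam_traces: list[np.ndarray] = []
        if family.name == "gaussian":
            coef, b0, ok, _sweeps = _weighted_enet_solve(
                D, w_gauss, z_gauss, coef, b0, xv_gauss, l1, l2,
                use_intercept, tol, lam_traces,
            )
            converged[li] = ok
            eta = b0 + D @ coef
        else:
            ok = False
            eta = b0 + D @ coef
            obj_old = _penalized_objective(family, y_arr, eta, coef[q:], lam, alpha, pf)
            max_outer = MAX_OUTER_COX if family.name == "cox" else MAX_OUTER
            for _ in range(max_outer):
                w, z = _working_response(family, y_arr, eta)
                xv = (w[:, None] * D * D).sum(axis=0)
                coef_prev = coef.copy()
                b0_prev = b0
                coef, b0, inner_ok, _sweeps = _weighted_enet_solve(
                    D, w, z, coef, b0, xv, l1, l2, use_intercept, tol, lam_traces,
                )
                eta = b0 + D @ coef
                obj_new = _penalized_objective(family, y_arr, eta, coef[q:], lam, alpha, pf)
                halvings = 0
                while obj_new > obj_old + 1e-12 and halvings < 8:
                    coef = 0.5 * (coef + coef_prev)
                    b0 = 0.5 * (b0 + b0_prev)
                    eta = b0 + D @ coef
                    obj_new = _penalized_objective(family, y_arr, eta, coef[q:], lam, alpha, pf)
                    halvings += 1
                obj_old = obj_new
                step = max(
                    float(np.max(np.abs(coef - coef_prev))) if P else 0.0,
                    abs(b0 - b0_prev),
                )
                # stop on stationarity of the true (non-surrogate) problem
                g_true = D.T @ fam.gradient_vector(family, y_arr, eta)
                pen_grad = g_true + lam * (1 - alpha) * pf_full * coef
                act = coef != 0.0
                eps = 1e-9 * lam * alpha + 1e-12
                ok_inact = np.all(np.abs(g_true[~act & (pf_full > 0)])
                                  <= l1[~act & (pf_full > 0)] + eps)
                ok_act = np.all(np.abs(pen_grad[act & (pf_full > 0)]
                                       + l1[act & (pf_full > 0)]
                                       * np.sign(coef[act & (pf_full > 0)])) <= 100 * eps)
                ok_unpen = np.all(np.abs(g_true[pf_full == 0.0]) <= 100 * eps) if q else True
                if (ok_inact and ok_act and ok_unpen) or step < tol:
                    # quadratic-convergence families hit stationarity first;
                    # the diagonal Cox surrogate converges linearly and exits
                    # on a vanishing outer step instead
                    ok = True
                    break
            if family.name == "cox":
                coef, kkt_rel = _fista_refine(D, y_arr, family, coef, l1, l2)
                eta = D @ coef
                ok = ok or kkt_rel <= 1e-6
            converged[li] = ok
        cov_coefs[:, li] = coef[:q]
        coefs[:, li] = coef[q:]
        intercepts[li] = b0
        etas[:, li] = eta
        objective[li] = _penalized_objective(family, y_arr, eta, coef[q:], lam, alpha, pf)
        traces.append(lam_traces)

    return FitResult(
        coefficients=coefs,
        covariate_coefficients=cov_coefs,
        intercept=intercepts,
        linear_predictor=etas,
        converged=converged,
        objective=objective,
        objective_traces=traces,
    )


# ---------------------------------------------------------------------
# unpenalized fits
# ---------------------------------------------------------------------


def _check_rank(D0: np.ndarray, col_names) -> None:
    if D0.shape[1] == 0:
        return
    r = np.abs(np.diag(np.linalg.qr(D0, mode="r")))
    bad = np.nonzero(r < 1e-10 * max(r.max(), 1.0))[0]
    if bad.size:
        names = [str(col_names[i]) for i in bad]
        raise CollinearityError(
            f"covariate design is rank deficient; offending columns: {names}"
        )


def _unpenalized_glm(D0: np.ndarray, response, family: fam.FamilySpec) -> np.ndarray:
    """Unpenalized family fit on an explicit design.

    Gaussian by least squares; binomial by damped Newton to near machine
    precision (the path initialization needs the null-model gradient to
    match the lambda grid exactly); Cox by L-BFGS with exact gradient.
    """
    if family.name == "gaussian":
        theta, *_ = np.linalg.lstsq(D0, np.asarray(response, dtype=np.float64), rcond=None)
        return theta

    if family.name == "binomial":
        y = np.asarray(response, dtype=np.float64)
        n = y.shape[0]
        theta = np.zeros(D0.shape[1])
        f_old = fam.loss(family, y, D0 @ theta)
        for _ in range(100):
            eta = D0 @ theta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            grad = D0.T @ (p - y) / n
            if np.max(np.abs(grad)) < 1e-14:
                break
            W = np.maximum(p * (1.0 - p), 1e-10) / n
            H = D0.T @ (W[:, None] * D0)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(H, grad, rcond=None)
            t = 1.0
            for _ in range(30):
                cand = theta - t * step
                f_new = fam.loss(family, y, D0 @ cand)
                if f_new <= f_old + 1e-15:
                    break
                t *= 0.5
            theta = theta - t * step
            f_old = f_new
        return theta

    def fun(theta):
        eta = D0 @ theta
        g = fam.gradient_vector(family, response, eta)
        return fam.loss(family, response, eta), D0.T @ g

    theta0 = np.zeros(D0.shape[1])
    res = optimize.minimize(fun, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-12})
    return res.x


def covariate_only_fit(
    Z: np.ndarray | None, response, family: fam.FamilySpec, col_names=None
):
    """Fit the unpenalized family model on (intercept, Z); return r^(0).

    The returned residual initializes the path: for the Gaussian with no
    covariates it is y - mean(y); for the binomial, y minus the fitted
    probabilities; for Cox (no intercept), the negated gradient vector so
    that the screening statistic is |x^T residual| in every family.
    """
    if Z is None:
        Z = np.empty((0, 0))
    Z = np.asarray(Z, dtype=np.float64)
    if Z.size == 0 and Z.ndim == 2 and Z.shape[1] == 0 and family.name != "cox":
        n = len(response) if family.name != "cox" else len(response.time)
        Z = np.empty((n, 0))
    n = Z.shape[0] if Z.shape[0] else (
        len(response.time) if family.name == "cox" else len(response)
    )
    if Z.shape[0] == 0:
        Z = np.empty((n, 0))
    q = Z.shape[1]
    if col_names is None:
        col_names = [f"covar_{i}" for i in range(q)]

    if family.name == "cox":
        if response.n_events == 0:
            raise DegenerateResponseError("Cox response has no observed events")
        D0 = Z
        _check_rank(D0, col_names)
        theta = _unpenalized_glm(D0, response, family) if q else np.zeros(0)
        eta = D0 @ theta if q else np.zeros(n)
        resid = -fam.cox_residual(response, eta)
        return CovariateFit(coefficients=theta, intercept=0.0, eta=eta, residual=resid)

    y = np.asarray(response, dtype=np.float64)
    D0 = np.column_stack([np.ones(n), Z])
    _check_rank(D0, ["intercept"] + list(col_names))
    theta = _unpenalized_glm(D0, y, family)
    eta = D0 @ theta
    if family.name == "gaussian":
        resid = fam.gaussian_residual(y, eta)
    else:
        resid = fam.binomial_residual(y, eta)
    return CovariateFit(coefficients=theta[1:], intercept=float(theta[0]),
                        eta=eta, residual=resid)


def relaxed_refit(
    X_A: np.ndarray, Z: np.ndarray | None, response, family: fam.FamilySpec
):
    """Unpenalized refit on (intercept, covariates, active columns).

    Undoes lasso shrinkage on the selected variables; covariates must be
    carried along so that the refit stays adjusted.  Rank-deficient Gaussian
    designs fall back to the minimal-norm least-squares solution with a
    warning.  Returns (covariate coefficients with intercept first where the
    family has one, active coefficients).
    """
    X_A = np.asarray(X_A, dtype=np.float64)
    n = X_A.shape[0]
    if Z is None:
        Z = np.empty((n, 0))
    Z = np.asarray(Z, dtype=np.float64)
    q = Z.shape[1]

    if family.name == "cox":
        D0 = np.hstack([Z, X_A])
        theta = _unpenalized_glm(D0, response, family)
        return theta[:q], theta[q:]

    D0 = np.column_stack([np.ones(n), Z, X_A])
    if family.name == "gaussian":
        y = np.asarray(response, dtype=np.float64)
        if np.linalg.matrix_rank(D0) < D0.shape[1]:
            warnings.warn(
                "relaxed refit design is rank deficient; returning the "
                "minimal-norm least-squares solution",
                RuntimeWarning,
            )
        theta, *_ = np.linalg.lstsq(D0, y, rcond=None)
    else:
        theta = _unpenalized_glm(D0, np.asarray(response, dtype=np.float64), family)
    return theta[: q + 1], theta[q + 1:]
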