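"""The semi-supervised composition estimator.

Given a component basis (loadings ``L``, scores ``P``) computed on the
``t`` selected sites, the estimator searches for cell proportions
``R = P_aug V`` and cell-type profiles ``M = L_aug A`` — i.e. linear
transformations of the basis — that minimise the penalised negative
log-likelihood

    (1/2 sigma^2) || O~ - L_aug A (P_aug V)^T - L_aug B X^T ||_F^2
        - sum_h (alpha_h - 1) sum_i log( (P_aug V)_ih )

subject to every proportion >= epsilon, row sums within a small slack of
1, and every profile entry inside the [0,1] box.  ``L_aug``/``P_aug``
carry an appended column of ones composing the per-site mean level and
the per-cell-type mean fraction, which makes the constraint set
feasible.  Only ``(d+1)(2k+p)`` parameters are learned, versus
``nk + m(k+p)`` in the unrestricted factorization.

When measured cell counts are available for a few samples, a two-stage
*imputation* variant first estimates the profile matrix from those
samples by box-constrained least squares and then solves the remaining
problem in ``V, B`` — convex for concentration parameters >= 1 — with
near-equality constraints tying the reference rows to their measured
counts; this anchors all estimates in absolute scale and makes the
component-to-cell-type assignment authoritative.

Numerics: both fits run an interior trust-region method (trust-constr)
with analytic gradients and exact Hessian-vector products under sparse
linear constraints.  The objective is minimised after multiplication by
sigma^2 — the argmin is unchanged and gradient magnitudes become O(1),
which makes the gradient tolerance meaningful; reported objectives are
on the original scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, lsq_linear, minimize

from .exceptions import ValidationError
from .prior import DirichletPrior
from .refactor import ComponentBasis

__all__ = [
    "SolverOptions",
    "BayesCCEFit",
    "ImputationInput",
    "estimate_sigma2",
    "fit_bayescce",
    "estimate_M_from_reference",
    "fit_bayescce_impute",
    "feasible_impute_basis",
]

EPSILON = 1e-4  # positivity floor on proportions
SUM_SLACK = 0.05  # allowed deviation of proportion row sums from 1
REF_SLACK = 0.01  # allowed deviation from measured counts (imputation)


@dataclass(frozen=True)
class SolverOptions:
    """Tunables of the constrained fit.

    ``epsilon``, ``sum_slack`` and ``ref_slack`` are the constraint
    relaxations (positivity floor, simplex slack, measured-count slack);
    ``delta_M`` optionally softens the [0,1] profile box (hard by
    default — the box is linear and feasible after the ones-column
    augmentation).  ``n_starts`` jittered restarts are run and the best
    final objective kept.  ``gtol``/``xtol`` apply to the sigma^2-scaled
    objective.
    """

    epsilon: float = EPSILON
    sum_slack: float = SUM_SLACK
    ref_slack: float = REF_SLACK
    delta_M: float = 0.0
    n_starts: int = 5
    seed: int = 0
    jitter: float = 0.01
    max_iter: int = 2000
    gtol: float = 1e-6
    xtol: float = 1e-9
    constraint_tol: float = 1e-8
    solver: str = "barrier"  # "barrier" (exact-Newton interior point) or "trust-constr"


@dataclass(frozen=True)
class ImputationInput:
    """Measured proportions for a subset of the samples."""

    R0: pd.DataFrame  # n0 x k, rows on the simplex within the ref slack
    is_external: bool = False

    def __post_init__(self):
        if not isinstance(self.R0, pd.DataFrame):
            raise ValidationError("R0 must be a DataFrame indexed by sample id")
        if self.R0.shape[0] < 1:
            raise ValidationError("need at least one reference sample")
        vals = self.R0.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(np.abs(vals.sum(axis=1) - 1.0) > REF_SLACK):
            raise ValidationError(
                "reference proportions must be nonnegative with row sums within "
                f"{REF_SLACK:.0%} of 1"
            )

    @property
    def reference_sample_ids(self) -> tuple[str, ...]:
        return tuple(map(str, self.R0.index))


@dataclass(frozen=True)
class BayesCCEFit:
    """Result of a composition fit."""

    R_hat: pd.DataFrame  # n x k
    M_hat: pd.DataFrame  # t x k
    A: np.ndarray  # (d+1) x k
    V: np.ndarray  # (d+1) x k
    B: np.ndarray | None  # (d+1) x p
    sigma2: float
    objective: float
    start_objective: float
    converged: bool
    assignment: dict[int, str]
    assignment_is_heuristic: bool
    n_starts: int = 1

    def report(self) -> dict:
        return {
            "objective": self.objective,
            "start_objective": self.start_objective,
            "sigma2": self.sigma2,
            "converged": self.converged,
            "assignment": {str(k): v for k, v in self.assignment.items()},
            "assignment_is_heuristic": self.assignment_is_heuristic,
            "n_starts": self.n_starts,
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.R_hat.to_csv(outdir / "R_hat.tsv", sep="\t", index_label="sample_id")
        self.M_hat.to_csv(outdir / "M_hat.tsv", sep="\t", index_label="site_id")
        (outdir / "fit_report.json").write_text(json.dumps(self.report(), indent=2))


# ---------------------------------------------------------------------------
# Noise-variance estimation


def _to_array(M, allow_none=False):
    if M is None and allow_none:
        return None
    M = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, float)
    if M.ndim == 1:
        M = M[:, None]
    return M


def estimate_sigma2(
    O_trunc: np.ndarray | pd.DataFrame,
    P: np.ndarray,
    X: np.ndarray | pd.DataFrame | None = None,
) -> float:
    """Pooled residual variance of the basis regression.

    Site-wise OLS of each row of the truncated matrix on the scores (and
    covariates, with an intercept); returns the mean squared residual
    pooled over all t*n entries.  Held fixed during the main fit.
    """
    O = np.atleast_2d(_to_array(O_trunc))
    Xv = _to_array(X, allow_none=True)
    P = np.asarray(P, dtype=float)
    cols = [np.ones((P.shape[0], 1)), P]
    if Xv is not None:
        cols.append(Xv)
    design = np.hstack(cols)
    if design.shape[0] != O.shape[1]:
        raise ValidationError("score matrix rows must match sample count")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            c
            for c in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, c, axis=1)) == rank
        ]
        raise ValidationError(
            f"rank-deficient design matrix; collinear columns (0=intercept): {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, O.T, rcond=None)
    resid = O - (design @ coef).T
    return float(np.mean(resid**2))


# ---------------------------------------------------------------------------
# Objective machinery

# Below this fraction of epsilon the log is continued quadratically so
# the objective stays finite if the solver steps slightly infeasible.
_LOG_GUARD_FRACTION = 0.1


def _safe_log(r: np.ndarray, floor: float) -> tuple[np.ndarray, np.ndarray]:
    """log(r) with a C1 quadratic continuation below ``floor``."""
    r = np.asarray(r, dtype=float)
    val = np.empty_like(r)
    grad = np.empty_like(r)
    hi = r >= floor
    val[hi] = np.log(r[hi])
    grad[hi] = 1.0 / r[hi]
    lo = ~hi
    dr = r[lo] - floor
    val[lo] = np.log(floor) + dr / floor - dr**2 / (2 * floor**2)
    grad[lo] = 1.0 / floor - dr / floor**2
    return val, grad


def _augment(M: np.ndarray) -> np.ndarray:
    return np.hstack([M, np.ones((M.shape[0], 1))])


class _Objective:
    """sigma^2-scaled objective over x = [vec A, vec V, vec B].

    The data term is evaluated through the Gram matrix of the left
    factor, so each call costs O((d+1)^2 n + nk) rather than O(t n d).
    ``w = (alpha - 1) sigma^2`` is the scaled prior weight.
    """

    def __init__(self, L_aug, P_aug, O_trunc, alpha, sigma2, X, epsilon):
        self.L_aug = L_aug
        self.P_aug = P_aug
        self.O = O_trunc
        self.sigma2 = sigma2
        self.X = X
        self.w = (np.asarray(alpha, float) - 1.0) * sigma2
        self.floor = epsilon * _LOG_GUARD_FRACTION
        self.d1 = L_aug.shape[1]
        self.k = alpha.size
        self.p = 0 if X is None else X.shape[1]
        self.G = L_aug.T @ L_aug
        self.T = L_aug.T @ O_trunc
        self.o2 = float(np.sum(O_trunc**2))
        self.nvar = self.d1 * self.k * 2 + self.d1 * self.p

    def unpack(self, x):
        d1, k, p = self.d1, self.k, self.p
        A = x[: d1 * k].reshape(d1, k)
        V = x[d1 * k : 2 * d1 * k].reshape(d1, k)
        B = x[2 * d1 * k :].reshape(d1, p) if p else None
        return A, V, B

    def pack(self, A, V, B):
        parts = [A.ravel(), V.ravel()]
        if self.p:
            parts.append(B.ravel())
        return np.concatenate(parts)

    def _common(self, x):
        A, V, B = self.unpack(x)
        R = self.P_aug @ V  # n x k
        C = A @ R.T  # (d+1) x n
        if self.p:
            C = C + B @ self.X.T
        E = self.G @ C - self.T  # d(data)/dC, scaled
        return A, V, B, R, C, E

    def value_and_grad(self, x):
        A, V, B, R, C, E = self._common(x)
        f_data = 0.5 * (self.o2 - 2.0 * np.sum(C * self.T) + np.sum(C * (self.G @ C)))
        logR, dlogR = _safe_log(R, self.floor)
        f_prior = -float(self.w @ logR.sum(axis=0))
        gA = E @ R
        gR = E.T @ A - dlogR * self.w[None, :]
        gV = self.P_aug.T @ gR
        grads = [gA.ravel(), gV.ravel()]
        if self.p:
            grads.append((E @ self.X).ravel())
        return f_data + f_prior, np.concatenate(grads)

    def hessp(self, x, y):
        """Exact Hessian-vector product of the scaled objective."""
        A, V, B, R, C, E = self._common(x)
        dA, dV, dB = self.unpack(y)
        dR = self.P_aug @ dV
        dC = dA @ R.T + A @ dR.T
        if self.p:
            dC = dC + dB @ self.X.T
        GdC = self.G @ dC
        HA = GdC @ R + E @ dR
        rr = np.maximum(R, self.floor)
        HR = GdC.T @ A + E.T @ dA + (self.w[None, :] / rr**2) * dR
        HV = self.P_aug.T @ HR
        out = [HA.ravel(), HV.ravel()]
        if self.p:
            out.append((GdC @ self.X).ravel())
        return np.concatenate(out)

    def unscaled(self, f: float) -> float:
        return f / self.sigma2


def _embed(block, col0: int, nvar: int) -> sp.csr_matrix:
    """Place a (sparse) block into the full variable space."""
    block = sp.csr_matrix(block)
    left = sp.csr_matrix((block.shape[0], col0))
    right = sp.csr_matrix((block.shape[0], nvar - col0 - block.shape[1]))
    return sp.hstack([left, block, right]).tocsr()


def _linear_constraints(objective, options):
    d1, k = objective.d1, objective.k
    P_aug = sp.csr_matrix(objective.P_aug)
    L_aug = sp.csr_matrix(objective.L_aug)
    nvar = objective.nvar
    cons = []
    # proportions >= epsilon (n*k rows), over vec V
    A_R = sp.kron(P_aug, sp.eye(k))
    cons.append(LinearConstraint(_embed(A_R, d1 * k, nvar), options.epsilon, np.inf))
    # row sums within slack (n rows)
    A_sum = sp.kron(P_aug, np.ones((1, k)))
    cons.append(
        LinearConstraint(
            _embed(A_sum, d1 * k, nvar), 1.0 - options.sum_slack, 1.0 + options.sum_slack
        )
    )
    # profile box (t*k rows), over vec A
    A_M = sp.kron(L_aug, sp.eye(k))
    cons.append(
        LinearConstraint(_embed(A_M, 0, nvar), -options.delta_M, 1.0 + options.delta_M)
    )
    return cons


def _strictly_feasible(x, constraints, margin=1e-7):
    for c in constraints:
        Ax = c.A @ x
        lb = np.broadcast_to(c.lb, Ax.shape)
        ub = np.broadcast_to(c.ub, Ax.shape)
        lo = np.isfinite(lb)
        hi = np.isfinite(ub)
        if np.any(Ax[lo] - lb[lo] <= margin) or np.any(ub[hi] - Ax[hi] <= margin):
            return False
    return True


def _initial_point(objective, prior, rng, options, constraints=None):
    """Prior-centred start: V0 maps scores to the prior-mean proportions
    (plus jitter), A0 maps loadings to the site means.

    When ``constraints`` are given, the start is blended toward a
    strictly interior point (constant profiles at the grand mean,
    constant proportions at the prior mean — exact because the score
    columns sum to zero) until it is strictly feasible; returns None if
    no blend succeeds.
    """
    d1, k = objective.d1, objective.k
    P_aug, L_aug = objective.P_aug, objective.L_aug
    n = P_aug.shape[0]
    R0 = np.tile(prior.mean, (n, 1)) + rng.normal(0.0, options.jitter, size=(n, k))
    R0 = np.clip(R0, 2 * options.epsilon, None)
    R0 /= R0.sum(axis=1, keepdims=True)
    V0, *_ = np.linalg.lstsq(P_aug, R0, rcond=None)
    site_means = np.clip(objective.O.mean(axis=1), 0.0, 1.0)
    A0, *_ = np.linalg.lstsq(L_aug, np.tile(site_means[:, None], (1, k)), rcond=None)
    B0 = np.zeros((d1, objective.p)) if objective.p else None
    x0 = objective.pack(A0, V0, B0)
    if constraints is None:
        return x0

    mean_props = np.clip(prior.mean, 4 * options.epsilon, None)
    mean_props = mean_props / mean_props.sum()
    V_safe = np.zeros((d1, k))
    V_safe[-1] = mean_props
    A_safe = np.zeros((d1, k))
    A_safe[-1] = np.clip(float(objective.O.mean()), 0.05, 0.95)
    x_safe = objective.pack(A_safe, V_safe, B0)
    for theta in (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0):
        x = (1.0 - theta) * x0 + theta * x_safe
        if _strictly_feasible(x, constraints):
            return x
    return None


class _SolveResult:
    def __init__(self, x, fun, converged, niter):
        self.x = x
        self.fun = fun
        self.converged = converged
        self.niter = niter


def _dense_hessian(obj, x: np.ndarray) -> np.ndarray:
    """Assemble the exact (small) Hessian column-wise from hessp."""
    n = x.size
    H = np.empty((n, n))
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        H[:, j] = obj.hessp(x, e)
        e[j] = 0.0
    return 0.5 * (H + H.T)


def _barrier_minimize(obj, x0, constraints, options):
    """Primal log-barrier interior-point method with exact Newton steps.

    The iterate stays strictly feasible throughout (fraction-to-boundary
    line search), so the returned solution satisfies every inequality by
    construction.  The barrier parameter starts balanced against the
    objective scale and is reduced geometrically until the duality-gap
    bound ``m * mu`` is negligible relative to the objective.
    """
    A = sp.vstack([c.A for c in constraints]).tocsr()
    lb = np.concatenate([np.broadcast_to(c.lb, c.A.shape[0]) for c in constraints])
    ub = np.concatenate([np.broadcast_to(c.ub, c.A.shape[0]) for c in constraints])
    has_lb, has_ub = np.isfinite(lb), np.isfinite(ub)
    AT = A.T.tocsr()
    m_cons = int(has_lb.sum() + has_ub.sum())

    def slacks(x):
        Ax = A @ x
        s_lo = np.where(has_lb, Ax - lb, np.inf)
        s_hi = np.where(has_ub, ub - Ax, np.inf)
        return Ax, s_lo, s_hi

    def barrier(s_lo, s_hi):
        return -(np.log(s_lo[has_lb]).sum() + np.log(s_hi[has_ub]).sum())

    x = x0.copy()
    _, s_lo, s_hi = slacks(x)
    if np.any(s_lo <= 0) or np.any(s_hi <= 0):
        raise ValidationError("infeasible starting point for the interior-point solver")

    f0, _ = obj.value_and_grad(x)
    mu = max(1e-2 * abs(f0), 1e-6) / m_cons
    mu_end = 1e-9 * max(abs(f0), 1.0) / m_cons
    niter = 0
    converged = True
    while True:
        # Newton loop for the current barrier parameter
        for _ in range(60):
            if niter >= options.max_iter:
                converged = False
                break
            f, g = obj.value_and_grad(x)
            _, s_lo, s_hi = slacks(x)
            c = np.where(has_ub, 1.0 / s_hi, 0.0) - np.where(has_lb, 1.0 / s_lo, 0.0)
            g_mu = g + mu * (AT @ c)
            gnorm = np.linalg.norm(g_mu, np.inf)
            if gnorm <= max(0.1 * mu, options.gtol):
                break
            d = np.where(has_lb, 1.0 / s_lo**2, 0.0) + np.where(has_ub, 1.0 / s_hi**2, 0.0)
            H = _dense_hessian(obj, x) + mu * (AT @ sp.diags(d) @ A).toarray()
            # modified Newton: regularise until positive definite
            tau = 0.0
            I = np.eye(H.shape[0])
            for _ in range(30):
                try:
                    from scipy.linalg import cho_factor, cho_solve

                    cf = cho_factor(H + tau * I, lower=True)
                    p = cho_solve(cf, -g_mu)
                    break
                except np.linalg.LinAlgError:
                    tau = max(2.0 * tau, 1e-8 * max(np.abs(np.diag(H)).max(), 1.0))
            else:  # pragma: no cover - extreme ill-conditioning
                p = -g_mu
            # fraction-to-boundary step cap
            Ap = A @ p
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = np.concatenate(
                    [
                        np.where((Ap < 0) & has_lb, -s_lo / Ap, np.inf),
                        np.where((Ap > 0) & has_ub, s_hi / Ap, np.inf),
                    ]
                )
            alpha = min(1.0, 0.99 * steps.min())
            # Armijo backtracking on the barrier objective
            phi0 = f + mu * barrier(s_lo, s_hi)
            slope = float(g_mu @ p)
            accepted = False
            for _ in range(40):
                x_new = x + alpha * p
                _, s_lo_n, s_hi_n = slacks(x_new)
                if np.all(s_lo_n > 0) and np.all(s_hi_n > 0):
                    f_new = obj.value_and_grad(x_new)[0] + mu * barrier(s_lo_n, s_hi_n)
                    if f_new <= phi0 + 1e-4 * alpha * slope:
                        accepted = True
                        break
                alpha *= 0.5
            if not accepted:
                break  # no progress at this mu; tighten mu or stop
            x = x_new
            niter += 1
        if mu <= mu_end or niter >= options.max_iter:
            break
        mu = max(mu * 0.15, mu_end)
    f_final = obj.value_and_grad(x)[0]
    return _SolveResult(x, f_final, converged and niter < options.max_iter, niter)


def _solve(obj, x0, constraints, options):
    if options.solver == "barrier":
        return _barrier_minimize(obj, x0, constraints, options)
    res = minimize(
        lambda x: obj.value_and_grad(x),
        x0,
        jac=True,
        hessp=obj.hessp,
        method="trust-constr",
        constraints=constraints,
        options={
            "maxiter": options.max_iter,
            "gtol": options.gtol,
            "xtol": options.xtol,
            "verbose": 0,
        },
    )
    return _SolveResult(
        res.x,
        res.fun,
        bool(res.status in (1, 2) and res.constr_violation < 1e-6),
        res.niter,
    )


def fit_bayescce(
    basis: ComponentBasis,
    O_trunc: pd.DataFrame | np.ndarray,
    prior: DirichletPrior,
    X: pd.DataFrame | np.ndarray | None = None,
    options: SolverOptions | None = None,
) -> BayesCCEFit:
    """Fit cell proportions by constrained penalised likelihood.

    ``O_trunc`` is the t x n beta matrix restricted to the basis' sites.
    The noise variance is estimated once up front from the basis
    regression and held fixed.  ``options.n_starts`` jittered restarts
    are run and the best final objective kept.

    Without measured cell counts, component h is *labelled* with the
    h-th prior cell type but the assignment is heuristic: components
    correspond to cell types only up to relabelling (and affine scale);
    use the evaluation module's permutation matching against any ground
    truth.
    """
    options = options or SolverOptions()
    O = _to_array(O_trunc)
    if O.shape != (basis.t, basis.n):
        raise ValidationError(
            f"O_trunc shape {O.shape} does not match basis (t={basis.t}, n={basis.n})"
        )
    if basis.d < prior.k:
        warnings.warn(
            f"d={basis.d} < k={prior.k}: the basis may not span all cell types"
        )
    Xv = _to_array(X, allow_none=True)

    sigma2 = max(estimate_sigma2(O, basis.P, Xv), 1e-12)
    L_aug, P_aug = _augment(basis.L), _augment(basis.P)
    obj = _Objective(L_aug, P_aug, O, prior.alpha, sigma2, Xv, options.epsilon)
    constraints = _linear_constraints(obj, options)

    rng = np.random.default_rng(options.seed)
    best = None
    start_obj = None
    for _ in range(max(1, options.n_starts)):
        x0 = _initial_point(obj, prior, rng, options, constraints)
        solve_opts = options
        if x0 is None:  # no strictly interior blend found
            x0 = _initial_point(obj, prior, rng, options)
            if options.solver == "barrier":
                solve_opts = _dc_replace(options, solver="trust-constr")
        if start_obj is None:
            start_obj = obj.value_and_grad(x0)[0]
        res = _solve(obj, x0, constraints, solve_opts)
        if best is None or res.fun < best.fun:
            best = res

    A, V, B = obj.unpack(best.x)
    R_hat = np.maximum(P_aug @ V, options.epsilon)
    M_hat = L_aug @ A
    converged = best.converged
    if not converged:
        warnings.warn(f"fit did not fully converge after {best.niter} iterations")
    names = list(prior.cell_type_names)
    sample_ids = list(basis.sample_ids)
    return BayesCCEFit(
        R_hat=pd.DataFrame(R_hat, index=sample_ids, columns=names),
        M_hat=pd.DataFrame(M_hat, index=list(basis.selected_sites), columns=names),
        A=A,
        V=V,
        B=B,
        sigma2=sigma2,
        objective=float(obj.unscaled(best.fun)),
        start_objective=float(obj.unscaled(start_obj)),
        converged=converged,
        assignment={h: names[h] for h in range(prior.k)},
        assignment_is_heuristic=True,
        n_starts=options.n_starts,
    )


# ---------------------------------------------------------------------------
# Imputation mode


def _interior_point_lp(constraints, nvar: int) -> np.ndarray | None:
    """A strictly interior point of the linear constraint set, or None.

    Solves the Chebyshev-center-style LP max s over {lb + s <= A x <=
    ub - s}; a positive optimal margin certifies strict feasibility.
    """
    rows = []
    rhs = []
    for c in constraints:
        A = sp.csr_matrix(c.A)
        m = A.shape[0]
        lb = np.broadcast_to(c.lb, m)
        ub = np.broadcast_to(c.ub, m)
        lo, hi = np.isfinite(lb), np.isfinite(ub)
        ones = np.ones((int(lo.sum()), 1))
        if lo.any():
            rows.append(sp.hstack([-A[lo], ones]))
            rhs.append(-lb[lo])
        if hi.any():
            rows.append(sp.hstack([A[hi], np.ones((int(hi.sum()), 1))]))
            rhs.append(ub[hi])
    A_ub = sp.vstack(rows).tocsc()
    b_ub = np.concatenate(rhs)
    c_obj = np.zeros(nvar + 1)
    c_obj[-1] = -1.0
    res = linprog(
        c_obj,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * nvar + [(0.0, 1.0)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-9:
        return None
    return res.x[:-1]


def _min_reference_deviation(P0_aug: np.ndarray, R0: np.ndarray) -> float:
    """Smallest achievable max |P0 v - r0| over columns (Chebyshev LP)."""
    n0, d1 = P0_aug.shape
    worst = 0.0
    for h in range(R0.shape[1]):
        A_ub = np.block(
            [[P0_aug, -np.ones((n0, 1))], [-P0_aug, -np.ones((n0, 1))]]
        )
        b_ub = np.concatenate([R0[:, h], -R0[:, h]])
        c = np.zeros(d1 + 1)
        c[-1] = 1.0
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * (d1 + 1))
        if res.success:
            worst = max(worst, float(res.x[-1]))
    return worst


def estimate_M_from_reference(
    O0: np.ndarray | pd.DataFrame,
    R0: np.ndarray | pd.DataFrame,
    X0: np.ndarray | pd.DataFrame | None = None,
) -> np.ndarray:
    """Cell-type profiles from samples with measured proportions.

    Solves, independently per site j, the box-constrained least squares

        min_{0 <= M_j <= 1}  || O0_j - R0 M_j^T - X0 S_j^T ||^2

    (covariate effects S_j unconstrained) — a standard quadratic program
    per site.  The unconstrained solution is computed in closed form for
    all sites at once; the QP is run only for sites whose solution
    leaves the box.  Requires at least k reference samples.
    """
    O0 = np.atleast_2d(_to_array(O0))
    R0v = _to_array(R0)
    X0v = _to_array(X0, allow_none=True)
    n0, k = R0v.shape
    if O0.shape[1] != n0:
        raise ValidationError("O0 columns must match reference samples")
    if n0 < k:
        raise ValidationError(
            f"underdetermined: {n0} reference samples for k={k} cell types"
        )
    if np.linalg.matrix_rank(R0v) < k:
        warnings.warn("reference proportions are rank deficient; minimum-norm solution")
    design = R0v if X0v is None else np.hstack([R0v, X0v])
    p = 0 if X0v is None else X0v.shape[1]

    coef, *_ = np.linalg.lstsq(design, O0.T, rcond=None)  # (k+p) x t
    M = coef[:k].T.copy()
    viol = np.where((M < 0).any(axis=1) | (M > 1).any(axis=1))[0]
    if viol.size:
        lb = np.concatenate([np.zeros(k), np.full(p, -np.inf)])
        ub = np.concatenate([np.ones(k), np.full(p, np.inf)])
        for j in viol:
            sol = lsq_linear(
                design, O0[j], bounds=(lb, ub), method="bvls" if p == 0 else "trf"
            )
            M[j] = sol.x[:k]
    return np.clip(M, 0.0, 1.0)


def _impute_constraints(P_aug, ref_idx, nonref_idx, R0, options, nvar):
    """Stage-2 constraint set: measured-count band on reference rows,
    relaxed simplex on the remaining rows (over vec V; any trailing B
    columns are unconstrained)."""
    k = R0.shape[1]
    P_sp = sp.csr_matrix(P_aug)
    cons = [
        LinearConstraint(
            _embed(sp.kron(P_sp[ref_idx], sp.eye(k)), 0, nvar),
            R0.ravel() - options.ref_slack,
            R0.ravel() + options.ref_slack,
        )
    ]
    if len(nonref_idx):
        cons.append(
            LinearConstraint(
                _embed(sp.kron(P_sp[nonref_idx], sp.eye(k)), 0, nvar),
                options.epsilon,
                np.inf,
            )
        )
        cons.append(
            LinearConstraint(
                _embed(sp.kron(P_sp[nonref_idx], np.ones((1, k))), 0, nvar),
                1.0 - options.sum_slack,
                1.0 + options.sum_slack,
            )
        )
    return cons


def feasible_impute_basis(
    O: pd.DataFrame,
    selected_sites: list[str],
    imp: "ImputationInput",
    d_start: int,
    X: pd.DataFrame | np.ndarray | None = None,
    options: "SolverOptions | None" = None,
    d_max: int = 50,
    d_step: int = 2,
) -> ComponentBasis:
    """Smallest basis (by component count) on which the imputation
    constraints admit an interior point.

    The measured-count band ties ``n0 k`` linear combinations of the
    scores to fixed values; a basis of only a few components generally
    cannot reproduce them within the measurement slack while keeping the
    remaining samples on the relaxed simplex.  Starting from ``d_start``
    the component count is increased until the constraint polytope is
    certified nonempty by linear programming (no ground truth is
    involved — only the measured counts).  Raises if no ``d`` up to
    ``d_max`` is feasible.
    """
    from .refactor import compute_components

    options = options or SolverOptions()
    sample_ids = list(map(str, O.columns))
    pos = {s: i for i, s in enumerate(sample_ids)}
    ref_ids = list(imp.reference_sample_ids)
    missing = [s for s in ref_ids if s not in pos]
    if missing:
        raise ValidationError(f"reference sample ids not in the dataset: {missing}")
    ref_idx = np.array([pos[s] for s in ref_ids])
    nonref_idx = np.array(
        [i for i in range(len(sample_ids)) if i not in set(ref_idx)], dtype=int
    )
    R0 = imp.R0.to_numpy(dtype=float)
    k = R0.shape[1]
    d = d_start
    cap = min(d_max, len(selected_sites), len(sample_ids) - 1)
    while True:
        basis = compute_components(O, selected_sites, d=d, X=X)
        P_aug = _augment(basis.P)
        nvar = (d + 1) * k
        cons = _impute_constraints(P_aug, ref_idx, nonref_idx, R0, options, nvar)
        if _interior_point_lp(cons, nvar) is not None:
            return basis
        if d >= cap:
            raise ValidationError(
                f"imputation constraints remain infeasible up to d={d}; "
                "increase ref_slack or measure counts for fewer/cleaner samples"
            )
        d = min(d + d_step, cap)


def _impute_start(
    P_aug: np.ndarray,
    R_start: np.ndarray,
    ref_idx: np.ndarray,
    R0: np.ndarray,
    band: float,
) -> np.ndarray:
    """Start for stage 2: per column, the least-squares fit of the target
    proportions constrained to reproduce the measured counts within the
    (slightly shrunk) measurement band — a small convex QP per column."""
    from scipy.optimize import minimize as _min

    d1 = P_aug.shape[1]
    k = R_start.shape[1]
    P0 = P_aug[ref_idx]
    V = np.empty((d1, k))
    for h in range(k):
        target = R_start[:, h]
        v_ls, *_ = np.linalg.lstsq(P_aug, target, rcond=None)

        def fun(v):
            r = P_aug @ v - target
            return float(r @ r), 2.0 * (P_aug.T @ r)

        Jc = np.vstack([-P0, P0])
        r0h = R0[:, h]

        def cfun(v):
            P0v = P0 @ v
            return np.concatenate([r0h + band - P0v, P0v - (r0h - band)])

        res = _min(
            fun,
            v_ls,
            jac=True,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": cfun, "jac": lambda v: Jc}],
            options={"maxiter": 300, "ftol": 1e-14},
        )
        V[:, h] = res.x if res.success else v_ls
    return V


class _ImputeObjective:
    """Stage-2 scaled objective over x = [vec V, vec B], profile fixed.

    Quadratic in (V, B) plus the prior term, so the Hessian-vector
    product is exact; the problem is convex whenever all concentration
    parameters are >= 1 and remains well behaved otherwise.
    """

    def __init__(self, M_fixed, L_aug, P_aug, O_trunc, alpha, sigma2, X, epsilon):
        self.M = M_fixed
        self.L_aug = L_aug
        self.P_aug = P_aug
        self.O = O_trunc
        self.sigma2 = sigma2
        self.X = X
        self.w = (np.asarray(alpha, float) - 1.0) * sigma2
        self.floor = epsilon * _LOG_GUARD_FRACTION
        self.d1 = P_aug.shape[1]
        self.k = alpha.size
        self.p = 0 if X is None else X.shape[1]
        # Gram-form precomputation: data term through M'M, M'O, L'L, L'O
        self.GM = M_fixed.T @ M_fixed  # k x k
        self.TM = M_fixed.T @ O_trunc  # k x n
        self.o2 = float(np.sum(O_trunc**2))
        if self.p:
            self.GL = L_aug.T @ L_aug
            self.TL = L_aug.T @ O_trunc
            self.ML = M_fixed.T @ L_aug  # k x (d+1)
        self.nvar = self.d1 * self.k + self.d1 * self.p

    def unpack(self, x):
        d1, k, p = self.d1, self.k, self.p
        V = x[: d1 * k].reshape(d1, k)
        B = x[d1 * k :].reshape(d1, p) if p else None
        return V, B

    def pack(self, V, B):
        return np.concatenate([V.ravel(), B.ravel()]) if self.p else V.ravel()

    def value_and_grad(self, x):
        V, B = self.unpack(x)
        R = self.P_aug @ V  # n x k
        # f_data = 0.5 || O - M R^T - L B X^T ||^2 (scaled by sigma^2 via w)
        ER = self.GM @ R.T - self.TM  # k x n, d(data)/d(R^T) without covariates
        f_data = 0.5 * (self.o2 + np.sum(R.T * (ER - self.TM)))
        if self.p:
            CB = B @ self.X.T  # (d+1) x n
            f_data += 0.5 * np.sum(CB * (self.GL @ CB)) + np.sum(
                (self.ML.T @ R.T - self.TL) * CB
            )
            ER = ER + self.ML @ CB
        logR, dlogR = _safe_log(R, self.floor)
        f_prior = -float(self.w @ logR.sum(axis=0))
        gR = ER.T - dlogR * self.w[None, :]
        gV = self.P_aug.T @ gR
        grads = [gV.ravel()]
        if self.p:
            gB = self.GL @ CB @ self.X + (self.ML.T @ R.T - self.TL) @ self.X
            grads.append(gB.ravel())
        return f_data + f_prior, np.concatenate(grads)

    def hessp(self, x, y):
        V, B = self.unpack(x)
        dV, dB = self.unpack(y)
        R = self.P_aug @ V
        dR = self.P_aug @ dV
        dER = self.GM @ dR.T  # k x n
        if self.p:
            dCB = dB @ self.X.T
            dER = dER + self.ML @ dCB
        rr = np.maximum(R, self.floor)
        HR = dER.T + (self.w[None, :] / rr**2) * dR
        out = [(self.P_aug.T @ HR).ravel()]
        if self.p:
            HB = self.GL @ dCB @ self.X + self.ML.T @ dR.T @ self.X
            out.append(HB.ravel())
        return np.concatenate(out)

    def unscaled(self, f: float) -> float:
        return f / self.sigma2


def fit_bayescce_impute(
    basis: ComponentBasis,
    O_trunc: pd.DataFrame | np.ndarray,
    prior: DirichletPrior,
    imp: ImputationInput,
    X: pd.DataFrame | np.ndarray | None = None,
    options: SolverOptions | None = None,
) -> BayesCCEFit:
    """Two-stage fit anchored by measured cell counts.

    Stage 1 estimates the profile matrix from the reference samples by
    per-site box-constrained least squares; stage 2 solves the remaining
    problem in ``V`` (and ``B``), constraining reference rows to the
    measured counts within the measurement slack and non-reference rows
    to the relaxed simplex.  The component-to-cell-type assignment is
    the identity against the measured table's columns and is
    authoritative.
    """
    options = options or SolverOptions()
    O = _to_array(O_trunc)
    if O.shape != (basis.t, basis.n):
        raise ValidationError("O_trunc shape does not match basis")
    sample_ids = list(basis.sample_ids)
    pos = {s: i for i, s in enumerate(sample_ids)}
    ref_ids = list(imp.reference_sample_ids)
    missing = [s for s in ref_ids if s not in pos]
    if missing:
        raise ValidationError(f"reference sample ids not in the dataset: {missing}")
    ref_idx = np.array([pos[s] for s in ref_ids])
    nonref_idx = np.array(
        [i for i in range(len(sample_ids)) if i not in set(ref_idx)], dtype=int
    )

    Xv = _to_array(X, allow_none=True)
    R0 = imp.R0.to_numpy(dtype=float)
    k = R0.shape[1]
    if prior.k != k:
        raise ValidationError("prior and measured counts disagree on k")

    # Stage 1: profiles from the reference samples (fixed thereafter).
    M_fixed = estimate_M_from_reference(
        O[:, ref_idx], R0, None if Xv is None else Xv[ref_idx]
    )


    # Stage 2: fit of V (and B) with the profile fixed.
    sigma2 = max(estimate_sigma2(O, basis.P, Xv), 1e-12)
    L_aug, P_aug = _augment(basis.L), _augment(basis.P)
    obj = _ImputeObjective(
        M_fixed, L_aug, P_aug, O, prior.alpha, sigma2, Xv, options.epsilon
    )

    d1 = obj.d1
    nvar = obj.nvar
    cons = _impute_constraints(P_aug, ref_idx, nonref_idx, R0, options, nvar)

    # Certify feasibility of the constraint set and obtain a strictly
    # interior anchor for the starts.
    center = _interior_point_lp(cons, nvar)
    if center is None:
        worst = _min_reference_deviation(P_aug[ref_idx], R0)
        raise ValidationError(
            "infeasible constraint set: the component basis cannot reproduce "
            f"the measured counts closer than {worst:.4f} "
            f"(ref_slack={options.ref_slack}); increase d or ref_slack"
        )

    rng = np.random.default_rng(options.seed)
    n = len(sample_ids)
    best = None
    start_obj = None
    for _ in range(max(1, options.n_starts)):
        R_start = np.tile(prior.mean, (n, 1)) + rng.normal(
            0.0, options.jitter, size=(n, k)
        )
        R_start = np.clip(R_start, 2 * options.epsilon, None)
        R_start /= R_start.sum(axis=1, keepdims=True)
        R_start[ref_idx] = np.clip(R0, 2 * options.epsilon, None)
        B0 = np.zeros((d1, obj.p)) if obj.p else None
        V0 = _impute_start(P_aug, R_start, ref_idx, R0, 0.9 * options.ref_slack)
        x0 = obj.pack(V0, B0)
        solve_opts = options
        if options.solver == "barrier":
            for theta in (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0):
                cand = (1.0 - theta) * x0 + theta * center
                if _strictly_feasible(cand, cons):
                    x0 = cand
                    break
            else:
                solve_opts = _dc_replace(options, solver="trust-constr")
        if start_obj is None:
            start_obj = obj.value_and_grad(x0)[0]
        res = _solve(obj, x0, cons, solve_opts)
        if best is None or res.fun < best.fun:
            best = res

    V, B = obj.unpack(best.x)
    R_hat = np.maximum(P_aug @ V, options.epsilon)
    converged = best.converged
    if not converged:
        warnings.warn(
            f"imputation fit did not fully converge after {best.niter} iterations"
        )
    names = list(imp.R0.columns.astype(str))
    # A is reported as the least-squares preimage of the fixed profile.
    A_equiv, *_ = np.linalg.lstsq(L_aug, M_fixed, rcond=None)
    return BayesCCEFit(
        R_hat=pd.DataFrame(R_hat, index=sample_ids, columns=names),
        M_hat=pd.DataFrame(M_fixed, index=list(basis.selected_sites), columns=names),
        A=A_equiv,
        V=V,
        B=B,
        sigma2=sigma2,
        objective=float(obj.unscaled(best.fun)),
        start_objective=float(obj.unscaled(start_obj)),
        converged=converged,
        assignment={h: names[h] for h in range(k)},
        assignment_is_heuristic=False,
        n_starts=options.n_starts,
    )
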