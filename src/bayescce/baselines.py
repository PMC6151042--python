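"""Reference-based and reference-free baseline estimators.

* :func:`reference_based_estimate` — the classical constrained
  projection: given known cell-type profiles, each sample's proportions
  solve a simplex-constrained least-squares problem (a small QP).
* :func:`fit_nnmf` — constrained non-negative matrix factorization by
  alternating minimisation (QP over proportions, box-constrained least
  squares over profiles), on the most variable sites.
* :func:`construct_equivalent_solution` — the executable form of the
  non-identifiability argument: for any factorization there is a
  near-identity transform ``Q`` mixing two cell types that yields a
  *different* feasible factorization with *exactly* the same objective.
  This is why unconstrained reference-free factorizations recover linear
  combinations of cell proportions rather than the proportions
  themselves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import estimate_M_from_reference
from .exceptions import ValidationError

__all__ = [
    "EquivalentSolution",
    "reference_based_estimate",
    "fit_nnmf",
    "admissible_c_max",
    "construct_equivalent_solution",
    "NNMF_MAX_SITES",
]

#: Variable-site pre-filter size for the factorization baseline.
NNMF_MAX_SITES = 10_000


@dataclass(frozen=True)
class EquivalentSolution:
    """A distinct factorization with identical fit, by construction."""

    Q: np.ndarray  # k x k transform
    c: float
    c_max: float
    R_tilde: np.ndarray
    M_tilde: np.ndarray
    columns_swapped: bool

    def to_json(self, path) -> None:
        from pathlib import Path

        payload = {
            "c": self.c,
            "c_max": self.c_max,
            "columns_swapped": self.columns_swapped,
            "Q": self.Q.tolist(),
            "R_tilde": self.R_tilde.tolist(),
            "M_tilde": self.M_tilde.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _as_array(M) -> np.ndarray:
    return M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, float)


# ---------------------------------------------------------------------------
# Reference-based QP


def _simplex_lsq_kkt(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Equality-only KKT solve of min r'Gr - 2b'r s.t. sum r = 1."""
    k = G.shape[0]
    KKT = np.zeros((k + 1, k + 1))
    KKT[:k, :k] = 2.0 * G
    KKT[:k, k] = 1.0
    KKT[k, :k] = 1.0
    rhs = np.concatenate([2.0 * b, [1.0]])
    sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
    return sol[:k]


def _simplex_lsq(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """min ||y - M r||^2 s.t. r >= 0, sum r = 1.

    The sum-constrained solution is computed from the KKT system; only
    when it leaves the nonnegative orthant is the full QP solved (SLSQP,
    k is small).
    """
    from scipy.optimize import minimize

    k = M.shape[1]
    G = M.T @ M
    b = M.T @ y
    r = _simplex_lsq_kkt(G, b)
    if np.all(r >= 0):
        return r / r.sum()

    def fun(r):
        return float(r @ G @ r - 2.0 * b @ r), 2.0 * (G @ r - b)

    r0 = np.full(k, 1.0 / k)
    res = minimize(
        fun,
        r0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda r: r.sum() - 1.0, "jac": lambda r: np.ones(k)}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    r = np.clip(res.x, 0.0, None)
    return r / r.sum()


def reference_based_estimate(
    O: pd.DataFrame | np.ndarray, M: pd.DataFrame | np.ndarray
) -> pd.DataFrame | np.ndarray:
    """Proportions from known profiles, per-sample simplex-constrained QP.

    When both inputs are DataFrames, rows are matched on the site-id
    intersection (order of ``O``); an empty intersection is an error.
    """
    if isinstance(O, pd.DataFrame) and isinstance(M, pd.DataFrame):
        common = [s for s in O.index if s in set(M.index)]
        if not common:
            raise ValidationError("no common sites between O and the reference profiles")
        Ov = O.loc[common].to_numpy(dtype=float)
        Mv = M.loc[common].to_numpy(dtype=float)
        R = np.vstack([_simplex_lsq(Mv, Ov[:, i]) for i in range(Ov.shape[1])])
        return pd.DataFrame(R, index=list(O.columns), columns=list(M.columns))
    Ov, Mv = _as_array(O), _as_array(M)
    if Ov.shape[0] != Mv.shape[0]:
        raise ValidationError("O and M must share their site dimension")
    return np.vstack([_simplex_lsq(Mv, Ov[:, i]) for i in range(Ov.shape[1])])


# ---------------------------------------------------------------------------
# Alternating NNMF


def fit_nnmf(
    O: pd.DataFrame | np.ndarray,
    k: int,
    *,
    max_sites: int = NNMF_MAX_SITES,
    max_rounds: int = 200,
    rel_tol: float = 1e-6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Constrained NNMF of the beta matrix by alternating minimisation.

    Pre-selects the ``max_sites`` most variable sites (ties broken by
    site id), initialises the profile matrix with k-means centroids of
    the samples, then alternates the per-sample simplex QP (R step) and
    the per-site box-constrained least squares (M step) until the
    relative objective change drops below ``rel_tol``.  Each half-step
    solves its subproblem exactly, so the objective never increases.

    Returns ``(M, R, objective_trajectory)``.
    """
    if isinstance(O, pd.DataFrame):
        site_ids = np.array(list(map(str, O.index)))
        Ov = O.to_numpy(dtype=float)
    else:
        Ov = np.asarray(O, dtype=float)
        site_ids = np.array([f"site{j}" for j in range(Ov.shape[0])])
    if k < 1:
        raise ValidationError("k must be >= 1")

    if Ov.shape[0] > max_sites:
        var = Ov.var(axis=1, ddof=1)
        order = np.lexsort((site_ids, -var))
        Ov = Ov[order[:max_sites]]

    m, n = Ov.shape
    if k == 1:
        R = np.ones((n, 1))
        M = Ov.mean(axis=1, keepdims=True)
        obj = float(np.sum((Ov - M @ R.T) ** 2))
        return M, R, [obj]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(Ov.T)  # samples as observations
    M = np.clip(km.cluster_centers_.T, 0.0, 1.0)  # m x k

    trajectory: list[float] = []
    prev: float | None = None
    for _ in range(max_rounds):
        R = reference_based_estimate(Ov, M)
        M = estimate_M_from_reference(Ov, R)
        obj = float(np.sum((Ov - M @ R.T) ** 2))
        trajectory.append(obj)
        if prev is not None and prev - obj <= rel_tol * max(prev, 1e-300):
            break
        prev = obj
    return M, R, trajectory


# ---------------------------------------------------------------------------
# Non-identifiability transform


def admissible_c_max(M_hat: np.ndarray) -> tuple[float, bool]:
    """Largest admissible mixing coefficient for the given profiles.

    ``c_max = min_j min{ (1 - M_j1)/(1 - M_j2), M_j1 / M_j2 }`` taken
    over sites; when that bound is not below 1, the roles of the first
    two cell types are swapped (second return value).  Profiles must be
    strictly inside (0,1) on the first two columns and the two columns
    must differ.
    """
    M_hat = _as_array(M_hat)
    m1, m2 = M_hat[:, 0], M_hat[:, 1]
    if np.allclose(m1, m2):
        raise ValidationError(
            "the first two profile columns are identical; the two cell types "
            "are indistinguishable and the transform is undefined"
        )
    if np.any((M_hat[:, :2] <= 0) | (M_hat[:, :2] >= 1)):
        raise ValidationError("profile entries must lie strictly in (0,1)")

    def bound(a, b):
        return float(np.min(np.minimum((1.0 - a) / (1.0 - b), a / b)))

    c12 = bound(m1, m2)
    if c12 < 1.0:
        return c12, False
    return bound(m2, m1), True


def construct_equivalent_solution(
    M_hat: np.ndarray | pd.DataFrame,
    R_hat: np.ndarray | pd.DataFrame,
    c: float,
) -> EquivalentSolution:
    """Build the equal-objective factorization ``(M Q^{-T}, R Q)``.

    ``Q`` is the identity except ``Q_11 = 1-c``, ``Q_12 = c``; its
    inverse is the identity except ``Q^{-1}_11 = 1/(1-c)``,
    ``Q^{-1}_12 = c/(c-1)``.  Because ``Q^{-T} Q^T = I`` the residual
    ``O - M R^T`` is unchanged, rows of ``R Q`` still sum to one, and
    for ``0 < c < c_max`` the transformed profiles stay inside (0,1).
    """
    M_hat, R_hat = _as_array(M_hat), _as_array(R_hat)
    k = R_hat.shape[1]
    if M_hat.shape[1] != k or k < 2:
        raise ValidationError("need matching profile/proportion matrices with k >= 2")
    c_max, swapped = admissible_c_max(M_hat)
    if swapped:
        perm = np.arange(k)
        perm[[0, 1]] = [1, 0]
        M_hat = M_hat[:, perm]
        R_hat = R_hat[:, perm]
    if not 0.0 < c < c_max:
        raise ValidationError(
            f"c={c} outside the admissible range (0, {c_max:.6g})"
        )
    Q = np.eye(k)
    Q[0, 0] = 1.0 - c
    Q[0, 1] = c
    Q_inv = np.eye(k)
    Q_inv[0, 0] = 1.0 / (1.0 - c)
    Q_inv[0, 1] = c / (c - 1.0)
    R_tilde = R_hat @ Q
    M_tilde = M_hat @ Q_inv.T
    return EquivalentSolution(
        Q=Q, c=float(c), c_max=float(c_max), R_tilde=R_tilde, M_tilde=M_tilde,
        columns_swapped=swapped,
    )
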