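"""Dirichlet priors on cell-type composition.

A heterogeneous tissue sample is a mixture of ``k`` cell types with
proportions on the probability simplex.  Across individuals these
proportions are modelled as draws from a Dirichlet distribution with
concentration parameters ``alpha_1..alpha_k``; the parameters are fitted
by maximum likelihood to previously measured cell counts (no methylation
data is needed to build the prior).

The module provides the :class:`DirichletPrior` container, the
fixed-point maximum-likelihood fitter, the (unnormalised) log prior
density term used by the deconvolution objective, and tab-delimited IO
for prior and raw cell-count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "DirichletPrior",
    "WHOLE_BLOOD_K6",
    "WHOLE_BLOOD_K3",
    "uniform_prior",
    "fit_dirichlet_mle",
    "log_prior_density",
    "read_prior",
    "write_prior",
    "read_cell_counts",
]

#: Floor applied to zero proportions before taking logs (rows are
#: renormalised afterwards).  The Dirichlet log-likelihood is undefined
#: at exact zeros, which occur in raw cell-count tables for rare types.
ZERO_FLOOR = 1e-6


@dataclass(frozen=True)
class DirichletPrior:
    """Concentration parameters of a Dirichlet cell-composition prior."""

    alpha: np.ndarray
    cell_type_names: tuple[str, ...]
    source_n: int | None = None

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        names = tuple(self.cell_type_names)
        object.__setattr__(self, "cell_type_names", names)
        if alpha.ndim != 1:
            raise ValidationError("alpha must be a 1-d vector")
        if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
            raise ValidationError("all Dirichlet parameters must be finite and > 0")
        if len(names) != alpha.size:
            raise ValidationError(
                f"{len(names)} cell-type names for {alpha.size} parameters"
            )
        if len(set(names)) != len(names):
            raise ValidationError("cell-type names must be unique")

    @property
    def k(self) -> int:
        return self.alpha.size

    @property
    def mean(self) -> np.ndarray:
        """Prior mean proportions alpha / sum(alpha)."""
        return self.alpha / self.alpha.sum()


#: Whole-blood prior over six leukocyte types, fitted by maximum
#: likelihood to high-resolution clinical cell counts of 595 adults.
WHOLE_BLOOD_K6 = DirichletPrior(
    alpha=np.array([15.0727, 1.8439, 2.5392, 1.7934, 0.7240, 0.7404]),
    cell_type_names=("Granulocytes", "Monocytes", "CD4T", "CD8T", "Bcells", "NK"),
    source_n=595,
)

#: The same cell counts collapsed to three major types.
WHOLE_BLOOD_K3 = DirichletPrior(
    alpha=np.array([7.7681, 0.9503, 2.9876]),
    cell_type_names=("Granulocytes", "Monocytes", "Lymphocytes"),
    source_n=595,
)


def uniform_prior(k: int, cell_type_names: tuple[str, ...] | None = None) -> DirichletPrior:
    """Non-informative prior: all concentration parameters equal to 1.

    Under this prior the log-density term of the deconvolution objective
    vanishes identically, reducing the model to its constraint set.
    """
    if cell_type_names is None:
        cell_type_names = tuple(f"CT{h + 1}" for h in range(k))
    return DirichletPrior(alpha=np.ones(k), cell_type_names=cell_type_names)


def _validate_simplex_rows(P: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValidationError("proportions must be an n x k matrix")
    if np.any(P < -tol):
        raise ValidationError("proportions must be nonnegative")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"row {bad} sums to {sums[bad]:.8f}, not 1 (tolerance {tol})"
        )
    return P


def _floor_and_renormalize(P: np.ndarray, floor: float = ZERO_FLOOR) -> np.ndarray:
    P = np.clip(P, floor, None)
    return P / P.sum(axis=1, keepdims=True)


def _inv_digamma(y: np.ndarray) -> np.ndarray:
    # Newton inversion of the digamma function (Minka-style init).
    y = np.asarray(y, dtype=float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(8):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def _newton_polish(
    alpha: np.ndarray, mean_log_p: np.ndarray, n: int, tol: float, max_iter: int = 200
) -> tuple[np.ndarray, bool]:
    """Damped Newton ascent on the Dirichlet log-likelihood.

    The Hessian is -diag(q) + c 11' with q = n psi'(alpha) and
    c = n psi'(sum alpha); its inverse is applied via Sherman-Morrison.
    """
    for _ in range(max_iter):
        g = n * (digamma(alpha.sum()) - digamma(alpha) + mean_log_p)
        q = n * polygamma(1, alpha)
        c = n * polygamma(1, alpha.sum())
        # Newton step: solve (diag(q) - c 11') p = g
        gq = g / q
        denom = 1.0 / c - np.sum(1.0 / q)
        p = gq + (gq.sum() / denom) / q
        step = 1.0
        f0 = dirichlet_loglik(alpha, mean_log_p, n)
        for _ in range(50):
            cand = alpha + step * p
            if np.all(cand > 0) and dirichlet_loglik(cand, mean_log_p, n) >= f0:
                break
            step *= 0.5
        else:
            return alpha, False
        moved = np.max(np.abs(step * p))
        alpha = alpha + step * p
        if moved < tol:
            return alpha, True
    return alpha, False


def dirichlet_loglik(alpha: np.ndarray, mean_log_p: np.ndarray, n: int) -> float:
    """Dirichlet log-likelihood in terms of the sufficient statistic
    ``mean_log_p = (1/n) sum_i log p_i`` (per component)."""
    return float(
        n * (gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * mean_log_p).sum())
    )


def fit_dirichlet_mle(
    proportions: np.ndarray | pd.DataFrame,
    cell_type_names: tuple[str, ...] | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> DirichletPrior:
    """Maximum-likelihood Dirichlet fit to observed proportion vectors.

    Uses the classical fixed-point iteration on the digamma equations,

        alpha_h <- psi^{-1}( psi(sum_l alpha_l) + mean_i log p_ih ),

    initialised by moment matching.  Convergence is declared when the
    maximum absolute parameter change drops below ``tol``.

    Parameters
    ----------
    proportions
        n x k matrix; every row nonnegative and summing to 1 within
        1e-6.  Zeros are floored at ``ZERO_FLOOR`` and rows renormalised.
    cell_type_names
        Optional labels; taken from the DataFrame columns if present.

    Raises
    ------
    ValidationError
        If rows are not on the simplex or n < 2k.
    ConvergenceError
        If the iteration does not converge (e.g. the degenerate case of
        all rows identical, where the MLE diverges).
    """
    if isinstance(proportions, pd.DataFrame):
        if cell_type_names is None:
            cell_type_names = tuple(map(str, proportions.columns))
        proportions = proportions.to_numpy(dtype=float)
    P = _validate_simplex_rows(proportions)
    n, k = P.shape
    if n < 2 * k:
        raise ValidationError(f"need at least 2k={2 * k} samples to fit, got {n}")
    P = _floor_and_renormalize(P)

    mean_p = P.mean(axis=0)
    mean_p2 = (P**2).mean(axis=0)
    mean_log_p = np.log(P).mean(axis=0)

    # Moment-matching initialisation: common precision from the first
    # component with non-degenerate variance.
    var_p = mean_p2 - mean_p**2
    ok = var_p > 1e-12
    if not np.any(ok):
        raise ConvergenceError(
            "all proportion rows are (numerically) identical; the Dirichlet "
            "MLE diverges in this concentration limit",
            last_iterate=None,
            grad_norm=np.inf,
        )
    j = int(np.argmax(var_p))
    s0 = (mean_p[j] - mean_p2[j]) / var_p[j]
    alpha = np.clip(mean_p * max(s0, 1e-3), 1e-8, None)

    converged = False
    for _ in range(max_iter):
        new_alpha = _inv_digamma(digamma(alpha.sum()) + mean_log_p)
        if not np.all(np.isfinite(new_alpha)) or np.any(new_alpha <= 0):
            grad = n * (digamma(alpha.sum()) - digamma(alpha) + mean_log_p)
            raise ConvergenceError(
                "fixed-point iteration left the parameter domain",
                last_iterate=alpha,
                grad_norm=float(np.linalg.norm(grad)),
            )
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            converged = True
            break
        if alpha.sum() > 1e12:
            grad = n * (digamma(alpha.sum()) - digamma(alpha) + mean_log_p)
            raise ConvergenceError(
                "Dirichlet MLE diverging (near-degenerate proportions)",
                last_iterate=alpha,
                grad_norm=float(np.linalg.norm(grad)),
            )
    if not converged:
        # Fixed-point convergence is linear and stalls for concentrated
        # distributions; finish with damped Newton steps using the
        # diagonal-plus-rank-one Hessian (Sherman-Morrison inverse).
        alpha, converged = _newton_polish(alpha, mean_log_p, n, tol)
    if not converged:
        grad = n * (digamma(alpha.sum()) - digamma(alpha) + mean_log_p)
        raise ConvergenceError(
            f"no convergence after {max_iter} fixed-point iterations "
            "plus Newton polishing",
            last_iterate=alpha,
            grad_norm=float(np.linalg.norm(grad)),
        )

    if cell_type_names is None:
        cell_type_names = tuple(f"CT{h + 1}" for h in range(k))
    return DirichletPrior(alpha=alpha, cell_type_names=cell_type_names, source_n=n)


def log_prior_density(R: np.ndarray, prior: DirichletPrior) -> float:
    """Unnormalised Dirichlet log prior over all samples.

    Returns ``sum_h (alpha_h - 1) sum_i log R_ih`` — exactly the prior
    term of the deconvolution objective; the normalising constant is
    omitted since it does not depend on ``R``.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[1] != prior.k:
        raise ValidationError(f"R must have k={prior.k} columns")
    if np.any(R <= 0):
        raise ValidationError("log prior density requires strictly positive entries")
    return float(((prior.alpha - 1.0) * np.log(R).sum(axis=0)).sum())


# ---------------------------------------------------------------------------
# IO


def write_prior(prior: DirichletPrior, path: str | Path) -> None:
    df = pd.DataFrame(
        {"cell_type_name": prior.cell_type_names, "alpha": prior.alpha}
    )
    df.to_csv(path, sep="\t", index=False)


def read_prior(path: str | Path) -> DirichletPrior:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type_name", "alpha"} <= set(df.columns):
        raise ValidationError(
            f"{path}: prior file needs columns 'cell_type_name' and 'alpha'"
        )
    return DirichletPrior(
        alpha=df["alpha"].to_numpy(dtype=float),
        cell_type_names=tuple(df["cell_type_name"].astype(str)),
    )


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    """Read a samples x cell-types table of counts or proportions.

    Counts are row-normalised to proportions; the index column holds
    sample identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValidationError(f"{path}: negative cell counts")
    sums = vals.sum(axis=1)
    if np.any(sums <= 0):
        raise ValidationError(f"{path}: a sample has zero total count")
    return pd.DataFrame(vals / sums[:, None], index=df.index, columns=df.columns)
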