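"""Sparse low-rank basis of cell-composition variation (ReFACTor).

The deconvolution model searches for cell proportions inside the span of
a small principal-component basis computed from the sites most
informative for the dominant low-rank structure of the data.  The
procedure:

1. (optionally) residualise each site on the covariates by OLS;
2. standardise each site (mean 0, unit sample sd);
3. rank sites by the Euclidean distance between their standardised row
   and its rank-``k`` truncated-SVD approximation, ascending — sites the
   low-rank structure explains best come first;
4. keep the top ``t`` sites and run PCA (site-centred SVD) on the
   truncated, covariate-adjusted matrix to obtain loadings ``L`` (t x d)
   and scores ``P`` (n x d).

Defaults ``t=500``, ``k=6`` match standard practice on methylation
arrays; ``d`` defaults to 6 for simulated data and 10 for real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ComponentBasis",
    "select_informative_sites",
    "compute_components",
    "DEFAULT_T",
    "DEFAULT_K",
    "DEFAULT_D_SIMULATED",
    "DEFAULT_D_REAL",
]

DEFAULT_T = 500
DEFAULT_K = 6
DEFAULT_D_SIMULATED = 6
DEFAULT_D_REAL = 10


@dataclass(frozen=True)
class ComponentBasis:
    """Loadings/scores of the first ``d`` components on selected sites."""

    selected_sites: tuple[str, ...]
    L: np.ndarray  # t x d loadings
    P: np.ndarray  # n x d scores
    explained_variance: np.ndarray  # d
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        if self.L.shape != (len(self.selected_sites), self.P.shape[1]):
            raise ValidationError("L dimensions inconsistent with selected sites / d")
        if self.P.shape != (len(self.sample_ids), self.d):
            raise ValidationError("P dimensions inconsistent")

    @property
    def t(self) -> int:
        return self.L.shape[0]

    @property
    def d(self) -> int:
        return self.L.shape[1]

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "selected_sites.txt").write_text(
            "\n".join(self.selected_sites) + "\n"
        )
        pd.DataFrame(
            self.P,
            index=list(self.sample_ids),
            columns=[f"PC{j + 1}" for j in range(self.d)],
        ).to_csv(outdir / "scores.tsv", sep="\t", index_label="sample_id")


def _as_matrix(O: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(O, pd.DataFrame):
        return O.to_numpy(dtype=float), list(map(str, O.index)), list(map(str, O.columns))
    O = np.asarray(O, dtype=float)
    return (
        O,
        [f"site{j}" for j in range(O.shape[0])],
        [f"sample{i}" for i in range(O.shape[1])],
    )


def _covariate_design(X: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray | None:
    if X is None:
        return None
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    if Xv.shape[0] != n:
        raise ValidationError(f"covariate table has {Xv.shape[0]} rows for n={n} samples")
    return np.column_stack([np.ones(n), Xv])


def _residualize(mat: np.ndarray, design: np.ndarray | None) -> np.ndarray:
    """OLS residuals of each row of ``mat`` on the design (with intercept)."""
    if design is None:
        return mat
    coef, *_ = np.linalg.lstsq(design, mat.T, rcond=None)
    return mat - (design @ coef).T


def select_informative_sites(
    O: pd.DataFrame | np.ndarray,
    k: int = DEFAULT_K,
    t: int = DEFAULT_T,
    X: pd.DataFrame | np.ndarray | None = None,
) -> list[str]:
    """Rank sites by low-rank reconstruction error and return the top t.

    Zero-variance sites can never be selected before any varying site;
    ties are broken by site-identifier order.
    """
    mat, site_ids, sample_ids = _as_matrix(O)
    m, n = mat.shape
    if t > m:
        raise ValidationError(f"t={t} exceeds the number of sites m={m}")
    if not k < min(m, n):
        raise ValidationError(f"k={k} must be smaller than min(m, n)={min(m, n)}")

    design = _covariate_design(X, n)
    adj = _residualize(mat, design)

    mu = adj.mean(axis=1, keepdims=True)
    sd = adj.std(axis=1, ddof=1, keepdims=True)
    varying = sd[:, 0] > 0
    Z = np.zeros_like(adj)
    Z[varying] = (adj[varying] - mu[varying]) / sd[varying]

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    Zk = (U[:, :k] * s[:k]) @ Vt[:k]
    dist = np.linalg.norm(Z - Zk, axis=1)
    dist[~varying] = np.inf

    order = np.lexsort((np.array(site_ids), dist))
    return [site_ids[j] for j in order[:t]]


def compute_components(
    O: pd.DataFrame | np.ndarray,
    selected_sites: list[str],
    d: int,
    X: pd.DataFrame | np.ndarray | None = None,
) -> ComponentBasis:
    """PCA on the covariate-adjusted, site-centred truncated matrix.

    Returns loadings ``L = U_d`` (orthonormal columns) and scores
    ``P = V_d diag(s_d)`` so that ``L @ P.T`` reconstructs the centred
    truncated matrix when ``d`` equals its rank.  Sign convention: each
    loading column has nonnegative sum (columns of L and P flipped
    jointly otherwise).
    """
    mat, site_ids, sample_ids = _as_matrix(O)
    n = mat.shape[1]
    index = {sid: j for j, sid in enumerate(site_ids)}
    try:
        rows = [index[s] for s in selected_sites]
    except KeyError as e:
        raise ValidationError(f"selected site {e} not present in the matrix") from None
    sub = mat[rows]

    design = _covariate_design(X, n)
    sub = _residualize(sub, design)
    sub = sub - sub.mean(axis=1, keepdims=True)

    rank = np.linalg.matrix_rank(sub)
    if d > min(len(rows), n):
        raise ValidationError(f"d={d} exceeds matrix dimensions {sub.shape}")
    if d > rank:
        raise ValidationError(
            f"d={d} exceeds the rank of the truncated matrix (achievable rank {rank})"
        )

    U, s, Vt = np.linalg.svd(sub, full_matrices=False)
    L = U[:, :d]
    P = Vt[:d].T * s[:d]
    flip = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * flip
    P = P * flip
    explained = (s[:d] ** 2) / max(n - 1, 1)
    return ComponentBasis(
        selected_sites=tuple(selected_sites),
        L=L,
        P=P,
        explained_variance=explained,
        sample_ids=tuple(sample_ids),
    )
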