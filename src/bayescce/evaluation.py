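"""Quality metrics for composition estimates.

Reference-free deconvolution recovers components only up to relabelling
(and, without anchoring cell counts, up to affine scale), so estimates
are scored after matching estimated columns to truth columns:

* MAC — mean absolute Pearson correlation over the best bijective
  matching of estimated components to true cell types;
* MAE — mean absolute error per matched pair, optionally after min-max
  rescaling each estimated column to [0,1] (the treatment applied to
  components that carry no absolute scale);
* per-cell-type R² — variance of each true proportion column explained
  by an OLS predictor on all k components jointly.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import ValidationError

__all__ = [
    "EvaluationReport",
    "match_and_mac",
    "mae",
    "explained_variance_per_celltype",
    "evaluate",
]

#: Above this k the exhaustive k! permutation search is replaced by
#: Hungarian assignment on the |r| matrix.
EXHAUSTIVE_K_MAX = 8


@dataclass(frozen=True)
class EvaluationReport:
    mac: float
    per_cell_type_abs_corr: np.ndarray
    mae: float
    per_cell_type_mae: np.ndarray
    permutation: tuple[int, ...]  # estimated column -> truth column
    r2_per_cell_type: np.ndarray
    excluded_samples: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "mac": self.mac,
            "per_cell_type_abs_corr": list(map(float, self.per_cell_type_abs_corr)),
            "mae": self.mae,
            "per_cell_type_mae": list(map(float, self.per_cell_type_mae)),
            "permutation": list(self.permutation),
            "r2_per_cell_type": list(map(float, self.r2_per_cell_type)),
            "excluded_samples": list(self.excluded_samples),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_table(self) -> str:
        lines = [f"{'component':>10} {'|r|':>8} {'MAE':>8} {'R2':>8}"]
        for est, tru in enumerate(self.permutation):
            lines.append(
                f"{est}->{tru:<7} {self.per_cell_type_abs_corr[est]:8.4f} "
                f"{self.per_cell_type_mae[est]:8.4f} {self.r2_per_cell_type[tru]:8.4f}"
            )
        lines.append(f"{'mean':>10} {self.mac:8.4f} {self.mae:8.4f}")
        return "\n".join(lines)


def _as_array(R) -> np.ndarray:
    R = R.to_numpy(dtype=float) if isinstance(R, pd.DataFrame) else np.asarray(R, float)
    if R.ndim != 2:
        raise ValidationError("expected an n x k matrix")
    return R


def _abs_corr_matrix(R_est: np.ndarray, R_true: np.ndarray) -> np.ndarray:
    """|Pearson r| between every estimated and true column; zero-variance
    columns get correlation 0 (with a warning), never an exception."""
    k = R_est.shape[1]
    C = np.zeros((k, k))
    se = R_est.std(axis=0)
    st = R_true.std(axis=0)
    if np.any(se == 0) or np.any(st == 0):
        warnings.warn("zero-variance column encountered; its correlations set to 0")
    Ez = (R_est - R_est.mean(axis=0)) / np.where(se == 0, 1.0, se)
    Tz = (R_true - R_true.mean(axis=0)) / np.where(st == 0, 1.0, st)
    C = np.abs(Ez.T @ Tz) / R_est.shape[0]
    C[se == 0, :] = 0.0
    C[:, st == 0] = 0.0
    return C


def match_and_mac(
    R_est,
    R_true,
    allow_permutation: bool = True,
) -> tuple[tuple[int, ...], np.ndarray, float]:
    """Best bijection between estimated and true columns, by MAC.

    Returns ``(permutation, per_pair_abs_corr, mac)`` where
    ``permutation[i]`` is the truth column assigned to estimated column
    ``i``.  With ``allow_permutation=False`` the identity assignment is
    scored instead.  Ties are broken by the lexicographically smallest
    permutation.
    """
    Re, Rt = _as_array(R_est), _as_array(R_true)
    if Re.shape != Rt.shape:
        raise ValidationError(f"shape mismatch: {Re.shape} vs {Rt.shape}")
    n, k = Re.shape
    if n < 3:
        raise ValidationError("need at least 3 samples to correlate")
    C = _abs_corr_matrix(Re, Rt)

    if not allow_permutation:
        perm = tuple(range(k))
    elif k <= EXHAUSTIVE_K_MAX:
        best, perm = -np.inf, tuple(range(k))
        for p in itertools.permutations(range(k)):
            score = C[np.arange(k), p].sum()
            if score > best + 1e-15:
                best, perm = score, p
    else:
        rows, cols = linear_sum_assignment(-C)
        perm = tuple(int(c) for c in cols[np.argsort(rows)])

    per_pair = C[np.arange(k), list(perm)]
    return perm, per_pair, float(per_pair.mean())


def mae(
    R_est,
    R_true,
    rescale: bool = False,
    permutation: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, float]:
    """Mean absolute error per matched column pair, and its mean.

    With ``rescale`` on, each estimated column is min-max scaled to
    [0,1] first — the treatment applied to components that are only
    defined up to affine transformation.  A constant estimated column is
    left unscaled with a warning.
    """
    Re, Rt = _as_array(R_est), _as_array(R_true)
    if Re.shape != Rt.shape:
        raise ValidationError(f"shape mismatch: {Re.shape} vs {Rt.shape}")
    k = Re.shape[1]
    if permutation is None:
        permutation = tuple(range(k))
    if rescale:
        Re = Re.copy()
        for h in range(k):
            lo, hi = Re[:, h].min(), Re[:, h].max()
            if hi > lo:
                Re[:, h] = (Re[:, h] - lo) / (hi - lo)
            else:
                warnings.warn(f"constant estimated column {h} left unscaled")
    per = np.array(
        [np.abs(Re[:, h] - Rt[:, permutation[h]]).mean() for h in range(k)]
    )
    return per, float(per.mean())


def explained_variance_per_celltype(components, R_true) -> np.ndarray:
    """R² of each true proportion column under OLS on all components.

    Fits, per cell type, ordinary least squares of the truth column on
    the k components plus an intercept (minimum-norm solution with a
    warning if the components are collinear).
    """
    P, Rt = _as_array(components), _as_array(R_true)
    n, k = P.shape
    if Rt.shape[0] != n:
        raise ValidationError("sample-count mismatch")
    if n <= k + 1:
        raise ValidationError(f"need n > k+1 = {k + 1} samples, got {n}")
    design = np.column_stack([np.ones(n), P])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear components; using the minimum-norm OLS solution")
    coef, *_ = np.linalg.lstsq(design, Rt, rcond=None)
    resid = Rt - design @ coef
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Rt - Rt.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return np.clip(r2, 0.0, 1.0)


def evaluate(
    R_est,
    R_true,
    *,
    allow_permutation: bool = True,
    rescale: bool = False,
    exclude_samples: tuple[str, ...] = (),
) -> EvaluationReport:
    """Full report: matching, MAC, MAE and per-cell-type R².

    ``exclude_samples`` removes rows (by identifier, when DataFrames are
    given) before any metric is computed — used to hold out reference
    samples with known counts when scoring imputation.
    """
    if exclude_samples:
        if not isinstance(R_est, pd.DataFrame) or not isinstance(R_true, pd.DataFrame):
            raise ValidationError("sample exclusion requires DataFrame inputs")
        keep = [s for s in R_est.index if s not in set(exclude_samples)]
        R_est = R_est.loc[keep]
        R_true = R_true.loc[keep]
    perm, per_corr, mac_val = match_and_mac(R_est, R_true, allow_permutation)
    per_mae, mean_mae = mae(R_est, R_true, rescale=rescale, permutation=perm)
    r2 = explained_variance_per_celltype(R_est, R_true)
    return EvaluationReport(
        mac=mac_val,
        per_cell_type_abs_corr=per_corr,
        mae=mean_mae,
        per_cell_type_mae=per_mae,
        permutation=perm,
        r2_per_cell_type=r2,
        excluded_samples=tuple(exclude_samples),
    )
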