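"""Synthetic heterogeneous methylation data with known ground truth.

The generative model: each cell type ``h`` has a mean methylation level
``mu_jh`` at site ``j`` (beta scale, in [0,1]) with per-site biological
variability ``sd_jh``.  For each simulated individual, cell-specific
levels are drawn from normal distributions with these parameters
truncated to [0,1]; the observed beta value is the mixture of those
levels weighted by the individual's cell proportions (a Dirichlet draw),
plus additive Gaussian technical noise:

    O_ji = sum_h R_ih * m_jhi + (S X^T)_ji + eps_ji,   eps_ji ~ N(0, sigma^2)

A *shared-profile* mode reuses one mean matrix for all individuals
(``m_jhi = mu_jh``), which makes the technical-noise level exactly
identifiable by regressing ``O`` on the true proportions.

Profile parameters are fabricated rather than fitted to sorted-cell
data: a configurable fraction of sites is cell-type informative (means
separated by at least a given gap across cell types) and the remainder
share one mean across types.  This preserves the structure real mixtures
exhibit — few informative sites, bounded variability — while keeping the
generator self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError
from .prior import DirichletPrior, fit_dirichlet_mle

__all__ = [
    "ProfileModel",
    "SimulatedDataset",
    "make_profile_model",
    "simulate_dataset",
    "estimate_noisy_prior",
    "recover_sigma",
    "write_dataset",
]

DEFAULT_SIGMA = 0.01  # technical-noise sd on the beta scale
DEFAULT_SD = 0.05  # per-site biological sd of cell-specific levels
DEFAULT_INFORMATIVE_FRACTION = 0.25


@dataclass(frozen=True)
class ProfileModel:
    """Per-site, per-cell-type mean/sd of methylation levels."""

    mu: np.ndarray  # m x k, in [0,1]
    sd: np.ndarray  # m x k, >= 0
    site_ids: tuple[str, ...]
    cell_type_names: tuple[str, ...]
    informative_sites: np.ndarray | None = None  # indices, by construction

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sd", sd)
        if mu.shape != sd.shape or mu.ndim != 2:
            raise ValidationError("mu and sd must be m x k matrices of equal shape")
        if np.any(mu < 0) or np.any(mu > 1):
            raise ValidationError("mu entries must lie in [0,1]")
        if np.any(sd < 0):
            raise ValidationError("sd entries must be nonnegative")
        if len(self.site_ids) != mu.shape[0]:
            raise ValidationError("site_ids length mismatch")
        if len(self.cell_type_names) != mu.shape[1]:
            raise ValidationError("cell_type_names length mismatch")

    @property
    def m(self) -> int:
        return self.mu.shape[0]

    @property
    def k(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated beta-value matrix with its generating ground truth."""

    O: pd.DataFrame  # m sites x n samples
    R_true: pd.DataFrame  # n samples x k
    M_shared: pd.DataFrame | None  # m x k mean profiles (shared mode)
    alpha_true: DirichletPrior
    sigma: float
    seed: int
    X: pd.DataFrame | None = None  # n x p covariates
    S: pd.DataFrame | None = None  # m x p covariate effects
    per_individual_profiles: np.ndarray | None = None  # n x m x k

    @property
    def m(self) -> int:
        return self.O.shape[0]

    @property
    def n(self) -> int:
        return self.O.shape[1]

    @property
    def k(self) -> int:
        return self.R_true.shape[1]


def make_profile_model(
    m: int,
    k: int,
    seed: int,
    separation: float = 0.3,
    *,
    informative_fraction: float = DEFAULT_INFORMATIVE_FRACTION,
    sd: float = DEFAULT_SD,
    cell_type_names: tuple[str, ...] | None = None,
) -> ProfileModel:
    """Fabricate profile parameters with a controlled informative fraction.

    ``round(informative_fraction * m)`` sites get cell-type means whose
    max-min gap is at least ``separation`` (two anchor cell types at the
    ends of the gap, the rest uniform between them); all other sites
    share a single mean across cell types.  Means are constructed inside
    [0,1], so no clipping can shrink the gap.
    """
    if k < 2:
        raise ValidationError("need at least k=2 cell types")
    if m < k:
        raise ValidationError(f"need m >= k sites, got m={m}, k={k}")
    if not 0 <= separation <= 1:
        raise ValidationError("separation must lie in [0,1]")
    rng = np.random.default_rng(seed)

    n_inf = int(round(informative_fraction * m))
    mu = np.empty((m, k))
    # Uninformative sites: identical mean across cell types.
    base = rng.uniform(0.05, 0.95, size=m)
    mu[:] = base[:, None]

    inf_idx = rng.choice(m, size=n_inf, replace=False)
    inf_idx.sort()
    for j in inf_idx:
        low = rng.uniform(0.0, max(1.0 - separation, 1e-12))
        gap = separation + rng.uniform(0.0, max(0.0, min(0.25, 1.0 - separation - low)))
        levels = np.concatenate(
            [[low, low + gap], rng.uniform(low, low + gap, size=k - 2)]
        )
        mu[j] = levels[rng.permutation(k)]

    mu = np.clip(mu, 0.0, 1.0)
    sd_mat = np.full((m, k), float(sd))
    site_ids = tuple(f"cg{j:08d}" for j in range(m))
    if cell_type_names is None:
        cell_type_names = tuple(f"CT{h + 1}" for h in range(k))
    return ProfileModel(
        mu=mu,
        sd=sd_mat,
        site_ids=site_ids,
        cell_type_names=cell_type_names,
        informative_sites=inf_idx,
    )


def _truncnorm_01(rng: np.random.Generator, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Normal(mu, sd) truncated to [0,1] by inverse-CDF (bounded runtime)."""
    sd = np.broadcast_to(sd, mu.shape)
    out = np.array(np.broadcast_to(mu, mu.shape), dtype=float, copy=True)
    pos = sd > 0
    a = norm.cdf((0.0 - mu[pos]) / sd[pos])
    b = norm.cdf((1.0 - mu[pos]) / sd[pos])
    u = rng.uniform(size=int(pos.sum()))
    out[pos] = mu[pos] + sd[pos] * norm.ppf(a + u * (b - a))
    return np.clip(out, 0.0, 1.0)  # guards ppf round-off at the edges


def simulate_dataset(
    profiles: ProfileModel,
    n: int,
    alpha: DirichletPrior,
    sigma: float = DEFAULT_SIGMA,
    *,
    shared_profiles: bool = False,
    clip: bool = True,
    seed: int = 0,
    n_covariates: int = 0,
    covariate_effect_sd: float = 0.02,
    keep_profiles: bool = False,
) -> SimulatedDataset:
    """Simulate an m x n beta-value matrix with known composition.

    Parameters
    ----------
    shared_profiles
        If True, every individual uses the mean matrix ``mu`` directly
        (no per-individual biological draw); the noiseless observation
        is then exactly ``mu @ R_true.T``.
    clip
        Clip observed values to [0,1] after adding noise (beta values
        are bounded by definition).  Disable for noise-recovery checks.
    n_covariates
        If positive, adds ``p`` standard-normal covariate columns with
        Normal(0, covariate_effect_sd) per-site effects before noise.
    keep_profiles
        Retain the n x m x k per-individual draws (memory-heavy).
    """
    if alpha.k != profiles.k:
        raise ValidationError(
            f"prior has k={alpha.k} but profiles have k={profiles.k}"
        )
    if sigma < 0:
        raise ValidationError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    m, k = profiles.m, profiles.k

    R = rng.dirichlet(alpha.alpha, size=n)
    R /= R.sum(axis=1, keepdims=True)

    if shared_profiles:
        signal = profiles.mu @ R.T  # m x n
        per_ind = None
    else:
        signal = np.empty((m, n))
        per_ind = np.empty((n, m, k)) if keep_profiles else None
        for i in range(n):
            levels = _truncnorm_01(rng, profiles.mu, profiles.sd)
            signal[:, i] = levels @ R[i]
            if per_ind is not None:
                per_ind[i] = levels

    X = S = None
    if n_covariates > 0:
        Xv = rng.standard_normal((n, n_covariates))
        Sv = rng.normal(0.0, covariate_effect_sd, size=(m, n_covariates))
        signal = signal + Sv @ Xv.T
        X = pd.DataFrame(
            Xv,
            index=[f"S{i + 1:04d}" for i in range(n)],
            columns=[f"covar{p + 1}" for p in range(n_covariates)],
        )
        S = pd.DataFrame(Sv, index=list(profiles.site_ids), columns=X.columns)

    O = signal + rng.normal(0.0, sigma, size=signal.shape) if sigma > 0 else signal
    if clip:
        O = np.clip(O, 0.0, 1.0)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    O_df = pd.DataFrame(O, index=list(profiles.site_ids), columns=sample_ids)
    R_df = pd.DataFrame(R, index=sample_ids, columns=list(alpha.cell_type_names))
    M_df = pd.DataFrame(
        profiles.mu, index=list(profiles.site_ids), columns=list(alpha.cell_type_names)
    )
    return SimulatedDataset(
        O=O_df,
        R_true=R_df,
        M_shared=M_df if shared_profiles else None,
        alpha_true=alpha,
        sigma=float(sigma),
        seed=int(seed),
        X=X,
        S=S,
        per_individual_profiles=per_ind,
    )


def estimate_noisy_prior(
    alpha_true: DirichletPrior, n_prior: int, seed: int
) -> DirichletPrior:
    """Emulate prior misspecification: refit the prior from a small
    sample of proportion vectors drawn from the true Dirichlet.

    Mirrors the study design in which the prior handed to the estimator
    is learned from the measured cell counts of only a few dozen
    individuals rather than known exactly.
    """
    if n_prior < 2 * alpha_true.k:
        raise ValidationError(
            f"n_prior must be >= 2k = {2 * alpha_true.k} for a stable MLE"
        )
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha_true.alpha, size=n_prior)
    return fit_dirichlet_mle(draws, cell_type_names=alpha_true.cell_type_names)


def recover_sigma(O, R_true) -> float:
    """Technical-noise sd implied by regressing sites on true proportions.

    Regresses each site's observed values on the true proportion matrix
    with an intercept (minimum-norm least squares; the intercept lies in
    the span of the simplex rows) and returns the square root of the
    pooled mean squared residual over all entries.  In shared-profile
    mode with clipping off this recovers the generating sigma exactly up
    to sampling error.
    """
    Ov = O.to_numpy(dtype=float) if isinstance(O, pd.DataFrame) else np.asarray(O, float)
    Rv = R_true.to_numpy(dtype=float) if isinstance(R_true, pd.DataFrame) else np.asarray(R_true, float)
    design = np.column_stack([np.ones(Rv.shape[0]), Rv])
    coef, *_ = np.linalg.lstsq(design, Ov.T, rcond=None)
    resid = Ov - (design @ coef).T
    return float(np.sqrt(np.mean(resid**2)))


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write beta matrix, truth tables and a JSON parameter sidecar.

    The beta matrix is tab-delimited, sites x samples, values printed to
    six decimals; returns a name -> path mapping of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "beta_values.tsv"
    ds.O.to_csv(p, sep="\t", float_format="%.6f", index_label="site_id")
    paths["beta_values"] = str(p)

    p = outdir / "R_true.tsv"
    ds.R_true.to_csv(p, sep="\t", index_label="sample_id")
    paths["R_true"] = str(p)

    p = outdir / "alpha_true.tsv"
    pd.DataFrame(
        {"cell_type_name": ds.alpha_true.cell_type_names, "alpha": ds.alpha_true.alpha}
    ).to_csv(p, sep="\t", index=False)
    paths["alpha_true"] = str(p)

    if ds.X is not None:
        p = outdir / "covariates.tsv"
        ds.X.to_csv(p, sep="\t", index_label="sample_id")
        paths["covariates"] = str(p)

    sidecar = {
        "m": ds.m,
        "n": ds.n,
        "k": ds.k,
        "sigma": ds.sigma,
        "seed": ds.seed,
        "alpha_true": list(map(float, ds.alpha_true.alpha)),
        "cell_type_names": list(ds.alpha_true.cell_type_names),
        "shared_profiles": ds.M_shared is not None,
        "n_covariates": 0 if ds.X is None else ds.X.shape[1],
    }
    p = outdir / "simulation_params.json"
    p.write_text(json.dumps(sidecar, indent=2))
    paths["params"] = str(p)
    return paths
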