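"""File IO, run configuration and the end-to-end pipeline.

Tables are tab-delimited UTF-8: beta matrices are sites x samples (array
convention), proportion tables are samples x cell types.  Every pipeline
run writes a JSON manifest echoing the configuration, the seed, the
package version and SHA-256 checksums of all inputs and outputs, so a
seeded run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    EPSILON,
    REF_SLACK,
    SUM_SLACK,
    ImputationInput,
    SolverOptions,
    feasible_impute_basis,
    fit_bayescce,
    fit_bayescce_impute,
)
from .evaluation import evaluate
from .exceptions import ValidationError
from .prior import (
    WHOLE_BLOOD_K6,
    DirichletPrior,
    read_cell_counts,
    read_prior,
    uniform_prior,
)
from .refactor import (
    DEFAULT_D_REAL,
    DEFAULT_D_SIMULATED,
    DEFAULT_K,
    DEFAULT_T,
    compute_components,
    select_informative_sites,
)
from .simulator import (
    DEFAULT_SIGMA,
    make_profile_model,
    simulate_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "read_beta_matrix", "run_pipeline"]

logger = logging.getLogger("bayescce")

MISSING_SITE_FRACTION = 0.10  # sites with more missing values are dropped

MODES = ("simulate", "fit", "impute", "evaluate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "fit"
    k: int = DEFAULT_K
    d: int | None = None  # default: 10 for fit/impute, 6 for simulate
    t: int = DEFAULT_T
    epsilon: float = EPSILON
    sum_slack: float = SUM_SLACK
    ref_slack: float = REF_SLACK
    seed: int = 0
    n_starts: int = 5
    # paths
    data_path: str | None = None
    covariates_path: str | None = None
    prior_path: str | None = None
    cell_counts_path: str | None = None
    truth_path: str | None = None
    estimates_path: str | None = None
    out_dir: str = "bayescce_out"
    # simulate-mode parameters
    m: int = 2000
    n: int = 300
    sigma: float = DEFAULT_SIGMA
    separation: float = 0.3

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        for name in ("sum_slack", "ref_slack"):
            v = getattr(self, name)
            if not 0 <= v <= 0.2:
                raise ValidationError(f"{name} must lie in [0, 0.2], got {v}")
        if self.d is None:
            self.d = DEFAULT_D_SIMULATED if self.mode == "simulate" else DEFAULT_D_REAL
        if self.d < self.k:
            logger.warning("d=%d < k=%d: basis may not span all cell types", self.d, self.k)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_beta_matrix(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a sites x samples beta-value matrix.

    Values must lie in [0,1] or be missing.  Sites missing in more than
    10% of samples are dropped (and reported in the returned log);
    remaining missing values are imputed with the site mean.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate site id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    bad &= ~np.isnan(vals)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: value {vals[j, i]} outside [0,1] at site "
            f"{df.index[j]!r}, sample {df.columns[i]!r}"
        )
    miss_frac = np.isnan(vals).mean(axis=1)
    dropped = [str(s) for s in df.index[miss_frac > MISSING_SITE_FRACTION]]
    if dropped:
        logger.info("dropping %d sites with >%.0f%% missing values",
                    len(dropped), 100 * MISSING_SITE_FRACTION)
        df = df.loc[miss_frac <= MISSING_SITE_FRACTION]
        vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        site_means = np.nanmean(vals, axis=1, keepdims=True)
        vals = np.where(np.isnan(vals), site_means, vals)
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    return df, dropped


def _load_prior(config: RunConfig) -> DirichletPrior:
    from .prior import fit_dirichlet_mle

    if config.prior_path:
        p = Path(config.prior_path)
        df = pd.read_csv(p, sep="\t")
        if {"cell_type_name", "alpha"} <= set(df.columns):
            return read_prior(p)
        # otherwise: a raw cell-count table to fit
        counts = read_cell_counts(p)
        return fit_dirichlet_mle(counts)
    if config.mode == "simulate":
        if config.k == WHOLE_BLOOD_K6.k:
            return WHOLE_BLOOD_K6
        from .prior import WHOLE_BLOOD_K3

        if config.k == WHOLE_BLOOD_K3.k:
            return WHOLE_BLOOD_K3
    logger.warning("no prior supplied; using a non-informative prior (alpha=1)")
    return uniform_prior(config.k)


def run_pipeline(config: RunConfig) -> dict:
    """Dispatch one run and write its artifacts and manifest.

    Returns the manifest dictionary.  Module errors propagate as
    package exceptions carrying context; the CLI converts them to a
    nonzero exit status.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    for name in ("data_path", "covariates_path", "prior_path",
                 "cell_counts_path", "truth_path", "estimates_path"):
        p = getattr(config, name)
        if p:
            inputs[name] = _sha256(p)

    if config.mode == "simulate":
        prior = _load_prior(config)
        profiles = make_profile_model(
            config.m, prior.k, seed=config.seed, separation=config.separation
        )
        ds = simulate_dataset(
            profiles, config.n, prior, sigma=config.sigma, seed=config.seed
        )
        for name, path in write_dataset(ds, out).items():
            outputs[name] = _sha256(path)

    elif config.mode in ("fit", "impute"):
        if not config.data_path:
            raise ValidationError(f"{config.mode} mode requires data_path")
        O, dropped = read_beta_matrix(config.data_path)
        X = None
        if config.covariates_path:
            X = pd.read_csv(config.covariates_path, sep="\t", index_col=0)
            X = X.loc[list(O.columns)]
        prior = _load_prior(config)
        sites = select_informative_sites(O, k=config.k, t=min(config.t, O.shape[0]), X=X)
        options = SolverOptions(
            epsilon=config.epsilon,
            sum_slack=config.sum_slack,
            ref_slack=config.ref_slack,
            seed=config.seed,
            n_starts=config.n_starts,
        )
        excluded: tuple[str, ...] = ()
        if config.mode == "impute":
            if not config.cell_counts_path:
                raise ValidationError("impute mode requires cell_counts_path")
            counts = read_cell_counts(config.cell_counts_path)
            imp = ImputationInput(R0=counts)
            basis = feasible_impute_basis(
                O, sites, imp, d_start=config.d, X=X, options=options
            )
            O_trunc = O.loc[list(sites)]
            fit = fit_bayescce_impute(basis, O_trunc, prior, imp, X=X, options=options)
            excluded = imp.reference_sample_ids
        else:
            basis = compute_components(O, sites, d=config.d, X=X)
            O_trunc = O.loc[list(sites)]
            fit = fit_bayescce(basis, O_trunc, prior, X=X, options=options)
        fit.write(out)
        for f in ("R_hat.tsv", "M_hat.tsv", "fit_report.json"):
            outputs[f] = _sha256(out / f)
        if dropped:
            (out / "dropped_sites.txt").write_text("\n".join(dropped) + "\n")
            outputs["dropped_sites.txt"] = _sha256(out / "dropped_sites.txt")
        if config.truth_path:
            R_true = pd.read_csv(config.truth_path, sep="\t", index_col=0)
            report = evaluate(
                fit.R_hat,
                R_true.loc[fit.R_hat.index],
                allow_permutation=fit.assignment_is_heuristic,
                exclude_samples=excluded,
            )
            report.to_json(out / "evaluation.json")
            outputs["evaluation.json"] = _sha256(out / "evaluation.json")

    elif config.mode == "evaluate":
        if not (config.estimates_path and config.truth_path):
            raise ValidationError("evaluate mode requires estimates_path and truth_path")
        R_est = pd.read_csv(config.estimates_path, sep="\t", index_col=0)
        R_true = pd.read_csv(config.truth_path, sep="\t", index_col=0)
        excluded = ()
        if config.cell_counts_path:
            excluded = tuple(read_cell_counts(config.cell_counts_path).index.astype(str))
        report = evaluate(
            R_est, R_true.loc[R_est.index], exclude_samples=excluded
        )
        report.to_json(out / "evaluation.json")
        (out / "evaluation.txt").write_text(report.to_table() + "\n")
        outputs["evaluation.json"] = _sha256(out / "evaluation.json")
        outputs["evaluation.txt"] = _sha256(out / "evaluation.txt")

    config.to_json(out / "config.json")
    outputs["config.json"] = _sha256(out / "config.json")
    manifest = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": inputs,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
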