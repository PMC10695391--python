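"""Virtual-patient generation preserving the fitted cohort's structure.

A virtual LGG patient is a parameter set (six rates), a pre-chemotherapy
tumor volume, a total dose budget and a fatal volume.  Rates are drawn
from a multivariate log-normal whose log-scale mean and covariance come
from the fitted per-patient table, sampled through the Cholesky factor so
that all pairwise correlations are preserved simultaneously; draws are
rejected until they satisfy alpha2 < alpha1 and rho2 > rho1 and stay
within [min/2, 2*max] of each source column.  Initial volumes come from a
Gaussian kernel density estimate over packaged baseline volumes, dose
budgets from a rounded-normal cycle count (mean 19, sd 7, bounds [6, 34],
five doses per cycle) and fatal volumes from a normal (mean 280 cm^3,
sd 20 cm^3) truncated positive.  All truncations are by redraw, which
avoids probability atoms at the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fitting import FITTED_NAMES
from .model import DEFAULT_CLEARANCE, InvalidInputError, ModelParams


class CohortConfigError(ValueError):
    """The cohort specification cannot produce valid samples."""


@dataclass(frozen=True)
class VirtualPatient:
    params: ModelParams
    V0: float  # pre-chemotherapy volume, cm^3
    dose_budget: int  # total individual doses
    V_fatal: float  # critical volume, cm^3

    def __post_init__(self) -> None:
        if not self.V0 > 0:
            raise InvalidInputError("initial volume must be positive")
        if self.dose_budget < 1:
            raise InvalidInputError("dose budget must be >= 1")
        if not self.V_fatal > 0:
            raise InvalidInputError("fatal volume must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one generated cohort."""

    n_patients: int = 100
    seed: int = 0
    cycles_mean: float = 19.0
    cycles_spread: float = 7.0  # standard deviation of the cycle draw
    cycles_bounds: tuple = (6, 34)
    doses_per_cycle: int = 5
    fixed_cycles: int | None = None
    fatal_mean: float = 280.0  # cm^3
    fatal_spread: float = 20.0  # cm^3 (standard deviation)
    baseline_volumes: tuple | None = None  # cm^3; None -> packaged stand-in
    param_table: pd.DataFrame | None = None  # None -> packaged fitted table

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")
        lo, hi = self.cycles_bounds
        if not lo <= hi:
            raise InvalidInputError("cycle bounds must be ordered")
        if self.cycles_spread <= 0 or self.fatal_spread <= 0:
            raise InvalidInputError("spreads must be positive")


@dataclass(frozen=True)
class CorrelationSummary:
    """Rank correlations and log-scale moments of a fitted-parameter table."""

    labels: tuple
    spearman: np.ndarray  # symmetric, unit diagonal
    log_mean: np.ndarray
    log_cov: np.ndarray
    col_min: np.ndarray  # per-column envelope of the source table
    col_max: np.ndarray


def _as_table(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    missing = [c for c in FITTED_NAMES if c not in df.columns]
    if missing:
        raise InvalidInputError(f"parameter table is missing columns: {missing}")
    return df[list(FITTED_NAMES)].astype(float)


def summarize_parameters(table) -> CorrelationSummary:
    """Spearman correlations plus log-scale mean/covariance of the table."""
    df = _as_table(table)
    if len(df) < 3:
        raise InvalidInputError("need at least 3 patients to summarize")
    for col in df.columns:
        if df[col].nunique() == 1:
            raise CohortConfigError(
                f"column {col!r} is constant: rank correlation undefined"
            )
    rho = spearmanr(df.values).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    logs = np.log(df.values)
    return CorrelationSummary(
        labels=tuple(df.columns),
        spearman=rho,
        log_mean=logs.mean(axis=0),
        log_cov=np.cov(logs, rowvar=False),
        col_min=df.values.min(axis=0),
        col_max=df.values.max(axis=0),
    )


def _cholesky_psd(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor with a ridge repair for near-semidefinite input."""
    ridge = 0.0
    scale = float(np.trace(cov)) / cov.shape[0]
    for _ in range(12):
        try:
            return np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-12 * scale)
    raise CohortConfigError("covariance could not be repaired to positive definite")


def sample_parameters(
    summary: CorrelationSummary,
    n: int,
    rng: np.random.Generator,
    beta: float = 0.1,
    lam: float = DEFAULT_CLEARANCE,
) -> list[ModelParams]:
    """Draw n correlated parameter sets (log-normal via the Cholesky factor).

    The Gaussian copula on the log scale is built to reproduce the source
    table's rank correlations (``r = 2 sin(pi r_s / 6)``); using the raw
    log-scale Pearson covariance instead systematically understates the
    Spearman targets.  Marginal log variances come from the table.
    Rejection keeps only draws with alpha2 < alpha1, rho2 > rho1 and every
    rate within [min/2, 2*max] of its source column.
    """
    sd = np.sqrt(np.diag(summary.log_cov))
    corr = 2.0 * np.sin(np.pi * summary.spearman / 6.0)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sd, sd)
    chol = _cholesky_psd(cov)
    idx = {name: i for i, name in enumerate(summary.labels)}
    lo = summary.col_min / 2.0
    hi = summary.col_max * 2.0
    out: list[ModelParams] = []
    attempts = 0
    while len(out) < n:
        batch = max(64, 2 * (n - len(out)))
        attempts += batch
        z = rng.standard_normal((batch, len(summary.labels)))
        draws = np.exp(summary.log_mean + z @ chol.T)
        ok = (
            (draws[:, idx["alpha2"]] < draws[:, idx["alpha1"]])
            & (draws[:, idx["rho2"]] > draws[:, idx["rho1"]])
            & np.all((draws >= lo) & (draws <= hi), axis=1)
        )
        for row in draws[ok]:
            if len(out) == n:
                break
            vals = dict(zip(summary.labels, row))
            out.append(ModelParams(beta=beta, lam=lam, **vals))
        if attempts >= 10000 and len(out) / attempts < 0.01:
            raise CohortConfigError(
                f"rejection acceptance rate {len(out) / attempts:.2%} below 1%"
            )
    return out


def _baseline_volumes(spec: CohortSpec) -> np.ndarray:
    if spec.baseline_volumes is not None:
        vols = np.asarray(spec.baseline_volumes, dtype=float)
    else:
        from .io import load_fixture

        vols = np.asarray(load_fixture().baseline_volumes, dtype=float)
    if vols.size == 0:
        raise CohortConfigError("no baseline volumes configured for the KDE")
    return vols


def sample_initial_volume(spec: CohortSpec, rng: np.random.Generator) -> float:
    """One draw from a Gaussian KDE over the baseline diagnosis volumes.

    Silverman's rule sets the bandwidth; draws are truncated positive by
    redraw.
    """
    vols = _baseline_volumes(spec)
    h = vols.std(ddof=1) * (4.0 / (3.0 * vols.size)) ** 0.2 if vols.size > 1 else 1.0
    while True:
        v = rng.choice(vols) + rng.normal(0.0, h)
        if v > 0:
            return float(v)


def sample_dose_budget(spec: CohortSpec, rng: np.random.Generator) -> int:
    """Total dose budget: cycles (rounded normal, redrawn into bounds) x 5."""
    if spec.fixed_cycles is not None:
        return int(spec.fixed_cycles) * spec.doses_per_cycle
    lo, hi = spec.cycles_bounds
    while True:
        c = int(round(rng.normal(spec.cycles_mean, spec.cycles_spread)))
        if lo <= c <= hi:
            return c * spec.doses_per_cycle


def sample_fatal_volume(spec: CohortSpec, rng: np.random.Generator) -> float:
    """Fatal volume draw (normal, truncated positive by redraw)."""
    while True:
        v = rng.normal(spec.fatal_mean, spec.fatal_spread)
        if v > 0:
            return float(v)


def source_table(spec: CohortSpec) -> pd.DataFrame:
    if spec.param_table is not None:
        return _as_table(spec.param_table)
    from .io import load_fixture

    return load_fixture().param_table


def generate_cohort(spec: CohortSpec) -> list[VirtualPatient]:
    """A reproducible cohort: pure function of the spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    summary = summarize_parameters(source_table(spec))
    params = sample_parameters(summary, spec.n_patients, rng)
    patients = []
    for pset in params:
        patients.append(
            VirtualPatient(
                params=pset,
                V0=sample_initial_volume(spec, rng),
                dose_budget=sample_dose_budget(spec, rng),
                V_fatal=sample_fatal_volume(spec, rng),
            )
        )
    return patients
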