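"""Per-patient parameter estimation from longitudinal tumor volumes.

The patient-specific rates (rho1, rho2, psi, alpha1, alpha2, tau) are
estimated by multi-start Nelder-Mead minimization of the RMSE between the
model's total volume and the observed volumes, with the persister
reversion rate beta held fixed (0.1 day^-1) and the clearance rate set by
the drug half-life.  The search runs in log space so all rates stay
positive, and alpha2 is parameterized as alpha1 times a ratio in (0, 1),
which enforces alpha2 < alpha1 without constraining the simplex.

rho2 > rho1 (faster regrowth of the resistant phenotype) is expected but
not imposed during the search; the result records whether it holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _kernel
from .model import (
    DEFAULT_CLEARANCE,
    IntegrationError,
    InvalidInputError,
    ModelParams,
    SimulationConfig,
)
from .protocols import Protocol

FITTED_NAMES = ("rho1", "rho2", "tau", "psi", "alpha1", "alpha2")

#: default per-parameter search bounds (day^-1): a wide envelope around the
#: range of rates observed in fitted LGG cohorts
DEFAULT_BOUNDS = {
    "rho1": (5.7e-5, 1.26e-2),
    "rho2": (1.73e-4, 1.02e-1),
    "tau": (1.69e-4, 9.64e-2),
    "psi": (1.9e-2, 9.79),
    "alpha1": (2.2e-2, 5.13),
    "alpha2": (4e-3, 8.9e-1),
}


class FitError(RuntimeError):
    """All restarts of the optimizer failed."""


#: integration settings used inside the fit objective: volumes carry ~18%
#: measurement error, so 1e-6 relative integration accuracy is far below
#: any resolvable objective difference while roughly halving the cost of
#: each evaluation
FIT_SIM_CONFIG = SimulationConfig(rel_tol=1e-6, abs_tol=1e-8)


@dataclass(frozen=True)
class TumorDiameters:
    """Three orthogonal tumor diameters (cm) from an MRI study."""

    D1: float
    D2: float
    D3: float

    def __post_init__(self) -> None:
        if min(self.D1, self.D2, self.D3) < 0:
            raise InvalidInputError("diameters must be >= 0")


def ellipsoid_volume(d: TumorDiameters) -> float:
    """Ellipsoid approximation of tumor volume: V = D1*D2*D3/2 (cm^3)."""
    return d.D1 * d.D2 * d.D3 / 2.0


@dataclass(frozen=True)
class PatientRecord:
    """Longitudinal volume observations plus the delivered dose schedule.

    Times are days from diagnosis; the schedule's dose times share that
    origin.  ``volume_uncertainty`` is the fractional measurement error of
    the volumetry (0.18 from comparing segmentation with the ellipsoid
    approximation); it documents the data quality and is not used to
    weight the fit.
    """

    patient_id: str
    obs_times: np.ndarray
    obs_volumes: np.ndarray
    schedule: Protocol
    volume_uncertainty: float = 0.18

    def __post_init__(self) -> None:
        t = np.asarray(self.obs_times, dtype=float)
        v = np.asarray(self.obs_volumes, dtype=float)
        object.__setattr__(self, "obs_times", t)
        object.__setattr__(self, "obs_volumes", v)
        if t.size != v.size or t.size < 2:
            raise InvalidInputError("need >= 2 paired observations")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("observation times must be strictly increasing")
        if np.any(v <= 0):
            raise InvalidInputError("observed volumes must be positive")

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)


@dataclass(frozen=True)
class FitConfig:
    """Multi-start Nelder-Mead settings."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_restarts: int = 20
    seed: int = 0
    beta_fixed: float = 0.1
    max_iterations: int = 1200
    x_tolerance: float = 1e-4  # log-scale parameter resolution
    f_tolerance: float = 1e-4  # cm^3

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise InvalidInputError("need at least one restart")
        for name in FITTED_NAMES:
            lo, hi = self.bounds[name]
            if not (0 < lo < hi):
                raise InvalidInputError(f"bounds for {name} must be 0 < lo < hi")


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    rmse: float  # cm^3
    restart_table: tuple  # per restart: (restart index, rmse, converged)
    rho2_gt_rho1: bool

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise InvalidInputError("rmse must be >= 0")


def _model_volumes(
    params: ModelParams, record: PatientRecord, sim_cfg: SimulationConfig
) -> np.ndarray:
    """Total model volume at the observation times.

    The clock is re-zeroed at the first observation (whose volume is the
    initial condition); doses before the first observation are outside the
    modelled window and ignored.
    """
    t0 = record.obs_times[0]
    eval_times = record.obs_times - t0
    d_times = record.schedule.times - t0
    keep = d_times >= 0
    d_times = d_times[keep]
    d_e0 = record.schedule.e0s[keep]
    y0 = np.array([record.obs_volumes[0], 0.0, 0.0, 0.0, 0.0, 0.0])
    status, volumes = _kernel.eval_total_volume(
        y0, params.as_vector(), d_times, d_e0, eval_times,
        sim_cfg.rel_tol, sim_cfg.abs_tol, sim_cfg.max_step_dosing,
    )
    if status != _kernel.OK:
        raise IntegrationError(
            f"simulation failed for patient {record.patient_id} at "
            f"rho1={params.rho1:g}, psi={params.psi:g}"
        )
    return volumes


def rmse_objective(
    params: ModelParams, record: PatientRecord, sim_cfg: SimulationConfig | None = None
) -> float:
    """Root mean squared error (cm^3) between model and observed volumes."""
    if sim_cfg is None:
        sim_cfg = FIT_SIM_CONFIG
    volumes = _model_volumes(params, record, sim_cfg)
    return float(np.sqrt(np.mean((volumes - record.obs_volumes) ** 2)))


def _decode(x: np.ndarray, config: FitConfig) -> ModelParams:
    rho1, rho2, tau, psi, alpha1 = np.exp(x[:5])
    alpha2 = alpha1 * expit(x[5])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rho2<=rho1 allowed during the search
        return ModelParams(
            rho1=rho1, rho2=rho2, psi=psi, alpha1=alpha1, alpha2=alpha2,
            tau=tau, beta=config.beta_fixed, lam=DEFAULT_CLEARANCE,
        )


def fit_patient(
    record: PatientRecord,
    config: FitConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
) -> FitResult:
    """Multi-start Nelder-Mead fit of the six free rates to one patient.

    Starting points are drawn uniformly (log-uniformly in value) within the
    configured bounds from a generator seeded by ``config.seed``, so the
    result is reproducible.  The restart with the smallest RMSE wins.
    """
    if config is None:
        config = FitConfig()
    if sim_cfg is None:
        sim_cfg = FIT_SIM_CONFIG
    rng = np.random.default_rng(config.seed)

    lo = np.log([config.bounds[n][0] for n in FITTED_NAMES[:5]])
    hi = np.log([config.bounds[n][1] for n in FITTED_NAMES[:5]])
    a2_lo, a2_hi = config.bounds["alpha2"]

    # confine the search to the prescribed bounds (one decade of slack):
    # beyond them the objective is a plateau, and absurdly large rates
    # would make the piecewise integration arbitrarily expensive
    margin = np.log(10.0)

    def objective(x: np.ndarray) -> float:
        if (
            np.any(x[:5] < lo - margin)
            or np.any(x[:5] > hi + margin)
            or abs(x[5]) > 50
        ):
            return 1e12
        try:
            return rmse_objective(_decode(x, config), record, sim_cfg)
        except IntegrationError:
            return 1e12

    runs = []
    for i in range(config.n_restarts):
        x0 = np.empty(6)
        x0[:5] = rng.uniform(lo, hi)
        # start the alpha2/alpha1 ratio within bounds for alpha2 when possible
        alpha1_0 = np.exp(x0[4])
        r_lo = min(max(a2_lo / alpha1_0, 1e-6), 0.98)
        r_hi = min(max(a2_hi / alpha1_0, r_lo + 1e-6), 0.999)
        x0[5] = logit(rng.uniform(r_lo, r_hi))
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iterations,
                "xatol": config.x_tolerance,
                "fatol": config.f_tolerance,
                "adaptive": True,
            },
        )
        # a restart that merely hit the iteration cap is still a usable
        # candidate; only plateau values (failed integrations / out of
        # bounds throughout) disqualify one
        usable = res.fun < 1e11
        converged = bool(res.success) and usable
        runs.append([i, float(res.fun), converged, res.x.copy(), usable])
    if not any(r[4] for r in runs):
        raise FitError(
            f"all {config.n_restarts} restarts failed: "
            f"{[(r[0], r[1], r[2]) for r in runs]}"
        )

    # polish the two leading candidates: re-initializing the simplex at the
    # incumbent escapes the degenerate collapse Nelder-Mead is prone to
    for run in sorted((r for r in runs if r[4]), key=lambda r: r[1])[:2]:
        fun, x = run[1], run[3]
        for _ in range(3):
            res = minimize(
                objective,
                x,
                method="Nelder-Mead",
                options={
                    "maxiter": config.max_iterations,
                    "xatol": config.x_tolerance / 10.0,
                    "fatol": config.f_tolerance / 100.0,
                    "adaptive": True,
                },
            )
            improved = fun - res.fun
            fun, x = float(res.fun), res.x.copy()
            if improved < config.f_tolerance:
                break
        run[1], run[3] = fun, x
        run[2] = bool(res.success)

    best = min((r for r in runs if r[4]), key=lambda r: r[1])
    table = [(r[0], r[1], r[2]) for r in runs]
    params = _decode(best[3], config)
    return FitResult(
        params=params,
        rmse=best[1],
        restart_table=tuple(table),
        rho2_gt_rho1=params.rho2 > params.rho1,
    )
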