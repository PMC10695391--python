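"""Core compartment model of low-grade glioma response to temozolomide.

The model tracks the volumes (cm^3) of five well-mixed tumor cell
populations — drug-sensitive ``V_S``, damaged ``V_D`` (dying by delayed
mitotic catastrophe), intermediate persisters ``V_PI``, stabilized
persisters ``V_P`` and fully resistant ``V_R`` — together with the
normalized drug effect ``E``:

    dV_S/dt  = rho1*V_S - psi*V_S*E - alpha1*V_S*E + beta*V_P
    dV_D/dt  = psi*V_S*E - tau*V_D
    dV_PI/dt = alpha1*V_S*E - V_PI*f(E)
    dV_P/dt  = V_PI*f(E) - alpha2*V_P*E - beta*V_P
    dV_R/dt  = rho2*V_R + alpha2*V_P*E
    dE/dt    = -lam*E

with the sigmoid activation ``f(E) = f_scale*(1 - tanh((E - f_center)/f_width))``,
which is appreciable only at low drug effect: intermediate persisters
stabilize to the full persister phenotype after a dose has washed out.
Oral TMZ doses are impulses that add ``E0`` to ``E`` and leave all volumes
continuous; drug washout is first order with clearance ``lam`` derived from
the ~2 h plasma half-life.

The system is linear in the volumes given E(t), so trajectories scale with
the initial volume; this is exploited by several downstream analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel


class InvalidInputError(ValueError):
    """An argument violates a model precondition."""


class IntegrationError(RuntimeError):
    """The piecewise integrator failed on some interval."""


def clearance_rate(half_life_hours: float) -> float:
    """First-order clearance rate (day^-1) from a half-life in hours."""
    if not half_life_hours > 0:
        raise InvalidInputError(f"half-life must be positive, got {half_life_hours}")
    return 24.0 * math.log(2.0) / half_life_hours


#: clearance rate for the ~2 h TMZ plasma half-life, day^-1 (prints as 8.32)
DEFAULT_CLEARANCE = clearance_rate(2.0)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the compartment system (all day^-1 unless noted).

    ``alpha2 < alpha1`` is required: full resistance is harder to acquire
    than the persister state.  ``rho2 > rho1`` (post-treatment regrowth is
    faster) is the biologically expected ordering; it is warned about, not
    enforced, because fitted values may occasionally violate it.
    """

    rho1: float  # sensitive proliferation
    rho2: float  # resistant proliferation
    psi: float  # damage rate under drug
    alpha1: float  # sensitive -> intermediate persister, per unit E
    alpha2: float  # persister -> resistant, per unit E
    tau: float  # damaged-cell death (mitotic catastrophe)
    beta: float = 0.1  # persister -> sensitive reversion
    lam: float = DEFAULT_CLEARANCE  # drug clearance
    f_scale: float = 7.5  # activation amplitude, day^-1
    f_center: float = 0.01  # activation midpoint on the E axis
    f_width: float = 0.01  # activation steepness scale

    def __post_init__(self) -> None:
        for name in (
            "rho1", "rho2", "psi", "alpha1", "alpha2", "tau",
            "beta", "lam", "f_scale", "f_center", "f_width",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be strictly positive, got {v}")
        if not self.alpha2 < self.alpha1:
            raise InvalidInputError(
                f"alpha2 ({self.alpha2}) must be smaller than alpha1 ({self.alpha1})"
            )
        if not self.rho2 > self.rho1:
            warnings.warn(
                f"rho2 ({self.rho2}) <= rho1 ({self.rho1}): resistant cells are "
                "expected to proliferate faster than sensitive ones",
                stacklevel=3,
            )

    def as_vector(self) -> np.ndarray:
        """Parameter vector in the kernel's ordering."""
        return np.array(
            [
                self.rho1, self.rho2, self.psi, self.alpha1, self.alpha2,
                self.beta, self.tau, self.lam,
                self.f_scale, self.f_center, self.f_width,
            ]
        )


STATE_FIELDS = ("V_S", "V_D", "V_PI", "V_P", "V_R", "E")


@dataclass(frozen=True)
class SystemState:
    """Compartment volumes (cm^3) and normalized drug effect at one instant."""

    V_S: float
    V_D: float = 0.0
    V_PI: float = 0.0
    V_P: float = 0.0
    V_R: float = 0.0
    E: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")

    @property
    def total_volume(self) -> float:
        return self.V_S + self.V_D + self.V_PI + self.V_P + self.V_R

    def as_array(self) -> np.ndarray:
        return np.array([self.V_S, self.V_D, self.V_PI, self.V_P, self.V_R, self.E])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for the piecewise integrator."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10  # cm^3
    output_step: float = 1.0  # days
    horizon: float = 3650.0  # days
    half_life_hours: float = 2.0
    max_step_dosing: float = 5.0  # step cap while doses remain, days
    max_step_free: float = 30.0  # step cap after the last dose, days

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol", "output_step", "horizon",
                     "half_life_hours", "max_step_dosing", "max_step_free"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time course of the system on an output grid.

    Dose times appear twice: the left limit (pre-dose) and the state just
    after the impulse.  Total volume is continuous across doses; only E
    jumps.
    """

    times: np.ndarray  # shape (n,)
    states: np.ndarray  # shape (n, 6), columns ordered as STATE_FIELDS
    dose_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    dose_e0: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total_volume(self) -> np.ndarray:
        return self.states[:, :5].sum(axis=1)

    def state_at(self, index: int) -> SystemState:
        return SystemState.from_array(self.states[index])

    def to_frame(self):
        """Trajectory as a pandas DataFrame (one row per output node)."""
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_days", self.times)
        df["V_total"] = self.total_volume
        return df


def activation_rate(E, params: ModelParams):
    """Persister stabilization rate f(E), day^-1; high only at low drug effect."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise InvalidInputError("drug effect E must be >= 0")
    out = params.f_scale * (1.0 - np.tanh((E - params.f_center) / params.f_width))
    return float(out) if out.ndim == 0 else out


def derivatives(state: SystemState, params: ModelParams) -> np.ndarray:
    """Instantaneous rates (cm^3/day; day^-1 for E), ordered as STATE_FIELDS."""
    return _kernel.rhs(state.as_array(), params.as_vector())


def apply_dose(state: SystemState, E0: float) -> SystemState:
    """Impulsive oral dose: E jumps by E0, all volumes unchanged."""
    if not 0 < E0 <= 1:
        raise InvalidInputError(f"dose effect E0 must be in (0, 1], got {E0}")
    return replace(state, E=state.E + E0)


def _check_schedule(dose_times: np.ndarray, horizon: float) -> None:
    if dose_times.size == 0:
        return
    if np.any(np.diff(dose_times) < 0):
        raise InvalidInputError("dose times must be non-decreasing")
    if dose_times[0] < 0 or dose_times[-1] > horizon:
        raise InvalidInputError("dose times must lie within [0, horizon]")


def simulate(
    params: ModelParams,
    V_S0: float,
    schedule,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Integrate the model from ``(V_S0, 0, 0, 0, 0, 0)`` under a dose schedule.

    ``schedule`` is anything with ``times`` and ``e0s`` arrays (a
    :class:`~gliotmz.protocols.Protocol`) or an iterable of ``(time, e0)``
    pairs.  The trajectory is sampled on the regular output grid plus both
    one-sided limits at every dose time.
    """
    if config is None:
        config = SimulationConfig()
    if not V_S0 > 0:
        raise InvalidInputError(f"initial volume must be positive, got {V_S0}")
    if hasattr(schedule, "times"):
        d_times = np.asarray(schedule.times, dtype=float)
        d_e0 = np.asarray(schedule.e0s, dtype=float)
    else:
        pairs = list(schedule)
        d_times = np.array([t for t, _ in pairs], dtype=float)
        d_e0 = np.array([e for _, e in pairs], dtype=float)
    _check_schedule(d_times, config.horizon)

    grid = np.arange(0.0, config.horizon + 0.5 * config.output_step, config.output_step)
    if grid[-1] < config.horizon:
        grid = np.append(grid, config.horizon)

    p = params.as_vector()
    y = np.array([V_S0, 0.0, 0.0, 0.0, 0.0, 0.0])
    times_out = [0.0]
    states_out = [y.copy()]
    t = 0.0
    i_grid = 1
    i_dose = 0
    n_d = d_times.size
    while True:
        next_grid = grid[i_grid] if i_grid < grid.size else np.inf
        next_dose = d_times[i_dose] if i_dose < n_d else np.inf
        t_next = min(next_grid, next_dose)
        if not np.isfinite(t_next):
            break
        if t_next > t:
            status, _, _, _ = _kernel.integrate_segment(
                y, t, t_next, p, config.rel_tol, config.abs_tol,
                config.max_step_dosing if i_dose < n_d else config.max_step_free,
                -1.0, False,
            )
            if status != _kernel.OK:
                reason = {
                    _kernel.NEGATIVE_STATE: "negative compartment",
                    _kernel.OVERFLOW: "runaway volume",
                }.get(status, "step underflow")
                raise IntegrationError(
                    f"integration failed on [{t:g}, {t_next:g}] days: {reason}"
                )
            t = t_next
        if next_dose <= next_grid:
            # record the left limit, stack all doses at this time, record again
            times_out.append(t)
            states_out.append(y.copy())
            while i_dose < n_d and d_times[i_dose] <= t:
                y[5] += d_e0[i_dose]
                i_dose += 1
            times_out.append(t)
            states_out.append(y.copy())
            if next_dose == next_grid:
                i_grid += 1
        else:
            times_out.append(t)
            states_out.append(y.copy())
            i_grid += 1

    return Trajectory(
        times=np.array(times_out),
        states=np.array(states_out),
        dose_times=d_times,
        dose_e0=d_e0,
    )
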