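"""Dosing schedules and the closed-loop adaptive-therapy scheduler.

Protocols studied:

- ``C28``: the standard cyclic scheme — 28-day cycles with one dose on each
  of the first five days, then 23 rest days.
- ``ID-k``: individual doses separated by ``k`` rest days (k a multiple of
  7 in the study designs, but any spacing is accepted).
- ``STUPP``: six weeks of weekday dosing at half effect (the concomitant
  radiochemotherapy phase; radiotherapy itself is not modelled).

Dose times are days from treatment start; the first dose of every builder
is at time 0.  The adaptive scheduler withholds scheduled doses while the
simulated tumor volume at periodic screenings sits below a threshold
fraction of the treatment-start volume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model import (
    IntegrationError,
    InvalidInputError,
    ModelParams,
    SimulationConfig,
    Trajectory,
    simulate,
)


@dataclass(frozen=True)
class DoseEvent:
    """One oral dose: time (days from treatment start) and peak effect E0."""

    time: float
    e0: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidInputError(f"dose time must be >= 0, got {self.time}")
        if not 0 < self.e0 <= 1:
            raise InvalidInputError(f"dose effect must be in (0, 1], got {self.e0}")


@dataclass(frozen=True)
class Protocol:
    name: str
    doses: tuple

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidInputError("dose times must be non-decreasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([d.time for d in self.doses], dtype=float)

    @property
    def e0s(self) -> np.ndarray:
        return np.array([d.e0 for d in self.doses], dtype=float)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def shifted(self, offset: float) -> "Protocol":
        """Same schedule with all dose times moved by ``offset`` days."""
        return Protocol(
            self.name, tuple(DoseEvent(d.time + offset, d.e0) for d in self.doses)
        )


def build_c28(n_cycles: int, e0: float = 1.0, start: float = 0.0) -> Protocol:
    """Cyclic protocol: doses on days 0-4 of each 28-day cycle."""
    if n_cycles < 1:
        raise InvalidInputError(f"need at least one cycle, got {n_cycles}")
    doses = tuple(
        DoseEvent(start + 28.0 * c + d, e0)
        for c in range(n_cycles)
        for d in range(5)
    )
    return Protocol("C28", doses)


def build_id(spacing_days: float, n_doses: int, e0: float = 1.0) -> Protocol:
    """Individual doses every ``spacing_days`` days, first at day 0."""
    if spacing_days < 1:
        raise InvalidInputError(f"spacing must be >= 1 day, got {spacing_days}")
    if n_doses < 1:
        raise InvalidInputError(f"need at least one dose, got {n_doses}")
    doses = tuple(DoseEvent(k * float(spacing_days), e0) for k in range(n_doses))
    return Protocol(f"ID{spacing_days:g}", doses)


def build_stupp(e0: float = 0.5) -> Protocol:
    """Six weeks of weekday dosing (30 doses) at half effect by default."""
    doses = tuple(
        DoseEvent(7.0 * week + day, e0) for week in range(6) for day in range(5)
    )
    return Protocol("STUPP", doses)


def resolve_protocol(label: str, n_doses: int, e0: float = 1.0) -> Protocol:
    """Build the named protocol sized to a per-patient dose budget.

    ``C28`` converts the budget to cycles of five doses (rounded up to a
    whole cycle); ``ID<k>`` delivers the budget as individual doses spaced
    k days; ``STUPP`` ignores the budget (fixed 30 half-effect doses).
    """
    label = label.upper()
    if label == "C28":
        n_cycles = max(1, -(-n_doses // 5))
        return build_c28(n_cycles, e0=e0)
    if label == "STUPP":
        return build_stupp()
    m = re.fullmatch(r"ID(\d+)", label)
    if m:
        return build_id(int(m.group(1)), n_doses, e0=e0)
    raise InvalidInputError(f"unknown protocol label: {label!r}")


@dataclass(frozen=True)
class AdaptiveConfig:
    """Closed-loop schedule adaptation from periodic volume screenings.

    At each screening (every ``screening_interval`` days from treatment
    start) the simulated total volume is compared against
    ``threshold_fraction`` times the treatment-start volume; while below,
    scheduled doses in the upcoming screening window are withheld (lost,
    not deferred).
    """

    screening_interval: float = 90.0
    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.screening_interval > 0:
            raise InvalidInputError("screening interval must be positive")
        if not 0 < self.threshold_fraction <= 1:
            raise InvalidInputError("threshold fraction must be in (0, 1]")


def administered_doses(
    params: ModelParams,
    V_S0: float,
    base: Protocol,
    cfg: AdaptiveConfig,
    sim_cfg: SimulationConfig | None = None,
) -> Protocol:
    """Doses actually delivered when a base protocol is run adaptively.

    Treatment (and the screening clock) starts at t=0 with volume ``V_S0``,
    which is the adaptive reference.  The decision taken at screening time
    ``t_s`` governs doses in ``[t_s, t_s + screening_interval)``; the first
    window ``[0, interval)`` precedes any decision and is always delivered.
    Screenings stop once the base schedule is exhausted.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    if base.n_doses == 0:
        raise InvalidInputError("base protocol must contain at least one dose")
    p = params.as_vector()
    interval = cfg.screening_interval
    reference = V_S0
    base_times = base.times
    base_e0 = base.e0s
    last_dose_time = base_times[-1]

    y = np.array([V_S0, 0.0, 0.0, 0.0, 0.0, 0.0])
    administered: list[DoseEvent] = []
    t = 0.0
    k = 0
    while t < sim_cfg.horizon and t <= last_dose_time:
        window_end = min((k + 1) * interval, sim_cfg.horizon)
        if k == 0:
            deliver = True  # first window precedes any screening decision
        else:
            volume = float(y[:5].sum())
            deliver = volume >= cfg.threshold_fraction * reference
        if deliver:
            mask = (base_times >= t) & (base_times < window_end)
            for bt, be in zip(base_times[mask], base_e0[mask]):
                administered.append(DoseEvent(float(bt), float(be)))
        # advance the state to the next screening (doses applied inside)
        seg_times = np.array(
            [d.time for d in administered if t <= d.time < window_end]
        )
        seg_e0 = np.array([d.e0 for d in administered if t <= d.time < window_end])
        tt = t
        for dt_i, de_i in zip(seg_times, seg_e0):
            if dt_i > tt:
                status, _, _, _ = _kernel.integrate_segment(
                    y, tt, dt_i, p, sim_cfg.rel_tol, sim_cfg.abs_tol,
                    sim_cfg.max_step_dosing, -1.0, False,
                )
                if status != _kernel.OK:
                    raise IntegrationError(f"adaptive run failed near t={tt:g}")
                tt = dt_i
            y[5] += de_i
        if window_end > tt:
            status, _, _, _ = _kernel.integrate_segment(
                y, tt, window_end, p, sim_cfg.rel_tol, sim_cfg.abs_tol,
                sim_cfg.max_step_dosing, -1.0, False,
            )
            if status != _kernel.OK:
                raise IntegrationError(f"adaptive run failed near t={tt:g}")
        t = window_end
        k += 1

    return Protocol(
        f"{base.name}-adaptive", tuple(sorted(administered, key=lambda d: d.time))
    )


def simulate_adaptive(
    params: ModelParams,
    V_S0: float,
    base: Protocol,
    cfg: AdaptiveConfig,
    sim_cfg: SimulationConfig | None = None,
):
    """Simulate a base protocol under adaptive dose withholding.

    Returns ``(trajectory, administered)`` where ``administered`` is the
    sub-protocol of base doses actually given (see
    :func:`administered_doses` for the screening rules).
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    administered = administered_doses(params, V_S0, base, cfg, sim_cfg)
    trajectory = simulate(params, V_S0, administered, sim_cfg)
    return trajectory, administered
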