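"""In silico clinical trials: survival endpoints, KM curves, log-rank tests.

A virtual patient's overall survival is the time from simulation start
until the total tumor volume reaches their fatal volume; treatment begins
after a 30-day lead-in.  Two-arm trials draw independent cohorts, size
each patient's protocol from their own dose budget (a C28 arm uses
budget/5 cycles, an ID arm the budget as individual doses), and compare
arms with the Kaplan-Meier estimator and the log-rank test.  The module
also provides the loss-of-control sweep (smallest dose spacing with no net
shrinkage), the shrinkage statistic, the per-arm sample-size sweep and the
trial-safety check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from . import _kernel
from .cohort import CohortSpec, VirtualPatient, generate_cohort
from .model import IntegrationError, InvalidInputError, ModelParams, SimulationConfig
from .protocols import Protocol, build_id, resolve_protocol

DAYS_PER_MONTH = 30.4375

#: days of post-dosing follow-up used when locating the trajectory minimum;
#: long enough for the damaged compartment (tau >= ~1.7e-3/day) to clear
_MIN_SEARCH_TAIL = 3000.0


@dataclass(frozen=True)
class TrialSpec:
    n_per_arm: int = 100
    lead_in: float = 30.0  # days before treatment start
    alpha: float = 0.05
    horizon: float = 18250.0  # days (~50 years); later events are censored
    seed: int = 0
    dose_e0: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise InvalidInputError("need at least 2 patients per arm")
        if self.lead_in < 0:
            raise InvalidInputError("lead-in must be >= 0")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class SurvivalOutcome:
    patient_id: int
    time: float  # days from simulation start
    event: bool  # True: fatal volume reached; False: horizon-censored


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # days; inf if the curve never reaches 0.5


@dataclass(frozen=True)
class TrialResult:
    label_a: str
    label_b: str
    outcomes_a: tuple
    outcomes_b: tuple
    km_a: KMCurve
    km_b: KMCurve
    logrank_statistic: float
    p_value: float
    median_a: float  # days
    median_b: float  # days
    gain_months: float | None  # (median_b - median_a) in months; None if undefined


def time_to_fatal(
    vp: VirtualPatient,
    protocol: Protocol,
    spec: TrialSpec,
    sim_cfg: SimulationConfig | None = None,
) -> SurvivalOutcome:
    """First time the total volume reaches the patient's fatal volume.

    Protocol times are relative to treatment start and are shifted by the
    lead-in.  Crossing times are refined to ~0.1-day precision inside the
    bracketing solver step; if the cap is not reached by the horizon the
    outcome is censored there.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    y0 = np.array([vp.V0, 0.0, 0.0, 0.0, 0.0, 0.0])
    d_times = protocol.times + spec.lead_in
    status, t_cross, _, _, _ = _kernel.run_protocol(
        y0, vp.params.as_vector(), d_times, protocol.e0s, spec.horizon,
        sim_cfg.rel_tol, sim_cfg.abs_tol,
        sim_cfg.max_step_dosing, sim_cfg.max_step_free,
        vp.V_fatal, 0.0,
    )
    if status != _kernel.OK:
        raise IntegrationError("survival simulation failed")
    if t_cross >= 0.0:
        return SurvivalOutcome(id(vp), max(t_cross, 1e-6), True)
    return SurvivalOutcome(id(vp), spec.horizon, False)


def kaplan_meier(outcomes) -> KMCurve:
    """Product-limit survival estimate; censored times shrink the risk set."""
    outcomes = list(outcomes)
    if not outcomes:
        raise InvalidInputError("need at least one outcome")
    times = np.array([o.time for o in outcomes])
    events = np.array([o.event for o in outcomes], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.values.astype(float)
    surv = kmf.survival_function_.iloc[:, 0].values
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).values
    median = float(kmf.median_survival_time_)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, median=median)


def logrank_test(a, b) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and its p-value."""
    a, b = list(a), list(b)
    if not a or not b:
        raise InvalidInputError("both arms must be non-empty")
    if not any(o.event for o in a) and not any(o.event for o in b):
        raise InvalidInputError("log-rank test undefined without any events")
    res = _ll_logrank(
        np.array([o.time for o in a]),
        np.array([o.time for o in b]),
        event_observed_A=np.array([o.event for o in a], dtype=bool),
        event_observed_B=np.array([o.event for o in b], dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


def _arm_outcomes(cohort, label, spec, sim_cfg):
    outs = []
    for i, vp in enumerate(cohort):
        protocol = resolve_protocol(label, vp.dose_budget, e0=spec.dose_e0)
        o = time_to_fatal(vp, protocol, spec, sim_cfg)
        outs.append(SurvivalOutcome(i, o.time, o.event))
    return tuple(outs)


def run_trial(
    spec: TrialSpec,
    cohort_spec: CohortSpec,
    protocol_a: str,
    protocol_b: str,
    sim_cfg: SimulationConfig | None = None,
    matched: bool = False,
) -> TrialResult:
    """One two-arm trial; arms are independently generated by default.

    Arm cohorts are drawn with seeds derived from ``spec.seed``; each
    patient's dose budget sizes whichever protocol their arm prescribes.
    With ``matched=True`` the same generated patients populate both arms
    (virtual twins), which removes between-patient variability from the
    comparison.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    seed_a, seed_b = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31)
    cohort_a = generate_cohort(
        replace(cohort_spec, n_patients=spec.n_per_arm, seed=int(seed_a))
    )
    cohort_b = (
        cohort_a
        if matched
        else generate_cohort(
            replace(cohort_spec, n_patients=spec.n_per_arm, seed=int(seed_b))
        )
    )
    outcomes_a = _arm_outcomes(cohort_a, protocol_a, spec, sim_cfg)
    outcomes_b = _arm_outcomes(cohort_b, protocol_b, spec, sim_cfg)
    km_a = kaplan_meier(outcomes_a)
    km_b = kaplan_meier(outcomes_b)
    stat, p = logrank_test(outcomes_a, outcomes_b)
    if math.isfinite(km_a.median) and math.isfinite(km_b.median):
        gain = (km_b.median - km_a.median) / DAYS_PER_MONTH
    else:
        gain = None
    return TrialResult(
        label_a=protocol_a,
        label_b=protocol_b,
        outcomes_a=outcomes_a,
        outcomes_b=outcomes_b,
        km_a=km_a,
        km_b=km_b,
        logrank_statistic=stat,
        p_value=p,
        median_a=km_a.median,
        median_b=km_b.median,
        gain_months=gain,
    )


def run_adaptive_trial(
    spec: TrialSpec,
    cohort_spec: CohortSpec,
    base_label: str,
    adaptive_cfg,
    sim_cfg: SimulationConfig | None = None,
):
    """Base ID protocol (arm A) versus its adaptive variant (arm B).

    Arm B patients run the same base schedule but doses are withheld at
    screenings while the volume sits below the adaptive threshold; each
    patient's administered subset follows from their own simulated
    dynamics (the screening decisions are scale-invariant, so the lead-in
    growth before treatment start does not change them).

    Returns ``(result, administered_counts, budgets)`` where the two
    tuples give, per arm-B patient, the doses actually delivered and the
    full dose budget.
    """
    from .protocols import administered_doses

    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    seed_a, seed_b = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31)
    cohort_a = generate_cohort(
        replace(cohort_spec, n_patients=spec.n_per_arm, seed=int(seed_a))
    )
    cohort_b = generate_cohort(
        replace(cohort_spec, n_patients=spec.n_per_arm, seed=int(seed_b))
    )
    outcomes_a = _arm_outcomes(cohort_a, base_label, spec, sim_cfg)
    outcomes_b = []
    doses_given = []
    for i, vp in enumerate(cohort_b):
        base = resolve_protocol(base_label, vp.dose_budget, e0=spec.dose_e0)
        loop_cfg = replace(sim_cfg, horizon=float(base.times[-1]) + 1.0)
        administered = administered_doses(
            vp.params, vp.V0, base, adaptive_cfg, loop_cfg
        )
        doses_given.append(administered.n_doses)
        o = time_to_fatal(vp, administered, spec, sim_cfg)
        outcomes_b.append(SurvivalOutcome(i, o.time, o.event))
    outcomes_b = tuple(outcomes_b)
    km_a = kaplan_meier(outcomes_a)
    km_b = kaplan_meier(outcomes_b)
    stat, p = logrank_test(outcomes_a, outcomes_b)
    gain = (
        (km_b.median - km_a.median) / DAYS_PER_MONTH
        if math.isfinite(km_a.median) and math.isfinite(km_b.median)
        else None
    )
    result = TrialResult(
        label_a=base_label,
        label_b=f"{base_label}-adaptive",
        outcomes_a=outcomes_a,
        outcomes_b=outcomes_b,
        km_a=km_a,
        km_b=km_b,
        logrank_statistic=stat,
        p_value=p,
        median_a=km_a.median,
        median_b=km_b.median,
        gain_months=gain,
    )
    return result, tuple(doses_given), tuple(vp.dose_budget for vp in cohort_b)


DEFAULT_SPACINGS = tuple(range(7, 99, 7))


def _tracked_min(params, V0, protocol, sim_cfg):
    """Post-start minimum total volume under a protocol from t=0.

    The run stops early once the volume exceeds ten times its starting
    value: after drug washout the total volume has a single minimum, so a
    tumor that has regrown past that point can only keep growing, and the
    early stop keeps runaway (high rho2) parameter sets affordable.
    """
    y0 = np.array([V0, 0.0, 0.0, 0.0, 0.0, 0.0])
    t_end = (protocol.times[-1] if protocol.n_doses else 0.0) + _MIN_SEARCH_TAIL
    status, _, _, v_min, _ = _kernel.run_protocol(
        y0, params.as_vector(), protocol.times, protocol.e0s, t_end,
        sim_cfg.rel_tol, sim_cfg.abs_tol,
        sim_cfg.max_step_dosing, sim_cfg.max_step_free,
        10.0 * V0, 0.0,
    )
    if status != _kernel.OK:
        raise IntegrationError("volume-minimum simulation failed")
    return float(v_min)


def _min_volume_under_id(params, n_doses, spacing, sim_cfg, V0=10.0):
    """(start volume, post-start minimum) under an ID protocol from t=0."""
    protocol = build_id(spacing, n_doses)
    return V0, _tracked_min(params, V0, protocol, sim_cfg)


def loss_of_control_threshold(
    params: ModelParams,
    n_doses: int,
    spacings=DEFAULT_SPACINGS,
    sim_cfg: SimulationConfig | None = None,
):
    """Smallest tested spacing at which treatment yields no net shrinkage.

    Control is lost at spacing s when the minimum total volume after
    treatment start never drops below the treatment-start volume.  Returns
    the smallest such spacing, or None if every tested spacing shrinks the
    tumor.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    spacings = list(spacings)
    if any(b < a for a, b in zip(spacings, spacings[1:])):
        raise InvalidInputError("spacings must be sorted ascending")
    for s in spacings:
        v0, v_min = _min_volume_under_id(params, n_doses, s, sim_cfg)
        if v_min >= v0 * (1.0 - 1e-9):
            return s
    return None


def max_volume_loss(
    params: ModelParams,
    V0: float,
    protocol: Protocol,
    sim_cfg: SimulationConfig | None = None,
) -> float:
    """Treatment-start volume minus the post-start minimum (cm^3, >= 0 when
    the tumor shrinks; 0 for monotone growth)."""
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    return float(V0 - _tracked_min(params, V0, protocol, sim_cfg))


def sample_size_sweep(
    spec: TrialSpec,
    cohort_spec: CohortSpec,
    protocol_b: str,
    sizes=tuple(range(10, 101, 10)),
    trials_per_size: int = 20,
    sim_cfg: SimulationConfig | None = None,
):
    """Log-rank p for repeated trials at increasing per-arm sizes.

    Returns ``(p_matrix, min_all_significant)``: the |sizes| x trials
    matrix of p-values against C28, and the smallest size at which every
    trial is significant at ``spec.alpha`` (None if no size achieves it).
    """
    sizes = list(sizes)
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise InvalidInputError("sizes must be ascending")
    if trials_per_size < 1:
        raise InvalidInputError("need at least one trial per size")
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        len(sizes) * trials_per_size
    ) % (2**31)
    p = np.empty((len(sizes), trials_per_size))
    for i, size in enumerate(sizes):
        for j in range(trials_per_size):
            trial_spec = replace(
                spec, n_per_arm=size, seed=int(seeds[i * trials_per_size + j])
            )
            p[i, j] = run_trial(
                trial_spec, cohort_spec, "C28", protocol_b, sim_cfg
            ).p_value
    all_sig = np.all(p < spec.alpha, axis=1)
    min_size = next((s for s, ok in zip(sizes, all_sig) if ok), None)
    return p, min_size


def check_safety(
    cohort,
    spacing: float,
    sim_cfg: SimulationConfig | None = None,
):
    """True iff no patient loses volume control at this dose spacing.

    A patient is offending when an ID protocol at ``spacing`` sized to
    their own dose budget never brings the volume below its value at
    treatment start.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    cohort = list(cohort)
    if not cohort:
        raise InvalidInputError("cohort must be non-empty")
    offending = []
    for i, vp in enumerate(cohort):
        v0, v_min = _min_volume_under_id(
            vp.params, vp.dose_budget, spacing, sim_cfg, V0=vp.V0
        )
        if v_min >= v0 * (1.0 - 1e-9):
            offending.append(i)
    return len(offending) == 0, offending
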