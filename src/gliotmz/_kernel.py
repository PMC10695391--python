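"""Compiled integration kernel for the persister-resistance ODE system.

The state vector is ``y = (V_S, V_D, V_PI, V_P, V_R, E)`` and the parameter
vector is ``p = (rho1, rho2, psi, alpha1, alpha2, beta, tau, lam, f_scale,
f_center, f_width)``.  Between doses the system is smooth; doses are exact
impulses on ``E`` applied by the callers.  The stepper is an adaptive
Dormand-Prince 5(4) pair with elementwise error control; it always lands
exactly on segment endpoints so dose times are hit without event detection.

Everything here is numba-compiled; the public modules wrap these functions
with validated dataclasses.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the integrators
OK = 0
STEP_UNDERFLOW = 1
NEGATIVE_STATE = 2
OVERFLOW = 3

#: total volume (cm^3) beyond which a trajectory is treated as a runaway;
#: far above any physiological scale, this only aborts explosive parameter
#: sets proposed during optimization before they reach floating overflow
V_RUNAWAY = 1e30

_MIN_STEP = 1e-12
_SAFETY = 0.9
_MAX_STEPS = 2_000_000  # per segment; never approached by sane inputs

# indices into the parameter vector
RHO1, RHO2, PSI, ALPHA1, ALPHA2, BETA, TAU, LAM, FSCALE, FCENTER, FWIDTH = range(11)


@njit(cache=True)
def rhs(y, p):
    """Right-hand side of the compartment system plus exponential clearance."""
    vs, vd, vpi, vp, vr, e = y[0], y[1], y[2], y[3], y[4], y[5]
    f_e = p[FSCALE] * (1.0 - np.tanh((e - p[FCENTER]) / p[FWIDTH]))
    out = np.empty(6)
    out[0] = p[RHO1] * vs - p[PSI] * vs * e - p[ALPHA1] * vs * e + p[BETA] * vp
    out[1] = p[PSI] * vs * e - p[TAU] * vd
    out[2] = p[ALPHA1] * vs * e - vpi * f_e
    out[3] = vpi * f_e - p[ALPHA2] * vp * e - p[BETA] * vp
    out[4] = p[RHO2] * vr + p[ALPHA2] * vp * e
    out[5] = -p[LAM] * e
    return out


@njit(cache=True)
def _dp_step(y, h, p):
    """One Dormand-Prince 5(4) step; returns (y5, error_estimate)."""
    k1 = rhs(y, p)
    k2 = rhs(y + h * (1.0 / 5.0) * k1, p)
    k3 = rhs(y + h * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2), p)
    k4 = rhs(y + h * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2 + 32.0 / 9.0 * k3), p)
    k5 = rhs(
        y
        + h
        * (
            19372.0 / 6561.0 * k1
            - 25360.0 / 2187.0 * k2
            + 64448.0 / 6561.0 * k3
            - 212.0 / 729.0 * k4
        ),
        p,
    )
    k6 = rhs(
        y
        + h
        * (
            9017.0 / 3168.0 * k1
            - 355.0 / 33.0 * k2
            + 46732.0 / 5247.0 * k3
            + 49.0 / 176.0 * k4
            - 5103.0 / 18656.0 * k5
        ),
        p,
    )
    y5 = y + h * (
        35.0 / 384.0 * k1
        + 500.0 / 1113.0 * k3
        + 125.0 / 192.0 * k4
        - 2187.0 / 6784.0 * k5
        + 11.0 / 84.0 * k6
    )
    k7 = rhs(y5, p)
    # difference between 5th and embedded 4th order solutions
    err = h * (
        (35.0 / 384.0 - 5179.0 / 57600.0) * k1
        + (500.0 / 1113.0 - 7571.0 / 16695.0) * k3
        + (125.0 / 192.0 - 393.0 / 640.0) * k4
        + (-2187.0 / 6784.0 + 92097.0 / 339200.0) * k5
        + (11.0 / 84.0 - 187.0 / 2100.0) * k6
        - 1.0 / 40.0 * k7
    )
    return y5, err


@njit(cache=True)
def _error_norm(err, y_old, y_new, rtol, atol):
    norm = 0.0
    for i in range(6):
        scale = atol + rtol * max(abs(y_old[i]), abs(y_new[i]))
        r = err[i] / scale
        norm += r * r
    return np.sqrt(norm / 6.0)


@njit(cache=True)
def _clamp_negatives(y, atol):
    """Flush sub-tolerance components to zero; flag material negativity.

    Components smaller than atol are below the resolved scale and are set
    to exactly zero.  Besides guarding positivity this kills phantom
    stiffness: a vanishing intermediate-persister volume (or drug effect)
    otherwise keeps its fast decay mode in the error control and pins the
    explicit stepper at the stability limit long after the component has
    become physically irrelevant.  The negativity guard is a loose multiple
    of atol: the embedded error control keeps local errors near atol, so
    excursions an order of magnitude beyond it indicate a genuine solver
    failure on this (linear, positivity preserving) system.
    """
    for i in range(6):
        if y[i] < atol:
            if y[i] < -100.0 * atol - 1e-300:
                return False
            y[i] = 0.0
    return True


@njit(cache=True)
def _initial_step(y, p, rtol, atol, span):
    """Starting step from the scaled first/second derivative magnitudes."""
    f0 = rhs(y, p)
    d0 = 0.0
    d1 = 0.0
    for i in range(6):
        scale = atol + rtol * abs(y[i])
        r0 = y[i] / scale
        r1 = f0[i] / scale
        d0 += r0 * r0
        d1 += r1 * r1
    d0 = np.sqrt(d0 / 6.0)
    d1 = np.sqrt(d1 / 6.0)
    if d0 < 1e-5 or d1 < 1e-5:
        h0 = 1e-6
    else:
        h0 = 0.01 * d0 / d1
    y1 = y + h0 * f0
    f1 = rhs(y1, p)
    d2 = 0.0
    for i in range(6):
        scale = atol + rtol * abs(y[i])
        r = (f1[i] - f0[i]) / scale
        d2 += r * r
    d2 = np.sqrt(d2 / 6.0) / h0
    dm = max(d1, d2)
    if dm > 1e-15:
        h1 = (0.01 / dm) ** 0.2
    else:
        h1 = max(1e-6, h0 * 1e3)
    h = min(100.0 * h0, h1)
    if h > span:
        h = span
    return h


@njit(cache=True)
def integrate_segment(y, t0, t1, p, rtol, atol, max_step, v_cap, track_min):
    """Integrate from t0 to t1 with no impulses inside the interval.

    Mutates ``y`` in place to the state at ``t1`` (or at the cap crossing).
    Returns ``(status, t_cross, t_min, v_min)``:

    - ``t_cross``: first time total volume >= ``v_cap`` (-1.0 if never, or
      if ``v_cap <= 0`` which disables the check).  Resolved to ~0.05 day by
      a fixed-step refinement inside the bracketing step.
    - ``t_min``/``v_min``: running minimum of total volume over accepted
      step endpoints (only if ``track_min``; else (-1, inf)).
    """
    span = t1 - t0
    t_min = t0
    v0 = y[0] + y[1] + y[2] + y[3] + y[4]
    v_min = v0 if track_min else np.inf
    if v_cap > 0.0 and v0 >= v_cap:
        return OK, t0, t_min, v_min
    if span <= 0.0:
        return OK, -1.0, t_min, v_min

    t = t0
    h = _initial_step(y, p, rtol, atol, span)
    if h > max_step:
        h = max_step
    n_steps = 0
    while t < t1:
        n_steps += 1
        if n_steps > _MAX_STEPS:
            return STEP_UNDERFLOW, -1.0, t_min, v_min
        if h > t1 - t:
            h = t1 - t
        y_new, err = _dp_step(y, h, p)
        norm = _error_norm(err, y, y_new, rtol, atol)
        if not np.isfinite(norm):
            # overflowing trial step: shrink hard and retry
            h = h * 0.2
            if h < _MIN_STEP:
                return STEP_UNDERFLOW, -1.0, t_min, v_min
            continue
        if norm <= 1.0:
            # accepted
            if not _clamp_negatives(y_new, atol):
                return NEGATIVE_STATE, -1.0, t_min, v_min
            if y_new[0] + y_new[1] + y_new[2] + y_new[3] + y_new[4] > V_RUNAWAY:
                return OVERFLOW, -1.0, t_min, v_min
            t_prev = t
            y_prev = y.copy()
            t = t + h
            for i in range(6):
                y[i] = y_new[i]
            v = y[0] + y[1] + y[2] + y[3] + y[4]
            if track_min and v < v_min:
                v_min = v
                t_min = t
            if v_cap > 0.0 and v >= v_cap:
                # refine the crossing with a 0.05-day fixed-step walk
                tc = t_prev
                yc = y_prev
                dt = 0.05
                while tc < t:
                    step = min(dt, t - tc)
                    yc2, _ = _dp_step(yc, step, p)
                    tc += step
                    vcur = yc2[0] + yc2[1] + yc2[2] + yc2[3] + yc2[4]
                    yc = yc2
                    if vcur >= v_cap:
                        break
                return OK, tc, t_min, v_min
            # grow the step
            if norm > 1e-10:
                fac = _SAFETY * norm ** (-0.2)
            else:
                fac = 8.0
            if fac > 8.0:
                fac = 8.0
            h = h * fac
            if h > max_step:
                h = max_step
        else:
            fac = _SAFETY * norm ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            h = h * fac
            if h < _MIN_STEP:
                return STEP_UNDERFLOW, -1.0, t_min, v_min
    return OK, -1.0, t_min, v_min


@njit(cache=True)
def run_protocol(
    y0,
    p,
    dose_times,
    dose_e0,
    t_end,
    rtol,
    atol,
    max_step_dosing,
    max_step_free,
    v_cap,
    track_from,
):
    """Simulate a full impulsive-dose schedule from t=0 to t_end.

    Doses (sorted, within [0, t_end]) add ``dose_e0[i]`` to E at
    ``dose_times[i]``.  Minimum total volume is tracked for t >= track_from;
    if ``v_cap > 0`` the run stops at the first crossing of the cap.

    Returns ``(status, t_cross, t_min, v_min, y_final)``.
    """
    y = y0.copy()
    t = 0.0
    v_min = np.inf
    t_min = -1.0
    v_start = y[0] + y[1] + y[2] + y[3] + y[4]
    if track_from <= 0.0:
        v_min = v_start
        t_min = 0.0
    if v_cap > 0.0 and v_start >= v_cap:
        return OK, 0.0, t_min, v_min, y
    n = dose_times.shape[0]
    for i in range(n + 1):
        t_next = dose_times[i] if i < n else t_end
        if t_next > t_end:
            t_next = t_end
        if t_next > t:
            track = t >= track_from or t_next > track_from
            max_step = max_step_dosing if i < n else max_step_free
            status, t_cross, tm, vm = integrate_segment(
                y, t, t_next, p, rtol, atol, max_step, v_cap, track
            )
            if status != OK:
                return status, -1.0, t_min, v_min, y
            if track and vm < v_min and tm >= track_from:
                v_min = vm
                t_min = tm
            if t_cross >= 0.0:
                return OK, t_cross, t_min, v_min, y
            t = t_next
        if i < n and dose_times[i] <= t_end:
            y[5] += dose_e0[i]
    return OK, -1.0, t_min, v_min, y


@njit(cache=True)
def eval_total_volume(y0, p, dose_times, dose_e0, eval_times, rtol, atol, max_step):
    """Total volume at each of ``eval_times`` under an impulsive schedule.

    ``eval_times`` must be sorted and non-negative; doses sorted.  A dose at
    exactly an evaluation time is applied after the state is recorded (the
    impulse moves E only, so total volume is unaffected either way).
    Returns (status, volumes).
    """
    y = y0.copy()
    t = 0.0
    n_ev = eval_times.shape[0]
    n_d = dose_times.shape[0]
    out = np.empty(n_ev)
    i_ev = 0
    i_d = 0
    while i_ev < n_ev:
        # next breakpoint: evaluation node or dose, whichever first
        if i_d < n_d and dose_times[i_d] < eval_times[i_ev]:
            t_next = dose_times[i_d]
            is_dose = True
        else:
            t_next = eval_times[i_ev]
            is_dose = False
        if t_next > t:
            status, _, _, _ = integrate_segment(
                y, t, t_next, p, rtol, atol, max_step, -1.0, False
            )
            if status != OK:
                return status, out
            t = t_next
        if is_dose:
            y[5] += dose_e0[i_d]
            i_d += 1
        else:
            out[i_ev] = y[0] + y[1] + y[2] + y[3] + y[4]
            i_ev += 1
            # apply any dose that coincides with this node
            while i_d < n_d and dose_times[i_d] <= t:
                y[5] += dose_e0[i_d]
                i_d += 1
    return OK, out
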