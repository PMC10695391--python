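# Methods

## Model

`gliotmz` simulates the volumetric response of low-grade gliomas (LGG) to
temozolomide (TMZ) with a linear compartment model of five well-mixed cell
populations, each measured as the volume it occupies (cm³):

- **V_S** — drug-sensitive cells, proliferating at ρ₁ (day⁻¹);
- **V_D** — drug-damaged cells, dying by delayed mitotic catastrophe at τ;
- **V_PI** — intermediate (freshly induced) persister cells;
- **V_P** — stabilized drug-tolerant persister cells, reverting to the
  sensitive phenotype at β or converting to full resistance under renewed
  drug exposure at α₂;
- **V_R** — irreversibly resistant cells, proliferating at ρ₂ > ρ₁.

The normalized drug effect E (0 = none, 1 = peak of a standard oral dose)
decays exponentially at λ = 24·ln2 / t₁ₕ₂ with a 2-hour plasma half-life
(λ ≈ 8.32 day⁻¹). The coupled system is

    V_S' = ρ₁V_S − ψV_S·E − α₁V_S·E + βV_P
    V_D' = ψV_S·E − τV_D
    V_PI' = α₁V_S·E − V_PI·f(E)
    V_P' = V_PI·f(E) − α₂V_P·E − βV_P
    V_R' = ρ₂V_R + α₂V_P·E
    E'  = −λE

with the sigmoid activation f(E) = 7.5·(1 − tanh((E − 0.01)/0.01)) day⁻¹.
f is appreciable only at low E: persisters induced by a dose stabilize only
after that dose has washed out, so a *subsequent* dose is required to
convert them to resistance. Each oral dose is an impulse adding E₀ (default
1; 0.5 for the weekday phase of the Stupp regimen) to E, leaving all
volumes continuous. Because the volume equations are linear given E(t),
trajectories scale exactly with the initial volume; several tests and the
loss-of-control sweep exploit this.

Assumptions worth restating: exponential (unbounded) growth with no
carrying capacity; irreversible resistance with no fitness cost off drug
(which is why adaptive schedules cannot add survival in this model);
well-mixed compartments with no spatial structure; radiotherapy not
modelled.

## Numerics

Integration is piecewise between dose times with an adaptive
Dormand–Prince 5(4) pair compiled with numba; the stepper always lands on
segment endpoints, so impulses are applied exactly rather than detected.
Defaults: rel_tol 1e-8, abs_tol 1e-10 cm³.

Components that fall below abs_tol are flushed to exactly zero. Besides
clamping the small negative excursions an explicit method can produce on a
positivity-preserving linear system (excursions beyond ~100·abs_tol abort
the run instead), the flush removes *phantom stiffness*: a vanishing V_PI
keeps its fast decay mode f(0) ≈ 13 day⁻¹ inside the error control and
would otherwise pin the step size at the stability limit for years of
simulated time after the compartment is physically empty.

Fatal-volume crossings are located inside the bracketing accepted step by
a fixed 0.05-day forward walk (~0.1-day precision). Trajectory runaways
past 1e30 cm³ abort with an error; this is only reachable by absurd
parameter sets proposed during optimization. Volume minima (for the
shrinkage and loss-of-control analyses) are tracked at accepted step
endpoints with the step capped at 5 days during dosing; the post-washout
total volume has a single minimum (its derivative ρ₁V_S + ρ₂V_R − τV_D is
non-decreasing once E ≈ 0), so these runs stop early once the volume has
regrown past ten times its treatment-start value.

## Per-patient fitting

The six free rates (ρ₁, ρ₂, τ, ψ, α₁, α₂) are estimated per patient by
multi-start Nelder–Mead (default 20 restarts, log-uniform starts) on the
RMSE between the model's total volume and the observations, with β fixed
at 0.1 day⁻¹ and λ at 8.32 day⁻¹. The simulation clock is re-zeroed at
the first observation, whose volume is the initial condition. The search
runs in log space (positivity by construction) with α₂ = α₁·σ(u),
σ the logistic function, enforcing α₂ < α₁ without constraints; ρ₂ > ρ₁
is *not* imposed (it is a biological expectation, not a fit constraint)
and is reported post hoc. The objective is a plateau outside the
prescribed bounds extended by one decade — beyond that, log-space
excursions would make the piecewise integration arbitrarily expensive.
The two best restarts are polished by re-running Nelder–Mead from their
endpoints (re-initializing the simplex escapes the degenerate collapse
the method is prone to in six dimensions). Simplex tolerances are 1e-4
(log-parameter resolution ≪ 0.1%, objective resolution 1e-4 cm³ against
volumes carrying 18% measurement error); the objective integrates at
rel_tol 1e-6, again far below any resolvable objective difference.
Default bounds span 0.1× to 10× the envelope of the packaged fitted
cohort. Fits are unweighted.

Noiseless synthetic records are recovered to within 10% per parameter.
With 18% multiplicative noise the problem is ill-conditioned — parameters
trade off along ridges — and only median-level accuracy (<30% per
parameter over patients) is tested, on records that mimic clinical
follow-up (a watch-and-wait phase, cyclic treatment, surveillance ending
near the fatal volume). Real records with different observation designs
may identify the rates better or worse.

## Virtual patients

A virtual patient = six rates + initial volume V₀ + dose budget + fatal
volume. Rates are drawn from a multivariate log-normal sampled through
the Cholesky factor of a Gaussian copula built from the fitted table's
Spearman matrix (r = 2·sin(π·r_s/6)) with the table's marginal log
variances; the rank-correlation conversion is used because the raw
log-scale Pearson covariance measurably understates the rank targets
(α₁–ψ by ~0.15 at n = 200). Draws are rejected until α₂ < α₁, ρ₂ > ρ₁
and every rate lies in [min/2, 2·max] of its source column; β and λ stay
fixed. All bounded draws use redraw, not clipping, to avoid probability
atoms at the bounds.

Initial volumes come from a Gaussian KDE (Silverman bandwidth) over a
packaged **synthetic** list of seven baseline volumes (18–130 cm³)
standing in for the study's unpublished 32-patient diagnosis-volume
sample; it spans the range reported for LGG at diagnosis but its spread
is otherwise uncalibrated, and downstream survival-gain magnitudes are
sensitive to it. Dose budgets are 5 × a cycle count drawn from a rounded
normal (mean 19, sd 7, redrawn into [6, 34]); fatal volumes from a normal
(mean 280 cm³, sd 20 cm³, positive). The printed "variance" of 7 cycles
and 20 cm³ are interpreted as standard deviations — with true variances
the stated truncation bounds would be vacuous — and both are
configurable.

What the generator does *not* emulate: covariate structure (age,
histology, IDH status), measurement noise on the virtual trajectories,
and the exact marginal shapes of the original cohort (log-normal tails
are heavier than a natural-scale regression chain would give). Passing
cohort tests therefore demonstrate internal consistency with the packaged
seven-patient table, not calibration to any clinical population.

## In silico trials

Each patient is simulated from 30 days before treatment start; overall
survival is the time from simulation start until the total volume reaches
the patient's fatal volume, censored at a 50-year horizon. Protocols:
C28 (five daily doses, then 23 rest days, per 28-day cycle), ID-k (one
dose every k days), Stupp (six weeks of weekday half-effect doses). Each
patient's dose budget fixes their total dose count in whichever arm they
occupy (C28 arm: budget/5 cycles). Arms are sampled independently by
default — the design of a real trial; a matched-twins mode (identical
patients in both arms) exists and roughly halves the between-trial spread
of the gain estimates. Kaplan–Meier estimation and the log-rank test come
from lifelines; the median is the smallest time with S ≤ 0.5, and gains
are reported in months of 30.4375 days.

Loss of control at spacing k means the minimum total volume after
treatment start never falls below the treatment-start volume; the
threshold of a patient is the smallest such k among multiples of 7 up to
98. The safety check rejects any spacing at which at least one cohort
patient loses control.

Adaptive scheduling: screenings every 90 days from treatment start; the
decision at a screening governs doses in [t_s, t_s + interval) — the
first window precedes any decision and is always delivered — and doses
are withheld (lost, not deferred) while the volume sits below a threshold
fraction of the treatment-start volume. Screenings stop once the base
schedule is exhausted. Decisions compare a volume ratio, so they are
invariant to the overall volume scale.

## Problem sizes

The test suite runs survival-gain checks at 5 trials per spacing and
sample-size checks at 8 trials per size (100 and 30–40 patients per arm
respectively); the acceptance script uses 5 trials for the ID14/ID21 gain,
20 trials each for the ID7/ID42 gains and the significance fractions, and
an ascending early-stopping scan for the minimal all-significant arm size.
These counts were chosen to estimate medians and fractions to the
precision the comparisons need.

## Known limitations

- Survival-gain magnitudes and small-cohort power depend strongly on
  between-patient heterogeneity, which is reconstructed here from a
  seven-row parameter table and a synthetic initial-volume stand-in;
  gains for widely spaced protocols (ID35/ID42) and significance
  fractions at 30–40 patients per arm are the quantities most affected.
- The KM median is undefined when fewer than half of an arm's patients
  reach the fatal volume before the horizon; gains are then reported as
  unavailable (the log-rank p-value is still computed).
- The fit treats all observations equally; no identifiability or
  posterior analysis is attempted.
- Integration is explicit; the model's stiffness is mild (λ ≈ 8.32 day⁻¹
  dominates) but pathological parameter sets are handled by rejection
  (bounds plateau, runaway guard) rather than by a stiff solver.
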