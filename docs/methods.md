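# Methods

## Models and assumptions

`oncodyn` describes the number of mutated cells `x(t)` in one incipient
tumour as a scalar population. Three deterministic laws are implemented
(module `growth`):

* Richards / generalized logistic, `dx/dt = νr·x − νμ·x^((ν+1)/ν)`, chosen
  because one shape parameter ν interpolates between symmetric logistic
  growth (ν = 1) and Gompertz-like, strongly asymmetric growth (ν → ∞).
* ERM1, the Volterra-style extension with a second density-dependent death
  term. It has a closed-form extinction threshold
  `A = ((μ − √(μ²−4rγ))/2γ)^ν` (implemented in the numerically stable
  companion form `y_A = 2r/(μ + √(μ²−4rγ))` to avoid cancellation when
  A ≪ K), but its growth/saturation asymmetry `(A/K)^(1/ν)` is below 1 for
  every ν, so trajectories are step-like.
* ERM2, Richards minus an immune clearance `s(t)` cells/day with `x = 0`
  absorbing. For constant s the stationary drift
  `g(x) = νr·x − νμ·x^((ν+1)/ν) − s` is unimodal on x > 0; its two positive
  roots (threshold A, capacity K) are bracketed by `s/(νr)` below, the
  Richards capacity above, and the drift maximum between, and found by
  Brent's method. Linearization rates use the analytic derivative
  `g'(x) = νr − (ν+1)μ·x^(1/ν)`; a central-difference linearizer is kept as
  an independent cross-check for the tests.

Assumptions worth stating: a single well-mixed cluster (no spatial
structure, no clonal competition); the immune response removes a fixed
*number* (not fraction) of cells per day; and the host outlives the
simulation horizon (no competing mortality).

## Stationary and moving threshold approximations

Writing `A ~ 10^a` and expanding `A^(1/ν) = exp(a·ln10/ν)` to first order
gives `A ≈ s/(νr − μ(ν + a·ln10))`. The exponent a is resolved
self-consistently (iterate `a ← log10(A)` from a = 2 until |Δa| < 1e-3,
at most 50 iterations) because the defining relation only fixes A's order of
magnitude. The same form with `s → s_m(t) − m̄(t)` gives the per-day moving
threshold; `m̄` is the realized mean mutation count over the current
menstrual phase (28-day blocks in acyclic stretches, where `s_m` is constant
and the averaging interval is arbitrary). The expansion is accurate when
A ≪ K; the suite checks a factor-of-3 agreement with the numerically located
root for thresholds spanning 10–1e6 cells, a band chosen by us (the source
analysis illustrates the approximation only graphically).

## Mutation process

Each of n healthy stem cells mutates within a day with probability
`p(t) = p0(1 + δt/(100T))`, independently, so the daily influx is exactly
Binomial(n, p(t)) (mean np, variance np(1−p)). Sampling is exact binomial —
no Poisson or Gaussian shortcut — because threshold crossings are driven by
the distribution's tail. `p(t)` is clipped at 1 with a warning; T is stored
in days (config accepts years, 1 y = 365 d).

## Complete daily-step model

The Euler–Maruyama discretization of ERM2 with the mutation increments, at a
fixed step of 1 day:
`x(t+1) = max(x + [νr·x − νμ·x^((ν+1)/ν) − s_m(t)] + m(t), 0)`.
The state stays real-valued (hybrid construction: continuous drift, integer
increments). With p ≡ 0 and constant s the iteration *is* the explicit-Euler
ERM2 map, bit for bit — the suite asserts exact equality.

Event rules (configurable): an upward crossing of `Ā(t)` is a **transition**
once the cluster reaches a confirmation size of 10× the threshold at the
crossing day (or stays above the threshold for 365 days); returning below
the threshold earlier is a **rescue**. The confirmation size is our
operational stand-in for an undefined diagnosis rule; both constants are
parameters. A lifetime run stops at the transition — risk curves need onset
ages only, which saves orders of magnitude of compute. Extinction events are
reported only for excursions that had crossed the threshold; sub-threshold
mutation flickers (a few cells for a day or two) are not events.

The day loop skips runs of days with `x = 0` and `m(t) ≤ s_m(t)` (the state
provably stays 0 there), which makes whole-lifetime simulation cheap without
changing the trajectory.

## Immune schedule and life histories

The menstrual cycle is reduced to two phases: a fixed 14-day luteal phase
(`s_min`) and a variable follicular phase (`s_max`; menstruation days are
folded into it, since the schedule has only two branches). Follicular length
is resampled every cycle from N(14, 2.4²) days truncated at 1 day (bias
< 0.01 day); cycles run follicular-first from menarche (age 12) and the last
partial cycle is cut at the effective menopause. Menopause M is fixed at 51 y
(case 1) or drawn from N(51, 4.86²) truncated below menarche + 1 y
(cases 2–3); in case 3 a Bernoulli(0.26) subset of women extends cycling by
an HRT duration drawn from the gamma distribution with mode 6 y and SD 4.8 y
(shape/scale solved exactly from those two constraints). Case 0 is the
acyclic baseline (`s_max` for life). HRT schedules are identical square
waves to premenopausal cycles — progesterone cycling continues during
treatment.

## Cohort Monte Carlo

Each woman gets an independent substream from `SeedSequence(seed).spawn`
(woman i's stream is independent of scheduling), further split into
(menopause/HRT, cycles, mutations) children so that cohorts simulated under
different cases with the same master seed are pairwise coupled: case 3's
schedule is case 2's with extra luteal exposure, so under coupling the
ordering of transition times is a per-woman, not merely statistical,
property. Different master seeds give independent cohorts (common random
numbers off). Risk at a band edge is the fraction of women with a transition
by that age (all women in the denominator — onset only, no censoring), with
95% Clopper–Pearson bounds. Registry incidence tables are converted with the
standard actuarial transform `R(t) = 100(1 − exp(−Σ rate·width))`.

## Default human-risk parameters (placeholders, calibrated once)

The published analysis keeps its numeric tables (n, p0, δ, ν, r, μ) in
supplementary material; the main text anchors only the immune offsets
`s_min = n·p0 + 262` and `s_max = n·p0 + 354` cells/day. Our defaults are
therefore *placeholders chosen once* and documented here, not the published
values:

* breast preset: n = 3.25e7 stem cells, p0 = 4e-4/day (n·p0 = 13 000/day,
  so the daily influx SD is √(np) ≈ 114), δ = 1.7% over T = 84 y, ν = 1,
  r = 0.2/day, K = 2e12 cells.
* typical preset (constant `s_max`): n = 1.05e8, p0 = 4e-4
  (n·p0 = 42 000/day), δ = 0.26%, same growth law.

Rationale: transitions require the clearance margin (262 or 354 cells/day at
birth, shrinking as n·p0·δ·t/(100T) grows) to fall to a few noise standard
deviations. With these numbers the weak-immunity (luteal) channel activates
around the menopausal ages and the strong-immunity channel only in old age,
separating the two regimes of the risk curve; the lifetime (by 85) risk of
the case-3 cohort lands near the ~13% scale quoted for breast cancer, and
the constant-response cohort shows the exponential-like rise of typical
cancers. Outcomes are *very* sensitive to δ (a hallmark of
threshold-crossing models); the presets fix the study conditions for the
examples and tests and should be refit before any quantitative use.

## Synthetic data

Tumour fixtures integrate a chosen true model, sample a day grid, and apply
multiplicative lognormal noise (caliper-style errors scale with size); specs
are JSON-serializable with mandatory seeds, so fixtures regenerate
bit-exactly. Two canned shapes mimic published mouse experiments: dense
individual measurements following a strongly asymmetric curve (65
replicates × 9 days) and eight per-day means following a symmetric ν = 1
curve. Volumes convert at 1e9 cells/cm³. Incidence fixtures produce 5-year
bands with an exponential-in-age rate or a "breast-like" polynomial rise
that flattens near age ~50. What passing tests on these fixtures do *not*
show: behaviour under real measurement error structure, inter-animal growth
heterogeneity (all replicates share one true curve), or registry artefacts
(age heaping, cohort effects).

## Fitting

Shooting fits: integrate from the first observation (or a supplied known
inoculum x0) and minimize squared residuals on log sizes (sizes span
decades; the loss of the source analysis is unstated, and a linear loss
would be dominated by the largest tumours — a linear option is retained).
Parameters are optimized in log10 space with bounds (ν ∈ [0.1, 1e6], rates
positive) by trust-region least squares, multi-started over
ν ∈ {1, 10, 1e3, 1e5}, r from the early-time log-slope, and (μ, s) or
(μ, γ) from threshold/capacity re-parameterizations at A ∈ {1e2, 1e4},
K = 2×max(data). Fits are deterministic given the data and init grid.
`K_below_data` flags a fitted capacity below the largest observation
(biologically inconsistent). Replicated datasets fit all points; the ODE is
solved once per residual evaluation on the unique times.

## Numerical choices

LSODA with rtol 1e-9 (1e-11 for first-passage work) and scaled atol;
extinction handled by a terminal event at 1e-6 cells followed by clamping to
0 (the ERM2 field reaches 0 with non-zero slope, so event detection avoids
negative overshoot); an overflow guard aborts at 1e15 cells. First-passage
times use the integrator's event root-finding on dense output, which
resolves the ERM1 step-timing span of four orders of magnitude. Ties and
degenerate configurations (no threshold, s too large, non-positive
approximation denominators) return explicit "no threshold"/"extinction
only"/NaN results instead of raising mid-sweep.

## Problem sizes used by the tests

Cohort properties run at 2 000 women per case (ordering, shapes) and 1 200
women per follicular-length grid point at a cutoff age of 58 — at the
calibrated presets the risk by 51 is ~1%, too few transitions at these
cohort sizes to resolve the cycle-length trend, while by 58 the same
mechanism (luteal exposure fraction) is well resolved; the interactive
examples use 400–600 women. Parameter-recovery checks use 50 noisy
replicates; property checks use 100 random parameter sets per model. The
noisy-recovery fixture starts near the threshold (1.2×A), where the immune
term is a first-order effect and hence identifiable.

## Known limitations

Single-cluster scalar state (no multi-focal disease); mutation counts enter
as a net daily influx (no genotype structure or multi-hit accumulation); the
immune response is exogenous (no immune-cell dynamics); phase labels and the
moving threshold are undefined during progression beyond the confirmation
size (the simulation stops there in the risk pipeline); and the published
shares of luteal-phase transitions (76%/63%) and the 1.75-fold short-cycle
risk ratio depend on the unpublished parameter tables — this package
reproduces their directions (luteal share > 50%, ratio > 1), not their
magnitudes.
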