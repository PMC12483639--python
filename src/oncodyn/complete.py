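"""The complete daily-step cancer development model.

Carcinogenesis is modelled as a non-autonomous stochastic difference equation
with a one-day step: deterministic ERM2-style drift (growth minus a
time-varying immune clearance ``s_m(t)``), plus an integer number of new
mutations ``m(t) ~ Binomial(n, p(t))`` each day, clamped at zero:

    x(t+1) = max(F(x, t), 0),
    F(x, t) = x + [nu*r*x - nu*mu*x**((nu+1)/nu) - s_m(t)] + m(t).

The interplay of the mutation influx and the immune response produces a
*moving extinction threshold*: per day,

    A_bar(t) ~ (s_m(t) - m_bar(t)) / (nu*r - mu*(nu + a*ln 10)),

where ``m_bar`` is the time-average of m(t) over an interval on which s_m is
roughly constant (here: the current menstrual phase) and ``10**a`` is the
threshold's order of magnitude.  A cluster crossing A_bar(t) usually
progresses into cancer (a *transition*); if the threshold rises faster than
the cluster grows, the cluster drops back below it and cancer is avoided
(a *rescue event*).

The state x is kept continuous even though mutations are integers (hybrid
construction: ODE drift plus integer increments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .growth import GrowthParams, GrowthConfigError, IntegrationError, OVERFLOW_GUARD
from .immune import ImmuneParams, LifeHistory, daily_schedule, DAYS_PER_YEAR
from .mutation import MutationParams, mutation_probability

__all__ = [
    "Trajectory",
    "step",
    "moving_threshold",
    "simulate_lifetime",
    "detect_events",
]

LN10 = math.log(10.0)


@dataclass
class Trajectory:
    """Daily record of one simulated lifetime.

    ``x`` is the cluster size at the start of each day (cells, >= 0);
    ``s_m`` and ``m`` are that day's immune response and mutation count;
    ``A_bar`` the moving-threshold approximation.  ``events`` is a list of
    ``(type, day)`` with type in {"crossing", "rescue", "transition",
    "extinction"}.  When a run stops early (transition found and
    ``stop_at_transition``), the arrays are truncated at the stopping day.
    """

    days: np.ndarray
    x: np.ndarray | None
    s_m: np.ndarray | None
    m: np.ndarray | None
    A_bar: np.ndarray | None
    events: list[tuple[str, int]] = field(default_factory=list)
    transition_day: int | None = None

    @property
    def transition_age_years(self) -> float | None:
        if self.transition_day is None:
            return None
        return self.transition_day / DAYS_PER_YEAR

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": self.days, "x": self.x, "s_m": self.s_m, "m": self.m, "A_bar": self.A_bar}
        )


def step(x: float, t: float, growth: GrowthParams, s_m: float, m: float) -> float:
    """One day of the complete model: ``max(F(x, t), 0)``.

    Note that F always uses the drift formula (not the absorbing ODE branch):
    from x = 0 the day's outcome is ``max(m - s_m, 0)``, so a burst of
    mutations can re-seed an extinct cluster.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if m < 0:
        raise ValueError("m must be >= 0")
    nu, r, mu = growth.nu, growth.r, growth.mu
    F = x + (nu * r * x - nu * mu * x ** ((nu + 1.0) / nu) - s_m) + m
    return max(F, 0.0)


def moving_threshold(s_m, m_bar, growth: GrowthParams, a: float):
    """Instantaneous moving-threshold approximation A_bar (cells).

    Lower when the immune response is weaker (luteal phases) at fixed
    mutation influx; with ``m_bar = 0`` and constant s it reduces exactly to
    the stationary-threshold approximation.  A non-positive denominator marks
    the segment invalid (NaN).
    """
    denom = growth.nu * growth.r - growth.mu * (growth.nu + a * LN10)
    s_m = np.asarray(s_m, dtype=float)
    out = (s_m - np.asarray(m_bar, dtype=float)) / denom
    if denom <= 0:
        out = np.full_like(out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _phase_mean_by_day(values: np.ndarray, boundaries: np.ndarray, horizon: int) -> np.ndarray:
    """Per-day mean of ``values`` over the immune segment containing each day.

    ``boundaries`` are segment start days (floats) inside [0, horizon); the
    implicit segments [0, b0) and [b_last, horizon) are included.
    """
    edges = np.unique(np.clip(np.concatenate(([0.0], boundaries, [float(horizon)])), 0, horizon))
    idx = np.searchsorted(edges, np.arange(horizon, dtype=float), side="right") - 1
    sums = np.bincount(idx, weights=values, minlength=edges.size)
    counts = np.bincount(idx, minlength=edges.size)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return means[idx]


def detect_events(
    x: np.ndarray,
    threshold: np.ndarray,
    rescue_window: int = 365,
    confirm_factor: float = 10.0,
) -> list[tuple[str, int]]:
    """Classify threshold crossings on a recorded trajectory.

    An upward *crossing* is a day where x moves from <= A_bar (or 0) to
    > A_bar.  It becomes a *rescue* if x returns to <= A_bar within
    ``rescue_window`` days before reaching the confirmation size
    ``confirm_factor * max(A_bar at crossing, 1)``, and a *transition*
    otherwise (confirmation size reached, or no return within the window).
    Days where x hits 0 from above are *extinction* events.
    """
    events: list[tuple[str, int]] = []
    above = False
    cand = -1
    conf = math.inf
    n = len(x)
    for t in range(n):
        thr = threshold[t] if threshold is not None else math.inf
        is_above = (x[t] > thr) and (x[t] > 0)
        if not above and is_above:
            above = True
            cand = t
            conf = confirm_factor * max(thr, 1.0)
            events.append(("crossing", t))
        elif above:
            if is_above and (x[t] >= conf or t - cand > rescue_window):
                events.append(("transition", cand))
                return events
            if not is_above:
                events.append(("rescue", cand))
                above = False
        if t > 0 and x[t] == 0.0 and x[t - 1] > 0.0:
            events.append(("extinction", t))
    return events


def _resolve_a(growth: GrowthParams, s_typical: float, m_typical: float) -> float:
    """Self-consistent order-of-magnitude exponent a for the moving threshold."""
    a = 2.0
    for _ in range(50):
        A = moving_threshold(s_typical, m_typical, growth, a)
        if not np.isfinite(A) or A <= 0:
            return a
        a_new = math.log10(A)
        if abs(a_new - a) < 1e-3:
            return a_new
        a = a_new
    return a


def simulate_lifetime(
    growth: GrowthParams,
    mutation: MutationParams,
    life: LifeHistory,
    immune: ImmuneParams,
    horizon_years: float,
    rng: np.random.Generator,
    *,
    x0: float = 0.0,
    record: bool = True,
    stop_at_transition: bool = True,
    rescue_window: int = 365,
    confirm_factor: float = 10.0,
    a: float | None = None,
) -> Trajectory:
    """Simulate one lifetime of the complete model, day by day.

    Draws m(t) ~ Binomial(n, p(t)) per day, evaluates the immune schedule
    from the life history, iterates the clamped daily map and classifies
    threshold events.  The moving threshold uses the realized phase-average
    mutation count in each menstrual phase.  With ``stop_at_transition`` the
    run ends at the transition (the cohort pipeline only needs onset ages);
    progression to the carrying capacity is not simulated there.

    Reproducible: identical generator states and inputs give identical
    trajectories (integer binomial sampling, deterministic drift).
    """
    if horizon_years > 110:
        raise ValueError("horizon must be <= 110 years")
    horizon = int(round(horizon_years * DAYS_PER_YEAR))
    days = np.arange(horizon)
    s = daily_schedule(life, immune, horizon)
    p = mutation_probability(days.astype(float), mutation)
    m = rng.binomial(mutation.n, p).astype(np.int64)

    # averaging segments for m_bar: each menstrual phase while cycling; 28-day
    # blocks in the acyclic stretches (s_m constant there, any interval works)
    bounds = life.phase_boundaries_days()
    menarche_d = life.menarche_age * DAYS_PER_YEAR
    stop_d = life.effective_menopause * DAYS_PER_YEAR
    segs = [np.arange(0.0, min(menarche_d, horizon), 28.0)]
    segs.append(bounds[(bounds >= menarche_d) & (bounds <= min(stop_d, horizon))])
    if stop_d < horizon:
        segs.append(np.arange(stop_d, horizon, 28.0))
    m_bar = _phase_mean_by_day(m.astype(float), np.concatenate(segs), horizon)
    if a is None:
        a = _resolve_a(growth, float(np.max(s)), mutation.n * mutation.p0)
    A_bar = moving_threshold(s, m_bar, growth, a)
    if np.any(~np.isfinite(A_bar)):
        raise GrowthConfigError("moving threshold undefined: non-positive denominator")

    nu, r, mu = growth.nu, growth.r, growth.mu
    nur = nu * r
    numu = nu * mu
    expo = (nu + 1.0) / nu

    x_arr = np.zeros(horizon) if record else None
    events: list[tuple[str, int]] = []
    transition_day: int | None = None

    # days whose mutation burst can lift an extinct cluster off zero
    seeds = np.flatnonzero(m > s)
    n_seeds = seeds.size
    ptr = 0

    x = float(x0)
    if record:
        x_arr[0] = x
    above = False
    crossed_once = x > A_bar[0] and x > 0  # only excursions that crossed A_bar
    cand = -1
    conf = math.inf
    t = 0
    end = horizon - 1
    while t < end:
        if x == 0.0 and not above:
            while ptr < n_seeds and seeds[ptr] < t:
                ptr += 1
            if ptr >= n_seeds or seeds[ptr] >= end:
                t = end
                break
            t = int(seeds[ptr])  # x stays 0 on the skipped days (arrays already 0)
            ptr += 1
        x_new = x + (nur * x - numu * x**expo - s[t]) + m[t]
        if x_new < 0.0:
            x_new = 0.0
        if x_new > OVERFLOW_GUARD:
            raise IntegrationError(f"overflow guard: x exceeded {OVERFLOW_GUARD:g} cells")
        if record:
            x_arr[t + 1] = x_new
        is_above = (x_new > A_bar[t + 1]) and (x_new > 0)
        if not above and is_above:
            above = True
            crossed_once = True
            cand = t + 1
            conf = confirm_factor * max(A_bar[cand], 1.0)
            events.append(("crossing", cand))
        elif above:
            if is_above and (x_new >= conf or (t + 1) - cand > rescue_window):
                events.append(("transition", cand))
                transition_day = cand
                if stop_at_transition:
                    t += 1
                    break
                above = False  # keep simulating; only first transition recorded
            elif not is_above:
                events.append(("rescue", cand))
                above = False
        if x_new == 0.0 and x > 0.0 and crossed_once:
            # deaths of sub-threshold mutation flickers are not reported:
            # only excursions that crossed the moving threshold count
            events.append(("extinction", t + 1))
            crossed_once = False
        x = x_new
        t += 1

    last = t
    if record:
        days_out, x_out = days[: last + 1], x_arr[: last + 1]
        s_out, m_out, ab_out = s[: last + 1], m[: last + 1], A_bar[: last + 1]
    else:
        days_out = days[: last + 1]
        x_out = s_out = m_out = ab_out = None
    return Trajectory(
        days=days_out,
        x=x_out,
        s_m=s_out,
        m=m_out,
        A_bar=ab_out,
        events=events,
        transition_day=transition_day,
    )
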