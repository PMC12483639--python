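"""Monte-Carlo estimation of age-specific cumulative cancer risk.

The theoretical age-specific cumulative risk ``R_hat(t)`` is the percentage
of simulated women whose complete-model trajectory transitions to cancer by
age ``t``.  Each woman gets an independent random substream derived from
(master seed, woman index), so cohorts are reproducible regardless of
scheduling and pairwise coupled across immune cases when the master seed is
shared (common random numbers).

The actual risk ``R(t)`` is estimated from registry age-specific incidence
tables with the standard actuarial transform
``R(t) = 100 * (1 - exp(-sum_{bands <= t} rate * width))``.

All simulated women count in the denominator: the model describes onset only
(no competing mortality, no censoring).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .complete import simulate_lifetime
from .growth import GrowthParams
from .immune import (
    DAYS_PER_YEAR,
    ImmuneParams,
    LifeHistoryConfig,
    phase_label_at,
    sample_life_history,
)
from .mutation import MutationParams

__all__ = [
    "CohortRiskCurve",
    "IncidenceTable",
    "simulate_transitions",
    "simulate_cohort",
    "cumulative_risk_from_incidence",
    "cycle_length_sweep",
    "bucket_risk_ratio",
]

DEFAULT_BAND_EDGES = np.arange(5.0, 90.0, 5.0)  # ends at the 85+ band edge


@dataclass
class CohortRiskCurve:
    """Cumulative risk (%) at each age-band edge, with binomial uncertainty.

    ``risk[i]`` is the percentage of the cohort with a transition at age
    <= ``age_band_edges[i]``; ``ci_lo``/``ci_hi`` are 95% Clopper-Pearson
    bounds.  ``transition_ages`` (years; NaN = no transition) and
    ``transition_phases`` carry the per-woman outcomes for downstream
    analyses.
    """

    age_band_edges: np.ndarray
    risk: np.ndarray
    n_women: int
    n_transitions: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    transition_ages: np.ndarray | None = None
    transition_phases: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_band": self.age_band_edges,
                "n_at_risk": self.n_women,
                "n_transitions": self.n_transitions,
                "risk_pct": self.risk,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )

    def risk_at(self, age: float) -> float:
        """Cumulative risk (%) by ``age`` years, from the raw transition ages."""
        if self.transition_ages is None:
            raise ValueError("per-woman transition ages were not recorded")
        return 100.0 * float(np.mean(self.transition_ages <= age))


@dataclass(frozen=True)
class IncidenceTable:
    """Age-specific incidence rates per person-year on contiguous bands."""

    age_lo: np.ndarray
    age_hi: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rate) < 0):
            raise ValueError("incidence rates must be >= 0")
        if np.any(np.asarray(self.age_hi) <= np.asarray(self.age_lo)):
            raise ValueError("bands must have positive width")

    @classmethod
    def from_csv(cls, path) -> "IncidenceTable":
        """Read CSV columns age_lo, age_hi, rate_per_100k_person_years."""
        df = pd.read_csv(path, comment="#")
        return cls(
            age_lo=df["age_lo"].to_numpy(float),
            age_hi=df["age_hi"].to_numpy(float),
            rate=df["rate_per_100k_person_years"].to_numpy(float) / 1e5,
        )


def cumulative_risk_from_incidence(table: IncidenceTable) -> np.ndarray:
    """Actuarial cumulative risk (%) at each band's upper edge.

    ``R(t) = 100 * (1 - exp(-sum rate * width))`` over bands up to t: the
    standard transform of registry incidence rates into cumulative risk.
    Non-decreasing and bounded by 100 by construction.
    """
    widths = np.asarray(table.age_hi) - np.asarray(table.age_lo)
    cum_hazard = np.cumsum(np.asarray(table.rate) * widths)
    return 100.0 * (1.0 - np.exp(-cum_hazard))


def _clopper_pearson(k: np.ndarray, n: int, alpha: float = 0.05):
    lo = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    hi = np.where(k < n, stats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    return lo, hi


def simulate_transitions(
    growth: GrowthParams,
    mutation: MutationParams,
    immune: ImmuneParams,
    life_config: LifeHistoryConfig,
    n_women: int,
    seed: int,
    horizon_years: float = 85.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-woman transition ages (years; NaN = none) and phase labels.

    Phase labels refer to the menstrual phase containing the transition
    crossing day: 'luteal', 'follicular', 'post' (after effective menopause),
    'pre' (before menarche) or 'none'.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_women)
    ages = np.full(n_women, np.nan)
    phases = np.full(n_women, "none", dtype=object)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rng_life, rng_mut = rng.spawn(2)
        life = sample_life_history(rng_life, life_config)
        traj = simulate_lifetime(
            growth,
            mutation,
            life,
            immune,
            horizon_years,
            rng_mut,
            record=False,
            stop_at_transition=True,
        )
        if traj.transition_day is not None:
            ages[i] = traj.transition_day / DAYS_PER_YEAR
            phases[i] = phase_label_at(traj.transition_day, life)
    return ages, phases


def simulate_cohort(
    growth: GrowthParams,
    mutation: MutationParams,
    immune: ImmuneParams,
    life_config: LifeHistoryConfig,
    n_women: int,
    seed: int,
    horizon_years: float = 85.0,
    age_band_edges: np.ndarray | None = None,
) -> CohortRiskCurve:
    """Monte-Carlo cumulative-risk curve for one cohort configuration.

    Simulates ``n_women`` independent lifetimes and tabulates the percentage
    with a transition by each age-band edge (default: 5-year registry bands
    up to 85+), with 95% binomial confidence bands.
    """
    if n_women < 100:
        raise ValueError("n_women must be >= 100 for a meaningful risk curve")
    edges = DEFAULT_BAND_EDGES if age_band_edges is None else np.asarray(age_band_edges, float)
    ages, phases = simulate_transitions(
        growth, mutation, immune, life_config, n_women, seed, horizon_years
    )
    k = np.array([np.sum(ages <= e) for e in edges])
    lo, hi = _clopper_pearson(k, n_women)
    return CohortRiskCurve(
        age_band_edges=edges,
        risk=100.0 * k / n_women,
        n_women=n_women,
        n_transitions=k,
        ci_lo=100.0 * lo,
        ci_hi=100.0 * hi,
        transition_ages=ages,
        transition_phases=np.asarray(phases),
    )


def cycle_length_sweep(
    growth: GrowthParams,
    mutation: MutationParams,
    immune: ImmuneParams,
    life_config: LifeHistoryConfig,
    tf_grid,
    age_cut: float = 51.0,
    n_women: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Risk by ``age_cut`` versus (fixed) follicular phase length tf.

    For each tf the follicular length is pinned (luteal stays 14 days) and a
    fresh cohort is simulated to ``age_cut``.  Each transition is labelled by
    the phase containing its crossing day; luteal/follicular shares are
    percentages of the cycling-phase transitions (NaN when there are none).
    """
    rows = []
    for tf in tf_grid:
        cfg = replace(life_config, fixed_follicular_days=float(tf))
        ages, phases = simulate_transitions(
            growth, mutation, immune, cfg, n_women, seed, horizon_years=age_cut
        )
        hit = ages <= age_cut
        n_hit = int(np.sum(hit))
        lut = int(np.sum(hit & (phases == "luteal")))
        fol = int(np.sum(hit & (phases == "follicular")))
        n_cyc = lut + fol
        rows.append(
            {
                "tf_days": float(tf),
                "cycle_days": float(tf) + life_config.luteal_days,
                "risk_pct": 100.0 * n_hit / n_women,
                "n_transitions": n_hit,
                "luteal_share_pct": 100.0 * lut / n_cyc if n_cyc else np.nan,
                "follicular_share_pct": 100.0 * fol / n_cyc if n_cyc else np.nan,
            }
        )
    return pd.DataFrame(rows)


def bucket_risk_ratio(
    sweep: pd.DataFrame,
    short_cycle: tuple[float, float] = (22.0, 25.0),
    long_cycle: tuple[float, float] = (25.0, 31.0),
) -> float:
    """Mean risk over short cycle lengths divided by mean over long ones.

    Buckets are in total cycle days (luteal + follicular); grid points whose
    cycle length falls in [lo, hi] enter each bucket with equal weight.
    """
    c = sweep["cycle_days"].to_numpy()
    short = sweep.loc[(c >= short_cycle[0]) & (c <= short_cycle[1]), "risk_pct"]
    long_ = sweep.loc[(c > long_cycle[0]) & (c <= long_cycle[1]), "risk_pct"]
    if short.empty or long_.empty:
        raise ValueError("tf grid does not cover both cycle-length buckets")
    return float(short.mean() / long_.mean())
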