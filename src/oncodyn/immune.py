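"""Time-varying immune response over a simulated woman's lifetime.

The immune system clears a number of mutated cells per day, ``s_m(t)``.  The
menstrual cycle is simplified to two phases: a fixed 14-day luteal phase with
higher progesterone and a weaker response ``s_min``, and a variable
follicular phase (menstruation days included) with the stronger response
``s_max``.  Before menarche and after the effective menopause ``M`` the
response is constantly ``s_max``.  ``M`` combines natural menopause with an
optional hormone-replacement-therapy (HRT) extension during which cyclic
progesterone exposure, and hence the square-wave schedule, continues.

Three cohort cases are supported (plus an acyclic baseline):

* case 0 - constant ``s_max`` for the whole life (typical-cancer baseline),
* case 1 - fixed menopause at the mean age (51 y), no HRT,
* case 2 - normally distributed menopause age, no HRT,
* case 3 - distributed menopause, extended by a gamma-distributed HRT
  duration for a Bernoulli subset of women (default 26%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "ImmuneParams",
    "LifeHistoryConfig",
    "LifeHistory",
    "immune_response_at",
    "daily_schedule",
    "sample_life_history",
    "gamma_from_mode_sd",
    "phase_label_at",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ImmuneParams:
    """Immune clearance levels (cells/day) and HRT usage parameters."""

    s_min: float
    s_max: float
    hrt_fraction: float = 0.26
    hrt_mode: float = 6.0  # years
    hrt_sd: float = 4.8  # years

    def __post_init__(self) -> None:
        if not 0 <= self.s_min <= self.s_max:
            raise ValueError("need 0 <= s_min <= s_max")
        if not 0 <= self.hrt_fraction <= 1:
            raise ValueError("hrt_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LifeHistoryConfig:
    """Sampling configuration for one cohort's life histories."""

    case: int = 3
    menarche_age: float = 12.0  # years
    luteal_days: float = 14.0
    follicular_mean: float = 14.0  # days
    follicular_sd: float = 2.4  # days
    fixed_follicular_days: float | None = None
    menopause_mean: float = 51.0  # years
    menopause_sd: float = 4.86  # years
    hrt_fraction: float = 0.26
    hrt_mode: float = 6.0  # years
    hrt_sd: float = 4.8  # years

    def __post_init__(self) -> None:
        if self.case not in (0, 1, 2, 3):
            raise ValueError(f"unknown case {self.case}; use 0, 1, 2 or 3")


@dataclass
class LifeHistory:
    """One simulated woman's reproductive timeline.

    Cycle phases run follicular-first from menarche; the last (possibly
    partial) cycle is cut off at the effective menopause.  Phase lengths are
    kept in (float) days; the luteal length is exactly 14 days by default.
    """

    menarche_age: float  # years
    phase_lengths: np.ndarray  # days, ordered from menarche
    phase_is_luteal: np.ndarray  # bool, same length
    menopause_age: float  # years (natural)
    hrt_years: float = 0.0

    _boundaries: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def effective_menopause(self) -> float:
        """Menopause age extended by HRT duration (years)."""
        return self.menopause_age + self.hrt_years

    @property
    def cycle_phases(self) -> list[tuple[str, float]]:
        return [
            ("luteal" if lut else "follicular", float(length))
            for length, lut in zip(self.phase_lengths, self.phase_is_luteal)
        ]

    def phase_boundaries_days(self) -> np.ndarray:
        """Phase start times in days since birth (monotone, from menarche)."""
        if self._boundaries is None:
            starts = self.menarche_age * DAYS_PER_YEAR + np.concatenate(
                ([0.0], np.cumsum(self.phase_lengths))
            )
            self._boundaries = starts
        return self._boundaries


def immune_response_at(t, life: LifeHistory, params: ImmuneParams):
    """Immune response s_m(t) (cells/day) at age ``t`` in days since birth.

    Piecewise constant and right-continuous: s_max before menarche, s_min in
    luteal / s_max in follicular phases while cycling, s_max after the
    effective menopause.  Vectorized over ``t``.
    """
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    menarche_d = life.menarche_age * DAYS_PER_YEAR
    stop_d = life.effective_menopause * DAYS_PER_YEAR
    bounds = life.phase_boundaries_days()
    out = np.full(t.shape, params.s_max, dtype=float)
    cycling = (t >= menarche_d) & (t < stop_d)
    if life.phase_lengths.size and np.any(cycling):
        idx = np.searchsorted(bounds, t[cycling], side="right") - 1
        idx = np.clip(idx, 0, life.phase_is_luteal.size - 1)
        lut = life.phase_is_luteal[idx]
        vals = np.where(lut, params.s_min, params.s_max)
        out[cycling] = vals
    if scalar:
        return float(out[0])
    return out


def daily_schedule(life: LifeHistory, params: ImmuneParams, horizon_days: int) -> np.ndarray:
    """s_m for integer days 0..horizon_days-1 (value at each day's start)."""
    return immune_response_at(np.arange(horizon_days, dtype=float), life, params)


def phase_label_at(t_days: float, life: LifeHistory) -> str:
    """Label a day as 'pre', 'luteal', 'follicular' or 'post' (menopause)."""
    menarche_d = life.menarche_age * DAYS_PER_YEAR
    stop_d = life.effective_menopause * DAYS_PER_YEAR
    if t_days < menarche_d:
        return "pre"
    if t_days >= stop_d or not life.phase_lengths.size:
        return "post"
    bounds = life.phase_boundaries_days()
    idx = int(np.searchsorted(bounds, t_days, side="right")) - 1
    idx = min(max(idx, 0), life.phase_is_luteal.size - 1)
    return "luteal" if life.phase_is_luteal[idx] else "follicular"


def gamma_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """Gamma (shape k, scale theta) with the given mode and standard deviation.

    Solves ``(k - 1) * theta = mode`` and ``k * theta**2 = sd**2`` exactly:
    theta is the positive root of ``theta**2 + mode*theta - sd**2 = 0`` and
    ``k = mode/theta + 1 > 1`` whenever mode > 0.
    """
    if mode <= 0 or sd <= 0:
        raise ValueError("mode and sd must be > 0 (mode -> 0 hits the k -> 1 boundary)")
    theta = (-mode + math.sqrt(mode * mode + 4.0 * sd * sd)) / 2.0
    k = mode / theta + 1.0
    return k, theta


def _sample_menopause(rng: np.random.Generator, cfg: LifeHistoryConfig) -> tuple[float, float]:
    """(natural menopause age, hrt years) for one woman under the case rules."""
    if cfg.case == 0:
        return cfg.menarche_age, 0.0  # no cycling at all
    if cfg.case == 1:
        return cfg.menopause_mean, 0.0
    lo = cfg.menarche_age + 1.0  # normal tail must not put menopause before menarche
    M = rng.normal(cfg.menopause_mean, cfg.menopause_sd)
    while M < lo:
        M = rng.normal(cfg.menopause_mean, cfg.menopause_sd)
    if cfg.case == 2:
        return M, 0.0
    hrt = 0.0
    if rng.random() < cfg.hrt_fraction:
        k, theta = gamma_from_mode_sd(cfg.hrt_mode, cfg.hrt_sd)
        hrt = rng.gamma(k, theta)
    return M, hrt


def _sample_cycles(
    rng: np.random.Generator, cfg: LifeHistoryConfig, span_days: float
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating follicular/luteal phase lengths covering ``span_days``.

    The follicular length is resampled independently for every cycle from
    N(mean, sd**2) truncated at 1 day (the truncation shifts the mean by
    far less than 0.01 day at the default 14 +- 2.4), unless a fixed length
    is configured for cycle-length sweeps.
    """
    if span_days <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    mean_cycle = cfg.luteal_days + (
        cfg.fixed_follicular_days
        if cfg.fixed_follicular_days is not None
        else cfg.follicular_mean
    )
    n_cycles = int(span_days / mean_cycle * 1.2) + 8
    lengths: list[np.ndarray] = []
    total = 0.0
    while total < span_days:
        if cfg.fixed_follicular_days is not None:
            tf = np.full(n_cycles, float(cfg.fixed_follicular_days))
        else:
            tf = rng.normal(cfg.follicular_mean, cfg.follicular_sd, size=n_cycles)
            tf = np.maximum(tf, 1.0)
        block = np.empty(2 * n_cycles)
        block[0::2] = tf
        block[1::2] = cfg.luteal_days
        lengths.append(block)
        total += float(block.sum())
    phases = np.concatenate(lengths)
    # trim to the first phase reaching the span; the schedule cuts at M anyway
    keep = np.searchsorted(np.cumsum(phases), span_days, side="left") + 1
    phases = phases[:keep]
    is_luteal = np.zeros(phases.size, dtype=bool)
    is_luteal[1::2] = True
    return phases, is_luteal


def sample_life_history(rng: np.random.Generator, cfg: LifeHistoryConfig) -> LifeHistory:
    """Draw one LifeHistory under the configured cohort case.

    The generator is split into independent child streams for (menopause,
    HRT) and cycle lengths, so cohorts simulated under different cases with a
    shared master seed stay pairwise coupled (common random numbers).
    """
    rng_meno, rng_cycles = rng.spawn(2)
    M, hrt = _sample_menopause(rng_meno, cfg)
    span_days = max((M + hrt) - cfg.menarche_age, 0.0) * DAYS_PER_YEAR
    phases, is_luteal = _sample_cycles(rng_cycles, cfg, span_days)
    return LifeHistory(
        menarche_age=cfg.menarche_age,
        phase_lengths=phases,
        phase_is_luteal=is_luteal,
        menopause_age=M,
        hrt_years=hrt,
    )
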