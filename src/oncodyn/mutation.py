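"""Binomial model of daily stem-cell mutations.

A fixed pool of ``n`` healthy stem cells is considered; each cell mutates
within one day independently with probability ``p(t)``, so the number of new
mutated cells per day is Binomial(n, p(t)) with mean ``n*p(t)`` and variance
``n*p(t)*(1 - p(t))``.  The per-cell probability drifts linearly with age,
``p(t) = p0 * (1 + delta * t / (100 * T))``, reaching a ``delta`` percent
increase at the life expectancy ``T``.

Sampling is exact binomial (no normal or Poisson shortcut): threshold
crossings in the complete model are driven by the tail of the daily mutation
count, which approximations distort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MutationParams",
    "mutation_probability",
    "binomial_pmf",
    "sample_daily_mutations",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class MutationParams:
    """Daily mutation-process parameters.

    n: healthy stem cells exposed (count); p0: per-cell daily mutation
    probability at birth; delta: percent increase of p over a lifetime;
    T: life expectancy in days (use ``from_years`` to pass years).
    """

    n: int
    p0: float
    delta: float = 0.0
    T: float = 84.0 * DAYS_PER_YEAR

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.p0 < 1.0:
            raise ValueError("p0 must satisfy 0 <= p0 < 1")
        if self.T <= 0:
            raise ValueError("T must be > 0")

    @classmethod
    def from_years(
        cls, n: int, p0: float, delta: float = 0.0, life_expectancy_years: float = 84.0
    ) -> "MutationParams":
        return cls(n=n, p0=p0, delta=delta, T=life_expectancy_years * DAYS_PER_YEAR)


def mutation_probability(t, params: MutationParams):
    """Per-cell daily mutation probability p(t) at age ``t`` (days).

    Linear drift from p0 at birth to p0*(1 + delta/100) at T; values are
    clipped at 1 with a warning (unattainable in sensible configurations but
    must not crash parameter sweeps).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    p = params.p0 * (1.0 + params.delta * t / (100.0 * params.T))
    if np.any(p > 1.0):
        warnings.warn("mutation probability clipped at 1", RuntimeWarning, stacklevel=2)
        p = np.minimum(p, 1.0)
    if p.ndim == 0:
        return float(p)
    return p


def binomial_pmf(m, n: int, p: float):
    """P(m mutations among n cells), exact binomial mass.

    Thin wrapper over the log-space implementation in scipy.stats so the mass
    stays numerically stable for n up to 1e9.
    """
    m_arr = np.asarray(m)
    if np.any(m_arr < 0) or np.any(m_arr > n):
        raise ValueError("need 0 <= m <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("need 0 <= p <= 1")
    out = stats.binom.pmf(m_arr, n, p)
    if out.ndim == 0:
        return float(out)
    return out


def sample_daily_mutations(t, params: MutationParams, rng: np.random.Generator):
    """Draw the mutation count m(t) ~ Binomial(n, p(t)) for day(s) ``t``.

    ``t`` may be a scalar or an array of days; one exact draw per entry,
    reproducible under a fixed generator state.
    """
    p = mutation_probability(t, params)
    out = rng.binomial(params.n, p)
    if np.ndim(out) == 0:
        return int(out)
    return out
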