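"""Canned parameter sets for the human risk case studies.

The published figures rely on supplementary parameter tables that print only
two anchors in the main text: the immune-response offsets over the mean daily
mutation influx, ``s_min = n*p0 + 262`` and ``s_max = n*p0 + 354`` cells/day.
The remaining values (n, p0, delta, nu, r, mu, life expectancy T) are
placeholders chosen once so that those offsets make sense dynamically — see
docs/methods.md for the calibration reasoning.  They are NOT the published
table values and carry no claim of matching them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .growth import GrowthParams
from .immune import ImmuneParams, LifeHistoryConfig
from .mutation import MutationParams

__all__ = ["RiskPreset", "breast_preset", "typical_preset", "S_MIN_OFFSET", "S_MAX_OFFSET"]

# printed in the complete-model example: cells/day over the mean influx n*p0
S_MIN_OFFSET = 262.0
S_MAX_OFFSET = 354.0


@dataclass(frozen=True)
class RiskPreset:
    """Bundle of everything a cohort simulation needs."""

    growth: GrowthParams
    mutation: MutationParams
    immune: ImmuneParams
    life: LifeHistoryConfig

    def with_case(self, case: int) -> "RiskPreset":
        from dataclasses import replace

        return RiskPreset(self.growth, self.mutation, self.immune, replace(self.life, case=case))


def _build(case: int, n: int, p0: float, delta: float, nu: float, r: float, K: float) -> RiskPreset:
    np0 = n * p0
    growth = GrowthParams.richards_from_capacity(nu, r, K)
    growth = GrowthParams("erm2", nu=nu, r=r, mu=growth.mu, s=np0 + S_MAX_OFFSET)
    mutation = MutationParams.from_years(n=n, p0=p0, delta=delta, life_expectancy_years=84.0)
    immune = ImmuneParams(s_min=np0 + S_MIN_OFFSET, s_max=np0 + S_MAX_OFFSET)
    life = LifeHistoryConfig(case=case)
    return RiskPreset(growth=growth, mutation=mutation, immune=immune, life=life)


def breast_preset(case: int = 3) -> RiskPreset:
    """Breast-cancer-like configuration with the cycling immune schedule.

    The luteal immune deficit (s_min) activates the transition channel around
    the menopausal ages while the follicular/postmenopausal channel (s_max)
    only activates in old age, reproducing the polynomial-then-linear shape of
    the cumulative risk.
    """
    return _build(case=case, n=32_500_000, p0=4e-4, delta=1.7, nu=1.0, r=0.2, K=2e12)


def typical_preset() -> RiskPreset:
    """Typical-cancer (e.g. colorectal) configuration: constant s_max for life.

    A larger stem-cell pool and a gentler mutation drift spread the constant-
    immune-response transition channel over the mid and late ages, giving the
    exponential-like cumulative risk of most cancers.
    """
    return _build(case=0, n=105_000_000, p0=4e-4, delta=0.26, nu=1.0, r=0.2, K=2e12)
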