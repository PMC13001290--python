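"""Moments of healthy years lived after 60 via a Markov chain with rewards.

The number of healthy years ``HY`` accumulated between age 60 and the cap
at age 90 is generated by two independent stochastic processes: annual
survival (probability ``s_x = 1 - q_x``) and an annual Bernoulli healthy
"reward" with success probability ``h_x``, the cross-sectional prevalence
of health at age ``x``.  Because the chain is a pure age ladder with a
single absorbing state, the first three raw moments of ``HY`` satisfy a
scalar backward recursion, equivalent to the matrix
``(I - U')^{-1}``-style formulation for this structure but simpler to
verify.

Two reward-timing conventions are supported:

* ``occupancy`` — anyone alive at exact age ``x`` earns the Bernoulli
  reward for the year ``[x, x+1)``, whether or not they survive it;
* ``survived-year`` — the reward is earned only if the year is survived.

The default conditions on being healthy at 60 (``h_60`` replaced by 1 in
the first step), so the distribution applies to people who reach age 60
in a healthy state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schedules import AGE_CAP, AGE_START, MortalitySchedule, PrevalenceSchedule

#: Variance below this is treated as a degenerate (point-mass) distribution.
DEGENERATE_VAR_TOL = 1e-12

_TIMINGS = ("occupancy", "survived-year")


def check_shared_grid(mortality: MortalitySchedule, prevalence: PrevalenceSchedule) -> None:
    """Require aligned contiguous grids starting at the age origin."""
    if not np.array_equal(mortality.ages, prevalence.ages):
        raise ValueError("mortality and prevalence must share an age grid")
    if mortality.ages[0] != AGE_START:
        raise ValueError(f"the age grid must start at {AGE_START}")


@dataclass(frozen=True)
class RewardConvention:
    """Reward timing and conditioning for the rewards recursion."""

    timing: str = "occupancy"
    condition_on_healthy_at_60: bool = True

    def __post_init__(self) -> None:
        if self.timing not in _TIMINGS:
            raise ValueError(f"unknown reward timing {self.timing!r}; expected one of {_TIMINGS}")


@dataclass(frozen=True)
class MomentSet:
    """First three raw and central moments of healthy years after 60.

    ``m1`` is healthy life expectancy (HLE) in years after 60; the "HLE
    age" adds the age origin.  ``sdhl`` is the standard deviation of
    healthy longevity.  ``skewness`` is ``None`` when the distribution is
    degenerate (variance below tolerance).
    """

    m1: float
    m2: float
    m3: float

    @property
    def mean(self) -> float:
        return self.m1

    @property
    def variance(self) -> float:
        return self.m2 - self.m1**2

    @property
    def third_central(self) -> float:
        return self.m3 - 3.0 * self.m1 * self.m2 + 2.0 * self.m1**3

    @property
    def degenerate(self) -> bool:
        return self.variance < DEGENERATE_VAR_TOL

    @property
    def skewness(self) -> float | None:
        if self.degenerate:
            return None
        return self.third_central / self.variance**1.5

    @property
    def hle_age(self) -> float:
        return AGE_START + self.m1

    @property
    def sdhl(self) -> float:
        return math.sqrt(max(self.variance, 0.0))

    def validate(self) -> "MomentSet":
        span = float(AGE_CAP - AGE_START)
        if not 0.0 <= self.m1 <= span:
            raise ValueError(f"m1={self.m1} outside [0, {span}]")
        if self.m2 < self.m1**2 - 1e-9:
            raise ValueError(f"infeasible moments: m2={self.m2} < m1^2={self.m1 ** 2}")
        return self


def compute_raw_moments(
    mortality: MortalitySchedule,
    prevalence: PrevalenceSchedule,
    convention: RewardConvention = RewardConvention(),
) -> MomentSet:
    """Backward recursion for the first three raw moments of healthy years.

    With ``s_x = 1 - q_x`` and the boundary ``m_k(90) = 0`` (the cap at
    age 90), the occupancy-timing recursion for ``x = 89 .. 60`` is::

        m1(x) = h_x + s_x m1(x+1)
        m2(x) = h_x + 2 h_x s_x m1(x+1) + s_x m2(x+1)
        m3(x) = h_x + 3 h_x s_x m1(x+1) + 3 h_x s_x m2(x+1) + s_x m3(x+1)

    and under survived-year timing every right-hand side is multiplied by
    ``s_x`` with the lone ``h_x`` moved inside.  Returns the moments at
    age 60.

    The grid may be any contiguous run of ages starting at 60 (the full
    analysis uses 60-89 with the cap at 90; shorter grids cap at the last
    age plus one, which is convenient for hand-checkable toys).
    """
    check_shared_grid(mortality, prevalence)
    s = mortality.sx
    h = prevalence.hx.copy()
    if convention.condition_on_healthy_at_60:
        h[0] = 1.0
    m1 = m2 = m3 = 0.0
    if convention.timing == "occupancy":
        for i in range(len(s) - 1, -1, -1):
            m3 = h[i] + 3.0 * h[i] * s[i] * m1 + 3.0 * h[i] * s[i] * m2 + s[i] * m3
            m2 = h[i] + 2.0 * h[i] * s[i] * m1 + s[i] * m2
            m1 = h[i] + s[i] * m1
    else:
        for i in range(len(s) - 1, -1, -1):
            m3 = s[i] * (h[i] + 3.0 * h[i] * m1 + 3.0 * h[i] * m2 + m3)
            m2 = s[i] * (h[i] + 2.0 * h[i] * m1 + m2)
            m1 = s[i] * (h[i] + m1)
    return MomentSet(m1, m2, m3).validate()


def sullivan_m1(
    mortality: MortalitySchedule,
    prevalence: PrevalenceSchedule,
    condition_on_healthy_at_60: bool = True,
) -> float:
    """Direct Sullivan-type sum ``sum_x l_x h_x`` with ``l_60 = 1``.

    Independent closed form for the occupancy-timing mean; used as a
    cross-check of the recursion, not by the pipeline itself.
    """
    check_shared_grid(mortality, prevalence)
    h = prevalence.hx.copy()
    if condition_on_healthy_at_60:
        h[0] = 1.0
    lx = np.concatenate([[1.0], np.cumprod(mortality.sx)[:-1]])
    return float(np.sum(lx * h))


def to_central(raw: MomentSet) -> dict[str, float | None]:
    """Expand a raw ``MomentSet`` into the reported central quantities.

    Returns mean, variance, third central moment, skewness (``None`` when
    degenerate), the HLE age and SDHL.  Raises if ``m2 < m1^2`` beyond
    tolerance, which no distribution can produce.
    """
    raw.validate()
    return {
        "mean": raw.mean,
        "variance": max(raw.variance, 0.0),
        "third_central": raw.third_central,
        "skewness": raw.skewness,
        "hle_age": raw.hle_age,
        "sdhl": raw.sdhl,
    }
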