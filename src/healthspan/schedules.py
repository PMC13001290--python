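"""Age-indexed schedules shared across the pipeline.

The analysis runs on a fixed single-year age grid from 60 to 89 (the last
age at which a transition can occur before the artificial cap at age 90).
Two schedules drive the model:

* a mortality schedule ``q_x`` — the annual probability of dying during
  the year of age ``[x, x+1)``;
* a healthy-prevalence schedule ``h_x`` — the probability of being in the
  healthy state at age ``x``, estimated from cross-sectional survey
  proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: First age of the analysis window.
AGE_START = 60
#: Cap: anyone still healthy at this age is treated as losing health here.
AGE_CAP = 90

#: Default transition-age grid 60..89 inclusive.
DEFAULT_AGES = np.arange(AGE_START, AGE_CAP)


def _validate_ages(ages: np.ndarray) -> np.ndarray:
    ages = np.asarray(ages, dtype=int)
    if ages.ndim != 1 or ages.size == 0:
        raise ValueError("ages must be a non-empty 1-D integer grid")
    if np.any(np.diff(ages) != 1):
        raise ValueError("ages must be contiguous single-year integers")
    if ages[0] < AGE_START or ages[-1] >= AGE_CAP:
        raise ValueError(
            f"ages must lie within [{AGE_START}, {AGE_CAP - 1}], got "
            f"[{ages[0]}, {ages[-1]}]"
        )
    return ages


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual death probabilities ``q_x`` on a contiguous age grid.

    Parameters
    ----------
    ages : array of int
        Contiguous single-year ages within [60, 89].
    qx : array of float
        Annual probability of death at each age; each entry in [0, 1).
    source : str
        Provenance tag (e.g. a life-table key or ``"pooled"``).
    """

    ages: np.ndarray
    qx: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", _validate_ages(self.ages))
        qx = np.asarray(self.qx, dtype=float)
        if qx.shape != self.ages.shape:
            raise ValueError("qx must align with ages")
        if np.any(~np.isfinite(qx)) or np.any(qx < 0) or np.any(qx >= 1):
            raise ValueError("q_x must lie in [0, 1)")
        object.__setattr__(self, "qx", qx)

    @property
    def sx(self) -> np.ndarray:
        """Annual survival probabilities ``1 - q_x``."""
        return 1.0 - self.qx


@dataclass(frozen=True)
class PrevalenceSchedule:
    """Probability of being healthy ``h_x`` on a contiguous age grid.

    ``n_weighted`` and ``n_unweighted`` carry the stratum sizes behind each
    estimate when the schedule comes from survey data; synthetic schedules
    leave them empty.
    """

    ages: np.ndarray
    hx: np.ndarray
    n_weighted: np.ndarray = field(default_factory=lambda: np.array([]))
    n_unweighted: np.ndarray = field(default_factory=lambda: np.array([]))
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", _validate_ages(self.ages))
        hx = np.asarray(self.hx, dtype=float)
        if hx.shape != self.ages.shape:
            raise ValueError("hx must align with ages")
        if np.any(~np.isfinite(hx)) or np.any(hx <= 0) or np.any(hx > 1):
            raise ValueError("h_x must lie in (0, 1]")
        object.__setattr__(self, "hx", hx)


def require_full_grid(schedule: MortalitySchedule | PrevalenceSchedule) -> None:
    """Raise if a schedule does not cover the full 60..89 grid."""
    if schedule.ages[0] != AGE_START or schedule.ages[-1] != AGE_CAP - 1:
        missing = sorted(set(range(AGE_START, AGE_CAP)) - set(schedule.ages.tolist()))
        raise ValueError(f"schedule must cover ages 60-89; missing ages {missing}")
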