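"""Synthetic mortality, prevalence and survey microdata generators.

Real inputs to the pipeline are access-restricted survey microdata and
national life tables, so this module fabricates inputs with the same
statistical structure: Gompertz mortality (hazard rising exponentially
with age), logistic age-declining healthy prevalence, and person-wave
microdata with calibrated-style positive heterogeneous weights, chronic
condition indicators, cognitive scores and a dementia flag.

It also provides :func:`simulate_healthy_years`, a Monte-Carlo oracle
that simulates the exact stochastic model whose moments the rewards
recursion computes — the arbiter of internal consistency between the
analytic and simulated routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .moments import RewardConvention, check_shared_grid
from .schedules import (
    AGE_CAP,
    AGE_START,
    DEFAULT_AGES,
    MortalitySchedule,
    PrevalenceSchedule,
)

#: Cognitive tests recorded in the microdata.
COGNITIVE_TESTS = ("time_orientation", "verbal_fluency", "memory")
EDUCATION_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard ``a * exp(b * (x - 60))`` at age ``x``.

    ``a`` is the baseline hazard at age 60 (per year, > 0); ``b`` the
    log-hazard slope (per year, >= 0).  Converted to an annual death
    probability via ``q = 1 - exp(-hazard)``, which keeps ``q < 1`` for
    every parameter choice.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("baseline hazard a must be >= 0")
        if self.b < 0:
            raise ValueError("slope b must be >= 0")


@dataclass(frozen=True)
class PrevalenceCurveParams:
    """Logistic healthy-prevalence curve.

    ``h_x = floor + (1 - floor) / (1 + exp(k * (x - x0)))`` — a curve
    that starts near 1, declines with age at steepness ``k`` around the
    midpoint ``x0``, and levels off at ``floor``.
    """

    x0: float
    k: float
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < 1.0:
            raise ValueError("floor must lie in [0, 1)")
        if self.k < 0:
            raise ValueError("steepness k must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Stratified design of a synthetic survey: records per (wave, sex, age)."""

    ages: np.ndarray = field(default_factory=lambda: DEFAULT_AGES.copy())
    n_per_stratum: int = 50
    waves: tuple[str, ...] = ("w1",)
    sexes: tuple[str, ...] = ("male", "female")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum must be >= 1")
        if not self.waves or not self.sexes:
            raise ValueError("waves and sexes must be non-empty")


@dataclass(frozen=True)
class WeightSpec:
    """Lognormal calibrated-style weights: ``exp(Normal(mu, sigma))``.

    Calibrated survey weights need not sum to the stratum size, so no
    per-stratum normalisation is applied.
    """

    mu: float = 0.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class CognitionSpec:
    """Cognitive-score and dementia generators.

    Scores are Normal with an education-specific mean that declines
    linearly with age, and share a latent cognitive-ability factor across
    the three tests (``test_correlation``), since the tests probe the
    same construct; dementia is Bernoulli with a logistic age-increasing
    probability.  Defaults put roughly 5-15% of old-age records below a
    mean − 1.5 SD threshold.
    """

    education_means: dict[str, float] = field(
        default_factory=lambda: {"low": -0.3, "medium": 0.0, "high": 0.3}
    )
    education_probs: tuple[float, ...] = (0.3, 0.45, 0.25)
    age_slope: float = -0.012
    score_sd: float = 1.0
    test_correlation: float = 0.6
    dementia_x0: float = 100.0
    dementia_k: float = 0.18

    def dementia_prob(self, ages: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.dementia_k * (np.asarray(ages, float) - self.dementia_x0)))


@dataclass(frozen=True)
class OracleResult:
    """Monte-Carlo estimates of the healthy-years distribution.

    ``m1..m3`` are empirical raw moments of healthy years with standard
    errors ``se1..se3``; ``pmf`` is the empirical exit-age distribution
    on {60, ..., 90} (exit age = 60 + accumulated healthy years).
    """

    m1: float
    m2: float
    m3: float
    se1: float
    se2: float
    se3: float
    ages: np.ndarray
    pmf: np.ndarray
    n_sim: int
    seed: int


def gen_mortality_schedule(params: GompertzParams, ages: np.ndarray = DEFAULT_AGES) -> MortalitySchedule:
    """Annual death probabilities from a Gompertz hazard.

    ``q_x = 1 - exp(-a * exp(b * (x - 60)))``, guaranteed in [0, 1).
    """
    if params.a <= 0:
        raise ValueError("baseline hazard a must be > 0 for a mortality schedule")
    ages = np.asarray(ages, dtype=int)
    hazard = params.a * np.exp(params.b * (ages - AGE_START))
    qx = 1.0 - np.exp(-hazard)
    return MortalitySchedule(ages=ages, qx=qx, source=f"gompertz(a={params.a},b={params.b})")


def gen_health_prevalence(
    params: PrevalenceCurveParams, ages: np.ndarray = DEFAULT_AGES
) -> PrevalenceSchedule:
    """Logistic healthy-prevalence curve on the age grid (nonincreasing)."""
    ages = np.asarray(ages, dtype=int)
    hx = params.floor + (1.0 - params.floor) / (1.0 + np.exp(params.k * (ages - params.x0)))
    return PrevalenceSchedule(ages=ages, hx=hx, label=f"logistic(x0={params.x0},k={params.k})")


def _curve_values(curve: PrevalenceCurveParams, ages: np.ndarray) -> np.ndarray:
    return curve.floor + (1.0 - curve.floor) / (1.0 + np.exp(curve.k * (ages - curve.x0)))


def gen_microdata(
    spec: CohortSpec,
    condition_curves: dict[str, dict[str, PrevalenceCurveParams]],
    weights: WeightSpec = WeightSpec(),
    cognition: CognitionSpec = CognitionSpec(),
    frailty: float = 0.0,
) -> pd.DataFrame:
    """Generate person-wave survey-like microdata.

    Parameters
    ----------
    spec : CohortSpec
        Stratified design; every (wave, sex, age) stratum gets exactly
        ``n_per_stratum`` records.
    condition_curves : dict
        Per sex, a mapping from condition name to the healthy-prevalence
        curve for that condition: a record at age ``x`` carries the
        condition with probability ``1 - h_x``.  Conditions are drawn
        independently unless ``frailty > 0``, in which case a shared
        per-person latent Normal shifts every condition's log-odds.
    weights : WeightSpec
        Distribution of the positive calibrated-style weight.
    cognition : CognitionSpec
        Cognitive score and dementia generators.
    frailty : float
        Scale of the shared latent frailty (0 disables it; the default,
        since no dependence structure between conditions is asserted).

    Returns
    -------
    pandas.DataFrame
        One row per person-wave with columns ``id, wave, country, sex,
        age, weight, cond_<name>..., score_<test>..., education,
        dementia``.  Reproducible given ``spec.seed``.
    """
    for sex in spec.sexes:
        if sex not in condition_curves or not condition_curves[sex]:
            raise ValueError(f"no condition curves supplied for sex {sex!r}")
    rng = np.random.default_rng(spec.seed)
    condition_names = sorted({c for curves in condition_curves.values() for c in curves})

    frames = []
    next_id = 0
    for wave in spec.waves:
        for sex in spec.sexes:
            n = spec.n_per_stratum * len(spec.ages)
            ages = np.repeat(spec.ages, spec.n_per_stratum)
            w = np.exp(rng.normal(weights.mu, weights.sigma, size=n))
            latent = rng.normal(size=n) if frailty > 0 else np.zeros(n)
            cols: dict[str, np.ndarray] = {
                "id": np.arange(next_id, next_id + n),
                "wave": np.repeat(wave, n),
                "country": np.repeat("SYN", n),
                "sex": np.repeat(sex, n),
                "age": ages,
                "weight": w,
            }
            next_id += n
            for cond in condition_names:
                curve = condition_curves[sex][cond]
                p_cond = 1.0 - _curve_values(curve, ages)
                if frailty > 0:
                    with np.errstate(divide="ignore"):
                        logit = np.log(p_cond / (1.0 - p_cond))
                    p_cond = 1.0 / (1.0 + np.exp(-(logit + frailty * latent)))
                cols[f"cond_{cond}"] = rng.random(n) < p_cond
            edu = rng.choice(EDUCATION_LEVELS, size=n, p=cognition.education_probs)
            edu_mean = np.vectorize(cognition.education_means.__getitem__)(edu).astype(float)
            score_mean = edu_mean + cognition.age_slope * (ages - AGE_START)
            rho = cognition.test_correlation
            ability = rng.normal(size=n)  # shared factor; marginal SD preserved
            for test in COGNITIVE_TESTS:
                noise = rng.normal(size=n)
                z = np.sqrt(rho) * ability + np.sqrt(1.0 - rho) * noise
                cols[f"score_{test}"] = score_mean + cognition.score_sd * z
            cols["education"] = edu
            cols["dementia"] = rng.random(n) < cognition.dementia_prob(ages)
            frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def simulate_healthy_years(
    mortality: MortalitySchedule,
    prevalence: PrevalenceSchedule,
    convention: RewardConvention = RewardConvention(),
    n_sim: int = 100_000,
    seed: int = 0,
) -> OracleResult:
    """Monte-Carlo oracle for the healthy-years model.

    Simulates ``n_sim`` individuals alive at 60.  Each year of age ``x``
    is survived with probability ``1 - q_x``; a Bernoulli(``h_x``)
    healthy reward accrues under the stated convention (occupancy: earned
    by anyone alive at exact age ``x``; survived-year: earned only if the
    year is survived).  Healthy years are capped by the age limit of the
    grid (30 on the full 60-89 grid).  Exit age is 60 + accumulated
    healthy years.
    """
    check_shared_grid(mortality, prevalence)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    s = mortality.sx
    h = prevalence.hx.copy()
    if convention.condition_on_healthy_at_60:
        h[0] = 1.0

    alive = np.ones(n_sim, dtype=bool)
    hy = np.zeros(n_sim, dtype=np.int64)
    for i in range(len(s)):
        healthy = rng.random(n_sim) < h[i]
        survive = rng.random(n_sim) < s[i]
        if convention.timing == "occupancy":
            hy += alive & healthy
        else:
            hy += alive & survive & healthy
        alive &= survive

    span = len(s)  # cap age = last grid age + 1
    pmf = np.bincount(hy, minlength=span + 1).astype(float) / n_sim
    hyf = hy.astype(float)
    powers = [hyf, hyf**2, hyf**3]
    means = [float(p.mean()) for p in powers]
    if n_sim > 1:
        ses = [float(p.std(ddof=1) / np.sqrt(n_sim)) for p in powers]
    else:
        ses = [float("nan")] * 3
    return OracleResult(
        m1=means[0],
        m2=means[1],
        m3=means[2],
        se1=ses[0],
        se2=ses[1],
        se3=ses[2],
        ages=np.arange(AGE_START, AGE_START + span + 1),
        pmf=pmf,
        n_sim=n_sim,
        seed=seed,
    )
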