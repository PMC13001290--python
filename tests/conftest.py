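import numpy as np
import pytest

import healthspan as hs


@pytest.fixture(scope="session")
def gompertz_schedule() -> hs.MortalitySchedule:
    return hs.gen_mortality_schedule(hs.GompertzParams(a=0.01, b=0.1))


@pytest.fixture(scope="session")
def logistic_prevalence() -> hs.PrevalenceSchedule:
    return hs.gen_health_prevalence(hs.PrevalenceCurveParams(x0=75.0, k=0.2, floor=0.1))


@pytest.fixture(scope="session")
def fitted_distribution(gompertz_schedule, logistic_prevalence) -> hs.ExitAgeDistribution:
    ms = hs.compute_raw_moments(gompertz_schedule, logistic_prevalence)
    _, dist = hs.solve_maxent(ms)
    return dist


def random_schedules(rng: np.random.Generator):
    """A random (mortality, prevalence) pair on the full 60-89 grid."""
    mort = hs.gen_mortality_schedule(
        hs.GompertzParams(a=rng.uniform(0.003, 0.03), b=rng.uniform(0.0, 0.12))
    )
    prev = hs.gen_health_prevalence(
        hs.PrevalenceCurveParams(
            x0=rng.uniform(68.0, 84.0), k=rng.uniform(0.05, 0.3), floor=rng.uniform(0.0, 0.3)
        )
    )
    return mort, prev


def random_pmf(rng: np.random.Generator, size: int = 31) -> np.ndarray:
    """A strictly positive random pmf (Dirichlet) on the exit-age support."""
    return rng.dirichlet(np.full(size, 0.5))
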