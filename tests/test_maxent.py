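"""Maximum-entropy fits: exact cases, moment recovery, optimality, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import healthspan as hs
from healthspan.maxent import MaxEntError

from .conftest import random_schedules

AGES = np.arange(60, 91)


def _uniform_momentset() -> hs.MomentSet:
    """Raw moments of healthy years under the uniform exit-age pmf."""
    hy = np.arange(0, 31, dtype=float)
    w = np.full(31, 1 / 31)
    return hs.MomentSet(*(float(w @ hy**k) for k in (1, 2, 3)))


class TestExactCases:
    def test_uniform_moments_give_uniform_pmf(self):
        """The unconstrained entropy maximiser is recovered with lambda = 0."""
        sol, dist = hs.solve_maxent(_uniform_momentset())
        assert sol.converged
        assert np.allclose(dist.pmf, 1 / 31, atol=1e-8)
        assert np.allclose(sol.lambdas, 0.0, atol=1e-6)

    def test_degenerate_point_mass_at_cap(self):
        """Zero variance at 30 healthy years forces all mass onto age 90."""
        sol, dist = hs.solve_maxent(hs.MomentSet(30.0, 900.0, 27000.0))
        assert dist.pmf[-1] == 1.0
        assert dist.pmf[:-1].sum() == 0.0
        assert sol.scale == 0.0

    @pytest.mark.parametrize("sd", [3.0, 6.0])
    def test_symmetric_targets_give_symmetric_pmf(self, sd):
        ms = hs.MomentSet(15.0, 15.0**2 + sd**2, 3 * 15.0 * (15.0**2 + sd**2) - 2 * 15.0**3)
        assert ms.skewness == pytest.approx(0.0, abs=1e-12)
        _, dist = hs.solve_maxent(ms)
        assert np.allclose(dist.pmf, dist.pmf[::-1], atol=1e-8)


class TestMomentRecovery:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_normalisation_and_recovery(self, seed):
        """Fitted pmf sums to 1 within 1e-10 and reproduces mean, variance
        and skewness of the target moment set within 1e-6."""
        m, p = random_schedules(np.random.default_rng(seed))
        ms = hs.compute_raw_moments(m, p)
        sol, dist = hs.solve_maxent(ms)
        assert sol.converged
        assert abs(dist.pmf.sum() - 1.0) <= 1e-10
        mean, var, mu3 = dist.moments()
        assert mean == pytest.approx(60 + ms.m1, abs=1e-6)
        assert var == pytest.approx(ms.variance, abs=1e-6)
        assert mu3 / var**1.5 == pytest.approx(ms.skewness, abs=1e-6)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_unique_optimum_across_restarts(self, seed):
        m, p = random_schedules(np.random.default_rng(seed))
        ms = hs.compute_raw_moments(m, p)
        _, dist0 = hs.solve_maxent(ms)
        _, dist1 = hs.solve_maxent(ms, lambda0=np.array([0.5, -0.5, 0.2]))
        assert np.allclose(dist0.pmf, dist1.pmf, atol=1e-8)

    @pytest.mark.parametrize("seed", [5, 17])
    def test_entropy_dominates_constrained_oracle(self, seed):
        """An independent constrained optimiser (SLSQP on the raw pmf) finds
        no feasible distribution with higher entropy."""
        from scipy.optimize import minimize

        m, p = random_schedules(np.random.default_rng(seed))
        ms = hs.compute_raw_moments(m, p)
        _, dist = hs.solve_maxent(ms)

        x = AGES.astype(float)
        # raw exit-age moments from the healthy-years moments (X = 60 + HY)
        targets = [
            60.0 + ms.m1,
            3600.0 + 120.0 * ms.m1 + ms.m2,
            216000.0 + 10800.0 * ms.m1 + 180.0 * ms.m2 + ms.m3,
        ]

        def neg_entropy(q):
            q = np.clip(q, 1e-300, None)
            return float(np.sum(q * np.log(q)))

        cons = [{"type": "eq", "fun": lambda q: q.sum() - 1.0}]
        for k, t in zip((1, 2, 3), targets):
            scale = 31.0**k
            cons.append(
                {"type": "eq", "fun": lambda q, k=k, t=t, s=scale: (float(q @ x**k) - t) / s}
            )
        res = minimize(
            neg_entropy, np.full(31, 1 / 31), method="SLSQP",
            bounds=[(0.0, 1.0)] * 31, constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        assert res.success
        solver_entropy = -float(np.sum(dist.pmf * np.log(np.clip(dist.pmf, 1e-300, None))))
        assert solver_entropy >= -res.fun - 1e-6
        assert np.allclose(res.x, dist.pmf, atol=1e-3)


class TestFeasibilityErrors:
    def test_variance_bound_violation(self):
        # mean exit age 62 cannot carry variance 100 on [60, 90]
        with pytest.raises(MaxEntError, match="variance"):
            hs.solve_maxent(hs.MomentSet(2.0, 104.0, 700.0))

    def test_mean_outside_support(self):
        with pytest.raises(ValueError):
            hs.MomentSet(35.0, 35.0**2 + 1.0, 43000.0).validate()


class TestDistributionHelpers:
    def test_survival_point_mass(self):
        pmf = np.zeros(31)
        pmf[-1] = 1.0
        lhealth = hs.survival_from_pmf(pmf)
        assert np.allclose(lhealth[:-1], 1.0)
        assert lhealth[-1] == 0.0

    def test_survival_two_atom(self):
        pmf = np.zeros(31)
        pmf[0], pmf[1] = 0.5, 0.5
        lhealth = hs.survival_from_pmf(pmf)
        assert lhealth[0] == 1.0
        assert lhealth[1] == pytest.approx(0.5)
        assert lhealth[2] == pytest.approx(0.0)

    def test_survival_uniform_closed_form(self):
        lhealth = hs.survival_from_pmf(np.full(31, 1 / 31))
        expected = (91 - np.arange(60, 92)) / 31
        assert np.allclose(lhealth, np.clip(expected, 0, None), atol=1e-12)

    def test_mode_tie_goes_to_smallest_age(self):
        assert hs.mode_of(np.full(31, 1 / 31)) == (60, pytest.approx(1 / 31))

    def test_mode_point_mass(self):
        pmf = np.zeros(31)
        pmf[86 - 60] = 1.0
        assert hs.mode_of(pmf) == (86, 1.0)

    def test_tail_diagnostic_identical_and_disjoint(self):
        a = np.zeros(31)
        a[0] = 1.0
        b = np.zeros(31)
        b[-1] = 1.0
        same = hs.tail_diagnostic(a, a)
        assert same["tv"] == 0.0 and not same["diff"].any()
        assert hs.tail_diagnostic(a, b)["tv"] == pytest.approx(1.0)

    def test_tail_diagnostic_against_oracle(self, gompertz_schedule, logistic_prevalence):
        """Maxent fit vs Monte-Carlo pmf: a finite, smallish TV distance."""
        ms = hs.compute_raw_moments(gompertz_schedule, logistic_prevalence)
        _, dist = hs.solve_maxent(ms)
        oracle = hs.simulate_healthy_years(
            gompertz_schedule, logistic_prevalence, n_sim=100_000, seed=9
        )
        out = hs.tail_diagnostic(dist.pmf, oracle.pmf)
        assert 0.0 < out["tv"] < 0.5

    def test_support_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hs.tail_diagnostic(np.full(31, 1 / 31), np.full(30, 1 / 30))
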