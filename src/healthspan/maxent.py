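"""Maximum-entropy exit-age distribution from three moments.

Given the mean, variance and third central moment of healthy years after
60, reconstruct the discrete distribution of the exit age (the age at
which a person healthy at 60 dies or becomes unhealthy) on the 31-atom
support {60, ..., 90} that maximises Shannon entropy subject to those
moments.  The solution is the exponential family

    p_x(lambda) ∝ exp(l1 z_x + l2 z_x^2 + l3 z_x^3),

with ``z_x = (x - mu) / sigma`` the age standardised to the target mean
and SD — a raw-age polynomial basis is numerically hazardous at these
magnitudes.  The multipliers solve the strictly convex dual (log-partition
minus lambda·targets) by Newton's method with backtracking; the Hessian is
the covariance of the basis under the current distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .moments import DEGENERATE_VAR_TOL, MomentSet
from .schedules import AGE_CAP, AGE_START


class MaxEntError(RuntimeError):
    """Infeasible moment targets or failed convergence (never silent)."""


@dataclass(frozen=True)
class ExitAgeDistribution:
    """Discrete pmf of the age of health loss on {60, ..., 90}.

    ``pmf[i]`` is the probability of losing health at ``ages[i]``
    (the paper-style "phloss"); :meth:`survival` gives the probability of
    being healthy until each age ("lhealth").
    """

    ages: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        pmf = np.asarray(self.pmf, dtype=float)
        if ages[0] != AGE_START or ages[-1] != AGE_CAP or np.any(np.diff(ages) != 1):
            raise ValueError(f"support must be the full grid {AGE_START}..{AGE_CAP}")
        if pmf.shape != ages.shape:
            raise ValueError("pmf must align with ages")
        if np.any(pmf < -1e-15):
            raise ValueError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > 1e-10:
            raise ValueError(f"pmf must sum to 1 within 1e-10, got {pmf.sum()!r}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "pmf", np.clip(pmf, 0.0, None))

    def survival(self) -> np.ndarray:
        """``lhealth_x = sum_{y >= x} pmf_y`` for x = 60..91 (last entry 0)."""
        return survival_from_pmf(self.pmf)

    def mode(self) -> tuple[int, float]:
        return mode_of(self.pmf, self.ages)

    def moments(self) -> tuple[float, float, float]:
        """Mean, variance and third central moment of the exit age."""
        a = self.ages.astype(float)
        mu = float(self.pmf @ a)
        var = float(self.pmf @ (a - mu) ** 2)
        mu3 = float(self.pmf @ (a - mu) ** 3)
        return mu, var, mu3


@dataclass(frozen=True)
class MaxEntSolution:
    """Multipliers and convergence diagnostics of a maxent fit."""

    lambdas: np.ndarray  # multipliers on (z, z^2, z^3)
    center: float
    scale: float
    converged: bool
    residual: float
    iterations: int


def _feasibility_check(mean_age: float, var: float) -> None:
    lo, hi = float(AGE_START), float(AGE_CAP)
    if not lo <= mean_age <= hi:
        raise MaxEntError(f"mean exit age {mean_age:.4f} outside the support [{lo}, {hi}]")
    var_bound = (mean_age - lo) * (hi - mean_age)
    if var > var_bound + 1e-9:
        raise MaxEntError(
            f"variance {var:.4f} exceeds the bound (mean-60)(90-mean) = {var_bound:.4f} "
            f"for a distribution on [{lo}, {hi}]"
        )


def solve_maxent(
    moments: MomentSet,
    ages: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
    lambda0: np.ndarray | None = None,
) -> tuple[MaxEntSolution, ExitAgeDistribution]:
    """Fit the three-moment maximum-entropy exit-age distribution.

    Parameters
    ----------
    moments : MomentSet
        Raw moments of healthy years after 60; the exit age is
        ``60 + healthy years``, so the targets are shifted accordingly.
    ages : array, optional
        Support; defaults to the full grid 60..90.
    tol : float
        Convergence tolerance on the standardised moment residuals.
    max_iter : int
        Newton iteration cap.
    lambda0 : array, optional
        Initial multipliers (default zero, i.e. the uniform distribution).

    Raises
    ------
    MaxEntError
        If the targets are infeasible on the support or Newton does not
        converge within ``max_iter`` iterations.
    """
    if ages is None:
        ages = np.arange(AGE_START, AGE_CAP + 1)
    ages = np.asarray(ages, dtype=int)
    moments.validate()

    mean_age = AGE_START + moments.m1
    var = max(moments.variance, 0.0)
    mu3 = moments.third_central

    if var < DEGENERATE_VAR_TOL:
        # Degenerate distribution: all mass at the (integer) mean exit age.
        pmf = np.zeros(ages.size)
        pmf[int(round(mean_age)) - ages[0]] = 1.0
        sol = MaxEntSolution(
            lambdas=np.zeros(3), center=mean_age, scale=0.0,
            converged=True, residual=0.0, iterations=0,
        )
        return sol, ExitAgeDistribution(ages=ages, pmf=pmf)

    _feasibility_check(mean_age, var)
    sd = math.sqrt(var)
    z = (ages.astype(float) - mean_age) / sd
    basis = np.vstack([z, z**2, z**3])  # shape (3, n_ages)
    targets = np.array([0.0, 1.0, mu3 / sd**3])

    lam = np.zeros(3) if lambda0 is None else np.asarray(lambda0, dtype=float).copy()

    def dual_and_pmf(l: np.ndarray) -> tuple[float, np.ndarray]:
        eta = l @ basis
        shift = eta.max()  # overflow guard
        w = np.exp(eta - shift)
        zsum = w.sum()
        return float(shift + np.log(zsum) - l @ targets), w / zsum

    value, p = dual_and_pmf(lam)
    residual = float("inf")
    for it in range(1, max_iter + 1):
        grad = basis @ p - targets
        residual = float(np.max(np.abs(grad)))
        if residual < tol:
            sol = MaxEntSolution(
                lambdas=lam, center=mean_age, scale=sd,
                converged=True, residual=residual, iterations=it - 1,
            )
            return sol, ExitAgeDistribution(ages=ages, pmf=p)
        centered = basis - (basis @ p)[:, None]
        hess = (centered * p) @ centered.T  # covariance of the basis under p
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess + 1e-12 * np.eye(3), -grad, rcond=None)[0]
        # Backtracking line search on the convex dual (Armijo condition,
        # with absolute slack so rounding noise in the dual value cannot
        # stall the final Newton steps).
        t = 1.0
        g_dot_step = float(grad @ step)
        for _ in range(60):
            cand = lam + t * step
            cand_value, cand_p = dual_and_pmf(cand)
            if cand_value <= value + 1e-4 * t * g_dot_step + 1e-12:
                break
            t *= 0.5
        lam, value, p = cand, cand_value, cand_p

    raise MaxEntError(
        f"maxent did not converge in {max_iter} iterations: residual={residual:.3e}, "
        f"targets(mean={mean_age:.4f}, var={var:.4f}, mu3={mu3:.4f}), lambdas={lam}"
    )


def survival_from_pmf(pmf: np.ndarray) -> np.ndarray:
    """Tail sums of a pmf on 60..90: entry ``i`` is P(exit age >= 60 + i).

    Returns 32 entries covering ages 60..91; the first is 1 and the last
    0 by construction.
    """
    pmf = np.asarray(pmf, dtype=float)
    tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
    tail[0] = pmf.sum()
    return tail


def mode_of(pmf: np.ndarray, ages: np.ndarray | None = None) -> tuple[int, float]:
    """Modal age and its probability; ties broken to the smallest age."""
    pmf = np.asarray(pmf, dtype=float)
    if ages is None:
        ages = np.arange(AGE_START, AGE_START + pmf.size)
    i = int(np.argmax(pmf))  # argmax returns the first (smallest-age) maximum
    return int(ages[i]), float(pmf[i])


def tail_diagnostic(pmf: np.ndarray, reference: np.ndarray) -> dict[str, object]:
    """Per-age signed differences (pmf − reference) and total variation.

    Purely diagnostic: quantifies how far a fitted maxent distribution
    sits from an empirical or Monte-Carlo reference, e.g. underestimation
    of health-loss probabilities in the old-age tail.
    """
    pmf = np.asarray(pmf, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pmf.shape != reference.shape:
        raise ValueError("pmf and reference must share a support")
    diff = pmf - reference
    return {"diff": diff, "tv": float(0.5 * np.abs(diff).sum())}
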