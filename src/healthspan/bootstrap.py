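"""Weighted non-parametric bootstrap of prevalence, propagated end-to-end.

Sampling uncertainty enters the pipeline through the survey prevalence
estimates only; mortality schedules are held fixed.  For every stratum
(wave × sex × age under a given health measure), records are resampled
with replacement and the replicate prevalence recomputed; each replicate
prevalence schedule is then pushed through the rewards recursion, the
maximum-entropy fit and the comparison statistics, and percentile
confidence intervals are read off the replicate distribution (2.5th and
97.5th percentiles at the default 95% level).

Two resampling estimators are available, since "weighted sampling with
replacement" admits both readings:

* ``selection`` (default) — records drawn with probability proportional
  to their calibrated weight; replicate prevalence is the unweighted
  mean of the resampled healthy indicators;
* ``reweight`` — records drawn uniformly; replicate prevalence is the
  weighted mean over the resample.

Replicate ``r`` uses seed ``base_seed + r``, so any replicate is
reproducible independently of how many replicates are run in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import hellinger, phi_hl
from .maxent import MaxEntError, mode_of, solve_maxent
from .moments import MomentSet, RewardConvention, compute_raw_moments
from .schedules import AGE_CAP, AGE_START, MortalitySchedule, PrevalenceSchedule

_ESTIMATORS = ("selection", "reweight")


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 5000
    base_seed: int = 0
    ci_level: float = 95.0
    estimator: str = "selection"
    #: Fraction of maxent-failed replicates tolerated before the run fails.
    max_drop_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0.0 < self.ci_level < 100.0:
            raise ValueError("ci_level must lie in (0, 100)")
        if self.estimator not in _ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}; expected one of {_ESTIMATORS}")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with replicate values and a percentile CI."""

    point: float
    replicates: np.ndarray
    lower: float
    upper: float


def percentile_ci(
    values: Sequence[float] | np.ndarray, level: float = 95.0, integer: bool = False
) -> tuple[float, float]:
    """Percentile interval with linear interpolation between order statistics.

    Follows the standard linear rule (position ``(n-1) q`` between sorted
    values).  For inherently integer quantities such as the modal age,
    each endpoint snaps to the nearest value actually attained by a
    replicate, keeping integer endpoints.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no values to summarise")
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha], method="linear")
    if integer:
        attained = np.unique(values)
        lo = float(attained[np.argmin(np.abs(attained - lo))])
        hi = float(attained[np.argmin(np.abs(attained - hi))])
    return float(lo), float(hi)


class _StratumSampler:
    """Pre-indexed weighted resampler over (wave, sex, age) strata."""

    def __init__(self, microdata: pd.DataFrame, healthy: pd.Series,
                 strata: Sequence[str] = ("wave", "sex", "age")) -> None:
        data = microdata.loc[healthy.index]
        self.strata_cols = list(strata)
        self.keys: list[tuple] = []
        self._healthy: list[np.ndarray] = []
        self._weights: list[np.ndarray] = []
        self._cumw: list[np.ndarray] = []
        for key, grp in data.groupby(self.strata_cols, sort=True):
            w = grp["weight"].to_numpy(dtype=float)
            if np.any(w <= 0):
                raise ValueError(f"non-positive weight in stratum {key}")
            if len(grp) == 1:
                warnings.warn(f"stratum {key} has a single record; its CI is degenerate")
            self.keys.append(key)
            self._healthy.append(healthy.loc[grp.index].to_numpy(dtype=float))
            self._weights.append(w)
            cw = np.cumsum(w)
            self._cumw.append(cw / cw[-1])

    def replicate(self, rng: np.random.Generator, estimator: str) -> np.ndarray:
        """One replicate prevalence per stratum, in key order."""
        out = np.empty(len(self.keys))
        for i, (hl, w, cw) in enumerate(zip(self._healthy, self._weights, self._cumw)):
            n = hl.size
            if estimator == "selection":
                idx = np.searchsorted(cw, rng.random(n), side="left")
                out[i] = hl[idx].mean()
            else:
                idx = rng.integers(0, n, size=n)
                out[i] = float(np.sum(w[idx] * hl[idx]) / np.sum(w[idx]))
        return out


def bootstrap_prevalence(
    microdata: pd.DataFrame,
    healthy: pd.Series,
    config: BootstrapConfig,
    strata: Sequence[str] = ("wave", "sex", "age"),
) -> Iterator[pd.DataFrame]:
    """Stream of replicate prevalence tables (one row per stratum)."""
    sampler = _StratumSampler(microdata, healthy, strata)
    key_frame = pd.DataFrame(sampler.keys, columns=sampler.strata_cols)
    for r in range(config.n_reps):
        rng = np.random.default_rng(config.base_seed + r)
        table = key_frame.copy()
        table["h"] = sampler.replicate(rng, config.estimator)
        table["replicate"] = r
        yield table


def _schedule_from(h: np.ndarray, ages: np.ndarray, label: str) -> PrevalenceSchedule:
    # replicate proportions can touch 0; the recursion tolerates it but the
    # schedule contract does not, so floor at a negligible level
    return PrevalenceSchedule(ages=ages, hx=np.clip(h, 1e-12, 1.0), label=label)


def bootstrap_pipeline(
    microdata: pd.DataFrame,
    healthy: pd.Series,
    mortality: Mapping[str, MortalitySchedule],
    wave: str,
    config: BootstrapConfig,
    convention: RewardConvention = RewardConvention(),
    run_maxent: bool = True,
    compare_pair: tuple[str, str] | None = None,
) -> dict[str, BootstrapResult]:
    """Propagate prevalence resampling through moments, maxent and comparison.

    Parameters
    ----------
    mortality : mapping sex -> MortalitySchedule
        Held fixed across replicates (mortality sampling error is not
        modelled).
    wave : str
        The wave analysed; strata are (sex, age) within it.
    run_maxent : bool
        Whether to fit the exit-age distribution per replicate (adds the
        per-age health-loss probabilities, the mode and, with
        ``compare_pair``, the outsurvival and Hellinger statistics).
    compare_pair : (sex1, sex2), optional
        Populations for the outsurvival statistic (sex1 outsurviving
        sex2) and Hellinger distance; defaults to ("male", "female") when
        both are present.

    Returns
    -------
    dict mapping quantity name -> BootstrapResult.  Per-sex keys are
    ``"<sex>:hle_age"``, ``"<sex>:sdhl"``, ``"<sex>:skewness"`` and, with
    maxent, ``"<sex>:mode_age"``, ``"<sex>:mode_prob"`` and
    ``"<sex>:phloss_<age>"``; comparison keys are ``"phi"`` and ``"hd"``.

    Raises
    ------
    RuntimeError
        If more than ``config.max_drop_fraction`` of replicates fail the
        maxent fit.
    """
    data = microdata[microdata["wave"] == wave]
    healthy_w = healthy.loc[healthy.index.intersection(data.index)]
    sampler = _StratumSampler(data, healthy_w, ("sex", "age"))
    sexes = sorted({k[0] for k in sampler.keys})
    for sex in sexes:
        if sex not in mortality:
            raise ValueError(f"no mortality schedule for sex {sex!r}")
    if compare_pair is None and {"male", "female"} <= set(sexes):
        compare_pair = ("male", "female")

    ages = np.arange(AGE_START, AGE_CAP)
    sex_slices = {
        sex: np.array([i for i, k in enumerate(sampler.keys) if k[0] == sex]) for sex in sexes
    }
    for sex, idx in sex_slices.items():
        got = [sampler.keys[i][1] for i in idx]
        if got != list(ages):
            missing = sorted(set(ages.tolist()) - set(got))
            raise ValueError(f"sex {sex!r} has empty strata at ages {missing}")

    def evaluate(h_by_stratum: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        pmfs: dict[str, np.ndarray] = {}
        for sex in sexes:
            sched = _schedule_from(h_by_stratum[sex_slices[sex]], ages, f"{wave}:{sex}")
            ms = compute_raw_moments(mortality[sex], sched, convention)
            out[f"{sex}:hle_age"] = ms.hle_age
            out[f"{sex}:sdhl"] = ms.sdhl
            out[f"{sex}:skewness"] = np.nan if ms.skewness is None else ms.skewness
            if run_maxent:
                _, dist = solve_maxent(ms)
                pmfs[sex] = dist.pmf
                mode_age, mode_prob = mode_of(dist.pmf, dist.ages)
                out[f"{sex}:mode_age"] = float(mode_age)
                out[f"{sex}:mode_prob"] = mode_prob
                for age, p in zip(dist.ages, dist.pmf):
                    out[f"{sex}:phloss_{age}"] = float(p)
        if run_maxent and compare_pair is not None:
            p1, p2 = pmfs[compare_pair[0]], pmfs[compare_pair[1]]
            out["phi"] = phi_hl(p1, p2).phi
            out["hd"] = hellinger(p1, p2).hd
        return out

    # point estimates from the full-sample weighted prevalence
    point_h = np.empty(len(sampler.keys))
    for i, (hl, w) in enumerate(zip(sampler._healthy, sampler._weights)):
        point_h[i] = float(np.sum(w * hl) / np.sum(w))
    point = evaluate(point_h)

    replicate_rows: list[dict[str, float]] = []
    n_dropped = 0
    for r in range(config.n_reps):
        rng = np.random.default_rng(config.base_seed + r)
        h_rep = sampler.replicate(rng, config.estimator)
        try:
            replicate_rows.append(evaluate(h_rep))
        except MaxEntError:
            n_dropped += 1
    if n_dropped > config.max_drop_fraction * config.n_reps:
        raise RuntimeError(
            f"{n_dropped}/{config.n_reps} replicates failed the maxent fit "
            f"(tolerance {config.max_drop_fraction:.1%})"
        )

    results: dict[str, BootstrapResult] = {}
    for key, pt in point.items():
        reps = np.array([row[key] for row in replicate_rows])
        lo, hi = percentile_ci(reps, config.ci_level, integer=key.endswith("mode_age"))
        results[key] = BootstrapResult(point=float(pt), replicates=reps, lower=lo, upper=hi)
    return results
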