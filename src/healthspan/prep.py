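"""From microdata and life tables to the schedules the model consumes.

This module implements the data-preparation layer: parsing period life
tables (the standard HMD 1x1 text layout or a simplified tidy CSV),
turning per-record condition indicators and cognitive scores into a
binary healthy/unhealthy state under a configurable health-measure
definition, estimating weighted age-specific healthy prevalence, and
pooling mortality across countries with respondent-count weights.

Microdata conventions: one row per person-wave with columns ``id, wave,
country, sex, age, weight`` plus ``cond_<name>`` boolean condition
indicators, ``score_<test>`` cognitive scores (may be missing),
``education`` and ``dementia``.  Analysis is restricted to ages 60 and
over; ages 90+ fall outside the 60-89 estimation grid.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .schedules import AGE_CAP, AGE_START, MortalitySchedule, PrevalenceSchedule

logger = logging.getLogger(__name__)

_MODES = ("all-free", "at-most-one", "cognitive-threshold")
#: Tests used by the cognitive health measures.
COGNITIVE_TESTS = ("time_orientation", "verbal_fluency", "memory")


@dataclass(frozen=True)
class HealthMeasureDef:
    """Definition of a prevalence-based health measure.

    * ``all-free`` — healthy iff free from every condition in
      ``conditions`` (e.g. life free from major chronic conditions, or
      from cardiovascular disease only);
    * ``at-most-one`` — healthy iff at most one condition is present
      (the multimorbidity-oriented measure);
    * ``cognitive-threshold`` — healthy iff every cognitive test score
      lies above (reference mean − ``threshold_sd`` × reference SD) and
      there is no dementia/Alzheimer's diagnosis.  With
      ``education_adjusted`` the reference statistics are computed within
      each education stratum.
    """

    name: str
    mode: str
    conditions: tuple[str, ...] = ()
    threshold_sd: float = 1.5
    education_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.mode in ("all-free", "at-most-one") and not self.conditions:
            raise ValueError(f"mode {self.mode!r} requires a non-empty condition set")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")


# ---------------------------------------------------------------------------
# Life tables


def _parse_hmd_age(token: str) -> int:
    return int(token.rstrip("+"))


def read_life_table(
    path_or_buffer,
    dialect: str = "hmd",
    country: str = "",
    sex: str = "",
) -> dict[tuple[str, int, str], MortalitySchedule]:
    """Parse period life tables into per-(country, year, sex) schedules.

    ``dialect="hmd"`` expects the HMD 1x1 period life-table text layout
    (descriptive header lines, then columns ``Year Age mx qx ax lx dx Lx
    Tx ex``); country and sex are not encoded in the file body and are
    supplied by the caller.  The open-age ``110+`` row parses without
    error but lies outside the 60-89 grid.  ``dialect="csv"`` expects a
    tidy file with columns ``year, age, sex, qx`` and optionally
    ``country``.

    Every (country, year, sex) group must cover ages 60-89 completely;
    a missing age raises an error naming it.
    """
    if dialect == "hmd":
        rows = _read_hmd_rows(path_or_buffer)
        frame = pd.DataFrame(rows, columns=["year", "age", "qx"])
        frame["country"] = country
        frame["sex"] = sex
    elif dialect == "csv":
        frame = pd.read_csv(path_or_buffer, float_precision="round_trip")
        required = {"year", "age", "sex", "qx"}
        if missing := required - set(frame.columns):
            raise ValueError(f"simplified life-table CSV missing columns {sorted(missing)}")
        if "country" not in frame.columns:
            frame["country"] = country
        frame["age"] = [_parse_hmd_age(str(a)) for a in frame["age"]]
    else:
        raise ValueError(f"unknown life-table dialect {dialect!r}")

    bad = frame[(frame["qx"] < 0) | (frame["qx"] > 1)]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(f"q_x={r['qx']} outside [0, 1] at year={r['year']} age={r['age']}")

    out: dict[tuple[str, int, str], MortalitySchedule] = {}
    grid = frame[(frame["age"] >= AGE_START) & (frame["age"] < AGE_CAP)]
    for (ctry, year, sx), grp in grid.groupby(["country", "year", "sex"], sort=True):
        grp = grp.sort_values("age")
        missing_ages = sorted(set(range(AGE_START, AGE_CAP)) - set(grp["age"]))
        if missing_ages:
            raise ValueError(
                f"life table ({ctry!r}, {year}, {sx!r}) missing ages {missing_ages}"
            )
        out[(str(ctry), int(year), str(sx))] = MortalitySchedule(
            ages=grp["age"].to_numpy(),
            qx=grp["qx"].to_numpy(dtype=float),
            source=f"{ctry}:{year}:{sx}",
        )
    return out


def _read_hmd_rows(path_or_buffer) -> list[tuple[int, int, float]]:
    if isinstance(path_or_buffer, (str, bytes)) or hasattr(path_or_buffer, "__fspath__"):
        with open(path_or_buffer) as fh:
            lines = fh.readlines()
    else:
        lines = path_or_buffer.readlines()
    rows: list[tuple[int, int, float]] = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "Year":
            header_seen = True
            if tokens[:4] != ["Year", "Age", "mx", "qx"]:
                raise ValueError(f"unexpected HMD column header: {line.strip()!r}")
            continue
        if not header_seen:
            continue  # descriptive preamble
        if len(tokens) != 10:
            raise ValueError(f"malformed HMD row at line {lineno}: {line.strip()!r}")
        try:
            year = int(tokens[0])
            age = _parse_hmd_age(tokens[1])
            qx = float(tokens[3])
        except ValueError as exc:
            raise ValueError(f"malformed HMD row at line {lineno}: {line.strip()!r}") from exc
        rows.append((year, age, qx))
    if not header_seen:
        raise ValueError("no HMD column header line found")
    return rows


def write_simple_life_table(
    schedules: Mapping[tuple[str, int, str], MortalitySchedule], path_or_buffer
) -> None:
    """Serialise schedules to the simplified CSV dialect (canonical form).

    Reading the produced file back with ``read_life_table(dialect="csv")``
    and re-serialising reproduces it byte-for-byte.
    """
    records = []
    for (country, year, sex) in sorted(schedules):
        sched = schedules[(country, year, sex)]
        for age, qx in zip(sched.ages, sched.qx):
            records.append({"country": country, "year": year, "sex": sex, "age": age, "qx": repr(float(qx))})
    pd.DataFrame(records, columns=["country", "year", "sex", "age", "qx"]).to_csv(
        path_or_buffer, index=False
    )


# ---------------------------------------------------------------------------
# Health indicators


def derive_health_indicator(
    microdata: pd.DataFrame,
    measure: HealthMeasureDef,
    missing_conditions_as_absent: bool = False,
    reference_per_wave: bool = False,
) -> tuple[pd.Series, int]:
    """Per-record healthy boolean under a health-measure definition.

    Returns ``(healthy, n_dropped)``: a boolean Series indexed by the
    retained records and the number of records dropped for missingness.
    Condition-based modes drop records with a missing indicator unless
    ``missing_conditions_as_absent``; the cognitive mode drops records
    with every test score missing, evaluates the threshold rule per
    available test, and lets a dementia diagnosis override the scores.
    Cognitive reference means/SDs pool all person-wave observations and
    both sexes (optionally per wave; within education strata when the
    measure is education-adjusted).
    """
    if measure.mode in ("all-free", "at-most-one"):
        cols = [f"cond_{c}" for c in measure.conditions]
        if missing := [c for c in cols if c not in microdata.columns]:
            raise ValueError(f"microdata lacks condition columns {missing}")
        block = microdata[cols]
        if missing_conditions_as_absent:
            block = block.where(block.notna(), other=False)
            kept = microdata.index
        else:
            kept = microdata.index[block.notna().all(axis=1)]
            block = block.loc[kept]
        n_dropped = len(microdata) - len(kept)
        counts = block.astype(bool).sum(axis=1)
        healthy = counts == 0 if measure.mode == "all-free" else counts <= 1
    else:
        score_cols = [f"score_{t}" for t in COGNITIVE_TESTS]
        needed = score_cols + ["dementia"] + (["education"] if measure.education_adjusted else [])
        if missing := [c for c in needed if c not in microdata.columns]:
            raise ValueError(f"microdata lacks columns {missing}")
        scores = microdata[score_cols]
        kept = microdata.index[scores.notna().any(axis=1)]
        n_dropped = len(microdata) - len(kept)
        data = microdata.loc[kept]
        group_keys: list[pd.Series] = []
        if reference_per_wave:
            group_keys.append(data["wave"])
        if measure.education_adjusted:
            group_keys.append(data["education"])
        passed = pd.Series(True, index=kept)
        for col in score_cols:
            s = data[col]
            if group_keys:
                grouped = s.groupby(group_keys)
                mean, sd = grouped.transform("mean"), grouped.transform("std")
            else:
                mean, sd = s.mean(), s.std()
            thresh = mean - measure.threshold_sd * sd
            # a reference without variation cannot discriminate: skip the test
            if np.isscalar(thresh):
                if not np.isfinite(thresh) or sd == 0:
                    continue
            else:
                thresh = thresh.where(np.isfinite(thresh) & (sd > 0), -np.inf)
            # missing individual scores are skipped, not failed
            passed &= (s > thresh) | s.isna()
        healthy = passed & ~data["dementia"].astype(bool)
    if n_dropped:
        logger.info("measure %s: dropped %d records with missing inputs", measure.name, n_dropped)
    return healthy.rename("healthy"), n_dropped


# ---------------------------------------------------------------------------
# Weighted prevalence


def compute_weighted_prevalence(
    microdata: pd.DataFrame,
    healthy: pd.Series,
    strata: Iterable[str] = ("wave", "sex", "age"),
) -> pd.DataFrame:
    """Weighted healthy prevalence per stratum.

    ``h = sum(weight * healthy) / sum(weight)`` within each stratum,
    reported together with the weighted and unweighted respondent counts.
    Invariant to a global rescaling of the weights within a stratum.
    """
    strata = list(strata)
    data = microdata.loc[healthy.index].copy()
    data["healthy"] = healthy.astype(float)
    if (data["weight"] <= 0).any():
        raise ValueError("weights must be strictly positive")

    def agg(grp: pd.DataFrame) -> pd.Series:
        w = grp["weight"].to_numpy()
        return pd.Series(
            {
                "h": float(np.sum(w * grp["healthy"].to_numpy()) / np.sum(w)),
                "n_weighted": float(np.sum(w)),
                "n": int(len(grp)),
            }
        )

    table = data.groupby(strata, sort=True).apply(agg, include_groups=False).reset_index()
    table["n"] = table["n"].astype(int)
    return table


def prevalence_schedule(
    table: pd.DataFrame,
    wave: str,
    sex: str,
    ages: np.ndarray | None = None,
) -> PrevalenceSchedule:
    """Extract one (wave, sex) h_x schedule from a prevalence table.

    Errors if any age stratum on the grid is empty, naming the stratum.
    """
    if ages is None:
        ages = np.arange(AGE_START, AGE_CAP)
    sub = table[(table["wave"] == wave) & (table["sex"] == sex)].set_index("age")
    missing = [int(a) for a in ages if a not in sub.index]
    if missing:
        raise ValueError(f"empty strata for wave={wave!r} sex={sex!r} at ages {missing}")
    sub = sub.loc[ages]
    return PrevalenceSchedule(
        ages=np.asarray(ages, dtype=int),
        hx=sub["h"].to_numpy(dtype=float),
        n_weighted=sub["n_weighted"].to_numpy(dtype=float),
        n_unweighted=sub["n"].to_numpy(),
        label=f"{wave}:{sex}",
    )


# ---------------------------------------------------------------------------
# Pooled mortality


def pool_weighted_mortality(
    schedules: Mapping[str, MortalitySchedule],
    country_weights: Mapping[str, float | np.ndarray],
) -> MortalitySchedule:
    """Respondent-weighted average of q_x across countries.

    ``pooled q_x = sum_c w_c q_x,c / sum_c w_c`` where ``w_c`` is the
    (weighted) respondent count for the stratum in country ``c`` — a
    scalar or a per-age array.  A single country passes through
    unchanged.
    """
    if not schedules:
        raise ValueError("no schedules to pool")
    if missing := sorted(set(schedules) - set(country_weights)):
        raise ValueError(f"no pooling weights for countries {missing}")
    first = next(iter(schedules.values()))
    ages = first.ages
    num = np.zeros(ages.size)
    den = np.zeros(ages.size)
    for country, sched in schedules.items():
        if not np.array_equal(sched.ages, ages):
            raise ValueError("all schedules must share an age grid")
        w = np.broadcast_to(np.asarray(country_weights[country], dtype=float), ages.shape)
        if np.any(w < 0):
            raise ValueError(f"negative pooling weight for {country!r}")
        num += w * sched.qx
        den += w
    if np.any(den <= 0):
        zero_ages = ages[den <= 0].tolist()
        raise ValueError(f"zero total pooling weight at ages {zero_ages}")
    return MortalitySchedule(ages=ages, qx=num / den, source="pooled")
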