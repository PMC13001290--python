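"""End-to-end orchestration: scenario -> schedules -> moments -> distributions.

A run is described by a configuration (YAML file or plain dict) naming
either a synthetic scenario (per-sex Gompertz mortality and logistic
condition-prevalence curves, a stratified cohort design) or input paths
(microdata CSV plus a simplified life-table CSV).  The stages are

    simulate/ingest -> prepare -> moments -> maxent -> compare -> bootstrap

and every stage is also callable on its own.  Outputs are tidy CSVs
(prevalence, moments, pmfs, comparisons, optional CIs) plus a JSON
manifest echoing the full configuration and seed, so a run is
reproducible and idempotent given its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapConfig, bootstrap_pipeline
from .compare import hellinger, phi_hl
from .maxent import solve_maxent
from .moments import MomentSet, RewardConvention, compute_raw_moments
from .prep import (
    HealthMeasureDef,
    compute_weighted_prevalence,
    derive_health_indicator,
    prevalence_schedule,
    read_life_table,
)
from .schedules import AGE_CAP, AGE_START, MortalitySchedule
from .synthetic import (
    CohortSpec,
    CognitionSpec,
    GompertzParams,
    PrevalenceCurveParams,
    WeightSpec,
    gen_microdata,
    gen_mortality_schedule,
)


class ConfigError(ValueError):
    """Invalid run configuration (caught by the CLI as exit code 2)."""


#: Default synthetic scenario: a single condition ("chronic") with female
#: mortality advantage and later health loss, the pattern the comparison
#: statistics are designed to detect.
DEFAULT_SCENARIO: dict[str, Any] = {
    "n_per_stratum": 200,
    "waves": ["w1"],
    "sexes": ["male", "female"],
    "mortality": {
        "male": {"a": 0.012, "b": 0.095},
        "female": {"a": 0.008, "b": 0.095},
    },
    "conditions": {
        "chronic": {
            "male": {"x0": 76.0, "k": 0.12, "floor": 0.05},
            "female": {"x0": 79.0, "k": 0.12, "floor": 0.05},
        }
    },
    "weight_sigma": 0.5,
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "healthspan_out"
    scenario: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_SCENARIO))
    microdata_path: str | None = None
    life_table_path: str | None = None
    measure: dict[str, Any] = field(
        default_factory=lambda: {"name": "free_of_chronic", "mode": "all-free", "conditions": ["chronic"]}
    )
    convention: dict[str, Any] = field(
        default_factory=lambda: {"timing": "occupancy", "condition_on_healthy_at_60": True}
    )
    maxent_tol: float = 1e-9
    bootstrap: dict[str, Any] = field(default_factory=lambda: {"enabled": False, "n_reps": 200})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        if unknown := set(raw) - known:
            raise ConfigError(f"unknown configuration keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        try:
            self.measure_def()
            self.reward_convention()
            if self.microdata_path is None:
                self.mortality_schedules()
                self.condition_curves()
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    # -- typed views of the raw config ------------------------------------

    def measure_def(self) -> HealthMeasureDef:
        m = dict(self.measure)
        m["conditions"] = tuple(m.get("conditions", ()))
        return HealthMeasureDef(**m)

    def reward_convention(self) -> RewardConvention:
        return RewardConvention(**self.convention)

    def cohort_spec(self) -> CohortSpec:
        sc = self.scenario
        return CohortSpec(
            ages=np.arange(AGE_START, AGE_CAP),
            n_per_stratum=int(sc.get("n_per_stratum", 200)),
            waves=tuple(sc.get("waves", ["w1"])),
            sexes=tuple(sc.get("sexes", ["male", "female"])),
            seed=self.seed,
        )

    def mortality_schedules(self) -> dict[str, MortalitySchedule]:
        return {
            sex: gen_mortality_schedule(GompertzParams(**params))
            for sex, params in self.scenario["mortality"].items()
        }

    def condition_curves(self) -> dict[str, dict[str, PrevalenceCurveParams]]:
        out: dict[str, dict[str, PrevalenceCurveParams]] = {}
        for cond, by_sex in self.scenario["conditions"].items():
            for sex, params in by_sex.items():
                out.setdefault(sex, {})[cond] = PrevalenceCurveParams(**params)
        return out

    def bootstrap_config(self) -> BootstrapConfig:
        b = {k: v for k, v in self.bootstrap.items() if k != "enabled"}
        b.setdefault("base_seed", self.seed + 100_000)
        return BootstrapConfig(**b)


def run_all(config: RunConfig, write: bool = True) -> dict[str, Any]:
    """Execute the full pipeline and (optionally) write the output bundle.

    Returns a dict with the microdata, prevalence table, tidy moments,
    pmf and comparison frames, and bootstrap results when enabled.
    """
    measure = config.measure_def()
    convention = config.reward_convention()

    if config.microdata_path is not None:
        microdata = pd.read_csv(config.microdata_path)
        if config.life_table_path is None:
            raise ConfigError("microdata_path requires life_table_path")
        tables = read_life_table(config.life_table_path, dialect="csv")
        mortality = {sex: sched for (_, _, sex), sched in tables.items()}
    else:
        spec = config.cohort_spec()
        microdata = gen_microdata(
            spec,
            config.condition_curves(),
            weights=WeightSpec(sigma=float(config.scenario.get("weight_sigma", 0.5))),
            cognition=CognitionSpec(),
        )
        mortality = config.mortality_schedules()

    healthy, n_dropped = derive_health_indicator(microdata, measure)
    prevalence = compute_weighted_prevalence(microdata, healthy)

    waves = sorted(prevalence["wave"].unique())
    sexes = sorted(prevalence["sex"].unique())

    moment_rows, pmf_rows, comparison_rows = [], [], []
    dists: dict[tuple[str, str], Any] = {}
    for wave in waves:
        for sex in sexes:
            sched = prevalence_schedule(prevalence, wave, sex)
            ms = compute_raw_moments(mortality[sex], sched, convention)
            moment_rows.append(
                {
                    "measure": measure.name, "wave": wave, "sex": sex,
                    "m1": ms.m1, "m2": ms.m2, "m3": ms.m3,
                    "hle_age": ms.hle_age, "sdhl": ms.sdhl,
                    "skewness": np.nan if ms.skewness is None else ms.skewness,
                }
            )
            _, dist = solve_maxent(ms, tol=config.maxent_tol)
            dists[(wave, sex)] = dist
            lhealth = dist.survival()
            for i, age in enumerate(dist.ages):
                pmf_rows.append(
                    {
                        "measure": measure.name, "wave": wave, "sex": sex,
                        "age": int(age), "phloss": dist.pmf[i], "lhealth": lhealth[i],
                    }
                )
        if {"male", "female"} <= set(sexes):
            p_m, p_f = dists[(wave, "male")], dists[(wave, "female")]
            phi = phi_hl(p_m, p_f)
            hd = hellinger(p_m, p_f)
            comparison_rows.append(
                {
                    "measure": measure.name, "wave": wave,
                    "phi": phi.phi, "complement": phi.complement,
                    "hd": hd.hd, "bc": hd.bc,
                }
            )

    results: dict[str, Any] = {
        "microdata": microdata,
        "n_dropped": n_dropped,
        "prevalence": prevalence,
        "moments": pd.DataFrame(moment_rows),
        "pmf": pd.DataFrame(pmf_rows),
        "comparison": pd.DataFrame(comparison_rows),
        "distributions": dists,
        "mortality": mortality,
    }

    if config.bootstrap.get("enabled", False):
        bconfig = config.bootstrap_config()
        ci_rows = []
        for wave in waves:
            boot = bootstrap_pipeline(
                microdata, healthy, mortality, wave, bconfig, convention
            )
            for key, res in boot.items():
                ci_rows.append(
                    {
                        "measure": measure.name, "wave": wave, "quantity": key,
                        "point": res.point, "lower": res.lower, "upper": res.upper,
                    }
                )
        results["ci"] = pd.DataFrame(ci_rows)

    if write:
        _write_bundle(config, results)
    return results


def _write_bundle(config: RunConfig, results: dict[str, Any]) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["prevalence"].to_csv(outdir / "prevalence.csv", index=False)
    results["moments"].to_csv(outdir / "moments.csv", index=False)
    results["pmf"].to_csv(outdir / "pmf.csv", index=False)
    results["comparison"].to_csv(outdir / "comparison.csv", index=False)
    if "ci" in results:
        results["ci"].to_csv(outdir / "ci.csv", index=False)
    manifest = {
        "package": "healthspan",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "maxent_tol": config.maxent_tol,
        "records": int(len(results["microdata"])),
        "records_dropped": int(results["n_dropped"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
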