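"""Data preparation: life-table parsing, health indicators, weighted prevalence."""

import io

import numpy as np
import pandas as pd
import pytest

import healthspan as hs
from healthspan.prep import write_simple_life_table


def _hmd_text(ages=range(60, 90), qx=0.01, year=1950, extra_rows=()):
    lines = [
        "Synthetica, Life tables (period 1x1), Females\tLast modified: 01 Jan 2020",
        "",
        "  Year          Age         mx       qx       ax          lx       dx       Lx        Tx     ex",
    ]
    for age in ages:
        lines.append(
            f"  {year}           {age}      {qx:.5f}  {qx:.5f}   0.50     100000     1000    99500   1000000     10.00"
        )
    lines.extend(extra_rows)
    return "\n".join(lines) + "\n"


class TestLifeTableParsing:
    def test_identity_parse(self, tmp_path):
        path = tmp_path / "fltper_1x1.txt"
        path.write_text(_hmd_text())
        tables = hs.read_life_table(path, dialect="hmd", country="SYN", sex="female")
        sched = tables[("SYN", 1950, "female")]
        assert sched.ages.tolist() == list(range(60, 90))
        assert np.allclose(sched.qx, 0.01)

    def test_open_age_row_accepted_but_excluded(self, tmp_path):
        extra = [
            "  1950           110+      0.90000  1.00000   0.50     10     10    5   5     0.50"
        ]
        path = tmp_path / "lt.txt"
        path.write_text(_hmd_text(extra_rows=extra))
        tables = hs.read_life_table(path, dialect="hmd", country="SYN", sex="female")
        sched = tables[("SYN", 1950, "female")]
        assert sched.ages.max() == 89

    def test_missing_age_named_in_error(self, tmp_path):
        path = tmp_path / "lt.txt"
        path.write_text(_hmd_text(ages=[a for a in range(60, 90) if a != 75]))
        with pytest.raises(ValueError, match="75"):
            hs.read_life_table(path, dialect="hmd", country="SYN", sex="female")

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "lt.txt"
        path.write_text(_hmd_text() + "  1950  61  garbage\n")
        with pytest.raises(ValueError, match="malformed"):
            hs.read_life_table(path, dialect="hmd", country="SYN", sex="female")

    def test_q_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "lt.txt"
        path.write_text(_hmd_text(qx=1.5))
        with pytest.raises(ValueError, match="outside"):
            hs.read_life_table(path, dialect="hmd", country="SYN", sex="female")

    def test_csv_dialect_roundtrip_bit_exact(self, tmp_path):
        sched = hs.gen_mortality_schedule(hs.GompertzParams(0.011, 0.093))
        tables = {("SYN", 2004, "male"): sched}
        first = io.StringIO()
        write_simple_life_table(tables, first)
        path = tmp_path / "lt.csv"
        path.write_text(first.getvalue())
        reread = hs.read_life_table(path, dialect="csv")
        assert np.array_equal(reread[("SYN", 2004, "male")].qx, sched.qx)
        second = io.StringIO()
        write_simple_life_table(reread, second)
        assert second.getvalue() == first.getvalue()

    def test_csv_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("year,age\n1950,60\n")
        with pytest.raises(ValueError, match="missing columns"):
            hs.read_life_table(path, dialect="csv")


def _micro(rows):
    base = {
        "id": 0, "wave": "w1", "country": "SYN", "sex": "female", "age": 60,
        "weight": 1.0, "cond_a": False, "cond_b": False, "cond_c": False,
        "score_time_orientation": 0.0, "score_verbal_fluency": 0.0, "score_memory": 0.0,
        "education": "medium", "dementia": False,
    }
    return pd.DataFrame([{**base, **r, "id": i} for i, r in enumerate(rows)])


class TestHealthIndicators:
    MEASURE_ALL = hs.HealthMeasureDef(name="all", mode="all-free", conditions=("a", "b", "c"))
    MEASURE_ONE = hs.HealthMeasureDef(name="one", mode="at-most-one", conditions=("a", "b", "c"))

    def test_all_free(self):
        micro = _micro([{}, {"cond_a": True}])
        healthy, dropped = hs.derive_health_indicator(micro, self.MEASURE_ALL)
        assert healthy.tolist() == [True, False]
        assert dropped == 0

    def test_at_most_one(self):
        micro = _micro([{}, {"cond_a": True}, {"cond_a": True, "cond_b": True}])
        healthy, _ = hs.derive_health_indicator(micro, self.MEASURE_ONE)
        assert healthy.tolist() == [True, True, False]

    def test_missing_condition_dropped_or_kept(self):
        micro = _micro([{}, {"cond_a": np.nan}])
        healthy, dropped = hs.derive_health_indicator(micro, self.MEASURE_ALL)
        assert dropped == 1 and len(healthy) == 1
        healthy, dropped = hs.derive_health_indicator(
            micro, self.MEASURE_ALL, missing_conditions_as_absent=True
        )
        assert dropped == 0 and healthy.tolist() == [True, True]

    def test_dementia_overrides_scores(self):
        # scores exactly at the reference mean are above the -1.5 SD bar
        rows = [{"score_memory": s} for s in (-1.0, 0.0, 1.0)]
        rows.append({"dementia": True})
        micro = _micro(rows)
        measure = hs.HealthMeasureDef(name="cog", mode="cognitive-threshold")
        healthy, _ = hs.derive_health_indicator(micro, measure)
        assert healthy.iloc[-1] == np.False_
        assert healthy.iloc[1] == np.True_

    def test_threshold_rule(self):
        scores = [0.0] * 10 + [-10.0]
        micro = _micro([{"score_memory": s} for s in scores])
        measure = hs.HealthMeasureDef(name="cog", mode="cognitive-threshold")
        healthy, _ = hs.derive_health_indicator(micro, measure)
        assert not healthy.iloc[-1]  # far below mean - 1.5 SD
        assert healthy.iloc[:-1].all()

    def test_all_scores_missing_dropped(self):
        micro = _micro(
            [{}, {f"score_{t}": np.nan for t in ("time_orientation", "verbal_fluency", "memory")}]
        )
        measure = hs.HealthMeasureDef(name="cog", mode="cognitive-threshold")
        healthy, dropped = hs.derive_health_indicator(micro, measure)
        assert dropped == 1 and len(healthy) == 1

    def test_education_adjusted_reference(self):
        """Per-stratum references: a low score is judged against its stratum.

        A small low-education stratum scoring far below a large
        high-education majority fails the pooled -1.5 SD rule but is
        typical within its own stratum.
        """
        rows = [{"education": "low", "score_memory": s} for s in (-5.0, -5.1)]
        rows += [{"education": "high", "score_memory": s} for s in (-0.1, 0.1) * 9]
        micro = _micro(rows)
        adj = hs.HealthMeasureDef(name="cog", mode="cognitive-threshold", education_adjusted=True)
        healthy_adj, _ = hs.derive_health_indicator(micro, adj)
        assert healthy_adj.all()  # every score is typical within its stratum
        pooled = hs.HealthMeasureDef(name="cog", mode="cognitive-threshold")
        healthy_pool, _ = hs.derive_health_indicator(micro, pooled)
        assert healthy_pool.sum() < len(micro)  # pooled reference fails low stratum

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            hs.HealthMeasureDef(name="x", mode="composite")
        with pytest.raises(ValueError):
            hs.HealthMeasureDef(name="x", mode="all-free", conditions=())


class TestWeightedPrevalence:
    def test_weighted_arithmetic(self):
        micro = _micro([{"weight": 2.0}, {"weight": 1.0, "cond_a": True}, {"weight": 1.0}])
        healthy, _ = hs.derive_health_indicator(micro, TestHealthIndicators.MEASURE_ALL)
        table = hs.compute_weighted_prevalence(micro, healthy)
        assert table["h"].iloc[0] == pytest.approx(0.75)
        assert table["n"].iloc[0] == 3
        assert table["n_weighted"].iloc[0] == pytest.approx(4.0)

    def test_equal_weights_match_unweighted(self):
        micro = _micro([{}, {"cond_a": True}, {}, {}])
        healthy, _ = hs.derive_health_indicator(micro, TestHealthIndicators.MEASURE_ALL)
        table = hs.compute_weighted_prevalence(micro, healthy)
        assert table["h"].iloc[0] == pytest.approx(0.75)

    def test_all_healthy_gives_one(self):
        micro = _micro([{"weight": w} for w in (0.5, 2.5, 7.0)])
        healthy, _ = hs.derive_health_indicator(micro, TestHealthIndicators.MEASURE_ALL)
        table = hs.compute_weighted_prevalence(micro, healthy)
        assert table["h"].iloc[0] == 1.0

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        micro = _micro([{"weight": w, "cond_a": bool(c)} for w, c in
                        zip(rng.lognormal(size=20), rng.integers(0, 2, 20))])
        healthy, _ = hs.derive_health_indicator(micro, TestHealthIndicators.MEASURE_ALL)
        base = hs.compute_weighted_prevalence(micro, healthy)["h"].iloc[0]
        micro2 = micro.assign(weight=micro["weight"] * 1234.5)
        scaled = hs.compute_weighted_prevalence(micro2, healthy)["h"].iloc[0]
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_schedule_extraction_errors_on_empty_stratum(self):
        micro = _micro([{"age": a} for a in range(60, 89)])  # age 89 absent
        healthy, _ = hs.derive_health_indicator(micro, TestHealthIndicators.MEASURE_ALL)
        table = hs.compute_weighted_prevalence(micro, healthy)
        with pytest.raises(ValueError, match="89"):
            hs.prevalence_schedule(table, "w1", "female")


class TestPooledMortality:
    def _sched(self, q):
        ages = np.arange(60, 90)
        return hs.MortalitySchedule(ages=ages, qx=np.full(30, q))

    def test_equal_weights_mean(self):
        pooled = hs.pool_weighted_mortality(
            {"A": self._sched(0.01), "B": self._sched(0.03)}, {"A": 1.0, "B": 1.0}
        )
        assert np.allclose(pooled.qx, 0.02)

    def test_single_country_identity(self):
        pooled = hs.pool_weighted_mortality({"A": self._sched(0.017)}, {"A": 12.0})
        assert np.allclose(pooled.qx, 0.017)

    def test_weighted_average(self):
        pooled = hs.pool_weighted_mortality(
            {"A": self._sched(0.01), "B": self._sched(0.05)}, {"A": 3.0, "B": 1.0}
        )
        assert np.allclose(pooled.qx, 0.02)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            hs.pool_weighted_mortality(
                {"A": self._sched(0.01), "B": self._sched(0.05)}, {"A": 0.0, "B": 0.0}
            )

    def test_missing_country_weight_rejected(self):
        with pytest.raises(ValueError, match="no pooling weights"):
            hs.pool_weighted_mortality({"A": self._sched(0.01)}, {})
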