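import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitdfort._rounding import round_half_up_int
from vitdfort.burden import (
    BurdenSummary,
    LifeTable,
    MortalityTable,
    calibrate_total_deaths,
    deaths_prevented,
    group_midpoint,
    preventable_yll,
    total_yll,
)
from vitdfort.errors import CoverageError, DomainError
from vitdfort.synthetic_data import default_burden_inputs


class TestGroupMidpoint:
    def test_closed_group(self):
        assert group_midpoint(70, 74) == 72.5

    def test_open_group_default_offset(self):
        assert group_midpoint(85, None) == 87.5

    def test_open_group_custom_offset(self):
        assert group_midpoint(85, None, open_group_offset=4.0) == 89.0


class TestTotalYll:
    def test_hand_computed_toy_example(self, toy_mortality, toy_life):
        summary = total_yll(toy_mortality, toy_life)
        assert summary.total_deaths == 150
        assert summary.total_yll == pytest.approx(100 * 14.5 + 50 * 8.9)
        assert summary.total_yll == pytest.approx(1895.0)

    def test_empty_table(self, toy_life):
        empty = MortalityTable(
            frame=pd.DataFrame(columns=["sex", "age_low", "age_high", "deaths"])
        )
        summary = total_yll(empty, toy_life)
        assert summary.total_deaths == 0
        assert summary.total_yll == 0

    def test_calibrated_synthetic_defaults_near_target(self):
        mort, life = default_burden_inputs()
        summary = total_yll(mort, life)
        assert summary.total_deaths == 229_827
        assert abs(summary.total_yll - 2.8e6) / 2.8e6 < 0.05

    def test_uncovered_stratum_reported(self, toy_mortality):
        # life table only covers males -> female stratum must be named
        male_only = LifeTable(
            frame=pd.DataFrame(
                [
                    {"sex": "male", "age": 0.0, "ex": 80.0},
                    {"sex": "male", "age": 100.0, "ex": 2.0},
                ]
            )
        )
        with pytest.raises(CoverageError, match="female"):
            total_yll(toy_mortality, male_only)

    def test_additivity_under_split(self, toy_mortality, toy_life):
        whole = total_yll(toy_mortality, toy_life).total_yll
        part = toy_mortality.frame.copy()
        a, b = part.copy(), part.copy()
        a["deaths"] = [40, 10]
        b["deaths"] = [60, 40]
        split_sum = (
            total_yll(MortalityTable(a), toy_life).total_yll
            + total_yll(MortalityTable(b), toy_life).total_yll
        )
        assert split_sum == pytest.approx(whole)

    @settings(max_examples=30, deadline=None)
    @given(
        deaths=st.lists(
            st.integers(min_value=0, max_value=5000), min_size=18, max_size=18
        ),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_oracle_double_loop_equivalence(self, deaths, seed):
        rng = np.random.default_rng(seed)
        groups = [(5 * i, 5 * i + 4) for i in range(17)] + [(85, None)]
        rows = [
            {
                "sex": "male",
                "age_low": lo,
                "age_high": float("nan") if hi is None else hi,
                "deaths": d,
            }
            for (lo, hi), d in zip(groups, deaths)
        ]
        mort = MortalityTable(frame=pd.DataFrame(rows))
        ages = np.arange(0, 111, 5.0)
        ex = np.maximum(1.0, 85.0 - 0.9 * ages + rng.uniform(0, 0.001, ages.size))
        ex = np.minimum.accumulate(ex)  # enforce non-increasing
        life = LifeTable(
            frame=pd.DataFrame(
                [{"sex": "male", "age": a, "ex": e} for a, e in zip(ages, ex)]
            )
        )
        # independent naive oracle: python loop over strata
        expected = 0.0
        for (lo, hi), d in zip(groups, deaths):
            mid = lo + 2.5 if hi is None else (lo + hi + 1) / 2
            expected += d * float(np.interp(mid, ages, ex))
        assert total_yll(mort, life).total_yll == pytest.approx(expected, abs=1e-9)


class TestCalibrateTotalDeaths:
    def test_published_anchor(self):
        assert calibrate_total_deaths(25_281, 0.11) == 229_827

    def test_trivial(self):
        assert calibrate_total_deaths(100, 0.5) == 200

    @given(
        t=st.integers(min_value=1000, max_value=1_000_000),
        r=st.floats(min_value=0.05, max_value=0.95),
    )
    def test_round_trip_recovery(self, t, r):
        prevented = round_half_up_int(t * r)
        assert abs(calibrate_total_deaths(prevented, r) - t) <= 1 / r

    @pytest.mark.parametrize("prevented,rrr", [(0, 0.1), (-5, 0.1), (10, 0), (10, 1.0)])
    def test_domain_errors(self, prevented, rrr):
        with pytest.raises(DomainError):
            calibrate_total_deaths(prevented, rrr)


class TestPreventableBurden:
    def test_published_prevented_counts(self):
        assert round_half_up_int(deaths_prevented(229_827, 0.11)) == 25_281
        assert round_half_up_int(deaths_prevented(229_827, 0.15)) == 34_474

    def test_zero_rrr(self):
        assert deaths_prevented(123_456, 0.0) == 0.0

    def test_preventable_yll_examples(self):
        assert preventable_yll(2_800_000, 0.11) == pytest.approx(308_000)
        assert preventable_yll(1895, 0.13) == pytest.approx(246.35)
        assert preventable_yll(42.0, 1.0) == 42.0

    @given(
        burden_x=st.floats(min_value=0, max_value=1e7),
        r1=st.floats(min_value=0, max_value=1),
        r2=st.floats(min_value=0, max_value=1),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    def test_monotone_and_homogeneous(self, burden_x, r1, r2, scale):
        lo, hi = sorted((r1, r2))
        assert deaths_prevented(burden_x, lo) <= deaths_prevented(burden_x, hi)
        assert preventable_yll(burden_x, lo) <= preventable_yll(burden_x, hi)
        assert deaths_prevented(scale * burden_x, r1) == pytest.approx(
            scale * deaths_prevented(burden_x, r1)
        )

    @pytest.mark.parametrize("rrr", [-0.1, 1.1])
    def test_rrr_domain(self, rrr):
        with pytest.raises(DomainError):
            deaths_prevented(100, rrr)
        with pytest.raises(DomainError):
            preventable_yll(100, rrr)


class TestTableValidation:
    def test_negative_deaths_rejected(self):
        with pytest.raises(DomainError):
            MortalityTable(
                frame=pd.DataFrame(
                    [{"sex": "male", "age_low": 0, "age_high": 4.0, "deaths": -1}]
                )
            )

    def test_overlapping_groups_rejected(self):
        with pytest.raises(DomainError):
            MortalityTable(
                frame=pd.DataFrame(
                    [
                        {"sex": "male", "age_low": 0, "age_high": 4.0, "deaths": 1},
                        {"sex": "male", "age_low": 3, "age_high": 9.0, "deaths": 1},
                    ]
                )
            )

    def test_life_table_must_be_nonincreasing(self):
        with pytest.raises(DomainError):
            LifeTable(
                frame=pd.DataFrame(
                    [
                        {"sex": "male", "age": 0.0, "ex": 10.0},
                        {"sex": "male", "age": 5.0, "ex": 12.0},
                    ]
                )
            )

    def test_burden_summary_rejects_negative_yll(self):
        with pytest.raises(DomainError):
            BurdenSummary(total_deaths=1, total_yll=-1.0)
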