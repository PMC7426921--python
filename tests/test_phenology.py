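"""Monthly series construction, the Pearson test against a brute-force
oracle, and the correlation-strength bins."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bevan_severity import (Strength, classify_strength, correlation_matrix,
                            monthly_series, pearson_with_p)
from bevan_severity.phenology import SERIES_VARIABLES
from conftest import make_record


def oracle_pearson(x, y):
    """Direct covariance / std formula, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


class TestMonthlySeries:
    def test_single_event_in_july(self, flat_env):
        series = monthly_series([make_record(month=7)], flat_env, "Cerambycidae")
        assert dict(zip([m for _, m in series.months], series.frequency))[7] == 1
        assert series.frequency.sum() == 1

    def test_counts_match_brute_force_tally(self, flat_env):
        records = [
            make_record(month=5, species="A b", count=2),
            make_record(month=5, species="C d"),
            make_record(month=5, species="A b", depot="1b"),
            make_record(month=7, species="A b"),
            make_record(month=7, species="Thanasimus formicarius",
                        family="Cleridae"),  # other family, excluded
        ]
        series = monthly_series(records, flat_env, "Cerambycidae")
        by_month = {m: i for i, (_, m) in enumerate(series.months)}
        # May: events = {(A b,1a),(C d,1a),(A b,1b)} -> 3; species {A b, C d} -> 2
        assert series.frequency[by_month[5]] == 3
        assert series.species_number[by_month[5]] == 2
        assert series.frequency[by_month[7]] == 1
        assert series.species_number[by_month[7]] == 1

    def test_density_from_pooled_monthly_individuals(self, flat_env):
        records = [make_record(month=6, count=4), make_record(month=6, depot="1b",
                                                              count=6)]
        series = monthly_series(records, flat_env, "Cerambycidae",
                                area_map={"1a": 2.0, "1b": 3.0}, duration=0.5)
        i = [m for _, m in series.months].index(6)
        assert series.density[i] == pytest.approx((10 / 5.0) / 0.5)

    def test_month_without_environment_named_in_error(self, flat_env):
        with pytest.raises(KeyError, match="2015-03"):
            monthly_series([make_record(month=3)], flat_env, "Cerambycidae")

    def test_pooled_years_merge_calendar_months(self, flat_env):
        records = [make_record(year=2015, month=7), make_record(year=2016, month=7)]
        env = flat_env + [e.model_copy(update={"year": 2016}) for e in flat_env]
        pooled = monthly_series(records, env, "Cerambycidae", pool_years=True)
        assert len(pooled.months) == 7
        i = [m for _, m in pooled.months].index(7)
        assert pooled.frequency[i] == 2
        per_year = monthly_series(records, env, "Cerambycidae")
        assert len(per_year.months) == 14


class TestPearsonWithP:
    def test_perfect_linearity(self):
        res = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.strength is Strength.excellent

    def test_antisymmetry(self):
        x = [1.0, 2.5, 3.0, 7.0]
        assert pearson_with_p(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_hand_vector_matches_formula_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(oracle_pearson(x, y), abs=1e-12)

    def test_undefined_flagged_not_nan(self):
        too_short = pearson_with_p([1, 2], [3, 4])
        constant = pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        for res in (too_short, constant):
            assert not res.defined and res.r is None and res.p is None

    def test_p_decreases_with_abs_r_at_fixed_n(self):
        # tilt a fixed noise pattern increasingly towards the x line
        x = np.arange(10.0)
        noise = np.array([0.5, -1.2, 0.8, -0.3, 1.1, -0.9, 0.2, -0.5, 0.7, -0.4])
        results = [pearson_with_p(x, slope * x + noise) for slope in (0.1, 0.5, 2.0)]
        rs = [abs(res.r) for res in results]
        ps = [res.p for res in results]
        assert rs == sorted(rs)
        assert ps == sorted(ps, reverse=True)

    @given(st.lists(st.floats(-100, 100).map(lambda v: round(v, 6)),
                    min_size=3, max_size=30),
           st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=150)
    def test_matches_oracle_on_random_vectors(self, x, rnd):
        y = [rnd.uniform(-100, 100) for _ in x]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            assert not pearson_with_p(x, y).defined
            return
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(oracle_pearson(x, y), abs=1e-12)


class TestClassifyStrength:
    @pytest.mark.parametrize("r, expected", [
        (0.922, Strength.high),          # the reported temperature link
        (0.0, Strength.none),
        (-0.544, Strength.intermediate), # reported RH-temperature r
        (0.15, Strength.low),
        (1.0, Strength.excellent),
        (-1.0, Strength.excellent),
        (0.295, Strength.low),
        (0.2951, Strength.intermediate),
        (0.705, Strength.intermediate),
        (0.995, Strength.high),
    ])
    def test_bin_assignment(self, r, expected):
        assert classify_strength(r) is expected

    def test_total_and_unique_over_grid(self):
        grid = np.round(np.arange(0.0, 1.0 + 1e-12, 1e-4), 10)
        labels = {classify_strength(v) for v in grid}
        assert labels == set(Strength)  # every bin reachable
        for v in grid:  # totality: classification never fails, sign-symmetric
            assert classify_strength(-v) is classify_strength(v)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)


class TestCorrelationMatrix:
    @pytest.fixture
    def series(self, flat_env):
        rng = np.random.default_rng(7)
        records = []
        for month in range(4, 11):
            for i in range(int(rng.integers(1, 5))):
                records.append(make_record(month=month, species=f"S {i}",
                                           count=int(rng.integers(1, 4))))
        return monthly_series(records, flat_env, "Cerambycidae")

    def test_diagonal_is_excellent_unity(self, series):
        results = {(c.var_x, c.var_y): c for c in correlation_matrix(series)}
        for v in SERIES_VARIABLES:
            assert results[(v, v)].r == 1.0
            assert results[(v, v)].strength is Strength.excellent

    def test_symmetry(self, series):
        results = {(c.var_x, c.var_y): c for c in correlation_matrix(series)}
        for vx in SERIES_VARIABLES:
            for vy in SERIES_VARIABLES:
                a, b = results[(vx, vy)], results[(vy, vx)]
                assert a.defined == b.defined
                if a.defined:
                    assert a.r == pytest.approx(b.r, abs=1e-15)

    def test_undefined_pairs_propagate_flagged(self, flat_env):
        # single event: frequency has variance, species_number == frequency,
        # but rh is constant -> rh pairs undefined
        series = monthly_series([make_record(month=7)], flat_env, "Cerambycidae")
        results = {(c.var_x, c.var_y): c for c in correlation_matrix(series)}
        assert not results[("rh", "frequency")].defined

    def test_too_few_months_rejected(self, series):
        series.months = series.months[:2]
        series.frequency = series.frequency[:2]
        with pytest.raises(ValueError):
            correlation_matrix(series)
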