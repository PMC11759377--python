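"""Allometric fits, the six-level classification and the change typology."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import healthscaling as hs
from conftest import ols_normal_equations

L = hs.AllometricLevel


def _panel_from_rows(rows):
    return pd.DataFrame(
        rows, columns=["city_id", "city_name", "year", "gdp", "beds", "doctors"]
    )


class TestAllometricFit:
    def test_identity_power_law(self):
        g = [2.0, 5.0, 11.0, 30.0]
        b, k, r2 = hs.allometric_fit(g, g)
        assert b == pytest.approx(1.0, abs=1e-12)
        assert k == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_response(self):
        b, k, _ = hs.allometric_fit([1.0, 2.0, 4.0], [3.0, 3.0, 3.0])
        assert b == 0.0
        assert k == pytest.approx(np.log(3.0))

    def test_matches_normal_equations_oracle(self):
        g, a = [1.0, 2.0, 4.0, 8.0], [2.0, 3.0, 5.0, 9.0]
        slope, intercept = ols_normal_equations(np.log(g), np.log(a))
        b, k, _ = hs.allometric_fit(g, a)
        assert b == pytest.approx(slope, abs=1e-10)
        assert k == pytest.approx(intercept, abs=1e-10)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0.1, 1e4), st.floats(0.1, 1e4)),
            min_size=3,
            max_size=8,
        )
    )
    def test_oracle_equivalence_small_instances(self, pairs):
        g = [p[0] for p in pairs]
        a = [p[1] for p in pairs]
        if np.ptp(np.log(g)) == 0 or np.ptp(np.log(a)) == 0:
            return
        slope, intercept = ols_normal_equations(np.log(g), np.log(a))
        b, k, _ = hs.allometric_fit(g, a)
        assert b == pytest.approx(slope, abs=1e-10)
        assert k == pytest.approx(intercept, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c_g=st.floats(0.01, 100.0),
        c_a=st.floats(0.01, 100.0),
    )
    def test_scale_invariance_of_exponent(self, c_g, c_a):
        g = np.array([1.0, 3.0, 7.0, 20.0])
        a = np.array([2.0, 5.0, 9.0, 25.0])
        b0, k0, r0 = hs.allometric_fit(g, a)
        b1, k1, r1 = hs.allometric_fit(c_g * g, c_a * a)
        assert b1 == pytest.approx(b0, abs=1e-8)
        assert r1 == pytest.approx(r0, abs=1e-8)
        assert k1 == pytest.approx(k0 - b0 * np.log(c_g) + np.log(c_a), abs=1e-8)

    def test_nonpositive_pairs_dropped(self):
        b, _, _ = hs.allometric_fit([1, 2, 4, 0, 8], [1, 2, 4, 5, 8])
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(hs.InsufficientDataError):
            hs.allometric_fit([1.0, 2.0], [1.0, 2.0])

    def test_degenerate_predictor_raises(self):
        with pytest.raises(hs.DegenerateInputError):
            hs.allometric_fit([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(hs.ContractError):
            hs.allometric_fit([1.0, 2.0, 3.0], [1.0, 2.0])


class TestClassifyLevel:
    @pytest.mark.parametrize(
        "b,level",
        [
            (2.5, L.POSITIVE3),
            (2.0, L.POSITIVE3),  # lower bound inclusive
            (1.2162, L.POSITIVE2),
            (1.0, L.POSITIVE2),
            (0.9, L.POSITIVE1),
            (0.85, L.POSITIVE1),
            (0.7, L.NEGATIVE1),
            (0.5, L.NEGATIVE1),
            (0.3, L.NEGATIVE2),
            (0.0, L.NEGATIVE2),
            (-0.1, L.NEGATIVE3),
        ],
    )
    def test_bands_inclusive_lower_bounds(self, b, level):
        assert hs.classify_level(b) is level

    def test_grade_monotone_in_b(self):
        grid = np.linspace(-1.0, 3.0, 4001)
        grades = [int(hs.classify_level(b)) for b in grid]
        assert grades == sorted(grades)

    @pytest.mark.parametrize("b", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_rejected(self, b):
        with pytest.raises(ValueError):
            hs.classify_level(b)


class TestVerticalAllometry:
    def test_noiseless_recovery_with_level(self, noiseless_panel):
        fit = hs.vertical_allometry(noiseless_panel, "doctors", 2012)
        assert fit.b == pytest.approx(0.9, abs=1e-9)
        assert fit.level is L.POSITIVE1
        assert fit.orientation == "vertical"
        assert fit.n_used == 41

    def test_level_consistent_with_b(self, default_panel):
        for year in (2009, 2016, 2022):
            fit = hs.vertical_allometry(default_panel, "beds", year)
            assert fit.level is hs.classify_level(fit.b)

    def test_absent_year_raises(self, default_panel):
        with pytest.raises(hs.InsufficientDataError):
            hs.vertical_allometry(default_panel, "beds", 1999)


class TestHorizontalAllometry:
    def _exact_city(self, b, growth=1.05, years=range(2009, 2016)):
        rows = []
        gdp = 100.0
        for year in years:
            rows.append(("X1", "X1", year, gdp, gdp**b, gdp**b))
            gdp *= growth
        return _panel_from_rows(rows)

    def test_exact_power_link_over_time(self):
        fit = hs.horizontal_allometry(self._exact_city(1.3), "beds", "X1", (2009, 2015))
        assert fit.b == pytest.approx(1.3, abs=1e-9)
        assert fit.level is L.POSITIVE2
        assert fit.window == "2009-2015"

    def test_constant_resource_is_negative2(self):
        rows = [("X1", "X1", y, 100.0 * 1.05 ** (y - 2009), 50.0, 50.0) for y in range(2009, 2016)]
        fit = hs.horizontal_allometry(_panel_from_rows(rows), "beds", "X1", (2009, 2015))
        assert fit.b == 0.0
        assert fit.level is L.NEGATIVE2

    def test_toy_series_matches_oracle(self):
        g = [10.0, 12.0, 15.0, 18.0, 22.0]
        a = [20.0, 23.0, 27.0, 31.0, 36.0]
        rows = [("X1", "X1", 2009 + i, g[i], a[i], a[i]) for i in range(5)]
        slope, intercept = ols_normal_equations(np.log(g), np.log(a))
        fit = hs.horizontal_allometry(_panel_from_rows(rows), "beds", "X1", (2009, 2013))
        assert fit.b == pytest.approx(slope, abs=1e-10)
        assert fit.k == pytest.approx(intercept, abs=1e-10)

    def test_endpoint_estimator_growth_ratio(self):
        g = [10.0, 12.0, 15.0, 18.0, 22.0]
        a = [20.0, 23.0, 27.0, 31.0, 36.0]
        rows = [("X1", "X1", 2009 + i, g[i], a[i], a[i]) for i in range(5)]
        fit = hs.horizontal_allometry(
            _panel_from_rows(rows), "beds", "X1", (2009, 2013), estimator="endpoint"
        )
        expected = np.log(a[-1] / a[0]) / np.log(g[-1] / g[0])
        assert fit.b == pytest.approx(expected, abs=1e-12)

    def test_unknown_city_raises_lookup_error(self, default_panel):
        with pytest.raises(KeyError):
            hs.horizontal_allometry(default_panel, "beds", "NOPE", (2009, 2015))

    def test_window_too_short_raises(self, default_panel):
        with pytest.raises(hs.InsufficientDataError):
            hs.horizontal_allometry(default_panel, "beds", "C001", (2009, 2010))


def _fit_with_level(level, city="A", resource="beds"):
    # representative exponent for each band
    b = {L.POSITIVE3: 2.1, L.POSITIVE2: 1.5, L.POSITIVE1: 0.9,
         L.NEGATIVE1: 0.6, L.NEGATIVE2: 0.2, L.NEGATIVE3: -0.4}[level]
    return hs.AllometricFit(
        orientation="horizontal", resource=resource, b=b, k=0.0, r2=1.0,
        n_used=7, level=level, city_id=city, window="w",
    )


class TestChangeTypology:
    def test_exhaustive_transition_table(self):
        for before, after in itertools.product(L, L):
            ch = hs.change_typology(_fit_with_level(before), _fit_with_level(after))
            delta = int(after) - int(before)
            assert ch.grade_delta == delta
            expected = (
                "stable" if delta == 0
                else "upgrade" if delta == 1
                else "fast_upgrade" if delta >= 2
                else "decline" if delta == -1
                else "fast_decline"
            )
            assert ch.change_type == expected
            assert (abs(delta) >= 2) == (ch.change_type in ("fast_upgrade", "fast_decline"))

    def test_delta_antisymmetric(self):
        for before, after in itertools.product(L, L):
            fwd = hs.change_typology(_fit_with_level(before), _fit_with_level(after))
            rev = hs.change_typology(_fit_with_level(after), _fit_with_level(before))
            assert fwd.grade_delta == -rev.grade_delta

    def test_mismatched_city_or_resource_rejected(self):
        a = _fit_with_level(L.POSITIVE2, city="A")
        b = _fit_with_level(L.POSITIVE2, city="B")
        with pytest.raises(hs.ContractError):
            hs.change_typology(a, b)
        c = _fit_with_level(L.POSITIVE2, resource="doctors")
        with pytest.raises(hs.ContractError):
            hs.change_typology(a, c)


class TestWindowSummary:
    def _changes(self, kinds):
        out = []
        deltas = {"stable": 0, "upgrade": 1, "fast_upgrade": 2, "decline": -1, "fast_decline": -2}
        for i, kind in enumerate(kinds):
            out.append(
                hs.AllometricChange(
                    city_id=f"C{i}", resource="beds",
                    level_before=L.POSITIVE2,
                    level_after=L(int(L.POSITIVE2) + deltas[kind]),
                    grade_delta=deltas[kind], change_type=kind,
                )
            )
        return out

    def test_nineteen_of_fortyone_changed_share(self):
        kinds = ["upgrade"] * 11 + ["decline"] * 8 + ["stable"] * 22
        summ = hs.window_summary(self._changes(kinds))
        assert summ["n"] == 41
        assert summ["n_changed"] == 19
        assert summ["changed_share"] == 46.34

    def test_all_stable(self):
        summ = hs.window_summary(self._changes(["stable"] * 5))
        assert summ["change_type"]["stable"]["share"] == 100.0
        assert summ["change_type"]["upgrade"]["share"] == 0.0
        assert summ["change_type"]["fast_decline"]["share"] == 0.0

    def test_equal_thirds(self):
        summ = hs.window_summary(self._changes(["stable", "upgrade", "fast_decline"]))
        for kind in ("stable", "upgrade", "fast_decline"):
            assert summ["change_type"][kind]["share"] == 33.33

    def test_shares_sum_to_100_within_rounding(self):
        kinds = ["stable"] * 3 + ["upgrade"] * 2 + ["decline"] * 2
        summ = hs.window_summary(self._changes(kinds))
        total = sum(v["share"] for v in summ["change_type"].values())
        assert total == pytest.approx(100.0, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(hs.InsufficientDataError):
            hs.window_summary([])
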