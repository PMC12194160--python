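import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aviclim import timeseries as ts
from aviclim import windows
from aviclim.errors import NoResultError, UndefinedCorrelationError


def exact_spearman(x, y):
    """Tie-free oracle: 1 - 6 sum(d^2) / (n (n^2 - 1))."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    n = len(x)
    return 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))


def midrank(v):
    """Average ranks (ties get the mean rank), brute force."""
    v = np.asarray(v, dtype=float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        out[i] = less + (equal + 1) / 2.0
    return out


class TestEnumerateWindows:
    @pytest.mark.parametrize("variable", ts.CLIMATE_VARIABLES)
    @pytest.mark.parametrize("season", ts.SEASONS)
    def test_144_unique_candidates(self, variable, season):
        wins = windows.enumerate_windows(variable, season)
        assert len(wins) == 144
        keys = {(w.duration, w.end_month, w.year_offset) for w in wins}
        assert len(keys) == 144
        assert {w.duration for w in wins} == set(range(1, 13))
        assert {w.end_month for w in wins} == set(range(1, 13))

    def test_wintering_set_contains_table_style_window(self):
        # a 12-month drought-index window ending in April of the focal year
        wins = windows.enumerate_windows("spei", ts.WINTERING)
        assert any(
            w.duration == 12 and w.end_month == 4 and w.year_offset == -1
            for w in wins
        )

    def test_aggregation_follows_variable(self):
        assert all(w.agg == "sum" for w in windows.enumerate_windows("precip"))
        assert all(w.agg == "mean" for w in windows.enumerate_windows("tm"))

    def test_positions_step_back_from_season_end(self):
        wins = windows.enumerate_windows("tm", ts.BREEDING)
        steps = sorted({windows.steps_back(w, ts.BREEDING) for w in wins})
        assert steps == list(range(12))

    def test_duplicate_year_anchor_variant_doubles_the_set(self):
        wins = windows.enumerate_windows(
            "tm", ts.BREEDING, duplicate_year_anchors=True
        )
        assert len(wins) == 288

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            windows.enumerate_windows("humidity")


class TestWindowValue:
    def test_constant_spei_mean(self, flat_climate):
        w = windows.CandidateWindow("spei", 6, 8, 0)
        assert windows.window_value(flat_climate, w, 2001, ts.BREEDING) == 0.5

    def test_precip_sums(self, flat_climate):
        w = windows.CandidateWindow("precip", 3, 8, 0)
        assert windows.window_value(flat_climate, w, 2001, ts.BREEDING) == 30.0

    def test_month_index_mean(self, month_index_climate):
        w = windows.CandidateWindow("tm", 2, 12, 0)
        # November and December of the wintering reference year
        val = windows.window_value(
            month_index_climate, w, 2001, ts.BREEDING
        )
        assert val == 11.5

    def test_span_before_series_start_is_missing(self, flat_climate):
        w = windows.CandidateWindow("tm", 12, 3, 0)
        assert np.isnan(windows.window_value(flat_climate, w, 2000, ts.BREEDING))

    def test_series_matches_scalar(self, month_index_climate):
        w = windows.CandidateWindow("tm", 4, 6, 0)
        series = windows.window_value_series(
            month_index_climate, w, [2001, 2002], ts.BREEDING
        )
        scalars = [
            windows.window_value(month_index_climate, w, sy, ts.BREEDING)
            for sy in (2001, 2002)
        ]
        np.testing.assert_allclose(series, scalars)

    def test_wintering_anchor_uses_following_calendar_year(self, month_index_climate):
        # wintering season 2001 ends in February 2002; a 1-month window at
        # end_month 2, offset 0 must read February of 2002
        w = windows.CandidateWindow("tm", 1, 2, 0)
        assert windows.window_value(month_index_climate, w, 2001, ts.WINTERING) == 2.0


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = windows.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        rho, _ = windows.spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([3.0, 1.0, 4.0, 2.0])
        rho, _ = windows.spearman_correlation(x, y)
        rx, ry = midrank(x), midrank(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            windows.spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pairwise_deletion(self):
        rho, _ = windows.spearman_correlation(
            [1, 2, np.nan, 3, 4], [2, 4, 5, 6, 8]
        )
        assert rho == pytest.approx(1.0)

    @given(
        perm=st.permutations(list(range(8))),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_exact_formula_without_ties(self, perm):
        x = np.arange(8.0)
        y = np.array(perm, dtype=float)
        rho, _ = windows.spearman_correlation(x, y)
        assert rho == pytest.approx(exact_spearman(x, y), abs=1e-12)

    @given(
        data=st.lists(
            st.tuples(st.integers(-100, 100), st.integers(-100, 100)),
            min_size=5,
            max_size=12,
            unique_by=(lambda t: t[0], lambda t: t[1]),
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, data):
        x = np.array([t[0] for t in data], dtype=float)
        y = np.array([t[1] for t in data], dtype=float)
        rho1, _ = windows.spearman_correlation(x, y)
        rho2, _ = windows.spearman_correlation(np.exp(x / 50), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-9)


def _abundance_frame(species, season, season_years, values):
    return pd.DataFrame(
        {
            "species": species,
            "season": season,
            "season_year": season_years,
            "value": values,
        }
    )


class TestScan:
    def test_scan_is_exhaustive(self, synthetic_tables):
        counts = synthetic_tables["counts"]
        climate = synthetic_tables["climate"]
        abund = ts.seasonal_abundance(counts, ts.BREEDING, drop_incomplete=True)
        sub = abund[abund["species"] == "O_leucocephala"]
        best = windows.scan_best_window(sub, climate, "spei", season=ts.BREEDING)
        # brute-force re-scan: no candidate beats the returned |rho|
        sy = sub["season_year"].to_numpy()
        ab = sub["value"].to_numpy()
        for w in windows.enumerate_windows("spei", ts.BREEDING):
            wv = windows.window_value_series(climate, w, sy, ts.BREEDING)
            keep = ~np.isnan(wv)
            if keep.sum() < 8:
                continue
            rho, _ = windows.spearman_correlation(ab[keep], wv[keep])
            assert abs(rho) <= abs(best.rho) + 1e-12

    def test_sign_flip_keeps_selected_window(self, synthetic_tables):
        counts = synthetic_tables["counts"]
        climate = synthetic_tables["climate"]
        abund = ts.seasonal_abundance(counts, ts.BREEDING, drop_incomplete=True)
        sub = abund[abund["species"] == "O_leucocephala"].copy()
        best = windows.scan_best_window(sub, climate, "spei", season=ts.BREEDING)
        flipped = sub.copy()
        flipped["value"] = -flipped["value"]
        best_f = windows.scan_best_window(
            flipped, climate, "spei", season=ts.BREEDING
        )
        assert best_f.window == best.window
        assert best_f.rho == pytest.approx(-best.rho, abs=1e-12)

    def test_degenerate_single_candidate_equals_direct_correlation(
        self, synthetic_tables, monkeypatch
    ):
        climate = synthetic_tables["climate"]
        counts = synthetic_tables["counts"]
        abund = ts.seasonal_abundance(counts, ts.BREEDING, drop_incomplete=True)
        sub = abund[abund["species"] == "A_nyroca"]
        w = windows.CandidateWindow("tm", 1, 8, 0)
        monkeypatch.setattr(
            windows, "enumerate_windows", lambda *a, **k: [w]
        )
        best = windows.scan_best_window(sub, climate, "tm", season=ts.BREEDING)
        wv = windows.window_value_series(
            climate, w, sub["season_year"].to_numpy(), ts.BREEDING
        )
        rho, p = windows.spearman_correlation(sub["value"].to_numpy(), wv)
        assert best.window == w
        assert best.rho == pytest.approx(rho, abs=1e-12)
        assert best.p_value == pytest.approx(p, abs=1e-12)

    def test_all_candidates_undefined_raises(self, flat_climate):
        sub = _abundance_frame(
            "sp", ts.BREEDING, list(range(2001, 2010)), list(range(9))
        )
        # constant spei gives zero variance in every candidate
        with pytest.raises(NoResultError):
            windows.scan_best_window(sub, flat_climate, "spei", season=ts.BREEDING)


class TestSelectBestVariable:
    def _result(self, variable, rho):
        return windows.WindowScanResult(
            "sp", ts.BREEDING, variable,
            windows.CandidateWindow(variable, 1, 8, 0), rho, 0.05, 18,
        )

    def test_argmax(self):
        results = [
            self._result("tm", 0.2),
            self._result("tmax", 0.7),
            self._result("precip", -0.5),
        ]
        assert windows.select_best_variable(results).variable == "tmax"

    def test_singleton(self):
        r = self._result("tmin", 0.3)
        assert windows.select_best_variable([r]) is r

    def test_tie_prefers_drought_index_with_warning(self):
        results = [self._result("tmax", 0.6), self._result("spei", -0.6)]
        with pytest.warns(UserWarning, match="tie"):
            best = windows.select_best_variable(results)
        assert best.variable == "spei"

    def test_empty_raises(self):
        with pytest.raises(NoResultError):
            windows.select_best_variable([])


def test_scan_table_columns():
    w = windows.CandidateWindow("spei", 12, 3, 0)
    r = windows.WindowScanResult("sp", ts.BREEDING, "spei", w, 0.7, 0.001, 18)
    table = windows.scan_table([r])
    assert list(table.columns) == [
        "season", "species", "corr_coef", "p", "variable",
        "window_duration", "window_location", "year_offset", "n_years",
    ]
    assert table.loc[0, "window_location"] == 3
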