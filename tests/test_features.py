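import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollencast.features import (
    EmaSpec,
    WindowSpec,
    build_sequence_dataset,
    build_tabular_dataset,
    ema,
    ema_feature_block,
    ema_series,
    lag_indices,
)
from pollencast.io_ingest import extract_seasons
from pollencast.metrics import scheme_for


def ema_oracle(values, alpha):
    """Direct evaluation of the weighted-sum definition."""
    num = den = 0.0
    for k, x in enumerate(reversed(values)):
        w = (1.0 - alpha) ** k
        num += w * x
        den += w
    return num / den


class TestEma:
    def test_constant_series(self):
        assert ema([5, 5, 5], 0.3) == pytest.approx(5.0)

    def test_alpha_one_puts_all_weight_on_newest(self):
        assert ema([1, 2, 3], 1.0) == pytest.approx(3.0)

    def test_hand_computed_value(self):
        assert ema([1, 2, 3], 0.5) == pytest.approx(4.25 / 1.75)

    @pytest.mark.parametrize("bad", [[], None])
    def test_empty_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            ema(bad or [], 0.5)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_out_of_range_rejected(self, alpha):
        with pytest.raises(ValueError):
            ema([1.0], alpha)

    @settings(derandomize=True, max_examples=60)
    @given(
        values=st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=40),
        alpha=st.floats(0.01, 1.0),
    )
    def test_matches_direct_summation_oracle(self, values, alpha):
        assert ema(values, alpha) == pytest.approx(ema_oracle(values, alpha), abs=1e-9)

    def test_ema_series_agrees_with_scalar_windows(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        out = ema_series(x, 7)
        a = EmaSpec(7).effective_alpha
        for i in range(6, 60):
            assert out[i] == pytest.approx(ema(x[i - 6 : i + 1], a), abs=1e-12)
        assert np.isnan(out[:6]).all()


class TestEmaFeatureBlock:
    def test_constant_series_gives_neutral_ratios(self):
        e3, e7, e20, r13, r37, r720 = ema_feature_block([4.0] * 25, 24)
        assert (e3, e7, e20) == pytest.approx((4.0, 4.0, 4.0))
        assert (r13, r37, r720) == pytest.approx((1.0, 1.0, 1.0))

    def test_zero_series_emits_neutral_ratios(self):
        block = ema_feature_block([0.0] * 25, 24)
        assert block == pytest.approx((0.0, 0.0, 0.0, 1.0, 1.0, 1.0))

    def test_increasing_series_has_ratios_above_one(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.uniform(0.5, 2.0, 40)) + 1.0
        _, _, _, r13, r37, _ = ema_feature_block(x, 39)
        assert r13 > 1.0 and r37 > 1.0

    def test_short_history_rejected(self):
        with pytest.raises(ValueError):
            ema_feature_block([1.0] * 10, 9)


class TestLagIndices:
    @pytest.mark.parametrize(
        "w, n, expected_first, expected_last, expected_len",
        [(14, 4, 18, 4, 15), (1, 1, 2, 1, 2), (20, 7, 27, 7, 21)],
    )
    def test_window_geometry(self, w, n, expected_first, expected_last, expected_len):
        lags = lag_indices(WindowSpec(w=w, n=n))
        assert lags[0] == expected_first
        assert lags[-1] == expected_last
        assert len(lags) == expected_len

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(w=0, n=1)


def _index_valued_fixture(season_days=120):
    """Pollen concentration equal to the running day index + 1: any leakage
    shows up as a lag column differing from (target index - lag)."""
    dates = pd.date_range("2022-01-01", "2022-12-31", freq="D")
    conc = np.zeros(len(dates))
    start = 90
    conc[start : start + season_days] = np.arange(1.0, season_days + 1.0)
    pollen = pd.DataFrame({"date": dates, "taxon": "Betula", "concentration": conc})
    meteo = pd.DataFrame({"date": dates})
    for v, base in (("tg", 120), ("tn", 60), ("tx", 180), ("hu", 60), ("cc", 4),
                    ("ss", 40), ("fg", 30), ("pp", 10130), ("qq", 150), ("sd", 0)):
        meteo[v] = pd.array([base] * len(dates), dtype="Int64")
    return extract_seasons(pollen), meteo


class TestBuildTabular:
    @pytest.mark.parametrize("n", [1, 4, 7])
    def test_pollen_inputs_predate_target_by_horizon(self, n):
        seasons, meteo = _index_valued_fixture()
        table = build_tabular_dataset(seasons, meteo, WindowSpec(14, n), scheme_for("Betula"))
        assert len(table) > 0
        # concentration equals the in-season day index, so wherever the
        # lagged day is inside the season the raw lag value must sit exactly
        # n days behind the target; earlier lags are pre-season zeros
        inside = table["target"] > n
        assert inside.any()
        assert (table.loc[inside, "target"] - table.loc[inside, f"pollen__lag{n}"] == n).all()
        assert (table.loc[~inside, f"pollen__lag{n}"] == 0).all()

    def test_longer_horizon_never_gains_rows(self, betula_seasons, betula_ds, betula_scheme):
        t1 = build_tabular_dataset(betula_seasons, betula_ds.meteo, WindowSpec(7, 1), betula_scheme)
        t7 = build_tabular_dataset(betula_seasons, betula_ds.meteo, WindowSpec(7, 7), betula_scheme)
        assert len(t7) <= len(t1)

    def test_row_count_matches_brute_force_eligibility(self, betula_seasons, betula_ds, betula_scheme):
        n = 4
        table = build_tabular_dataset(betula_seasons, betula_ds.meteo, WindowSpec(7, n), betula_scheme)
        first_day = betula_ds.meteo["date"].min()
        eligible = 0
        for s in betula_seasons:
            for d in s.records["date"]:
                history = (d - first_day).days  # contiguous daily panel
                if history - n >= 19 and history >= 19:
                    eligible += 1
        assert len(table) == eligible

    def test_no_missing_values_in_rows(self, betula_seasons, betula_ds, betula_scheme):
        table = build_tabular_dataset(betula_seasons, betula_ds.meteo, WindowSpec(7, 1), betula_scheme)
        assert not table.drop(columns="target_class").isna().any().any()
        assert set(table["target_class"]) <= {"low", "medium", "high"}


class TestBuildSequence:
    def test_shapes_for_printed_example(self, betula_seasons, betula_ds, betula_scheme):
        seq = build_sequence_dataset(betula_seasons, betula_ds.meteo, WindowSpec(14, 4), betula_scheme)
        assert seq.pollen.shape[1:] == (14,)
        assert seq.meteo.shape[1:] == (19, 10)

    def test_smallest_window(self, betula_seasons, betula_ds, betula_scheme):
        seq = build_sequence_dataset(betula_seasons, betula_ds.meteo, WindowSpec(1, 1), betula_scheme)
        assert seq.pollen.shape[1:] == (1,)
        assert seq.meteo.shape[1:] == (3, 10)

    @pytest.mark.parametrize("n", [1, 4])
    def test_pollen_lags_end_horizon_days_before_target(self, n):
        seasons, meteo = _index_valued_fixture()
        seq = build_sequence_dataset(seasons, meteo, WindowSpec(5, n), scheme_for("Betula"))
        # newest pollen lag is the last vector entry: exactly n behind the
        # target wherever the lagged day is inside the season
        inside = seq.target > n
        assert inside.any()
        assert np.all(seq.target[inside] - seq.pollen[inside, -1] == n)
        # oldest is n + w - 1 behind
        oldest_in = seq.target > n + 5 - 1
        assert np.all(seq.target[oldest_in] - seq.pollen[oldest_in, 0] == n + 5 - 1)

    def test_shuffled_source_rows_give_identical_datasets(self, betula_ds, betula_scheme):
        rng = np.random.default_rng(0)
        shuffled = betula_ds.meteo.sample(frac=1.0, random_state=1).reset_index(drop=True)
        seasons = extract_seasons(betula_ds.pollen.sample(frac=1.0, random_state=2))
        a = build_sequence_dataset(seasons, shuffled, WindowSpec(7, 1), betula_scheme)
        b = build_sequence_dataset(
            extract_seasons(betula_ds.pollen), betula_ds.meteo, WindowSpec(7, 1), betula_scheme
        )
        np.testing.assert_array_equal(a.pollen, b.pollen)
        np.testing.assert_array_equal(a.meteo, b.meteo)
        np.testing.assert_array_equal(a.target, b.target)
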