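import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sslseascape import dvm
from sslseascape import preprocess as sp
from sslseascape import synthetic as ssyn
from sslseascape.io import ValidationError

from _oracles import michalsky_altitude, pearson_direct, wmd_direct


class TestSolarAltitude:
    def test_equator_equinox_noon_near_zenith(self):
        # 2021 March equinox; solar noon at Greenwich is ~12:07 UTC.  Near the
        # zenith the altitude is maximally sensitive to small ephemeris errors,
        # so take the maximum over the transit window.
        times = np.datetime64("2021-03-20T12:00:00") + np.arange(16) * np.timedelta64(60, "s")
        alt = dvm.solar_altitude(times, 0.0, 0.0)
        assert float(alt.max()) == pytest.approx(90.0, abs=0.5)

    def test_matches_independent_ephemeris_at_cruise_start(self):
        t = np.datetime64("2021-12-11T13:00:00")
        assert dvm.solar_altitude(t, 28.0, -15.5) == pytest.approx(
            michalsky_altitude(t, 28.0, -15.5), abs=0.3
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_spot_checks_against_ephemeris(self, seed):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(-60, 60)
        lon = rng.uniform(-180, 180)
        t = np.datetime64("2021-12-11T00:00:00") + np.timedelta64(int(rng.integers(0, 32 * 24 * 60)), "m")
        assert dvm.solar_altitude(t, lat, lon) == pytest.approx(michalsky_altitude(t, lat, lon), abs=0.3)

    def test_daily_periodicity(self):
        t0 = np.datetime64("2021-12-15T10:00:00")
        a0 = dvm.solar_altitude(t0, 18.0, -25.0)
        a1 = dvm.solar_altitude(t0 + np.timedelta64(24, "h"), 18.0, -25.0)
        assert abs(a1 - a0) < 1.0


class TestClassifyDiel:
    @pytest.mark.parametrize("alt,expected", [(30.0, "day"), (-30.0, "night"), (18.0, "transition"),
                                              (-18.0, "transition"), (0.0, "transition")])
    def test_threshold_convention(self, alt, expected):
        assert dvm.classify_diel(alt) == expected

    def test_partition_of_a_tropical_day(self, at_full_day, at_day_labels):
        labels = at_day_labels
        counts = {k: int(np.sum(labels == k)) for k in ("day", "night", "transition")}
        assert sum(counts.values()) == at_full_day[38].n_cols
        assert all(v > 0 for v in counts.values())


class TestMeanProfiles:
    def test_identical_fields_give_zero_delta(self, toy_grid):
        toy_grid.cell_sv[:] = -65.0
        labels = np.array(["day", "day", "day", "night", "night", "night"], dtype=object)
        prof = dvm.mean_profiles(toy_grid, labels)
        np.testing.assert_allclose(prof.delta, 0.0, atol=1e-9)

    def test_single_bin_delta(self, toy_grid):
        toy_grid.cell_sv[:] = np.nan
        toy_grid.cell_sv[0, 0], toy_grid.cell_sv[0, 1] = -70.0, -60.0
        labels = np.array(["day", "night", "transition", "transition", "transition", "transition"], dtype=object)
        prof = dvm.mean_profiles(toy_grid, labels)
        assert prof.delta[0] == pytest.approx(10.0, abs=1e-9)

    def test_requires_both_phases(self, toy_grid):
        labels = np.array(["day"] * 6, dtype=object)
        with pytest.raises(ValidationError):
            dvm.mean_profiles(toy_grid, labels)

    def test_migration_sign_pattern(self, at_full_day, at_day_labels):
        # above the migration midpoint the layer is present at night -> delta > 0;
        # below, it is present by day -> delta < 0
        prof = dvm.mean_profiles(at_full_day[38], at_day_labels)
        mid = (ssyn.AT.layers[0].day_center_depth + ssyn.AT.layers[0].night_center_depth) / 2
        z = prof.depth_bins
        upper = (z > 30) & (z < mid - 50)
        lower = (z > mid + 50) & (z < 560)
        assert np.nanmean(prof.delta[upper] > 0) > 0.95
        assert np.nanmean(prof.delta[lower] < 0) > 0.95


class TestWMD:
    def test_symmetric_gaussian_layer(self):
        z = np.arange(800) + 0.5
        sv = sp.linear_to_db(1e-7 * np.exp(-((z - 400.0) ** 2) / (2 * 30.0**2)))
        g = _single_column_grid(sv, z)
        assert dvm.compute_wmd(g).wmd[0] == pytest.approx(400.0, abs=1.0)

    def test_two_equal_cells(self):
        z = np.array([100.0, 300.0])
        g = _single_column_grid(np.array([-70.0, -70.0]), z)
        assert dvm.compute_wmd(g).wmd[0] == pytest.approx(200.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(17)
        z = np.arange(100) + 0.5
        sv = rng.uniform(-90, -55, 100)
        sv[rng.random(100) < 0.2] = np.nan
        g = _single_column_grid(sv, z)
        assert dvm.compute_wmd(g).wmd[0] == pytest.approx(wmd_direct(sv, z), rel=1e-12)

    @given(st.floats(min_value=-20, max_value=20, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_db_offset_invariance(self, shift):
        z = np.arange(50) + 0.5
        rng = np.random.default_rng(4)
        sv = rng.uniform(-90, -55, 50)
        a = dvm.compute_wmd(_single_column_grid(sv, z)).wmd[0]
        b = dvm.compute_wmd(_single_column_grid(sv + shift, z)).wmd[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_missing_column_is_nan(self):
        g = _single_column_grid(np.full(10, np.nan), np.arange(10) + 0.5)
        assert np.isnan(dvm.compute_wmd(g).wmd[0])

    def test_within_populated_depth_range(self, at_full_day):
        series = dvm.compute_wmd(at_full_day[38])
        g = at_full_day[38]
        assert np.all(series.wmd >= g.depth_bins[0]) and np.all(series.wmd <= g.depth_bins[-1])


class TestCrossFrequency:
    def _series(self, values, t0="2021-12-15T12:00:00"):
        n = len(values)
        times = np.datetime64(t0) + np.arange(n) * np.timedelta64(60, "s")
        return dvm.WMDSeries(np.asarray(values, float), times, np.zeros(n), np.zeros(n))

    def test_identical_series_r_one(self):
        s = self._series([100.0, 200.0, 300.0, 250.0])
        labels = np.array(["day", "day", "night", "night"], dtype=object)
        out = dvm.cross_frequency_validation(s, s, labels)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_mirrored_series_r_minus_one(self):
        a = self._series([100.0, 200.0, 300.0, 250.0])
        b = self._series([-100.0, -200.0, -300.0, -250.0])
        labels = np.array(["day"] * 4, dtype=object)
        out = dvm.cross_frequency_validation(a, b, labels)
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(200, 40, 50), rng.normal(300, 60, 50)
        out = dvm.cross_frequency_validation(self._series(x), self._series(y), np.array(["day"] * 50, dtype=object))
        assert out["pearson_r"] == pytest.approx(pearson_direct(x, y), rel=1e-12)

    def test_too_few_pairs_rejected(self):
        s = self._series([100.0, 200.0])
        with pytest.raises(ValidationError):
            dvm.cross_frequency_validation(s, s, np.array(["day", "night"], dtype=object))

    def test_dvm_amplitude_recovers_configured_migration(self, at_full_day, at_day_labels):
        w18 = dvm.compute_wmd(at_full_day[18], threshold_db=-70.0)
        w38 = dvm.compute_wmd(at_full_day[38], threshold_db=-70.0)
        out = dvm.cross_frequency_validation(w18, w38, at_day_labels)
        configured = ssyn.AT.layers[0].night_center_depth - ssyn.AT.layers[0].day_center_depth
        assert out["amplitude_day_night_18"] == pytest.approx(configured, abs=5.0)
        assert out["amplitude_day_night_38"] == pytest.approx(configured, abs=5.0)
        assert out["pearson_r"] > 0.99


def _single_column_grid(sv, depth_bins):
    return sp.IntegrationGrid(
        frequency_khz=38.0,
        cell_sv=np.asarray(sv, float)[:, None],
        depth_bins=np.asarray(depth_bins, float),
        depth_bin_m=float(depth_bins[1] - depth_bins[0]) if len(depth_bins) > 1 else 1.0,
        cell_distance_nmi=0.1,
        cell_start_nmi=np.zeros(1),
        cell_time=np.array([np.datetime64("2021-12-15T12:00:00")]),
        cell_lat=np.zeros(1),
        cell_lon=np.zeros(1),
        n_samples=np.ones((len(depth_bins), 1), dtype=int),
    )
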