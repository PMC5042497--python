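from datetime import date

import numpy as np
import pandas as pd
import pytest

from nichekit.activity import (ActivitySample, CircularActivity, SunClock,
                               activity_isopleth, activity_overlap,
                               camera_summary, circular_kde, overlap_matrix,
                               solar_times, sun_adjust, sun_adjust_records)
from nichekit.io import CameraRecord
from nichekit.simulate import ActivityMixtureConfig, generate_activity_times


def _isopleth_from_mask(mask, level=0.95):
    from nichekit.activity import ActivityIsopleth
    mask = np.asarray(mask, dtype=bool)
    return ActivityIsopleth(level=level, selected=mask,
                            grid_step=24.0 / len(mask))


class TestSolar:
    def test_equator_equinox(self):
        sc = solar_times(0.0, 0.0, date(2007, 3, 20))
        assert sc.sunrise == pytest.approx(6.0, abs=10 / 60)
        assert sc.sunset == pytest.approx(18.0, abs=12 / 60)

    def test_southern_site_december_solstice_long_day(self):
        sc = solar_times(-18.98, -56.65, date(2006, 12, 21), utc_offset=-4.0)
        assert sc.day_length > 12.0

    def test_sunrise_before_noon_before_sunset(self):
        for m in range(1, 13):
            sc = solar_times(-18.98, -56.65, date(2007, m, 15),
                             utc_offset=-4.0)
            assert sc.sunrise < 12.5 < sc.sunset

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            solar_times(70.0, 0.0, date(2007, 6, 21))


class TestSunAdjust:
    def test_identity_on_equinoctial_day(self):
        sun = SunClock(date(2007, 1, 1), 6.0, 18.0, 0.0, 0.0)
        for t in [0.0, 3.5, 6.0, 12.0, 18.0, 23.9]:
            assert sun_adjust(t, sun) == pytest.approx(t % 24.0, abs=1e-9)

    def test_daytime_formula(self):
        sun = SunClock(date(2007, 1, 1), 5.0, 19.0, 0.0, 0.0)
        assert sun_adjust(8.0, sun) == pytest.approx(6 + 12 * 3 / 14)

    def test_anchors_exact(self):
        for sr, ss in [(5.0, 19.0), (6.5, 17.2), (4.9, 18.01)]:
            sun = SunClock(date(2007, 1, 1), sr, ss, 0.0, 0.0)
            assert sun_adjust(sr, sun) == pytest.approx(6.0)
            assert sun_adjust(ss, sun) == pytest.approx(18.0)

    def test_circular_bijection_strictly_increasing(self):
        sun = SunClock(date(2007, 1, 1), 5.25, 18.75, 0.0, 0.0)
        t = np.linspace(5.25, 5.25 + 24, 2000, endpoint=False)
        s = np.array([sun_adjust(v, sun) for v in t])
        unwrapped = np.where(s >= 6.0, s, s + 24.0)  # start at sunrise
        assert np.all(np.diff(unwrapped) > 0)
        assert unwrapped[-1] - unwrapped[0] < 24.0

    def test_record_batch_matches_scalar(self):
        ts = pd.to_datetime(["2007-06-15 08:30:00", "2007-06-15 22:00:00"])
        out = sun_adjust_records(ts, -18.98, -56.65, utc_offset=-4.0)
        sun = solar_times(-18.98, -56.65, date(2007, 6, 15), utc_offset=-4.0)
        assert out[0] == pytest.approx(sun_adjust(8.5, sun))
        assert out[1] == pytest.approx(sun_adjust(22.0, sun))


class TestCircularKde:
    def test_uniform_limit(self, rng):
        d = circular_kde(ActivitySample("u", rng.uniform(0, 24, 2000)))
        assert np.abs(d.density - 1 / 24).max() < 0.01
        assert d.mass() == pytest.approx(1.0, abs=1e-6)

    def test_unimodal_recovery(self):
        mix = ActivityMixtureConfig("x", ((2.0, 8.0, 1.0),))
        t = generate_activity_times(mix, 2000, seed=7)
        d = circular_kde(ActivitySample("x", t))
        delta = (d.mode_hour() - 2.0 + 12) % 24 - 12
        assert abs(delta) < 0.25

    def test_mass_is_one_and_periodic(self, rng):
        d = circular_kde(ActivitySample("x", rng.uniform(0, 24, 200)),
                         kappa=8.0)
        assert d.mass() == pytest.approx(1.0, abs=1e-9)
        # density at 0 and just below 24 must agree (periodicity)
        assert d.density[0] == pytest.approx(d.density[-1], rel=0.05)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">= 10"):
            circular_kde(ActivitySample("x", np.arange(5)))

    def test_identical_observations_warn_max_kappa(self):
        with pytest.warns(UserWarning, match="identical"):
            d = circular_kde(ActivitySample("x", np.full(20, 3.0)))
        assert d.kappa == 1024.0

    def test_rotation_equivariance(self, rng):
        t = rng.vonmises(0.0, 4.0, 400) * 24 / (2 * np.pi) % 24
        d1 = circular_kde(ActivitySample("a", t), kappa=32.0)
        d2 = circular_kde(ActivitySample("a", (t + 6.0) % 24), kappa=32.0)
        shift = int(6.0 / d1.grid_step)
        np.testing.assert_allclose(np.roll(d1.density, shift), d2.density,
                                   rtol=1e-9)


class TestIsopleth:
    def test_uniform_half_mass_half_day(self, rng):
        d = circular_kde(ActivitySample("u", rng.uniform(0, 24, 3000)))
        iso = activity_isopleth(d, 0.5)
        assert iso.total_duration == pytest.approx(12.0, abs=0.5)

    def test_unimodal_single_interval_contains_mode(self):
        mix = ActivityMixtureConfig("x", ((14.0, 6.0, 1.0),))
        d = circular_kde(ActivitySample(
            "x", generate_activity_times(mix, 800, seed=1)), kappa=16.0)
        iso = activity_isopleth(d, 0.5)
        assert len(iso.intervals) == 1
        (s, e), = iso.intervals
        assert s <= d.mode_hour() <= e

    def test_nesting(self):
        mix = ActivityMixtureConfig("x", ((20.0, 3.0, 0.6), (6.0, 3.0, 0.4)))
        d = circular_kde(ActivitySample(
            "x", generate_activity_times(mix, 600, seed=2)), kappa=8.0)
        i50 = activity_isopleth(d, 0.5)
        i95 = activity_isopleth(d, 0.95)
        assert np.all(i95.selected[i50.selected])

    def test_wrapping_interval_reported_past_midnight(self):
        mix = ActivityMixtureConfig("x", ((0.0, 8.0, 1.0),))
        d = circular_kde(ActivitySample(
            "x", generate_activity_times(mix, 800, seed=3)), kappa=8.0)
        iso = activity_isopleth(d, 0.5)
        assert len(iso.intervals) == 1
        (s, e), = iso.intervals
        assert s > 12.0 and e > 24.0   # e.g. (22.1, 25.9)


class TestOverlap:
    def test_identity_and_disjoint(self):
        a = _isopleth_from_mask([1, 1, 0, 0] * 360)
        assert activity_overlap(a, a)["percent"] == 100.0
        b = _isopleth_from_mask([0, 0, 1, 1] * 360)
        assert activity_overlap(a, b)["percent"] == 0.0

    def test_interval_arithmetic(self):
        m = 1440
        a = np.zeros(m, bool); a[: m // 2] = True            # [0, 12)
        b = np.zeros(m, bool); b[m // 4: 3 * m // 4] = True  # [6, 18)
        out = activity_overlap(_isopleth_from_mask(a), _isopleth_from_mask(b))
        assert out["percent"] == pytest.approx(100 * 6 / 18, abs=0.1)
        assert out["a_in_b"] == pytest.approx(50.0, abs=0.1)

    def test_symmetry_and_bounds(self, rng):
        a = _isopleth_from_mask(rng.random(1440) < 0.4)
        b = _isopleth_from_mask(rng.random(1440) < 0.6)
        ab = activity_overlap(a, b)["percent"]
        ba = activity_overlap(b, a)["percent"]
        assert ab == ba and 0 <= ab <= 100

    def test_matrix_symmetric_unit_diagonal(self, rng):
        iso = {s: _isopleth_from_mask(rng.random(1440) < 0.5)
               for s in "abc"}
        m = overlap_matrix(iso)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 100.0)


class TestCameraSummary:
    def test_published_shares(self):
        records = []
        for sp, n in [("crab-eating fox", 1176), ("brown-nosed coati", 419),
                      ("crab-eating raccoon", 77), ("ocelot", 68),
                      ("other", 33)]:
            records += [CameraRecord("S1", sp, pd.Timestamp("2007-02-01"))
                        ] * n
        out = camera_summary(records, trap_days=2238).set_index("species")
        assert out["n"].sum() == 1773
        assert round(out.loc["crab-eating fox", "percent"]) == 66
        assert round(out.loc["brown-nosed coati", "percent"]) == 24
        assert out.loc["crab-eating fox", "per_100_trap_days"] == \
            pytest.approx(100 * 1176 / 2238)

    def test_empty(self):
        out = camera_summary([])
        assert out.empty


class TestModelFrontEnd:
    def test_fit_summary_and_kappa(self):
        mix = ActivityMixtureConfig("fox", ((20.0, 4.0, 1.0),))
        t = generate_activity_times(mix, 400, seed=9)
        res = CircularActivity(ActivitySample("fox", t)).fit()
        assert res.kappa > 0
        tab = res.summary()
        assert set(tab["level"]) == {0.95, 0.5}
        assert (tab.set_index("level").loc[0.5, "active_hours"]
                < tab.set_index("level").loc[0.95, "active_hours"])

    def test_polar_plot_smoke(self):
        import matplotlib
        matplotlib.use("Agg")
        mix = ActivityMixtureConfig("fox", ((20.0, 4.0, 1.0),))
        res = CircularActivity(ActivitySample(
            "fox", generate_activity_times(mix, 50, seed=0))).fit(kappa=8.0)
        ax = res.plot()
        assert ax.get_title() == "fox"

    def test_from_records_sun_adjusts(self):
        ts = pd.date_range("2007-06-01 20:00", periods=30, freq="D")
        recs = [CameraRecord("S1", "fox", t) for t in ts]
        model = CircularActivity.from_records(recs, "fox", -18.98, -56.65,
                                              utc_offset=-4.0)
        assert len(model.sample) == 30
        assert np.all((model.sample.sun_times >= 0)
                      & (model.sample.sun_times < 24))
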