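"""Movement classification, site detection, phenology and phase tiling."""

import numpy as np
import pandas as pd
import pytest

from flyway.exceptions import NoMigrationError, NoWinteringSiteError
from flyway.geo import haversine_km
from flyway.segmentation import (
    Site,
    classify_movement,
    detect_departure_arrival,
    detect_nest_site,
    detect_stopovers,
    detect_wintering_site,
    segment_annual_cycle,
)

from conftest import make_fixes


class TestClassifyMovement:
    def test_50km_in_1h_is_flight(self):
        fx = make_fixes([0, 1], [50.0, 50.4496], [4.0, 4.0])  # ~50 km north
        labels = classify_movement(fx)
        assert labels[1] == "flight"

    def test_identical_positions_stationary(self):
        fx = make_fixes([0, 1, 2], [50.0] * 3, [4.0] * 3)
        assert (classify_movement(fx) == "stationary").all()

    def test_speed_equal_to_threshold_is_stationary(self):
        # ~12 km in 30 min = ~24 km/h; with the threshold set to exactly the
        # computed speed the strict > convention labels the fix stationary
        from flyway.segmentation import point_speeds_kmh

        lat2 = 50.0 + 12.0 / haversine_km((50.0, 4.0), (51.0, 4.0))
        fx = make_fixes([0, 0.5], [50.0, lat2], [4.0, 4.0])
        v = point_speeds_kmh(fx)[1]
        assert v == pytest.approx(24.0, abs=1e-6)
        assert classify_movement(fx, v)[1] == "stationary"
        assert classify_movement(fx, v - 1e-9)[1] == "flight"

    def test_first_fix_inherits_second(self):
        fx = make_fixes([0, 1], [50.0, 51.0], [4.0, 4.0])
        labels = classify_movement(fx)
        assert labels[0] == labels[1] == "flight"

    def test_raising_threshold_never_reduces_stationary_count(self, small_population):
        _, trajectories, _ = small_population
        fx = trajectories[0].fixes.iloc[:5000]
        counts = [
            (classify_movement(fx, thr) == "stationary").sum() for thr in (5, 24, 50, 100)
        ]
        assert counts == sorted(counts)


class TestWinteringSite:
    def _residency(self, t0, days, lat, lon, n_per_day=8):
        times = np.arange(t0, t0 + days * 24, 24 / n_per_day)
        return times, np.full(times.size, lat), np.full(times.size, lon)

    def test_single_long_residency_returned(self, pipeline_config):
        t, la, lo = self._residency(0, 150, 46.0, -1.0)
        site = detect_wintering_site(make_fixes(t, la, lo), pipeline_config)
        assert site.lat == pytest.approx(46.0, abs=1e-6)

    def test_southernmost_of_two_long_residencies(self, pipeline_config):
        # 25 d at lat 54, then 90 d at lat 46: both > 20 d, southernmost wins
        t1, la1, lo1 = self._residency(0, 25, 54.0, 8.0)
        t2, la2, lo2 = self._residency(26 * 24, 90, 46.0, -1.0)
        fx = make_fixes(np.concatenate([t1, t2]), np.concatenate([la1, la2]),
                        np.concatenate([lo1, lo2]))
        site = detect_wintering_site(fx, pipeline_config)
        assert site.lat == pytest.approx(46.0, abs=1e-6)

    def test_18_day_residency_rejected(self, pipeline_config):
        t, la, lo = self._residency(0, 18, 46.0, -1.0)
        with pytest.raises(NoWinteringSiteError):
            detect_wintering_site(make_fixes(t, la, lo), pipeline_config)


class TestNestSite:
    def test_unique_mode_cell(self):
        g = 0.0001
        lat = np.concatenate([np.full(80, 53.00005), np.linspace(53.01, 53.02, 20)])
        lon = np.concatenate([np.full(80, 8.00005), np.linspace(8.01, 8.02, 20)])
        fx = make_fixes(np.arange(100.0), lat, lon)
        site = detect_nest_site(fx, g)
        assert site.lat == pytest.approx(53.00005, abs=1e-9)
        assert site.lon == pytest.approx(8.00005, abs=1e-9)
        assert site.provenance == "grid_mode"

    def test_tie_broken_toward_mean_position(self):
        g = 0.0001
        # 4 cells with 25 fixes each; extra spread pulls the mean toward cell (0, 0)
        cells = [(0, 0), (0, 1), (1, 0), (1, 1)]
        lat = np.concatenate([np.full(25, 53.0 + (i + 0.5) * g) for i, _ in cells] + [np.full(4, 53.00005)])
        lon = np.concatenate([np.full(25, 8.0 + (j + 0.5) * g) for _, j in cells] + [np.full(4, 7.995)])
        lat, lon = lat[:104], lon[:104]
        fx = make_fixes(np.arange(float(lat.size)), lat, lon)
        site = detect_nest_site(fx, g)
        # mean is pulled west/south => the (0,0) cell centre is nearest
        assert site.lat == pytest.approx(53.0 + 0.5 * g, abs=1e-9)

    def test_jittered_nest_recovered_within_one_cell(self):
        g = 0.0001
        rng = np.random.default_rng(1)
        true_lat, true_lon = 53.00005, 8.00005  # a cell centre
        sd_deg = 3.0 / 111194.9  # 3 m jitter
        lat = true_lat + rng.normal(0, sd_deg, 500)
        lon = true_lon + rng.normal(0, sd_deg, 500)
        fx = make_fixes(np.arange(500.0), lat, lon)
        site = detect_nest_site(fx, g)
        assert abs(site.lat - true_lat) <= g
        assert abs(site.lon - true_lon) <= g

    def test_grid_shift_consistency(self):
        g = 0.0001
        rng = np.random.default_rng(2)
        lat = 53.0 + rng.normal(0, 5e-5, 200)
        lon = 8.0 + rng.normal(0, 5e-5, 200)
        fx = make_fixes(np.arange(200.0), lat, lon)
        s1 = detect_nest_site(fx, g)
        shifted = fx.copy()
        shifted["lat"] += 7 * g
        shifted["lon"] -= 3 * g
        s2 = detect_nest_site(shifted, g)
        assert s2.lat - s1.lat == pytest.approx(7 * g, abs=1e-9)
        assert s2.lon - s1.lon == pytest.approx(-3 * g, abs=1e-9)

    def test_mean_position_fallback(self):
        fx = make_fixes([0, 1], [53.0, 53.01], [8.0, 8.01])
        site = detect_nest_site(fx, use_mean_position=True)
        assert site.provenance == "mean_position"
        assert site.lat == pytest.approx(53.005)


class TestDepartureArrival:
    def test_buffer_crossing_within_one_interval(self, segmented):
        """Detected departures/arrivals fall within one fix interval (30 min)
        after the true buffer-crossing instant."""
        pc, out, truth = segmented
        interval = pd.Timedelta(minutes=30)
        checked = 0
        for bird_id, (phases, legs, sites) in out.items():
            tl = truth.legs[truth.legs.bird_id == bird_id]
            for leg in legs:
                row = tl[(tl.season == leg.season) & (tl.cycle_year == leg.cycle_year)]
                assert len(row) == 1
                row = row.iloc[0]
                dep = leg.fixes["timestamp"].iloc[0]
                arr = leg.fixes["timestamp"].iloc[-1]
                assert abs(dep - row.departure) <= 2 * interval
                assert abs(arr - row.arrival) <= 2 * interval
                checked += 1
        assert checked == 6 * 2 * 2  # birds x years x seasons

    def test_resident_bird_raises(self):
        fx = make_fixes(np.arange(0, 100, 0.5), np.full(200, 46.0), np.full(200, -1.0))
        with pytest.raises(NoMigrationError):
            detect_departure_arrival(fx, Site("wintering", 46.0, -1.0))

    def test_sub_buffer_excursion_no_false_departure(self):
        # 15 km excursion inside a 20 km buffer: no departure signal
        lat_15 = 46.0 + 15.0 / 111.1949
        t = np.arange(0, 48, 0.5)
        lat = np.full(t.size, 46.0)
        lat[40:50] = lat_15
        fx = make_fixes(t, lat, np.full(t.size, -1.0))
        with pytest.raises(NoMigrationError):
            detect_departure_arrival(fx, Site("wintering", 46.0, -1.0))


class TestStopovers:
    def _leg(self, bouts, total_h=20.0, dt_h=0.5):
        """Northbound flight at ~55 km/h, paused during stationary bouts.

        bouts: list of (start_h, dur_h); the continuous position advances
        at 0.5 deg lat per moving hour and is sampled at the fix grid.
        """
        times = np.arange(0, total_h, dt_h)

        def paused_before(t):
            return sum(max(0.0, min(t, s + d) - s) for s, d in bouts)

        lat = np.array([40.0 + 0.5 * (t - paused_before(t)) for t in times])
        return make_fixes(times, lat, np.zeros(times.size))

    def test_pure_flight_no_stopovers(self, pipeline_config):
        assert detect_stopovers(self._leg([]), pipeline_config) == []

    def test_90min_bout_detected_once(self, pipeline_config):
        stops = detect_stopovers(self._leg([(8.0, 1.5)]), pipeline_config)
        assert len(stops) == 1
        dur_min = (stops[0].end - stops[0].start) / pd.Timedelta(minutes=1)
        assert abs(dur_min - 90.0) <= 30.0

    def test_45min_bout_ignored(self, pipeline_config):
        # 45 min < the 60-min rule
        assert detect_stopovers(self._leg([(8.0, 0.75)]), pipeline_config) == []

    def test_recovery_against_generator_truth(self, segmented):
        """Stopover counts match the generator for bouts >= 90 min that are
        mutually >= 20 km apart."""
        pc, out, truth = segmented
        for bird_id, (phases, legs, sites) in out.items():
            for leg in legs:
                tstops = truth.stopovers[
                    (truth.stopovers.bird_id == bird_id)
                    & (truth.stopovers.season == leg.season)
                    & (truth.stopovers.cycle_year == leg.cycle_year)
                ]
                if len(tstops) and (tstops["duration_h"] < 1.5).any():
                    continue  # short true bouts may drop below the 60-min rule
                found = detect_stopovers(leg.fixes, pc)
                assert len(found) == len(tstops)


class TestAnnualCycle:
    def test_counts_and_ordering(self, segmented):
        pc, out, truth = segmented
        for bird_id, (phases, legs, sites) in out.items():
            assert sum(l.season == "spring" for l in legs) == 2
            assert sum(l.season == "autumn" for l in legs) == 2
            kinds = [p.phase for p in phases]
            assert kinds[0] == "wintering"
            # wintering and breeding alternate through the migration blocks
            core = [k for k in kinds if k in ("wintering", "breeding")]
            assert all(a != b for a, b in zip(core[:-1], core[1:]))

    def test_phases_tile_without_overlap(self, segmented):
        pc, out, _ = segmented
        for bird_id, (phases, legs, sites) in out.items():
            for a, b in zip(phases[:-1], phases[1:]):
                assert a.end < b.start
                assert a.start < a.end

    def test_sites_unique_per_cycle(self, segmented):
        pc, out, _ = segmented
        for bird_id, (phases, legs, sites) in out.items():
            keys = [(s.kind, s.cycle_year) for s in sites]
            assert len(keys) == len(set(keys))

    def test_site_positions_match_truth(self, segmented):
        pc, out, truth = segmented
        for bird_id, (phases, legs, sites) in out.items():
            ts = truth.sites[truth.sites.bird_id == bird_id]
            for s in sites:
                row = ts[(ts.kind == s.kind) & (ts.cycle_year == s.cycle_year)]
                if row.empty:  # final wintering site is not in the truth table
                    continue
                d = haversine_km((s.lat, s.lon), (row.iloc[0].lat, row.iloc[0].lon))
                assert d < 2.0  # km; fix jitter + centroid error
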