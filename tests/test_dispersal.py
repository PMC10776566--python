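"""Advection, fate classification, connectivity and dispersal statistics."""

import numpy as np
import pytest

from seaconnect.dispersal import (
    ConnectivityMatrix,
    OutOfDomainError,
    Particle,
    SpawningSite,
    TrajectorySet,
    advect,
    connectivity_matrix,
    dispersal_stats,
    interpolate_velocity,
    read_sites_geojson,
    run_simulation,
    write_sites_geojson,
)
from seaconnect.fixtures import FixtureConfig, make_sites, make_velocity_field
from seaconnect.geo import haversine_km


class TestInterpolation:
    def test_node_identity(self, uniform_east_field):
        f = uniform_east_field
        u, v = interpolate_velocity(f, float(f.lon[3]), float(f.lat[4]), f.time[0])
        assert (u, v) == (pytest.approx(0.1), pytest.approx(0.0))

    def test_uniform_everywhere(self, uniform_east_field):
        u, v = interpolate_velocity(uniform_east_field, -0.137, 0.421, uniform_east_field.time[1])
        assert u == pytest.approx(0.1) and v == pytest.approx(0.0)

    def test_midpoint_bilinear_average(self, small_config):
        """u = {0,0,1,1} on the 4 surrounding nodes averages to 0.5 at the centre."""
        f = make_velocity_field(small_config, "zero")
        f.u[:, 4, 3] = 0.0
        f.u[:, 4, 4] = 0.0
        f.u[:, 5, 3] = 1.0
        f.u[:, 5, 4] = 1.0
        lon_m = 0.5 * (f.lon[3] + f.lon[4])
        lat_m = 0.5 * (f.lat[4] + f.lat[5])
        u, _ = interpolate_velocity(f, float(lon_m), float(lat_m), f.time[0])
        assert u == pytest.approx(0.5)

    def test_outside_grid_raises(self, zero_field):
        with pytest.raises(OutOfDomainError):
            interpolate_velocity(zero_field, 10.0, 0.0, zero_field.time[0])


class TestAdvection:
    def test_zero_field_no_motion(self, zero_field, one_site):
        p = advect(zero_field, one_site, "2008-01-02", release_cell=(-1.0, 0.0), max_days=2, sites_all=[])
        assert p.fate == "expired"
        assert p.dispersal_km == 0.0

    def test_uniform_eastward_daily_displacement(self, uniform_east_field, one_site):
        """0.1 m/s for 24 h = 8.64 km eastward at the equator."""
        p = advect(uniform_east_field, one_site, "2008-01-02", release_cell=(-1.0, 0.0), max_days=1, sites_all=[])
        assert p.dispersal_km == pytest.approx(8.64, abs=0.1)
        assert p.final_lon > -1.0 and p.final_lat == pytest.approx(0.0)

    def test_release_on_land_rejected(self, small_config, one_site):
        from shapely.geometry import box

        f = make_velocity_field(small_config, "zero", land_polygons=[box(-2, -2, 2, 2)])
        with pytest.raises(ValueError, match="land"):
            advect(f, one_site, "2008-01-02", release_cell=(-1.0, 0.0), sites_all=[])

    def test_settles_at_first_entry_hour(self, uniform_east_field, small_config):
        """A downstream settlement polygon catches the particle at the same hour
        a fine-step (1 s) reference integration first enters it."""
        sites = make_sites(small_config, [("Src", -1.0, 0.0, 6.0, (2, 6)), ("Dst", -0.7, 0.0, 6.0, (2, 6))],
                           field=uniform_east_field, settlement_buffer_km=0.0)
        cell = (-1.0, 0.0)
        p = advect(uniform_east_field, sites[0], "2008-01-02", release_cell=cell,
                   sites_all=[sites[1]], max_days=30)
        ref = advect(uniform_east_field, sites[0], "2008-01-02", release_cell=cell,
                     sites_all=[sites[1]], max_days=30, step=1.0 / 3600.0)
        assert p.fate == "settled" and p.settle_site == "Dst"
        assert abs(p.n_hours - ref.n_hours) <= 1

    def test_out_of_grid_is_lost(self, small_config, one_site):
        f = make_velocity_field(small_config, "uniform", {"u": 5.0, "v": 0.0})
        p = advect(f, one_site, "2008-01-02", release_cell=(-1.0, 0.0), max_days=30, sites_all=[])
        assert p.fate == "lost_open_ocean"

    def test_step_halving_converges(self, small_config, one_site):
        """Halving the step changes final position by well under 1 km in a smooth field."""
        f = make_velocity_field(small_config, "double_gyre", {"amplitude": 0.15})
        p1 = advect(f, one_site, "2008-01-02", release_cell=(-1.0, 0.0), step=1.0, max_days=10, sites_all=[])
        p2 = advect(f, one_site, "2008-01-02", release_cell=(-1.0, 0.0), step=0.5, max_days=10, sites_all=[])
        d = haversine_km(p1.final_lon, p1.final_lat, p2.final_lon, p2.final_lat)
        assert d < 1.0

    def test_solid_rotation_returns_to_start(self, small_config, one_site):
        """One full rotation period brings the particle back to within 1% of the
        circle's circumference (4th-order integrator)."""
        period = 5.0
        f = make_velocity_field(small_config, "solid_rotation",
                                {"period_days": period, "lon_c": 0.0, "lat_c": 0.0})
        start = (-0.5, 0.0)
        p = advect(f, one_site, "2008-01-02", release_cell=start, step=1.0,
                   max_days=int(period), sites_all=[], method="rk4")
        radius_km = haversine_km(start[0], start[1], 0.0, 0.0)
        circumference = 2 * np.pi * radius_km
        assert p.dispersal_km < 0.01 * circumference


class TestSimulation:
    def test_particle_counting_single(self, zero_field, small_config):
        site = make_sites(small_config, [("A", -1.0, 0.0, 3.0, (2, 11))], field=zero_field)[0]
        site.release_cells = site.release_cells[:1]
        trajs = run_simulation(zero_field, [site], years=[2008], release_per_day=1)
        assert len(trajs) == 10

    def test_particle_counting_product(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, n_days=400)  # cover two spawning years
        field = make_velocity_field(cfg, "zero")
        sites = make_sites(cfg, [("A", -1.0, 0.0, 6.0, (2, 6)), ("B", 1.0, 0.0, 6.0, (2, 6))],
                           field=field)
        for s in sites:
            s.release_cells = s.release_cells[:3]
            s.settlement_polygon = s.polygon.buffer(-1)  # disable instant settlement
        trajs = run_simulation(field, sites, years=[2008, 2009], release_per_day=2, max_days=2)
        assert len(trajs) == 2 * 3 * 5 * 2 * 2

    def test_zero_field_all_expired(self, zero_field, small_config):
        site = make_sites(small_config, [("A", -1.0, 0.0, 6.0, (2, 4))], field=zero_field)[0]
        site.settlement_polygon = site.polygon.buffer(-1)
        trajs = run_simulation(zero_field, [site], years=[2008], release_per_day=1)
        assert all(p.fate == "expired" for p in trajs.particles)
        assert all(p.dispersal_km == 0.0 for p in trajs.particles)

    def test_season_outside_coverage_rejected(self, zero_field, small_config):
        site = make_sites(small_config, [("A", -1.0, 0.0, 6.0, (300, 310))], field=zero_field)[0]
        with pytest.raises(ValueError, match="coverage"):
            run_simulation(zero_field, [site], years=[2008])

    def test_fates_partition_releases(self, small_config):
        """Every particle has exactly one fate; fate counts sum to releases."""
        f = make_velocity_field(small_config, "double_gyre", {"amplitude": 0.3})
        sites = make_sites(small_config, [("A", -1.0, -1.0, 9.0, (2, 6)), ("B", 1.0, 1.0, 9.0, (2, 6))],
                           field=f, settlement_buffer_km=5.0)
        trajs = run_simulation(f, sites, years=[2008], release_per_day=1, min_age_hours=24.0)
        df = trajs.to_dataframe()
        assert set(df["fate"]).issubset({"settled", "beached", "lost_open_ocean", "expired"})
        assert len(df) == sum(len(s.release_cells) * 5 for s in sites)
        settled = df["fate"] == "settled"
        assert df.loc[settled, "settle_site"].notna().all()
        assert df.loc[~settled, "settle_site"].isna().all()


class TestConnectivity:
    def _trajs(self, fates_sites, source="A"):
        particles = [
            Particle(source_site=source, release_time=np.datetime64("2008-01-01"),
                     fate=f, settle_site=s, dispersal_km=1.0, final_lon=0, final_lat=0, n_hours=1)
            for f, s in fates_sites
        ]
        return TrajectorySet(particles=particles, site_names=["A", "B"])

    def test_all_beached_gives_zero_matrix(self):
        trajs = self._trajs([("beached", None)] * 4)
        cm = connectivity_matrix(trajs)
        assert np.allclose(cm.P[0], 0.0)

    def test_full_local_retention_is_identity_row(self):
        trajs = self._trajs([("settled", "A")] * 5)
        cm = connectivity_matrix(trajs)
        assert cm.P[0, 0] == 1.0 and cm.P[0, 1] == 0.0
        assert cm.local_retention[0] == 1.0

    def test_rows_sum_to_at_most_one(self, small_config):
        f = make_velocity_field(small_config, "double_gyre", {"amplitude": 0.3})
        sites = make_sites(small_config, [("A", -1.0, -1.0, 9.0, (2, 6)), ("B", 1.0, 1.0, 9.0, (2, 6))], field=f)
        trajs = run_simulation(f, sites, years=[2008], release_per_day=1, min_age_hours=24.0)
        cm = connectivity_matrix(trajs, sites)
        sums = np.nansum(cm.P, axis=1)
        assert np.all(sums <= 1.0 + 1e-12)

    def test_unreleased_site_row_is_undefined(self):
        trajs = self._trajs([("settled", "A")] * 3)
        cm = connectivity_matrix(trajs)
        assert np.all(np.isnan(cm.P[1]))

    def test_uniform_flow_transfer_matches_reference_integrator(self, small_config, uniform_east_field):
        """Two-site uniform-flow transfer probability agrees with 1 s-step reference."""
        f = uniform_east_field
        sites = make_sites(small_config, [("Src", -1.0, 0.0, 3.0, (2, 3)), ("Dst", -0.7, 0.0, 3.0, (2, 3))],
                           field=f, settlement_buffer_km=0.0)
        kw = dict(years=[2008], release_per_day=1, min_age_hours=24.0, max_days=8)
        coarse = run_simulation(f, sites, step=1.0, **kw)
        fine = run_simulation(f, sites, step=1.0 / 60.0, **kw)
        P1 = connectivity_matrix(coarse, sites).P
        P2 = connectivity_matrix(fine, sites).P
        assert P1[0, 1] > 0
        assert P1[0, 1] == pytest.approx(P2[0, 1], abs=1e-9)


class TestDispersalStats:
    def _from_distances(self, ds):
        particles = [
            Particle(source_site="A", release_time=np.datetime64("2008-01-01"), fate="expired",
                     settle_site=None, dispersal_km=float(d), final_lon=0, final_lat=0, n_hours=1)
            for d in ds
        ]
        return TrajectorySet(particles=particles, site_names=["A"])

    def test_single_particle(self):
        s = dispersal_stats(self._from_distances([10.0]))["pooled"]
        assert (s["mean"], s["sd"], s["max"]) == (10.0, 0.0, 10.0)

    def test_small_set(self):
        s = dispersal_stats(self._from_distances([1.0, 2.0, 3.0]))["pooled"]
        assert s["mean"] == 2.0 and s["max"] == 3.0

    def test_halfnormal_q95_matches_closed_form(self):
        """Empirical q95 of half-normal distances within 2% of σ·Φ⁻¹(0.975)."""
        from scipy.stats import halfnorm

        sigma = 40.0
        rng = np.random.default_rng(0)
        d = np.abs(rng.normal(0, sigma, size=10000))
        s = dispersal_stats(self._from_distances(d))["pooled"]
        assert s["q95"] == pytest.approx(halfnorm.ppf(0.95, scale=sigma), rel=0.02)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dispersal_stats(TrajectorySet(particles=[], site_names=[]))


class TestSiteGeometry:
    def test_release_cells_inside_polygon_and_ocean(self, zero_field, small_config):
        site = make_sites(small_config, [("A", -1.0, 0.0, 9.0, (2, 6))], field=zero_field)[0]
        assert len(site.release_cells) >= 4
        from shapely.geometry import Point

        for lon, lat in site.release_cells:
            assert site.polygon.contains(Point(lon, lat))
            assert not zero_field.is_land(lon, lat)

    def test_invalid_season_rejected(self, one_site):
        with pytest.raises(ValueError, match="season"):
            SpawningSite(name="X", polygon=one_site.polygon, release_cells=[], season=(200, 100))

    def test_geojson_round_trip(self, tmp_path, zero_field, small_config):
        sites = make_sites(small_config, [("A", -1.0, 0.0, 9.0, (2, 6))], field=zero_field)
        p = tmp_path / "sites.geojson"
        write_sites_geojson(sites, p)
        back = read_sites_geojson(p, field=zero_field)
        assert back[0].name == "A"
        assert back[0].season == (2, 6)
        assert back[0].polygon.equals(sites[0].polygon)
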