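"""Synthetic multi-year GPS trajectories with known ground truth.

The generator emulates the annual cycle of a long-lived migratory shorebird
on a north-east Atlantic flyway: each bird owns a wintering and a breeding
site (small between-year positional jitter — high site fidelity), migrates
twice a year along a great-circle route perturbed laterally by a persistent
per-bird offset plus per-year noise, pauses at stopovers drawn from a
Poisson/Gamma process, and is sampled at a nominal fix interval with
optional injected multi-day gaps.  Chain migration is induced by pairing
wintering and breeding centres in matching latitudinal order, so birds
wintering further north also breed further north.

Every random quantity is drawn from a single seeded generator, and the
generative values (true sites, true buffer-crossing departure/arrival
times, true stopover intervals, latent individual effects and the implied
repeatability of migration timing) are returned as :class:`GroundTruth`,
so downstream segmentation and mixed-model estimates can be scored against
a known answer.

A separate, much lighter generator (:func:`simulate_repeatability_table`)
draws ready-made repeated-measures tables with an exact target intraclass
correlation, for testing the variance-component machinery in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .exceptions import ConfigError
from .track_io import Trajectory

KM_PER_DEG_LAT = np.pi / 180.0 * geo.EARTH_RADIUS_KM  # 111.1949 km

_DEFAULT_WINTERING = ((36.8, -6.3), (43.5, -1.5), (47.2, -2.2))
_DEFAULT_BREEDING = ((52.8, 8.2), (58.5, 24.5), (64.5, 26.0))


@dataclass
class SimConfig:
    """Study-design and noise parameters of the trajectory generator.

    Units: distances km, durations as named (days/hours/minutes), speeds
    km/h, dates as day-of-year.  ``breeding_centres``/``wintering_centres``
    are matched by index and must be ordered consistently (south to north)
    to produce chain migration.
    """

    n_individuals: int = 6
    n_years: int = 2
    breeding_centres: tuple = _DEFAULT_BREEDING
    wintering_centres: tuple = _DEFAULT_WINTERING
    centre_scatter_km: float = 40.0  # between-bird scatter around a centre
    site_fidelity_sd_km: float = 0.5  # within-bird between-year site jitter
    resident_jitter_km: float = 0.15  # fix-level scatter at a residency/stopover
    timing_mu_doy: float = 95.0  # mean spring departure day-of-year
    autumn_mu_doy: float = 205.0  # mean autumn departure day-of-year
    timing_between_sd_d: float = 8.0
    timing_within_sd_d: float = 4.0
    route_lateral_sd_km: float = 15.0
    route_between_sd_km: float = 40.0
    stopover_rate: float = 2.0  # mean stopovers per migration leg
    stopover_duration_shape: float = 2.0
    stopover_duration_scale_h: float = 12.0
    cruise_speed_kmh: float = 65.0
    fix_interval_min: float = 30.0
    gap_prob: float = 0.0  # probability a leg gets an injected >24 h gap
    start_year: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if self.n_years < 2:
            raise ConfigError("n_years must be >= 2 (repeatability needs repeats)")
        if self.cruise_speed_kmh <= 24.0:
            raise ConfigError("cruise_speed_kmh must exceed 24 (the flight threshold)")
        for name in (
            "centre_scatter_km",
            "site_fidelity_sd_km",
            "resident_jitter_km",
            "timing_between_sd_d",
            "timing_within_sd_d",
            "route_lateral_sd_km",
            "route_between_sd_km",
            "stopover_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.stopover_duration_shape <= 0 or self.stopover_duration_scale_h <= 0:
            raise ConfigError("stopover_duration_shape and stopover_duration_scale_h must be > 0")
        if self.fix_interval_min <= 0:
            raise ConfigError("fix_interval_min must be > 0")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ConfigError("gap_prob must lie in [0, 1]")
        if len(self.breeding_centres) != len(self.wintering_centres):
            raise ConfigError("breeding_centres and wintering_centres must pair up")


@dataclass
class GroundTruth:
    """Generative truth: sites, phenology, stopovers and latent effects."""

    sites: pd.DataFrame  # bird_id, cycle_year, kind, lat, lon
    legs: pd.DataFrame  # bird_id, season, cycle_year, departure, arrival, dep_doy, ...
    stopovers: pd.DataFrame  # bird_id, season, cycle_year, lat, lon, start, end
    individuals: pd.DataFrame  # latent effects and mean sites per bird
    variance: dict  # generative variance components and implied R

    @property
    def r_true_timing(self) -> float:
        return self.variance["r_true_timing"]


def _offset_point(lat: float, lon: float, east_km: float, north_km: float):
    dlat = north_km / KM_PER_DEG_LAT
    dlon = east_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return lat + dlat, lon + dlon


def _jitter(rng, lat, lon, sd_km, n=None):
    if n is None:
        e, nn = rng.normal(0.0, sd_km, size=2)
        return _offset_point(lat, lon, e, nn)
    e = rng.normal(0.0, sd_km, size=n)
    nn = rng.normal(0.0, sd_km, size=n)
    dlat = nn / KM_PER_DEG_LAT
    dlon = e / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return lat + dlat, lon + dlon


def _leg_waypoints(rng, origin, dest, bird_offset_km, lateral_sd_km, n_stopovers):
    """Via points of one migration leg: fixed shape points plus stopover
    way-points, each displaced perpendicular to the local leg bearing."""
    shape_fracs = [0.3, 0.55, 0.8]
    stop_fracs = [0.2 + 0.6 * (j + 1) / (n_stopovers + 1) for j in range(n_stopovers)]
    fracs = []
    for f in sorted(shape_fracs + stop_fracs):
        if not fracs or f - fracs[-1][0] > 0.02:
            fracs.append([f, f in stop_fracs])
        elif f in stop_fracs:  # stopover wins a collision with a shape point
            fracs[-1] = [f, True]
    points = [(origin[0], origin[1], False)]
    for f, is_stop in fracs:
        lat, lon = geo.great_circle_points(origin, dest, np.array([f]))
        base = (float(lat[0]), float(lon[0]))
        brg = geo.initial_bearing_deg(base, dest)
        off = bird_offset_km + rng.normal(0.0, lateral_sd_km)
        plat, plon = geo.destination_point(base, brg + 90.0, off)
        points.append((plat, plon, is_stop))
    points.append((dest[0], dest[1], False))
    return points


def simulate_population(config: SimConfig):
    """Simulate the population; returns ``(trajectories, ground_truth)``.

    Each trajectory spans ``n_years`` annual cycles starting and ending in
    the wintering area; identical configs (including seed) give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    base = pd.Timestamp(f"{config.start_year}-01-01", tz="UTC")
    speed = config.cruise_speed_kmh
    buffer_km = 20.0

    n_centres = len(config.breeding_centres)
    sexes = ("F", "M")
    countries = ("Germany", "France", "Poland")

    trajectories = []
    site_rows, leg_rows, stop_rows, ind_rows = [], [], [], []

    for i in range(config.n_individuals):
        bird_id = f"bird_{i:03d}"
        ci = i % n_centres
        wlat0, wlon0 = config.wintering_centres[ci]
        blat0, blon0 = config.breeding_centres[ci]
        wlat, wlon = _jitter(rng, wlat0, wlon0, config.centre_scatter_km)
        blat, blon = _jitter(rng, blat0, blon0, config.centre_scatter_km)

        b_spring = rng.normal(0.0, config.timing_between_sd_d)
        b_autumn = rng.normal(0.0, config.timing_between_sd_d)
        off_spring = rng.normal(0.0, config.route_between_sd_km)
        off_autumn = rng.normal(0.0, config.route_between_sd_km)

        # Per-year realised sites (wintering site y is used at the start of
        # cycle y; the final autumn returns to wintering site n_years).
        wsites, bsites = [], []
        for y in range(config.n_years + 1):
            wsites.append(_jitter(rng, wlat, wlon, config.site_fidelity_sd_km))
        for y in range(config.n_years):
            bsites.append(_jitter(rng, blat, blon, config.site_fidelity_sd_km))

        # ---- build the continuous itinerary: list of segments -------------
        # segment = (t0_h, t1_h, kind, payload); times in hours since `base`
        segments = []
        gap_windows = []
        t = 0.0  # start of tracking: Jan 1 of start_year, on the wintering site

        for y in range(config.n_years):
            year = config.start_year + y
            year_h = (pd.Timestamp(f"{year}-01-01", tz="UTC") - base) / pd.Timedelta(hours=1)

            for season in ("spring", "autumn"):
                if season == "spring":
                    mu, b_eff, route_off = config.timing_mu_doy, b_spring, off_spring
                    origin, dest = wsites[y], bsites[y]
                    site_kind = "wintering"
                else:
                    mu, b_eff, route_off = config.autumn_mu_doy, b_autumn, off_autumn
                    origin, dest = bsites[y], wsites[y + 1]
                    site_kind = "breeding"

                dep_doy = mu + b_eff + rng.normal(0.0, config.timing_within_sd_d)
                t_dep = year_h + (dep_doy - 1.0) * 24.0
                # keep the preceding residency detectable (> 20 d)
                t_dep = max(t_dep, t + 20.5 * 24.0)
                segments.append((t, t_dep, "resident", (origin, site_kind)))

                n_stop = int(rng.poisson(config.stopover_rate))
                way = _leg_waypoints(
                    rng, origin, dest, route_off, config.route_lateral_sd_km, n_stop
                )
                t_cursor = t_dep
                leg_stop_rows = []
                for k in range(len(way) - 1):
                    p0, p1 = way[k], way[k + 1]
                    dist = geo.haversine_km((p0[0], p0[1]), (p1[0], p1[1]))
                    t_next = t_cursor + dist / speed
                    segments.append((t_cursor, t_next, "flight", ((p0[0], p0[1]), (p1[0], p1[1]))))
                    t_cursor = t_next
                    if p1[2]:  # stopover way-point
                        dur_h = max(
                            1.0,
                            rng.gamma(config.stopover_duration_shape, config.stopover_duration_scale_h),
                        )
                        segments.append((t_cursor, t_cursor + dur_h, "stopover", ((p1[0], p1[1]), None)))
                        leg_stop_rows.append(
                            {
                                "bird_id": bird_id,
                                "season": season,
                                "cycle_year": year,
                                "lat": p1[0],
                                "lon": p1[1],
                                "start": base + pd.Timedelta(hours=t_cursor),
                                "end": base + pd.Timedelta(hours=t_cursor + dur_h),
                                "duration_h": dur_h,
                            }
                        )
                        t_cursor += dur_h
                t_arr = t_cursor
                stop_rows.extend(leg_stop_rows)

                # truth: buffer-crossing instants (first/last segments leave or
                # approach the site radially, so crossing is exact in time)
                dep_cross = t_dep + buffer_km / speed
                arr_cross = t_arr - buffer_km / speed
                leg_rows.append(
                    {
                        "bird_id": bird_id,
                        "season": season,
                        "cycle_year": year,
                        "departure": base + pd.Timedelta(hours=dep_cross),
                        "arrival": base + pd.Timedelta(hours=arr_cross),
                        "leg_start": base + pd.Timedelta(hours=t_dep),
                        "leg_end": base + pd.Timedelta(hours=t_arr),
                        "dep_doy": dep_doy,
                        "n_stopovers": len(leg_stop_rows),
                        "total_stopover_h": float(sum(r["duration_h"] for r in leg_stop_rows)),
                        "origin_lat": origin[0],
                        "origin_lon": origin[1],
                        "dest_lat": dest[0],
                        "dest_lon": dest[1],
                        "origin_kind": site_kind,
                    }
                )
                if rng.random() < config.gap_prob:
                    mid = 0.5 * (t_dep + t_arr)
                    gap_windows.append((mid - 12.6, mid + 12.6))
                t = t_arr

            site_rows.append(
                {"bird_id": bird_id, "cycle_year": year, "kind": "wintering",
                 "lat": wsites[y][0], "lon": wsites[y][1]}
            )
            site_rows.append(
                {"bird_id": bird_id, "cycle_year": year, "kind": "breeding",
                 "lat": bsites[y][0], "lon": bsites[y][1]}
            )

        # trailing wintering residency so the final site is detectable
        t_end = t + 30.0 * 24.0
        segments.append((t, t_end, "resident", (wsites[config.n_years], "wintering")))

        # ---- sample fixes on a uniform time grid ---------------------------
        dt_h = config.fix_interval_min / 60.0
        times = np.arange(0.0, t_end, dt_h)
        starts = np.array([s[0] for s in segments])
        idx = np.searchsorted(starts, times, side="right") - 1
        lat = np.empty_like(times)
        lon = np.empty_like(times)
        gs = np.zeros_like(times)
        for k, (t0, t1, kind, payload) in enumerate(segments):
            m = idx == k
            if not np.any(m):
                continue
            if kind == "flight":
                p0, p1 = payload
                frac = (times[m] - t0) / max(t1 - t0, 1e-12)
                la, lo = geo.great_circle_points(p0, p1, frac)
                lat[m], lon[m] = la, lo
                gs[m] = speed
            else:
                (slat, slon) = payload[0]
                la, lo = _jitter(rng, slat, slon, config.resident_jitter_km, n=int(m.sum()))
                lat[m], lon[m] = la, lo

        keep = np.ones(times.shape, dtype=bool)
        for g0, g1 in gap_windows:
            keep &= ~((times > g0) & (times < g1))
        times, lat, lon, gs = times[keep], lat[keep], lon[keep], gs[keep]

        fixes = pd.DataFrame(
            {
                "timestamp": base + pd.to_timedelta(np.round(times * 3600.0).astype("int64"), unit="s"),
                "lat": lat,
                "lon": lon,
                "ground_speed": gs,
            }
        )
        trajectories.append(
            Trajectory(
                bird_id=bird_id,
                fixes=fixes,
                sex=sexes[i % 2],
                capture_country=countries[ci % len(countries)],
                tag_type="synthetic-gps",
            )
        )
        ind_rows.append(
            {
                "bird_id": bird_id,
                "sex": sexes[i % 2],
                "capture_country": countries[ci % len(countries)],
                "centre_index": ci,
                "winter_mean_lat": wlat,
                "winter_mean_lon": wlon,
                "breed_mean_lat": blat,
                "breed_mean_lon": blon,
                "timing_effect_spring_d": b_spring,
                "timing_effect_autumn_d": b_autumn,
                "route_offset_spring_km": off_spring,
                "route_offset_autumn_km": off_autumn,
            }
        )

    bsd, wsd = config.timing_between_sd_d, config.timing_within_sd_d
    denom = bsd**2 + wsd**2
    truth = GroundTruth(
        sites=pd.DataFrame(site_rows),
        legs=pd.DataFrame(leg_rows),
        stopovers=pd.DataFrame(
            stop_rows,
            columns=["bird_id", "season", "cycle_year", "lat", "lon", "start", "end", "duration_h"],
        ),
        individuals=pd.DataFrame(ind_rows),
        variance={
            "timing_between_var_d2": bsd**2,
            "timing_within_var_d2": wsd**2,
            "r_true_timing": bsd**2 / denom if denom > 0 else 0.0,
            "route_between_var_km2": config.route_between_sd_km**2,
            "route_within_var_km2": config.route_lateral_sd_km**2,
        },
    )
    return trajectories, truth


def simulate_repeatability_table(
    r_true: float,
    n_ids: int,
    n_obs_per_id: int,
    family: str = "gaussian",
    seed: int = 0,
    n_clusters: int = 3,
) -> pd.DataFrame:
    """Repeated-measures table (id, cluster, dt, y) with known repeatability.

    Gaussian family: residual variance fixed at 1 and id-effect variance
    ``r_true / (1 - r_true)``, so the latent intraclass correlation is
    exactly ``r_true``; fixed cluster effects and a mild log(dt+1) slope are
    added on top so *adjusted* repeatability is what recovers ``r_true``.
    Count family: log-link Poisson with latent id effects whose variance is
    chosen against the log-link distribution variance ln(1 + 1/lambda0) at
    the baseline mean, matching the latent-scale repeatability convention.

    The exact generative parameters and per-id latent effects are stored in
    ``table.attrs``.
    """
    if not 0.0 <= r_true < 1.0:
        raise ConfigError("r_true must lie in [0, 1); r_true = 1 is degenerate")
    if n_ids < 2 or n_obs_per_id < 2:
        raise ConfigError("n_ids and n_obs_per_id must both be >= 2")
    if family not in ("gaussian", "count"):
        raise ConfigError(f"family must be gaussian or count, got {family!r}")

    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(n_ids), n_obs_per_id)
    cluster = ids % n_clusters
    cluster_eff = np.linspace(0.0, 1.0, n_clusters)[cluster]
    dt = rng.lognormal(mean=np.log(30.0), sigma=0.3, size=ids.size)
    log_dt = np.log(dt + 1.0)

    if family == "gaussian":
        sigma2_id = r_true / (1.0 - r_true)
        u = rng.normal(0.0, np.sqrt(sigma2_id), size=n_ids) if sigma2_id > 0 else np.zeros(n_ids)
        e = rng.normal(0.0, 1.0, size=ids.size)
        y = 10.0 + cluster_eff + 0.2 * log_dt + u[ids] + e
    else:
        lam0 = 5.0
        sigma2_d = np.log(1.0 + 1.0 / lam0)
        sigma2_id = r_true / (1.0 - r_true) * sigma2_d
        u = rng.normal(0.0, np.sqrt(sigma2_id), size=n_ids) if sigma2_id > 0 else np.zeros(n_ids)
        eta = np.log(lam0) + 0.1 * cluster_eff + u[ids]
        y = rng.poisson(np.exp(eta)).astype(float)

    table = pd.DataFrame(
        {"id": [f"id_{k:05d}" for k in ids], "cluster": [f"c{c}" for c in cluster], "dt": dt, "y": y}
    )
    table.attrs.update(
        {
            "r_true": r_true,
            "family": family,
            "sigma2_id": float(sigma2_id),
            "sigma2_res": 1.0 if family == "gaussian" else None,
            "id_effects": u,
            "seed": seed,
        }
    )
    return table
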