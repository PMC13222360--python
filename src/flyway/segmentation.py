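"""Annual-cycle segmentation: sites, phenology, stopovers and phases.

A trajectory is decomposed with rule-based operational definitions (no
behavioural-state models):

* flight vs stationary behaviour from point-to-point speeds against a
  24 km/h threshold;
* residencies as maximal runs of fixes staying within a radius of their
  running centroid; wintering sites are the southernmost residency longer
  than 20 days, breeding sites come from a 0.0001-degree nest grid;
* departure and arrival as the crossing of a 20 km buffer around the
  seasonal site (first fix beyond/within the boundary, no interpolation);
* stopovers as >= 60 min of stationary behaviour at a single spot
  (5 km radius) inside a migration leg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .config import PipelineConfig
from .exceptions import (
    FormatError,
    InsufficientDataError,
    NoMigrationError,
    NoWinteringSiteError,
    SegmentationError,
)
from .track_io import Trajectory


@dataclass
class Site:
    kind: str  # breeding, wintering or nest
    lat: float
    lon: float
    bird_id: str = ""
    cycle_year: int = -1
    provenance: str = "mean_position"  # or grid_mode


@dataclass
class PhaseInterval:
    phase: str  # wintering, breeding, stopover, migration_flight
    start: pd.Timestamp
    end: pd.Timestamp
    centroid: tuple
    n_fixes: int


@dataclass
class SeasonTrack:
    """Fixes of one migration leg (departure fix through arrival fix)."""

    bird_id: str
    season: str  # spring or autumn
    cycle_year: int
    fixes: pd.DataFrame
    origin: Site
    destination: Site


def _hav_scalar(lat1, lon1, lat2, lon2) -> float:
    """Fast scalar haversine (km) for tight loops."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    h = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * geo.EARTH_RADIUS_KM * math.asin(math.sqrt(min(1.0, h)))


def point_speeds_kmh(fixes: pd.DataFrame) -> np.ndarray:
    """Speed of each fix from the step leading into it; element 0 repeats
    element 1 (the first fix inherits the label of the second)."""
    if len(fixes) < 2:
        raise InsufficientDataError("speeds need >= 2 fixes")
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    t = fixes["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("zero or negative time difference between consecutive fixes")
    d = geo.step_distances_km(lat, lon)
    v = d / dt
    return np.concatenate([[v[0]], v])


def classify_movement(fixes: pd.DataFrame, speed_threshold_kmh: float = 24.0) -> np.ndarray:
    """Label each fix ``flight`` or ``stationary``.

    A fix is *flight* iff its point-to-point speed strictly exceeds the
    threshold; exactly 24.0 km/h is stationary.
    """
    v = point_speeds_kmh(fixes)
    return np.where(v > speed_threshold_kmh, "flight", "stationary")


@dataclass
class _Residency:
    start: int  # fix indices, inclusive
    end: int
    lat: float  # centroid of member fixes
    lon: float
    duration_d: float
    kind: str = ""


def find_residencies(fixes: pd.DataFrame, radius_km: float) -> list[_Residency]:
    """Maximal runs of fixes staying within ``radius_km`` of their running
    centroid.  Flight sequences degrade into single-fix runs; residencies
    are the long runs.  The centroid of a compact fix cloud stands in for
    its medoid at a fraction of the cost."""
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    t = fixes["timestamp"].astype("int64").to_numpy() / 86400e9  # days
    runs = []
    start = 0
    s_lat, s_lon, n = lat[0], lon[0], 1
    for j in range(1, len(lat)):
        if _hav_scalar(lat[j], lon[j], s_lat / n, s_lon / n) <= radius_km:
            s_lat += lat[j]
            s_lon += lon[j]
            n += 1
        else:
            runs.append(
                _Residency(start, j - 1, s_lat / n, s_lon / n, float(t[j - 1] - t[start]))
            )
            start, s_lat, s_lon, n = j, lat[j], lon[j], 1
    runs.append(_Residency(start, len(lat) - 1, s_lat / n, s_lon / n, float(t[-1] - t[start])))
    return runs


def detect_wintering_site(
    fixes: pd.DataFrame,
    config: PipelineConfig,
    bird_id: str = "",
    cycle_year: int = -1,
) -> Site:
    """Southernmost residency longer than the minimum wintering stay.

    Candidate residencies need a duration strictly above
    ``winter_min_stay_days``; among them the one with the southernmost
    centroid wins (a bird moving further south after a >20 d stay is
    assigned the later, more southerly site).  The site position is the
    mean of the member fixes.
    """
    candidates = [
        r
        for r in find_residencies(fixes, config.site_radius_km)
        if r.duration_d > config.winter_min_stay_days
    ]
    if not candidates:
        raise NoWinteringSiteError(
            f"no residency longer than {config.winter_min_stay_days} d for {bird_id or 'track'}"
        )
    best = min(candidates, key=lambda r: r.lat)
    members = fixes.iloc[best.start : best.end + 1]
    return Site(
        kind="wintering",
        lat=float(members["lat"].mean()),
        lon=float(members["lon"].mean()),
        bird_id=bird_id,
        cycle_year=cycle_year,
    )


def detect_nest_site(
    breeding_fixes: pd.DataFrame,
    nest_grid_deg: float = 0.0001,
    bird_id: str = "",
    cycle_year: int = -1,
    use_mean_position: bool = False,
) -> Site:
    """Nest = centre of the densest cell of a lat/lon grid over the
    breeding fixes; ties go to the cell centre nearest the mean position.
    With ``use_mean_position`` the mean of all breeding fixes is used
    instead (the fallback when no nest can be resolved)."""
    if len(breeding_fixes) == 0:
        raise InsufficientDataError("no breeding fixes for nest detection")
    lat = breeding_fixes["lat"].to_numpy(dtype=float)
    lon = breeding_fixes["lon"].to_numpy(dtype=float)
    mean_lat, mean_lon = float(lat.mean()), float(lon.mean())
    if use_mean_position:
        return Site("nest", mean_lat, mean_lon, bird_id, cycle_year, "mean_position")

    gi = np.floor(lat / nest_grid_deg).astype("int64")
    gj = np.floor(lon / nest_grid_deg).astype("int64")
    cells, counts = np.unique(np.stack([gi, gj], axis=1), axis=0, return_counts=True)
    top = cells[counts == counts.max()]
    centres_lat = (top[:, 0] + 0.5) * nest_grid_deg
    centres_lon = (top[:, 1] + 0.5) * nest_grid_deg
    d = geo.haversine_arrays_km(centres_lat, centres_lon, mean_lat, mean_lon)
    k = int(np.argmin(d))
    return Site("nest", float(centres_lat[k]), float(centres_lon[k]), bird_id, cycle_year, "grid_mode")


def detect_departure_arrival(fixes: pd.DataFrame, site: Site, site_buffer_km: float = 20.0):
    """Buffer-crossing phenology relative to one site.

    Departure is the timestamp of the first fix outside the buffer after a
    residency inside it; arrival is the first fix back inside after being
    outside.  Either may be None when the trajectory covers only one
    transition.  Excursions that never cross the buffer produce no false
    departures (crossing is strict: distance < buffer is inside).
    """
    d = geo.haversine_arrays_km(
        fixes["lat"].to_numpy(dtype=float), fixes["lon"].to_numpy(dtype=float), site.lat, site.lon
    )
    inside = d < site_buffer_km
    if inside.all():
        raise NoMigrationError("bird never left the site buffer")
    ts = fixes["timestamp"]
    departure = arrival = None
    exits = np.flatnonzero(inside[:-1] & ~inside[1:]) + 1
    if exits.size:
        departure = ts.iloc[exits[0]]
        entries = np.flatnonzero(~inside[:-1] & inside[1:]) + 1
        entries = entries[entries > exits[0]]
        if entries.size:
            arrival = ts.iloc[entries[0]]
    elif inside.any():  # enters without ever leaving: arrival only
        arrival = ts.iloc[int(np.argmax(inside))]
    return departure, arrival


def detect_stopovers(season_fixes: pd.DataFrame, config: PipelineConfig) -> list[PhaseInterval]:
    """Stopovers within one migration leg.

    A stopover is >= ``stopover_min_duration_min`` of stationary behaviour
    at a single spot (``stopover_spot_radius_km`` around the running
    centroid).  Each run of stationary-labelled fixes is extended backwards
    by one fix — the step *into* the first stationary fix is mostly flight,
    but the bird is already at the spot when that fix is taken — so bout
    duration is measured from first presence at the spot.
    """
    if len(season_fixes) < 2:
        return []
    labels = classify_movement(season_fixes, config.speed_threshold_kmh)
    stationary = labels == "stationary"
    lat = season_fixes["lat"].to_numpy(dtype=float)
    lon = season_fixes["lon"].to_numpy(dtype=float)
    ts = season_fixes["timestamp"].reset_index(drop=True)

    out = []
    j = 0
    n = len(stationary)
    while j < n:
        if not stationary[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and stationary[k + 1]:
            k += 1
        start = max(0, j - 1)  # include the approach fix
        # split the run wherever a fix strays from the running centroid
        seg_start = start
        s_lat, s_lon, m = lat[start], lon[start], 1
        bounds = []
        for q in range(start + 1, k + 1):
            if _hav_scalar(lat[q], lon[q], s_lat / m, s_lon / m) <= config.stopover_spot_radius_km:
                s_lat += lat[q]
                s_lon += lon[q]
                m += 1
            else:
                bounds.append((seg_start, q - 1))
                seg_start, s_lat, s_lon, m = q, lat[q], lon[q], 1
        bounds.append((seg_start, k))
        for a, b in bounds:
            dur_min = (ts.iloc[b] - ts.iloc[a]) / pd.Timedelta(minutes=1)
            if dur_min >= config.stopover_min_duration_min:
                sl = slice(a, b + 1)
                out.append(
                    PhaseInterval(
                        phase="stopover",
                        start=ts.iloc[a],
                        end=ts.iloc[b],
                        centroid=(float(lat[sl].mean()), float(lon[sl].mean())),
                        n_fixes=b - a + 1,
                    )
                )
        j = k + 1
    return out


def _choose_site(fixes: pd.DataFrame, res: _Residency, kind: str, config: PipelineConfig,
                 bird_id: str, cycle_year: int) -> Site:
    members = fixes.iloc[res.start : res.end + 1]
    if kind == "breeding":
        nest = detect_nest_site(members, config.nest_grid_deg, bird_id, cycle_year)
        return Site("breeding", nest.lat, nest.lon, bird_id, cycle_year, nest.provenance)
    return Site(
        "wintering",
        float(members["lat"].mean()),
        float(members["lon"].mean()),
        bird_id,
        cycle_year,
    )


def segment_annual_cycle(trajectory: Trajectory, config: PipelineConfig):
    """Segment one multi-year trajectory.

    Returns ``(phases, season_tracks, sites)``.  Long residencies
    (> ``winter_min_stay_days``) are classified breeding/wintering by
    latitude (breeding lies poleward of the bird's latitudinal midpoint);
    consecutive wintering residencies within one non-breeding period are
    resolved to the southernmost.  Migration legs run from the first fix
    outside the origin-site buffer to the first fix inside the
    destination-site buffer.
    """
    fixes = trajectory.fixes.reset_index(drop=True)
    if len(fixes) < 10:
        raise InsufficientDataError(f"{trajectory.bird_id}: too few fixes to segment")
    residencies = [
        r
        for r in find_residencies(fixes, config.site_radius_km)
        if r.duration_d > config.winter_min_stay_days
    ]
    if len(residencies) < 2:
        raise SegmentationError(
            f"{trajectory.bird_id}: found {len(residencies)} long residencies; "
            "need at least a wintering and a breeding residency"
        )
    lats = [r.lat for r in residencies]
    lat_mid = 0.5 * (min(lats) + max(lats))
    for r in residencies:
        r.kind = "breeding" if r.lat > lat_mid else "wintering"

    # collapse consecutive same-kind residencies: southernmost wintering
    # (>20 d rule), longest breeding
    chosen: list[_Residency] = []
    for r in residencies:
        if chosen and chosen[-1].kind == r.kind:
            if r.kind == "wintering":
                if r.lat < chosen[-1].lat:
                    chosen[-1] = r
            elif r.duration_d > chosen[-1].duration_d:
                chosen[-1] = r
        else:
            chosen.append(r)
    if len(chosen) < 2:
        raise SegmentationError(f"{trajectory.bird_id}: unresolvable cycle structure")

    ts = fixes["timestamp"]
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)

    season_tracks: list[SeasonTrack] = []
    sites: list[Site] = []
    labels = np.empty(len(fixes), dtype=object)
    labels[:] = chosen[0].kind
    site_cache: dict[int, Site] = {}

    def site_for(idx: int, cycle_year: int) -> Site:
        if idx not in site_cache:
            site_cache[idx] = _choose_site(
                fixes, chosen[idx], chosen[idx].kind, config, trajectory.bird_id, cycle_year
            )
        return site_cache[idx]

    for i in range(len(chosen) - 1):
        r0, r1 = chosen[i], chosen[i + 1]
        season = "spring" if r0.kind == "wintering" else "autumn"
        d_orig = geo.haversine_arrays_km(lat, lon, r0.lat, r0.lon)
        d_dest = geo.haversine_arrays_km(lat, lon, r1.lat, r1.lon)
        lo, hi = r0.start, r1.end
        in_dest = np.flatnonzero(d_dest[lo : hi + 1] < config.site_buffer_km)
        if in_dest.size == 0:
            raise SegmentationError(f"{trajectory.bird_id}: no approach to residency {i + 1}")
        first_in_dest = lo + in_dest[0]
        in_orig = np.flatnonzero(d_orig[lo:first_in_dest] < config.site_buffer_km)
        if in_orig.size == 0:
            raise SegmentationError(f"{trajectory.bird_id}: no residency at origin {i}")
        dep_idx = lo + in_orig[-1] + 1
        arr_idx = first_in_dest
        if dep_idx >= arr_idx:
            raise SegmentationError(f"{trajectory.bird_id}: empty migration leg {i}")
        dep_time, arr_time = ts.iloc[dep_idx], ts.iloc[arr_idx]
        cycle_year = int(dep_time.year)

        origin = site_for(i, cycle_year)
        # a wintering residency spanning New Year belongs to the cycle of
        # the spring that follows it
        dest = site_for(i + 1, cycle_year + 1 if season == "autumn" else cycle_year)
        leg_fixes = fixes.iloc[dep_idx : arr_idx + 1].reset_index(drop=True)
        season_tracks.append(
            SeasonTrack(trajectory.bird_id, season, cycle_year, leg_fixes, origin, dest)
        )
        labels[dep_idx:arr_idx] = "migration_flight"
        labels[arr_idx:] = r1.kind
        for so in detect_stopovers(leg_fixes, config):
            m = (ts >= so.start) & (ts <= so.end)
            labels[m.to_numpy()] = "stopover"

    # a wintering residency belongs to the cycle of the spring it precedes
    for idx, site in site_cache.items():
        sites.append(site)
    sites.sort(key=lambda s: (s.cycle_year, s.kind))

    phases = _runs_to_phases(labels, fixes)
    return phases, season_tracks, sites


def _runs_to_phases(labels: np.ndarray, fixes: pd.DataFrame) -> list[PhaseInterval]:
    """Maximal same-label runs as phase intervals; runs of a single fix are
    merged into their predecessor so every interval has start < end."""
    ts = fixes["timestamp"]
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    bounds = [0]
    for j in range(1, len(labels)):
        if labels[j] != labels[j - 1]:
            bounds.append(j)
    bounds.append(len(labels))
    phases = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2 and phases:  # merge degenerate single-fix runs
            prev = phases.pop()
            phases.append(
                PhaseInterval(prev.phase, prev.start, ts.iloc[b - 1], prev.centroid,
                              prev.n_fixes + (b - a))
            )
            continue
        phases.append(
            PhaseInterval(
                phase=str(labels[a]),
                start=ts.iloc[a],
                end=ts.iloc[b - 1],
                centroid=(float(lat[a:b].mean()), float(lon[a:b].mean())),
                n_fixes=b - a,
            )
        )
    return phases
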