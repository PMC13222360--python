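"""Per-bird-season-year migration parameters, spatial clusters and
migration-distance classes.

The master parameter table holds one row per bird x season x cycle-year
with phenology (departure/arrival, duration), distances (linear great-circle
between departure and arrival positions; flown path length), stopover
statistics, site coordinates and the mean fix interval (dt) — the input to
the repeatability and similarity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .config import PipelineConfig
from .exceptions import InsufficientDataError
from .segmentation import SeasonTrack, detect_stopovers
from .track_io import SamplingSummary, sampling_summary


def haversine_km(a, b) -> float:
    """Great-circle distance in km between (lat, lon) points (degrees)."""
    return geo.haversine_km(a, b)


def flown_distance_km(season_track) -> float:
    """Path length: sum of consecutive-fix great-circle distances."""
    fixes = season_track.fixes if isinstance(season_track, SeasonTrack) else season_track
    if len(fixes) < 2:
        raise InsufficientDataError("flown distance needs >= 2 fixes")
    return float(
        np.sum(geo.step_distances_km(fixes["lat"].to_numpy(float), fixes["lon"].to_numpy(float)))
    )


def compute_migration_record(
    track: SeasonTrack,
    config: PipelineConfig,
    sampling: SamplingSummary | None = None,
    sex: str = "unknown",
    capture_country: str = "",
) -> dict:
    """All derived parameters of one migration leg as a plain dict (one row
    of the master table).  ``mean_stopover_h`` is missing (NaN) when the leg
    has no stopovers."""
    fixes = track.fixes
    if sampling is None:
        sampling = sampling_summary(fixes)
    departure = fixes["timestamp"].iloc[0]
    arrival = fixes["timestamp"].iloc[-1]
    stopovers = detect_stopovers(fixes, config)
    stop_h = [(s.end - s.start) / pd.Timedelta(hours=1) for s in stopovers]
    dep_pos = (float(fixes["lat"].iloc[0]), float(fixes["lon"].iloc[0]))
    arr_pos = (float(fixes["lat"].iloc[-1]), float(fixes["lon"].iloc[-1]))
    if track.season == "spring":
        wsite, bsite = track.origin, track.destination
    else:
        bsite, wsite = track.origin, track.destination
    return {
        "bird_id": track.bird_id,
        "season": track.season,
        "cycle_year": track.cycle_year,
        "departure": departure,
        "arrival": arrival,
        "departure_doy": float(departure.dayofyear + departure.hour / 24.0 + departure.minute / 1440.0),
        "arrival_doy": float(arrival.dayofyear + arrival.hour / 24.0 + arrival.minute / 1440.0),
        "duration_d": float((arrival - departure) / pd.Timedelta(days=1)),
        "linear_km": haversine_km(dep_pos, arr_pos),
        "flown_km": flown_distance_km(track),
        "n_stopovers": len(stopovers),
        "total_stopover_h": float(np.sum(stop_h)) if stop_h else 0.0,
        "mean_stopover_h": float(np.mean(stop_h)) if stop_h else np.nan,
        "breeding_lat": bsite.lat,
        "breeding_lon": bsite.lon,
        "wintering_lat": wsite.lat,
        "wintering_lon": wsite.lon,
        "dt_min": sampling.mean_interval_min,
        "sex": sex,
        "capture_country": capture_country,
    }


def build_migration_table(season_tracks, config: PipelineConfig, metadata: dict | None = None) -> pd.DataFrame:
    """Master parameter table from accepted season tracks.

    ``metadata`` maps bird_id -> (sex, capture_country).
    """
    metadata = metadata or {}
    rows = []
    for tr in season_tracks:
        sex, country = metadata.get(tr.bird_id, ("unknown", ""))
        rows.append(compute_migration_record(tr, config, sex=sex, capture_country=country))
    cols = [
        "bird_id", "season", "cycle_year", "departure", "arrival", "departure_doy",
        "arrival_doy", "duration_d", "linear_km", "flown_km", "n_stopovers",
        "total_stopover_h", "mean_stopover_h", "breeding_lat", "breeding_lon",
        "wintering_lat", "wintering_lon", "dt_min", "sex", "capture_country",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ClusterAssignment:
    """Per-bird breeding/wintering cluster labels and the combined
    comparison cluster (birds are comparable iff both match)."""

    table: pd.DataFrame  # bird_id, breeding_cluster, wintering_cluster, cluster_id
    radius_km: float
    seeds: dict  # (kind, label) -> (lat, lon)

    @property
    def n_clusters(self) -> int:
        return int(self.table["cluster_id"].nunique())


def _leader_cluster(df: pd.DataFrame, radius_km: float, kind: str):
    """Greedy leader clustering in deterministic order: descending latitude,
    then longitude, then bird id.  A site joins the first cluster whose seed
    lies within the radius, else founds a new cluster."""
    df = df.sort_values(["lat", "lon", "bird_id"], ascending=[False, False, True])
    seeds: list[tuple] = []
    labels = {}
    for _, row in df.iterrows():
        for ci, (slat, slon) in enumerate(seeds):
            if geo.haversine_km((row["lat"], row["lon"]), (slat, slon)) <= radius_km:
                labels[row["bird_id"]] = ci
                break
        else:
            seeds.append((row["lat"], row["lon"]))
            labels[row["bird_id"]] = len(seeds) - 1
    return labels, {(kind, i): s for i, s in enumerate(seeds)}


def cluster_sites(mean_sites: pd.DataFrame, cluster_radius_km: float = 250.0) -> ClusterAssignment:
    """Cluster per-bird mean breeding and wintering sites.

    ``mean_sites`` columns: bird_id, breeding_lat, breeding_lon,
    wintering_lat, wintering_lon (multi-year means, one row per bird).
    """
    b = mean_sites.rename(columns={"breeding_lat": "lat", "breeding_lon": "lon"})[
        ["bird_id", "lat", "lon"]
    ]
    w = mean_sites.rename(columns={"wintering_lat": "lat", "wintering_lon": "lon"})[
        ["bird_id", "lat", "lon"]
    ]
    bl, bseeds = _leader_cluster(b, cluster_radius_km, "breeding")
    wl, wseeds = _leader_cluster(w, cluster_radius_km, "wintering")
    rows = [
        {
            "bird_id": bid,
            "breeding_cluster": bl[bid],
            "wintering_cluster": wl[bid],
            "cluster_id": f"B{bl[bid]}W{wl[bid]}",
        }
        for bid in mean_sites["bird_id"]
    ]
    return ClusterAssignment(pd.DataFrame(rows), cluster_radius_km, {**bseeds, **wseeds})


def mean_sites_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-bird multi-year mean breeding and wintering coordinates."""
    g = records.groupby("bird_id", as_index=False)[
        ["breeding_lat", "breeding_lon", "wintering_lat", "wintering_lon"]
    ].mean()
    return g


def assign_distance_class(records: pd.DataFrame) -> pd.DataFrame:
    """Add a per-bird ``distance_class`` (short/medium/long) from tertiles
    of the per-bird mean linear migration distance; birds exactly on a
    cut-point fall in the lower class."""
    per_bird = records.groupby("bird_id")["linear_km"].mean()
    if per_bird.size < 3:
        raise InsufficientDataError("distance classes need >= 3 birds")
    c1, c2 = np.quantile(per_bird.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])

    def classify(d: float) -> str:
        if d <= c1:
            return "short"
        if d <= c2:
            return "medium"
        return "long"

    mapping = per_bird.map(classify)
    out = records.copy()
    out["distance_class"] = out["bird_id"].map(mapping)
    return out


def attach_clusters(records: pd.DataFrame, clusters: ClusterAssignment) -> pd.DataFrame:
    """Merge cluster labels into the master table."""
    return records.merge(clusters.table, on="bird_id", how="left")
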