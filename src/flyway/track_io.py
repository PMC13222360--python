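"""Reading and writing GPS-track data and derived results.

The on-disk interchange format is a Movebank-dialect CSV with columns
``timestamp`` (ISO-8601, UTC), ``location-long``, ``location-lat``,
``individual-local-identifier`` and an optional ``ground-speed``.  In memory
a trajectory is a per-bird :class:`pandas.DataFrame` of fixes wrapped in a
small dataclass carrying bird-level metadata.

The module also enforces the pipeline's data-hygiene rules: rows with
unparseable or out-of-bounds coordinates are dropped (with a logged count),
duplicate timestamps are collapsed to their first occurrence, and complete
migration legs are discarded when they contain an inter-fix gap longer than
the configured maximum (24 h by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

MOVEBANK_COLUMNS = {
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "individual-local-identifier": "bird_id",
    "ground-speed": "ground_speed",
}
PLAIN_COLUMNS = {
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "bird_id": "bird_id",
    "ground_speed": "ground_speed",
}
_REQUIRED = ("timestamp", "lon", "lat", "bird_id")


@dataclass
class Trajectory:
    """All fixes of one bird, time-sorted, plus bird-level metadata."""

    bird_id: str
    fixes: pd.DataFrame  # columns: timestamp (UTC), lat, lon [, ground_speed]
    sex: str = "unknown"  # F, M or unknown
    capture_country: str = ""
    tag_type: str = ""

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise FormatError(f"fixes of {self.bird_id} are not time-sorted")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


@dataclass
class SamplingSummary:
    """Per-track sampling metadata; ``mean_interval_min`` is the dt covariate."""

    mean_interval_min: float
    max_gap_h: float
    n_fixes: int


def sampling_summary(fixes: pd.DataFrame) -> SamplingSummary:
    """Mean consecutive-fix interval (min), maximum gap (h) and fix count."""
    if len(fixes) < 2:
        raise InsufficientDataError("sampling summary needs >= 2 fixes")
    dt_s = np.diff(fixes["timestamp"].astype("int64").to_numpy()) / 1e9
    return SamplingSummary(
        mean_interval_min=float(np.mean(dt_s) / 60.0),
        max_gap_h=float(np.max(dt_s) / 3600.0),
        n_fixes=len(fixes),
    )


def read_tracks(path, dialect: str = "movebank_csv") -> list[Trajectory]:
    """Read a GPS-fix CSV and return one time-sorted Trajectory per bird.

    Rows with unparseable timestamps or coordinates outside [-90, 90] x
    [-180, 180] are dropped with a logged count; exact duplicate timestamps
    within a bird are collapsed to the first occurrence.
    """
    if dialect == "movebank_csv":
        colmap = MOVEBANK_COLUMNS
    elif dialect == "plain_csv":
        colmap = PLAIN_COLUMNS
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, dtype={c: str for c in colmap})
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    missing = [c for c, std in colmap.items() if std in _REQUIRED and c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=colmap)
    keep = [std for std in colmap.values() if std in df.columns]
    df = df[keep]

    n0 = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    if "ground_speed" in df.columns:
        df["ground_speed"] = pd.to_numeric(df["ground_speed"], errors="coerce")
    ok = (
        df["timestamp"].notna()
        & df["lat"].between(-90.0, 90.0)
        & df["lon"].between(-180.0, 180.0)
        & df["bird_id"].notna()
    )
    n_dropped = int(n0 - ok.sum())
    if n_dropped:
        logger.warning("read_tracks: dropped %d unparseable/out-of-bounds rows", n_dropped)
    df = df[ok]
    if df.empty:
        raise EmptyInputError(f"no valid rows in {path}")

    trajectories = []
    for bird_id, g in df.groupby("bird_id", sort=True):
        g = g.sort_values("timestamp", kind="mergesort")
        n_dup = int(g["timestamp"].duplicated().sum())
        if n_dup:
            logger.warning("read_tracks: bird %s: collapsed %d duplicate timestamps", bird_id, n_dup)
            g = g[~g["timestamp"].duplicated()]
        trajectories.append(
            Trajectory(bird_id=str(bird_id), fixes=g.drop(columns="bird_id").reset_index(drop=True))
        )
    return trajectories


def write_tracks(trajectories, path) -> None:
    """Write trajectories as a Movebank-dialect CSV (inverse of read_tracks)."""
    frames = []
    for tr in trajectories:
        g = tr.fixes.copy()
        g["individual-local-identifier"] = tr.bird_id
        frames.append(g)
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out = df.rename(
        columns={"lon": "location-long", "lat": "location-lat", "ground_speed": "ground-speed"}
    )
    cols = ["timestamp", "location-long", "location-lat", "individual-local-identifier"]
    if "ground-speed" in out.columns:
        cols.append("ground-speed")
    out[cols].to_csv(path, index=False)


def filter_gap_tracks(fixes: pd.DataFrame, max_gap_h: float = 24.0):
    """Accept or discard one migration leg on the >max_gap_h gap rule.

    Returns ``(status, summary)`` where status is ``"accepted"`` or
    ``"discarded"``.  The rule is a strict inequality: a gap of exactly
    ``max_gap_h`` hours is accepted.  Idempotent; depends only on timestamps.
    """
    summary = sampling_summary(fixes)
    status = "discarded" if summary.max_gap_h > max_gap_h else "accepted"
    return status, summary


def track_to_geojson_feature(fixes: pd.DataFrame, properties: dict) -> dict:
    """One RFC 7946 LineString feature from a fix table ([lon, lat] order)."""
    coords = [[round(float(lo), 6), round(float(la), 6)] for la, lo in zip(fixes["lat"], fixes["lon"])]
    return {"type": "Feature", "geometry": {"type": "LineString", "coordinates": coords}, "properties": properties}


def write_outputs(records: pd.DataFrame, tracks, out_dir, manifest: dict | None = None) -> dict:
    """Write the parameter table (CSV), segmented tracks (GeoJSON) and manifest.

    ``tracks`` is an iterable of ``(properties_dict, fixes_frame)`` pairs.
    Returns a dict of written paths.  An empty record list yields a
    header-only CSV.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    csv_path = out / "migration_records.csv"
    records.to_csv(csv_path, index=False)
    paths["records"] = str(csv_path)

    features = [track_to_geojson_feature(fixes, props) for props, fixes in tracks]
    gj = {"type": "FeatureCollection", "features": features}
    gj_path = out / "season_tracks.geojson"
    gj_path.write_text(json.dumps(gj))
    paths["geojson"] = str(gj_path)

    if manifest is not None:
        man_path = out / "run_manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        paths["manifest"] = str(man_path)
    return paths
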