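"""End-to-end orchestration: simulate/read -> segment -> metrics ->
repeatability -> similarity, with a reproducible run manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config snapshot, seed, stage timings, software versions and
SHA-256 digests of all written files, so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .exceptions import FlywayError
from .metrics import (
    assign_distance_class,
    attach_clusters,
    build_migration_table,
    cluster_sites,
    mean_sites_from_records,
)
from .repeatability import adjusted_repeatability, distance_class_trend, sensitivity_suite
from .segmentation import segment_annual_cycle
from .similarity import build_similarity_table, compare_track_types
from .simulate import SimConfig, simulate_population
from .track_io import filter_gap_tracks, read_tracks, sampling_summary, write_outputs, write_tracks

logger = logging.getLogger(__name__)

GAUSSIAN_TRAITS = (
    "departure_doy",
    "arrival_doy",
    "duration_d",
    "linear_km",
    "flown_km",
    "total_stopover_h",
    "mean_stopover_h",
    "breeding_lat",
    "breeding_lon",
    "wintering_lat",
    "wintering_lon",
)
COUNT_TRAITS = ("n_stopovers",)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_STAGES = ("segment", "metrics", "repeatability", "similarity")


def run_pipeline(cfg: dict, out_dir, until: str = "similarity") -> dict:
    """Run the analysis chain up to (and including) stage ``until``.

    ``cfg`` sections: ``simulate`` (SimConfig fields; optional), ``io``
    (``input_csv`` when not simulating), ``analysis`` (PipelineConfig
    fields), ``statistics`` (``traits``, ``sensitivity: bool``).
    Stage order: segment -> metrics -> repeatability -> similarity.
    """
    if until not in _STAGES:
        raise FlywayError(f"unknown stage {until!r}; choose from {_STAGES}")
    rank = _STAGES.index(until)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = PipelineConfig.from_dict(cfg.get("analysis", {}))
    timings = {}
    counts = {}

    t0 = time.time()
    if "simulate" in cfg:
        sim = SimConfig(**cfg["simulate"])
        trajectories, truth = simulate_population(sim)
        write_tracks(trajectories, out / "simulated_tracks.csv")
        truth.legs.to_csv(out / "ground_truth_legs.csv", index=False)
        truth.sites.to_csv(out / "ground_truth_sites.csv", index=False)
        meta = {t.bird_id: (t.sex, t.capture_country) for t in trajectories}
    elif "io" in cfg and cfg["io"].get("input_csv"):
        trajectories = read_tracks(cfg["io"]["input_csv"], cfg["io"].get("dialect", "movebank_csv"))
        meta = {t.bird_id: (t.sex, t.capture_country) for t in trajectories}
    else:
        raise FlywayError("config needs either a 'simulate' block or io.input_csv")
    timings["input"] = time.time() - t0

    # --- segmentation + gap filter -------------------------------------
    t0 = time.time()
    season_tracks, all_phases, discarded = [], [], 0
    for tr in trajectories:
        phases, legs, sites = segment_annual_cycle(tr, pc)
        all_phases.extend((tr.bird_id, ph) for ph in phases)
        for leg in legs:
            status, _ = filter_gap_tracks(leg.fixes, pc.max_gap_h)
            if status == "accepted":
                season_tracks.append(leg)
            else:
                discarded += 1
                logger.warning("discarded %s %s %d (gap > %.0f h)",
                               leg.bird_id, leg.season, leg.cycle_year, pc.max_gap_h)
    counts["season_tracks_accepted"] = len(season_tracks)
    counts["season_tracks_discarded"] = discarded
    timings["segmentation"] = time.time() - t0

    phases_df = pd.DataFrame(
        [
            {"bird_id": b, "phase": p.phase, "start": p.start, "end": p.end,
             "lat": p.centroid[0], "lon": p.centroid[1], "n_fixes": p.n_fixes}
            for b, p in all_phases
        ]
    )
    phases_df.to_csv(out / "phases.csv", index=False)
    if rank < 1:
        return _finish(cfg, pc, out, timings, counts, pd.DataFrame(), season_tracks)

    # --- metrics ---------------------------------------------------------
    t0 = time.time()
    records = build_migration_table(season_tracks, pc, meta)
    clusters = cluster_sites(mean_sites_from_records(records), pc.cluster_radius_km)
    records = attach_clusters(records, clusters)
    if records["bird_id"].nunique() >= 3:
        records = assign_distance_class(records)
    timings["metrics"] = time.time() - t0
    if rank < 2:
        return _finish(cfg, pc, out, timings, counts, records, season_tracks)

    # --- repeatability ---------------------------------------------------
    t0 = time.time()
    stats_cfg = cfg.get("statistics", {})
    traits = tuple(stats_cfg.get("traits", GAUSSIAN_TRAITS))
    rep_rows = []
    for season in ("spring", "autumn"):
        sub = records[records["season"] == season]
        if sub["bird_id"].nunique() < 2:
            continue
        for trait in traits:
            try:
                res = adjusted_repeatability(sub, trait, "gaussian", pc)
            except FlywayError as exc:
                logger.warning("repeatability %s/%s failed: %s", season, trait, exc)
                continue
            rep_rows.append(_rep_row(res, season))
        for trait in COUNT_TRAITS:
            if trait not in sub.columns:
                continue
            try:
                res = adjusted_repeatability(sub, trait, "count", pc)
            except (FlywayError, TypeError) as exc:
                logger.warning("count repeatability %s/%s failed: %s", season, trait, exc)
                continue
            rep_rows.append(_rep_row(res, season))
    rep_df = pd.DataFrame(rep_rows)
    rep_df.to_csv(out / "repeatability.csv", index=False)
    timings["repeatability"] = time.time() - t0

    # --- sensitivity + distance classes ---------------------------------
    t0 = time.time()
    if stats_cfg.get("sensitivity", False):
        by_radius = {}
        base = records.drop(columns=["breeding_cluster", "wintering_cluster", "cluster_id"])
        for radius in pc.sensitivity_radii_km:
            cl = cluster_sites(mean_sites_from_records(base), radius)
            by_radius[radius] = attach_clusters(base, cl)
        per_trait, pairwise, covariate = sensitivity_suite(by_radius, traits, pc)
        per_trait.to_csv(out / "sensitivity_by_radius.csv", index=False)
        pairwise.to_csv(out / "sensitivity_pairwise.csv", index=False)
        covariate.to_csv(out / "sensitivity_covariates.csv", index=False)

    if "distance_class" in records.columns and stats_cfg.get("distance_class_trend", True):
        fast = PipelineConfig(**{**pc.to_dict(), "n_boot": 0, "n_perm": 0})
        trend_rows = []
        for season in ("spring", "autumn"):
            for klass in ("short", "medium", "long"):
                sub = records[(records["season"] == season) & (records["distance_class"] == klass)]
                if sub["bird_id"].nunique() < 2:
                    continue
                for trait in traits:
                    try:
                        res = adjusted_repeatability(sub, trait, "gaussian", fast)
                        trend_rows.append({"trait": trait, "season": season,
                                           "distance_class": klass, "R": res.R})
                    except FlywayError:
                        continue
        if trend_rows:
            trend_in = pd.DataFrame(trend_rows)
            trend = distance_class_trend(trend_in)
            trend_in.to_csv(out / "repeatability_by_distance_class.csv", index=False)
            trend.to_csv(out / "distance_class_trend.csv", index=False)
    timings["sensitivity"] = time.time() - t0
    if rank < 3:
        return _finish(cfg, pc, out, timings, counts, records, season_tracks)

    # --- similarity ------------------------------------------------------
    t0 = time.time()
    sim_table = build_similarity_table(season_tracks, clusters)
    sim_table.to_csv(out / "similarity_records.csv", index=False)
    contrast_rows = []
    if not sim_table.empty and sim_table["pair_type"].nunique() == 2:
        for response in ("mean", "median"):
            c = compare_track_types(sim_table, response)
            contrast_rows.append(
                {"response": response, "percent_reduction_same": c.percent_reduction_same,
                 "z": c.z_stat, "p": c.p_value, "season_z": c.season_z, "season_p": c.season_p,
                 "n_records": c.n_records}
            )
    pd.DataFrame(contrast_rows).to_csv(out / "similarity_contrast.csv", index=False)
    timings["similarity"] = time.time() - t0

    return _finish(cfg, pc, out, timings, counts, records, season_tracks)


def _finish(cfg, pc, out, timings, counts, records, season_tracks) -> dict:
    """Write the master table, GeoJSON tracks and the run manifest."""
    geo_tracks = [
        (
            {"bird_id": tr.bird_id, "season": tr.season, "cycle_year": tr.cycle_year},
            tr.fixes,
        )
        for tr in season_tracks
    ]
    manifest = {
        "package_version": __version__,
        "config": {**cfg, "analysis": pc.to_dict()},
        "seed": pc.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "counts": counts,
        "versions": _versions(),
    }
    write_outputs(records, geo_tracks, out, manifest=manifest)
    manifest["digests"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.geojson"))
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _rep_row(res, season) -> dict:
    return {
        "trait": res.trait,
        "season": season,
        "family": res.family,
        "R": res.R,
        "ci_lo": res.ci95[0],
        "ci_hi": res.ci95[1],
        "p_perm": res.p_perm,
        "sigma2_id": res.components.sigma2_id,
        "sigma2_res": res.components.sigma2_res,
        "n_obs": res.components.n_obs,
        "n_ids": res.components.n_ids,
        "notes": "; ".join(res.warnings),
    }


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
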