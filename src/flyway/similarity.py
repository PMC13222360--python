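"""Migration-route fidelity from directed nearest-neighbour distances.

For an ordered pair of season tracks, every fix of the focal track is
matched to its nearest neighbour (great-circle distance) on the other
track; the overall mean and median of those distances summarise how close
the two routes run.  Within-individual records pair a bird's consecutive
years; between-individual records pair tracks of distinct birds that share
the same breeding-and-wintering comparison cluster.  A mixed model on the
log distances then contrasts the two pair types: the fitted coefficient for
"same individual" translates into a percent reduction in route separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import BallTree

from . import geo
from .exceptions import ContrastError, InsufficientDataError
from .metrics import ClusterAssignment
from .segmentation import SeasonTrack

_BRUTE_FORCE_MAX = 64  # below this a direct scan beats tree construction


@dataclass
class SimilarityContrast:
    response: str  # mean or median
    percent_reduction_same: float
    z_stat: float
    p_value: float
    season_z: float
    season_p: float
    coefficients: dict  # name -> (estimate, se)
    level_means_km: dict  # pair_type -> (fit, lo, hi), back-transformed
    n_records: int


def directed_nn_distances(focal, other) -> np.ndarray:
    """Distance (km) from each focal fix to its nearest fix on ``other``.

    Directed: the result has one entry per focal fix and is generally
    asymmetric in its arguments.  Uses a haversine ball tree above a small
    size cutoff and an exact O(n*m) scan below it; both give identical
    results.
    """
    f = _latlon(focal)
    o = _latlon(other)
    if f.shape[0] == 0 or o.shape[0] == 0:
        raise InsufficientDataError("both tracks must be non-empty")
    if f.shape[0] * o.shape[0] <= _BRUTE_FORCE_MAX * _BRUTE_FORCE_MAX:
        d = geo.haversine_arrays_km(
            f[:, None, 0], f[:, None, 1], o[None, :, 0], o[None, :, 1]
        )
        return d.min(axis=1)
    tree = BallTree(np.radians(o), metric="haversine")
    dist, _ = tree.query(np.radians(f), k=1)
    return dist[:, 0] * geo.EARTH_RADIUS_KM


def _latlon(track) -> np.ndarray:
    if isinstance(track, SeasonTrack):
        track = track.fixes
    if isinstance(track, pd.DataFrame):
        return track[["lat", "lon"]].to_numpy(dtype=float)
    return np.asarray(track, dtype=float).reshape(-1, 2)


def build_similarity_table(season_tracks, clusters: ClusterAssignment) -> pd.DataFrame:
    """Similarity records for all eligible ordered track pairs.

    Within-individual: consecutive-year pairs (year t -> t+1) per bird and
    season.  Between-individual: all ordered pairs of tracks from distinct
    birds sharing the same comparison cluster and season, any year
    combination.  Each record carries the overall mean and median directed
    nearest-neighbour distance.
    """
    cl = clusters.table.set_index("bird_id")["cluster_id"]
    by_key: dict = {}
    for tr in season_tracks:
        by_key.setdefault((tr.bird_id, tr.season), []).append(tr)
    rows = []
    for (bird, season), tracks in sorted(by_key.items()):
        tracks = sorted(tracks, key=lambda t: t.cycle_year)
        for a, b in zip(tracks[:-1], tracks[1:]):
            if b.cycle_year != a.cycle_year + 1:
                continue
            rows.append(_record(a, b, "same_individual", cl.get(bird, "none")))
    birds = sorted(by_key)
    for bird_a, season_a in birds:
        for bird_b, season_b in birds:
            if bird_a == bird_b or season_a != season_b:
                continue
            ca, cb = cl.get(bird_a, None), cl.get(bird_b, None)
            if ca is None or ca != cb:
                continue
            for ta in by_key[(bird_a, season_a)]:
                for tb in by_key[(bird_b, season_b)]:
                    rows.append(_record(ta, tb, "different_individuals", ca))
    return pd.DataFrame(
        rows,
        columns=[
            "pair_type", "season", "cluster_id", "focal_bird", "other_bird",
            "focal_year", "other_year", "mean_nn_km", "median_nn_km", "n_fixes_focal",
        ],
    )


def _record(a: SeasonTrack, b: SeasonTrack, pair_type: str, cluster_id) -> dict:
    d = directed_nn_distances(a, b)
    return {
        "pair_type": pair_type,
        "season": a.season,
        "cluster_id": cluster_id,
        "focal_bird": a.bird_id,
        "other_bird": b.bird_id,
        "focal_year": a.cycle_year,
        "other_year": b.cycle_year,
        "mean_nn_km": float(np.mean(d)),
        "median_nn_km": float(np.median(d)),
        "n_fixes_focal": int(d.size),
    }


def compare_track_types(table: pd.DataFrame, response: str = "mean") -> SimilarityContrast:
    """Within- vs between-individual route-separation contrast.

    Fits a Gaussian mixed model on log distance with fixed effects season
    and pair type and random intercepts for comparison cluster and focal
    bird (birds nested in clusters); Wald z-tests for the parametric terms.
    The multiplicative effect of "same individual" is reported as a percent
    reduction, (1 - exp(coef)) * 100.
    """
    import statsmodels.formula.api as smf

    col = {"mean": "mean_nn_km", "median": "median_nn_km"}[response]
    if table["pair_type"].nunique() < 2:
        raise ContrastError("both pair types are required for the contrast")
    df = table.copy()
    df["log_d"] = np.log(np.maximum(df[col].to_numpy(dtype=float), 1e-3))
    df["same"] = (df["pair_type"] == "same_individual").astype(float)
    df["spring"] = (df["season"] == "spring").astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if df["cluster_id"].nunique() > 1:
            model = smf.mixedlm(
                "log_d ~ spring + same",
                df,
                groups="cluster_id",
                re_formula="1",
                vc_formula={"bird": "0 + C(focal_bird)"},
            )
        else:
            model = smf.mixedlm("log_d ~ spring + same", df, groups="focal_bird")
        fit = model.fit(reml=True)

    coef = {name: (float(fit.params[name]), float(fit.bse[name]))
            for name in ("Intercept", "spring", "same")}
    z_same = coef["same"][0] / coef["same"][1]
    z_spring = coef["spring"][0] / coef["spring"][1]
    from scipy import stats as sps

    level_means = {}
    # marginal linear predictor per pair type, seasons averaged
    cov = fit.cov_params().loc[["Intercept", "spring", "same"], ["Intercept", "spring", "same"]].to_numpy()
    for level, same_val in (("different_individuals", 0.0), ("same_individual", 1.0)):
        xv = np.array([1.0, 0.5, same_val])
        est = float(xv @ np.array([coef["Intercept"][0], coef["spring"][0], coef["same"][0]]))
        se = float(np.sqrt(max(xv @ cov @ xv, 0.0)))  # guard degenerate fits
        level_means[level] = (np.exp(est), np.exp(est - 1.96 * se), np.exp(est + 1.96 * se))

    return SimilarityContrast(
        response=response,
        percent_reduction_same=float((1.0 - np.exp(coef["same"][0])) * 100.0),
        z_stat=float(z_same),
        p_value=float(2.0 * sps.norm.sf(abs(z_same))),
        season_z=float(z_spring),
        season_p=float(2.0 * sps.norm.sf(abs(z_spring))),
        coefficients=coef,
        level_means_km=level_means,
        n_records=len(df),
    )
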