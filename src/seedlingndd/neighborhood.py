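"""Neighborhood crowding predictors for every focal seedling and interval.

Six metrics per record:

* ``s_con`` — living conspecific seedlings sharing the 2 m x 2 m quadrat,
  focal individual excluded.
* ``a_con`` — distance-weighted conspecific adult basal area,
  sum of BA_i / max(d_i, d_min) over conspecific stems within ``radius_m`` of
  the quadrat centre, BA in m^2 (DBH in cm), d in m.
* ``s_totpd`` / ``s_totfd`` — sum over heterospecific seedling neighbors in
  the quadrat of (phylogenetic | functional) distance x individual count.
* ``a_totpd`` / ``a_totfd`` — the same over adult stems within ``radius_m``.

Distances are measured from the quadrat centre (the unbiased single-point
summary of a 2 m quadrat).  The inverse-distance weight of ``a_con`` is
floored at ``d_min`` (default 0.5 m) so a stem overhanging the quadrat cannot
dominate the sum.  Neighborhoods crossing the plot boundary are flagged
``truncated`` rather than edge-corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import quadrat_centers
from .distances import SpeciesDistances
from .errors import InvalidArgumentError

DEFAULT_RADIUS_M = 20.0
DEFAULT_D_MIN_M = 0.5

METRIC_COLUMNS = ["s_con", "a_con", "s_totpd", "a_totpd", "s_totfd", "a_totfd"]


def basal_area_m2(dbh_cm) -> np.ndarray:
    """Cross-sectional area at breast height, m^2 for DBH in cm."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    return np.pi * (dbh_cm / 200.0) ** 2


def adult_conspecific_density(
    stems: pd.DataFrame,
    quadrat_center: tuple[float, float],
    species: str,
    radius_m: float = DEFAULT_RADIUS_M,
    d_min_m: float = DEFAULT_D_MIN_M,
) -> float:
    """Distance-weighted conspecific adult basal area around one quadrat."""
    if radius_m <= 0:
        raise InvalidArgumentError("radius_m must be > 0")
    sub = stems[stems["species"] == species]
    if sub.empty:
        return 0.0
    d = np.hypot(sub["x"].to_numpy() - quadrat_center[0], sub["y"].to_numpy() - quadrat_center[1])
    keep = d <= radius_m
    if not keep.any():
        return 0.0
    ba = basal_area_m2(sub["dbh_cm"].to_numpy()[keep])
    return float(np.sum(ba / np.maximum(d[keep], d_min_m)))


def conspecific_seedling_density(census_interval: pd.DataFrame, seedling_id: str) -> int:
    """Living same-species, same-quadrat seedlings, focal excluded."""
    row = census_interval[census_interval["seedling_id"] == seedling_id]
    if row.empty:
        raise InvalidArgumentError(f"seedling {seedling_id!r} absent from the interval census")
    sp = row["species"].iloc[0]
    q = row["quadrat_id"].iloc[0]
    mask = (
        (census_interval["quadrat_id"] == q)
        & (census_interval["species"] == sp)
        & (census_interval["seedling_id"] != seedling_id)
    )
    return int(mask.sum())


def heterospecific_crowding(
    neighbor_counts: pd.Series, focal_species: str, distance_matrix: pd.DataFrame
) -> float:
    """Sum of distance(focal, sp) x count over heterospecific neighbor species.

    ``neighbor_counts`` maps species label -> individual count; conspecific
    entries contribute nothing (their distance is zero and they are excluded
    explicitly).
    """
    missing = sorted(set(neighbor_counts.index) - set(distance_matrix.index))
    if missing:
        raise InvalidArgumentError(f"species missing from the distance matrix: {missing}")
    if focal_species not in distance_matrix.index:
        raise InvalidArgumentError(f"species missing from the distance matrix: [{focal_species!r}]")
    total = 0.0
    for sp, n in neighbor_counts.items():
        if sp == focal_species:
            continue
        total += float(distance_matrix.at[focal_species, sp]) * float(n)
    return total


def _adult_summaries(
    stems: pd.DataFrame,
    centers: pd.DataFrame,
    species: list[str],
    distances: SpeciesDistances,
    radius_m: float,
    d_min_m: float,
):
    """Per-quadrat adult crowding building blocks, vectorized over all stems.

    Returns (a_con, a_totpd, a_totfd, n_adults): the first three are
    quadrat x species arrays (a_con indexed by focal = conspecific species;
    the TOT metrics indexed by focal species), n_adults is per quadrat.
    """
    sp_index = {s: k for k, s in enumerate(species)}
    unknown = sorted(set(stems["species"]) - set(sp_index))
    if unknown:
        raise InvalidArgumentError(f"stem species missing from the distance matrices: {unknown}")
    nq = len(centers)
    ns = len(species)
    counts = np.zeros((nq, ns))
    ba_w = np.zeros((nq, ns))
    n_adults = np.zeros(nq, dtype=int)
    sx = stems["x"].to_numpy()
    sy = stems["y"].to_numpy()
    scode = stems["species"].map(sp_index).to_numpy()
    ba = basal_area_m2(stems["dbh_cm"].to_numpy())
    for qi, (cx, cy) in enumerate(zip(centers["cx"], centers["cy"])):
        d = np.hypot(sx - cx, sy - cy)
        keep = d <= radius_m
        n_adults[qi] = int(keep.sum())
        if not n_adults[qi]:
            continue
        code = scode[keep]
        counts[qi] = np.bincount(code, minlength=ns)
        ba_w[qi] = np.bincount(code, weights=ba[keep] / np.maximum(d[keep], d_min_m), minlength=ns)
    dp = distances.phylo.loc[species, species].to_numpy()
    df_ = distances.func.loc[species, species].to_numpy()
    # zero diagonal makes the conspecific term vanish automatically
    a_totpd = counts @ dp
    a_totfd = counts @ df_
    return ba_w, a_totpd, a_totfd, n_adults


def build_neighborhood_table(
    censuses: pd.DataFrame,
    stems: pd.DataFrame,
    distances: SpeciesDistances,
    plot_size_m: tuple[float, float] = (200.0, 200.0),
    subplot_size_m: float = 20.0,
    quadrat_size_m: float = 2.0,
    radius_m: float = DEFAULT_RADIUS_M,
    d_min_m: float = DEFAULT_D_MIN_M,
) -> pd.DataFrame:
    """One crowding record per living focal seedling per census interval.

    Seedling neighbor sets use the cohort present at the start of the
    interval (the interval's own census rows), so every predictor precedes
    the survival outcome it models.
    """
    if radius_m <= 0:
        raise InvalidArgumentError("radius_m must be > 0")
    species = distances.species
    sp_index = {s: k for k, s in enumerate(species)}
    unknown = sorted(set(censuses["species"]) - set(sp_index))
    if unknown:
        raise InvalidArgumentError(f"seedling species missing from the distance matrices: {unknown}")

    centers = quadrat_centers(plot_size_m, subplot_size_m, quadrat_size_m)
    missing_q = sorted(set(censuses["quadrat_id"]) - set(centers.index))
    if missing_q:
        raise InvalidArgumentError(f"census quadrats outside the plot grid: {missing_q}")
    centers = centers.loc[sorted(set(censuses["quadrat_id"]))]
    q_index = {q: k for k, q in enumerate(centers.index)}

    ba_w, a_totpd_q, a_totfd_q, n_adults = _adult_summaries(
        stems, centers, species, distances, radius_m, d_min_m
    )
    lx, ly = plot_size_m
    cx = centers["cx"].to_numpy()
    cy = centers["cy"].to_numpy()
    truncated = np.minimum.reduce([cx, cy, lx - cx, ly - cy]) < radius_m

    dp = distances.phylo.loc[species, species].to_numpy()
    df_ = distances.func.loc[species, species].to_numpy()
    ns = len(species)

    out_frames = []
    for interval_id, rows in censuses.groupby("interval_id", sort=False):
        qcode = rows["quadrat_id"].map(q_index).to_numpy()
        scode = rows["species"].map(sp_index).to_numpy()
        nq = len(centers)
        seed_counts = np.zeros((nq, ns))
        np.add.at(seed_counts, (qcode, scode), 1.0)
        s_con = seed_counts[qcode, scode] - 1.0  # exclude the focal individual
        s_totpd = (seed_counts @ dp)[qcode, scode]
        s_totfd = (seed_counts @ df_)[qcode, scode]
        out_frames.append(
            pd.DataFrame(
                {
                    "seedling_id": rows["seedling_id"].to_numpy(),
                    "interval_id": interval_id,
                    "s_con": s_con,
                    "a_con": ba_w[qcode, scode],
                    "s_totpd": s_totpd,
                    "a_totpd": a_totpd_q[qcode, scode],
                    "s_totfd": s_totfd,
                    "a_totfd": a_totfd_q[qcode, scode],
                    "n_adult_neighbors": n_adults[qcode],
                    "truncated": truncated[qcode],
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)
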